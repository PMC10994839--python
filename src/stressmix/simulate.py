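"""Synthetic plate experiments with known ground truth.

Generates complete mixture experiments with the statistical structure the
analysis assumes: every culture has logistic baseline growth; each chemical
multiplies relative growth by a known factor g; chosen subsets carry planted
interaction coefficients ι, so the true relative growth of mixture A is

    log G_A = Σ_{a∈A} log g_a + Σ_{k⊆A, |k|≥2} log ι_k.

Treatment growth parameters are calibrated numerically so the *AUC ratio* to
control equals the true G — planting effects on rate or capacity alone would
make the truth depend on the integration window. Plate noise is additive
Gaussian on OD, truncated at zero, with per-well substreams spawned from the
master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .panel import ChemicalPanel, MixtureDesign, enumerate_mixtures
from .phylo import TraitOnTree, tree_covariance

DEFAULT_TIMES = np.arange(0.0, 73.0)  # hourly readings over 0–72 h


class SpecError(ValueError):
    """The generator spec asks for something unreachable."""


@dataclass(frozen=True)
class CultureParams:
    """Baseline logistic growth for one culture, with optional per-culture
    overrides of the shared effect maps."""

    capacity: float  # K, OD units
    rate: float  # r, per hour
    inoculum: float  # N0, OD units
    single_effects: Mapping[str, float] | None = None
    interaction_terms: Mapping[tuple[str, ...], float] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.inoculum < self.capacity):
            raise SpecError("need 0 < inoculum < capacity")
        if self.rate <= 0:
            raise SpecError("rate must be positive")


@dataclass(frozen=True)
class GeneratorSpec:
    """Full description of a synthetic plate experiment."""

    panel: ChemicalPanel
    cultures: Mapping[str, CultureParams]
    single_effects: Mapping[str, float]
    interaction_terms: Mapping[tuple[str, ...], float] = field(default_factory=dict)
    n_replicates: int = 4
    n_controls: int = 45
    times: np.ndarray = field(default_factory=lambda: DEFAULT_TIMES.copy())
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.n_controls < 1:
            raise SpecError("replicate and control counts must be positive")
        for name, g in self.single_effects.items():
            if name not in self.panel:
                raise SpecError(f"effect for unknown chemical {name!r}")
            if g <= 0:
                raise SpecError(f"single effect for {name!r} must be positive")
        for combo, iota in self.interaction_terms.items():
            if len(combo) < 2:
                raise SpecError(f"interaction term {combo} needs >= 2 chemicals")
            if iota <= 0:
                raise SpecError(f"interaction term for {combo} must be positive")
            for name in combo:
                if name not in self.panel:
                    raise SpecError(f"interaction names unknown chemical {name!r}")

    def with_seed(self, seed: int) -> "GeneratorSpec":
        return replace(self, seed=seed)

    def effects_for(self, culture_id: str) -> tuple[dict[str, float], dict[int, float]]:
        """(singleton g by name, interaction ι by mask) for one culture."""
        cp = self.cultures[culture_id]
        singles = dict(self.single_effects)
        if cp.single_effects is not None:
            singles.update(cp.single_effects)
        terms = dict(self.interaction_terms)
        if cp.interaction_terms is not None:
            terms.update(cp.interaction_terms)
        masked = {
            MixtureDesign.from_names(combo, self.panel).mask: v for combo, v in terms.items()
        }
        return singles, masked


def true_g(spec: GeneratorSpec, culture_id: str, mixture: MixtureDesign) -> float:
    """Planted relative growth for one culture × mixture (log-linear model)."""
    singles, terms = spec.effects_for(culture_id)
    log_g = sum(np.log(singles.get(spec.panel.names[i], 1.0)) for i in mixture.members)
    for mask, iota in terms.items():
        if mask & ~mixture.mask == 0:  # planted subset contained in mixture
            log_g += np.log(iota)
    return float(np.exp(log_g))


def true_lattice(spec: GeneratorSpec, culture_id: str | None = None) -> dict[int, float]:
    """Planted G over all 2^n − 1 mixtures; keys are panel bitmasks.

    On this noiseless lattice the emergent-interaction recursion recovers
    exactly the planted ι's (and 1 where none was planted).
    """
    if culture_id is None:
        culture_id = next(iter(spec.cultures))
    return {
        m.mask: true_g(spec, culture_id, m) for m in enumerate_mixtures(spec.panel)
    }


# ---------------------------------------------------------------------------
# logistic curves and AUC calibration


def logistic_od(t: np.ndarray, capacity: float, rate: float, inoculum: float) -> np.ndarray:
    q = (capacity - inoculum) / inoculum
    return capacity / (1.0 + q * np.exp(-rate * np.asarray(t, float)))


def logistic_auc(capacity: float, rate: float, inoculum: float, horizon: float) -> float:
    """Closed-form ∫₀ᵀ of the logistic curve."""
    q = (capacity - inoculum) / inoculum
    # log((e^{rT}+q)/(1+q)) written overflow-safe for large rT
    rt = rate * horizon
    return (capacity / rate) * (rt + np.log1p(q * np.exp(-rt)) - np.log1p(q))


def calibrate_scale(
    params: CultureParams, g_target: float, horizon: float, tol: float = 1e-10
) -> float:
    """Scale factor u applied to both capacity and rate so that the treated
    logistic AUC over [0, horizon] equals ``g_target`` times the control AUC.

    Scaling K and r jointly keeps the curve shape plausible while the
    one-dimensional solve pins the AUC ratio; an unreachable target (the AUC
    ratio is bounded below as u → 0 with the inoculum fixed) raises
    :class:`SpecError`.
    """
    base = logistic_auc(params.capacity, params.rate, params.inoculum, horizon)
    target = g_target * base

    def f(log_u: float) -> float:
        u = np.exp(log_u)
        return logistic_auc(params.capacity * u, params.rate * u, params.inoculum, horizon) - target

    lo, hi = -18.0, 12.0
    if f(lo) > 0 or f(hi) < 0:
        raise SpecError(
            f"target G={g_target:g} unreachable for capacity={params.capacity}, "
            f"rate={params.rate}, inoculum={params.inoculum}"
        )
    return float(np.exp(brentq(f, lo, hi, xtol=tol)))


# ---------------------------------------------------------------------------
# plate simulation


def simulate_plate(
    spec: GeneratorSpec,
    cultures: Iterable[str] | None = None,
    mixtures: Sequence[MixtureDesign] | None = None,
) -> pd.DataFrame:
    """Simulate the long-format plate table for a generator spec.

    By default every culture gets all 2^n − 1 mixtures × ``n_replicates``
    treatment wells plus ``n_controls`` control wells (an 8-chemical panel at
    the defaults gives 255 × 4 + 45 = 1,200 wells per culture). ``cultures``
    and ``mixtures`` restrict the layout for focused studies. Two runs with
    the same spec (and seed) produce identical tables.
    """
    culture_ids = list(cultures) if cultures is not None else list(spec.cultures)
    designs = list(mixtures) if mixtures is not None else enumerate_mixtures(spec.panel)
    t = np.asarray(spec.times, float)
    horizon = float(t[-1])
    master = np.random.SeedSequence(spec.seed)

    wells: list[tuple[str, str, MixtureDesign, int]] = []
    for culture_id in culture_ids:
        for design in designs:
            label = design.label(spec.panel)
            for rep in range(1, spec.n_replicates + 1):
                wells.append((culture_id, label, design, rep))
        # controls are conditions like any other: n_controls of them, each
        # replicated n_replicates times (45 x 4 = 180 wells at the defaults,
        # giving (255 + 45) x 4 = 1,200 wells per culture)
        control = MixtureDesign.control(spec.panel)
        for rep in range(1, spec.n_controls * spec.n_replicates + 1):
            wells.append((culture_id, "", control, rep))

    streams = master.spawn(len(wells))
    frames = []
    scale_cache: dict[tuple[str, int], float] = {}
    for (culture_id, label, design, rep), ss in zip(wells, streams):
        params = spec.cultures[culture_id]
        if design.is_control:
            u = 1.0
        else:
            key = (culture_id, design.mask)
            if key not in scale_cache:
                scale_cache[key] = calibrate_scale(
                    params, true_g(spec, culture_id, design), horizon
                )
            u = scale_cache[key]
        od = logistic_od(t, params.capacity * u, params.rate * u, params.inoculum)
        if spec.noise_sd > 0:
            od = od + np.random.default_rng(ss).normal(0.0, spec.noise_sd, size=t.size)
            od = np.clip(od, 0.0, None)
        frames.append(
            pd.DataFrame(
                {
                    "culture": culture_id,
                    "well": f"{culture_id}|{label or 'control'}|r{rep}",
                    "chemicals": label,
                    "replicate": rep,
                    "time_h": t,
                    "od": od,
                    "mixture": [design] * t.size,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def truth_table(spec: GeneratorSpec) -> pd.DataFrame:
    """Planted effects as a tidy frame for test harnesses and CSV export."""
    rows = []
    for culture_id in spec.cultures:
        singles, terms = spec.effects_for(culture_id)
        for name, g in singles.items():
            rows.append({"culture": culture_id, "kind": "single", "chemicals": name, "value": g})
        for mask, iota in terms.items():
            label = MixtureDesign(mask, spec.panel.size).label(spec.panel)
            rows.append({"culture": culture_id, "kind": "interaction", "chemicals": label, "value": iota})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the study-shaped preset


#: Panel of the eight stressors emulated by the preset: two antibiotics, two
#: fungicides, two herbicides, a molluscicide and an insecticide.
PRESET_PANEL = ChemicalPanel(
    (
        "oxytetracycline",
        "amoxicillin",
        "chlorothalonil",
        "tebuconazole",
        "glyphosate",
        "diflufenican",
        "metaldehyde",
        "imidacloprid",
    )
)


def paperlike_preset(seed: int = 0, noise_sd: float = 0.01) -> GeneratorSpec:
    """A study-shaped experiment: 8 chemicals, 12 cultures, 4 replicates,
    45 controls, 72 h of hourly readings.

    One antibiotic (oxytetracycline-like) is strongly harmful (g ≈ 0.3),
    driving the bimodal split between mixtures with and without it; the other
    chemicals have mild effects near 1. A pairwise antagonism (ι = 2 against
    a harmful null) is planted between the antibiotic and the
    tebuconazole-like fungicide. Cultures vary in baseline growth and in
    susceptibility to the antibiotic. The per-culture parameters are fixed
    constants of the preset; ``seed`` only drives plate noise.
    """
    param_rng = np.random.default_rng(20240601)  # preset constants, not noise
    cultures: dict[str, CultureParams] = {}
    for i in range(1, 13):
        capacity = float(param_rng.uniform(0.9, 1.3))
        rate = float(param_rng.uniform(0.25, 0.5))
        oxy = float(np.clip(0.3 * param_rng.lognormal(0.0, 0.25), 0.15, 0.6))
        cultures[f"culture_{i:02d}"] = CultureParams(
            capacity=capacity,
            rate=rate,
            inoculum=0.01,
            single_effects={"oxytetracycline": oxy},
        )
    single_effects = {
        "oxytetracycline": 0.3,
        "amoxicillin": 0.85,
        "chlorothalonil": 0.9,
        "tebuconazole": 0.9,
        "glyphosate": 0.95,
        "diflufenican": 1.0,
        "metaldehyde": 0.95,
        "imidacloprid": 1.05,
    }
    interaction_terms = {("oxytetracycline", "tebuconazole"): 2.0}
    return GeneratorSpec(
        panel=PRESET_PANEL,
        cultures=cultures,
        single_effects=single_effects,
        interaction_terms=interaction_terms,
        noise_sd=noise_sd,
        seed=seed,
    )


def demo_preset(seed: int = 0, noise_sd: float = 0.01) -> GeneratorSpec:
    """A small, fast variant of :func:`paperlike_preset`: 3 chemicals,
    5 cultures, 4 replicates, 8 controls, same planted antagonism motif.
    Intended for demos, CLI walk-throughs and quick end-to-end checks."""
    panel = ChemicalPanel(("oxytetracycline", "tebuconazole", "glyphosate"))
    param_rng = np.random.default_rng(20240602)
    cultures = {
        f"culture_{i:02d}": CultureParams(
            capacity=float(param_rng.uniform(0.9, 1.3)),
            rate=float(param_rng.uniform(0.25, 0.5)),
            inoculum=0.01,
            single_effects={"oxytetracycline": float(np.clip(0.3 * param_rng.lognormal(0.0, 0.25), 0.15, 0.6))},
        )
        for i in range(1, 6)
    }
    return GeneratorSpec(
        panel=panel,
        cultures=cultures,
        single_effects={"oxytetracycline": 0.3, "tebuconazole": 0.9, "glyphosate": 0.95},
        interaction_terms={("oxytetracycline", "tebuconazole"): 2.0},
        n_controls=8,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# trees and Brownian traits


def random_tree(n_tips: int, rng: np.random.Generator | int | None = None,
                labels: Sequence[str] | None = None) -> dendropy.Tree:
    """Random binary rooted tree with exponential branch lengths (mean 1)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_tips)]
    nodes = [f"{l}:{rng.exponential(1.0):.6f}" for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.exponential(1.0):.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    newick = nodes[0].rsplit(":", 1)[0] + ";"
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def simulate_bm_traits(
    tree: dendropy.Tree,
    sigma2: float = 1.0,
    lambda_true: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> TraitOnTree:
    """Draw tip traits from a multivariate normal with the λ-scaled Brownian
    tree covariance (λ = 0: independent tips; λ = 1: pure Brownian motion)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if not 0.0 <= lambda_true <= 1.0:
        raise ValueError("lambda_true must be in [0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    C = tree_covariance(tree)
    V = lambda_true * C
    np.fill_diagonal(V, np.diag(C))
    L = np.linalg.cholesky(sigma2 * V + 1e-12 * np.eye(len(labels)))
    y = L @ rng.standard_normal(len(labels))
    return TraitOnTree(tree, dict(zip(labels, y.tolist())))
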