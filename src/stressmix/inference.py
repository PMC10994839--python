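"""Bootstrap significance machinery for responses and interactions.

The two-stage procedure: first each culture × mixture is gated on its growth
response — treatment and control replicate AUCs are resampled with
replacement, G recomputed, and a percentile CI formed; a CI containing 1
means no response and no interaction test. For gated mixtures, every
replicate AUC list entering the interaction formula is resampled per
bootstrap rep (the shared control pool once per rep, reused across all G
terms of that rep, since every G divides by the same controls), all
lower-order coefficients are recomputed from the resampled data, and the
target coefficient's percentile CI decides the category.

Every interaction coefficient here is a signed linear combination of log G
values over subset terms, so each bootstrap rep reduces to one matrix-vector
product over the resampled log G matrix.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .interactions import (
    CATEGORY_NO_RESPONSE,
    InteractionEstimate,
    IncompleteLatticeError,
    ResponseLattice,
    classify_interaction,
    _popcount_masks,
)
from .panel import ChemicalPanel, MixtureDesign

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapSettings:
    """Replication count, CI level and master seed for all resampling."""

    n_reps: int = 10_000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 100:
            raise ValueError("n_reps must be >= 100 for any CI claim")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Derive a named, non-overlapping random substream from the master seed.

    Hashing the key tuple means adding one (culture, mixture) analysis never
    perturbs another's resamples.
    """
    h = hashlib.blake2s(repr(keys).encode(), digest_size=8).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, int.from_bytes(h, "big")])
    )


@dataclass(frozen=True)
class GateResult:
    """Bootstrap response gate for one culture × mixture."""

    g_point: float
    ci_low: float
    ci_high: float
    significant: bool


def _resampled_means(
    values: np.ndarray, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    idx = rng.integers(0, values.size, size=(n_reps, values.size))
    return values[idx].mean(axis=1)


def bootstrap_g(
    treatment_aucs: np.ndarray,
    control_aucs: np.ndarray,
    settings: BootstrapSettings,
    rng: np.random.Generator | None = None,
) -> GateResult:
    """Percentile-bootstrap CI for relative growth G.

    Each rep resamples both replicate lists with replacement at their own
    sizes and recomputes G; ``significant`` is True when the CI excludes 1.
    Resamples with zero mean control AUC are redrawn (counted; a warning is
    issued past 1% of reps).
    """
    treat = np.asarray(treatment_aucs, float)
    ctrl = np.asarray(control_aucs, float)
    if treat.size < 2 or ctrl.size < 2:
        raise ValueError("need >= 2 replicates in each list to bootstrap")
    if rng is None:
        rng = substream(settings.seed, "gate")
    mt = _resampled_means(treat, settings.n_reps, rng)
    mc = _resampled_means(ctrl, settings.n_reps, rng)
    n_redraw = 0
    while True:
        bad = mc == 0
        if not bad.any():
            break
        n_redraw += int(bad.sum())
        mc[bad] = _resampled_means(ctrl, int(bad.sum()), rng)
    if n_redraw > 0.01 * settings.n_reps:
        warnings.warn(f"{n_redraw} zero-control resamples redrawn", stacklevel=2)
    g = mt / mc
    alpha = 1.0 - settings.ci_level
    lo, hi = np.quantile(g, [alpha / 2.0, 1.0 - alpha / 2.0])
    point = float(treat.mean() / ctrl.mean())
    return GateResult(point, float(lo), float(hi), not (lo <= 1.0 <= hi))


# ---------------------------------------------------------------------------
# log-linear coefficient vectors for the three interaction kinds


def _coefficients(mixture: MixtureDesign, kind: str, max_order: int | None) -> dict[int, float]:
    """Signed integer weights c_S such that log(coefficient) = Σ c_S log G_S."""
    full = mixture.mask
    n = mixture.size
    if kind == "net":
        coeffs = {full: 1.0}
        for i in mixture.members:
            coeffs[1 << i] = -1.0
        return coeffs
    if kind == "emergent":
        return {
            s: (-1.0) ** (n - s.bit_count())
            for s in _popcount_masks(full, 1, n)
        }
    if kind == "partial":
        if max_order is None or not 1 <= max_order < n:
            raise ValueError(f"partial kind needs 1 <= max_order < {n}")
        coeffs: dict[int, float] = {full: 1.0}
        for i in mixture.members:
            coeffs[1 << i] = coeffs.get(1 << i, 0.0) - 1.0
        # subtract log I_k = Σ_{∅≠S⊆k} (−1)^{|k|−|S|} log G_S for 2 <= |k| <= max_order
        for k in _popcount_masks(full, 2, max_order):
            for s in _popcount_masks(k, 1, k.bit_count()):
                coeffs[s] = coeffs.get(s, 0.0) - (-1.0) ** (k.bit_count() - s.bit_count())
        return {s: c for s, c in coeffs.items() if c != 0.0}
    raise ValueError(f"unknown interaction kind {kind!r}")


def bootstrap_interaction(
    lattice: ResponseLattice,
    mixture: MixtureDesign,
    kind: str,
    settings: BootstrapSettings,
    max_order: int | None = None,
    gate: GateResult | None = None,
) -> InteractionEstimate:
    """Bootstrap an interaction coefficient and classify it.

    ``kind`` is ``"net"``, ``"emergent"`` or ``"partial"`` (with
    ``max_order``). The gate is evaluated on an independent substream unless
    supplied; a failed gate yields category ``no_response`` without testing.
    """
    coeffs = _coefficients(mixture, kind, max_order)
    if lattice.control_aucs is None:
        raise IncompleteLatticeError("bootstrap needs replicate AUC data, not point G values")
    missing = [s for s in coeffs if s not in lattice.treatment_aucs]
    if missing:
        raise IncompleteLatticeError(
            f"lattice of {lattice.culture_id!r} is missing replicate data for masks {missing}"
        )
    if gate is None:
        gate = bootstrap_g(
            lattice.treatment_aucs[mixture.mask],
            lattice.control_aucs,
            settings,
            rng=substream(settings.seed, "gate", lattice.culture_id, mixture.mask),
        )

    floor = np.log(lattice.g_floor)
    # point estimate from observed means
    point_logs = {s: max(np.log(lattice.g(s)), floor) if lattice.g(s) > 0 else floor
                  for s in coeffs}
    log_point = sum(c * point_logs[s] for s, c in coeffs.items())
    estimate = float(np.exp(log_point))
    # null prediction = observed G_A divided by the coefficient
    null_prediction = float(np.exp(point_logs[mixture.mask] - log_point))

    rng = substream(settings.seed, "interaction", lattice.culture_id, mixture.mask,
                    kind, max_order)
    n_reps = settings.n_reps
    ctrl = lattice.control_aucs
    mc = _resampled_means(ctrl, n_reps, rng)
    while (mc == 0).any():
        mc[mc == 0] = _resampled_means(ctrl, int((mc == 0).sum()), rng)
    log_mc = np.log(mc)
    log_coef = np.zeros(n_reps)
    for s, c in coeffs.items():
        ms = _resampled_means(lattice.treatment_aucs[s], n_reps, rng)
        with np.errstate(divide="ignore"):
            log_g = np.log(ms) - log_mc
        log_coef += c * np.maximum(log_g, floor)
    alpha = 1.0 - settings.ci_level
    lo, hi = np.exp(np.quantile(log_coef, [alpha / 2.0, 1.0 - alpha / 2.0]))
    # percentile CIs can, rarely, exclude the point estimate at tiny n;
    # widen minimally rather than violate the CI-covers-estimate contract
    lo, hi = min(float(lo), estimate), max(float(hi), estimate)

    category = classify_interaction((lo, hi), null_prediction, gate.significant, estimate)
    kind_label = f"partial({max_order})" if kind == "partial" else kind
    return InteractionEstimate(
        lattice.culture_id, mixture, kind_label, estimate, lo, hi, null_prediction, category
    )


# ---------------------------------------------------------------------------
# table-level drivers


def gate_table(
    lattice: ResponseLattice,
    panel: ChemicalPanel,
    settings: BootstrapSettings,
) -> pd.DataFrame:
    """Response gate for every mixture of a lattice; one row per mixture."""
    rows = []
    for mask in lattice.masks():
        mixture = MixtureDesign(mask, panel.size)
        gate = bootstrap_g(
            lattice.treatment_aucs[mask],
            lattice.control_aucs,
            settings,
            rng=substream(settings.seed, "gate", lattice.culture_id, mask),
        )
        rows.append(
            {
                "culture": lattice.culture_id,
                "chemicals": mixture.label(panel),
                "complexity": mixture.size,
                "g": gate.g_point,
                "ci_low": gate.ci_low,
                "ci_high": gate.ci_high,
                "significant": gate.significant,
            }
        )
    return pd.DataFrame(rows)


def interaction_table(
    lattice: ResponseLattice,
    panel: ChemicalPanel,
    settings: BootstrapSettings,
    kind: str = "net",
    max_order: int | None = None,
    min_size: int = 2,
) -> pd.DataFrame:
    """Gate + bootstrap every mixture of size >= ``min_size`` in a lattice."""
    rows = []
    for mask in lattice.masks():
        mixture = MixtureDesign(mask, panel.size)
        if mixture.size < min_size:
            continue
        if kind == "partial" and max_order is not None and mixture.size <= max_order:
            continue
        est = bootstrap_interaction(lattice, mixture, kind, settings, max_order=max_order)
        rows.append(
            {
                "culture": est.culture_id,
                "chemicals": mixture.label(panel),
                "complexity": mixture.size,
                "kind": est.kind,
                "estimate": est.estimate,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "null_prediction": est.null_prediction,
                "category": est.category,
            }
        )
    return pd.DataFrame(rows)
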