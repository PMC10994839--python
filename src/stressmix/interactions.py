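"""Net and emergent interaction coefficients under the multiplicative null.

The null expectation for growth in a mixture is the product of the relative
growths under each constituent chemical alone (Bliss-type independence on the
relative-growth scale: two chemicals that each cut growth by 70% are expected
to leave 0.3 × 0.3 = 0.09 of control growth, a 91% reduction). The net
interaction N_A divides observed mixture growth by that product; the emergent
interaction I_A additionally divides out every lower-order interaction among
proper subsets of A, isolating the residual attributable to the full set.

All arithmetic is carried in log space — a product of up to 255 ratios
underflows otherwise — and exponentiated at the end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .panel import ChemicalPanel, MixtureDesign

log = logging.getLogger(__name__)

#: Relative-growth floor applied before log transform; zero-growth wells
#: otherwise make every containing interaction undefined.
G_FLOOR = 1e-4

CATEGORY_NO_RESPONSE = "no_response"
CATEGORY_MULTIPLICATIVE = "multiplicative"
CATEGORY_ANTAGONISTIC = "antagonistic"
CATEGORY_SYNERGISTIC = "synergistic"


class IncompleteLatticeError(KeyError):
    """A required sub-mixture is missing from the response lattice."""


class DomainError(ValueError):
    pass


def _popcount_masks(full_mask: int, min_size: int, max_size: int) -> list[int]:
    """Submasks of ``full_mask`` with popcount in [min_size, max_size]."""
    out = []
    sub = full_mask
    while True:
        k = sub.bit_count()
        if min_size <= k <= max_size:
            out.append(sub)
        if sub == 0:
            break
        sub = (sub - 1) & full_mask
    out.reverse()
    return out


class ResponseLattice:
    """Relative growth G over the non-empty subsets of a panel for one culture.

    Holds replicate AUC lists per mixture plus the shared control AUC pool
    (needed for bootstrap resampling), or plain point G values for noiseless
    lattices. Point G values below :data:`G_FLOOR` are floored before the log
    transform and flagged.
    """

    def __init__(
        self,
        culture_id: str,
        panel_size: int,
        g_values: Mapping[int, float] | None = None,
        treatment_aucs: Mapping[int, np.ndarray] | None = None,
        control_aucs: np.ndarray | None = None,
        g_floor: float = G_FLOOR,
    ) -> None:
        self.culture_id = culture_id
        self.panel_size = panel_size
        self.g_floor = float(g_floor)
        self.treatment_aucs = {m: np.asarray(a, float) for m, a in (treatment_aucs or {}).items()}
        self.control_aucs = None if control_aucs is None else np.asarray(control_aucs, float)
        self.floored_mixtures: set[int] = set()
        if g_values is not None:
            self._g = {int(m): float(g) for m, g in g_values.items()}
        else:
            if not self.treatment_aucs or self.control_aucs is None:
                raise ValueError("provide either g_values or treatment_aucs + control_aucs")
            ctrl_mean = float(np.mean(self.control_aucs))
            if ctrl_mean <= 0:
                raise DomainError(f"culture {culture_id!r}: mean control AUC is 0")
            self._g = {m: float(np.mean(a)) / ctrl_mean for m, a in self.treatment_aucs.items()}
        for m, g in self._g.items():
            if g < self.g_floor:
                self.floored_mixtures.add(m)
        if self.floored_mixtures:
            log.warning(
                "culture %s: %d mixtures floored at G=%g before log transform",
                culture_id, len(self.floored_mixtures), self.g_floor,
            )

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_auc_table(
        cls, aucs: pd.DataFrame, panel: ChemicalPanel, culture_id: str, **kw
    ) -> "ResponseLattice":
        """Build a lattice from an :func:`stressmix.growth.auc_table` frame."""
        sub = aucs[aucs["culture"] == culture_id]
        if sub.empty:
            raise KeyError(f"no rows for culture {culture_id!r}")
        treat: dict[int, np.ndarray] = {}
        ctrl = None
        for mixture, grp in sub.groupby("mixture", sort=False):
            vals = grp["auc"].to_numpy(float)
            if mixture.is_control:
                ctrl = vals
            else:
                treat[mixture.mask] = vals
        if ctrl is None:
            raise IncompleteLatticeError(f"culture {culture_id!r} has no control wells")
        return cls(culture_id, panel.size, treatment_aucs=treat, control_aucs=ctrl, **kw)

    @classmethod
    def from_g(cls, culture_id: str, panel_size: int,
               g: Mapping[MixtureDesign | int, float], **kw) -> "ResponseLattice":
        g_values = {(k.mask if isinstance(k, MixtureDesign) else int(k)): v for k, v in g.items()}
        return cls(culture_id, panel_size, g_values=g_values, **kw)

    # -- access -----------------------------------------------------------
    def masks(self) -> list[int]:
        return sorted(self._g, key=lambda m: (m.bit_count(), m))

    def mixtures(self) -> list[MixtureDesign]:
        return [MixtureDesign(m, self.panel_size) for m in self.masks()]

    def has(self, mixture: MixtureDesign | int) -> bool:
        return self._mask(mixture) in self._g

    def _mask(self, mixture: MixtureDesign | int) -> int:
        return mixture.mask if isinstance(mixture, MixtureDesign) else int(mixture)

    def g(self, mixture: MixtureDesign | int) -> float:
        m = self._mask(mixture)
        try:
            return self._g[m]
        except KeyError:
            raise IncompleteLatticeError(
                f"mixture mask {bin(m)} missing from lattice of {self.culture_id!r}"
            ) from None

    def log_g(self, mixture: MixtureDesign | int) -> float:
        return float(np.log(max(self.g(mixture), self.g_floor)))

    def _require(self, masks: Iterable[int]) -> None:
        missing = [m for m in masks if m not in self._g]
        if missing:
            names = [MixtureDesign(m, self.panel_size).members for m in missing]
            raise IncompleteLatticeError(
                f"lattice of {self.culture_id!r} is missing subsets {names}"
            )


# ---------------------------------------------------------------------------
# interaction coefficients


def combine_null(singles: Iterable[float]) -> float:
    """Multiplicative null prediction: the product of singleton G's.

    Two chemicals each leaving 30% of control growth predict 0.09 — a 91%
    reduction — in combination.
    """
    vals = np.asarray(list(singles), dtype=float)
    if vals.size == 0:
        raise DomainError("need at least one singleton G")
    if np.any(vals <= 0):
        raise DomainError(f"non-positive relative growth in {vals.tolist()}")
    return float(np.exp(np.sum(np.log(vals))))


def _check_combination(mixture: MixtureDesign, lattice: ResponseLattice) -> None:
    if mixture.size < 2:
        raise DomainError("interactions are defined for mixtures of >= 2 chemicals")
    if mixture.panel_size != lattice.panel_size:
        raise DomainError("mixture does not belong to the lattice's panel")


def net_interaction(lattice: ResponseLattice, mixture: MixtureDesign) -> float:
    """Net interaction N_A = G_A / Π_{a∈A} G_a."""
    _check_combination(mixture, lattice)
    singles = [1 << i for i in mixture.members]
    lattice._require([mixture.mask, *singles])
    log_n = lattice.log_g(mixture.mask) - sum(lattice.log_g(s) for s in singles)
    return float(np.exp(log_n))


def _emergent_logs(lattice: ResponseLattice, full_mask: int) -> dict[int, float]:
    """log I_k for every submask of ``full_mask`` with |k| >= 2, by the
    iterative construction: pairs first, then triples, each dividing G_k by
    its singleton G's and all previously computed lower-order I's."""
    logs: dict[int, float] = {}
    submasks = _popcount_masks(full_mask, 2, full_mask.bit_count())
    submasks.sort(key=lambda m: m.bit_count())
    for m in submasks:
        singles = [1 << i for i in range(lattice.panel_size) if m >> i & 1]
        val = lattice.log_g(m) - sum(lattice.log_g(s) for s in singles)
        for k in _popcount_masks(m, 2, m.bit_count() - 1):
            val -= logs[k]
        logs[m] = val
    return logs


def emergent_interaction(lattice: ResponseLattice, mixture: MixtureDesign) -> float:
    """Emergent interaction I_A by the iterative power-set construction.

    For |A| = 2 this equals :func:`net_interaction` exactly; for larger sets
    it divides G_A by all singleton G's and all lower-order interaction
    coefficients among proper subsets of A.
    """
    _check_combination(mixture, lattice)
    lattice._require(_popcount_masks(mixture.mask, 1, mixture.size))
    return float(np.exp(_emergent_logs(lattice, mixture.mask)[mixture.mask]))


def mobius_log_interaction(lattice: ResponseLattice, mixture: MixtureDesign) -> float:
    """Independent closed form for log I_A via inclusion–exclusion:
    Σ_{∅≠S⊆A} (−1)^{|A|−|S|} log G_S. Serves as the oracle for the iterative
    construction; exp of it must equal :func:`emergent_interaction`.
    """
    _check_combination(mixture, lattice)
    lattice._require(_popcount_masks(mixture.mask, 1, mixture.size))
    n = mixture.size
    total = 0.0
    for s in _popcount_masks(mixture.mask, 1, n):
        total += (-1.0) ** (n - s.bit_count()) * lattice.log_g(s)
    return float(total)


def partial_null_residual(
    lattice: ResponseLattice, mixture: MixtureDesign, max_order: int
) -> float:
    """Residual interaction after a null including terms up to ``max_order``.

    Divides G_A by the singleton G's and by every emergent I_k with
    2 <= |k| <= max_order, k ⊆ A. ``max_order = 1`` reduces to the net
    interaction; ``max_order = |A| − 1`` recovers the emergent interaction.
    """
    _check_combination(mixture, lattice)
    if not 1 <= max_order < mixture.size:
        raise DomainError(
            f"max_order must be in [1, {mixture.size - 1}] for |A|={mixture.size}"
        )
    if max_order == 1:
        return net_interaction(lattice, mixture)
    lattice._require(_popcount_masks(mixture.mask, 1, max_order) + [mixture.mask])
    logs = _emergent_logs_upto(lattice, mixture.mask, max_order)
    singles = [1 << i for i in mixture.members]
    val = lattice.log_g(mixture.mask) - sum(lattice.log_g(s) for s in singles)
    val -= sum(logs.values())
    return float(np.exp(val))


def _emergent_logs_upto(lattice: ResponseLattice, full_mask: int, max_order: int) -> dict[int, float]:
    logs: dict[int, float] = {}
    submasks = [m for m in _popcount_masks(full_mask, 2, max_order) if m != full_mask]
    submasks.sort(key=lambda m: m.bit_count())
    for m in submasks:
        singles = [1 << i for i in range(lattice.panel_size) if m >> i & 1]
        val = lattice.log_g(m) - sum(lattice.log_g(s) for s in singles)
        for k in _popcount_masks(m, 2, m.bit_count() - 1):
            val -= logs[k]
        logs[m] = val
    return logs


# ---------------------------------------------------------------------------
# classification


def classify_interaction(
    ci: tuple[float, float],
    null_prediction: float,
    gate_significant: bool,
    estimate: float | None = None,
) -> str:
    """Direction-aware antagonism/synergism call for an interaction CI.

    A mixture that failed the response gate is ``no_response`` regardless of
    its interaction CI. Otherwise a CI containing 1 is ``multiplicative``.
    A significant ratio is read against the direction of the null-predicted
    effect: when the null predicts reduced growth, a coefficient > 1 dampens
    the predicted harm (antagonistic) and < 1 deepens it (synergistic); when
    the null predicts increased growth the mapping flips.
    """
    low, high = ci
    if low > high:
        raise ValueError(f"CI bounds out of order: ({low}, {high})")
    if null_prediction <= 0:
        raise DomainError("null prediction must be positive")
    if not gate_significant:
        return CATEGORY_NO_RESPONSE
    if low <= 1.0 <= high:
        return CATEGORY_MULTIPLICATIVE
    if estimate is None:
        estimate = float(np.sqrt(low * high))
    ratio_up = estimate > 1.0
    if null_prediction > 1.0:
        return CATEGORY_SYNERGISTIC if ratio_up else CATEGORY_ANTAGONISTIC
    if null_prediction < 1.0:
        return CATEGORY_SYNERGISTIC if not ratio_up else CATEGORY_ANTAGONISTIC
    # Null of exactly 1 predicts no effect; any significant deviation
    # amplifies |G − 1| relative to that prediction.
    log.info("interaction with null prediction exactly 1 classified as synergistic")
    return CATEGORY_SYNERGISTIC


@dataclass(frozen=True)
class InteractionEstimate:
    """An interaction coefficient with its bootstrap CI and category."""

    culture_id: str
    mixture: MixtureDesign
    kind: str  # "net", "emergent" or "partial(m)"
    estimate: float
    ci_low: float
    ci_high: float
    null_prediction: float
    category: str

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            # percentile CIs can exclude the point estimate only through
            # floating pathologies; treat as a contract violation
            raise ValueError(
                f"estimate {self.estimate} outside CI ({self.ci_low}, {self.ci_high})"
            )
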