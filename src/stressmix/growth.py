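"""Spline fits to growth curves and AUC-based relative growth.

Each well's OD time series is fitted with a cubic smoothing spline (smoothing
chosen by generalized cross-validation) and integrated analytically over a
fixed window — 0–72 h by default — to give the area under the growth curve
(AUC), the fitness endpoint. Relative growth G for a culture × mixture is the
mean treatment AUC divided by the mean control AUC of that culture.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PPoly, make_interp_spline, make_smoothing_spline

from .panel import MixtureDesign

log = logging.getLogger(__name__)

DEFAULT_WINDOW = (0.0, 72.0)


class InsufficientDataError(ValueError):
    """Fewer time points than a spline fit requires."""


class UndefinedRatioError(ZeroDivisionError):
    """Mean control AUC is zero; relative growth is undefined."""


@dataclass(frozen=True)
class GrowthCurve:
    """A fitted piecewise-cubic growth curve, clamped at 0 for integration."""

    _ppoly: PPoly
    support: tuple[float, float]

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        return self._ppoly(t)

    def auc(self, t0: float, t1: float) -> float:
        return integrate_auc(self, t0, t1)


def fit_growth_curve(
    times: np.ndarray,
    od: np.ndarray,
    lam: float | None = None,
    baseline_correct: bool = False,
) -> GrowthCurve:
    """Fit a cubic smoothing spline to one well's OD time series.

    Parameters
    ----------
    times, od
        Strictly increasing hours and the matching non-negative readings;
        at least 4 points (an interpolating cubic is used at exactly 4,
        since GCV smoothing needs 5).
    lam
        Smoothing parameter; ``None`` selects it by generalized
        cross-validation.
    baseline_correct
        Subtract the minimum of the first three readings per well before
        fitting (off by default; raw absorbance is the primary path).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and od must be 1-d arrays of equal length")
    if t.size < 4:
        raise InsufficientDataError(f"need >= 4 time points, got {t.size}")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    if baseline_correct:
        y = y - np.min(y[:3])
    if np.any(y < 0):
        warnings.warn("negative OD readings clamped to 0 before fitting", stacklevel=2)
        y = np.clip(y, 0.0, None)
    if t.size == 4:
        spline = make_interp_spline(t, y, k=3)
    else:
        spline = make_smoothing_spline(t, y, lam=lam)
    return GrowthCurve(PPoly.from_spline(spline), (float(t[0]), float(t[-1])))


def integrate_auc(curve: GrowthCurve, t0: float = 0.0, t1: float = 72.0) -> float:
    """Analytic integral of the positive part of the fitted curve over [t0, t1].

    The piecewise polynomial is integrated exactly, with intervals where the
    fit dips below zero clipped out (the clamping contract), so the result is
    non-negative. The window must lie within the fitted support.
    """
    lo, hi = curve.support
    tol = 1e-9 * max(1.0, abs(hi))
    if t0 < lo - tol or t1 > hi + tol or t1 <= t0:
        raise ValueError(f"window [{t0}, {t1}] outside fitted support [{lo}, {hi}]")
    t0, t1 = max(t0, lo), min(t1, hi)
    p = curve._ppoly
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # PPoly.roots warns on deficient pieces
        roots = p.roots(extrapolate=False)
    roots = np.real(roots[np.isreal(roots)]) if np.iscomplexobj(roots) else roots
    cuts = np.unique(np.concatenate([[t0, t1], roots[(roots > t0) & (roots < t1)]]))
    total = 0.0
    for a, b in zip(cuts[:-1], cuts[1:]):
        if p((a + b) / 2.0) > 0:
            total += p.integrate(a, b)
    return max(float(total), 0.0)


def auc_table(
    plate: pd.DataFrame,
    window: tuple[float, float] = DEFAULT_WINDOW,
    lam: float | None = None,
    baseline_correct: bool = False,
) -> pd.DataFrame:
    """Fit and integrate every well of a validated plate table.

    Returns one row per well: culture, chemicals, mixture, replicate, auc.
    """
    records = []
    for well, grp in plate.groupby("well", sort=False):
        t = grp["time_h"].to_numpy(float)
        y = grp["od"].to_numpy(float)
        curve = fit_growth_curve(t, y, lam=lam, baseline_correct=baseline_correct)
        row = grp.iloc[0]
        records.append(
            {
                "culture": row["culture"],
                "well": well,
                "chemicals": row["chemicals"],
                "mixture": row["mixture"] if "mixture" in grp.columns else None,
                "replicate": int(row["replicate"]),
                "auc": integrate_auc(curve, *window),
            }
        )
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class RelativeGrowth:
    """Relative growth G for one culture × mixture, with the replicate-level
    AUCs needed for bootstrap resampling."""

    culture_id: str
    mixture: MixtureDesign
    g_point: float
    treatment_aucs: np.ndarray = field(repr=False)
    control_aucs: np.ndarray = field(repr=False)


def relative_growth(
    culture_id: str,
    mixture: MixtureDesign,
    treatment_aucs: np.ndarray,
    control_aucs: np.ndarray,
) -> RelativeGrowth:
    """G = mean treatment AUC / mean control AUC.

    Requires >= 1 treatment and >= 2 control replicates; a zero mean control
    AUC raises :class:`UndefinedRatioError` (the culture is flagged and
    excluded downstream rather than silently producing infinities).
    """
    treat = np.asarray(treatment_aucs, dtype=float)
    ctrl = np.asarray(control_aucs, dtype=float)
    if treat.size < 1:
        raise InsufficientDataError("need >= 1 treatment replicate")
    if ctrl.size < 2:
        raise InsufficientDataError("need >= 2 control replicates")
    denom = float(np.mean(ctrl))
    if denom <= 0:
        raise UndefinedRatioError(f"culture {culture_id!r}: mean control AUC is 0")
    return RelativeGrowth(culture_id, mixture, float(np.mean(treat)) / denom, treat, ctrl)


def flag_contamination(
    aucs: pd.DataFrame,
    factor: float = 1.5,
    cv_threshold: float = 0.5,
) -> pd.Series:
    """Heuristic contamination flag, applied only on request.

    Flags non-control wells whose AUC exceeds the culture's control mean by
    ``factor`` in a mixture whose replicates disagree with coefficient of
    variation above ``cv_threshold``. Returns a boolean Series over rows of
    ``aucs``.
    """
    flags = pd.Series(False, index=aucs.index)
    for culture, grp in aucs.groupby("culture"):
        is_ctrl = grp["chemicals"].fillna("").astype(str).str.strip() == ""
        ctrl_mean = grp.loc[is_ctrl, "auc"].mean()
        if not np.isfinite(ctrl_mean) or ctrl_mean <= 0:
            continue
        for chem, sub in grp[~is_ctrl].groupby("chemicals"):
            vals = sub["auc"].to_numpy(float)
            cv = vals.std(ddof=1) / vals.mean() if vals.size > 1 and vals.mean() > 0 else 0.0
            if cv > cv_threshold:
                flags.loc[sub.index[vals > factor * ctrl_mean]] = True
    return flags
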