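"""Result-level aggregations over gated responses and interaction calls.

These reproduce the study-style summaries: response-sign proportions by
mixture complexity with a linear trend, the complexity regression with an
indicator for a focal chemical, interaction-type proportions, the
interaction persistence lattice (edges between significant interactions one
complexity level apart), the interaction-order sufficiency table, and the
cross-strain emergent-interaction consistency proportion.
"""

from __future__ import annotations

from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .inference import BootstrapSettings, bootstrap_interaction, substream, bootstrap_g
from .interactions import (
    CATEGORY_ANTAGONISTIC,
    CATEGORY_SYNERGISTIC,
    ResponseLattice,
)
from .panel import ChemicalPanel, MixtureDesign

SIGNIFICANT_CATEGORIES = (CATEGORY_ANTAGONISTIC, CATEGORY_SYNERGISTIC)


def response_sign_table(gates: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Classify each culture × mixture response and aggregate by complexity.

    ``gates`` needs columns ``complexity, ci_low, ci_high`` (one row per
    culture × mixture). A response is negative when its CI lies entirely
    below 1, positive when entirely above, and none otherwise. Returns the
    per-complexity count/proportion table and an OLS fit of the negative
    proportion on complexity (intercept, slope, r2).
    """
    if gates.empty:
        raise ValueError("empty gate table")
    df = gates.copy()
    df["sign"] = np.where(
        df["ci_high"] < 1.0, "negative", np.where(df["ci_low"] > 1.0, "positive", "none")
    )
    counts = (
        df.groupby(["complexity", "sign"]).size().unstack(fill_value=0)
        .reindex(columns=["negative", "positive", "none"], fill_value=0)
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    table = counts.join(props, lsuffix="_count", rsuffix="_prop").reset_index()

    x = sm.add_constant(table["complexity"].to_numpy(float))
    y = table["negative_prop"].to_numpy(float)
    fit = sm.OLS(y, x).fit()
    trend = {
        "intercept": float(fit.params[0]),
        "slope": float(fit.params[1]) if len(fit.params) > 1 else 0.0,
        "r2": float(fit.rsquared) if np.var(y) > 0 else 0.0,
    }
    return table, trend


def complexity_regression(
    g_table: pd.DataFrame,
    panel: ChemicalPanel,
    focal_chemical: str | int,
) -> dict[str, float]:
    """OLS of per-mixture mean G on complexity and focal-chemical presence.

    ``g_table`` needs columns ``chemicals, complexity, g`` (replicate means,
    pooled across cultures or for one culture). Returns intercept, slope,
    focal_coefficient and r²; a constant response reports zero coefficients
    with ``degenerate=1``.
    """
    focal = panel.names[focal_chemical] if isinstance(focal_chemical, int) else focal_chemical
    if focal not in panel:
        raise ValueError(f"focal chemical {focal!r} not in panel")
    df = g_table.copy()
    present = df["chemicals"].fillna("").map(
        lambda s: float(focal in [t.strip() for t in str(s).split(";")])
    )
    y = df["g"].to_numpy(float)
    X = sm.add_constant(np.column_stack([df["complexity"].to_numpy(float), present]))
    if np.ptp(y) == 0:
        return {"intercept": float(y[0]), "slope": 0.0, "focal_coefficient": 0.0,
                "r2": 0.0, "degenerate": 1.0}
    fit = sm.OLS(y, X).fit()
    return {
        "intercept": float(fit.params[0]),
        "slope": float(fit.params[1]),
        "focal_coefficient": float(fit.params[2]),
        "r2": float(fit.rsquared),
        "degenerate": 0.0,
    }


def interaction_type_proportions(interactions: pd.DataFrame) -> pd.DataFrame:
    """Proportion of each interaction category by mixture complexity."""
    counts = (
        interactions.groupby(["complexity", "category"]).size().unstack(fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0).reset_index()


def build_interaction_lattice(
    interactions: pd.DataFrame, panel: ChemicalPanel
) -> tuple[nx.DiGraph, pd.DataFrame]:
    """Persistence lattice for one culture's interaction calls.

    Nodes are all mixtures with their category; directed edges run from a
    significantly interacting mixture to a significantly interacting superset
    exactly one chemical larger (Hasse-diagram edges restricted to
    antagonistic/synergistic endpoints). Returns the graph and its edge list.
    """
    if interactions["chemicals"].duplicated().any():
        dup = interactions.loc[interactions["chemicals"].duplicated(), "chemicals"].iloc[0]
        raise ValueError(f"duplicate mixture in interaction table: {dup!r}")
    G = nx.DiGraph()
    masks: dict[int, str] = {}
    for _, row in interactions.iterrows():
        design = MixtureDesign.from_names(
            [t for t in str(row["chemicals"]).split(";") if t], panel
        )
        masks[design.mask] = row["category"]
        G.add_node(row["chemicals"], mask=design.mask, complexity=design.size,
                   category=row["category"])
    sig = {m for m, c in masks.items() if c in SIGNIFICANT_CATEGORIES}
    edges = []
    for sub in sig:
        for i in range(panel.size):
            sup = sub | (1 << i)
            if sup != sub and sup in sig:
                sub_l = MixtureDesign(sub, panel.size).label(panel)
                sup_l = MixtureDesign(sup, panel.size).label(panel)
                G.add_edge(sub_l, sup_l)
                edges.append({"sub": sub_l, "super": sup_l,
                              "sub_complexity": MixtureDesign(sub, panel.size).size})
    return G, pd.DataFrame(edges, columns=["sub", "super", "sub_complexity"])


def terms_required_table(
    lattices: Mapping[str, ResponseLattice],
    panel: ChemicalPanel,
    settings: BootstrapSettings,
    max_complexity: int | None = None,
) -> pd.DataFrame:
    """How many interaction orders are needed to explain net interactions.

    For every culture × mixture with a significant net interaction, the
    partial-order null is tested at max_order = 2, 3, …; a mixture still
    significant at order m needs interaction terms beyond m-way. Returns
    counts (and fractions of the net-significant total) by complexity ×
    max_order; counts are non-increasing in max_order for a fixed seed.
    """
    max_complexity = max_complexity or panel.size
    rows = []
    for culture_id, lattice in lattices.items():
        for mask in lattice.masks():
            mixture = MixtureDesign(mask, panel.size)
            if not 3 <= mixture.size <= max_complexity:
                continue
            gate = bootstrap_g(
                lattice.treatment_aucs[mask], lattice.control_aucs, settings,
                rng=substream(settings.seed, "gate", culture_id, mask),
            )
            net = bootstrap_interaction(lattice, mixture, "net", settings, gate=gate)
            if net.category not in SIGNIFICANT_CATEGORIES:
                continue
            entry = {"culture": culture_id, "chemicals": mixture.label(panel),
                     "complexity": mixture.size, "net_significant": True}
            for order in range(2, mixture.size):
                est = bootstrap_interaction(
                    lattice, mixture, "partial", settings, max_order=order, gate=gate
                )
                entry[f"order_{order}"] = est.category in SIGNIFICANT_CATEGORIES
            rows.append(entry)
    detail = pd.DataFrame(rows)
    summary_rows = []
    if not detail.empty:
        for complexity, grp in detail.groupby("complexity"):
            total = len(grp)
            row = {"complexity": int(complexity), "net_interactions": total}
            for order in range(2, int(complexity)):
                col = f"order_{order}"
                remaining = int(grp[col].eq(True).sum()) if col in grp else 0
                row[f"remaining_order_{order}"] = remaining
                row[f"fraction_order_{order}"] = remaining / total
            summary_rows.append(row)
    return pd.DataFrame(summary_rows)


def emergent_consistency(interactions: pd.DataFrame, min_complexity: int = 3) -> float:
    """Cross-culture consistency of emergent interaction types.

    Among mixtures of ``min_complexity``+ chemicals where two or more
    cultures show a significant emergent interaction, the fraction where all
    such cultures agree on the type. NaN when no mixture qualifies.
    """
    sig = interactions[
        (interactions["complexity"] >= min_complexity)
        & interactions["category"].isin(SIGNIFICANT_CATEGORIES)
    ]
    qualifying = 0
    consistent = 0
    for _, grp in sig.groupby("chemicals"):
        if grp["culture"].nunique() < 2:
            continue
        qualifying += 1
        if grp["category"].nunique() == 1:
            consistent += 1
    return consistent / qualifying if qualifying else float("nan")
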