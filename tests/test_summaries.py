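import itertools

import numpy as np
import pandas as pd
import pytest

from stressmix import (
    BootstrapSettings,
    ChemicalPanel,
    build_interaction_lattice,
    complexity_regression,
    emergent_consistency,
    enumerate_mixtures,
    interaction_type_proportions,
    response_sign_table,
    terms_required_table,
)
from tests.test_inference import auc_lattice


def gate_frame(panel, classify, cultures=("c1",)):
    """Build a gate table directly: ``classify(mixture) -> (g, lo, hi)``."""
    rows = []
    for culture in cultures:
        for d in enumerate_mixtures(panel):
            g, lo, hi = classify(d)
            rows.append({"culture": culture, "chemicals": d.label(panel),
                         "complexity": d.size, "g": g, "ci_low": lo, "ci_high": hi,
                         "significant": not (lo <= 1.0 <= hi)})
    return pd.DataFrame(rows)


class TestResponseSignTable:
    def test_all_negative(self, panel3):
        gates = gate_frame(panel3, lambda d: (0.5, 0.4, 0.6))
        table, trend = response_sign_table(gates)
        assert (table["negative_prop"] == 1.0).all()

    def test_no_significant_responses_flat_trend(self, panel3):
        gates = gate_frame(panel3, lambda d: (1.0, 0.9, 1.1))
        table, trend = response_sign_table(gates)
        assert (table["none_prop"] == 1.0).all()
        assert trend["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_single_harmful_chemical_closed_form(self, panel8):
        """With only chemical A harmful, the negative proportion at
        complexity k equals the fraction of size-k subsets containing A,
        which is k/8."""
        harmful = panel8.names[0]

        def classify(d):
            if harmful in d.names(panel8):
                return (0.5, 0.4, 0.6)
            return (1.0, 0.95, 1.05)

        table, trend = response_sign_table(gate_frame(panel8, classify))
        for _, row in table.iterrows():
            assert row["negative_prop"] == pytest.approx(row["complexity"] / 8.0)
        assert trend["slope"] == pytest.approx(1.0 / 8.0, abs=1e-10)

    def test_proportions_sum_to_one(self, panel3):
        gates = gate_frame(panel3, lambda d: (0.5, 0.4, 0.6) if d.size > 1 else (1.0, 0.9, 1.1))
        table, _ = response_sign_table(gates)
        sums = table[["negative_prop", "positive_prop", "none_prop"]].sum(axis=1)
        assert np.allclose(sums, 1.0)


class TestComplexityRegression:
    def test_exact_recovery_on_noiseless_linear_data(self, panel8):
        focal = panel8.names[0]

        def classify(d):
            g = 1.0 - 0.03 * d.size - 0.42 * (focal in d.names(panel8))
            return (g, g - 0.01, g + 0.01)

        gates = gate_frame(panel8, classify)
        fit = complexity_regression(gates, panel8, focal)
        assert fit["intercept"] == pytest.approx(1.0, abs=1e-10)
        assert fit["slope"] == pytest.approx(-0.03, abs=1e-10)
        assert fit["focal_coefficient"] == pytest.approx(-0.42, abs=1e-10)

    def test_constant_g_reported_degenerate(self, panel3):
        gates = gate_frame(panel3, lambda d: (1.0, 0.9, 1.1))
        fit = complexity_regression(gates, panel3, "A")
        assert fit == {"intercept": 1.0, "slope": 0.0, "focal_coefficient": 0.0,
                       "r2": 0.0, "degenerate": 1.0}

    def test_unknown_focal_rejected(self, panel3):
        with pytest.raises(ValueError, match="focal"):
            complexity_regression(gate_frame(panel3, lambda d: (1.0, 0.9, 1.1)), panel3, "Z")


def interaction_frame(panel, category_of, culture="c1"):
    rows = []
    for d in enumerate_mixtures(panel):
        if d.size < 2:
            continue
        rows.append({"culture": culture, "chemicals": d.label(panel),
                     "complexity": d.size, "kind": "net", "estimate": 1.0,
                     "ci_low": 0.9, "ci_high": 1.1, "null_prediction": 0.5,
                     "category": category_of(d)})
    return pd.DataFrame(rows)


class TestInteractionLattice:
    def test_no_significant_interactions_no_edges(self, panel3):
        inter = interaction_frame(panel3, lambda d: "multiplicative")
        G, edges = build_interaction_lattice(inter, panel3)
        assert len(edges) == 0

    def test_persistent_antagonism_chain_edges_match_brute_force(self, panel8):
        """A pairwise antagonism propagating to every superset produces one
        edge per Hasse link between supersets of the pair."""
        pair = {0, 1}

        def cat(d):
            return "antagonistic" if pair <= set(d.members) else "multiplicative"

        inter = interaction_frame(panel8, cat)
        _, edges = build_interaction_lattice(inter, panel8)
        # brute force: count (sub, super) pairs one apart, both containing the pair
        sig = [d for d in enumerate_mixtures(panel8) if pair <= set(d.members)]
        expected = sum(
            1 for a, b in itertools.permutations(sig, 2)
            if b.size == a.size + 1 and a.issubset(b)
        )
        assert len(edges) == expected

    def test_no_edge_across_two_levels(self, panel3):
        def cat(d):
            return "antagonistic" if d.size in (1, 3) or d.members == (0, 1) else "multiplicative"

        # interactions only defined for size >= 2: {A,B} and {A,B,C} are one
        # apart -> edge; but a size-2/size-... gap case:
        def cat2(d):
            return "antagonistic" if d.size != 2 else "multiplicative"

        inter = interaction_frame(panel3, cat2)  # only the triple is significant (size>=2)
        _, edges = build_interaction_lattice(inter, panel3)
        assert len(edges) == 0

    def test_duplicate_mixture_rejected(self, panel3):
        inter = interaction_frame(panel3, lambda d: "multiplicative")
        dup = pd.concat([inter, inter.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            build_interaction_lattice(dup, panel3)

    def test_edges_subset_of_hasse_diagram(self, panel3, rng):
        cats = ["antagonistic", "synergistic", "multiplicative"]
        inter = interaction_frame(panel3, lambda d: cats[rng.integers(3)])
        _, edges = build_interaction_lattice(inter, panel3)
        from stressmix.io import parse_chemicals
        for _, e in edges.iterrows():
            sub = parse_chemicals(e["sub"], panel3)
            sup = parse_chemicals(e["super"], panel3)
            assert sub.issubset(sup) and sup.size == sub.size + 1


class TestInteractionTypeProportions:
    def test_rows_sum_to_one(self, panel3, rng):
        cats = ["antagonistic", "synergistic", "multiplicative", "no_response"]
        inter = interaction_frame(panel3, lambda d: cats[rng.integers(4)])
        props = interaction_type_proportions(inter)
        assert np.allclose(props.drop(columns="complexity").sum(axis=1), 1.0)


class TestTermsRequired:
    def test_pairwise_only_lattice_explained_at_order_two(self):
        """Planted two-way terms only: every net-significant triple+ mixture
        stops being significant once two-way terms enter the null."""
        rng = np.random.default_rng(31)
        lat = auc_lattice(rng, [0.5, 0.6, 0.7, 0.8], terms={0b0011: 2.0, 0b1100: 0.6},
                          rel_sd=0.005)
        panel = ChemicalPanel(tuple("WXYZ"))
        table = terms_required_table({"sim": lat}, panel, BootstrapSettings(n_reps=500, seed=4))
        assert (table["net_interactions"] > 0).any()
        remaining = [c for c in table.columns if c.startswith("remaining_")]
        assert table[remaining].fillna(0).to_numpy().sum() == 0

    def test_counts_non_increasing_in_order(self):
        rng = np.random.default_rng(32)
        lat = auc_lattice(rng, [0.5, 0.6, 0.7, 0.8],
                          terms={0b0011: 2.0, 0b0111: 1.5}, rel_sd=0.01)
        panel = ChemicalPanel(tuple("WXYZ"))
        table = terms_required_table({"sim": lat}, panel, BootstrapSettings(n_reps=500, seed=5))
        for _, row in table.iterrows():
            cols = [f"remaining_order_{k}" for k in range(2, int(row["complexity"]))]
            vals = [row["net_interactions"]] + [row[c] for c in cols if c in row and pd.notna(row[c])]
            assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestEmergentConsistency:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["culture", "chemicals", "complexity", "category"])

    def test_all_cultures_identical(self):
        rows = [(c, "A;B;C", 3, "antagonistic") for c in ("c1", "c2", "c3")]
        assert emergent_consistency(self.frame(rows)) == 1.0

    def test_half_mixed(self):
        rows = (
            [(c, "A;B;C", 3, "antagonistic") for c in ("c1", "c2")]
            + [("c1", "A;B;D", 3, "antagonistic"), ("c2", "A;B;D", 3, "synergistic")]
        )
        assert emergent_consistency(self.frame(rows)) == 0.5

    def test_single_culture_mixtures_do_not_qualify(self):
        rows = [("c1", "A;B;C", 3, "antagonistic")]
        assert np.isnan(emergent_consistency(self.frame(rows)))

    def test_pairs_excluded_by_complexity_floor(self):
        rows = [(c, "A;B", 2, "antagonistic") for c in ("c1", "c2")]
        assert np.isnan(emergent_consistency(self.frame(rows)))
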