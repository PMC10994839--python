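import dendropy
import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster
from scipy.stats import skew

from stressmix import (
    ResponseFingerprint,
    TraitOnTree,
    blombergs_K,
    hierarchical_cluster,
    mantel_kendall,
    normalize_trait,
    pagels_lambda,
    response_distance_matrix,
    simulate_bm_traits,
    tree_covariance,
)
from stressmix.phylo import _bm_profile_loglik, _lambda_cov
from stressmix.simulate import random_tree


def tree_from(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


# fixtures with expected statistics frozen from phytools::phylosig (R),
# run on the same newick strings and trait values
FIX1_NEWICK = "((A:1.2,B:0.8):0.5,((C:0.6,D:1.1):0.4,(E:0.9,F:0.7):0.3):0.6);"
FIX1_TRAITS = {"A": 1.3, "B": 0.9, "C": -0.2, "D": 0.4, "E": 2.1, "F": 1.7}
FIX1_K_PHYTOOLS = 0.9150271898
FIX1_LOGLIK_PHYTOOLS = -6.9056378425  # at phytools' lambda-hat = 7.33e-5

FIX2_NEWICK = "(((A:0.3,B:0.3):0.7,(C:0.5,D:0.5):0.5):0.4,((E:0.4,F:0.4):0.6,(G:0.2,H:0.2):0.8):0.4);"
FIX2_TRAITS = {"A": 0.12, "B": 0.25, "C": -0.91, "D": -0.70,
               "E": 1.43, "F": 1.20, "G": 0.66, "H": 0.79}
FIX2_K_PHYTOOLS = 2.0009864792
FIX2_LAMBDA_PHYTOOLS = 1.14812028  # unconstrained optimum above 1
FIX2_LOGLIK_PHYTOOLS = -4.38715032


class TestTreeCovariance:
    def test_shared_path_lengths(self):
        C = tree_covariance(tree_from("((A:1,B:1):1,C:2);"), labels=["A", "B", "C"])
        assert C[0, 0] == pytest.approx(2.0)
        assert C[0, 1] == pytest.approx(1.0)
        assert C[0, 2] == pytest.approx(0.0)


class TestResponseDistances:
    def test_identical_profiles_distance_zero(self):
        fps = [ResponseFingerprint(c, [1.0, 2.0, 3.0]) for c in "ab"]
        assert response_distance_matrix(fps)[0, 1] == 0.0

    def test_unit_difference(self):
        fps = [ResponseFingerprint("a", [1, 1, 1]), ResponseFingerprint("b", [1, 1, 2])]
        assert response_distance_matrix(fps)[0, 1] == pytest.approx(1.0)

    def test_triangle_inequality_on_random_profiles(self, rng):
        fps = [ResponseFingerprint(str(i), rng.standard_normal(10)) for i in range(12)]
        D = response_distance_matrix(fps)
        for _ in range(100):
            i, j, k = rng.choice(12, 3, replace=False)
            assert D[i, k] <= D[i, j] + D[j, k] + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            response_distance_matrix(
                [ResponseFingerprint("a", [1, 2]), ResponseFingerprint("b", [1, 2, 3])]
            )


class TestHierarchicalCluster:
    def test_recovers_planted_partition(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (5, 4)), rng.normal(10, 0.1, (5, 4))])
        fps = [ResponseFingerprint(str(i), x) for i, x in enumerate(X)]
        Z = hierarchical_cluster(response_distance_matrix(fps))
        labels = fcluster(Z, t=2, criterion="maxclust")
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_two_items_merge_at_their_distance(self):
        D = np.array([[0.0, 3.5], [3.5, 0.0]])
        Z = hierarchical_cluster(D)
        assert Z[0, 2] == pytest.approx(3.5)

    def test_identical_items_merge_at_zero(self):
        D = np.zeros((4, 4))
        Z = hierarchical_cluster(D)
        assert np.allclose(Z[:, 2], 0.0)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            hierarchical_cluster(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestMantelKendall:
    def symmetric(self, rng, n=8):
        D = np.abs(rng.standard_normal((n, n)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        return D

    def test_self_concordance(self, rng):
        D = self.symmetric(rng)
        tau, p = mantel_kendall(D, D, n_perm=199, rng=0)
        assert tau == pytest.approx(1.0)
        assert p == pytest.approx(1.0 / 200.0)

    def test_rank_invariance_under_monotone_transform(self, rng):
        D = self.symmetric(rng)
        tau, _ = mantel_kendall(D, np.exp(D) - 1, n_perm=99, rng=0)
        assert tau == pytest.approx(1.0)

    def test_constant_matrix_rejected(self, rng):
        D = self.symmetric(rng)
        with pytest.raises(ValueError, match="constant"):
            mantel_kendall(D, np.ones_like(D) - np.eye(len(D)), n_perm=99)


class TestPagelsLambda:
    def test_loglik_machinery_matches_phytools(self):
        """Profile log-likelihood evaluated at phytools' λ̂ reproduces its
        reported maximum to 1e-6."""
        trait = TraitOnTree(tree_from(FIX2_NEWICK), FIX2_TRAITS)
        ll = _bm_profile_loglik(trait.ordered_values(),
                                _lambda_cov(trait.covariance(), FIX2_LAMBDA_PHYTOOLS))
        assert ll == pytest.approx(FIX2_LOGLIK_PHYTOOLS, abs=1e-6)

    def test_boundary_estimates(self):
        # fixture 1: no signal, λ̂ at the 0 boundary (at least as good as
        # phytools' near-zero interior value); fixture 2: optimum above 1,
        # clipped to the [0, 1] bound the statistic is defined on
        lam1, ll1, _ = pagels_lambda(TraitOnTree(tree_from(FIX1_NEWICK), FIX1_TRAITS))
        assert lam1 == pytest.approx(0.0, abs=1e-6)
        assert ll1 >= FIX1_LOGLIK_PHYTOOLS - 1e-6
        lam2, _, p2 = pagels_lambda(TraitOnTree(tree_from(FIX2_NEWICK), FIX2_TRAITS))
        assert lam2 == pytest.approx(1.0, abs=1e-6)
        assert p2 < 0.05

    def test_lambda_zero_is_iid_normal_likelihood(self):
        """At λ = 0 the model collapses to independent tips with variances
        given by the tip depths; compare against a direct normal likelihood."""
        trait = TraitOnTree(tree_from(FIX1_NEWICK), FIX1_TRAITS)
        y = trait.ordered_values()
        d = np.diag(trait.covariance())
        ll0 = _bm_profile_loglik(y, np.diag(d))
        # profile out mean and rate by direct optimization
        from scipy.optimize import minimize

        def nll(params):
            mu, log_s2 = params
            s2 = np.exp(log_s2)
            return 0.5 * np.sum(np.log(2 * np.pi * s2 * d) + (y - mu) ** 2 / (s2 * d))

        res = minimize(nll, x0=[y.mean(), 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        assert ll0 == pytest.approx(-res.fun, abs=1e-6)

    def test_optimizer_sanity(self, rng):
        tree = random_tree(16, rng)
        trait = simulate_bm_traits(tree, 1.0, 0.6, rng)
        lam, ll, _ = pagels_lambda(trait)
        y, C = trait.ordered_values(), trait.covariance()
        assert ll >= _bm_profile_loglik(y, _lambda_cov(C, 0.0)) - 1e-9
        assert ll >= _bm_profile_loglik(y, _lambda_cov(C, 1.0)) - 1e-9

    def test_recovery_and_null(self, rng):
        tree = random_tree(32, rng)
        lam_bm = [pagels_lambda(simulate_bm_traits(tree, 1.0, 1.0, rng))[0] for _ in range(25)]
        lam_null = [pagels_lambda(simulate_bm_traits(tree, 1.0, 0.0, rng))[0] for _ in range(25)]
        assert np.median(lam_bm) >= 0.8
        assert np.median(lam_null) <= 0.2

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pagels_lambda(TraitOnTree(tree_from(FIX1_NEWICK), {k: 1.0 for k in FIX1_TRAITS}))


class TestBlombergsK:
    @pytest.mark.parametrize(
        "newick,traits,expected",
        [(FIX1_NEWICK, FIX1_TRAITS, FIX1_K_PHYTOOLS),
         (FIX2_NEWICK, FIX2_TRAITS, FIX2_K_PHYTOOLS)],
    )
    def test_matches_phytools(self, newick, traits, expected):
        k, _ = blombergs_K(TraitOnTree(tree_from(newick), traits), n_rand=10, rng=0)
        assert k == pytest.approx(expected, abs=1e-9)

    def test_star_tree_gives_unit_k_for_any_trait(self, rng):
        star = tree_from("(A:1,B:1,C:1,D:1,E:1);")
        for _ in range(5):
            vals = dict(zip("ABCDE", rng.standard_normal(5)))
            k, _ = blombergs_K(TraitOnTree(star, vals), n_rand=10, rng=0)
            assert k == pytest.approx(1.0, abs=1e-10)

    def test_affine_invariance(self, rng):
        trait = TraitOnTree(tree_from(FIX2_NEWICK), FIX2_TRAITS)
        shifted = TraitOnTree(tree_from(FIX2_NEWICK),
                              {k: 3.0 * v - 7.0 for k, v in FIX2_TRAITS.items()})
        k1, _ = blombergs_K(trait, n_rand=10, rng=0)
        k2, _ = blombergs_K(shifted, n_rand=10, rng=0)
        assert k1 == pytest.approx(k2, rel=1e-10)

    def test_brownian_calibration(self, rng):
        tree = random_tree(24, rng)
        ks = [blombergs_K(simulate_bm_traits(tree, 1.0, 1.0, rng), n_rand=10, rng=rng)[0]
              for _ in range(40)]
        assert 0.8 <= np.mean(ks) <= 1.2


class TestNormalizeTrait:
    def test_monotone(self, rng):
        y = rng.standard_normal(20)
        z = normalize_trait(y)
        assert np.all(np.argsort(y) == np.argsort(z))

    def test_symmetric_input_symmetric_output(self):
        z = normalize_trait([1.0, 2.0, 3.0, 4.0, 5.0])
        assert np.allclose(z + z[::-1], 0.0, atol=1e-12)

    def test_reduces_skew(self, rng):
        y = -np.exp(rng.standard_normal(200))  # strongly left-skewed
        assert abs(skew(normalize_trait(y))) < abs(skew(y))

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            normalize_trait([2.0, 2.0, 2.0, 2.0])
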