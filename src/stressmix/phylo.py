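"""Phylogenetic signal in stressor-response phenotypes.

Strain response fingerprints (the vector of relative growths over all
mixtures) are compared by Euclidean distance and hierarchical clustering;
association with the phylogeny is tested with a Mantel test using Kendall's
rank correlation τ. Per-chemical scalar responses are tested for signal with
Pagel's λ (maximum likelihood under a Brownian-motion model whose shared
covariances are scaled by λ, likelihood-ratio test against λ = 0) and
Blomberg's K (observed vs Brownian-expected variance partitioning, p-value by
tip-label randomization).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2, kendalltau, norm, rankdata


@dataclass(frozen=True)
class ResponseFingerprint:
    """A strain's ordered vector of G values over the mixture enumeration."""

    culture_id: str
    profile: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "profile", np.asarray(self.profile, float))


@dataclass(frozen=True)
class TraitOnTree:
    """A scalar trait at every tip of a phylogeny."""

    tree: dendropy.Tree
    values: Mapping[str, float]

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def ordered_values(self) -> np.ndarray:
        labels = self.tip_labels()
        missing = [l for l in labels if l not in self.values]
        extra = sorted(set(self.values) - set(labels))
        if missing or extra:
            raise ValueError(f"trait/tip mismatch: missing {missing}, extra {extra}")
        return np.array([self.values[l] for l in labels], float)

    def covariance(self) -> np.ndarray:
        return tree_covariance(self.tree)


def tree_covariance(tree: dendropy.Tree, labels: Sequence[str] | None = None) -> np.ndarray:
    """Brownian-motion covariance: C[i, j] = shared root-to-MRCA path length.

    Rows/columns follow ``labels`` if given, else the tree's leaf iteration
    order.
    """
    leaves = list(tree.leaf_node_iter())
    order = {leaf.taxon.label: i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    C = np.zeros((n, n))
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    # postorder: tips below each internal node; pairs split across children
    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = order[node.taxon.label]
            below[id(node)] = [i]
            C[i, i] = depth[id(node)]
        else:
            groups = [below[id(ch)] for ch in node.child_nodes()]
            d = depth[id(node)]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for i in groups[gi]:
                        for j in groups[gj]:
                            C[i, j] = C[j, i] = d
            below[id(node)] = [i for g in groups for i in g]
    if labels is not None:
        idx = [order[l] for l in labels]
        C = C[np.ix_(idx, idx)]
    return C


def patristic_distance_matrix(tree: dendropy.Tree, labels: Sequence[str] | None = None) -> np.ndarray:
    """Pairwise tip-to-tip path lengths, ordered like ``labels``."""
    pdm = tree.phylogenetic_distance_matrix()
    leaves = list(tree.leaf_node_iter())
    if labels is None:
        labels = [l.taxon.label for l in leaves]
    taxa = {l.taxon.label: l.taxon for l in leaves}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return D


# ---------------------------------------------------------------------------
# fingerprints, distances, clustering


def response_distance_matrix(fingerprints: Sequence[ResponseFingerprint]) -> np.ndarray:
    """Pairwise Euclidean distances between response profiles."""
    if len(fingerprints) < 2:
        raise ValueError("need >= 2 fingerprints")
    lengths = {f.profile.size for f in fingerprints}
    if len(lengths) != 1:
        raise ValueError(f"profile length mismatch: {sorted(lengths)}")
    X = np.vstack([f.profile for f in fingerprints])
    return squareform(pdist(X, metric="euclidean"))


def hierarchical_cluster(distances: np.ndarray, method: str = "average") -> np.ndarray:
    """SciPy linkage matrix over a symmetric distance matrix."""
    D = np.asarray(distances, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("input must be a symmetric square distance matrix")
    return linkage(squareform(D, checks=False), method=method)


# ---------------------------------------------------------------------------
# Mantel test with Kendall's tau


def mantel_kendall(
    d1: np.ndarray,
    d2: np.ndarray,
    n_perm: int = 9_999,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """One-sided Mantel test of two distance matrices using Kendall's τ.

    τ is computed on the vectorized upper triangles; the null distribution
    permutes rows and columns of ``d2`` jointly. Returns (τ, p) with
    p = (1 + #{permuted τ >= observed}) / (n_perm + 1).
    """
    D1, D2 = np.asarray(d1, float), np.asarray(d2, float)
    if D1.shape != D2.shape or D1.ndim != 2 or D1.shape[0] != D1.shape[1]:
        raise ValueError("distance matrices must be square with equal dimensions")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n = D1.shape[0]
    iu = np.triu_indices(n, k=1)
    v1, v2 = D1[iu], D2[iu]
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("constant distance vector: tau undefined")
    tau = kendalltau(v1, v2).statistic
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        tau_p = kendalltau(v1, D2[np.ix_(perm, perm)][iu]).statistic
        if tau_p >= tau:
            count += 1
    return float(tau), (1.0 + count) / (n_perm + 1.0)


# ---------------------------------------------------------------------------
# Pagel's lambda


def _bm_profile_loglik(y: np.ndarray, V: np.ndarray) -> float:
    """BM log-likelihood profiled over the root state and rate."""
    n = y.size
    L = np.linalg.cholesky(V)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    z = np.linalg.solve(L, y)
    one = np.linalg.solve(L, np.ones(n))
    mu = (one @ z) / (one @ one)
    resid = z - mu * one
    sigma2 = float(resid @ resid) / n
    return -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def pagels_lambda(trait: TraitOnTree, tol: float = 1e-8) -> tuple[float, float, float]:
    """Maximum-likelihood Pagel's λ on [0, 1] with a LR test against λ = 0.

    λ scales the off-diagonal (shared-history) entries of the BM tree
    covariance; λ = 0 is an independent-tips model, λ = 1 pure Brownian
    motion. Returns (λ̂, log-likelihood at λ̂, p).
    """
    y = trait.ordered_values()
    if y.size < 4:
        raise ValueError("need >= 4 tips")
    if np.ptp(y) == 0:
        raise ValueError("trait variance is zero")
    C = trait.covariance()

    def nll(lam: float) -> float:
        return -_bm_profile_loglik(y, _lambda_cov(C, lam))

    res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": tol})
    lam_hat = float(res.x)
    ll_hat = -float(res.fun)
    # bounded search can stall near an edge; check the boundaries explicitly
    for edge in (0.0, 1.0):
        ll_edge = -nll(edge)
        if ll_edge > ll_hat:
            lam_hat, ll_hat = edge, ll_edge
    ll0 = -nll(0.0)
    lr = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(chi2.sf(lr, df=1))
    return lam_hat, ll_hat, p


# ---------------------------------------------------------------------------
# Blomberg's K


def blombergs_K(
    trait: TraitOnTree,
    n_rand: int = 1_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Blomberg's K with a tip-label randomization test.

    K is the ratio of the observed MSE0/MSE — tip variance about the
    phylogenetically corrected mean over the generalized least-squares error
    under the tree covariance — to its expectation under Brownian motion on
    the same tree; K = 1 matches BM, K > 1 indicates trait conservatism.
    p is the (add-one) proportion of ``n_rand`` tip shuffles whose GLS error
    is at most the observed one.
    """
    y = trait.ordered_values()
    n = y.size
    if n < 4:
        raise ValueError("need >= 4 tips")
    if np.ptp(y) == 0:
        raise ValueError("trait variance is zero")
    V = trait.covariance()
    Vinv = np.linalg.inv(V)
    w = Vinv @ np.ones(n)
    swv = float(w.sum())
    expected = (np.trace(V) - n / swv) / (n - 1)

    def mse_pair(vals: np.ndarray) -> tuple[float, float]:
        a = float(w @ vals) / swv
        r = vals - a
        return float(r @ r) / (n - 1), float(r @ Vinv @ r) / (n - 1)

    mse0, mse = mse_pair(y)
    k = (mse0 / mse) / expected
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    count = 0
    for _ in range(n_rand):
        _, mse_r = mse_pair(y[rng.permutation(n)])
        if mse_r <= mse:
            count += 1
    p = (1.0 + count) / (n_rand + 1.0)
    return float(k), float(p)


# ---------------------------------------------------------------------------
# trait normalization


def normalize_trait(values: Sequence[float]) -> np.ndarray:
    """Rank-based inverse-normal transform (deterministic, monotone).

    Maps average ranks r to Φ⁻¹((r − 0.5)/n), producing an approximately
    normal margin regardless of the input's skew; ties share their average
    rank. λ's likelihood assumes normal tip values, and raw relative-growth
    profiles are typically left-skewed.
    """
    y = np.asarray(values, float)
    if y.size < 4:
        raise ValueError("need >= 4 values")
    if np.ptp(y) == 0:
        raise ValueError("all values tied: transform undefined")
    ranks = rankdata(y, method="average")
    return norm.ppf((ranks - 0.5) / y.size)
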