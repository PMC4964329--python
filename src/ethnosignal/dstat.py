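"""Phylogenetic signal for binary traits: the D statistic.

For a binary trait on a rooted bifurcating tree, the raw statistic is the
sum of sister-clade differences

    sigma_d = sum over internal nodes |x(daughter1) - x(daughter2)|

where tip values are the observed 0/1 states and internal nodal values are
estimated tips-to-root by branch-length-weighted averaging of the two
daughters with Felsenstein's branch-length adjustment (daughter weights
proportional to 1/adjusted edge length; the merged node's edge is extended
by the product-over-sum correction).  A plain unweighted mean is available
as ``nodal="unweighted"`` for cross-checking against other implementations.

sigma_d is scaled against two null distributions:

* a permutation null — the tip states shuffled uniformly at random
  (prevalence preserved), the expectation if the trait is phylogenetically
  random; and
* a Brownian-threshold null — a continuous trait evolved by Brownian motion
  along the tree, with state 1 assigned to the top-ranked tips at the
  observed prevalence, the expectation under gradual, phylogenetically
  conserved evolution.

The D statistic is then

    D = (sigma_d_obs - mean(sigma_d_brownian))
        / (mean(sigma_d_random) - mean(sigma_d_brownian))

so D = 1 means "as random", D = 0 means "as Brownian-clumped", D < 0 means
more clumped than Brownian, D > 1 overdispersed.  Two one-sided Monte Carlo
p-values accompany it: p(D < 1), the fraction of random-null draws with
sigma_d at or below the observed value, and p(D > 0), the fraction of
Brownian-null draws at or above it.  Both use the plus-one (pseudo-count)
correction so a p-value is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .tree_io import PhyloTree, resolve_polytomies, tip_labels

__all__ = [
    "DResult",
    "TreeArrays",
    "sum_sister_differences",
    "permutation_null",
    "brownian_threshold_null",
    "simulate_brownian_threshold_trait",
    "d_statistic",
    "InsufficientVariationError",
]

NodalMode = Literal["weighted", "unweighted"]


class InsufficientVariationError(ValueError):
    """Trait has fewer than 2 tips in one of the two states."""


class TreeArrays:
    """Flat, index-based encoding of a rooted bifurcating tree.

    Tips get indices ``0 .. n-1`` (in leaf-iteration order), internal nodes
    ``n .. 2n-2`` in postorder, the root last.  Nodal-averaging weights are
    trait-independent, so they are precomputed here once and sigma_d becomes a
    single postorder sweep vectorizable over batches of state vectors.
    """

    def __init__(self, tree: PhyloTree, nodal: NodalMode = "weighted"):
        leaves = list(tree.leaf_node_iter())
        n = len(leaves)
        if n < 2:
            raise ValueError("tree must have at least 2 tips")
        self.tip_labels: tuple[str, ...] = tuple(lf.taxon.label for lf in leaves)
        self.n_tips = n
        index = {id(lf): i for i, lf in enumerate(leaves)}
        left = np.empty(n - 1, dtype=np.int64)
        right = np.empty(n - 1, dtype=np.int64)
        wl = np.empty(n - 1)
        wr = np.empty(n - 1)
        # adjusted edge lengths for the Felsenstein correction
        adj: dict[int, float] = {}
        k = 0
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                adj[id(node)] = node.edge.length or 0.0
                continue
            children = node.child_nodes()
            if len(children) != 2:
                raise ValueError(
                    "tree is not bifurcating; resolve polytomies first"
                )
            c1, c2 = children
            v1, v2 = adj[id(c1)], adj[id(c2)]
            idx = n + k
            left[k], right[k] = index[id(c1)], index[id(c2)]
            if nodal == "unweighted" or (v1 == 0.0 and v2 == 0.0):
                wl[k] = wr[k] = 0.5
                extra = 0.0
            elif v1 == 0.0:
                wl[k], wr[k] = 1.0, 0.0
                extra = 0.0
            elif v2 == 0.0:
                wl[k], wr[k] = 0.0, 1.0
                extra = 0.0
            else:
                wl[k] = (1.0 / v1) / (1.0 / v1 + 1.0 / v2)
                wr[k] = 1.0 - wl[k]
                extra = v1 * v2 / (v1 + v2)
            adj[id(node)] = (node.edge.length or 0.0) + extra
            index[id(node)] = idx
            k += 1
        assert k == n - 1
        self._left, self._right, self._wl, self._wr = left, right, wl, wr
        # sqrt-branch-length root-to-tip path matrix for Brownian simulation:
        # tip values = Z @ path_matrix.T with Z iid standard normal per edge
        edges = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
        m = np.zeros((n, len(edges)))
        stack: list[tuple[object, list[int]]] = [(tree.seed_node, [])]
        edge_idx = {id(e): j for j, e in enumerate(edges)}
        while stack:
            node, path = stack.pop()
            if node.is_leaf():
                for j in path:
                    m[index[id(node)], j] = 1.0
                continue
            for child in node.child_nodes():
                stack.append((child, path + [edge_idx[id(child)]]))
        lengths = np.array([nd.edge.length or 0.0 for nd in edges])
        self._path_sqrt = m * np.sqrt(lengths)

    def sigma_d(self, states: np.ndarray) -> np.ndarray:
        """sigma_d for a batch of state vectors, shape (B, n_tips) -> (B,)."""
        states = np.atleast_2d(np.asarray(states, dtype=float))
        if states.shape[1] != self.n_tips:
            raise ValueError(
                f"state vectors have {states.shape[1]} entries, tree has "
                f"{self.n_tips} tips"
            )
        b = states.shape[0]
        x = np.empty((b, 2 * self.n_tips - 1))
        x[:, : self.n_tips] = states
        sd = np.zeros(b)
        n = self.n_tips
        for k in range(n - 1):
            xl = x[:, self._left[k]]
            xr = x[:, self._right[k]]
            sd += np.abs(xl - xr)
            x[:, n + k] = self._wl[k] * xl + self._wr[k] * xr
        return sd

    def brownian_tips(self, n_sim: int, rng: np.random.Generator) -> np.ndarray:
        """Simulate Brownian tip values, shape (n_sim, n_tips).

        Increments are zero-mean normal with variance equal to branch length
        (sigma^2 = 1 per unit length — the scale is irrelevant after rank
        thresholding); zero-length edges contribute zero variance.
        """
        z = rng.standard_normal((n_sim, self._path_sqrt.shape[1]))
        return z @ self._path_sqrt.T


def _states_vector(
    arrays: TreeArrays, states: Mapping[str, int] | Sequence[int] | np.ndarray
) -> np.ndarray:
    if isinstance(states, Mapping):
        missing = [t for t in arrays.tip_labels if t not in states]
        if missing:
            raise ValueError(f"states missing for tips: {missing[:5]}")
        vec = np.array([states[t] for t in arrays.tip_labels], dtype=float)
    else:
        vec = np.asarray(states, dtype=float)
        if vec.shape != (arrays.n_tips,):
            raise ValueError(
                f"expected {arrays.n_tips} states, got shape {vec.shape}"
            )
    if not np.isin(vec, (0.0, 1.0)).all():
        raise ValueError("states must be binary (0/1)")
    return vec


def _as_arrays(tree: PhyloTree | TreeArrays, nodal: NodalMode) -> TreeArrays:
    if isinstance(tree, TreeArrays):
        return tree
    return TreeArrays(tree, nodal=nodal)


def sum_sister_differences(
    tree: PhyloTree | TreeArrays,
    states: Mapping[str, int] | Sequence[int] | np.ndarray,
    nodal: NodalMode = "weighted",
) -> float:
    """Observed sum of sister-clade differences for one binary trait."""
    arrays = _as_arrays(tree, nodal)
    return float(arrays.sigma_d(_states_vector(arrays, states)[None, :])[0])


def permutation_null(
    tree: PhyloTree | TreeArrays,
    states: Mapping[str, int] | Sequence[int] | np.ndarray,
    n_perm: int,
    seed: int,
    nodal: NodalMode = "weighted",
) -> np.ndarray:
    """sigma_d under uniform random permutations of the tip states."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    arrays = _as_arrays(tree, nodal)
    vec = _states_vector(arrays, states)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(vec, (n_perm, 1)), axis=1)
    return arrays.sigma_d(perms)


def _threshold_top_k(values: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Binary matrix with 1 at the k largest entries per row, random ties."""
    b, n = values.shape
    tie_break = rng.random(values.shape)
    order = np.lexsort((tie_break, -values))  # per-row, descending by value
    out = np.zeros((b, n))
    rows = np.repeat(np.arange(b), k)
    out[rows, order[:, :k].ravel()] = 1.0
    return out


def brownian_threshold_null(
    tree: PhyloTree | TreeArrays,
    k_ones: int,
    n_sim: int,
    seed: int,
    nodal: NodalMode = "weighted",
) -> np.ndarray:
    """sigma_d under the Brownian-threshold model at prevalence k_ones/n."""
    arrays = _as_arrays(tree, nodal)
    if not 0 < k_ones < arrays.n_tips:
        raise ValueError(f"k_ones must be in (0, {arrays.n_tips})")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    tips = arrays.brownian_tips(n_sim, rng)
    states = _threshold_top_k(tips, k_ones, rng)
    return arrays.sigma_d(states)


def simulate_brownian_threshold_trait(
    tree: PhyloTree | TreeArrays, k_ones: int, seed: int
) -> dict[str, int]:
    """One Brownian-threshold binary trait, as a tip-label -> state map."""
    arrays = _as_arrays(tree, "weighted")
    if not 0 < k_ones < arrays.n_tips:
        raise ValueError(f"k_ones must be in (0, {arrays.n_tips})")
    rng = np.random.default_rng(seed)
    tips = arrays.brownian_tips(1, rng)
    states = _threshold_top_k(tips, k_ones, rng)[0]
    return {t: int(s) for t, s in zip(arrays.tip_labels, states)}


@dataclass
class DResult:
    """D statistic of one binary trait on one tree, with its nulls."""

    sigma_d_obs: float
    sigma_d_random: np.ndarray
    sigma_d_brownian: np.ndarray
    d: float
    p_d_lt_1: float
    p_d_gt_0: float
    n_perm: int
    n_sim: int
    seed: int


def d_statistic(
    tree: PhyloTree | TreeArrays,
    states: Mapping[str, int] | Sequence[int] | np.ndarray,
    n_perm: int = 1000,
    n_sim: int = 1000,
    seed: int = 0,
    nodal: NodalMode = "weighted",
    resolve_seed: int | None = None,
) -> DResult:
    """Compute D and its two Monte Carlo p-values for one trait on one tree.

    ``p_d_lt_1 = (#{sigma_d_random <= sigma_d_obs} + 1) / (n_perm + 1)`` tests
    whether the trait is non-randomly (more clumped than randomly)
    distributed; ``p_d_gt_0 = (#{sigma_d_brownian >= sigma_d_obs} + 1) /
    (n_sim + 1)`` tests departure from the Brownian-threshold expectation.

    Raises :class:`InsufficientVariationError` when fewer than 2 tips carry
    either state — callers screening many categories should catch it and
    report the category as not analysable.
    """
    if not isinstance(tree, TreeArrays):
        has_polytomy = any(
            len(nd.child_nodes()) > 2 for nd in tree.preorder_internal_node_iter()
        )
        if has_polytomy:
            tree = resolve_polytomies(tree, seed if resolve_seed is None else resolve_seed)
        tree = TreeArrays(tree, nodal=nodal)
    arrays = tree
    vec = _states_vector(arrays, states)
    k = int(vec.sum())
    if k < 2 or k > arrays.n_tips - 2:
        raise InsufficientVariationError(
            f"need >= 2 tips in each state, got {k} of {arrays.n_tips}"
        )
    obs = float(arrays.sigma_d(vec[None, :])[0])
    rng = np.random.default_rng(seed)
    perm_seed, brown_seed = rng.integers(2**31 - 1, size=2)
    sd_r = permutation_null(arrays, vec, n_perm, int(perm_seed))
    sd_b = brownian_threshold_null(arrays, k, n_sim, int(brown_seed))
    denom = sd_r.mean() - sd_b.mean()
    if denom == 0.0:
        raise ValueError("degenerate nulls: mean(random) == mean(brownian)")
    d = (obs - sd_b.mean()) / denom
    p_lt1 = (int((sd_r <= obs).sum()) + 1) / (n_perm + 1)
    p_gt0 = (int((sd_b >= obs).sum()) + 1) / (n_sim + 1)
    return DResult(
        sigma_d_obs=obs,
        sigma_d_random=sd_r,
        sigma_d_brownian=sd_b,
        d=float(d),
        p_d_lt_1=p_lt1,
        p_d_gt_0=p_gt0,
        n_perm=n_perm,
        n_sim=n_sim,
        seed=seed,
    )
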