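"""Faith's phylogenetic diversity and between-category MNTD.

Faith's PD of a tip set is the total branch length of the union of
root-to-tip paths over the set; with ``include_root=False`` the unshared
root-ward portion above the set's most recent common ancestor is dropped.
PD is also expressed as a percentage of the whole-tree PD (same flag applied
to numerator and denominator), which says whether a category is spread
across the tree or confined to few clades.

The mean nearest taxon distance (MNTD) between two tip sets A and B averages,
over the members of each set, the patristic distance to the closest member
of the other set:

    MNTD(A, B) = [ sum_a min_b d(a, b) + sum_b min_a d(b, a) ] / (|A| + |B|)

Species shared between the sets either count at distance zero
(``include_zero``, the plain definition) or are skipped as self-matches
(``exclude``).  Significance of an observed MNTD is assessed against
random categories of the same size drawn from a stated species pool; small
MNTD means similarity, so the p-value is the (plus-one corrected) fraction
of null draws at or below the observed value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .tree_io import PhyloTree, tip_labels

__all__ = [
    "PDResult",
    "MNTDResult",
    "patristic_matrix",
    "faith_pd",
    "pd_percent",
    "mntd_between",
    "mntd_pvalue",
]

ConspecificPolicy = Literal["include_zero", "exclude"]


def patristic_matrix(tree: PhyloTree) -> pd.DataFrame:
    """Symmetric tip-by-tip matrix of path-length (patristic) distances.

    Computed as d(i, j) = depth(i) + depth(j) - 2 depth(mrca(i, j)) in one
    postorder sweep; zero diagonal.
    """
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    index = {id(lf): i for i, lf in enumerate(leaves)}
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    depths = np.array([depth[id(lf)] for lf in leaves])
    dist = np.zeros((n, n))
    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = [index[id(node)]]
            continue
        child_sets = [below.pop(id(c)) for c in node.child_nodes()]
        d_node = depth[id(node)]
        for sa, sb in combinations(child_sets, 2):
            ia = np.array(sa)[:, None]
            ib = np.array(sb)[None, :]
            d = depths[ia] + depths[ib] - 2.0 * d_node
            dist[ia, ib] = d
            dist[ib.T, ia.T] = d.T
        below[id(node)] = [i for s in child_sets for i in s]
    return pd.DataFrame(dist, index=labels, columns=labels)


def _spanning_edges(tree: PhyloTree, taxa: set[str], include_root: bool):
    """Nodes whose subtending edges form the PD spanning subtree."""
    present = set(tip_labels(tree))
    unknown = sorted(taxa - present)
    if unknown:
        raise ValueError(f"taxa not in tree: {unknown}")
    count: dict[int, int] = {}
    marked = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            c = 1 if node.taxon.label in taxa else 0
        else:
            c = sum(count[id(ch)] for ch in node.child_nodes())
        count[id(node)] = c
        if node.parent_node is None:
            continue
        on_path = c > 0 if include_root else 0 < c < len(taxa)
        if on_path:
            marked.append(node)
    return marked


def faith_pd(tree: PhyloTree, taxa: Iterable[str], include_root: bool = True) -> float:
    """Faith's PD: total branch length of the union of root-to-tip paths.

    With ``include_root=False`` only edges below the MRCA of ``taxa`` count
    (edges with the whole set on one side are dropped).
    """
    taxa = set(taxa)
    if not taxa:
        raise ValueError("taxa set is empty")
    return sum(nd.edge.length or 0.0 for nd in _spanning_edges(tree, taxa, include_root))


@dataclass(frozen=True)
class PDResult:
    category: str
    pd: float
    pd_percent: float


def pd_percent(tree: PhyloTree, taxa: Iterable[str], include_root: bool = True) -> float:
    """PD of ``taxa`` as a percentage of the same-tree all-tips PD."""
    total = faith_pd(tree, set(tip_labels(tree)), include_root=include_root)
    return 100.0 * faith_pd(tree, taxa, include_root=include_root) / total


def mntd_between(
    dist: pd.DataFrame,
    set_a: Iterable[str],
    set_b: Iterable[str],
    conspecific_policy: ConspecificPolicy = "include_zero",
) -> float:
    """Mean nearest taxon distance between two tip sets.

    ``include_zero`` counts species shared between the sets at distance 0;
    ``exclude`` skips self-matches, dropping a term entirely (numerator and
    denominator) when a species has no non-self counterpart.
    """
    a = sorted(set(set_a))
    b = sorted(set(set_b))
    if not a or not b:
        raise ValueError("both sets must be non-empty")
    for s in (a, b):
        unknown = [x for x in s if x not in dist.index]
        if unknown:
            raise ValueError(f"taxa not in distance matrix: {unknown}")
    sub = dist.loc[a, b].to_numpy(copy=True)
    if conspecific_policy == "exclude":
        shared = set(a) & set(b)
        for sp in shared:
            sub[a.index(sp), b.index(sp)] = np.inf
    elif conspecific_policy != "include_zero":
        raise ValueError(f"unknown conspecific policy {conspecific_policy!r}")
    mins_a = sub.min(axis=1)
    mins_b = sub.min(axis=0)
    terms = np.concatenate([mins_a, mins_b])
    terms = terms[np.isfinite(terms)]  # exclude-policy: drop empty-candidate terms
    if terms.size == 0:
        raise ValueError(
            "no valid nearest-taxon terms (sets identical under policy 'exclude')"
        )
    return float(terms.mean())


@dataclass
class MNTDResult:
    """Observed between-set MNTD with its random-category null."""

    focal: str
    other: str
    mntd: float
    null: np.ndarray
    p_value: float
    pool: str
    n_rand: int
    seed: int


def mntd_pvalue(
    tree_or_dist: PhyloTree | pd.DataFrame,
    focal: Iterable[str],
    other: Iterable[str],
    pool: Iterable[str],
    n_rand: int = 1000,
    seed: int = 0,
    conspecific_policy: ConspecificPolicy = "include_zero",
    focal_name: str = "focal",
    other_name: str = "other",
) -> MNTDResult:
    """Test whether ``focal`` is phylogenetically closer to ``other`` than to
    random same-size categories drawn from ``pool``.

    Each null replicate draws a uniform random subset of ``pool`` of size
    ``|other|`` and recomputes MNTD(focal, draw); the one-sided p-value
    (small MNTD = similar) is ``(#{null <= observed} + 1) / (n_rand + 1)``.
    A pool no larger than ``other`` makes every draw identical to ``other``;
    this degenerate case warns and returns p = 1.
    """
    dist = (
        tree_or_dist
        if isinstance(tree_or_dist, pd.DataFrame)
        else patristic_matrix(tree_or_dist)
    )
    focal = sorted(set(focal))
    other = sorted(set(other))
    pool = sorted(set(pool))
    if not set(other) <= set(pool):
        raise ValueError("`other` must be a subset of `pool`")
    observed = mntd_between(dist, focal, other, conspecific_policy)
    if len(pool) == len(other):
        warnings.warn(
            "species pool equals the tested category; null is degenerate, p = 1",
            stacklevel=2,
        )
        return MNTDResult(
            focal=focal_name,
            other=other_name,
            mntd=observed,
            null=np.full(n_rand, observed),
            p_value=1.0,
            pool=f"degenerate pool of {len(pool)}",
            n_rand=n_rand,
            seed=seed,
        )
    rng = np.random.default_rng(seed)
    pool_arr = np.array(pool, dtype=object)
    null = np.empty(n_rand)
    for r in range(n_rand):
        draw = pool_arr[rng.choice(len(pool_arr), size=len(other), replace=False)]
        null[r] = mntd_between(dist, focal, draw, conspecific_policy)
    p = (int((null <= observed).sum()) + 1) / (n_rand + 1)
    return MNTDResult(
        focal=focal_name,
        other=other_name,
        mntd=observed,
        null=null,
        p_value=p,
        pool=f"{len(pool)} species",
        n_rand=n_rand,
        seed=seed,
    )
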