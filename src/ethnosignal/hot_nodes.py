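"""Node-level overrepresentation ("hot node") tests.

For every internal node of a rooted tree, compare the observed number of
category members among its descendant tips with the distribution obtained
by shuffling the member labels uniformly over all tips (without
replacement).  A node is *hot* when its observed count strictly exceeds the
(1 - alpha) empirical quantile of its null counts, *cold* when it falls
strictly below the alpha quantile — one-sided tests on each tail,
mirroring the SIGMORE/SIGLESS outputs of randomization-based node
enrichment tools.  Because the shuffle is a uniform draw without
replacement, the per-node null is exactly Hypergeometric(N, K, n_i), which
serves as the analytic cross-check (:func:`hypergeometric_node_p`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .tree_io import PhyloTree, tip_labels

__all__ = [
    "HotNodeResult",
    "node_tip_counts",
    "hot_node_test",
    "hypergeometric_node_p",
]


def _internal_nodes(tree: PhyloTree):
    """Internal nodes in postorder with their descendant tip-index lists."""
    leaves = list(tree.leaf_node_iter())
    index = {id(lf): i for i, lf in enumerate(leaves)}
    labels = [lf.taxon.label for lf in leaves]
    below: dict[int, list[int]] = {}
    out = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = [index[id(node)]]
            continue
        tips = [i for c in node.child_nodes() for i in below[id(c)]]
        below[id(node)] = tips
        # stable id: (smallest descendant label, clade size) — unique because
        # nested clades differ in size and disjoint clades in smallest label
        node_id = f"{min(labels[i] for i in tips)}|{len(tips)}"
        out.append((node_id, node, tips))
    return labels, out


def node_tip_counts(tree: PhyloTree, members: Iterable[str]) -> pd.DataFrame:
    """Per-internal-node descendant-tip count ``n`` and member count ``k``."""
    members = set(members)
    labels, internals = _internal_nodes(tree)
    unknown = sorted(members - set(labels))
    if unknown:
        raise ValueError(f"members not in tree: {unknown}")
    member_idx = {i for i, lab in enumerate(labels) if lab in members}
    rows = [
        {"node": node_id, "n": len(tips), "k": len(member_idx & set(tips))}
        for node_id, _, tips in internals
    ]
    return pd.DataFrame(rows).set_index("node")


@dataclass
class HotNodeResult:
    """Per-node enrichment table plus the test configuration.

    ``table`` columns: ``n`` (descendant tips), ``k`` (observed members),
    ``p_exceed`` (plus-one corrected upper-tail probability under the
    shuffle null), ``flag`` in {hot, cold, ns}.
    """

    table: pd.DataFrame
    n_rand: int
    alpha: float
    seed: int
    n_members: int

    @property
    def hot(self) -> list[str]:
        return list(self.table.index[self.table["flag"] == "hot"])

    @property
    def cold(self) -> list[str]:
        return list(self.table.index[self.table["flag"] == "cold"])


def hot_node_test(
    tree: PhyloTree,
    members: Iterable[str],
    n_rand: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> HotNodeResult:
    """Randomization test for member overrepresentation at every node.

    Null replicates shuffle the member labels uniformly over all tips of the
    analysis tree.  Flags use strict inequalities against the empirical
    alpha / (1 - alpha) quantiles of each node's null counts; the root
    (where ``k`` always equals the number of members) can never be flagged.
    """
    members = set(members)
    labels, internals = _internal_nodes(tree)
    n_tips = len(labels)
    if not 0 < len(members) < n_tips:
        raise ValueError(
            f"need 0 < |members| < n_tips, got {len(members)} of {n_tips}"
        )
    unknown = sorted(members - set(labels))
    if unknown:
        raise ValueError(f"members not in tree: {unknown}")
    member_vec = np.array([lab in members for lab in labels], dtype=float)
    incidence = np.zeros((n_tips, len(internals)))
    for j, (_, _, tips) in enumerate(internals):
        incidence[tips, j] = 1.0
    rng = np.random.default_rng(seed)
    shuffles = rng.permuted(np.tile(member_vec, (n_rand, 1)), axis=1)
    null_counts = shuffles @ incidence  # (n_rand, n_nodes)
    k_obs = member_vec @ incidence
    hi = np.quantile(null_counts, 1.0 - alpha, axis=0)
    lo = np.quantile(null_counts, alpha, axis=0)
    p_exceed = ((null_counts >= k_obs).sum(axis=0) + 1) / (n_rand + 1)
    flags = np.where(k_obs > hi, "hot", np.where(k_obs < lo, "cold", "ns"))
    table = pd.DataFrame(
        {
            "n": [len(tips) for _, _, tips in internals],
            "k": k_obs.astype(int),
            "p_exceed": p_exceed,
            "flag": flags,
        },
        index=pd.Index([node_id for node_id, _, _ in internals], name="node"),
    )
    return HotNodeResult(
        table=table, n_rand=n_rand, alpha=alpha, seed=seed, n_members=len(members)
    )


def annotate_tree(tree: PhyloTree, result: HotNodeResult) -> PhyloTree:
    """Copy of the tree with hot/cold flags written as internal node labels."""
    out = tree.clone(depth=1)
    _, internals = _internal_nodes(out)
    for node_id, node, _ in internals:
        flag = result.table.loc[node_id, "flag"]
        if flag != "ns":
            node.label = str(flag)
    return out


def hypergeometric_node_p(n_total: int, k_members: int, n_i: int, k_i: int) -> float:
    """Exact upper-tail P(X >= k_i), X ~ Hypergeometric(N, K, n_i).

    Analytic form of the shuffle null at a single node: the number of
    members among ``n_i`` tips drawn without replacement from ``n_total``
    tips of which ``k_members`` are members.
    """
    if not (0 <= k_i <= min(n_i, k_members)) or n_i > n_total or k_members > n_total:
        raise ValueError(
            f"invalid counts: N={n_total}, K={k_members}, n={n_i}, k={k_i}"
        )
    return float(stats.hypergeom.sf(k_i - 1, n_total, k_members, n_i))
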