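"""Synthetic trees, pseudo-posterior ensembles and binary traits.

Every analysis stage in this package can be exercised without external data:
this module simulates Yule (pure-birth) and birth-death trees, perturbs a
base tree into a pseudo-posterior ensemble (random nearest-neighbor
interchanges plus multiplicative log-normal branch jitter, emulating the
topological and branch-length spread of a Bayesian credible set), and
plants binary traits with known signal structure:

* ``random`` — exactly round(prevalence * n) ones placed uniformly, the
  D ~ 1 regime;
* ``brownian_threshold`` — a Brownian trait thresholded at the given
  prevalence (shares its simulator with the D-statistic null), the D ~ 0
  regime;
* ``clade_clumped`` — all tips of one clade plus optional random noise
  tips, the D < 0 / hot-node regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import yaml

from .dstat import simulate_brownian_threshold_trait
from .tree_io import PhyloTree, TreeEnsemble, tip_labels

__all__ = [
    "SimConfig",
    "simulate_yule_tree",
    "simulate_birth_death_tree",
    "simulate_random_trait",
    "simulate_clade_trait",
    "simulate_brownian_threshold_trait",
    "perturb_ensemble",
    "pick_clade",
    "generate_dataset",
]


def _new_tree(labels: Iterable[str]) -> tuple[dendropy.Tree, dendropy.TaxonNamespace]:
    tns = dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    return tree, tns


def _label(i: int) -> str:
    return f"Sp{i + 1:04d}"


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> PhyloTree:
    """Pure-birth tree with ``n_tips`` extant tips.

    Waiting times between speciations are exponential with rate
    (lineages * birth_rate); a final exponential waiting time is appended
    after the last split so terminal branches are strictly positive.
    Branch lengths are in units of expected 1/birth_rate.
    """
    return simulate_birth_death_tree(n_tips, birth_rate, 0.0, seed)


def simulate_birth_death_tree(
    n_tips: int, birth_rate: float = 1.0, death_rate: float = 0.0, seed: int = 0
) -> PhyloTree:
    """Constant-rate birth-death tree conditioned on ``n_tips`` extant tips.

    Forward Gillespie simulation from two lineages; runs that go extinct or
    overshoot restart with a fresh stream from the same generator, and
    extinct lineages are pruned from the returned tree.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if birth_rate <= 0 or death_rate < 0 or death_rate >= birth_rate:
        raise ValueError("need 0 <= death_rate < birth_rate")
    rng = np.random.default_rng(seed)
    tree, tns = _new_tree([_label(i) for i in range(n_tips)])
    while True:
        nodes = _grow(rng, n_tips, birth_rate, death_rate)
        if nodes is not None:
            break
    root, extant = nodes
    # attach dendropy structure
    tree.seed_node = _to_dendropy(root, extant, tns)
    tree.is_rooted = True
    return tree


class _SimNode:
    __slots__ = ("birth", "death", "children", "parent")

    def __init__(self, birth: float):
        self.birth = birth
        self.death: float | None = None
        self.children: list["_SimNode"] = []
        self.parent: "_SimNode | None" = None


def _grow(rng, n_tips, birth, death):
    root = _SimNode(0.0)
    alive = [root]
    t = 0.0
    while len(alive) != n_tips:
        if not alive:
            return None  # extinct: retry
        total = len(alive) * (birth + death)
        t += rng.exponential(1.0 / total)
        node = alive.pop(rng.integers(len(alive)))
        if rng.random() < birth / (birth + death):
            for _ in range(2):
                child = _SimNode(t)
                child.parent = node
                node.children.append(child)
                alive.append(child)
            node.death = t
        else:
            node.death = t
    # final hanging time after the last event
    t += rng.exponential(1.0 / (len(alive) * birth))
    for node in alive:
        node.death = t
    return root, set(map(id, alive))


def _to_dendropy(root: _SimNode, extant: set[int], tns: dendropy.TaxonNamespace):
    """Convert, pruning extinct subtrees and collapsing unifurcations."""

    def convert(sim: _SimNode) -> dendropy.Node | None:
        if not sim.children:
            if id(sim) not in extant:
                return None
            node = dendropy.Node()
            node.edge.length = sim.death - sim.birth
            return node
        kids = [c for c in (convert(ch) for ch in sim.children) if c is not None]
        if not kids:
            return None
        if len(kids) == 1:  # extinct sister: splice through
            kids[0].edge.length += sim.death - sim.birth
            return kids[0]
        node = dendropy.Node()
        node.edge.length = sim.death - sim.birth
        for k in kids:
            node.add_child(k)
        return node

    out = convert(root)
    assert out is not None
    out.edge.length = None  # root has no subtending edge
    for i, leaf in enumerate(out.leaf_iter()):
        leaf.taxon = tns[i]
    return out


def simulate_random_trait(
    tips: Iterable[str], prevalence: float, seed: int = 0
) -> dict[str, int]:
    """Uniform random binary trait with exactly round(prevalence * n) ones."""
    tips = list(tips)
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    k = round(prevalence * len(tips))
    if k in (0, len(tips)):
        raise ValueError(
            f"prevalence {prevalence} rounds to a constant trait on {len(tips)} tips"
        )
    rng = np.random.default_rng(seed)
    ones = set(rng.choice(len(tips), size=k, replace=False).tolist())
    return {t: int(i in ones) for i, t in enumerate(tips)}


def pick_clade(tree: PhyloTree, target_size: int, seed: int = 0) -> dendropy.Node:
    """An internal node whose descendant tip count is closest to
    ``target_size`` (ties broken reproducibly), never the root."""
    candidates = []
    for node in tree.postorder_internal_node_iter():
        if node.parent_node is None:
            continue
        size = sum(1 for _ in node.leaf_iter())
        candidates.append((abs(size - target_size), size, node))
    if not candidates:
        raise ValueError("tree has no non-root internal nodes")
    candidates.sort(key=lambda t: (t[0], t[1], min(l.taxon.label for l in t[2].leaf_iter())))
    best = [c for c in candidates if c[0] == candidates[0][0]]
    rng = np.random.default_rng(seed)
    return best[rng.integers(len(best))][2]


def simulate_clade_trait(
    tree: PhyloTree,
    clade_node: dendropy.Node,
    extra_noise: int = 0,
    seed: int = 0,
) -> dict[str, int]:
    """Single-clade clumped trait: all tips under ``clade_node`` are 1, plus
    ``extra_noise`` random tips elsewhere."""
    if extra_noise < 0:
        raise ValueError("extra_noise must be >= 0")
    clade_tips = {leaf.taxon.label for leaf in clade_node.leaf_iter()}
    all_tips = list(tip_labels(tree))
    outside = [t for t in all_tips if t not in clade_tips]
    if not outside:
        raise ValueError("clade covers the whole tree")
    if extra_noise > len(outside):
        raise ValueError("extra_noise larger than the number of non-clade tips")
    rng = np.random.default_rng(seed)
    noise = set(
        np.array(outside, dtype=object)[
            rng.choice(len(outside), size=extra_noise, replace=False)
        ].tolist()
    )
    return {t: int(t in clade_tips or t in noise) for t in all_tips}


def _random_nni(tree: PhyloTree, rng: np.random.Generator) -> None:
    """One random nearest-neighbor interchange on a rooted bifurcating tree."""
    candidates = [
        nd
        for nd in tree.preorder_internal_node_iter()
        if nd.parent_node is not None
        and len(nd.child_nodes()) == 2
        and len(nd.parent_node.child_nodes()) == 2
    ]
    if not candidates:
        return
    x = candidates[rng.integers(len(candidates))]
    parent = x.parent_node
    sibling = next(c for c in parent.child_nodes() if c is not x)
    child = x.child_nodes()[rng.integers(2)]
    parent.remove_child(sibling)
    x.remove_child(child)
    x.add_child(sibling)
    parent.add_child(child)


def perturb_ensemble(
    tree: PhyloTree,
    n_trees: int,
    n_nni: int = 2,
    branch_jitter: float = 0.1,
    seed: int = 0,
) -> TreeEnsemble:
    """Pseudo-posterior ensemble around a base tree.

    Each ensemble tree applies ``n_nni`` random nearest-neighbor
    interchanges and multiplies every branch length by an independent
    log-normal factor with log-scale ``branch_jitter`` (0 disables).  The
    tip set is preserved exactly.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if n_nni < 0 or branch_jitter < 0:
        raise ValueError("n_nni and branch_jitter must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_trees):
        t = tree.clone(depth=1)
        for _ in range(n_nni):
            _random_nni(t, rng)
        if branch_jitter > 0:
            for node in t.preorder_node_iter():
                if node.parent_node is not None and node.edge.length:
                    node.edge.length *= float(
                        np.exp(rng.normal(0.0, branch_jitter))
                    )
        out.append(t)
    return TreeEnsemble(out)


@dataclass
class SimConfig:
    """Full recipe for one synthetic dataset (tree + ensemble + traits)."""

    n_tips: int = 200
    tree_model: str = "yule"  # or "birth_death"
    birth_rate: float = 1.0
    death_rate: float = 0.0
    trait_model: str = "random"  # random | brownian_threshold | clade_clumped
    prevalence: float = 0.25
    clade_size: int = 20
    extra_noise: int = 0
    ensemble_size: int = 50
    n_nni: int = 2
    branch_jitter: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tree_model not in {"yule", "birth_death"}:
            raise ValueError(f"unknown tree model {self.tree_model!r}")
        if self.trait_model not in {"random", "brownian_threshold", "clade_clumped"}:
            raise ValueError(f"unknown trait model {self.trait_model!r}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.trait_model == "clade_clumped" and not 2 <= self.clade_size <= self.n_tips - 1:
            raise ValueError("clade_size must be in [2, n_tips - 1]")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def generate_dataset(config: SimConfig) -> tuple[PhyloTree, TreeEnsemble, dict[str, int]]:
    """Base tree, perturbed ensemble and one trait vector per the config."""
    rng = np.random.default_rng(config.seed)
    tree_seed, ens_seed, trait_seed = (int(s) for s in rng.integers(2**31 - 1, size=3))
    if config.tree_model == "yule":
        tree = simulate_yule_tree(config.n_tips, config.birth_rate, tree_seed)
    else:
        tree = simulate_birth_death_tree(
            config.n_tips, config.birth_rate, config.death_rate, tree_seed
        )
    ensemble = perturb_ensemble(
        tree, config.ensemble_size, config.n_nni, config.branch_jitter, ens_seed
    )
    tips = tip_labels(tree)
    if config.trait_model == "random":
        trait = simulate_random_trait(tips, config.prevalence, trait_seed)
    elif config.trait_model == "brownian_threshold":
        k = round(config.prevalence * len(tips))
        trait = simulate_brownian_threshold_trait(tree, k, trait_seed)
    else:
        clade = pick_clade(tree, config.clade_size, trait_seed)
        trait = simulate_clade_trait(tree, clade, config.extra_noise, trait_seed)
    return tree, ensemble, trait
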