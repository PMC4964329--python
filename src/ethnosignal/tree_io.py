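"""Reading, validating, pruning and summarizing phylogenetic tree ensembles.

Trees are held as rooted :class:`dendropy.Tree` objects; an ensemble (for
example a posterior sample from a Bayesian analysis) is a list of trees over
one shared taxon set.  All downstream statistics here are rooted quantities,
so input trees are treated as rooted as written — any outgroup rooting is
assumed already applied, and outgroup taxa can be removed with
:func:`prune_to_taxa` before trait analyses.

Conventions: unquoted-label underscores become spaces on input (the common
Newick convention); branch lengths are in whatever units the input carries
(substitutions/site for molecular trees); zero-length edges are legal
everywhere.
"""

from __future__ import annotations

import random
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

from .use_records import normalize_name

__all__ = [
    "PhyloTree",
    "TreeEnsemble",
    "Bipartition",
    "read_tree_ensemble",
    "prune_to_taxa",
    "majority_consensus",
    "resolve_polytomies",
    "write_newick",
    "tip_labels",
    "total_branch_length",
]

# Rooted trees throughout; "PhyloTree" is the package-level name for them.
PhyloTree = dendropy.Tree


@dataclass(frozen=True)
class Bipartition:
    """One side of a split under the rooted convention: the descendant tip
    set of a node, with its support frequency across an ensemble."""

    clade: frozenset[str]
    support: float


def tip_labels(tree: PhyloTree) -> tuple[str, ...]:
    """Tip labels in tree (leaf-iteration) order."""
    return tuple(leaf.taxon.label for leaf in tree.leaf_node_iter())


def total_branch_length(tree: PhyloTree) -> float:
    return sum(e.length or 0.0 for e in tree.edges() if e.head_node.parent_node is not None)


@dataclass
class TreeEnsemble:
    """Ordered list of rooted trees over one shared taxon set.

    All ensemble-level statistics (medians, ranges, tree-fraction
    significance rules) are taken over exactly these trees, in this order.
    """

    trees: list[PhyloTree]
    taxa: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("ensemble is empty")
        ref = frozenset(tip_labels(self.trees[0]))
        for i, t in enumerate(self.trees[1:], start=1):
            labels = frozenset(tip_labels(t))
            if labels != ref:
                extra = sorted(labels ^ ref)
                raise ValueError(
                    f"tree {i} has a different taxon set than tree 0; "
                    f"mismatched labels: {extra}"
                )
        self.taxa = ref

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> PhyloTree:
        return self.trees[i]


def _normalize_tree_labels(tree: PhyloTree) -> None:
    seen: set[str] = set()
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None:
            raise ValueError("tree contains an unlabeled tip")
        name = normalize_name(leaf.taxon.label)
        leaf.taxon.label = name
        if name in seen:
            raise ValueError(f"duplicate tip label after normalization: {name!r}")
        seen.add(name)


def _infer_schema(path: Path) -> str:
    if path.suffix.lower() in {".nex", ".nexus", ".trees", ".t"}:
        return "nexus"
    with open(path) as fh:
        head = fh.read(512).lstrip()
    return "nexus" if head.upper().startswith("#NEXUS") else "newick"


def read_tree_ensemble(path: str | Path, schema: str | None = None) -> TreeEnsemble:
    """Read an ensemble of rooted trees from a Newick or NEXUS file.

    NEXUS ``Translate`` tables are resolved; tip labels are normalized
    through :func:`ethnosignal.use_records.normalize_name` so they join
    against use-record tables.  All trees must share one tip-label set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = schema or _infer_schema(path)
    if schema not in {"newick", "nexus"}:
        raise ValueError(f"unsupported tree format {schema!r}")
    try:
        trees = dendropy.TreeList.get(
            path=str(path), schema=schema, preserve_underscores=False
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"could not parse {path} as {schema}: {exc}") from exc
    if len(trees) == 0:
        raise ValueError(f"{path}: no trees found")
    out = []
    for i, t in enumerate(trees):
        t.is_rooted = True
        try:
            _normalize_tree_labels(t)
        except ValueError as exc:
            raise ValueError(f"tree {i}: {exc}") from exc
        out.append(t)
    return TreeEnsemble(out)


def prune_to_taxa(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Restrict a tree to the given tips.

    Unbranched internal nodes left by the pruning are collapsed with their
    branch lengths summed, so patristic distances among kept tips are
    preserved exactly.
    """
    keep = set(keep)
    present = set(tip_labels(tree))
    unknown = sorted(keep - present)
    if unknown:
        raise ValueError(f"labels not in tree: {unknown}")
    if len(keep) < 2:
        raise ValueError("need at least 2 tips to keep")
    pruned = tree.extract_tree_with_taxa_labels(labels=sorted(keep))
    pruned.is_rooted = True
    return pruned


def resolve_polytomies(tree: PhyloTree, seed: int) -> PhyloTree:
    """Return a strictly bifurcating copy, splitting polytomies at random
    (seeded) with zero-length inserted edges; patristic distances unchanged."""
    out = tree.clone(depth=1)
    out.resolve_polytomies(rng=random.Random(seed))
    for node in out.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            node.edge.length = 0.0
    out.is_rooted = True
    return out


def _clade_sets(tree: PhyloTree) -> dict[frozenset[str], float | None]:
    """Descendant-tip set -> subtending edge length, for every node below
    the root (tips included)."""
    out: dict[frozenset[str], float | None] = {}
    clade_of: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            clade = frozenset([node.taxon.label])
        else:
            clade = frozenset().union(*(clade_of[id(c)] for c in node.child_nodes()))
        clade_of[id(node)] = clade
        if node.parent_node is not None:
            out[clade] = node.edge.length
    return out


def majority_consensus(ensemble: TreeEnsemble, min_freq: float = 0.5) -> PhyloTree:
    """Majority-rule consensus of a rooted tree ensemble.

    The consensus contains exactly the clades (descendant tip sets) whose
    frequency across the ensemble exceeds ``min_freq``; because the
    threshold is above one half, retained clades are automatically pairwise
    compatible.  Each consensus edge carries the mean branch length of the
    corresponding edge over the trees that contain the clade, and internal
    nodes store the support frequency (also written as node labels by
    :func:`write_newick`).
    """
    if not 0.5 <= min_freq <= 1.0:
        raise ValueError("min_freq must be in [0.5, 1]")
    n = len(ensemble)
    count: Counter[frozenset[str]] = Counter()
    length_sum: dict[frozenset[str], float] = defaultdict(float)
    for tree in ensemble:
        for clade, length in _clade_sets(tree).items():
            count[clade] += 1
            length_sum[clade] += length or 0.0
    taxa = ensemble.taxa
    keep = [c for c in count if len(c) > 1 and count[c] / n > min_freq]
    keep.sort(key=len, reverse=True)

    tns = dendropy.TaxonNamespace(sorted(taxa))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    root = tree.seed_node
    root.clade = taxa
    root.support = 1.0
    nodes = [root]  # sorted large -> small ensures parents precede children

    def attach(clade: frozenset[str], node: dendropy.Node) -> None:
        parent = root
        for cand in nodes:
            if clade < cand.clade and len(cand.clade) < len(parent.clade):
                parent = cand
        parent.add_child(node)

    for clade in keep:
        node = dendropy.Node()
        node.clade = clade
        node.support = count[clade] / n
        node.edge.length = length_sum[clade] / count[clade]
        attach(clade, node)
        nodes.append(node)
    for label in sorted(taxa):
        leaf = dendropy.Node(taxon=tns.get_taxon(label))
        clade = frozenset([label])
        leaf.clade = clade
        leaf.edge.length = length_sum[clade] / count[clade]
        attach(clade, leaf)
    return tree


def write_newick(tree: PhyloTree, path: str | Path | None = None) -> str:
    """Serialize to Newick; consensus support values (if present) become
    internal node labels."""
    out = tree.clone(depth=1)
    for node in out.preorder_internal_node_iter():
        sup = getattr(node, "support", None)
        if sup is not None and node.parent_node is not None:
            node.label = f"{sup:g}"
    text = out.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        Path(path).write_text(text)
    return text
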