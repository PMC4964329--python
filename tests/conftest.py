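import json
from pathlib import Path

import dendropy
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

FIXTURES = Path(__file__).parent / "fixtures"

FOUR_TIP = "((A:1,B:1):1,(C:1,D:1):1);"


def parse(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return tree


@pytest.fixture
def four_tip_tree():
    return parse(FOUR_TIP)


@pytest.fixture(scope="session")
def hotnode20_tree():
    tree = dendropy.Tree.get(path=str(FIXTURES / "hotnode20.nwk"), schema="newick")
    tree.is_rooted = True
    return tree


@pytest.fixture(scope="session")
def mntd50_tree():
    tree = dendropy.Tree.get(path=str(FIXTURES / "mntd50.nwk"), schema="newick")
    tree.is_rooted = True
    return tree


@pytest.fixture(scope="session")
def fixture_oracle():
    return json.loads((FIXTURES / "fixtures.json").read_text())


# ---------------------------------------------------------------------------
# Independent oracles, deliberately naive: plain path-walking and recursion,
# no shared code with the implementation under test.


def patristic_oracle(tree, a: str, b: str) -> float:
    """Path-sum distance via explicit root-paths."""
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}

    def root_path(node):
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        return path

    pa, pb = root_path(leaves[a]), root_path(leaves[b])
    shared = {id(n) for n in pa} & {id(n) for n in pb}
    dist = 0.0
    for path in (pa, pb):
        for node in path:
            if id(node) not in shared:
                dist += node.edge.length or 0.0
    return dist


def pd_oracle(tree, taxa, include_root=True) -> float:
    """Faith's PD as an explicit union of root-to-tip edge sets."""
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    paths = {}
    for lab in taxa:
        node, path = leaves[lab], []
        while node.parent_node is not None:
            path.append(node)
            node = node.parent_node
        paths[lab] = path
    union = {id(n): n for p in paths.values() for n in p}
    if not include_root:
        shared = set.intersection(*({id(n) for n in p} for p in paths.values()))
        union = {k: v for k, v in union.items() if k not in shared}
    return sum(n.edge.length or 0.0 for n in union.values())


def mntd_oracle(tree, set_a, set_b) -> float:
    """All-pairs nearest-distance average (include_zero policy)."""
    terms = []
    for a in set_a:
        terms.append(min(patristic_oracle(tree, a, b) if a != b else 0.0 for b in set_b))
    for b in set_b:
        terms.append(min(patristic_oracle(tree, b, a) if a != b else 0.0 for a in set_a))
    return sum(terms) / len(terms)


def sigma_d_oracle(tree, states: dict) -> float:
    """Naive recursive sum of sister-clade differences with Felsenstein
    branch-length-weighted nodal averaging (independent of TreeArrays)."""

    def walk(node):
        # returns (nodal value, adjusted edge length, running sigma_d)
        if node.is_leaf():
            return float(states[node.taxon.label]), node.edge.length or 0.0, 0.0
        (x1, v1, s1), (x2, v2, s2) = (walk(c) for c in node.child_nodes())
        sd = s1 + s2 + abs(x1 - x2)
        if v1 == 0.0 and v2 == 0.0:
            x, extra = (x1 + x2) / 2.0, 0.0
        elif v1 == 0.0:
            x, extra = x1, 0.0
        elif v2 == 0.0:
            x, extra = x2, 0.0
        else:
            w1 = (1.0 / v1) / (1.0 / v1 + 1.0 / v2)
            x = w1 * x1 + (1.0 - w1) * x2
            extra = v1 * v2 / (v1 + v2)
        edge = (node.edge.length or 0.0) + extra if node.parent_node is not None else 0.0
        return x, edge, sd

    return walk(tree.seed_node)[2]
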