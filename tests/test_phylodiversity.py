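"""Faith's PD, patristic distances, and MNTD with its permutation null."""

import itertools

import numpy as np
import pytest
from scipy import stats

from ethnosignal import (
    faith_pd,
    mntd_between,
    mntd_pvalue,
    patristic_matrix,
    pd_percent,
    simulate_yule_tree,
    tip_labels,
)

from conftest import FOUR_TIP, parse, mntd_oracle, patristic_oracle, pd_oracle


def test_patristic_hand_values(four_tip_tree):
    d = patristic_matrix(four_tip_tree)
    assert d.loc["A", "B"] == pytest.approx(2.0)
    assert d.loc["A", "C"] == pytest.approx(4.0)
    assert (np.diag(d) == 0).all()


@pytest.mark.parametrize("seed", range(20))
def test_patristic_matches_path_sum_oracle(seed):
    tree = simulate_yule_tree(15, seed=seed)
    d = patristic_matrix(tree)
    labels = list(d.index)
    rng = np.random.default_rng(seed)
    for a, b in zip(rng.choice(labels, 10), rng.choice(labels, 10)):
        expected = 0.0 if a == b else patristic_oracle(tree, a, b)
        assert d.loc[a, b] == pytest.approx(expected, abs=1e-9)


def test_patristic_ultrametric_through_root():
    tree = parse("((A:1,B:1):1,(C:1,D:1):1);")
    d = patristic_matrix(tree)
    for a, b in [("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")]:
        assert d.loc[a, b] == pytest.approx(4.0)  # twice the root height


def test_faith_pd_hand_values(four_tip_tree):
    assert faith_pd(four_tip_tree, {"A", "B"}) == pytest.approx(3.0)
    assert faith_pd(four_tip_tree, {"A", "B", "C", "D"}) == pytest.approx(6.0)
    assert pd_percent(four_tip_tree, {"A", "B", "C", "D"}) == pytest.approx(100.0)
    assert pd_percent(four_tip_tree, {"A"}) == pytest.approx(100 * 2 / 6)
    assert faith_pd(four_tip_tree, {"A", "B"}, include_root=False) == pytest.approx(2.0)


def test_faith_pd_unknown_taxon(four_tip_tree):
    with pytest.raises(ValueError, match="X"):
        faith_pd(four_tip_tree, {"A", "X"})


@pytest.mark.parametrize("seed", range(25))
@pytest.mark.parametrize("include_root", [True, False])
def test_faith_pd_matches_edge_union_oracle(seed, include_root):
    tree = simulate_yule_tree(20, seed=seed)
    labels = list(tip_labels(tree))
    rng = np.random.default_rng(seed)
    for size in (2, 5, 11, 20):
        taxa = set(rng.choice(labels, size=size, replace=False))
        assert faith_pd(tree, taxa, include_root=include_root) == pytest.approx(
            pd_oracle(tree, taxa, include_root=include_root), abs=1e-9
        )


def test_faith_pd_monotone_under_taxon_addition():
    tree = simulate_yule_tree(30, seed=4)
    labels = list(tip_labels(tree))
    rng = np.random.default_rng(4)
    order = list(rng.permutation(labels))
    values = [faith_pd(tree, set(order[: k + 1])) for k in range(len(order))]
    assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
    pcts = [pd_percent(tree, set(order[: k + 1])) for k in range(0, 30, 5)]
    assert all(b >= a - 1e-12 for a, b in zip(pcts, pcts[1:]))


def test_fixture_oracle_values(mntd50_tree, fixture_oracle):
    d = patristic_matrix(mntd50_tree)
    for key, expected in fixture_oracle["patristic"].items():
        a, b = key.split("|")
        assert d.loc[a, b] == pytest.approx(expected, abs=1e-9)
    set1 = set(fixture_oracle["set1"])
    assert faith_pd(mntd50_tree, set1) == pytest.approx(fixture_oracle["pd_set1_root"])
    assert faith_pd(mntd50_tree, set1, include_root=False) == pytest.approx(
        fixture_oracle["pd_set1_noroot"]
    )
    assert faith_pd(mntd50_tree, set(d.index)) == pytest.approx(fixture_oracle["pd_all"])
    assert mntd_between(d, set1, set(fixture_oracle["set2"])) == pytest.approx(
        fixture_oracle["mntd_set1_set2"]
    )


def test_mntd_hand_values(four_tip_tree):
    d = patristic_matrix(four_tip_tree)
    assert mntd_between(d, {"A", "B"}, {"C", "D"}) == pytest.approx(4.0)
    assert mntd_between(d, {"A", "B"}, {"A", "B"}) == 0.0
    assert mntd_between(d, {"A", "B"}, {"A", "C"}) == pytest.approx((0 + 2 + 0 + 4) / 4)


def test_mntd_exclude_policy(four_tip_tree):
    d = patristic_matrix(four_tip_tree)
    # shared species A skips its self-match:
    # A->C (4), B->A (2) | A->B (2), C->A or B (4)
    value = mntd_between(d, {"A", "B"}, {"A", "C"}, conspecific_policy="exclude")
    assert value == pytest.approx((4 + 2 + 2 + 4) / 4)
    with pytest.raises(ValueError, match="exclude"):
        mntd_between(d, {"A"}, {"A"}, conspecific_policy="exclude")


@pytest.mark.parametrize("seed", range(10))
def test_mntd_symmetric_and_matches_oracle(seed, mntd50_tree):
    labels = list(tip_labels(mntd50_tree))
    rng = np.random.default_rng(seed)
    a = set(rng.choice(labels, size=6, replace=False))
    b = set(rng.choice(labels, size=9, replace=False))
    d = patristic_matrix(mntd50_tree)
    assert mntd_between(d, a, b) == pytest.approx(mntd_between(d, b, a))
    assert mntd_between(d, a, b) == pytest.approx(mntd_oracle(mntd50_tree, a, b), abs=1e-9)


def test_pd_and_mntd_scale_linearly(mntd50_tree):
    scaled = mntd50_tree.clone(depth=1)
    for node in scaled.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = (node.edge.length or 0.0) * 3.0
    labels = list(tip_labels(mntd50_tree))
    taxa = set(labels[:8])
    other = set(labels[20:30])
    assert faith_pd(scaled, taxa) == pytest.approx(3.0 * faith_pd(mntd50_tree, taxa))
    d1, d3 = patristic_matrix(mntd50_tree), patristic_matrix(scaled)
    assert mntd_between(d3, taxa, other) == pytest.approx(
        3.0 * mntd_between(d1, taxa, other)
    )


def test_mntd_pvalue_exhaustive_tiny_pool(four_tip_tree):
    """Pool of 4 choose 2 = 6 subsets: the Monte Carlo p-value must sit at the
    plus-one-corrected enumeration rank."""
    d = patristic_matrix(four_tip_tree)
    focal = {"A", "B"}
    other = {"C", "D"}
    pool = {"A", "B", "C", "D"}
    observed = mntd_between(d, focal, other)
    exact = [
        mntd_between(d, focal, set(sub)) for sub in itertools.combinations(sorted(pool), 2)
    ]
    exact_p = (sum(v <= observed for v in exact)) / len(exact)
    res = mntd_pvalue(d, focal, other, pool, n_rand=6000, seed=2)
    assert res.p_value == pytest.approx(exact_p, abs=0.03)


def test_mntd_pvalue_degenerate_pool_warns(four_tip_tree):
    d = patristic_matrix(four_tip_tree)
    with pytest.warns(UserWarning, match="degenerate"):
        res = mntd_pvalue(d, {"A", "B"}, {"C", "D"}, {"C", "D"}, n_rand=10, seed=0)
    assert res.p_value == 1.0


def test_mntd_pvalue_detects_adjacent_category(mntd50_tree):
    """A category directly adjacent to the focal set against a tree-wide pool
    should be detected as significantly similar."""
    labels = list(tip_labels(mntd50_tree))
    d = patristic_matrix(mntd50_tree)
    # nearest neighbours of the focal tips = most similar possible category
    focal = set(labels[:6])
    nearest = set()
    for t in focal:
        ranked = d.loc[t].drop(list(focal)).sort_values()
        nearest.add(ranked.index[0])
    pool = set(labels) - focal
    res = mntd_pvalue(d, focal, nearest, pool, n_rand=400, seed=5)
    assert res.p_value < 0.05


def test_pd_and_mntd_agree_with_picante(mntd50_tree, fixture_oracle, tmp_path):
    """Cross-check PD and between-set MNTD against the R package picante
    (an independent reference implementation) on the 50-tip fixture."""
    import subprocess

    import pandas as pd

    set1, set2 = fixture_oracle["set1"], fixture_oracle["set2"]
    labels = sorted(tip_labels(mntd50_tree))
    comm = pd.DataFrame(0, index=["c1", "c2"], columns=labels)
    comm.loc["c1", set1] = 1
    comm.loc["c2", set2] = 1
    comm.to_csv(tmp_path / "comm.csv")
    (tmp_path / "tree.nwk").write_text(
        mntd50_tree.as_string(schema="newick", suppress_rooting=True)
    )
    script = f"""
    suppressMessages({{library(picante); library(ape)}})
    tr <- read.tree("{tmp_path}/tree.nwk")
    comm <- as.matrix(read.csv("{tmp_path}/comm.csv", row.names=1, check.names=FALSE))
    pdres <- pd(comm, tr, include.root=TRUE)
    cd <- comdistnt(comm, cophenetic(tr), exclude.conspecifics=FALSE)
    cat(pdres$PD[1], pdres$PD[2], as.numeric(cd), "\\n")
    """
    (tmp_path / "check.R").write_text(script)
    out = subprocess.run(
        ["Rscript", str(tmp_path / "check.R")], capture_output=True, text=True, timeout=120
    )
    assert out.returncode == 0, out.stderr
    pd1, pd2, mntd = (float(x) for x in out.stdout.split())
    assert faith_pd(mntd50_tree, set(set1)) == pytest.approx(pd1, rel=1e-5)
    assert faith_pd(mntd50_tree, set(set2)) == pytest.approx(pd2, rel=1e-5)
    d = patristic_matrix(mntd50_tree)
    assert mntd_between(d, set(set1), set(set2)) == pytest.approx(mntd, rel=1e-5)


def test_mntd_pvalue_null_uniformity(mntd50_tree):
    """When `other` really is a uniform draw from the pool, the p-value is
    uniform on its attainable grid."""
    labels = list(tip_labels(mntd50_tree))
    d = patristic_matrix(mntd50_tree)
    focal = set(labels[:8])
    pool = labels[8:]
    rng = np.random.default_rng(12)
    pvals = []
    for i in range(200):
        other = set(rng.choice(pool, size=6, replace=False))
        pvals.append(
            mntd_pvalue(d, focal, other, set(pool), n_rand=99, seed=1000 + i).p_value
        )
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.005
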