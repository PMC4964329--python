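"""The D statistic: sigma_d, its two nulls, and the scaled statistic."""

import itertools

import numpy as np
import pytest

from ethnosignal import (
    InsufficientVariationError,
    TreeArrays,
    brownian_threshold_null,
    d_statistic,
    permutation_null,
    simulate_brownian_threshold_trait,
    simulate_random_trait,
    simulate_yule_tree,
    sum_sister_differences,
    tip_labels,
)

from conftest import FOUR_TIP, parse, sigma_d_oracle


def test_sigma_d_hand_examples(four_tip_tree):
    # equal branch lengths: weighted and unweighted averaging coincide
    assert sum_sister_differences(four_tip_tree, {"A": 1, "B": 1, "C": 0, "D": 0}) == pytest.approx(1.0)
    assert sum_sister_differences(four_tip_tree, {"A": 1, "B": 0, "C": 1, "D": 0}) == pytest.approx(2.0)
    assert sum_sister_differences(four_tip_tree, {"A": 0, "B": 0, "C": 0, "D": 0}) == 0.0
    assert sum_sister_differences(four_tip_tree, {"A": 1, "B": 1, "C": 1, "D": 1}) == 0.0


def test_sigma_d_rejects_bad_states(four_tip_tree):
    with pytest.raises(ValueError, match="binary"):
        sum_sister_differences(four_tip_tree, {"A": 2, "B": 0, "C": 0, "D": 0})
    with pytest.raises(ValueError, match="missing"):
        sum_sister_differences(four_tip_tree, {"A": 1, "B": 0, "C": 0})


@pytest.mark.parametrize("seed", range(100))
def test_sigma_d_matches_naive_recursive_oracle(seed):
    tree = simulate_yule_tree(10, seed=seed)
    tips = tip_labels(tree)
    rng = np.random.default_rng(seed)
    states = {t: int(s) for t, s in zip(tips, rng.integers(0, 2, size=10))}
    assert sum_sister_differences(tree, states) == pytest.approx(
        sigma_d_oracle(tree, states), abs=1e-12
    )


@pytest.mark.parametrize("seed", range(10))
def test_d_invariant_to_state_relabeling(seed):
    tree = simulate_yule_tree(30, seed=seed)
    tips = tip_labels(tree)
    states = simulate_random_trait(tips, 0.4, seed=seed)
    flipped = {t: 1 - s for t, s in states.items()}
    assert sum_sister_differences(tree, states) == pytest.approx(
        sum_sister_differences(tree, flipped), abs=1e-12
    )


def test_permutation_null_exhaustive_distribution(four_tip_tree):
    """Two of four tips in state 1: the shuffle distribution over the 6
    arrangements must match exhaustive enumeration."""
    states = {"A": 1, "B": 1, "C": 0, "D": 0}
    exact = []
    for ones in itertools.combinations("ABCD", 2):
        exact.append(sum_sister_differences(four_tip_tree, {t: int(t in ones) for t in "ABCD"}))
    exact = np.array(exact)
    samples = permutation_null(four_tip_tree, states, n_perm=6000, seed=3)
    for value in np.unique(exact):
        expected = (exact == value).mean()
        observed = (np.isclose(samples, value)).mean()
        se = np.sqrt(expected * (1 - expected) / 6000)
        assert abs(observed - expected) < 4 * se


def test_permutation_null_constant_and_deterministic(four_tip_tree):
    const = permutation_null(four_tip_tree, {"A": 0, "B": 0, "C": 0, "D": 0}, 50, seed=1)
    assert (const == 0).all()
    a = permutation_null(four_tip_tree, {"A": 1, "B": 0, "C": 1, "D": 0}, 100, seed=9)
    b = permutation_null(four_tip_tree, {"A": 1, "B": 0, "C": 1, "D": 0}, 100, seed=9)
    assert (a == b).all()


def test_brownian_null_on_star_tree_matches_permutation():
    """Equidistant independent tips make the thresholded trait exchangeable,
    so the Brownian and permutation null means agree."""
    star = parse("((" + ",".join(f"T{i}:1" for i in range(6)) + "):0,("
                 + ",".join(f"T{i}:1" for i in range(6, 12)) + "):0);")
    from ethnosignal import resolve_polytomies

    star = resolve_polytomies(star, seed=0)
    states = {f"T{i}": int(i < 4) for i in range(12)}
    sd_b = brownian_threshold_null(star, k_ones=4, n_sim=5000, seed=5)
    sd_r = permutation_null(star, states, n_perm=5000, seed=6)
    se = np.sqrt(sd_b.var() / 5000 + sd_r.var() / 5000)
    assert abs(sd_b.mean() - sd_r.mean()) < 4 * se


def test_brownian_null_zero_length_cherry_ties():
    """Sister tips on zero-length terminal edges receive identical Brownian
    values; random tie-breaking still produces valid k-of-n traits."""
    tree = parse("((A:0,B:0):1,(C:1,D:1):1);")
    arrays = TreeArrays(tree)
    vals = arrays.brownian_tips(200, np.random.default_rng(0))
    ia = arrays.tip_labels.index("A")
    ib = arrays.tip_labels.index("B")
    assert np.allclose(vals[:, ia], vals[:, ib])
    sd = brownian_threshold_null(tree, k_ones=2, n_sim=200, seed=1)
    assert sd.shape == (200,)


def test_d_statistic_definition_and_pvalues():
    tree = simulate_yule_tree(80, seed=2)
    tips = tip_labels(tree)
    states = simulate_random_trait(tips, 0.3, seed=3)
    res = d_statistic(tree, states, n_perm=400, n_sim=400, seed=4)
    expected_d = (res.sigma_d_obs - res.sigma_d_brownian.mean()) / (
        res.sigma_d_random.mean() - res.sigma_d_brownian.mean()
    )
    assert res.d == pytest.approx(expected_d)
    assert res.p_d_lt_1 == ((res.sigma_d_random <= res.sigma_d_obs).sum() + 1) / 401
    assert res.p_d_gt_0 == ((res.sigma_d_brownian >= res.sigma_d_obs).sum() + 1) / 401
    assert 1 / 401 <= res.p_d_lt_1 <= 1
    assert 1 / 401 <= res.p_d_gt_0 <= 1


def test_d_statistic_insufficient_variation(four_tip_tree):
    with pytest.raises(InsufficientVariationError):
        d_statistic(four_tip_tree, {"A": 1, "B": 0, "C": 0, "D": 0})
    with pytest.raises(InsufficientVariationError):
        d_statistic(four_tip_tree, {"A": 1, "B": 1, "C": 1, "D": 1})


def test_unweighted_nodal_mode_runs():
    tree = simulate_yule_tree(40, seed=8)
    tips = tip_labels(tree)
    states = simulate_random_trait(tips, 0.25, seed=9)
    res = d_statistic(tree, states, n_perm=200, n_sim=200, seed=10, nodal="unweighted")
    assert np.isfinite(res.d)


def test_d_calibration_small_scale():
    """Mean D over replicate traits: ~1 for random, ~0 for Brownian-threshold
    (quick version of the full-scale calibration check)."""
    tree = simulate_yule_tree(100, seed=21)
    arrays = TreeArrays(tree)
    tips = list(arrays.tip_labels)
    d_random, d_brownian = [], []
    for i in range(40):
        tr = simulate_random_trait(tips, 0.25, seed=300 + i)
        d_random.append(
            d_statistic(arrays, [tr[t] for t in tips], n_perm=250, n_sim=250, seed=i).d
        )
        bt = simulate_brownian_threshold_trait(arrays, 25, seed=700 + i)
        d_brownian.append(
            d_statistic(arrays, [bt[t] for t in tips], n_perm=250, n_sim=250, seed=1000 + i).d
        )
    assert abs(np.mean(d_random) - 1.0) < 0.15
    assert abs(np.mean(d_brownian)) < 0.15
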