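"""Checkerboard swaps, permutation chains and null-model verdicts."""

import numpy as np
import pytest
from conftest import checkerboard_count_oracle, random_flock_matrix

import flocknet as fn
from flocknet.nullmodel import count_checkerboards


def fm_from(m, site="m"):
    m = np.asarray(m, dtype=np.int8)
    return fn.FlockMatrix(site, tuple(f"s{j}" for j in range(m.shape[1])),
                          tuple(f"F{i}" for i in range(m.shape[0])), m)


def test_swap_flips_the_only_checkerboard():
    m = np.array([[1, 0], [0, 1]])
    out, swapped = fn.checkerboard_swap(m, np.random.default_rng(0))
    assert swapped
    np.testing.assert_array_equal(out, [[0, 1], [1, 0]])


def test_swap_flags_when_no_checkerboard_exists():
    m = np.ones((2, 2), dtype=int)
    out, swapped = fn.checkerboard_swap(m, np.random.default_rng(0))
    assert not swapped
    np.testing.assert_array_equal(out, m)


def test_swap_preserves_margins_and_is_involutive():
    rng = np.random.default_rng(1)
    for _ in range(20):
        m = (rng.random((6, 5)) < 0.5).astype(int)
        out, swapped = fn.checkerboard_swap(m, rng)
        np.testing.assert_array_equal(out.sum(0), m.sum(0))
        np.testing.assert_array_equal(out.sum(1), m.sum(1))
        if swapped:
            diff = np.argwhere(out != m)
            assert len(diff) == 4  # exactly one 2x2 flip
            # flipping the same cells again restores the original
            again = out.copy()
            again[diff[:, 0], diff[:, 1]] = 1 - again[diff[:, 0], diff[:, 1]]
            np.testing.assert_array_equal(again, m)


def test_count_checkerboards_matches_bruteforce():
    rng = np.random.default_rng(2)
    for _ in range(30):
        m = (rng.random((5, 6)) < rng.uniform(0.2, 0.8)).astype(int)
        assert count_checkerboards(m) == checkerboard_count_oracle(m)


@pytest.mark.parametrize("proposal", ["metropolis", "lazy", "retry"])
def test_chain_preserves_margins_and_is_deterministic(proposal):
    rng = np.random.default_rng(3)
    fm = random_flock_matrix(rng, n_flocks=10, n_species=6)
    states = list(fn.permutation_chain(fm, 200, np.random.default_rng(5),
                                       proposal=proposal))
    for s in states:
        np.testing.assert_array_equal(s.sum(0), fm.incidence.sum(0))
        np.testing.assert_array_equal(s.sum(1), fm.incidence.sum(1))
    replay = list(fn.permutation_chain(fm, 200, np.random.default_rng(5),
                                       proposal=proposal))
    np.testing.assert_array_equal(np.stack(states), np.stack(replay))


def test_chain_argument_validation(toy_fm):
    with pytest.raises(ValueError):
        list(fn.permutation_chain(toy_fm, 0))
    with pytest.raises(ValueError):
        list(fn.permutation_chain(toy_fm, 10, proposal="bogus"))
    with pytest.raises(ValueError):
        list(fn.permutation_chain(toy_fm, 10, burn_in=-1))


def test_frozen_matrix_chain_reproduces_observed_metrics():
    """A matrix with no checkerboard never moves: nulls equal the observed."""
    fm = fm_from(np.ones((3, 3)))
    assert count_checkerboards(fm.incidence) == 0
    ens = fn.null_metric_distribution(fm, ["cv"], n_perm=5, seed=0)
    obs = fn.network_cv(fn.build_network(fm))
    np.testing.assert_allclose(ens.null_values["cv"], obs)


def test_null_distribution_rejects_unknown_metric(toy_fm):
    with pytest.raises(ValueError, match="unknown metric"):
        fn.null_metric_distribution(toy_fm, ["betweenness"], n_perm=2, seed=0)


def test_null_distribution_reproducible(toy_fm):
    rng = np.random.default_rng(8)
    fm = random_flock_matrix(rng, n_flocks=8, n_species=6)
    a = fn.null_metric_distribution(fm, ["cv", "connectance"], n_perm=50, seed=4)
    b = fn.null_metric_distribution(fm, ["cv", "connectance"], n_perm=50, seed=4)
    np.testing.assert_array_equal(a.null_values["cv"], b.null_values["cv"])
    assert a.missing_counts() == b.missing_counts()


@pytest.mark.parametrize("observed, nulls, expected", [
    (5.0, [1, 2, 3], 0.0),           # above every null
    (0.5, [1, 2, 3], 1.0),           # below every null
    (50.0, list(range(100)), 0.49),  # 49 of 100 distinct nulls are larger
])
def test_upper_tail_pvalue_counting(observed, nulls, expected):
    assert fn.upper_tail_pvalue(observed, nulls) == pytest.approx(expected)


def test_upper_tail_pvalue_ties_not_counted():
    assert fn.upper_tail_pvalue(1.0, [1.0, 1.0, 2.0]) == pytest.approx(1 / 3)


def test_envelope_verdicts():
    nulls = np.linspace(0, 1, 1000)
    assert fn.envelope_verdict(2.0, nulls) == "higher"
    assert fn.envelope_verdict(-1.0, nulls) == "lower"
    assert fn.envelope_verdict(0.5, nulls) == "within"
    assert fn.envelope_verdict(0.99, nulls) == "higher"   # above 97.5th pct
    assert fn.envelope_verdict(0.01, nulls) == "lower"


def test_assess_network_small_site():
    rng = np.random.default_rng(12)
    fm = fn.generate_site(fn.SyntheticConfig(n_species=10, n_flocks=20,
                                             affinity=1.0), rng=rng)
    res = fn.assess_network(fm, n_perm=100, seed=9)
    assert 0.0 <= res.cv_pvalue <= 1.0
    assert res.cv_significant == (res.cv_pvalue < 0.05)
    assert set(res.envelope_verdicts) == {
        "avg_degree_norm", "connectance", "modularity_q", "clustering"}
    assert all(v in {"lower", "within", "higher", "undefined"}
               for v in res.envelope_verdicts.values())
    with pytest.raises(ValueError):
        fn.assess_network(fm, n_perm=0)


def test_metropolis_chain_uniform_on_tiny_class():
    """3x3, margins all 1 (permutation matrices): 6 states, uniform visits."""
    fm = fm_from(np.eye(3, dtype=int) + np.roll(np.eye(3, dtype=int), 1, axis=1))
    # margins are all 2; enumerate the reachable class by brute force
    from itertools import product
    mats = [np.array(bits).reshape(3, 3) for bits in product([0, 1], repeat=9)]
    target = [m for m in mats
              if (m.sum(0) == fm.incidence.sum(0)).all()
              and (m.sum(1) == fm.incidence.sum(1)).all()]
    counts = {m.tobytes(): 0 for m in np.asarray(target, dtype=np.int8)}
    for s in fn.permutation_chain(fm, 30_000, np.random.default_rng(17)):
        counts[s.tobytes()] += 1
    freqs = np.array(list(counts.values()))
    assert (freqs > 0).all()  # every fixed-margin matrix reached
    from scipy.stats import chisquare
    assert chisquare(freqs).pvalue > 0.001
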