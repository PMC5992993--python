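"""Symbol statistics and the G-test battery.

Every G statistic is checked against a brute-force re-evaluation of its
defining formula on raw count tables, built here with plain dictionaries
and explicit loops, independent of the package's vectorized counting.
"""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microstates import (LabelProcessSpec, LabelSequence,
                         geometric_lifetime_gtest, lifetime_distribution,
                         max_entropy, shannon_entropy, symbol_distribution,
                         synth_labels, transition_matrix)
from microstates import test_geometric_lifetimes as geometric_tests
from microstates import test_markov0 as markov0_test
from microstates import test_markov1 as markov1_test
from microstates import test_markov2 as markov2_test
from microstates import test_stationarity as stationarity_test
from microstates import test_symmetry as symmetry_test

# ---------------------------------------------------------------------------
# brute-force oracles (dict counting + explicit sums)
# ---------------------------------------------------------------------------

def brute_g0(x):
    pairs = Counter(zip(x[:-1], x[1:]))
    fi = Counter(x[:-1])
    fj = Counter(x[1:])
    n = len(x) - 1
    return 2.0 * sum(f * math.log(n * f / (fi[i] * fj[j]))
                     for (i, j), f in pairs.items())


def brute_g1(x):
    trip = Counter(zip(x[:-2], x[1:-1], x[2:]))
    fij = Counter((i, j) for i, j, _ in trip.elements())
    fjk = Counter((j, k) for _, j, k in trip.elements())
    fj = Counter(j for _, j, _ in trip.elements())
    return 2.0 * sum(f * math.log(f * fj[j] / (fij[i, j] * fjk[j, k]))
                     for (i, j, k), f in trip.items())


def brute_g2(x):
    quad = Counter(zip(x[:-3], x[1:-2], x[2:-1], x[3:]))
    fijk = Counter((i, j, k) for i, j, k, _ in quad.elements())
    fjkl = Counter((j, k, l) for _, j, k, l in quad.elements())
    fjk = Counter((j, k) for _, j, k, _ in quad.elements())
    return 2.0 * sum(f * math.log(f * fjk[j, k] / (fijk[i, j, k] * fjkl[j, k, l]))
                     for (i, j, k, l), f in quad.items())


def brute_g3(x, block_len):
    r = len(x) // block_len
    f = Counter()
    for b in range(r):
        xb = x[b * block_len:(b + 1) * block_len]
        for i, j in zip(xb[:-1], xb[1:]):
            f[b, i, j] += 1
    pooled = Counter((i, j) for _, i, j in f.elements())
    src_block = Counter((b, i) for b, i, _ in f.elements())
    src_total = Counter(i for _, i, _ in f.elements())
    return 2.0 * sum(
        c * math.log(c * src_total[i] / (src_block[b, i] * pooled[i, j]))
        for (b, i, j), c in f.items())


def brute_g4(x):
    pairs = Counter(zip(x[:-1], x[1:]))
    return 2.0 * sum(f * math.log(2 * f / (f + pairs[j, i]))
                     for (i, j), f in pairs.items() if i != j)


def random_sequence(seed, n=2000, ns=4):
    rng = np.random.default_rng(seed)
    return LabelSequence(rng.integers(0, ns, n), n_s=ns)


# ---------------------------------------------------------------------------
# basic statistics
# ---------------------------------------------------------------------------

class TestSymbolDistribution:
    def test_uniform_example(self):
        seq = LabelSequence([0, 1, 2, 3], n_s=4)
        assert symbol_distribution(seq).tolist() == [0.25] * 4

    def test_unvisited_states(self):
        seq = LabelSequence([0, 0, 0], n_s=4)
        assert symbol_distribution(seq).tolist() == [1.0, 0, 0, 0]

    def test_sums_to_one(self):
        assert symbol_distribution(random_sequence(0)).sum() == pytest.approx(1.0)


class TestTransitionMatrix:
    def test_alternating(self):
        model = transition_matrix(LabelSequence([0, 1, 0, 1, 0], n_s=2))
        assert np.allclose(model.T, [[0, 1], [1, 0]])
        assert np.array_equal(model.counts, [[0, 2], [2, 0]])

    def test_absorbing(self):
        model = transition_matrix(LabelSequence([0, 0, 0], n_s=2))
        assert model.T[0].tolist() == [1.0, 0.0]

    def test_unvisited_state_uniform_and_flagged(self):
        model = transition_matrix(LabelSequence([0, 0, 0], n_s=3))
        assert model.uniform_rows == (1, 2)
        assert np.allclose(model.T[1], 1 / 3)

    def test_rows_stochastic(self):
        model = transition_matrix(random_sequence(1))
        assert np.allclose(model.T.sum(axis=1), 1.0, atol=1e-12)


class TestEntropy:
    def test_delta_is_zero(self):
        assert shannon_entropy([1.0, 0, 0, 0]) == 0.0

    def test_uniform_four(self):
        assert shannon_entropy([0.25] * 4) == pytest.approx(math.log(4))

    def test_fair_coin(self):
        assert shannon_entropy([0.5, 0.5]) == pytest.approx(math.log(2))

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy([1.2, -0.2])

    @pytest.mark.parametrize("n_s,expected", [(4, math.log(4)), (1, 0.0),
                                              (2, math.log(2))])
    def test_max_entropy(self, n_s, expected):
        assert max_entropy(n_s) == pytest.approx(expected)

    def test_max_entropy_invalid(self):
        with pytest.raises(ValueError):
            max_entropy(0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(0, 3), min_size=2, max_size=200))
    def test_sequence_entropy_bounded(self, labels):
        seq = LabelSequence(labels, n_s=4)
        h = shannon_entropy(symbol_distribution(seq))
        assert 0.0 <= h <= max_entropy(4) + 1e-12


# ---------------------------------------------------------------------------
# G statistics vs brute force
# ---------------------------------------------------------------------------

class TestGAgainstBruteForce:
    @pytest.mark.parametrize("seed", range(3))
    @pytest.mark.parametrize("ns", [2, 3, 4])
    def test_all_statistics(self, seed, ns):
        seq = random_sequence(10 * seed + ns, n=1500, ns=ns)
        x = seq.labels.tolist()
        assert markov0_test(seq).statistic == pytest.approx(brute_g0(x), abs=1e-10)
        assert markov1_test(seq).statistic == pytest.approx(brute_g1(x), abs=1e-10)
        assert markov2_test(seq).statistic == pytest.approx(brute_g2(x), abs=1e-10)
        assert stationarity_test(seq, 300).statistic == pytest.approx(
            brute_g3(x, 300), abs=1e-10)
        assert symmetry_test(seq).statistic == pytest.approx(brute_g4(x), abs=1e-10)

    def test_dof_four_states(self, markov_seq):
        assert markov0_test(markov_seq).dof == 9
        assert markov1_test(markov_seq).dof == 36
        assert markov2_test(markov_seq).dof == 144
        assert symmetry_test(markov_seq).dof == 6
        # 48000 samples at block 5000 -> 9 blocks -> (9-1)*3*4
        seq = LabelSequence(markov_seq.labels[:48000], n_s=4)
        assert stationarity_test(seq, 5000).dof == 96


class TestMarkov0:
    def test_balanced_pairs_give_zero(self):
        # de Bruijn-style tiling: every pair equally frequent
        x = [0, 0, 1, 1] * 100 + [0]
        res = markov0_test(LabelSequence(x, n_s=2))
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)

    def test_alternating_rejected(self):
        x = [0, 1] * 500
        res = markov0_test(LabelSequence(x, n_s=2))
        assert res.p < 1e-6
        assert res.statistic == pytest.approx(brute_g0(x), abs=1e-10)


class TestLifetimes:
    def test_run_histogram(self):
        dist = lifetime_distribution(LabelSequence([0, 0, 1, 0], n_s=2), 0)
        assert dist.m == 2
        assert dist.p_emp.tolist() == [0.5, 0.5]
        assert dist.n_runs == 2

    def test_geometric_model_values(self):
        # T_00 = 0.5 -> q(1) = 0.5, q(2) = 0.25
        seq = LabelSequence([0, 0, 1, 0, 1, 0, 0, 1], n_s=2)
        dist = lifetime_distribution(seq, 0)
        t00 = transition_matrix(seq).T[0, 0]
        assert dist.q_geom[0] == pytest.approx(1 - t00)
        assert dist.q_geom[1] == pytest.approx((1 - t00) * t00)

    def test_constant_sequence_single_run(self):
        dist = lifetime_distribution(LabelSequence([1, 1, 1, 1], n_s=2), 1)
        assert dist.n_runs == 1 and dist.m == 4

    def test_absent_state_errors(self):
        with pytest.raises(ValueError):
            lifetime_distribution(LabelSequence([0, 0, 0], n_s=2), 1)

    def test_exact_geometric_gives_zero(self):
        from microstates.markov_stats import LifetimeDistribution
        q = np.array([0.5, 0.25, 0.125, 0.0625])
        dist = LifetimeDistribution(state=0, m=4, p_emp=q / q.sum(),
                                    q_geom=q, n_runs=100)
        assert geometric_lifetime_gtest(dist).statistic == pytest.approx(0.0, abs=1e-12)

    def test_fixed_run_length_rejected(self):
        spec = LabelProcessSpec(mode="semi_markov", n_states=4,
                                T=np.full((4, 4), 0.25),
                                lifetime=("fixed", 5), seed=0)
        seq = synth_labels(spec, 10_000)
        for res in geometric_tests(seq):
            assert res.p < 1e-6


class TestStationarity:
    def test_regime_change_rejected(self, chain_T):
        a = synth_labels(LabelProcessSpec(mode="markov", n_states=4,
                                          T=chain_T, seed=1), 10_000)
        # second regime: shuffled rows -> different transition structure
        T2 = chain_T[[1, 2, 3, 0]]
        b = synth_labels(LabelProcessSpec(mode="markov", n_states=4,
                                          T=T2, seed=2), 10_000)
        seq = LabelSequence(np.concatenate([a.labels, b.labels]), n_s=4)
        assert stationarity_test(seq, 5000).p < 1e-6

    def test_too_few_blocks(self):
        with pytest.raises(ValueError):
            stationarity_test(random_sequence(3, n=100), 80)


class TestSymmetry:
    def test_symmetric_counts_accept(self):
        res = symmetry_test(LabelSequence([0, 1, 0, 1, 0], n_s=2))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_deterministic_cycle_rejected(self):
        x = [0, 1, 2] * 300
        res = symmetry_test(LabelSequence(x, n_s=3))
        assert res.p < 1e-6
        assert res.statistic == pytest.approx(brute_g4(x), abs=1e-10)


class TestHigherOrderAlternatives:
    def test_second_order_rule_rejected_by_markov1(self):
        # next symbol determined by the pair two steps back: clearly 2nd order
        rng = np.random.default_rng(7)
        ns = 3
        tables = np.zeros((ns, ns, ns))
        for i, j in itertools.product(range(ns), range(ns)):
            tables[i, j, (i + j) % ns] = 0.9
            tables[i, j, (i + j + 1) % ns] = 0.1
        spec = LabelProcessSpec(mode="higher_order", n_states=ns,
                                tables=tables, seed=int(rng.integers(2**31)))
        seq = synth_labels(spec, 20_000)
        assert markov1_test(seq).p < 1e-6

    def test_third_order_rule_rejected_by_markov2(self):
        # next symbol depends deterministically on x[t-3]
        rng = np.random.default_rng(8)
        x = np.zeros(20_000, dtype=int)
        x[:3] = rng.integers(0, 2, 3)
        noise = rng.random(20_000)
        for t in range(3, len(x)):
            x[t] = x[t - 3] if noise[t] < 0.9 else 1 - x[t - 3]
        assert markov2_test(LabelSequence(x, n_s=2)).p < 1e-6


class TestInvariances:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_relabeling_invariance(self, seed):
        seq = random_sequence(seed, n=3000)
        perm = np.random.default_rng(seed).permutation(4)
        relabeled = LabelSequence(perm[seq.labels], n_s=4)
        for fn in (markov0_test, markov1_test, markov2_test, symmetry_test):
            assert fn(seq).statistic == pytest.approx(
                fn(relabeled).statistic, abs=1e-9)
        assert stationarity_test(seq, 500).statistic == pytest.approx(
            stationarity_test(relabeled, 500).statistic, abs=1e-9)

    def test_symmetry_time_reversal_invariance(self):
        seq = random_sequence(5, n=3000)
        rev = LabelSequence(seq.labels[::-1], n_s=4)
        assert symmetry_test(seq).statistic == pytest.approx(
            symmetry_test(rev).statistic, abs=1e-9)

    def test_statistics_nonnegative(self, markov_seq):
        sub = LabelSequence(markov_seq.labels[:20_000], n_s=4)
        for fn in (markov0_test, markov1_test, markov2_test, symmetry_test):
            assert fn(sub).statistic >= 0.0
        assert stationarity_test(sub, 2000).statistic >= 0.0
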