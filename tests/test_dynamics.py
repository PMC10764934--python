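import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capdyn.dynamics import (
    dwell_and_occurrence,
    dynamic_profile,
    entropy_rate,
    estimate_transition_matrix,
    stationary_distribution,
    trajectory_entropy,
)


def enumerate_trajectory_entropy(p, i, j, tail_mass=1e-12):
    """Independent oracle: entropy of the path ensemble from i to first hit
    of j, by exact prefix aggregation.

    Tracks, per length and current (non-target) state s, the total
    probability A[s] and the accumulated sum B[s] = sum over those prefixes
    of p * log2(p); completed trajectories (those stepping into j) contribute
    exactly. This enumerates every trajectory without pruning, aggregated by
    endpoint, and runs until the not-yet-absorbed mass is below tail_mass.
    """
    k = p.shape[0]
    log2p = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    a = np.zeros(k)
    b = np.zeros(k)
    a[i] = 1.0  # empty prefix starting at i
    h = 0.0  # accumulated -sum p log2 p over completed trajectories
    for _ in range(100_000):
        # completions: step from any s to the target j
        h -= (b * p[:, j] + a * p[:, j] * log2p[:, j]).sum()
        # extensions to non-target states
        a_new = np.zeros(k)
        b_new = np.zeros(k)
        for s2 in range(k):
            if s2 == j:
                continue
            a_new[s2] = (a * p[:, s2]).sum()
            b_new[s2] = (b * p[:, s2] + a * p[:, s2] * log2p[:, s2]).sum()
        a, b = a_new, b_new
        if a.sum() < tail_mass:
            break
    return h


def random_irreducible_chain(k, rng, floor=0.05):
    p = rng.dirichlet(np.ones(k), size=k)
    p = np.maximum(p, floor)
    return p / p.sum(axis=1, keepdims=True)


class TestDwellOccurrence:
    def test_single_run_sequence(self):
        dwell, total, occ = dwell_and_occurrence(np.zeros(240, dtype=int), 1, 2.0)
        assert dwell[0] == 480.0 and total[0] == 480.0 and occ[0] == 1.0

    def test_hand_enumerated_runs(self):
        dwell, total, occ = dwell_and_occurrence(np.array([0, 0, 1, 1, 0]), 2, 2.0)
        assert dwell[0] == pytest.approx(3.0)  # runs (2, 1) -> mean 1.5 frames
        assert total[0] == pytest.approx(6.0)
        assert occ[0] == pytest.approx(0.6)
        assert dwell[1] == pytest.approx(4.0) and total[1] == pytest.approx(4.0)
        assert occ[1] == pytest.approx(0.4)

    def test_unvisited_cap_missing_dwell_zero_occurrence(self):
        dwell, total, occ = dwell_and_occurrence(np.array([0, 0, 0]), 2, 2.0)
        assert np.isnan(dwell[1]) and total[1] == 0.0 and occ[1] == 0.0

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            dwell_and_occurrence(np.array([0, 3]), 2, 2.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(0, 4), min_size=2, max_size=200),
        st.floats(0.5, 3.0),
    )
    def test_conservation_properties(self, labels, tr):
        seq = np.array(labels)
        dwell, total, occ = dwell_and_occurrence(seq, 5, tr)
        assert total.sum() == pytest.approx(seq.size * tr, rel=1e-12)
        assert occ.sum() == pytest.approx(1.0, rel=1e-12)
        # dwell * n_runs == total, exactly, per visited CAP
        runs = np.concatenate(([True], np.diff(seq) != 0))
        for c in range(5):
            n_runs = (runs & (seq == c)).sum()
            if n_runs:
                assert dwell[c] * n_runs == pytest.approx(total[c], rel=1e-12)


class TestTransitionMatrix:
    def test_hand_counted_transitions(self):
        counts, p = estimate_transition_matrix(np.array([0, 0, 1, 1, 0]), 2)
        assert np.array_equal(counts, [[1, 1], [1, 1]])
        assert np.allclose(p, 0.5)

    def test_constant_sequence_missing_rows(self):
        counts, p = estimate_transition_matrix(np.zeros(10, dtype=int), 3)
        assert p[0, 0] == 1.0
        assert np.isnan(p[1]).all() and np.isnan(p[2]).all()

    def test_asymmetry_preserved(self):
        _, p = estimate_transition_matrix(np.array([0, 1, 1, 0, 1]), 2)
        assert p[0, 1] != p[1, 0]

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 3), min_size=2, max_size=300))
    def test_counts_sum_and_row_stochasticity(self, labels):
        seq = np.array(labels)
        counts, p = estimate_transition_matrix(seq, 4)
        assert counts.sum() == seq.size - 1
        visited_rows = counts.sum(axis=1) > 0
        assert np.allclose(p[visited_rows].sum(axis=1), 1.0, atol=1e-12)
        assert np.isnan(p[~visited_rows]).all()


class TestStationary:
    def test_symmetric_two_state(self):
        mu = stationary_distribution(np.array([[0.5, 0.5], [0.5, 0.5]]))
        np.testing.assert_allclose(mu, [0.5, 0.5])

    def test_hand_solved_two_state(self):
        mu = stationary_distribution(np.array([[0.9, 0.1], [0.5, 0.5]]))
        np.testing.assert_allclose(mu, [5 / 6, 1 / 6], atol=1e-12)

    def test_permutation_cycle_uniform(self):
        p = np.roll(np.eye(3), 1, axis=1)
        np.testing.assert_allclose(stationary_distribution(p), np.full(3, 1 / 3), atol=1e-12)

    def test_reducible_chain_rejected_with_classes(self):
        p = np.array([[1.0, 0.0], [0.5, 0.5]])
        with pytest.raises(ValueError, match="reducible"):
            stationary_distribution(p)


class TestTrajectoryEntropy:
    def test_deterministic_cycle_is_zero(self):
        p = np.roll(np.eye(4), 1, axis=1)
        h = trajectory_entropy(p)
        assert np.abs(h).max() < 1e-12

    def test_symmetric_two_state_is_two_bits(self):
        h = trajectory_entropy(np.array([[0.5, 0.5], [0.5, 0.5]]))
        np.testing.assert_allclose(h, 2.0, atol=1e-12)

    def test_two_state_off_diagonal_closed_form(self):
        # H_12 = h_1 / P_12 for a 2-state chain
        a, b = 0.3, 0.6
        p = np.array([[1 - a, a], [b, 1 - b]])
        h = trajectory_entropy(p)
        h1 = -(1 - a) * np.log2(1 - a) - a * np.log2(a)
        assert h[0, 1] == pytest.approx(h1 / a, rel=1e-12)

    def test_return_entropy_identity(self):
        """H_jj = H(P)/mu_j (first-return decomposition) on random chains."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = random_irreducible_chain(5, rng)
            h = trajectory_entropy(p)
            mu = stationary_distribution(p)
            hp = entropy_rate(p)
            assert np.abs(np.diag(h) - hp / mu).max() < 1e-9

    @pytest.mark.parametrize("k", [2, 3])
    def test_against_enumeration_oracle(self, k):
        rng = np.random.default_rng(k)
        for _ in range(5):
            p = random_irreducible_chain(k, rng, floor=0.1)
            h = trajectory_entropy(p)
            for i in range(k):
                for j in range(k):
                    if i == j:
                        continue
                    ho = enumerate_trajectory_entropy(p, i, j)
                    assert h[i, j] == pytest.approx(ho, abs=1e-3)

    def test_substochastic_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            trajectory_entropy(np.array([[0.5, 0.4], [0.5, 0.5]]))

    def test_reducible_rejected(self):
        p = np.array([[1.0, 0.0], [0.3, 0.7]])
        with pytest.raises(ValueError, match="reducible"):
            trajectory_entropy(p)


class TestDynamicProfile:
    def test_unvisited_state_entries_missing(self):
        seq = np.array([0, 1, 0, 1, 1, 0])
        prof = dynamic_profile("s", seq, k=3)
        assert not prof.visited[2]
        assert np.isnan(prof.transition[2]).all()
        assert np.isnan(prof.trajectory_entropy[2]).all()
        assert np.isnan(prof.trajectory_entropy[:, 2]).all()
        assert np.isfinite(prof.trajectory_entropy[:2, :2]).all()

    def test_monotone_dwell_with_self_transition(self):
        """Raising a state's generating self-transition raises its estimated
        mean dwell time (long chains, several seeds)."""
        from capdyn.synthetic import simulate_chain

        def mean_dwell(self_prob, seed):
            p = np.full((2, 2), 0.0)
            p[0] = [self_prob, 1 - self_prob]
            p[1] = [0.5, 0.5]
            seq = simulate_chain(p, 10_000, np.random.default_rng(seed))
            dwell, _, _ = dwell_and_occurrence(seq, 2, 1.0)
            return dwell[0]

        for seed in range(3):
            assert mean_dwell(0.8, seed) > mean_dwell(0.5, seed)
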