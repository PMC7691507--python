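"""Wright-Fisher drift core: exact distributions, simulation, closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from driftlik.wf import (
    PopulationSpec,
    compound_distribution,
    compound_pmf_matrix,
    drift_variance,
    grid_scan,
    nearest_count,
    simulate_trajectories,
    transition_matrix,
    transition_pmf,
)


def tvd(p, q):
    return 0.5 * np.abs(np.asarray(p) - np.asarray(q)).sum()


class TestTransitionPmf:
    def test_binomial_by_hand(self):
        np.testing.assert_allclose(
            transition_pmf(0.5, 4), np.array([1, 4, 6, 4, 1]) / 16
        )

    def test_absorbing_boundary(self):
        pmf = transition_pmf(0.0, 84)
        assert pmf[0] == 1.0 and pmf[1:].sum() == 0.0

    def test_mean_copy_count(self):
        pmf = transition_pmf(0.3, 84)
        assert np.dot(pmf, np.arange(85)) == pytest.approx(25.2)

    @pytest.mark.parametrize("p,M", [(-0.1, 84), (1.1, 84), (0.5, 0)])
    def test_rejects_bad_domain(self, p, M):
        with pytest.raises(ValueError):
            transition_pmf(p, M)


class TestCompoundDistribution:
    def test_two_step_enumeration(self):
        # independent oracle: build the 3x3 one-step matrix from binomial
        # coefficients by hand, square it, apply to the point mass at k0=1
        M = 2
        T = np.zeros((3, 3))
        for j in range(3):
            for k in range(3):
                p = j / M
                T[j, k] = math.comb(M, k) * p**k * (1 - p) ** (M - k)
        expected = (np.array([0.0, 1.0, 0.0]) @ T) @ T
        np.testing.assert_allclose(expected, [3 / 8, 1 / 4, 3 / 8])
        d = compound_distribution(1, PopulationSpec(copies_autosome=2, n_steps=2))
        np.testing.assert_allclose(d.pmf, expected, atol=1e-14)

    def test_loss_is_absorbing(self):
        d = compound_distribution(0, PopulationSpec(n_steps=50))
        assert d.pmf[0] == 1.0

    def test_one_step_reduces_to_binomial(self):
        d = compound_distribution(42, PopulationSpec(n_steps=1))
        np.testing.assert_allclose(d.pmf, transition_pmf(0.5, 84), atol=1e-14)

    def test_zero_steps_is_point_mass(self):
        d = compound_distribution(10, PopulationSpec(n_steps=0))
        assert d.pmf[10] == 1.0 and d.pmf.sum() == 1.0

    def test_x_linked_uses_half_copies(self):
        d = compound_distribution(10, PopulationSpec(n_steps=5), x_linked=True)
        assert d.copies == 42 and len(d.pmf) == 43

    def test_out_of_range_k0(self):
        with pytest.raises(ValueError):
            compound_distribution(85, PopulationSpec())

    def test_matches_matrix_power_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(12):
            M = int(rng.integers(2, 101))
            G = int(rng.integers(1, 101))
            k0 = int(rng.integers(0, M + 1))
            d = compound_distribution(
                k0, PopulationSpec(copies_autosome=M, n_steps=G)
            )
            oracle = np.linalg.matrix_power(transition_matrix(M), G)[k0]
            assert np.abs(d.pmf - oracle).max() < 1e-10

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        M=st.integers(2, 60),
        G=st.integers(0, 40),
        k0frac=st.floats(0, 1),
    )
    def test_normalization_martingale_absorption(self, M, G, k0frac):
        k0 = min(int(k0frac * M), M)
        spec = PopulationSpec(copies_autosome=M, n_steps=G)
        d = compound_distribution(k0, spec)
        assert abs(d.pmf.sum() - 1.0) < 1e-12
        assert (d.pmf >= 0).all()
        # drift is a martingale: mean frequency stays at p0
        assert abs(d.mean_frequency() - k0 / M) < 1e-10
        # mass in the absorbing states never decreases with extra steps
        d_next = compound_distribution(
            k0, PopulationSpec(copies_autosome=M, n_steps=G + 1)
        )
        assert d_next.loss_mass >= d.loss_mass - 1e-12
        assert d_next.fixation_mass >= d.fixation_mass - 1e-12


class TestDriftVariance:
    def test_closed_form_value(self):
        spec = PopulationSpec(n_steps=63)
        assert drift_variance(0.5, spec) == pytest.approx(
            0.25 * (1 - (83 / 84) ** 63)
        )

    def test_single_generation_is_binomial_variance(self):
        assert drift_variance(0.3, PopulationSpec(n_steps=1)) == pytest.approx(
            0.21 / 84
        )

    def test_zero_at_boundaries(self):
        spec = PopulationSpec(n_steps=10)
        assert drift_variance(0.0, spec) == 0.0
        assert drift_variance(1.0, spec) == 0.0

    @pytest.mark.parametrize("M,G,k0", [(84, 63, 42), (84, 10, 25), (42, 20, 7)])
    def test_matches_distribution_variance(self, M, G, k0):
        spec = PopulationSpec(copies_autosome=M, n_steps=G)
        d = compound_distribution(k0, spec)
        assert abs(d.variance_frequency() - drift_variance(k0 / M, spec)) < 1e-10


class TestSimulation:
    def test_loss_start_stays_lost(self):
        ts = simulate_trajectories(0, PopulationSpec(n_steps=10), 50, seed=0)
        assert (ts.trajectories == 0).all()

    def test_absorbed_rows_stay_absorbed(self):
        ts = simulate_trajectories(5, PopulationSpec(n_steps=40), 500, seed=1)
        traj = ts.trajectories
        for boundary in (0, ts.copies):
            hit = traj == boundary
            # once a row hits the boundary every later state equals it
            first = np.where(hit.any(axis=1), hit.argmax(axis=1), traj.shape[1])
            for i, f in enumerate(first):
                assert (traj[i, f:] == boundary).all() or f == traj.shape[1]

    def test_final_histogram_near_analytic(self):
        spec = PopulationSpec(n_steps=63)
        ts = simulate_trajectories(25, spec, 20_000, seed=2)
        analytic = compound_distribution(25, spec).pmf
        assert tvd(ts.final_histogram(), analytic) < 0.05

    def test_mean_within_three_standard_errors(self):
        spec = PopulationSpec(n_steps=63)
        ts = simulate_trajectories(25, spec, 50_000, seed=3)
        f = ts.final_frequencies
        se = f.std() / np.sqrt(len(f))
        assert abs(f.mean() - 25 / 84) < 3 * se

    def test_reproducible_given_seed(self):
        a = simulate_trajectories(10, PopulationSpec(n_steps=5), 100, seed=7)
        b = simulate_trajectories(10, PopulationSpec(n_steps=5), 100, seed=7)
        np.testing.assert_array_equal(a.trajectories, b.trajectories)


class TestGridScan:
    def test_default_grid_has_fifty_sets(self):
        sets = grid_scan(PopulationSpec(n_steps=1), n_reps=10, seed=0)
        assert len(sets) == 50

    def test_single_point_grid(self):
        sets = grid_scan(
            PopulationSpec(n_steps=1), p0_start=0.5, p0_end=0.5, n_reps=10, seed=0
        )
        assert len(sets) == 1

    def test_lowest_frequency_rounds_to_one_copy(self):
        assert nearest_count(0.01, 84) == 1  # 0.84 rounds to 1

    def test_ties_round_half_up(self):
        assert nearest_count(0.5, 3) == 2

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_scan(PopulationSpec(n_steps=1), p0_step=-0.01)

    def test_deterministic_given_seed(self):
        a = grid_scan(PopulationSpec(n_steps=2), p0_end=0.03, n_reps=50, seed=5)
        b = grid_scan(PopulationSpec(n_steps=2), p0_end=0.03, n_reps=50, seed=5)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.trajectories, y.trajectories)
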