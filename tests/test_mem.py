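import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_params
from energylandscape.mem import (
    MEMParams,
    all_patterns,
    all_state_energies,
    boltzmann_distribution,
    empirical_distribution,
    empirical_moments,
    fit_accuracy,
    fit_mem,
    pattern_code,
    pattern_decode,
    state_energy,
)
from energylandscape.synthetic import sample_mem_series

#: ceiling on max|J_fit - J_true| for 1e5 exact samples, frozen from a
#: 10-seed repetition of the recovery experiment (observed max 0.013)
J_RECOVERY_TOL = 0.02


class TestPatternCode:
    def test_all_inactive_and_all_active(self):
        assert pattern_code(-np.ones(7)) == 0
        assert pattern_code(np.ones(7)) == 127

    def test_bijection_k7(self):
        for c in range(128):
            assert pattern_code(pattern_decode(c, 7)) == c

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            pattern_code(np.array([1, 0, -1]))
        with pytest.raises(ValueError):
            pattern_decode(128, 7)


class TestEmpiricalMoments:
    def test_all_active(self):
        m1, m2 = empirical_moments(np.ones((5, 3)))
        np.testing.assert_allclose(m1, 1.0)
        np.testing.assert_allclose(m2, 1.0)

    def test_anticorrelated_pair(self):
        x = np.array([[1, -1], [-1, 1], [1, -1]])
        _, m2 = empirical_moments(x)
        assert m2[0, 1] == -1.0

    def test_hand_toy(self):
        x = np.array([[1, 1], [1, -1], [-1, 1], [1, 1]])
        m1, m2 = empirical_moments(x)
        np.testing.assert_allclose(m1, [0.5, 0.5])
        assert m2[0, 1] == 0.0
        np.testing.assert_allclose(np.diag(m2), 1.0)


class TestStateEnergy:
    def test_zero_params_zero_energy(self):
        p = MEMParams(h=np.zeros(3), J=np.zeros((3, 3)))
        for v in all_patterns(3):
            assert state_energy(v, p) == 0.0

    def test_single_network_field(self):
        p = MEMParams(h=np.array([0.7]), J=np.zeros((1, 1)))
        assert state_energy(np.array([1]), p) == pytest.approx(-0.7)

    def test_k2_aligned_coupling(self):
        j = 0.4
        p = MEMParams(h=np.zeros(2), J=np.array([[0, j], [j, 0]]))
        assert state_energy(np.array([1, 1]), p) == pytest.approx(-j)
        assert state_energy(np.array([1, -1]), p) == pytest.approx(j)

    def test_asymmetric_j_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            MEMParams(h=np.zeros(2), J=np.array([[0, 1.0], [0.5, 0]]))


class TestBoltzmannDistribution:
    def test_uniform_at_zero_params(self):
        p = boltzmann_distribution(MEMParams(h=np.zeros(7), J=np.zeros((7, 7))))
        np.testing.assert_allclose(p, 1 / 128)

    def test_k2_closed_form(self):
        j = 0.8
        p = boltzmann_distribution(MEMParams(h=np.zeros(2), J=np.array([[0, j], [j, 0]])))
        expected_aligned = np.exp(j) / (2 * np.exp(j) + 2 * np.exp(-j))
        assert p[3] == pytest.approx(expected_aligned)
        assert p[0] == pytest.approx(expected_aligned)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_normalized_and_offset_invariant(self, seed):
        rng = np.random.default_rng(seed)
        params = random_params(5, rng)
        p = boltzmann_distribution(params)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        # shifting all energies by a constant (via the h/J-independent
        # normalization) leaves probabilities unchanged
        e = all_state_energies(params)
        w = np.exp(-(e + 123.4 - (e + 123.4).min()))
        np.testing.assert_allclose(p, w / w.sum(), atol=1e-12)

    def test_flip_symmetry_with_zero_h(self, rng):
        params = random_params(5, rng)
        params = MEMParams(h=np.zeros(5), J=params.J)
        p = boltzmann_distribution(params)
        np.testing.assert_allclose(p, p[::-1], atol=1e-14)  # code c <-> complement


class TestFitMem:
    def test_uniform_data_gives_zero_params(self):
        # every pattern exactly once: empirical moments are all zero
        values = all_patterns(5)
        params, report = fit_mem(values)
        assert report.converged
        np.testing.assert_allclose(params.h, 0.0, atol=1e-4)
        np.testing.assert_allclose(params.J, 0.0, atol=1e-4)

    def test_recovery_from_exact_samples(self):
        rng = np.random.default_rng(0)
        true = random_params(7, rng)
        bts = sample_mem_series(true, 100_000, seed=100, mode="iid")
        fitted, report = fit_mem(bts.values)
        assert report.converged
        assert report.r > 0.99
        assert np.abs(fitted.J - true.J).max() < J_RECOVERY_TOL

    def test_moments_reproduced_within_tol(self):
        rng = np.random.default_rng(3)
        true = random_params(7, rng)
        bts = sample_mem_series(true, 20_000, seed=103, mode="iid")
        fitted, report = fit_mem(bts.values, tol=1e-5)
        emp1, emp2 = empirical_moments(bts.values)
        p = boltzmann_distribution(fitted)
        s = all_patterns(7).astype(float)
        np.testing.assert_allclose(s.T @ p, emp1, atol=2e-5)
        np.testing.assert_allclose((s * p[:, None]).T @ s, emp2, atol=2e-5)

    def test_two_learning_rates_agree(self):
        rng = np.random.default_rng(5)
        true = random_params(5, rng)
        bts = sample_mem_series(true, 5_000, seed=105, mode="iid")
        p1, r1 = fit_mem(bts.values, learning_rate=0.2, tol=1e-6)
        p2, r2 = fit_mem(bts.values, learning_rate=0.05, tol=1e-6)
        assert r1.converged and r2.converged
        assert np.abs(p1.J - p2.J).max() < 1e-5 * 10
        assert np.abs(p1.h - p2.h).max() < 1e-5 * 10

    def test_recovery_error_decreases_with_t(self):
        rng = np.random.default_rng(1)
        true = random_params(7, rng)
        errs = []
        for t in (10**3, 10**4, 10**5):
            bts = sample_mem_series(true, t, seed=50 + t, mode="iid")
            fitted, _ = fit_mem(bts.values)
            errs.append(np.abs(fitted.J - true.J).max())
        assert errs[0] > errs[1] > errs[2]

    def test_constant_network_rejected(self):
        values = np.ones((300, 3), dtype=int)
        values[::2, 1] = -1
        values[::3, 2] = -1
        with pytest.raises(ValueError, match="constant"):
            fit_mem(values)

    def test_nonconvergence_flagged(self):
        rng = np.random.default_rng(2)
        true = random_params(5, rng)
        bts = sample_mem_series(true, 2_000, seed=52, mode="iid")
        _, report = fit_mem(bts.values, max_iter=3)
        assert not report.converged
        assert report.max_discrepancy > 0


class TestFitAccuracy:
    def test_near_perfect_fit_accuracy_one(self):
        # K=2 pairwise MEM is saturated (3 params, 3 dof), so the fit can
        # match any interior empirical distribution exactly: D2 -> 0
        x = np.array([[1, 1]] * 9 + [[1, -1]] + [[-1, 1]] + [[-1, -1]] * 9)
        params, report = fit_mem(x, tol=1e-9)
        assert report.accuracy_defined
        assert report.accuracy > 0.999
        assert report.d2 < 1e-6

    def test_independent_data_flagged_undefined(self):
        # exact product distribution: all four K=2 patterns equally often
        x = all_patterns(2)
        x = np.repeat(x, 25, axis=0)
        params, _ = fit_mem(x)
        report = fit_accuracy(params, x)
        assert not report.accuracy_defined

    def test_strongly_coupled_model_high_accuracy(self):
        j = 1.0
        true = MEMParams(h=np.zeros(7), J=np.full((7, 7), j) - j * np.eye(7))
        bts = sample_mem_series(true, 50_000, seed=9, mode="iid")
        params, report = fit_mem(bts.values)
        assert report.accuracy > 0.9

    def test_empirical_distribution_sums_to_one(self, rng):
        x = rng.choice([-1, 1], size=(500, 4))
        p = empirical_distribution(x)
        assert p.sum() == pytest.approx(1.0)
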