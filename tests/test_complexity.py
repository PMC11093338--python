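"""TAP solutions, metastable counting, coupling statistics and SK diagnostics."""

import numpy as np
import pytest

import spikemaxent as sm

from conftest import random_pairwise


def sk_model(n, j0, j1, seed, with_fields=False):
    spec = sm.GroundTruthSpec(n_neurons=n, structure="sk_ensemble", J0=j0,
                              J1=j1, seed=seed, rate_sd_hz=0.0)
    model = sm.make_model(spec)
    h = model.h if with_fields else np.zeros(n)
    return sm.PairwiseModel(h, model.J)


class TestSolveTap:
    def test_decoupled_fixed_point(self):
        h = np.array([0.3, -0.7, 1.2])
        sol = sm.solve_tap(sm.PairwiseModel(h, np.zeros((3, 3))))
        assert sol.converged
        assert np.abs(sol.m - np.tanh(h)).max() < 1e-9

    def test_two_spin_unique_zero_solution(self):
        # h = 0, J = 0.2: grid scan of the 2-d damped map confirms a unique
        # fixed point at the origin; the solver must land there from anywhere
        model = sm.PairwiseModel(np.zeros(2), np.array([[0, 0.2], [0.2, 0]]))
        for init in ([0.9, 0.9], [-0.8, 0.5], [0.1, -0.9]):
            sol = sm.solve_tap(model, np.array(init))
            assert sol.converged
            assert np.abs(sol.m).max() < 1e-8
        # brute-force check on a grid: no other approximate fixed point
        g = np.linspace(-0.95, 0.95, 39)
        mx, my = np.meshgrid(g, g)
        arg1 = 0.2 * my - mx * 0.04 * (1 - my**2)
        arg2 = 0.2 * mx - my * 0.04 * (1 - mx**2)
        defect = np.maximum(np.abs(mx - np.tanh(arg1)), np.abs(my - np.tanh(arg2)))
        assert np.all(defect[(np.abs(mx) > 0.1) | (np.abs(my) > 0.1)] > 1e-3)

    def test_weak_coupling_init_independent(self):
        model = random_pairwise(10, seed=1, j_scale=0.03, h_loc=0.2)
        rng = np.random.default_rng(2)
        sols = [sm.solve_tap(model, rng.uniform(-1, 1, 10)).m for _ in range(10)]
        for s in sols[1:]:
            assert np.abs(s - sols[0]).max() < 1e-8

    def test_invalid_damping_rejected(self):
        model = random_pairwise(3, seed=3)
        with pytest.raises(ValueError):
            sm.solve_tap(model, damping=1.0)

    def test_nonconvergence_is_reported_not_raised(self):
        model = sk_model(16, 0, 3.0, seed=4)
        sol = sm.solve_tap(model, np.full(16, 0.5), damping=0.0, max_iter=50)
        assert isinstance(sol.converged, (bool, np.bool_))


class TestCountMetastable:
    def test_uncoupled_single_solution(self):
        model = sm.PairwiseModel(np.array([0.5, -0.3, 0.1]), np.zeros((3, 3)))
        rep = sm.count_metastable(model, n_inits=20, seed=0)
        assert rep.n_ms == 1
        assert rep.sigma == 0.0

    def test_strong_sk_sample_has_multiple_verified_solutions(self):
        # a strongly coupled SK draw whose TAP equations carry glassy roots
        model = sk_model(32, 0, 2.0, seed=0)
        rep = sm.count_metastable(model, n_inits=80, seed=1)
        assert rep.n_ms >= 2
        assert max(rep.meta["center_residuals"]) < 1e-9

    def test_discovery_monotone_in_inits(self):
        model = sk_model(24, 0, 1.5, seed=5)
        a = sm.count_metastable(model, n_inits=20, seed=3)
        b = sm.count_metastable(model, n_inits=40, seed=3)
        assert (b.n_ms or 0) >= (a.n_ms or 0)


class TestCouplingStatistics:
    def test_direct_arithmetic(self):
        J = np.zeros((3, 3))
        J[np.triu_indices(3, 1)] = [1.0, 2.0, 3.0]
        model = sm.PairwiseModel(np.zeros(3), J + J.T)
        rep = sm.coupling_statistics(model)
        assert rep.mean_j == pytest.approx(2.0)
        assert rep.std_j == pytest.approx(np.sqrt(2 / 3))
        assert rep.f == pytest.approx(np.sqrt(2 / 3) / 2)
        assert rep.j0_hat == pytest.approx(6.0)
        assert rep.j1_hat == pytest.approx(np.sqrt(3) * np.sqrt(2 / 3))

    def test_equal_couplings_zero_f(self):
        J = np.full((4, 4), 0.3)
        np.fill_diagonal(J, 0.0)
        rep = sm.coupling_statistics(sm.PairwiseModel(np.zeros(4), J))
        assert rep.std_j == 0.0 and rep.f == 0.0

    def test_zero_mean_flagged_infinite(self):
        J = np.zeros((3, 3))
        J[0, 1] = J[1, 0] = 0.5
        J[0, 2] = J[2, 0] = -0.5
        rep = sm.coupling_statistics(sm.PairwiseModel(np.zeros(3), J))
        assert np.isinf(rep.f)
        assert rep.flags

    def test_sk_parameter_estimators_consistent(self):
        # Ĵ0 = N·mean and Ĵ1 = √N·std recover the generating SK parameters
        j0s, j1s = [], []
        for seed in range(30):
            rep = sm.coupling_statistics(sk_model(200, 1.0, 0.5, seed=seed))
            j0s.append(rep.j0_hat)
            j1s.append(rep.j1_hat)
        assert abs(np.mean(j0s) - 1.0) < 3 * np.std(j0s) / np.sqrt(30)
        assert abs(np.mean(j1s) - 0.5) < 3 * np.std(j1s) / np.sqrt(30) + 1e-3


class TestStabilityAndSusceptibility:
    def test_zero_magnetization_gives_unit_s(self):
        model = sk_model(10, 0, 0.5, seed=6)
        tap = sm.TapSolution(np.zeros(10), True, 0.0, 1)
        mom = sm.Moments(np.zeros(10), np.eye(10))
        rep = sm.stability_and_susceptibility(model, tap, mom)
        assert rep.s_quantity == pytest.approx(1.0)
        assert rep.stability == pytest.approx(rep.j1_hat**2)

    def test_nonconverged_tap_rejected(self):
        model = sk_model(5, 0, 0.5, seed=7)
        tap = sm.TapSolution(np.zeros(5), False, 1.0, 10)
        with pytest.raises(ValueError, match="converged"):
            sm.stability_and_susceptibility(model, tap, sm.Moments(np.zeros(5), np.eye(5)))

    def test_independent_data_has_vanishing_chi_sg(self, rng):
        spins = np.where(rng.random((10, 100_000)) < 0.2, 1, -1).astype(np.int8)
        raster = sm.BinaryRaster(spins, 0.02, np.arange(10), np.full(10, 10.0))
        mom = sm.compute_moments(raster)
        model = sk_model(10, 0, 0.1, seed=8)
        tap = sm.solve_tap(model)
        rep = sm.stability_and_susceptibility(model, tap, mom)
        # sum of 90 squared noise terms of size ~1/T
        assert rep.chi_sg < 90 * 9.0 / 100_000 / 10


class TestPredictSkStats:
    def test_generative_recovery(self):
        model = sk_model(64, 0.0, 0.4, seed=9, with_fields=False)
        model = sm.PairwiseModel(np.full(64, -0.5), model.J)
        raster = sm.sample_model(model, 200_000, method="gibbs", seed=10)
        pred = sm.predict_sk_stats(sm.compute_moments(raster))
        target = 0.4 / np.sqrt(64)
        assert abs(pred.predicted_std_j - target) < 0.25 * target
        assert abs(pred.predicted_j1 - 0.4) < 0.25 * 0.4

    def test_zero_correlations_flagged(self):
        mom = sm.Moments(np.zeros(5), np.eye(5))
        pred = sm.predict_sk_stats(mom)
        assert pred.predicted_std_j == 0.0
        assert any("degenerate" in f for f in pred.flags)

    def test_permutation_invariance(self, rng):
        spins = np.where(rng.random((8, 20_000)) < 0.3, 1, -1).astype(np.int8)
        raster = sm.BinaryRaster(spins, 0.02, np.arange(8), np.ones(8))
        mom = sm.compute_moments(raster)
        perm = rng.permutation(8)
        mom_p = sm.compute_moments(raster.subset(perm))
        a = sm.predict_sk_stats(mom)
        b = sm.predict_sk_stats(mom_p)
        assert a.predicted_std_j == pytest.approx(b.predicted_std_j, abs=1e-12)
        assert a.predicted_mean_j == pytest.approx(b.predicted_mean_j, abs=1e-12)


class TestSingleFlipStability:
    def test_uncoupled_model_has_one_stable_state(self):
        model = sm.PairwiseModel(np.array([-1.0, -0.5, 2.0]), np.zeros((3, 3)))
        # unique stable state: each spin aligned with its field
        assert sm.count_single_flip_stable(model) == 1

    def test_strong_ferromagnetic_pair_has_two(self):
        J = np.array([[0, 2.0], [2.0, 0]])
        model = sm.PairwiseModel(np.zeros(2), J)
        assert sm.count_single_flip_stable(model) == 2  # both aligned states


@pytest.fixture(scope="module")
def surrogate_raster():
    spec = sm.GroundTruthSpec(n_neurons=40, coupling_scale=0.1,
                              rate_mean_hz=6.0, rate_sd_hz=1.2, seed=11)
    model = sm.make_model(spec)
    return sm.sample_model(model, 30_000, method="gibbs", seed=12)


class TestComplexityScan:

    def test_scan_shape_and_determinism(self, surrogate_raster):
        a = sm.complexity_scan(surrogate_raster, [10, 20], n_pops_per_n=2,
                               method="nmf", seed=13)
        b = sm.complexity_scan(surrogate_raster, [10, 20], n_pops_per_n=2,
                               method="nmf", seed=13)
        assert len(a) == 4
        assert a.equals(b)

    def test_uncoupled_surrogate_low_stability(self):
        spec = sm.GroundTruthSpec(n_neurons=30, coupling_scale=0.0, seed=14)
        raster = sm.sample_model(sm.make_model(spec), 40_000, method="gibbs",
                                 seed=15)
        scan = sm.complexity_scan(raster, [10, 15], n_pops_per_n=2,
                                  method="nmf", seed=16)
        # inferred couplings are pure sampling noise → stability well below 1
        assert scan["stability"].max() < 0.5

    def test_oversized_population_rejected(self, surrogate_raster):
        with pytest.raises(ValueError, match="exceeds"):
            sm.complexity_scan(surrogate_raster, [100], seed=0)

    def test_extrapolation_utility(self):
        import pandas as pd

        from spikemaxent.complexity import extrapolate_stability_crossing

        scan = pd.DataFrame({"n": [100, 200, 300], "stability": [0.2, 0.4, 0.6]})
        assert extrapolate_stability_crossing(scan) == pytest.approx(500.0)


class TestSkEnsembleScaling:
    def test_std_decays_as_inverse_sqrt_n(self):
        # std(J) = J1/√N: the log-log slope over N ∈ {50, 100, 200} is −1/2
        ns = [50, 100, 200]
        stds = []
        for n in ns:
            vals = [sm.coupling_statistics(sk_model(n, 1.0, 0.8, seed=s)).std_j
                    for s in range(6)]
            stds.append(np.mean(vals))
        slope = np.polyfit(np.log(ns), np.log(stds), 1)[0]
        assert abs(slope + 0.5) < 0.15

    def test_f_grows_with_n_at_fixed_positive_j0(self):
        # mean ~ J0/N shrinks faster than std ~ J1/√N, so f = std/mean grows
        ns = [50, 100, 200]
        fs = []
        for n in ns:
            vals = [sm.coupling_statistics(sk_model(n, 1.0, 0.8, seed=s)).f
                    for s in range(6)]
            fs.append(np.mean(vals))
        assert fs[0] < fs[1] < fs[2]
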