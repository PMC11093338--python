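"""Partition functions, entropies, KL divergences, G, and robustness probes."""

import numpy as np
import pytest

import spikemaxent as sm
from spikemaxent.models import enumerate_states
from spikemaxent.raster import EmpiricalDistribution
from spikemaxent.synthetic import exact_probabilities

from conftest import random_pairwise

ESTIMATORS = ["zhat", "most_sampled", "mean", "median"]


class TestExactPartition:
    def test_single_free_spin(self):
        model = sm.PairwiseModel(np.zeros(1), np.zeros((1, 1)))
        assert np.exp(sm.exact_partition(model).log_z) == pytest.approx(2.0)

    def test_two_spin_closed_form(self):
        J = 0.7
        model = sm.PairwiseModel(np.zeros(2), np.array([[0, J], [J, 0]]))
        z = np.exp(sm.exact_partition(model).log_z)
        assert z == pytest.approx(2 * np.exp(J) + 2 * np.exp(-J))

    def test_null_model_counts_states(self):
        model = sm.PairwiseModel(np.zeros(20), np.zeros((20, 20)))
        assert np.exp(sm.exact_partition(model).log_z) == pytest.approx(2**20)

    def test_size_limit(self):
        model = sm.PairwiseModel(np.zeros(21), np.zeros((21, 21)))
        with pytest.raises(ValueError):
            sm.exact_partition(model)


class TestEstimatePartition:
    @pytest.mark.parametrize("estimator", ESTIMATORS)
    def test_exact_probability_identity(self, estimator):
        # with p_data equal to the model's exact probabilities over all
        # states, every ratio e^{−E}/p equals Z, so all estimators are exact
        model = random_pairwise(7, seed=1, j_scale=0.25)
        p = exact_probabilities(model)
        emp = EmpiricalDistribution.from_probabilities(
            enumerate_states(7, np.int8), p)
        log_z = sm.exact_partition(model).log_z
        est = sm.estimate_partition(model, emp, estimator)
        assert abs(np.exp(est.log_z - log_z) - 1) < 1e-10

    def test_sampled_zhat_is_close(self):
        model = random_pairwise(10, seed=2, j_scale=0.2, h_loc=-1.0)
        raster = sm.sample_model(model, 50_000, seed=3)
        emp = sm.empirical_distribution(raster)
        log_z = sm.exact_partition(model).log_z
        est = sm.estimate_partition(model, emp, "zhat")
        assert abs(np.exp(est.log_z - log_z) - 1) < 0.05

    def test_empty_observed_set_rejected(self):
        model = random_pairwise(3, seed=4)
        emp = EmpiricalDistribution(np.empty((0, 3), dtype=np.int8),
                                    np.empty(0, dtype=np.int64), 0)
        with pytest.raises(ValueError, match="empty|samples"):
            sm.estimate_partition(model, emp)


class TestEntropies:
    def test_null_model_full_entropy(self):
        n = 6
        model = sm.PairwiseModel(np.zeros(n), np.zeros((n, n)))
        mom = sm.Moments(np.zeros(n), np.eye(n))
        s_pair, s_ind = sm.model_entropies(model, sm.IndependentModel(np.zeros(n)),
                                           mom, sm.exact_partition(model))
        assert s_pair == pytest.approx(n * np.log(2))
        assert s_ind == pytest.approx(n * np.log(2))

    def test_single_neuron_closed_form(self):
        h = 0.9
        model = sm.PairwiseModel([h], np.zeros((1, 1)))
        m = np.tanh(h)
        mom = sm.Moments([m], np.ones((1, 1)))
        s_pair, s_ind = sm.model_entropies(model, sm.IndependentModel([h]), mom,
                                           sm.exact_partition(model))
        expected = np.log(2 * np.cosh(h)) - h * np.tanh(h)
        assert s_pair == pytest.approx(expected)
        assert s_ind == pytest.approx(expected)

    def test_independent_bounds_pairwise(self):
        # maximum-entropy ordering: constraining correlations can only reduce entropy
        for seed in range(5):
            model = random_pairwise(6, seed=seed, j_scale=0.3)
            mom = sm.moments_from_probabilities(exact_probabilities(model), 6)
            s_pair, s_ind = sm.model_entropies(model, sm.fit_independent(mom),
                                               mom, sm.exact_partition(model))
            assert s_ind >= s_pair - 1e-10


class TestGoodness:
    def test_perfect_pairwise_fit(self):
        rep = sm.goodness(s_data=1.0, s_ind=1.3, s_pair=1.0)
        assert rep.g == 1.0 and rep.d_pair == 0.0

    def test_pairwise_no_better_than_independent(self):
        rep = sm.goodness(s_data=1.0, s_ind=1.3, s_pair=1.3)
        assert rep.g == 0.0

    def test_negative_g_flagged_not_dropped(self):
        rep = sm.goodness(s_data=1.0, s_ind=1.1, s_pair=1.2)
        assert rep.g < 0
        assert any("outlier" in f for f in rep.flags)

    def test_undefined_when_independent_is_exact(self):
        rep = sm.goodness(s_data=1.0, s_ind=1.0, s_pair=1.0)
        assert np.isnan(rep.g)
        assert any("undefined" in f for f in rep.flags)

    def test_estimated_partition_tagged_as_ghat(self):
        rep = sm.goodness(1.0, 1.3, 1.1, estimator_tag="zhat")
        assert rep.is_estimate

    def test_exact_and_estimated_agree_on_exact_input(self):
        # Ĝ from Ẑ on exact-probability input equals exact G
        model = random_pairwise(6, seed=7, j_scale=0.2)
        p = exact_probabilities(model)
        emp = EmpiricalDistribution.from_probabilities(enumerate_states(6, np.int8), p)
        mom = sm.moments_from_probabilities(p, 6)
        ind = sm.fit_independent(mom)
        s_data = float(-(p * np.log(p)).sum())
        for log_z in (sm.exact_partition(model),
                      sm.estimate_partition(model, emp, "zhat")):
            s_pair, s_ind = sm.model_entropies(model, ind, mom, log_z)
            rep = sm.goodness(s_data, s_ind, s_pair, log_z.estimator_tag)
            assert rep.g == pytest.approx(1.0, abs=1e-9)

    def test_goodness_from_probabilities_matches_entropy_route(self):
        model = random_pairwise(5, seed=8, j_scale=0.25)
        p = exact_probabilities(model)
        mom = sm.moments_from_probabilities(p, 5)
        fit = sm.fit_exact_maxent(mom)
        ind = sm.fit_independent(mom)
        direct = sm.goodness_from_probabilities(p, fit, ind)
        s_pair, s_ind = sm.model_entropies(fit, ind, mom, sm.exact_partition(fit))
        via_entropy = sm.goodness(float(-(p * np.log(p)).sum()), s_ind, s_pair)
        assert direct.g == pytest.approx(via_entropy.g, abs=1e-6)


class TestModelHierarchy:
    def test_kl_decreases_with_moment_order(self):
        # d_triplet ≤ d_pair ≤ d_ind on an enumerable higher-order truth
        p = sm.make_higher_order_truth(5, 0.08, seed=3)
        mom = sm.moments_from_probabilities(p, 5)
        S = enumerate_states(5)
        ind = sm.fit_independent(mom)
        pair = sm.fit_exact_maxent(mom)
        trip = sm.fit_triplet_boltzmann(enumerate_states(5, np.int8), weights=p,
                                        eta=0.1, n_iter=30_000)

        def kl(model, log_z):
            logq = -model.energy(S) - log_z
            nz = p > 0
            return float((p[nz] * (np.log(p[nz]) - logq[nz])).sum())

        d_ind = kl(ind.as_pairwise(), ind.log_z())
        d_pair = kl(pair, sm.exact_partition(pair).log_z)
        d_trip = kl(trip, sm.exact_partition(trip).log_z)
        assert d_trip <= d_pair + 1e-6
        assert d_pair <= d_ind + 1e-10
        assert d_trip < 0.5 * d_pair  # triplet terms capture real structure here


class TestPerturbativeSlope:
    def make_report(self, g, x):
        return sm.EvaluationReport(s_data=0, s_ind=0, s_pair=0, d_pair=0,
                                   d_ind=1, g=g, perturbation_parameter=x)

    def test_perfect_fits_give_zero_slope(self):
        reports = [self.make_report(1.0, x) for x in np.linspace(0.01, 0.4, 8)]
        fit = sm.fit_perturbative_slope(reports, range_max=0.5)
        assert fit.slope == 0.0

    def test_duplicated_points_leave_slope_unchanged(self):
        reports = [self.make_report(1 - 0.3 * x, x)
                   for x in np.linspace(0.05, 0.45, 6)]
        a = sm.fit_perturbative_slope(reports, 0.5)
        b = sm.fit_perturbative_slope(reports + reports, 0.5)
        assert a.slope == pytest.approx(b.slope)
        assert a.slope == pytest.approx(0.3)

    def test_insufficient_points_rejected(self):
        reports = [self.make_report(0.9, 0.1)] * 3
        with pytest.raises(ValueError, match="≥ 5"):
            sm.fit_perturbative_slope(reports, 0.5)

    def test_median_aggregation(self):
        reports = ([self.make_report(1 - 0.2 * x, x) for x in (0.1, 0.2, 0.3, 0.4, 0.45)]
                   + [self.make_report(1 - 0.2 * 0.1, 0.1)] * 2
                   + [self.make_report(0.0, 0.1)])  # one gross outlier, outvoted
        fit = sm.fit_perturbative_slope(reports, 0.5, aggregate="median")
        assert fit.slope == pytest.approx(0.2, abs=1e-9)


@pytest.fixture(scope="module")
def raster():
    model = random_pairwise(5, seed=30, j_scale=0.15, h_loc=-0.8)
    return sm.sample_model(model, 40_000, seed=31)


class TestSubsampleRobustness:

    def test_full_fraction_reproduces_full_data_g(self, raster):
        full_g = sm.evaluate_raster(raster, sm.fit_pseudolikelihood(raster)).g
        table = sm.subsample_robustness(raster, [1.0], seed=0)
        assert table.loc[0, "mean_g"] == pytest.approx(full_g, abs=1e-12)
        assert table.loc[0, "sd_g"] == 0.0

    def test_deterministic_under_seed(self, raster):
        a = sm.subsample_robustness(raster, [0.25, 1.0], n_repeats=3, seed=5)
        b = sm.subsample_robustness(raster, [0.25, 1.0], n_repeats=3, seed=5)
        assert a.equals(b)

    def test_tiny_fraction_rejected(self, raster):
        with pytest.raises(ValueError, match="100"):
            sm.subsample_robustness(raster, [0.001])

    def test_small_fractions_are_noisier(self, raster):
        table = sm.subsample_robustness(raster, [0.05, 1.0], n_repeats=6, seed=7)
        assert table.set_index("fraction").loc[0.05, "sd_g"] >= 0.0
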