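"""Self-contained benchmark experiments exercising the full pipeline.

Each function generates its own synthetic inputs from a seed, runs the
relevant part of the package from scratch, and returns summary numbers:
partition-estimator accuracy, Boltzmann moment matching, pseudo-likelihood
parameter recovery, goodness calibration under pairwise and independent
ground truths, the perturbative decay of G, and the spin-glass diagnostics.
They are used by the acceptance suite and by scripts/acceptance.py; sizes
are arguments so callers can trade precision against runtime.
"""

from __future__ import annotations

import numpy as np

from .complexity import coupling_statistics, count_metastable, solve_tap
from .evaluation import (estimate_partition, evaluate_raster, exact_partition,
                         fit_perturbative_slope, goodness_from_probabilities,
                         moments_from_probabilities)
from .inference import (fit_boltzmann, fit_exact_maxent, fit_independent,
                        fit_pseudolikelihood)
from .models import IndependentModel, PairwiseModel, enumerate_states, triu_indices
from .raster import EmpiricalDistribution, compute_moments, empirical_distribution
from .synthetic import (GroundTruthSpec, exact_probabilities,
                        make_higher_order_truth, make_model, sample_model)

__all__ = [
    "random_sparse_model",
    "partition_identity",
    "partition_estimator_accuracy",
    "boltzmann_moment_matching",
    "pseudolikelihood_recovery",
    "goodness_calibration",
    "closed_form_checks",
    "perturbative_decay",
    "complexity_mechanics",
]


def random_sparse_model(n: int, rng: np.random.Generator,
                        j_max: float = 0.3) -> PairwiseModel:
    """A neural-like random model: sparse activity fields, weak mixed couplings.

    h ~ Normal(−1, 0.5) puts isolated spike probabilities around 10–20%; the
    couplings are uniform on [−j_max, j_max], mirrored across the diagonal.
    """
    h = rng.normal(-1.0, 0.5, n)
    iu = triu_indices(n)
    J = np.zeros((n, n))
    J[iu] = rng.uniform(-j_max, j_max, iu[0].size)
    return PairwiseModel(h, J + J.T)


def partition_identity(n_values=range(2, 13), seed: int = 0) -> dict:
    """Max deviation of Ẑ/Z from 1 when p_data is the exact distribution.

    With the model's exact probabilities over all states standing in for the
    observed frequencies, every ratio e^{−E(ŝ)}/p(ŝ) equals Z, so all four
    estimators must reproduce Z to machine precision.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    count = 0
    for n in n_values:
        model = random_sparse_model(n, rng)
        p = exact_probabilities(model)
        emp = EmpiricalDistribution.from_probabilities(
            enumerate_states(n, np.int8), p)
        log_z = exact_partition(model).log_z
        for est in ("zhat", "most_sampled", "mean", "median"):
            dev = abs(np.exp(estimate_partition(model, emp, est).log_z - log_z) - 1)
            worst = max(worst, dev)
            count += 1
    return {"max_abs_deviation": worst, "n": count}


def partition_estimator_accuracy(n_models: int = 50, n: int = 20,
                                 n_samples: int = 50_000, seed: int = 0) -> dict:
    """Ẑ accuracy from finite samples, against exact enumeration at N = 20.

    For each random model, draws exact samples, estimates Z from the observed
    patterns, and compares with the enumerated Z. Reports the median relative
    error of Ẑ and how often Ẑ beats the most-sampled-state estimator.
    """
    rng = np.random.default_rng(seed)
    errs, wins = [], 0
    for k in range(n_models):
        model = random_sparse_model(n, rng)
        raster = sample_model(model, n_samples,
                              seed=int(rng.integers(2**31 - 1)))
        emp = empirical_distribution(raster)
        log_z = exact_partition(model).log_z
        e_zhat = abs(np.exp(estimate_partition(model, emp, "zhat").log_z - log_z) - 1)
        e_ms = abs(np.exp(
            estimate_partition(model, emp, "most_sampled").log_z - log_z) - 1)
        errs.append(e_zhat)
        wins += e_zhat < e_ms
    return {"median_abs_rel_err": float(np.median(errs)),
            "zhat_win_fraction": wins / n_models, "n": n_models}


def boltzmann_moment_matching(n: int = 8, n_samples: int = 200_000,
                              eta: float = 0.01, n_iter: int = 100_000,
                              n_cases: int = 3, seed: int = 0) -> dict:
    """Exact Boltzmann learning on surrogate data: moment error and KL ordering.

    Fits the pairwise model by plain gradient ascent with exact model moments
    and checks (a) the worst first/second-moment mismatch and (b) that
    d_pair < d_ind holds on every enumerable case.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    orderings = []
    for k in range(n_cases):
        spec = GroundTruthSpec(n_neurons=n, rate_mean_hz=6.27, rate_sd_hz=1.24,
                               coupling_scale=0.1,
                               seed=int(rng.integers(2**31 - 1)))
        raster = sample_model(make_model(spec), n_samples,
                              seed=int(rng.integers(2**31 - 1)))
        mom = compute_moments(raster)
        fit = fit_boltzmann(mom, eta=eta, n_iter=n_iter)
        refit = moments_from_probabilities(exact_probabilities(fit), n)
        iu = triu_indices(n)
        worst = max(worst,
                    float(np.abs(refit.means - mom.means).max()),
                    float(np.abs(refit.correlations[iu]
                                 - mom.correlations[iu]).max()))
        rep = evaluate_raster(raster, fit, estimator="exact")
        orderings.append(rep.d_pair < rep.d_ind)
    return {"max_moment_error": worst,
            "kl_ordering_holds": all(orderings), "n": n_cases}


def pseudolikelihood_recovery(n_models: int = 3, n: int = 10,
                              n_samples: int = 10**6, seed: int = 0) -> dict:
    """Coupling RMSE of pseudo-likelihood on large exact samples, plus the
    weighted-PL consistency check with exact state probabilities."""
    rng = np.random.default_rng(seed)
    rmses = []
    for k in range(n_models):
        model = random_sparse_model(n, rng)
        raster = sample_model(model, n_samples,
                              seed=int(rng.integers(2**31 - 1)))
        fit = fit_pseudolikelihood(raster)
        iu = triu_indices(n)
        rmses.append(float(np.sqrt(np.mean((fit.J[iu] - model.J[iu]) ** 2))))
    # population-level consistency: weights = exact probabilities
    small = random_sparse_model(3, rng)
    p = exact_probabilities(small)
    wfit = fit_pseudolikelihood(enumerate_states(3, np.int8), weights=p)
    werr = max(float(np.abs(wfit.h - small.h).max()),
               float(np.abs(wfit.J - small.J).max()))
    return {"max_coupling_rmse": float(np.max(rmses)),
            "mean_coupling_rmse": float(np.mean(rmses)),
            "weighted_pl_max_param_err": werr, "n": n_models}


def goodness_calibration(pairwise_grid=(5, 10, 15), pops_per_n: int = 2,
                         n_samples_pairwise: int = 10**6,
                         n_null_seeds: int = 50, n_null: int = 10,
                         n_samples_null: int = 10**5, seed: int = 0) -> dict:
    """G under pairwise and independent ground truths.

    Pairwise truth → the full pipeline (sample, pseudo-likelihood fit, exact
    partition, plug-in data entropy) should report G near 1. Independent
    truth → G should scatter near 0.
    """
    rng = np.random.default_rng(seed)
    gs_pair = []
    for n in pairwise_grid:
        for _ in range(pops_per_n):
            model_rng = np.random.default_rng(int(rng.integers(2**31 - 1)))
            h = model_rng.normal(-1.0, 0.4, n)
            iu = triu_indices(n)
            J = np.zeros((n, n))
            J[iu] = model_rng.normal(0.0, 0.12, iu[0].size)
            model = PairwiseModel(h, J + J.T)
            raster = sample_model(model, n_samples_pairwise,
                                  seed=int(rng.integers(2**31 - 1)))
            fit = fit_pseudolikelihood(raster)
            gs_pair.append(evaluate_raster(raster, fit, estimator="exact").g)
    gs_null = []
    for _ in range(n_null_seeds):
        model_rng = np.random.default_rng(int(rng.integers(2**31 - 1)))
        ind = IndependentModel(model_rng.normal(-1.0, 0.4, n_null))
        raster = sample_model(ind, n_samples_null,
                              seed=int(rng.integers(2**31 - 1)))
        fit = fit_pseudolikelihood(raster)
        gs_null.append(evaluate_raster(raster, fit, estimator="exact").g)
    return {"median_g_pairwise_truth": float(np.median(gs_pair)),
            "median_g_independent_truth": float(np.median(gs_null)),
            "n": len(gs_pair) + len(gs_null)}


def closed_form_checks(seed: int = 0) -> dict:
    """Deviations from exactly known results.

    - two-spin model at h = 0: ⟨s₁s₂⟩ = tanh J by enumeration;
    - null model: S_pair = N ln 2;
    - homogeneous independent neurons: H_m is Binomial(N, q);
    - connected-triple expansion identity on a random raster.
    """
    from scipy.stats import binom

    from .evaluation import model_entropies
    from .prediction import connected_from_raw, count_distribution, model_predicted_stats, triple_stats
    from .raster import BinaryRaster, Moments

    rng = np.random.default_rng(seed)
    # two-spin correlation
    J = 0.8
    model = PairwiseModel(np.zeros(2), np.array([[0, J], [J, 0]]))
    p = exact_probabilities(model)
    S = enumerate_states(2)
    two_spin_err = abs(float(p @ (S[:, 0] * S[:, 1])) - np.tanh(J))
    # null-model entropy
    n = 7
    null = PairwiseModel(np.zeros(n), np.zeros((n, n)))
    s_pair, _ = model_entropies(null, IndependentModel(np.zeros(n)),
                                Moments(np.zeros(n), np.eye(n)),
                                exact_partition(null))
    null_entropy_err = abs(s_pair - n * np.log(2))
    # binomial count law (closed form + a sampled raster)
    q, nn = 0.1, 5
    ind = IndependentModel(np.full(nn, np.arctanh(2 * q - 1)))
    _, cd = model_predicted_stats(ind, 0, method="closed_form")
    binom_err = float(np.abs(cd.h_m - binom.pmf(np.arange(nn + 1), nn, q)).max())
    # connected-triple identity
    spins = np.where(rng.random((6, 2000)) < 0.3, 1, -1).astype(np.int8)
    raster = BinaryRaster(spins, 0.02, np.arange(6), np.ones(6))
    ts = triple_stats(raster)
    corr_raw = (spins.astype(float) @ spins.T.astype(float)) / raster.n_bins
    mom = compute_moments(raster)
    identity_dev = float(np.abs(
        ts.c_connected - connected_from_raw(mom.means, corr_raw, ts.triples,
                                            ts.c)).max())
    return {"two_spin_tanh_err": two_spin_err,
            "null_model_entropy_err": null_entropy_err,
            "binomial_count_law_err": binom_err,
            "connected_triple_identity_dev": identity_dev, "n": 4}


def perturbative_decay(n: int = 10,
                       occupancies=(0.005, 0.01, 0.015, 0.02, 0.03, 0.04, 0.05),
                       n_seeds: int = 5, range_max: float = 0.5,
                       seed: int = 0) -> dict:
    """Linearity of 1−G in Nν̄δt on ground truths with triplet structure.

    Sweeps the occupancy of fixed random higher-order truths (the bin-size
    analog), fits each exactly at pairwise order, and evaluates G exactly by
    enumeration. Fits the through-origin line to the per-occupancy median of
    1−G below `range_max` and checks the medians are non-increasing.
    """
    reports = []
    for k in range(n_seeds):
        truth_seed = int(np.random.default_rng(seed + 7919 * k).integers(2**31 - 1))
        for occ in occupancies:
            p = make_higher_order_truth(n, occ, pair_scale=0.6,
                                        triplet_scale=0.6, seed=truth_seed)
            mom = moments_from_probabilities(p, n)
            pair = fit_exact_maxent(mom)
            ind = fit_independent(mom)
            reports.append(goodness_from_probabilities(
                p, pair, ind, n=n, perturbation_parameter=n * occ))
    fit = fit_perturbative_slope(reports, range_max=range_max,
                                 aggregate="median")
    xs = np.array([r.perturbation_parameter for r in reports])
    gs = np.array([r.g for r in reports])
    medians = [float(np.median(gs[xs == x])) for x in np.unique(xs)]
    monotone = bool(np.all(np.diff(medians) <= 1e-9))
    return {"slope": fit.slope, "r_squared": fit.r_squared,
            "median_g_monotone_decreasing": monotone,
            "median_g_values": medians, "n": len(reports)}


def complexity_mechanics(seed: int = 0, n_sk_draws: int = 10,
                         n_inits: int = 120,
                         scaling_ns=(50, 100, 200), draws_per_n: int = 6) -> dict:
    """TAP and SK-ensemble diagnostics.

    (a) J = 0 gives m = tanh h; (b) a weakly coupled model has exactly one
    TAP solution cluster; (c) among a batch of N=32, J1=2 SK draws at least
    one carries ≥ 2 verified TAP solutions; (d) std(J) of the SK ensemble
    scales as N^(−1/2) and f = std/mean grows with N at fixed J0 > 0.
    """
    rng = np.random.default_rng(seed)
    # (a) decoupled fixed point
    h = rng.normal(0, 0.8, 12)
    tap = solve_tap(PairwiseModel(h, np.zeros((12, 12))))
    tanh_err = float(np.abs(tap.m - np.tanh(h)).max())
    # (b) weak coupling: single cluster
    weak = random_sparse_model(10, rng, j_max=0.05)
    weak_rep = count_metastable(weak, n_inits=60,
                                seed=int(rng.integers(2**31 - 1)))
    # (c) strong-coupling SK batch
    max_n_ms, found_resid = 0, float("nan")
    for k in range(n_sk_draws):
        spec = GroundTruthSpec(n_neurons=32, structure="sk_ensemble", J0=0.0,
                               J1=2.0, rate_sd_hz=0.0, seed=seed + k)
        model = PairwiseModel(np.zeros(32), make_model(spec).J)
        rep = count_metastable(model, n_inits=n_inits,
                               seed=int(rng.integers(2**31 - 1)))
        if rep.n_ms and rep.n_ms > max_n_ms:
            max_n_ms = rep.n_ms
            found_resid = max(rep.meta["center_residuals"])
        if max_n_ms >= 2:
            break
    # (d) ensemble scaling
    stds, fs = [], []
    for n in scaling_ns:
        s_vals, f_vals = [], []
        for _ in range(draws_per_n):
            spec = GroundTruthSpec(n_neurons=n, structure="sk_ensemble", J0=1.0,
                                   J1=0.8, rate_sd_hz=0.0,
                                   seed=int(rng.integers(2**31 - 1)))
            rep = coupling_statistics(make_model(spec))
            s_vals.append(rep.std_j)
            f_vals.append(rep.f)
        stds.append(np.mean(s_vals))
        fs.append(np.mean(f_vals))
    slope = float(np.polyfit(np.log(scaling_ns), np.log(stds), 1)[0])
    return {"tap_tanh_err": tanh_err,
            "weak_coupling_n_clusters": weak_rep.n_ms,
            "strong_sk_max_n_ms": max_n_ms,
            "strong_sk_solution_residual": found_resid,
            "sk_std_loglog_slope": slope,
            "f_monotone_increasing": bool(fs[0] < fs[1] < fs[2]),
            "n": n_sk_draws + draws_per_n * len(scaling_ns)}
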