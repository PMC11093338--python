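"""Ground-truth model generation and synthetic spike rasters.

This module generates the study conditions every downstream stage is tested
against: pairwise (Ising) ground truths with heterogeneous, log-normally
distributed firing rates; block-independent group structure; the
Sherrington-Kirkpatrick (SK) ensemble with couplings Gaussian(J0/N, J1/√N);
and cortical-surrogate spike tables whose rate statistics emulate
high-density cortical recordings (e.g. visual-cortex-like mean 6.27 Hz,
SD 1.24 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._samplers import gibbs_sample
from .models import IndependentModel, PairwiseModel, TripletModel, enumerate_states
from .raster import BinaryRaster, SpikeTable

__all__ = [
    "GroundTruthSpec",
    "make_model",
    "sample_model",
    "sample_states",
    "simulate_cortical_surrogate",
]

EXACT_SAMPLING_LIMIT = 20


@dataclass
class GroundTruthSpec:
    """Parameters of a synthetic ground-truth population.

    Rates are drawn from a log-normal with the given mean and SD in Hz. The
    isolated-neuron spike probability at the reference bin size delta_t_ref is
    p_i = ν_i·δt (rejected when ≥ 1), which pins the fields h_i; couplings
    depend on `structure`:

    - "random_pairwise": J_ij ~ Gaussian(0, coupling_scale) on i<j, mirrored.
    - "independent_groups": same, but only within consecutive blocks of
      `group_size` neurons; zero between blocks.
    - "sk_ensemble": J_ij ~ Gaussian(J0/N, J1/√N) on i<j, mirrored — the SK
      parameterization in which J0, J1 are N-independent.
    """

    n_neurons: int
    rate_mean_hz: float = 6.27
    rate_sd_hz: float = 1.24
    delta_t_ref: float = 0.02
    coupling_scale: float = 0.1
    field_offset: float = 0.0
    structure: str = "random_pairwise"
    group_size: int | None = None
    J0: float = 0.0
    J1: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_neurons < 2:
            raise ValueError("n_neurons must be ≥ 2")
        if self.rate_mean_hz <= 0 or self.rate_sd_hz < 0:
            raise ValueError("rates must be positive")


def _lognormal_rates(spec: GroundTruthSpec, rng: np.random.Generator) -> np.ndarray:
    m, sd = spec.rate_mean_hz, spec.rate_sd_hz
    if sd == 0:
        return np.full(spec.n_neurons, m)
    sigma2 = np.log1p((sd / m) ** 2)
    mu = np.log(m) - 0.5 * sigma2
    return rng.lognormal(mu, np.sqrt(sigma2), size=spec.n_neurons)


def _fields_for_rates(rates: np.ndarray, delta_t: float, offset: float) -> np.ndarray:
    p = rates * delta_t
    if np.any(p >= 1.0):
        raise ValueError(
            "rates imply a bin spike probability ≥ 1 at this bin size; "
            "use a smaller delta_t or lower rates")
    return np.arctanh(2.0 * p - 1.0) + offset


def make_model(spec: GroundTruthSpec) -> PairwiseModel:
    """Draw a ground-truth pairwise model from the spec (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_neurons
    rates = _lognormal_rates(spec, rng)
    h = _fields_for_rates(rates, spec.delta_t_ref, spec.field_offset)

    J = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    if spec.structure == "random_pairwise":
        J[iu] = rng.normal(0.0, spec.coupling_scale, size=iu[0].size)
    elif spec.structure == "independent_groups":
        if spec.group_size is None or n % spec.group_size != 0:
            raise ValueError("group_size must divide n_neurons")
        g = spec.group_size
        same_group = (iu[0] // g) == (iu[1] // g)
        vals = np.zeros(iu[0].size)
        vals[same_group] = rng.normal(0.0, spec.coupling_scale, size=int(same_group.sum()))
        J[iu] = vals
    elif spec.structure == "sk_ensemble":
        J[iu] = rng.normal(spec.J0 / n, spec.J1 / np.sqrt(n), size=iu[0].size)
    else:
        raise ValueError(f"unknown structure {spec.structure!r}")
    J = J + J.T
    model = PairwiseModel(h, J, method_tag=f"truth:{spec.structure}",
                          meta={"rates_hz": rates, "delta_t_ref": spec.delta_t_ref,
                                "seed": spec.seed})
    return model


def exact_probabilities(model) -> np.ndarray:
    """Exact state probabilities by enumeration (N ≤ 20 pairwise, ≤ 15 triplet)."""
    limit = 15 if isinstance(model, TripletModel) else EXACT_SAMPLING_LIMIT
    if model.n > limit:
        raise ValueError(f"exact enumeration limited to N ≤ {limit}")
    states = enumerate_states(model.n)
    loge = -model.energy(states)
    loge -= loge.max()
    p = np.exp(loge)
    return p / p.sum()


def sample_states(model, n_samples: int, method: str = "exact",
                  burn_in: int = 1000, thin: int = 1,
                  seed: int = 0) -> np.ndarray:
    """Draw `n_samples` states (rows, ±1) from a fitted or ground-truth model.

    "exact" enumerates all 2^N probabilities and draws categorically (N ≤ 20);
    "gibbs" runs single-site heat-bath updates with a random scan, discarding
    `burn_in` full sweeps and keeping every `thin`-th sweep.
    """
    if isinstance(model, IndependentModel):
        # product model: direct Bernoulli draws regardless of N
        rng = np.random.default_rng(seed)
        p_plus = model.spike_probabilities()
        draws = rng.random((n_samples, model.n)) < p_plus
        return np.where(draws, 1, -1).astype(np.int8)
    if method == "exact":
        if model.n > EXACT_SAMPLING_LIMIT:
            raise ValueError(f"exact sampling requires N ≤ {EXACT_SAMPLING_LIMIT}")
        rng = np.random.default_rng(seed)
        p = exact_probabilities(model)
        idx = rng.choice(p.size, size=n_samples, p=p)
        return enumerate_states(model.n, dtype=np.int8)[idx]
    if method == "gibbs":
        if isinstance(model, TripletModel):
            raise ValueError("gibbs sampling implemented for pairwise models only")
        samples, _ = gibbs_sample(model.h, model.J, n_samples, burn_in, thin, seed)
        return samples
    raise ValueError(f"unknown sampling method {method!r}")


def sample_model(model, n_samples: int, method: str = "exact",
                 burn_in: int = 1000, thin: int = 1, seed: int = 0,
                 delta_t: float = 0.02) -> BinaryRaster:
    """Sample a model into a BinaryRaster at bin size `delta_t`.

    Rates are the realized fraction of +1 bins divided by δt, i.e. what the
    raster pipeline would report for a spike table with one spike per active
    bin.
    """
    s = sample_states(model, n_samples, method=method, burn_in=burn_in,
                      thin=thin, seed=seed).T  # N×T
    rates = (s == 1).mean(axis=1) / delta_t
    return BinaryRaster(s, delta_t, np.arange(model.n), rates)


def make_higher_order_truth(n_neurons: int, occupancy: float,
                            pair_scale: float = 0.6, triplet_scale: float = 1.2,
                            seed: int = 0) -> np.ndarray:
    """Exact state probabilities of a ground truth with genuine triplet structure.

    The model is written in lattice-gas (0/1) coordinates,
    p(x) ∝ exp(a Σx_i + Σ b_ij x_i x_j + Σ c_ijk x_i x_j x_k), with fixed
    random Gaussian pair (b) and triplet (c) interactions; the uniform field a
    is tuned so the mean occupancy ⟨x⟩ equals `occupancy`. Because the
    interactions are fixed while the occupancy shrinks, connected correlations
    of order n scale as occupancy^n — the small-ν̄δt structure of binarized
    spike data — so a pairwise fit degrades linearly in Nν̄δt, with
    N·occupancy playing the role of the perturbation parameter. Returns the
    probability vector over the 2^N enumerated states (N ≤ 20).
    """
    from itertools import combinations

    from scipy.optimize import brentq
    from scipy.special import logsumexp

    n = n_neurons
    if n > EXACT_SAMPLING_LIMIT:
        raise ValueError("exact higher-order truth limited to N ≤ 20")
    if not 0 < occupancy < 1:
        raise ValueError("occupancy must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    S = enumerate_states(n)
    X = (S + 1) / 2.0
    iu = np.triu_indices(n, 1)
    b = rng.normal(0.0, pair_scale, iu[0].size)
    base = (X[:, iu[0]] * X[:, iu[1]]) @ b
    if n >= 3:
        tr = np.array(list(combinations(range(n), 3)))
        c = rng.normal(0.0, triplet_scale, tr.shape[0])
        base = base + (X[:, tr[:, 0]] * X[:, tr[:, 1]] * X[:, tr[:, 2]]) @ c
    n_active = X.sum(axis=1)

    def probs(a):
        loge = n_active * a + base
        return np.exp(loge - logsumexp(loge))

    a = brentq(lambda a: probs(a) @ (n_active / n) - occupancy, -30.0, 15.0)
    return probs(a)


def simulate_cortical_surrogate(spec: GroundTruthSpec, duration_s: float,
                                delta_t: float | None = None,
                                method: str | None = None,
                                seed: int | None = None) -> SpikeTable:
    """Emit a surrogate spike table with cortical-recording-like statistics.

    Draws per-neuron rates from the log-normal spec, samples a ground-truth
    pairwise model whose fields reproduce those rates at `delta_t`, and places
    one spike uniformly at random inside each +1 bin, so that re-binarizing
    the emitted table at the same δt reproduces the generating raster exactly.
    """
    delta_t = spec.delta_t_ref if delta_t is None else delta_t
    if duration_s < 10 * delta_t:
        raise ValueError("duration must be much larger than the bin size")
    if delta_t != spec.delta_t_ref:
        spec = GroundTruthSpec(**{**spec.__dict__, "delta_t_ref": delta_t})
    model = make_model(spec)
    n_bins = int(np.floor(duration_s / delta_t + 1e-12))
    if method is None:
        method = "exact" if model.n <= EXACT_SAMPLING_LIMIT else "gibbs"
    sample_seed = spec.seed + 1 if seed is None else seed
    raster = sample_model(model, n_bins, method=method, seed=sample_seed,
                          delta_t=delta_t)
    rng = np.random.default_rng(sample_seed + 1)
    rows, bins = np.nonzero(raster.spins == 1)
    times = (bins + rng.random(bins.size)) * delta_t
    times = np.minimum(times, np.nextafter(n_bins * delta_t, 0.0))
    return SpikeTable(rows.astype(np.int64), times, np.arange(model.n),
                      0.0, n_bins * delta_t)
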