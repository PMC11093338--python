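"""Spike tables, binarization into ±1 rasters, empirical moments and pattern statistics.

The spin convention is the field's usual one: a neuron that spikes at least
once in a time bin of size δt maps to +1, a silent neuron to −1. Bins are
half-open [t0 + kδt, t0 + (k+1)δt); a trailing partial bin is dropped. All
entropies are in nats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTable",
    "BinaryRaster",
    "Moments",
    "EmpiricalDistribution",
    "bin_spikes",
    "compute_moments",
    "empirical_distribution",
    "select_population",
    "read_spike_tsv",
    "write_spike_tsv",
    "spins_to_binary",
    "binary_to_spins",
]


@dataclass
class SpikeTable:
    """Raw spike events (neuron id, time in seconds) before binning."""

    neuron_ids_of_events: np.ndarray
    times: np.ndarray
    neuron_ids: np.ndarray
    t_start: float
    t_end: float

    def __post_init__(self):
        self.neuron_ids_of_events = np.asarray(self.neuron_ids_of_events, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        if self.neuron_ids_of_events.size != self.times.size:
            raise ValueError("event ids and times must have equal length")
        if np.unique(self.neuron_ids).size != self.neuron_ids.size:
            raise ValueError("neuron_ids must be unique")
        if self.times.size:
            if self.times.min() < self.t_start or self.times.max() >= self.t_end:
                raise ValueError("all spike times must lie in [t_start, t_end)")
            missing = np.setdiff1d(self.neuron_ids_of_events, self.neuron_ids)
            if missing.size:
                raise ValueError(f"events reference unknown neuron ids {missing[:5]}")

    @property
    def n_neurons(self) -> int:
        return self.neuron_ids.size

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class BinaryRaster:
    """N×T matrix of ±1 spins binned at δt seconds, with per-neuron rates in Hz."""

    spins: np.ndarray
    delta_t: float
    neuron_ids: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        self.spins = np.asarray(self.spins, dtype=np.int8)
        if self.spins.ndim != 2 or self.spins.shape[1] < 1:
            raise ValueError("spins must be an N×T matrix with T ≥ 1")
        if not np.all(np.abs(self.spins) == 1):
            raise ValueError("raster entries must be ±1")
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0):
            raise ValueError("rates must be nonnegative")

    @property
    def n_neurons(self) -> int:
        return self.spins.shape[0]

    @property
    def n_bins(self) -> int:
        return self.spins.shape[1]

    @property
    def mean_rate(self) -> float:
        """ν̄ = (1/N) Σ_i ν_i in spikes/s."""
        return float(np.mean(self.rates))

    @property
    def perturbation_parameter(self) -> float:
        """Nν̄δt — the small parameter of the perturbative quality expansion."""
        return self.n_neurons * self.mean_rate * self.delta_t

    def subset(self, indices) -> "BinaryRaster":
        indices = np.asarray(indices, dtype=np.int64)
        return BinaryRaster(self.spins[indices], self.delta_t,
                            self.neuron_ids[indices], self.rates[indices])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.spins, index=pd.Index(self.neuron_ids, name="neuron_id"))


@dataclass
class Moments:
    """First and second data moments ⟨s_i⟩ and ⟨s_i s_j⟩ (time averages over bins)."""

    means: np.ndarray
    correlations: np.ndarray
    n_samples: int | None = None

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.correlations = np.asarray(self.correlations, dtype=float)
        if np.any(np.abs(self.means) > 1 + 1e-12):
            raise ValueError("|⟨s_i⟩| must be ≤ 1")
        if np.any(np.abs(self.correlations) > 1 + 1e-12):
            raise ValueError("|⟨s_i s_j⟩| must be ≤ 1")
        if not np.allclose(np.diag(self.correlations), 1.0, atol=1e-12):
            raise ValueError("correlation diagonal must be exactly 1")
        if not np.allclose(self.correlations, self.correlations.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.means.size

    @property
    def connected(self) -> np.ndarray:
        """Connected covariance C_ij = ⟨s_i s_j⟩ − ⟨s_i⟩⟨s_j⟩ (diagonal included)."""
        return self.correlations - np.outer(self.means, self.means)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.correlations)
        df.insert(0, "mean", self.means)
        return df


@dataclass
class EmpiricalDistribution:
    """Observed-pattern frequencies p_data over the set O of sampled ±1 states."""

    patterns: np.ndarray  # |O| × N, lexicographically sorted (−1 < +1)
    counts: np.ndarray
    n_samples: int
    _frequencies: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.patterns = np.asarray(self.patterns, dtype=np.int8)
        self.counts = np.asarray(self.counts)
        if not np.isclose(float(self.counts.sum()), self.n_samples, rtol=1e-12):
            raise ValueError("counts must sum to the number of samples")
        self._frequencies = self.counts / self.n_samples

    @classmethod
    def from_probabilities(cls, patterns: np.ndarray, probabilities: np.ndarray,
                           n_samples: int = 1) -> "EmpiricalDistribution":
        """Build a distribution whose p_data is an exact probability vector.

        Useful for identity checks where the observed-state frequencies are
        replaced by a model's exact probabilities; `counts` become fractional.
        """
        probabilities = np.asarray(probabilities, dtype=float)
        order = np.lexsort(np.asarray(patterns).T[::-1])
        return cls(np.asarray(patterns)[order], probabilities[order] * n_samples,
                   n_samples)

    @property
    def frequencies(self) -> np.ndarray:
        return self._frequencies

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def entropy(self) -> float:
        """Plug-in data entropy S_data = −Σ p_data ln p_data (nats)."""
        p = self._frequencies
        return float(-np.sum(p * np.log(p)))

    @property
    def most_sampled(self) -> np.ndarray:
        """Most common state s_0; ties broken lexicographically with −1 < +1."""
        # patterns are sorted lexicographically, so the first argmax wins ties
        return self.patterns[int(np.argmax(self.counts))]


def bin_spikes(spikes: SpikeTable, delta_t: float,
               time_mask: list[tuple[float, float]] | None = None) -> BinaryRaster:
    """Binarize a spike table at bin size δt.

    Bin k covers [t_start + kδt, t_start + (k+1)δt); a trailing partial bin is
    dropped. An entry is +1 iff at least one spike falls in the bin. When
    `time_mask` is given (non-overlapping intervals within the recording),
    only bins lying entirely inside some interval are kept — this is how
    condition splitting (e.g. lights-on vs lights-off epochs) and session
    concatenation are expressed; no bin straddles a mask boundary. Rates are
    spike counts inside retained bins divided by total retained time.
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    n_bins = int(np.floor((spikes.t_end - spikes.t_start) / delta_t + 1e-12))
    if n_bins < 1:
        raise ValueError("empty raster: delta_t exceeds the recording span")

    if time_mask is not None:
        mask = sorted((float(a), float(b)) for a, b in time_mask)
        for (a0, b0), (a1, b1) in zip(mask, mask[1:]):
            if a1 < b0:
                raise ValueError("time_mask intervals must be non-overlapping")
        for a, b in mask:
            if a < spikes.t_start - 1e-12 or b > spikes.t_end + 1e-12:
                raise ValueError("time_mask intervals must lie within the recording")
        edges_lo = spikes.t_start + np.arange(n_bins) * delta_t
        edges_hi = edges_lo + delta_t
        keep = np.zeros(n_bins, dtype=bool)
        for a, b in mask:
            keep |= (edges_lo >= a - 1e-9) & (edges_hi <= b + 1e-9)
        kept_bins = np.flatnonzero(keep)
    else:
        kept_bins = np.arange(n_bins)
    if kept_bins.size == 0:
        raise ValueError("empty raster: no bin lies fully inside the time mask")

    id_to_row = {int(nid): i for i, nid in enumerate(spikes.neuron_ids)}
    rows = np.array([id_to_row[int(i)] for i in spikes.neuron_ids_of_events],
                    dtype=np.int64)
    bin_idx = np.floor((spikes.times - spikes.t_start) / delta_t).astype(np.int64)
    in_range = bin_idx < n_bins

    n = spikes.n_neurons
    occupied = np.zeros((n, n_bins), dtype=bool)
    occupied[rows[in_range], bin_idx[in_range]] = True

    counts = np.zeros(n, dtype=np.int64)
    keep_lookup = np.zeros(n_bins, dtype=bool)
    keep_lookup[kept_bins] = True
    sel = in_range & keep_lookup[np.clip(bin_idx, 0, n_bins - 1)]
    np.add.at(counts, rows[sel], 1)

    spins = np.where(occupied[:, kept_bins], 1, -1).astype(np.int8)
    total_time = kept_bins.size * delta_t
    rates = counts / total_time
    return BinaryRaster(spins, delta_t, spikes.neuron_ids.copy(), rates)


def compute_moments(raster: BinaryRaster) -> Moments:
    """Time-averaged means ⟨s_i⟩ and correlations ⟨s_i s_j⟩ (unit diagonal)."""
    s = raster.spins.astype(np.float64)
    T = raster.n_bins
    means = s.mean(axis=1)
    corr = (s @ s.T) / T
    np.fill_diagonal(corr, 1.0)
    corr = 0.5 * (corr + corr.T)
    return Moments(means, corr, n_samples=T)


def empirical_distribution(raster: BinaryRaster) -> EmpiricalDistribution:
    """Pattern → count/T map over the observed states (columns of the raster)."""
    cols = np.ascontiguousarray(raster.spins.T)
    patterns, counts = np.unique(cols, axis=0, return_counts=True)
    return EmpiricalDistribution(patterns, counts, raster.n_bins)


def select_population(rates: np.ndarray, size: int,
                      mode: str = "random", exponent: float = 3.0,
                      seed: int | np.random.Generator = 0) -> np.ndarray:
    """Select a sub-population of `size` neurons.

    mode="random": uniform without replacement. mode="rate_matched": the first
    neuron i is drawn with probability ∝ ν_i; the remaining neurons j are then
    drawn without replacement with p(j) ∝ 1/|ν_i − ν_j|^exponent, so the
    population concentrates around the seed neuron's firing rate. A candidate
    with ν_j exactly equal to ν_i receives the maximum finite weight among
    candidates.
    """
    rates = np.asarray(rates, dtype=float)
    n_avail = rates.size
    if size > n_avail:
        raise ValueError(f"requested {size} neurons from a pool of {n_avail}")
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if mode == "random":
        return np.sort(rng.choice(n_avail, size=size, replace=False))
    if mode != "rate_matched":
        raise ValueError(f"unknown mode {mode!r}")

    if np.allclose(rates, rates[0]):
        warnings.warn("all rates identical; rate_matched falls back to uniform selection")
        return np.sort(rng.choice(n_avail, size=size, replace=False))

    first = int(rng.choice(n_avail, p=rates / rates.sum()))
    chosen = [first]
    candidates = np.array([k for k in range(n_avail) if k != first])
    for _ in range(size - 1):
        diff = np.abs(rates[first] - rates[candidates])
        with np.errstate(divide="ignore"):
            w = 1.0 / diff**exponent
        finite = np.isfinite(w)
        if finite.any():
            w[~finite] = w[finite].max() if finite.any() else 1.0
        else:
            w = np.ones_like(w)
        pick = int(rng.choice(candidates.size, p=w / w.sum()))
        chosen.append(int(candidates[pick]))
        candidates = np.delete(candidates, pick)
    return np.sort(np.array(chosen, dtype=np.int64))


# ---------------------------------------------------------------------------
# I/O: the TSV spike dialect and {0,1} conversion at the boundary


def read_spike_tsv(path, t_start: float | None = None,
                   t_end: float | None = None) -> SpikeTable:
    """Read a two-column TSV (neuron_id, time_s); header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if isinstance(df.iloc[0, 0], str):  # header row present
        df = pd.read_csv(path, sep="\t", comment="#")
        df.columns = ["neuron_id", "time_s"]
    else:
        df.columns = ["neuron_id", "time_s"]
    ids = df["neuron_id"].to_numpy(dtype=np.int64)
    times = df["time_s"].to_numpy(dtype=float)
    if t_start is None:
        t_start = float(times.min()) if times.size else 0.0
    if t_end is None:
        t_end = float(times.max()) + 1e-9 if times.size else 1.0
    return SpikeTable(ids, times, np.unique(ids), t_start, t_end)


def write_spike_tsv(spikes: SpikeTable, path) -> None:
    order = np.argsort(spikes.times, kind="stable")
    pd.DataFrame({
        "neuron_id": spikes.neuron_ids_of_events[order],
        "time_s": spikes.times[order],
    }).to_csv(path, sep="\t", index=False, float_format="%.12g")


def spins_to_binary(spins: np.ndarray) -> np.ndarray:
    """±1 → {0,1} (active = 1); conversion helper for the I/O boundary only."""
    return ((np.asarray(spins) + 1) // 2).astype(np.int8)


def binary_to_spins(binary: np.ndarray) -> np.ndarray:
    """{0,1} → ±1."""
    return (2 * np.asarray(binary, dtype=np.int8) - 1).astype(np.int8)
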