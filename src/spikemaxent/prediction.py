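"""Alternative performance measures: third-order correlations and H_m.

Beyond KL-based goodness, a pairwise model can be judged by how well it
predicts statistics it was not fitted to: third-order correlations
C_ijk = ⟨s_i s_j s_k⟩, their connected versions
C̃_ijk = ⟨(s_i−⟨s_i⟩)(s_j−⟨s_j⟩)(s_k−⟨s_k⟩)⟩, and H_m, the probability that
exactly m neurons are simultaneously active (+1) in a time bin. Each gets a
goodness score comparing pairwise against independent-model predictions,
e.g. G_C = 1 − Σ(C^data−C^pair)²/Σ(C^data−C^ind)².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .models import IndependentModel
from .raster import BinaryRaster
from .synthetic import sample_states

__all__ = [
    "TripleStats",
    "CountDistribution",
    "PredictionReport",
    "triple_stats",
    "count_distribution",
    "model_predicted_stats",
    "prediction_goodness",
]

# all C(N,3) triples are used up to this N; above, a seeded subsample
FULL_TRIPLE_LIMIT = 100
TRIPLE_SUBSAMPLE = 200_000


@dataclass
class TripleStats:
    """C_ijk and C̃_ijk over a set of i<j<k triples."""

    triples: np.ndarray  # (n_triples, 3) indices
    c: np.ndarray
    c_connected: np.ndarray
    source_tag: str = "data"
    n_samples_used: int | None = None

    def __post_init__(self):
        if np.any(np.abs(self.c) > 1 + 1e-9):
            raise ValueError("|C_ijk| must be ≤ 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "i": self.triples[:, 0], "j": self.triples[:, 1], "k": self.triples[:, 2],
            "c": self.c, "c_connected": self.c_connected, "source": self.source_tag,
        })


@dataclass
class CountDistribution:
    """H_m: probability that m of the N neurons are active in a bin, m = 0..N."""

    h_m: np.ndarray
    source_tag: str = "data"

    def __post_init__(self):
        self.h_m = np.asarray(self.h_m, dtype=float)
        if np.any(self.h_m < -1e-15):
            raise ValueError("H_m must be nonnegative")
        if abs(self.h_m.sum() - 1.0) > 1e-12:
            raise ValueError("H_m must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"m": np.arange(self.h_m.size), "h_m": self.h_m,
                             "source": self.source_tag})


@dataclass
class PredictionReport:
    g_c: float
    g_c_tilde: float
    g_h: float
    flags: list = field(default_factory=list)


def _select_triples(n: int, seed: int = 0) -> np.ndarray:
    if n < 3:
        raise ValueError("third-order statistics need N ≥ 3")
    all_triples = np.array(list(combinations(range(n), 3)), dtype=np.int64)
    if n <= FULL_TRIPLE_LIMIT:
        return all_triples
    rng = np.random.default_rng(seed)
    keep = rng.choice(all_triples.shape[0], size=TRIPLE_SUBSAMPLE, replace=False)
    return all_triples[np.sort(keep)]


def triple_stats(raster: BinaryRaster, source_tag: str = "data",
                 triples: np.ndarray | None = None, seed: int = 0) -> TripleStats:
    """Third-order and connected third-order correlations of a raster.

    The connected version is computed directly from centered spins; the
    algebraic expansion in raw moments is available as an independent check.
    For N above 100, a seeded subsample of 2·10^5 triples is used and
    recorded via the returned `triples` array.
    """
    if triples is None:
        triples = _select_triples(raster.n_neurons, seed)
    s = raster.spins.astype(np.float64)
    T = raster.n_bins
    i, j, k = triples[:, 0], triples[:, 1], triples[:, 2]
    c = np.einsum("at,at->a", s[i] * s[j], s[k]) / T
    sc = s - s.mean(axis=1, keepdims=True)
    ct = np.einsum("at,at->a", sc[i] * sc[j], sc[k]) / T
    return TripleStats(triples, c, ct, source_tag=source_tag, n_samples_used=T)


def connected_from_raw(means, pair_corr, triples, c) -> np.ndarray:
    """C̃_ijk from the raw-moment expansion: C − mᵢ⟨sⱼsₖ⟩ − mⱼ⟨sᵢsₖ⟩ − mₖ⟨sᵢsⱼ⟩ + 2mᵢmⱼmₖ."""
    i, j, k = triples[:, 0], triples[:, 1], triples[:, 2]
    m = np.asarray(means)
    return (np.asarray(c)
            - m[i] * pair_corr[j, k] - m[j] * pair_corr[i, k] - m[k] * pair_corr[i, j]
            + 2.0 * m[i] * m[j] * m[k])


def count_distribution(raster: BinaryRaster,
                       source_tag: str = "data") -> CountDistribution:
    """Empirical H_m: frequency of bins with exactly m active (+1) neurons."""
    m_per_bin = (raster.spins == 1).sum(axis=0)
    counts = np.bincount(m_per_bin, minlength=raster.n_neurons + 1)
    return CountDistribution(counts / raster.n_bins, source_tag=source_tag)


def _poisson_binomial(p: np.ndarray) -> np.ndarray:
    """Distribution of the number of successes of independent Bernoulli(p_i)."""
    h = np.array([1.0])
    for pi in p:
        h = np.convolve(h, [1.0 - pi, pi])
    return h


def model_predicted_stats(model, n_samples: int, seed: int = 0,
                          method: str = "auto", sampling: str = "auto",
                          triples: np.ndarray | None = None,
                          delta_t: float = 0.02):
    """Predicted (TripleStats, CountDistribution) for a fitted model.

    Independent models admit closed forms (C_ijk = m_i m_j m_k, C̃ = 0, H_m a
    Poisson-binomial law), used when method="auto" or "closed_form". Otherwise
    statistics come from model samples (exact for N ≤ 20, Gibbs above),
    conventionally with as many samples as in the data.
    """
    tag = "ind" if isinstance(model, IndependentModel) else "pair"
    if isinstance(model, IndependentModel) and method in ("auto", "closed_form"):
        if triples is None:
            triples = _select_triples(model.n, seed)
        m = model.means()
        i, j, k = triples[:, 0], triples[:, 1], triples[:, 2]
        ts = TripleStats(triples, m[i] * m[j] * m[k],
                         np.zeros(triples.shape[0]), source_tag=tag + ":closed_form",
                         n_samples_used=None)
        cd = CountDistribution(_poisson_binomial(model.spike_probabilities()),
                               source_tag=tag + ":closed_form")
        return ts, cd
    if method == "closed_form":
        raise ValueError("closed forms are only available for independent models")
    samp_method = sampling
    if sampling == "auto":
        samp_method = "exact" if model.n <= 20 else "gibbs"
    states = sample_states(model, n_samples, method=samp_method, seed=seed)
    raster = BinaryRaster(states.T, delta_t, np.arange(model.n),
                          (states == 1).mean(axis=0) / delta_t)
    ts = triple_stats(raster, source_tag=f"{tag}:{samp_method}", triples=triples,
                      seed=seed)
    cd = count_distribution(raster, source_tag=f"{tag}:{samp_method}")
    return ts, cd


def _score(data: np.ndarray, pair: np.ndarray, ind: np.ndarray,
           name: str, flags: list) -> float:
    num = float(np.sum((data - pair) ** 2))
    den = float(np.sum((data - ind) ** 2))
    if den == 0.0:
        flags.append(f"undefined:{name}:zero_denominator")
        return float("nan")
    g = 1.0 - num / den
    if g < 0:
        flags.append(f"outlier:{name}:negative")
    return g


def prediction_goodness(data: tuple[TripleStats, CountDistribution],
                        pair_pred: tuple[TripleStats, CountDistribution],
                        ind_pred: tuple[TripleStats, CountDistribution]) -> PredictionReport:
    """G_C, G_C̃ and G_H from data, pairwise-model and independent-model statistics.

    All three sources must share the same triple index set and m range.
    Negative values are retained and flagged, never dropped.
    """
    ts_d, cd_d = data
    ts_p, cd_p = pair_pred
    ts_i, cd_i = ind_pred
    if not (np.array_equal(ts_d.triples, ts_p.triples)
            and np.array_equal(ts_d.triples, ts_i.triples)):
        raise ValueError("triple index sets differ between sources")
    if not (cd_d.h_m.size == cd_p.h_m.size == cd_i.h_m.size):
        raise ValueError("H_m ranges differ between sources")
    flags: list = []
    g_c = _score(ts_d.c, ts_p.c, ts_i.c, "g_c", flags)
    g_ct = _score(ts_d.c_connected, ts_p.c_connected, ts_i.c_connected,
                  "g_c_tilde", flags)
    g_h = _score(cd_d.h_m, cd_p.h_m, cd_i.h_m, "g_h", flags)
    return PredictionReport(g_c=g_c, g_c_tilde=g_ct, g_h=g_h, flags=flags)
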