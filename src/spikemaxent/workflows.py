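"""End-to-end scan workflows: binarize → fit → evaluate across population grids.

These orchestrate the library over grids of population size, bin size and
condition masks, writing one CSV row per population with enough metadata
(seeds, method and estimator tags, flags) to re-run any row in isolation.
Negative-G rows are flagged, never dropped; filtering outliers is a post-hoc
decision left to the analyst.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import yaml

from .evaluation import ENUMERATION_LIMIT, evaluate_raster
from .inference import (fit_boltzmann, fit_independent, fit_mean_field_family,
                        fit_pseudolikelihood)
from .raster import BinaryRaster, SpikeTable, bin_spikes, compute_moments, select_population
from .synthetic import GroundTruthSpec, simulate_cortical_surrogate

__all__ = ["ScanConfig", "run_quality_scan", "run_condition_comparison",
           "AREA_BIN_PRESETS"]

logger = logging.getLogger("spikemaxent")

# per-area bin-size presets (seconds), reflecting the mean-rate differences
# between cortical areas (visual/auditory fast, motor and somatosensory slower)
AREA_BIN_PRESETS = {"visual": 0.02, "auditory": 0.02, "motor": 0.06,
                    "somatosensory": 0.14}


@dataclass
class ScanConfig:
    """Configuration of a quality scan (structured-text serializable)."""

    n_grid: list[int]
    n_pops_per_n: int = 5
    delta_t: list[float] = dc_field(default_factory=lambda: [0.02])
    method: str = "pl"  # ind | pl | boltzmann | nmf | tap | ip | sm
    estimator: str = "auto"  # exact | zhat | most_sampled | mean | median | auto
    enumeration_limit: int = ENUMERATION_LIMIT
    seed: int = 0
    input_path: str | None = None
    surrogate: dict | None = None  # GroundTruthSpec kwargs
    surrogate_duration_s: float = 600.0
    selection_mode: str = "random"
    out_dir: str | None = None

    def __post_init__(self):
        if not self.n_grid or not self.delta_t:
            raise ValueError("n_grid and delta_t must be nonempty")
        if self.seed is None:
            raise ValueError("a seed is required")

    @classmethod
    def from_yaml(cls, path) -> "ScanConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        doc = {k: v for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def _load_spikes(config: ScanConfig) -> SpikeTable:
    from .raster import read_spike_tsv

    if config.input_path is not None:
        return read_spike_tsv(config.input_path)
    if config.surrogate is None:
        raise ValueError("config needs either input_path or a surrogate spec")
    spec = GroundTruthSpec(**{"seed": config.seed, **config.surrogate})
    return simulate_cortical_surrogate(spec, config.surrogate_duration_s,
                                       delta_t=min(config.delta_t))


def _fit(raster: BinaryRaster, method: str, seed: int):
    moments = compute_moments(raster)
    if method == "pl":
        return fit_pseudolikelihood(raster)
    if method == "boltzmann":
        n_iter = 20_000 if raster.n_neurons <= 12 else 5_000
        return fit_boltzmann(moments, eta=0.05, n_iter=n_iter, seed=seed)
    if method in ("nmf", "tap", "ip", "sm"):
        return fit_mean_field_family(moments, method=method)
    if method == "ind":
        return fit_independent(moments).as_pairwise()
    raise ValueError(f"unknown inference method {method!r}")


def run_quality_scan(config: ScanConfig,
                     spikes: SpikeTable | None = None) -> pd.DataFrame:
    """Fit and evaluate populations over the (N, δt) grid of the config.

    For each population: binarize, fit independent + pairwise models,
    compute entropies/KL/G with the exact partition function when
    N ≤ enumeration_limit and the configured estimator above it. Stage errors
    are recorded per row and the scan continues. Deterministic per seed.
    """
    if spikes is None:
        spikes = _load_spikes(config)
    rng = np.random.default_rng(config.seed)
    rows = []
    for delta_t in config.delta_t:
        raster_full = bin_spikes(spikes, delta_t)
        for n in config.n_grid:
            for pop in range(config.n_pops_per_n):
                pop_seed = int(rng.integers(2**31 - 1))
                row = {"n": n, "delta_t": delta_t, "population": pop,
                       "method": config.method, "seed": pop_seed}
                try:
                    idx = select_population(raster_full.rates, n,
                                            mode=config.selection_mode,
                                            seed=pop_seed)
                    sub = raster_full.subset(idx)
                    model = _fit(sub, config.method, pop_seed)
                    rep = evaluate_raster(sub, model, estimator=config.estimator,
                                          enumeration_limit=config.enumeration_limit)
                    row.update(mean_rate=sub.mean_rate,
                               perturbation_parameter=sub.perturbation_parameter,
                               s_data=rep.s_data, s_ind=rep.s_ind,
                               s_pair=rep.s_pair, d_pair=rep.d_pair,
                               d_ind=rep.d_ind, g=rep.g,
                               estimator=rep.estimator_tag,
                               flags=";".join(rep.flags), error="")
                except Exception as exc:  # record and continue
                    logger.warning("row (N=%d, δt=%g, pop=%d) failed: %s",
                                   n, delta_t, pop, exc)
                    row.update(error=str(exc))
                rows.append(row)
    df = pd.DataFrame(rows)
    _write_outputs(df, config)
    return df


def run_condition_comparison(config: ScanConfig,
                             masks: dict[str, list[tuple[float, float]]],
                             spikes: SpikeTable | None = None,
                             add_random_control: bool = True,
                             downsample_to_shortest: bool = False) -> pd.DataFrame:
    """Quality scan per labeled epoch mask with shared populations.

    Each named mask (e.g. lights-on vs lights-off intervals) is scanned with
    the same random populations, enabling paired comparison of d_pair, d_ind
    and G across conditions. A duration-matched "random" control mask built
    from random bins of the whole recording is appended unless disabled;
    optionally every condition is randomly downsampled to the duration of the
    shortest one.
    """
    if spikes is None:
        spikes = _load_spikes(config)
    for name, intervals in masks.items():
        if not intervals:
            raise ValueError(f"mask {name!r} is empty")
    rng = np.random.default_rng(config.seed)
    durations = {name: sum(b - a for a, b in intervals)
                 for name, intervals in masks.items()}

    rasters: dict[str, BinaryRaster] = {}
    delta_t = config.delta_t[0]
    for name, intervals in masks.items():
        rasters[name] = bin_spikes(spikes, delta_t, time_mask=intervals)
    if add_random_control:
        full = bin_spikes(spikes, delta_t)
        n_keep = int(min(durations.values()) / delta_t)
        keep = np.sort(rng.choice(full.n_bins, size=n_keep, replace=False))
        rasters["random_control"] = BinaryRaster(full.spins[:, keep], delta_t,
                                                 full.neuron_ids, full.rates)
    if downsample_to_shortest:
        t_min = min(r.n_bins for r in rasters.values())
        for name, r in rasters.items():
            keep = np.sort(rng.choice(r.n_bins, size=t_min, replace=False))
            rasters[name] = BinaryRaster(r.spins[:, keep], delta_t,
                                         r.neuron_ids, r.rates)

    rows = []
    base = next(iter(rasters.values()))
    for n in config.n_grid:
        for pop in range(config.n_pops_per_n):
            pop_seed = int(rng.integers(2**31 - 1))
            idx = select_population(base.rates, n, mode=config.selection_mode,
                                    seed=pop_seed)
            for name, raster in rasters.items():
                row = {"condition": name, "n": n, "population": pop,
                       "delta_t": delta_t, "method": config.method,
                       "seed": pop_seed}
                try:
                    sub = raster.subset(idx)
                    model = _fit(sub, config.method, pop_seed)
                    rep = evaluate_raster(sub, model, estimator=config.estimator,
                                          enumeration_limit=config.enumeration_limit)
                    row.update(d_pair=rep.d_pair, d_ind=rep.d_ind, g=rep.g,
                               s_data=rep.s_data, estimator=rep.estimator_tag,
                               flags=";".join(rep.flags), error="")
                except Exception as exc:
                    logger.warning("condition row failed: %s", exc)
                    row.update(error=str(exc))
                rows.append(row)
    df = pd.DataFrame(rows)
    _write_outputs(df, config, name="condition_comparison")
    return df


def _write_outputs(df: pd.DataFrame, config: ScanConfig,
                   name: str = "quality_scan") -> None:
    if config.out_dir is None:
        return
    import pathlib

    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / f"{name}.csv", index=False)
    config.to_yaml(out / f"{name}_config.yaml")
    logger.info("wrote %s rows to %s", len(df), out / f"{name}.csv")
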