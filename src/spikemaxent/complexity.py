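"""Spin-glass complexity diagnostics of a fitted pairwise model.

A fitted Ising model with zero-mean, wide couplings resembles the
Sherrington-Kirkpatrick (SK) model, whose strong-coupling "complex" phase has
a number of metastable states N_ms growing exponentially with N. Metastable
states are identified with solutions m of the TAP equations

    m_i = tanh[ h_i + Σ_j J_ij m_j − m_i Σ_j J_ij² (1 − m_j²) ],

whose last term is the Onsager reaction correction. Diagnostics computed
here: the coupling statistics (mean, std, the ratio f = std/mean, and the SK
parameters Ĵ0 = N·mean, Ĵ1 = √N·std), the stability parameter J1²S with
S = N⁻¹Σ(1−m_i²)² (the normal phase destabilizes when J1²S > 1), the
spin-glass susceptibility χ_SG = (1/N)Σ_{i≠j} C̃_ij², the multi-start
metastable count N_ms and the complexity Σ = N⁻¹ ln N_ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import PairwiseModel, enumerate_states, triu_indices
from .raster import BinaryRaster, Moments, compute_moments, select_population

__all__ = [
    "TapSolution",
    "ComplexityReport",
    "SkPrediction",
    "solve_tap",
    "count_metastable",
    "coupling_statistics",
    "stability_and_susceptibility",
    "predict_sk_stats",
    "complexity_scan",
    "count_single_flip_stable",
    "extrapolate_stability_crossing",
]

TAP_DAMPING = 0.5
TAP_TOL = 1e-10
TAP_MAX_ITER = 10_000
CLUSTER_TOL = 1e-3


@dataclass
class TapSolution:
    m: np.ndarray
    converged: bool
    residual: float
    n_iterations: int


@dataclass
class ComplexityReport:
    mean_j: float = float("nan")
    std_j: float = float("nan")
    f: float = float("nan")
    j0_hat: float = float("nan")
    j1_hat: float = float("nan")
    s_quantity: float = float("nan")
    stability: float = float("nan")
    chi_sg: float = float("nan")
    n_ms: int | None = None
    sigma: float | None = None
    n: int | None = None
    flags: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)


@dataclass
class SkPrediction:
    """SK-theory coupling statistics implied by the data moments."""

    predicted_mean_j: float
    predicted_std_j: float
    predicted_j0: float  # N · mean
    predicted_j1: float  # √N · std
    flags: list = field(default_factory=list)


def _tap_rhs(model: PairwiseModel, m: np.ndarray) -> np.ndarray:
    onsager = m * ((model.J**2) @ (1.0 - m**2))
    return np.tanh(model.h + model.J @ m - onsager)


def solve_tap(model: PairwiseModel, init: np.ndarray | None = None,
              damping: float = TAP_DAMPING, tol: float = TAP_TOL,
              max_iter: int = TAP_MAX_ITER) -> TapSolution:
    """Damped fixed-point iteration of the TAP equations.

    m ← damping·m + (1−damping)·tanh[h + Jm − m∘(J²(1−m²))]. Converged when
    the sup-norm update falls below tol. Non-convergence is returned as a
    flag, never raised.
    """
    if not 0 <= damping < 1:
        raise ValueError("damping must lie in [0, 1)")
    if tol <= 0:
        raise ValueError("tol must be positive")
    m = np.zeros(model.n) if init is None else np.asarray(init, dtype=float).copy()
    for it in range(1, max_iter + 1):
        target = _tap_rhs(model, m)
        m_new = damping * m + (1.0 - damping) * target
        delta = np.abs(m_new - m).max()
        m = m_new
        if delta < tol:
            residual = float(np.abs(m - _tap_rhs(model, m)).max())
            return TapSolution(m, True, residual, it)
    residual = float(np.abs(m - _tap_rhs(model, m)).max())
    return TapSolution(m, False, residual, max_iter)


def count_metastable(model: PairwiseModel, n_inits: int = 100, seed: int = 0,
                     cluster_tol: float = CLUSTER_TOL,
                     damping: float = TAP_DAMPING, tol: float = TAP_TOL,
                     max_iter: int = TAP_MAX_ITER):
    """Multi-start TAP solution count and complexity Σ = ln(N_ms)/N.

    From `n_inits` uniform random points in (−1,1)^N plus the all-zero
    initialization, each start is driven to a TAP solution by a Powell-hybrid
    root solve of the fixed-point defect (falling back to damped iteration
    when the root solve fails). Root solving matters in the strong-coupling
    regime, where plain damped iteration is attracted to the paramagnetic
    m = 0 solution and never reaches the glassy roots. Every candidate is
    verified by re-substitution (residual < 1e-9) before counting; verified
    solutions are greedily clustered with sup-norm radius `cluster_tol`.
    """
    from scipy.optimize import root

    if n_inits < 1:
        raise ValueError("n_inits must be ≥ 1")
    verify_tol = max(1e-9, tol)
    rng = np.random.default_rng(seed)
    inits = [np.zeros(model.n)]
    inits += [rng.uniform(-1, 1, size=model.n) for _ in range(n_inits)]
    centers: list[np.ndarray] = []
    n_nonconverged = 0

    def defect(m):
        return m - _tap_rhs(model, m)

    for init in inits:
        res = root(defect, init, method="hybr", tol=1e-12)
        if res.success and np.abs(defect(res.x)).max() < verify_tol \
                and np.abs(res.x).max() < 1.0:
            m_sol = res.x
        else:
            sol = solve_tap(model, init, damping=damping, tol=tol,
                            max_iter=max_iter)
            if not sol.converged or sol.residual >= verify_tol:
                n_nonconverged += 1
                continue
            m_sol = sol.m
        for c in centers:
            if np.abs(m_sol - c).max() < cluster_tol:
                break
        else:
            centers.append(m_sol)
    report = ComplexityReport(n=model.n, meta={
        "cluster_tol": cluster_tol,
        "n_inits": n_inits + 1,
        "n_nonconverged": n_nonconverged,
        "centers": centers,
        "center_residuals": [float(np.abs(c - _tap_rhs(model, c)).max())
                             for c in centers],
    })
    if not centers:
        report.flags.append("undefined:no_converged_tap_start")
        return report
    report.n_ms = len(centers)
    report.sigma = float(np.log(len(centers)) / model.n)
    return report


def coupling_statistics(model: PairwiseModel) -> ComplexityReport:
    """Mean, population std, f = std/mean, and SK parameters of the couplings.

    Statistics are over the C(N,2) upper-triangle couplings; Ĵ0 = N·mean and
    Ĵ1 = √N·std invert the SK parameterization (mean J0/N, std J1/√N).
    f is flagged infinite when the mean is exactly zero.
    """
    if model.n < 2:
        raise ValueError("coupling statistics need N ≥ 2")
    Ju = model.couplings_upper
    mean_j = float(Ju.mean())
    std_j = float(Ju.std())  # population std
    report = ComplexityReport(mean_j=mean_j, std_j=std_j, n=model.n,
                              j0_hat=model.n * mean_j,
                              j1_hat=np.sqrt(model.n) * std_j)
    if mean_j == 0.0:
        report.f = float("inf")
        report.flags.append("f:zero_mean_coupling")
    else:
        report.f = std_j / mean_j
    return report


def stability_and_susceptibility(model: PairwiseModel, tap: TapSolution,
                                 moments: Moments,
                                 report: ComplexityReport | None = None) -> ComplexityReport:
    """S = N⁻¹Σ(1−m_i²)², the stability J1²S, and χ_SG from the data moments."""
    if not tap.converged:
        raise ValueError("stability requires a converged TAP solution")
    if report is None:
        report = coupling_statistics(model)
    m = tap.m
    report.s_quantity = float(np.mean((1.0 - m**2) ** 2))
    report.stability = report.j1_hat**2 * report.s_quantity
    C = moments.connected
    off = ~np.eye(moments.n, dtype=bool)
    report.chi_sg = float(np.sum(C[off] ** 2) / moments.n)
    return report


def predict_sk_stats(moments: Moments, n: int | None = None) -> SkPrediction:
    """SK mean-field prediction of the coupling statistics from data moments.

    Uses the weak-coupling linear-response relation
    J_ij ≈ C̃_ij / [(1−m_i²)(1−m_j²)] per pair; the mean and population std of
    those values over i<j give the predicted coupling statistics, and
    N·mean, √N·std the implied SK parameters. For data generated from an SK
    ensemble this recovers the generating J0/N and J1/√N. Degenerate moments
    (all connected correlations zero) yield predicted std 0, flagged.
    """
    n = moments.n if n is None else n
    m = moments.means
    C = moments.connected
    iu = triu_indices(moments.n)
    L = 1.0 - m**2
    denom = np.outer(L, L)[iu]
    if np.any(denom <= 0):
        raise ValueError("saturated means make the linear-response inversion singular")
    j_pred = C[iu] / denom
    flags = []
    if np.allclose(C[iu], 0.0):
        flags.append("degenerate:zero_connected_correlations")
    mean_j = float(j_pred.mean())
    std_j = float(j_pred.std())
    return SkPrediction(mean_j, std_j, n * mean_j, np.sqrt(n) * std_j, flags=flags)


def count_single_flip_stable(model: PairwiseModel) -> int:
    """States stable against every single spin flip (enumerated, N ≤ 20).

    The looser metastability notion used by earlier population-coding work,
    provided for comparison with the TAP-based count: a state s is counted
    when s_i·(h_i + Σ_j J_ij s_j) > 0 for every i.
    """
    if model.n > 20:
        raise ValueError("single-flip enumeration limited to N ≤ 20")
    S = enumerate_states(model.n)
    local = model.h + S @ model.J  # (2^N, N) local fields
    return int(np.all(S * local > 0, axis=1).sum())


def complexity_scan(raster: BinaryRaster, n_grid: list[int],
                    n_pops_per_n: int = 5, method: str = "pl", seed: int = 0,
                    n_inits: int = 0) -> pd.DataFrame:
    """Coupling statistics and stability across population sizes.

    For each N in `n_grid`, fits `n_pops_per_n` randomly selected populations
    with the requested inference method, then computes coupling statistics,
    a zero-init TAP solution and the stability/susceptibility diagnostics
    (plus a metastable count when n_inits > 0). Returns one row per
    population; deterministic for a fixed seed.
    """
    from .inference import fit_mean_field_family, fit_pseudolikelihood

    rng = np.random.default_rng(seed)
    rows = []
    for n in n_grid:
        if n > raster.n_neurons:
            raise ValueError(f"N={n} exceeds the {raster.n_neurons} available neurons")
        for pop in range(n_pops_per_n):
            idx = select_population(raster.rates, n, mode="random", seed=rng)
            sub = raster.subset(idx)
            moments = compute_moments(sub)
            if method == "pl":
                model = fit_pseudolikelihood(sub)
            else:
                model = fit_mean_field_family(moments, method=method)
            rep = coupling_statistics(model)
            tap = solve_tap(model)
            row = {"n": n, "population": pop, "method": method,
                   "mean_j": rep.mean_j, "std_j": rep.std_j, "f": rep.f,
                   "j0_hat": rep.j0_hat, "j1_hat": rep.j1_hat,
                   "tap_converged": tap.converged}
            if tap.converged:
                rep = stability_and_susceptibility(model, tap, moments, rep)
                row.update(s_quantity=rep.s_quantity, stability=rep.stability,
                           chi_sg=rep.chi_sg)
            if n_inits > 0:
                ms = count_metastable(model, n_inits=n_inits,
                                      seed=int(rng.integers(2**31 - 1)))
                row.update(n_ms=ms.n_ms, sigma=ms.sigma)
            rows.append(row)
    return pd.DataFrame(rows)


def extrapolate_stability_crossing(scan: pd.DataFrame,
                                   fit_range: tuple[int, int] | None = None) -> float:
    """Linear extrapolation of the per-N mean stability to the J1²S = 1 boundary.

    Fits stability against N over `fit_range` (inclusive) and returns the N at
    which the fitted line crosses 1 (inf if the slope is non-positive and the
    line never reaches it).
    """
    per_n = scan.groupby("n")["stability"].mean()
    if fit_range is not None:
        per_n = per_n[(per_n.index >= fit_range[0]) & (per_n.index <= fit_range[1])]
    if per_n.size < 2:
        raise ValueError("need at least two population sizes to extrapolate")
    slope, intercept = np.polyfit(per_n.index.to_numpy(float), per_n.to_numpy(), 1)
    if slope <= 0:
        return float("inf") if intercept < 1 else 0.0
    return float((1.0 - intercept) / slope)
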