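"""Inference of independent, pairwise and triplet maximum-entropy models.

Six routes to the pairwise couplings are provided, mirroring the standard
toolbox of the inverse-Ising literature:

- pseudo-likelihood maximization (N independent logistic problems, couplings
  symmetrized as (J_ij + J_ji)/2),
- Boltzmann learning (gradient ascent on the likelihood, with model moments
  from exact enumeration or persistent Gibbs chains),
- naive mean field (nMF), Thouless-Anderson-Palmer (TAP), independent-pair
  (IP) and Sessak-Monasson (SM) inversions of the measured moments.

No regularization is applied by default; a tiny ridge (1e-6) is used only as
a recorded fallback when a pseudo-likelihood sub-problem is perfectly
separable.
"""

from __future__ import annotations

import warnings

import numpy as np

from ._samplers import gibbs_persistent_sweep
from .models import (IndependentModel, PairwiseModel, TripletModel,
                     enumerate_states, triu_indices)
from .raster import BinaryRaster, Moments

__all__ = [
    "fit_independent",
    "fit_pseudolikelihood",
    "fit_boltzmann",
    "fit_mean_field_family",
    "fit_exact_maxent",
    "fit_triplet_boltzmann",
]

PL_GRAD_TOL = 1e-8
PL_RIDGE_FALLBACK = 1e-6


def _clip_means(means: np.ndarray, n_samples: int | None) -> tuple[np.ndarray, np.ndarray]:
    """Clip means into [−1+ε, 1−ε], ε = 1/(2T); returns (clipped, was_clipped)."""
    eps = 1.0 / (2 * n_samples) if n_samples else 1e-12
    clipped = np.clip(means, -1.0 + eps, 1.0 - eps)
    return clipped, clipped != means


def fit_independent(moments: Moments) -> IndependentModel:
    """Independent-model fields h_i = atanh(⟨s_i⟩), with saturation clipping."""
    m, flags = _clip_means(moments.means, moments.n_samples)
    return IndependentModel(np.arctanh(m), clipped=flags)


# ---------------------------------------------------------------------------
# Pseudo-likelihood


def _compress(data, weights=None):
    """Reduce (samples, weights) to unique patterns with merged weights."""
    if isinstance(data, BinaryRaster):
        samples = np.ascontiguousarray(data.spins.T)
    else:
        samples = np.ascontiguousarray(np.asarray(data, dtype=np.int8))
    T = samples.shape[0]
    if weights is None:
        patterns, counts = np.unique(samples, axis=0, return_counts=True)
        w = counts / T
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.size != T:
            raise ValueError("weights must have one entry per sample")
        if not np.isclose(weights.sum(), 1.0, atol=1e-8):
            raise ValueError("weights must sum to 1")
        patterns, inv = np.unique(samples, axis=0, return_inverse=True)
        w = np.zeros(patterns.shape[0])
        np.add.at(w, inv, weights)
    return patterns.astype(np.float64), w, T


def _logistic_newton(Z, y, w, ridge=0.0, tol=PL_GRAD_TOL, max_iter=200):
    """Maximize Σ_t w_t log σ(2 y_t (Z_t·θ)) by damped Newton; returns (θ, grad∞, ok)."""
    n_feat = Z.shape[1]
    theta = np.zeros(n_feat)
    for _ in range(max_iter):
        a = Z @ theta
        # u = dL/da = 2 y σ(−2 y a)
        u = 2.0 * y / (1.0 + np.exp(2.0 * y * a))
        grad = Z.T @ (w * u) - ridge * theta
        gnorm = np.abs(grad).max()
        if gnorm < tol:
            # a "converged" solution with enormous weights is separation in
            # disguise: the gradient vanishes exponentially along the ray
            ok = ridge > 0 or np.abs(theta).max() < 8.0
            return theta, gnorm, ok
        s = 1.0 / (1.0 + np.exp(-2.0 * a))
        d = w * 4.0 * s * (1.0 - s)
        H = (Z * d[:, None]).T @ Z + (ridge + 1e-14) * np.eye(n_feat)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return theta, gnorm, False
        # backtracking on the (concave) objective is rarely needed; cap huge steps
        norm = np.abs(step).max()
        if norm > 10.0:
            step *= 10.0 / norm
        theta = theta + step
        if not np.all(np.isfinite(theta)) or np.abs(theta).max() > 1e3:
            return theta, gnorm, False
    a = Z @ theta
    u = 2.0 * y / (1.0 + np.exp(2.0 * y * a))
    grad = Z.T @ (w * u) - ridge * theta
    return theta, np.abs(grad).max(), np.abs(grad).max() < tol


def fit_pseudolikelihood(data, weights=None) -> PairwiseModel:
    """Pairwise model by pseudo-likelihood maximization.

    `data` is a BinaryRaster or an (T, N) array of ±1 sample rows; optional
    per-sample `weights` (summing to 1) allow fitting to exact state
    probabilities. Each neuron's conditional distribution defines an
    unregularized logistic problem solved by Newton iteration to gradient
    sup-norm < 1e-8; the asymmetric solution is symmetrized as (J_ij+J_ji)/2.
    Perfectly separable sub-problems fall back to a tiny ridge (1e-6) and are
    recorded in ``meta["ridge_neurons"]``.
    """
    patterns, w, T = _compress(data, weights)
    if T < 2:
        raise ValueError("pseudo-likelihood needs at least two samples")
    n = patterns.shape[1]
    H = np.zeros(n)
    J_asym = np.zeros((n, n))
    grad_norms = np.zeros(n)
    ridge_neurons = []
    for i in range(n):
        others = np.delete(np.arange(n), i)
        Z = np.column_stack([np.ones(patterns.shape[0]), patterns[:, others]])
        y = patterns[:, i]
        theta, gnorm, ok = _logistic_newton(Z, y, w)
        if not ok:
            theta, gnorm, ok = _logistic_newton(Z, y, w, ridge=PL_RIDGE_FALLBACK)
            ridge_neurons.append(i)
            if not ok:
                warnings.warn(f"pseudo-likelihood sub-problem for neuron {i} "
                              f"did not reach tolerance (grad∞={gnorm:.2e})")
        H[i] = theta[0]
        J_asym[i, others] = theta[1:]
        grad_norms[i] = gnorm
    if ridge_neurons:
        warnings.warn(f"perfect separation: ridge fallback used for neurons "
                      f"{ridge_neurons}")
    J = 0.5 * (J_asym + J_asym.T)
    np.fill_diagonal(J, 0.0)
    return PairwiseModel(H, J, method_tag="pl",
                         meta={"grad_sup_norm": float(grad_norms.max()),
                               "ridge_neurons": ridge_neurons,
                               "n_samples": T})


# ---------------------------------------------------------------------------
# Boltzmann learning


def _pair_products(states: np.ndarray) -> np.ndarray:
    iu = triu_indices(states.shape[1])
    return states[:, iu[0]] * states[:, iu[1]]


def fit_boltzmann(moments: Moments, eta: float = 0.01, n_iter: int = 100_000,
                  gradient_mode: str = "exact", n_mc_samples: int = 25_000,
                  seed: int = 0, init: PairwiseModel | None = None) -> PairwiseModel:
    """Boltzmann learning: Δh_i = η(⟨s_i⟩_data − ⟨s_i⟩_model), likewise for J_ij.

    Model moments come from exact enumeration (N ≤ 20) or from persistent
    Gibbs chains ("mc" mode, one random-scan sweep of every chain per
    iteration). Divergence — the worst moment discrepancy growing tenfold over
    1000 iterations — aborts with diagnostics. Defaults are the conventional
    exact-mode setting (η = 0.01, 100000 iterations); large-N sampled runs
    typically use η = 0.001 with tens of thousands of samples per iteration.
    """
    n = moments.n
    iu = triu_indices(n)
    m_data = moments.means
    c_data = moments.correlations[iu]
    if init is not None:
        h, Ju = init.h.copy(), init.couplings_upper.copy()
    else:
        h, Ju = np.zeros(n), np.zeros(iu[0].size)

    disc_hist = []
    if gradient_mode == "exact":
        if n > 20:
            raise ValueError("exact Boltzmann learning requires N ≤ 20")
        S = enumerate_states(n)
        P2 = _pair_products(S)
        for it in range(n_iter):
            loge = S @ h + P2 @ Ju
            loge -= loge.max()
            p = np.exp(loge)
            p /= p.sum()
            dm = m_data - p @ S
            dc = c_data - p @ P2
            disc = max(np.abs(dm).max(), np.abs(dc).max())
            disc_hist.append(disc)
            _check_divergence(disc_hist, it, h, Ju)
            h += eta * dm
            Ju += eta * dc
    elif gradient_mode == "mc":
        rng = np.random.default_rng(seed)
        chains = np.where(rng.random((n_mc_samples, n)) < 0.5, 1.0, -1.0)
        J = _expand(Ju, n)
        for it in range(n_iter):
            gibbs_persistent_sweep(h, J, chains, 1,
                                   int(rng.integers(0, 2**31 - 1)))
            dm = m_data - chains.mean(axis=0)
            dc = c_data - _pair_products(chains).mean(axis=0)
            disc = max(np.abs(dm).max(), np.abs(dc).max())
            disc_hist.append(disc)
            _check_divergence(disc_hist, it, h, Ju)
            h += eta * dm
            Ju += eta * dc
            J = _expand(Ju, n)
    else:
        raise ValueError(f"unknown gradient_mode {gradient_mode!r}")

    J = _expand(Ju, n)
    return PairwiseModel(h, J, method_tag=f"boltzmann:{gradient_mode}",
                         meta={"iterations": n_iter,
                               "final_moment_discrepancy": float(disc_hist[-1]),
                               "eta": eta})


def fit_exact_maxent(moments: Moments, gtol: float = 1e-10) -> PairwiseModel:
    """High-precision pairwise fit by direct convex optimization (N ≤ 20).

    Minimizes log Z(h, J) − (h, J)·(data moments) — the exact negative
    log-likelihood up to a constant — with L-BFGS and analytic gradients.
    Reaches moment matching far beyond what plain gradient ascent achieves in
    reasonable time, which matters when the KL divergences being measured are
    themselves tiny.
    """
    from scipy.optimize import minimize
    from scipy.special import logsumexp

    n = moments.n
    if n > 20:
        raise ValueError("exact maximum-likelihood fitting requires N ≤ 20")
    iu = triu_indices(n)
    S = enumerate_states(n)
    D = np.hstack([S, _pair_products(S)])
    target = np.concatenate([moments.means, moments.correlations[iu]])

    def objective(theta):
        loge = D @ theta
        lz = logsumexp(loge)
        p = np.exp(loge - lz)
        return lz - theta @ target, p @ D - target

    res = minimize(objective, np.zeros(D.shape[1]), jac=True, method="L-BFGS-B",
                   options={"maxiter": 20_000, "ftol": 1e-18, "gtol": gtol})
    h, Ju = res.x[:n], res.x[n:]
    return PairwiseModel(h, _expand(Ju, n), method_tag="exact_ml",
                         meta={"iterations": int(res.nit),
                               "final_moment_discrepancy": float(np.abs(res.jac).max())})


def _expand(Ju: np.ndarray, n: int) -> np.ndarray:
    J = np.zeros((n, n))
    J[triu_indices(n)] = Ju
    return J + J.T


def _check_divergence(disc_hist, it, h, Ju):
    if it >= 1000 and disc_hist[-1] > 10.0 * disc_hist[-1001] and disc_hist[-1] > 1e-6:
        raise RuntimeError(
            f"Boltzmann learning diverging at iteration {it}: moment "
            f"discrepancy {disc_hist[-1]:.3e} vs {disc_hist[-1001]:.3e} 1000 "
            f"iterations earlier; max|h|={np.abs(h).max():.2f}, "
            f"max|J|={np.abs(Ju).max():.2f}")


# ---------------------------------------------------------------------------
# Mean-field family: nMF, TAP, IP, SM


def _pair_marginals(mi, mj, chi, eps):
    """2×2 pair marginal p(s_i=a, s_j=b), floored at eps and renormalized."""
    p = np.empty(4)
    for k, (a, b) in enumerate(((1, 1), (1, -1), (-1, 1), (-1, -1))):
        p[k] = (1.0 + a * mi + b * mj + a * b * chi) / 4.0
    p = np.maximum(p, eps)
    return p / p.sum()


def fit_mean_field_family(moments: Moments, method: str = "nmf") -> PairwiseModel:
    """Approximate inversion of the measured moments: nMF, TAP, IP or SM.

    - nmf: J = −(C⁻¹) off-diagonal; h_i = atanh(m_i) − Σ_j J_ij m_j.
    - tap: per-pair root of 2J²m_i m_j + J + (C⁻¹)_ij = 0 on the branch that
      reduces to nMF as couplings vanish; TAP fields include the Onsager
      reaction term.
    - ip: exact two-spin inversion from each 2×2 pair marginal,
      J_ij = ¼ ln[(p₊₊p₋₋)/(p₊₋p₋₊)].
    - sm: Sessak-Monasson small-correlation series combined with the IP
      resummation, J = J_nMF + J_IP − c_ij/[(1−m_i²)(1−m_j²) − c_ij²].

    A pseudocount of 1/(2T) guards the pair marginals (ip/sm) and the atanh.
    Overflowing SM pairs are recorded in ``meta["overflow_pairs"]``.
    """
    n = moments.n
    T = moments.n_samples
    eps = 1.0 / (2 * T) if T else 1e-12
    m, _ = _clip_means(moments.means, T)
    C = moments.correlations - np.outer(m, m)
    np.fill_diagonal(C, 1.0 - m**2)
    iu = triu_indices(n)
    meta: dict = {}

    if method in ("nmf", "tap", "sm"):
        eigvals = np.linalg.eigvalsh(C)
        if np.min(np.abs(eigvals)) < 1e-12:
            raise np.linalg.LinAlgError(
                f"connected covariance is singular (eigenvalue "
                f"{eigvals[np.argmin(np.abs(eigvals))]:.3e})")
        A = np.linalg.inv(C)
        J_nmf = -A.copy()
        np.fill_diagonal(J_nmf, 0.0)
        J_nmf = 0.5 * (J_nmf + J_nmf.T)

    if method in ("ip", "sm"):
        J_ip = np.zeros((n, n))
        h_pair_sum = np.zeros(n)
        chi = moments.correlations
        for a, b in zip(*iu):
            p = _pair_marginals(m[a], m[b], chi[a, b], eps)
            ppp, ppm, pmp, pmm = p
            J_ip[a, b] = J_ip[b, a] = 0.25 * np.log((ppp * pmm) / (ppm * pmp))
            h_pair_sum[a] += 0.25 * np.log((ppp * ppm) / (pmp * pmm))
            h_pair_sum[b] += 0.25 * np.log((ppp * pmp) / (ppm * pmm))

    h_ind = np.arctanh(m)
    if method == "nmf":
        J = J_nmf
        h = h_ind - J @ m
    elif method == "tap":
        J = np.zeros((n, n))
        fallback = []
        for a, b in zip(*iu):
            prod = m[a] * m[b]
            if abs(prod) < 1e-12:
                J[a, b] = J[b, a] = -A[a, b]
                continue
            disc = 1.0 - 8.0 * A[a, b] * prod
            if disc < 0:
                J[a, b] = J[b, a] = -A[a, b]
                fallback.append((int(a), int(b)))
                continue
            J[a, b] = J[b, a] = (-1.0 + np.sqrt(disc)) / (4.0 * prod)
        if fallback:
            meta["tap_nmf_fallback_pairs"] = fallback
        h = h_ind - J @ m + m * ((J**2) @ (1.0 - m**2))
    elif method == "ip":
        J = J_ip
        # field from each pair minus the (n−2)-fold over-counted single-spin term
        h = h_pair_sum - (n - 2) * h_ind
    elif method == "sm":
        c = C.copy()
        L = 1.0 - m**2
        denom = np.outer(L, L) - c**2
        with np.errstate(divide="ignore", invalid="ignore"):
            pair_nmf = c / denom
        J = J_nmf + J_ip - pair_nmf
        np.fill_diagonal(J, 0.0)
        bad = ~np.isfinite(J[iu])
        if bad.any():
            meta["overflow_pairs"] = [(int(a), int(b)) for a, b in
                                      zip(iu[0][bad], iu[1][bad])]
            warnings.warn(f"SM inversion overflowed on {int(bad.sum())} pairs; "
                          "entries left non-finite and flagged")
        h = h_ind - np.where(np.isfinite(J), J, 0.0) @ m
    else:
        raise ValueError(f"unknown method {method!r}")

    np.fill_diagonal(J, 0.0)
    return PairwiseModel(h, 0.5 * (J + J.T), method_tag=method, meta=meta)


# ---------------------------------------------------------------------------
# Triplet Boltzmann learning


def _triple_products(states: np.ndarray):
    n = states.shape[1]
    idx = np.array([(i, j, r) for i in range(n) for j in range(i + 1, n)
                    for r in range(j + 1, n)], dtype=np.int64)
    if idx.size == 0:
        raise ValueError("triplet model needs N ≥ 3")
    P3 = states[:, idx[:, 0]] * states[:, idx[:, 1]] * states[:, idx[:, 2]]
    return P3, idx


def fit_triplet_boltzmann(data, eta: float = 0.01, n_iter: int = 100_000,
                          seed: int = 0, weights=None) -> TripletModel:
    """Maximum-entropy model with third-order interactions K_ijr.

    Boltzmann learning matching first, second and third moments, with exact
    enumeration of the model moments (hence N ≤ 15). `data` is a BinaryRaster
    or an (T, N) array of ±1 rows with optional per-sample weights.
    """
    patterns, w, _ = _compress(data, weights)
    n = patterns.shape[1]
    if n > 15:
        raise ValueError("triplet Boltzmann learning requires N ≤ 15")
    iu = triu_indices(n)
    m_data = w @ patterns
    c_data = w @ (patterns[:, iu[0]] * patterns[:, iu[1]])
    P3_data, idx3 = _triple_products(patterns)
    t_data = w @ P3_data

    S = enumerate_states(n)
    P2 = _pair_products(S)
    P3, _ = _triple_products(S)

    h = np.zeros(n)
    Ju = np.zeros(iu[0].size)
    Ku = np.zeros(idx3.shape[0])
    disc_hist = []
    for it in range(n_iter):
        loge = S @ h + P2 @ Ju + P3 @ Ku
        loge -= loge.max()
        p = np.exp(loge)
        p /= p.sum()
        dm = m_data - p @ S
        dc = c_data - p @ P2
        dt = t_data - p @ P3
        disc = max(np.abs(dm).max(), np.abs(dc).max(), np.abs(dt).max())
        disc_hist.append(disc)
        _check_divergence(disc_hist, it, h, Ju)
        h += eta * dm
        Ju += eta * dc
        Ku += eta * dt

    J = _expand(Ju, n)
    K = np.zeros((n, n, n))
    for (i, j, r), v in zip(idx3, Ku):
        for a, b, c in ((i, j, r), (i, r, j), (j, i, r), (j, r, i), (r, i, j), (r, j, i)):
            K[a, b, c] = v
    return TripletModel(h, J, K, meta={
        "iterations": n_iter,
        "final_moment_discrepancy": float(disc_hist[-1]),
        "eta": eta,
    })
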