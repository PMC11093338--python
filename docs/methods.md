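# Methods

This note documents the models, estimators, numerical choices and synthetic
data behind `spikemaxent`, and what the test suite does and does not
establish.

## Binarization and moments

Spike tables (neuron id, time) are binned at δt with half-open bins
[t₀+kδt, t₀+(k+1)δt); a trailing partial bin is dropped. A neuron is +1 in a
bin iff it spikes at least once there; everything downstream uses the ±1
convention ({0,1} conversion exists only at the I/O boundary). Time masks
(condition splitting, session concatenation) keep only bins lying entirely
inside a mask interval, so no bin straddles an epoch boundary; rates are
spike counts in retained bins over retained time. All entropies and KL
divergences are in nats.

The empirical distribution is the plug-in pattern-frequency map; its entropy
estimator is biased downward by roughly (|O|−1)/2T, which is why the
goodness calibration experiments use T = 10⁵–10⁶ samples. Ties for the
most-sampled state s₀ are broken lexicographically (−1 < +1), which
coincides with "the silent state" whenever it is among the ties.

## Models and inference

- **Independent**: h_i = atanh⟨s_i⟩, with means clipped to [−1+ε, 1−ε],
  ε = 1/(2T) — a pseudocount-scale guard for silent or saturated neurons;
  clipped neurons are flagged on the returned model.
- **Pseudo-likelihood**: N separate logistic problems
  max Σ_t w_t log σ(2 s_i (h_i + Σ_j J_ij s_j)), solved by damped Newton on
  data compressed to unique patterns (a large speedup at small N), to
  gradient sup-norm 1e-8, unregularized. The asymmetric solution is
  symmetrized as (J_ij+J_ji)/2. Perfect separation — including "converged"
  solutions with |θ| > 8, where the gradient vanishes along a ray — falls
  back to a tiny ridge (1e-6) and is recorded in `meta["ridge_neurons"]`.
  Optional per-sample weights allow fitting to exact state probabilities,
  which recovers a pairwise-model's parameters to ~1e-8 and serves as the
  consistency oracle in tests.
- **Boltzmann learning**: Δh = η(⟨s⟩_data − ⟨s⟩_model), likewise for J.
  Model moments come from exact enumeration (N ≤ 20) or from persistent
  Gibbs chains (one random-scan sweep of every chain per iteration; chains
  persist across iterations, an implementation choice for efficiency).
  Defaults η = 0.01, 10⁵ iterations (exact mode); divergence — the worst
  moment gap growing tenfold over 1000 iterations — aborts with diagnostics.
- **fit_exact_maxent**: the same maximum-likelihood problem solved directly
  by L-BFGS on log Z(θ) − θ·(data moments) with analytic gradients (convex).
  Used wherever moment matching beyond ~1e-6 matters — notably the
  perturbative sweep, where the KL divergences being measured are O((ν̄δt)²)
  and plain gradient ascent's residual moment error would dominate.
- **Mean-field family** (from moments only): nMF J = −(C⁻¹) off-diagonal;
  TAP solves the per-pair quadratic 2J²m_i m_j + J + (C⁻¹)_ij = 0 on the
  branch continuous with nMF at zero coupling (negative discriminants fall
  back to the nMF value and are flagged); IP inverts each 2×2 pair marginal
  exactly, J = ¼ ln[(p₊₊p₋₋)/(p₊₋p₋₊)], with fields assembled as
  h_i = Σ_{j≠i} h_i^{(ij)} − (N−2)·atanh(m_i); SM combines the
  small-correlation series with the IP resummation,
  J = J_nMF + J_IP − c_ij/[(1−m_i²)(1−m_j²) − c_ij²]. Pair marginals are
  floored at 1/(2T) and renormalized; non-finite SM pairs are flagged and
  left non-finite rather than silently patched.
- **Triplet model**: adds a fully symmetric K_ijr (zero on repeated
  indices); fitted by Boltzmann learning with exact enumeration (N ≤ 15),
  matching first, second and third moments.

## Partition functions and goodness

Exact log Z is a logsumexp over all 2^N states (limit 20 spins pairwise, 15
with triplets; the state matrix is cached and shared). The sample-based
estimators work entirely in log space: Ẑ as
logsumexp(−2E) − logsumexp(log p + (−E)) over observed states; the
most-sampled estimator −E(s₀) − log p(s₀); mean and median of the ratios
e^{−E}/p, with the median taken on log-ratios (even-count median = midpoint
of the two central log-ratios) to avoid overflow. With p_data equal to the
model's exact probabilities over all states, every ratio equals Z and all
four estimators are exact to machine precision — the identity the tests pin
at 1e-10.

S_pair = −Σ h_i⟨s_i⟩ − Σ J_ij⟨s_i s_j⟩ + log Z, the cross-entropy form
valid for moment-matched fits; S_ind has the closed binary-entropy form.
G = (S_ind − S_pair)/(S_ind − S_data); results computed with an estimated
partition function are tagged as Ĝ so that estimator bias (Ĝ slightly
above G) is itself observable. Negative G is returned with an outlier flag,
never dropped; d_ind = 0 yields a flagged NaN. When the true distribution is
known (synthetic sweeps), `goodness_from_probabilities` computes all terms
by direct enumeration and no moment-matching assumption enters.

## Synthetic data: what it emulates, what it does not

`GroundTruthSpec` defaults encode the cortical regime the analysis targets:
log-normal rates with mean 6.27 Hz and SD 1.24 Hz (visual-cortex-like; other
areas' presets reach down to ~1.2 Hz with bin sizes 0.02–0.14 s), reference
bin 0.02 s, and weak mixed-sign couplings (`coupling_scale` 0.1, a free
parameter swept in tests since the real recordings' coupling strength is not
independently specified). Fields map a drawn rate ν to an isolated-spin
probability p = νδt (rejected at p ≥ 1). The SK branch draws
J ~ Gaussian(J0/N, J1/√N) i.i.d. on i<j, mirrored. Surrogate spike tables
place one spike uniformly inside each +1 bin — downstream analysis is
invariant to within-bin timing — so re-binarization reproduces the
generating raster exactly and the full raster pipeline is exercised.

For the perturbative sweep a pairwise ground truth is useless (its true G is
exactly 1), so `make_higher_order_truth` builds distributions with genuine
third-order structure: fixed random Gaussian pair and triplet interactions
in lattice-gas (0/1) coordinates, with a uniform field tuned by root-finding
so the mean occupancy equals ν̄δt. In this family connected correlations of
order k scale as (ν̄δt)^k, reproducing the mechanism that makes
d_ind ~ (Nν̄δt)² and d_pair ~ (Nν̄δt)³, hence 1−G linear in Nν̄δt. Both
interaction scales default to 0.6; the linearity is a statement about the
per-occupancy median of 1−G (individual truths scatter with their own
heterogeneity), which is how the slope fit aggregates.

None of the generators emulate non-stationarity, refractoriness, common
slow input, or spike-sorting artifacts. Passing tests therefore certify the
estimators and the pipeline mechanics, not the biological conclusions one
would draw from real recordings.

## TAP equations and complexity

`solve_tap` iterates m ← λm + (1−λ)tanh[h + Jm − m∘(J²(1−m²))] with damping
λ = 0.5, tol 1e-10, max 10⁴ iterations; the Onsager reaction term carries
the m_i factor (the standard form). Non-convergence is a returned flag,
never an exception.

`count_metastable` does not rely on that iteration to *find* solutions:
damped fixed-point iteration is attracted to the paramagnetic m = 0 root at
strong coupling and never reaches the glassy solutions. Each random start
(uniform in (−1,1)^N, plus the zero start) is instead driven by a
Powell-hybrid root solve of the fixed-point defect, with damped iteration as
fallback; every candidate is verified by re-substitution (residual < 1e-9)
before counting, and verified solutions are clustered with sup-norm radius
1e-3 (large enough to merge numerically identical roots, far below the
separation of genuine ones). N_ms is the cluster count, Σ = ln(N_ms)/N. At
finite N only a fraction of strongly coupled SK draws possess nontrivial TAP
roots at all — the nontrivial branch can vanish as the Onsager term comes in
— so ensemble statements are made over batches of draws. The looser
single-spin-flip stability count is provided separately
(`count_single_flip_stable`) for comparison; it typically far exceeds the
TAP count.

Coupling statistics use the population std over the C(N,2) upper-triangle
couplings; f = std/mean is flagged infinite at exactly zero mean. The SK
parameters are read off as Ĵ0 = N·mean and Ĵ1 = √N·std, and the stability
parameter is Ĵ1²S. χ_SG is implemented as (1/N)Σ_{i≠j}C̃_ij², the standard
zero-field form. `predict_sk_stats` maps data moments to implied coupling
statistics through the weak-coupling linear-response relation
J_ij ≈ C̃_ij/[(1−m_i²)(1−m_j²)]; on data simulated from an SK ensemble this
recovers the generating J0/N and J1/√N (tested at N = 64 within 25%), and
degenerate moments (no connected correlations) yield a flagged zero.

## Workflows

Scans iterate (δt, N, population), fit the requested method, and evaluate
with the exact partition function up to the enumeration limit (20, 
configurable) and the chosen estimator above it. Every row carries the seed,
method and estimator tags, and flags, so any row can be re-run in isolation;
stage errors are recorded per row and the scan continues. Negative-Ĝ rows
are flagged, never dropped — outlier filtering is a post-hoc analyst
decision. Condition comparisons share populations across masks, add a
duration-matched random-bin control by default, and can downsample all
conditions to the shortest.

## Problem sizes in the default test run

The acceptance-style experiments run at sizes chosen to make each property
detectable with comfortable margin: estimator benchmark 24 models × 50 000
samples at N = 20 (the script uses 50 models); parameter recovery 3 models ×
10⁶ samples at N = 10; goodness calibration at N ∈ {5,10,15} with 10⁶
samples (pairwise truth) and 24–50 independent-truth seeds with 10⁵ samples;
perturbative sweep 5 truths × 7 occupancies at N = 10, evaluated exactly;
complexity mechanics over batches of 6–12 SK draws per N. Thresholds
(1e-10 identity, 5% estimator error, 1e-3 moment matching, 0.02 coupling
RMSE, G ≥ 0.9 / |G| < 0.1 calibration, R² ≥ 0.8 linearity, −0.5±0.15
scaling slope) are fixed properties of the methods, not tuned to the runs.

## Known limitations

- Exact anything stops at 20 spins (15 with triplets); beyond that all
  statements go through sampling and Ẑ, inheriting their biases.
- The Gibbs sampler is single-site; at strong coupling (deep glassy phase)
  its mixing time is exactly the pathology the complexity diagnostics
  measure, so sampled moments there should be treated with suspicion.
- The SM inversion follows the series-plus-IP combination to the order
  stated above; stronger correlations can overflow individual pairs, which
  are flagged rather than repaired.
- `subsample_robustness` uses contiguous blocks to respect temporal
  dependence; it probes finite-data bias trends, not a bias correction.
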