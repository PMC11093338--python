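# spikemaxent

Pairwise maximum-entropy (PME) models of binarized neural population
activity: inference, partition-function estimation, goodness-of-fit, and
spin-glass complexity diagnostics.

## The problem

Binned at δt seconds, the joint activity of N neurons becomes a sequence of
±1 vectors **s**(t) (+1 = at least one spike in the bin). The PME model is
the maximum-entropy distribution matching the data's means ⟨s_i⟩ and
pairwise correlations ⟨s_i s_j⟩:

    p_pair(s) = (1/Z) exp( Σ_i h_i s_i + Σ_{i<j} J_ij s_i s_j ),

an Ising model with N(N+1)/2 parameters. Two questions drive this package:

1. **How good is the model?** Measured by G = 1 − d_pair/d_ind, where
   d_pair = D_KL(p_data‖p_pair) and d_ind is the same for the independent
   model (h_i = atanh⟨s_i⟩, J = 0). G = 1 means the pairwise model is
   perfect; G ≈ 0 means pairwise correlations buy nothing. In the
   perturbative regime, 1 − G grows linearly in Nν̄δt (population size ×
   mean rate × bin size). Alternative scores G_C, G_C̃ and G_H judge the
   model on third-order correlations and on H_m, the probability that m
   neurons fire simultaneously.
2. **How complex is the fitted model?** The inferred couplings resemble a
   Sherrington–Kirkpatrick (SK) ensemble (mean J0/N, std J1/√N). Solutions
   of the TAP equations
   m_i = tanh[h_i + Σ_j J_ij m_j − m_i Σ_j J_ij²(1−m_j²)] identify
   metastable states; the normal phase destabilizes when J1²S > 1 with
   S = N⁻¹Σ(1−m_i²)², and the complexity Σ = N⁻¹ ln N_ms counts glassy
   structure that makes sampling hard.

Computing G for large N requires the partition function. For N ≲ 20 it is
enumerated exactly; beyond that it is estimated from the observed states O:

    Ẑ = Σ_{ŝ∈O} e^{−2E(ŝ)} / Σ_{ŝ∈O} p_data(ŝ) e^{−E(ŝ)},

alongside the most-sampled-state, mean-ratio and median-ratio estimators.

## What's inside

| module | contents |
|---|---|
| `raster` | spike TSV I/O, binarization, moments, pattern frequencies, population selection (random / rate-matched) |
| `synthetic` | ground-truth models (random pairwise, independent groups, SK ensemble), exact & Gibbs samplers, cortical-surrogate spike tables, higher-order truths |
| `inference` | independent fit, pseudo-likelihood, Boltzmann learning (exact / persistent-chain MC), nMF/TAP/IP/Sessak-Monasson inversions, triplet models, exact convex ML |
| `evaluation` | exact and estimated partition functions, entropies, KL divergences, G, perturbative-slope fits, subsampling robustness |
| `prediction` | third-order correlations, H_m, and the scores G_C, G_C̃, G_H |
| `complexity` | TAP solver, metastable-state counting, coupling statistics, J1²S stability, χ_SG, SK predictions from data moments |
| `workflows` / `cli` | seeded scan pipelines over (N, δt, condition-mask) grids, writing CSV + manifests; `spikemaxent` console command |

No real recordings are required anywhere: the
`synthetic` module generates rasters with the relevant statistics
(populations up to ~500 neurons, log-normal rates, weak mixed-sign
correlations), and every claim is tested against exact enumeration or closed
forms.

## Worked example

`python examples/06_quality_scan_workflow.py` simulates a 600 s surrogate
recording of 20 neurons (log-normal rates, mean 6.27 Hz) and scans
population sizes 4, 8, 12 with pseudo-likelihood fits and exact partition
functions. It prints one row per population and the per-N median G:

```
 n  population  perturbation_parameter  d_ind  d_pair      g
 4           0                  0.4594 0.0036  0.0000 0.9917
 ...
12           2                  1.5760 0.0799  0.0250 0.6864

per-N median G:
n
4     0.992
8     0.911
12    0.686
```

Read: for N = 4 the pairwise model removes >99% of the independent model's
KL shortfall (G ≈ 0.99); by N = 12 the perturbation parameter Nν̄δt has
grown past 1.5 and G has fallen to ≈ 0.69 — the characteristic decay of
pairwise-model quality with population size. The other examples demonstrate
inference-method comparison (`02`), partition estimators and Ĝ vs G (`03`),
the higher-order scores (`04`), and the spin-glass diagnostics (`05`, where
a strongly coupled SK model shows J1²S > 1 and multiple metastable TAP
states).

The same scan is available from the shell:

```bash
spikemaxent simulate --n-neurons 20 --duration 600 --out spikes.tsv
spikemaxent scan --spikes spikes.tsv --n-grid 4,8,12 --pops-per-n 3 \
    --seed 0 --out scan_results
```

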