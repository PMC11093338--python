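"""Diagnose how close a fitted model sits to the spin-glass complex phase.

Draws Sherrington-Kirkpatrick ground truths (couplings Gaussian(J0/N, J1/√N))
at weak and strong coupling, and computes the complexity diagnostics: the
coupling statistics and their ratio f = std/mean, the TAP magnetizations, the
stability parameter J1²S (the normal phase destabilizes above 1), and the
multi-start count of metastable TAP states with the complexity
Σ = ln(N_ms)/N.
"""

import numpy as np

import spikemaxent as sm

for label, j1 in (("weak (normal phase)", 0.4), ("strong (glassy)", 2.0)):
    spec = sm.GroundTruthSpec(n_neurons=32, structure="sk_ensemble", J0=0.0,
                              J1=j1, rate_sd_hz=0.0, seed=0)
    model = sm.PairwiseModel(np.zeros(32), sm.make_model(spec).J)
    stats = sm.coupling_statistics(model)
    tap = sm.solve_tap(model)
    ms = sm.count_metastable(model, n_inits=150, seed=1)
    s_q = float(np.mean((1 - tap.m**2) ** 2))
    print(f"{label}: J1 = {j1}")
    print(f"  inferred J1_hat = {stats.j1_hat:.3f}, f = std/mean = {stats.f:.1f}")
    print(f"  TAP zero-init converged: {tap.converged}, S = {s_q:.3f}, "
          f"J1^2 S = {stats.j1_hat**2 * s_q:.3f} (boundary at 1)")
    print(f"  metastable TAP states: N_ms = {ms.n_ms}, "
          f"complexity Sigma = {ms.sigma:.4f}")
    print()
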