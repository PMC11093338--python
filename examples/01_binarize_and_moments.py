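"""Simulate a cortical-like spike table, binarize it, and inspect its statistics.

Generates 100 s of spikes from 20 neurons with visual-cortex-like rates
(log-normal, mean 6.27 Hz, SD 1.24 Hz) and weak mixed-sign couplings, bins
them at 20 ms into a ±1 raster, and prints the moments the maximum-entropy
models are built on.
"""

import numpy as np

import spikemaxent as sm

spec = sm.GroundTruthSpec(n_neurons=20, rate_mean_hz=6.27, rate_sd_hz=1.24,
                          coupling_scale=0.1, seed=0)
spikes = sm.simulate_cortical_surrogate(spec, duration_s=100.0, delta_t=0.02)
raster = sm.bin_spikes(spikes, 0.02)
moments = sm.compute_moments(raster)
emp = sm.empirical_distribution(raster)

print(f"raster: {raster.n_neurons} neurons x {raster.n_bins} bins at "
      f"dt={raster.delta_t} s")
print(f"mean rate       : {raster.mean_rate:.2f} Hz")
print(f"N*rate*dt       : {raster.perturbation_parameter:.3f}   "
      "(the perturbation parameter; quality decays linearly in it)")
print(f"mean <s_i>      : {moments.means.mean():+.3f}   "
      "(negative: most bins are silent)")
iu = np.triu_indices(raster.n_neurons, 1)
print(f"connected corr  : {moments.connected[iu].mean():+.4f} +- "
      f"{moments.connected[iu].std():.4f}  (weak, both signs)")
print(f"observed states : {emp.n_patterns} of 2^{raster.n_neurons} possible")
print(f"plug-in entropy : {emp.entropy:.3f} nats "
      f"(upper bound {raster.n_neurons * np.log(2):.3f})")
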