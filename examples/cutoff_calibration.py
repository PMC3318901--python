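"""Deriving the significant fold-change band from technical replicates.

The same pooled sample labeled on two channels should give identical
ratios; the spread of replicate pairs measures pure technical noise.
The 90th percentile of the % variation distribution becomes the
smallest fold change distinguishable from noise.
"""

from uroquant import SimulationConfig, calibrate, match_common_proteins, simulate_technical_replicates

config = SimulationConfig(seed=7, n_proteins=200, replicate_target_percent=25.0)
rep1, rep2 = simulate_technical_replicates(config)

pairs = match_common_proteins(rep1, rep2)
calibration = calibrate(pairs, quantile=0.90)

upper, lower = calibration.rounded_cutoffs()
print(f"common proteins passing evidence gates: {len(pairs)}")
print(f"replicate correlation r^2 = {calibration.r_squared:.4f}")
print(f"90th percentile of % variation = {(calibration.upper_cutoff - 1) * 100:.2f}%")
print(f"fold-change cutoffs: >{upper} or <{lower}")
print("\n90% of replicate pairs agree within that % variation, so only")
print("ratios outside the band reflect real differential excretion.")
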