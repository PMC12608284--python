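"""Simulate a demographically conditioned EEG cohort.

Generates a small cohort with the default class effect (MDD band power
raised most in beta, least in delta, scaled by age/education), then verifies
the injected structure with a Welch spectral estimate: the printed MDD-HC
band-power ratios exceed 1 in every band, with the largest shifts in the
alpha/beta range (the exact ordering at n=6 per group fluctuates with the
sampled demographics, which scale each subject's effect).
"""

import numpy as np
from scipy.signal import welch

from difnet import SyntheticCohortConfig, generate_cohort
from difnet.synthetic import EEG_BANDS

config = SyntheticCohortConfig(n_mdd=6, n_hc=6, duration=30.0, seed=42)
recordings, demographics = generate_cohort(config)

print(demographics.to_string(index=False))

powers = {label: {band: [] for band in EEG_BANDS} for label in ("MDD", "HC")}
for rec in recordings:
    f, p = welch(rec.data, fs=rec.sampling_rate, nperseg=1024, axis=-1)
    for band, (lo, hi) in EEG_BANDS.items():
        powers[rec.profile.label][band].append(
            p[:, (f >= lo) & (f <= hi)].sum(axis=-1).mean()
        )

print("\nMDD/HC group band-power ratio (1.0 = no effect):")
for band in EEG_BANDS:
    ratio = np.mean(powers["MDD"][band]) / np.mean(powers["HC"][band])
    print(f"  {band:6s} {ratio:5.2f}")
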