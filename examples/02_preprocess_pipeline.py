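"""Run the standard preprocessing chain on one synthetic recording.

Select channels -> notch + band-pass filter -> 4 s epochs at 75% overlap ->
peak-to-peak artifact rejection -> per-epoch z-scoring.  The printed epoch
count follows floor((n_samples - window) / step) + 1; the final tensor is
what the classifier consumes.
"""

import numpy as np

from difnet import (
    BandSpec,
    SubjectProfile,
    SyntheticCohortConfig,
    epoch_recording,
    filter_recording,
    generate_subject,
    reject_artifacts,
    select_channels,
    standardize,
)

profile = SubjectProfile("sub-001", "MDD", age=34, sex=1, education_years=16)
config = SyntheticCohortConfig(duration=60.0)
rec = generate_subject(profile, config, seed=1)
print(f"raw: {rec.data.shape[0]} channels x {rec.data.shape[1]} samples")

rec = select_channels(rec, list(rec.channel_names[:8]))
rec = filter_recording(rec, BandSpec.named("broadband"), notch_hz=50.0)
epochs = epoch_recording(rec, window=4.0, overlap=0.75)
print(f"epoched: {epochs.n_epochs} epochs of "
      f"{epochs.data.shape[1]}x{epochs.data.shape[2]}")

epochs.data[10, 0, 200] += 800.0  # inject one gross artifact
epochs = reject_artifacts(epochs, ptp_threshold=400.0)
print(f"after rejection: {epochs.n_epochs} epochs "
      f"(log: {epochs.rejection_log['n_rejected']} rejected)")

epochs = standardize(epochs)
print(f"standardized: channel means ~{np.abs(epochs.data.mean(-1)).max():.1e}, "
      f"sds ~{epochs.data.std(-1).mean():.3f}")
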