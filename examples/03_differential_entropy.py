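"""Differential-entropy analysis across demographic categories.

Computes the Gaussian-assumption DE (1/2 ln(2*pi*e*sigma^2), in nats) per
epoch and channel on filtered (not yet standardized) epochs — z-scoring
fixes every channel's variance at 1 and with it the DE — aggregates to
subject means, and compares the under-30 vs 30-and-over MDD age groups
with a two-sample t-test.  With the default generator the age groups
differ because age scales the MDD band-power effect.
"""

from difnet import (
    BandSpec,
    SyntheticCohortConfig,
    concat_epochs,
    epoch_recording,
    filter_recording,
    generate_cohort,
)
from difnet.features import compare_groups, de_table, split_mask, subject_means

config = SyntheticCohortConfig(n_mdd=10, n_hc=10, duration=20.0, seed=10)
recordings, _ = generate_cohort(config)
epochs = concat_epochs([
    epoch_recording(filter_recording(rec, BandSpec.named("broadband"),
                                     notch_hz=50.0))
    for rec in recordings
])

table = de_table(epochs)
per_subject = subject_means(table)
print(per_subject.round(3).to_string(index=False))

mdd = per_subject[per_subject["label"] == "MDD"]
comparison = compare_groups(
    mdd["de_nats"].to_numpy(), split_mask(mdd, "age"), category="age<30"
)
print(f"\nMDD DE, age<30 (n={comparison.group1_n}) vs >=30 "
      f"(n={comparison.group2_n}): "
      f"means {comparison.group1_mean:.3f} / {comparison.group2_mean:.3f}, "
      f"t={comparison.t_statistic:.2f}, p={comparison.p_value:.3g}")
print("A higher mean DE in the older MDD group reflects the age-scaled "
      "band-power effect (DE grows with signal variance).")
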