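# Methods

## Problem and scope

`difnet` implements an EEG-based depression classifier that dynamically
fuses demographic indicators (age, sex, years of education) with
spatiotemporal EEG features, together with the surrounding experimental
machinery: a synthetic cohort generator with known ground truth, the
standard resting-state preprocessing chain, differential-entropy (DE)
analysis, trial-level cross-validated training, and the comparative
experiment matrices (indicator combinations, module ablations, frequency
bands, subject categories). Real clinical corpora in this area are
access-restricted; every capability here is exercisable end to end on the
built-in synthetic cohorts, and adapters (EDF reading, a demographics CSV
contract) accept external data with the same montage conventions.

## Compute engine

The network runs on the package's own reverse-mode automatic
differentiation engine (`difnet.nn`): a tape-based `Tensor` over float64
numpy arrays with hand-written gradients for the convolution primitives and
composition for everything else. Convolutions are computed spectrally —
each operand is FFT'd once and channel contractions happen in the frequency
domain — because the temporal kernels span up to 250 samples, where direct
sliding-window convolution is slow and memory-hungry. Every primitive with
a custom gradient is validated against central finite differences in the
test suite; Adam follows the standard bias-corrected update.

## Signal model of the synthetic cohorts

Each channel is the sum of

1. a `1/f^alpha` Gaussian background (default exponent 1.0, 10 µV RMS),
2. one narrowband Gaussian process per classical band — delta 1–4, theta
   4–8, alpha 8–13, beta 13–30, gamma 30–40 Hz — with sinusoid-equivalent
   amplitudes of 20/10/15/5/2 µV respectively (a typical resting scalp
   profile), and
3. white measurement noise (2 µV SD).

Band rhythms are band-limited noise rather than fixed-frequency sinusoids.
This is a deliberate validity choice: with 4 s windows stepped by 1 s, a
sinusoid at an integer frequency keeps an identical phase in every epoch of
a subject, handing the classifier a subject fingerprint. Under trial-level
cross-validation (folds partition epochs, not subjects) such fingerprints
are label leaks — a model can score far above chance on a cohort with *no*
class effect by recognizing subjects. Narrowband noise has no stable phase,
so only genuine class structure separates the groups.

The diagnosis effect multiplies MDD band amplitudes by
`1 + class_effect[band] * (1 + c_age * age01 + c_edu * edu01)`, where
`age01`/`edu01` are min-max-normalized within the configured ranges and
`c_age = c_edu = 0.5` by default. Default per-band effects are 0.05 / 0.12 /
0.30 / 0.40 / 0.18 (delta…gamma): strongest in beta, weakest in delta, the
ordering the band-restricted experiments are designed to recover.
Demographics are drawn uniformly (age 18–65, education 6–22 integer years,
sex Bernoulli(0.5)); class-conditional ranges can be set to build cohorts
where demographics alone carry signal. Two canned configurations exist:
`beta_only_config` (class effect confined to beta) and
`demographics_only_config` (EEG is pure white noise — identically
distributed across subjects so there is nothing to fingerprint — with
disjoint age/education ranges between groups).

What the generator does *not* emulate: volume conduction and channel
covariance, non-stationarity, eye-blink/muscle artifacts (beyond optional
injected transients for testing the rejector), and any waveform-morphology
disease markers. Passing tests therefore demonstrate that the pipeline
recovers band-power and demographic structure, not that it would reach any
particular accuracy on clinical recordings.

## Preprocessing

Order: channel selection → notch + band-pass → epoching → artifact
rejection → standardization. A guard rejects rejection-after-z-scoring,
where a µV threshold is meaningless.

- Channel selection matches 10-20 names after a synonym normalization
  (T3/T7, T4/T8, T5/P7, T6/P8), so older-dialect montages interoperate.
- The band-pass is a windowed-sinc (Hamming) FIR applied forward–backward
  (zero phase); the number of taps follows the 3.3/Δf rule with the
  transition width tied to the low edge (≤ 2 Hz), giving ≈ 0.1 dB passband
  ripple at 250 Hz. The 50 Hz notch is a forward–backward IIR notch, Q=30.
- Epoching uses a 4 s window with 75 % overlap by default; the step is
  rounded to the nearest integer sample and the count is
  `floor((n - W)/S) + 1` (300 s at 250 Hz → 297 epochs).
- Artifact rejection drops any epoch whose per-channel peak-to-peak
  amplitude exceeds a threshold (default 400 µV), logging indices and
  counts; a `rejector` callable is the seam for plugging in a published
  rejection tool.
- Standardization z-scores each channel of each epoch independently. The
  per-epoch scope was chosen because the network consumes epochs
  independently; computing statistics over a recording or a training set
  are defensible alternatives with different leakage trade-offs. Epochs
  containing a constant channel are dropped and logged (configurable to
  raise instead).

## Differential entropy

DE uses the Gaussian-assumption estimator standard in the EEG literature,
`DE = 1/2 ln(2πe σ̂²)` nats with σ̂² the sample variance, which satisfies
`DE(aX) = DE(X) + ln|a|` exactly and converges to the closed form for a
unit Gaussian (≈ 1.4189 nats). The conventional negative sign of the
continuous definition (`h = -∫ f ln f`) is used; volt-scale EEG then lands
in the −10 nat regime. Group comparisons aggregate DE to subject means and
apply two-sample (or paired, when a pairing key exists) t-tests across the
demographic category splits (age < 30 vs ≥ 30, sex code, education < 16 vs
≥ 16).

## Architecture

Input is one standardized epoch, `(1, N_C, T)` with `N_C = 16`, `T = 1000`.

- **Multiscale block.** Three parallel branches with temporal kernels of
  250, 125 and 62 samples (1.0, 0.5 and 0.25 s at 250 Hz — coarse
  band-selective observation windows), each followed by a depthwise spatial
  convolution of size `(N_C, 1)` with depth multiplier 2 that collapses the
  electrode axis, then batch normalization, ELU, average pooling (1, 4) and
  dropout 0.5. Branch outputs concatenate and pass a second (1, 8) pool:
  `(3·F1·2, T/32)` = `(96, 31)` with `F1 = 16`. The ELU *before* pooling is
  load-bearing: averaging a raw signed filter response cancels oscillatory
  energy, making band power invisible downstream; rectification first turns
  the pool into a band-energy detector (the standard depthwise-separable
  EEG front-end). `F1 = 16` makes the concatenated width equal the encoder
  width (96) with no extra projection.
- **Transformer encoder (T1).** Two identical post-norm layers: multi-head
  self-attention (6 heads of dimension 16, model width 96) and a
  position-wise feed-forward of 4× width with ELU, each wrapped in residual
  + layer normalization, dropout 0.5. No positional encoding by default
  (attention is then permutation-equivariant, which the tests exploit); a
  sinusoidal encoding sits behind a flag. When the encoder is placed after
  the TCN (the T2→T1 ablation order), the incoming width is 32; the encoder
  adapts by keeping the head dimension implied by the largest head count
  ≤ 6 that divides the width (32 → 4 heads of 8).
- **TCN (T2).** Two residual blocks, 32 filters of kernel 4, dilations 1
  and 2; each block holds two dilated causal convolutions, each followed by
  batch normalization, ELU and dropout 0.3, with a 1×1 projection on the
  skip path when widths differ (96 → 32 in the first block). Left-only
  padding enforces causality exactly; the receptive field obeys
  `RFS = 1 + 2(K−1)(2^L − 1)` (19 samples at L=2, K=4), which the tests
  verify against perturbation probes.
- **Demographic fusion.** Active indicators are min-max normalized to
  [0, 1] with statistics fitted on the training partition only and applied
  frozen elsewhere (out-of-range values clip with a warning). Normalizing
  over the full dataset — a common but leaky alternative — is available
  explicitly. The indicator vector is tiled across the 31 sequence steps,
  convolved (width 3, 8 filters), globally average-pooled, and mapped by a
  dense unit through a sigmoid scaled to (0, 2), yielding one scalar F per
  example that multiplies the feature map elementwise. With fusion code N
  the stage is absent and the forward pass is bit-identical to a no-fusion
  network at shared weights.
- **Head.** Flatten → a single dense layer → softmax over {MDD, HC}; no
  hidden layers.

**Fusion initialization.** The fusion dense weights start unit-normal
(bias 0), so F is bounded in (0, 2) and centered on 1 but spread across
examples. An exactly-identity start (zero weights, F ≡ 1) was tried first
and fails in a specific, instructive way: the demographic pathway receives
no gradient until the EEG branch has already fit the training data, at
which point the loss is too small to move F — on a cohort where only
demographics carry signal, the fused variant stays at chance. With the
spread start the same experiment reaches high accuracy. The cost is that
fusion is not exactly the identity at initialization; its expectation still
is.

## Training and evaluation

Adam (lr 0.001), cross-entropy, batch size 32, up to 200 epochs at full
scale; all RNG streams derive from one root seed, so runs are
bit-reproducible. An inner stratified validation split (10 % of the
training partition) drives checkpointing: the parameters (including
normalization running statistics) of the best-validation-accuracy epoch are
restored after training. Non-finite loss aborts with a diagnostic rather
than training through NaNs.

Cross-validation is trial-level by default — folds partition epochs with
class stratification, so every subject's trials span train, validation and
test. This evaluates within-subject temporal generalization, not
subject-level generalization; a `subject_disjoint` mode exists for the
latter, and a `subject_finetune` mode splits each subject 80/20
(chronological by default; `floor(0.8·n)` trials to train).

A fourth mode, `blocked`, cuts each subject's epochs into k contiguous
chronological blocks, block i to fold i, and *purges* the boundary: the
later block's first `ceil(W/S) − 1` epochs — those whose windows reach back
into the previous block — are excluded from every fold (the epoch container
carries its window/step geometry so the purge width is automatic). Every
subject still spans all folds, and after purging no training window shares
a single sample with any test window. This matters because random
trial-level assignment with 75 % window overlap places test windows that
share up to 750 of their 1000 samples with training windows; a network that
merely memorizes training content then scores well above chance on data
with *no* class signal (measured at ≈ 0.60 on null bands here), and even
unpurged blocks leak measurably when blocks are short. The synthetic
benchmarks that make claims about class signal use purged blocked folds for
exactly this reason, while the plain random mode remains the default
protocol.

Metrics from the confusion matrix: accuracy, precision, recall, F1, and
Cohen's kappa with chance agreement
`P_e = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)] / N²`. The N² denominator is the
standard margin-product form and keeps kappa in [−1, 1] (a single-N
denominator makes P_e exceed 1 on any non-trivial matrix). Undefined
metrics (zero denominators) are reported as `None` with a flag, never
silently coerced to 0. Variant comparisons use a two-sided paired t-test on
fold-wise accuracies; identical vectors report p = 1 by convention.

## Experiment matrices and desk-scale benchmarks

Each matrix varies exactly one axis — indicator combination
(N/A/S/Y/AS/AY/SY/ASY), module order (baseline, +T1, +T2, +T2+T1, +T1+T2),
frequency band, or subject category (All/A1/A2/S1/S2/Y1/Y2 with thresholds
age 30 and education 16) — holding the fold plan, seed and training
configuration fixed, so comparisons are paired (certified by a fold-plan
hash carried in every result row).

Three canned benchmarks fix the library's reference study conditions, sized
so the injected effects are resolvable with clear statistical margins while
a full run stays in CPU-minutes. All three train with batch size 16 and no
inner validation split: at a few hundred trials a 10 % validation set is
~50 trials, whose ±4 % accuracy noise makes best-epoch checkpointing a
lottery, so the benchmarks keep the final-epoch parameters instead, and the
smaller batches roughly double the update count per pass at equal cost.

- **Signal recovery.** 10+10 subjects, 60 s each (≈ 1140 trials), class
  effect confined to beta; 2-fold blocked CV of the desk-scale no-fusion
  model, 10 training epochs; success is a one-sided binomial test of pooled
  test successes against 0.5. Shorter recordings (≈ 180 trials) were
  piloted and fail informatively: the network memorizes individual noise
  epochs instead of generalizing, which is the expected regime for deep
  models at that data-to-parameter ratio.
- **Demographic fusion.** 10+10 subjects, 30 s of pure-noise EEG with
  disjoint age/education ranges; DIFNet-AY vs DIFNet-N paired on a shared
  2-fold plan, 30 epochs, at the full architecture's dropout rates (0.5 /
  0.5 / 0.3) — the lighter desk dropout lets the EEG branch memorize noise
  before the fusion scalar moves.
- **Band selectivity.** The beta-only cohort at 100 s, five band-restricted
  preprocessing runs (delta…gamma) on identical blocked fold plans, 12
  epochs. Within a single band, per-epoch z-scoring removes the absolute
  amplitude shift, so the model must detect the in-band spectral-shape
  change (the rhythm's flat spectrum vs the 1/f background within the
  band) — a subtler cue than broadband relative power, which is why this
  benchmark uses the longest recordings: leak-free probes at half the data
  stay at chance while training accuracy climbs. The beta run should rank
  first because the other bands carry no class signal at all.

The desk-scale architecture (`compact_config`) keeps the topology and
shrinks widths: temporal kernels 62/31/15 with 2 filters per branch, a
single encoder layer (2 heads × 6), an 8-filter TCN, dropout 0.25/0.25/0.15.

## Numerical and degenerate-input choices

- Epoch step rounding: nearest integer sample.
- σ = 0 channels at standardization: drop the epoch and log (default) or
  raise.
- Attention uses max-subtracted softmax; weight rows sum to 1 within 1e−9.
- Filter edge effects: forward–backward application with pad length capped
  at signal length − 1; amplitude claims in tests are asserted on the
  steady-state interior.
- `compare_variants` on identical fold vectors returns p = 1.0 instead of
  the NaN a t-test would produce on zero variance.
- All stochastic components (cohort draw, weight init, dropout, batch
  shuffling, fold assignment) are seeded through `numpy` `SeedSequence`
  spawning; derived seeds stay below 2^31.

## On-disk formats

Cohorts: one compressed `.npz` per subject (float32 data, channel names,
rate) plus `demographics.csv` with columns
`subject_id,label,age,sex,education_years`. Epoch sets: one `.npz` plus a
JSON sidecar with provenance (stages applied, rejection log, per-epoch
demographics). EDF recordings are read through the optional `mne` extra;
the shipped writer targets the portable containers above.

## Known limitations

- The synthetic generator's effect sizes are free parameters, not estimates
  of any clinical dataset; headline accuracies reported for restricted
  clinical corpora are not reproducible here and are not targets.
- Trial-level CV with 75 % window overlap shares samples between train and
  test epochs by construction; this mirrors the evaluated protocol but
  inflates accuracy relative to subject-disjoint evaluation, which is why
  the generator deliberately avoids subject fingerprints.
- The engine is CPU-only float64; full-scale (200-epoch, 53-subject)
  training is hours, not minutes — the desk-scale configurations exist for
  exactly this reason.
- Batch normalization statistics make eval-mode outputs depend on training
  history; checkpoints therefore include running statistics.
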