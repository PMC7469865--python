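# Methods

`erpdecode` implements a multivariate decoding analysis of cued visual
spatial attention from epoched multichannel EEG, together with the group
statistics and between-subject linkage analyses that such studies report,
and a synthetic cohort generator used to validate the whole chain end to
end. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic validation does and does not
establish.

## The decoding model

Attention-related ERP components (EDAN, ADAN, LDAP, the target N1
modulation) are small — typically under 1 µV — so single-trial decoding is
hopeless at realistic noise levels. The pipeline therefore decodes
**trial-averaged scalp patterns**: for each subject, condition and time
point, trials are randomly split into `n_groups = 3` equal groups (one or
two remainder trials per condition are omitted when the count is not
divisible by 3), each group is averaged into one channel vector, and each
vector is z-scored across channels (sample SD, n−1). The z-scoring
consumes any voltage offset common to all channels — e.g. slow drift
accumulated since the baseline — which would otherwise separate the
classes for reasons unrelated to attention.

A linear SVM (C = 1, the conventional default; exposed in
`DecoderConfig`) is trained on the patterns of two groups (2 classes × 2
groups = 4 training patterns) and predicts the two held-out patterns;
three folds × `n_iterations = 20` fresh random groupings give **120
decoding attempts per time point** (2 conditions × 3 folds × 20
iterations). Accuracy time courses are smoothed with a centered
five-point moving average (±40 ms at 50 Hz); edge windows shrink rather
than pad, so no data are invented beyond the epoch. Prediction ties
(decision value exactly 0) resolve deterministically to the first class
label.

Channel contributions are reported as **activation maps**: the SVM weight
vector multiplied by the covariance of the training patterns (the
standard forward-model transform of backward-model weights), averaged
over folds and iterations. The covariance is computed per time point from
the normalized patterns that entered training; raw-feature and pooled
variants were considered and rejected to keep the maps on the same scale
as the decoded features.

## Preprocessing

Continuous data: 0.1–40 Hz band-pass (order-2 Butterworth, applied
forward–backward, i.e. 12 dB/oct per direction and zero phase) and an
equiripple FIR band-stop at 50 Hz (49–51 Hz stopband, 2 Hz transitions;
the mains notch bandwidth and ripple are not standardized anywhere, so
they are configurable). Epochs destined for decoding get an 8 Hz two-way
least-squares FIR low-pass whose order follows `3 · floor(sfreq/cutoff)`
(93 at 250 Hz / 8 Hz; scipy's least-squares design needs an odd tap
count, so the filter has order 94). The plain least-squares objective is
dominated by the wide stopband, which leaves visible passband ripple; a
5:1 passband weight plus exact DC normalization keeps the passband flat
to ~1% while still attenuating 10 Hz by a factor >40 per pass. The 8 Hz
low-pass exists to keep alpha-band (8–13 Hz) activity out of the decoded
patterns; an alpha-power control path (band-pass, squared analytic
amplitude, 20 Hz anti-alias low-pass) is provided to verify that
conclusions do not rest on alpha lateralization.

Epochs are cut half-open `[start, end)` on the sample grid. With cue
epochs −1000..1400 ms and target epochs −500..1000 ms at 250 Hz, trimming
200 ms from both ends (edge-artifact guard) and decimating to 50 Hz
(every 5th sample; the 8 Hz low-pass is the anti-alias step) yields
exactly **100 cue-locked** (−800..1180 ms) and **55 target-locked**
(−300..780 ms) points. The inclusive-endpoint convention would give
101/56.

Artifact screening applies four criteria — moving-window peak-to-peak
(200 ms / 50 ms / 150 µV) on all EEG channels, absolute threshold
(100 µV), an HEOG step function (400 ms window, 10 ms step, 40 µV;
difference of half-window means, sensitive to small saccades), and a VEOG
blink criterion (200 ms / 10 ms / 50 µV restricted to −200..200 ms around
stimulus onset). Windows are evaluated only where they fit entirely
inside the epoch (full-window semantics); the rejection mask is the union
over criteria, so order is irrelevant. A residual-gaze report
(grand-average HEOG difference between cue conditions, convertible to
degrees with a configurable 16 µV/° factor — a conventional figure,
treated as an assumption) quantifies what screening left behind.

## Group statistics

Per time point, a one-tailed Wilcoxon signed-rank test asks whether the
median subject accuracy exceeds 0.5. The exact null distribution is used
for n ≤ 25 without rank ties, the normal approximation with continuity
correction otherwise; zero differences are dropped (standard convention —
the choice is documented because it is rarely stated). Benjamini–Hochberg
FDR at q < 0.05 corrects across time points (Benjamini–Yekutieli is
available), and surviving runs shorter than 3 contiguous points are
discarded as likely isolated chance hits.

**Onset** is the earliest significant time at or after 0 ms; pre-event
significant points (possible under noise) are never reported as onsets.
The onset's sampling distribution comes from bootstrap resampling of
subjects (100 resamples), re-running the whole signed-rank → FDR →
contiguity → onset chain inside each resample (re-using the original
mask would understate the uncertainty). Resamples with no detectable
onset are recorded as missing, excluded from the summary, and counted.
Cohort onsets are compared with a two-sample t test on the bootstrap
values.

## Between-subject linkage

Per time point, Pearson correlation (two-tailed) links a per-subject
scalar — N1 attention modulation (mean amplitude 170–210 ms over the
posterior ROI contralateral to the target, cued minus uncued with the
negative sign preserved), mean or median RT, or the RT validity effect —
to the subject's decoding accuracy. Two cohorts measuring the same
relation are combined per time point with the Liptak–Stouffer weighted-Z
rule, `Z = Σ √N_i Z_i / √(Σ N_i)` with `Z_i = Φ⁻¹(1 − p_i)`; p values are
clipped to `[1e−12, 1 − 1e−12]` before the normal quantile.

Cluster-level significance uses a permutation test on the size (number of
contiguous points, minimum 1) of runs with combined p < .05. Each of the
1,000 iterations shuffles the subject pairing **once per cohort and
applies the identical shuffle at every time point**, preserving the
temporal autocorrelation of the accuracy series; the largest significant
run per iteration forms the null. A cluster's p is the fraction of null
values ≥ its size (ties count as exceeding — conservative); a size
exceeding every null value is reported as "< .001". Shuffles are uniform
permutations (the identity is allowed), the standard exchangeability
argument. The univariate counterpart correlates per-channel difference
waves with the same scalar, corrects across channels with BH at each time
point, and evaluates per-channel clusters against the null of the maximum
(over channels) largest run under the same shared shuffle.

## The synthetic cohort generator

The generator produces the statistical structure the analysis assumes and
nothing more:

* **Cue epochs** carry a lateralized slow component — fixed Gaussian-bump
  topography over posterior and frontal sites, sign-mirrored across the
  midline, unit maximum — that ramps up linearly over 150 ms from a
  subject-specific onset and is sustained to the epoch end. Polarity
  flips between cue-left and cue-right, so the planted left-minus-right
  difference wave peaks at `effect_amplitude_uv`.
* **Target epochs** carry a contralateral posterior N1 (Gaussian in time,
  peak 190 ms, width 20 ms) whose spatiotemporal kernel is scaled so the
  standard ROI/window measurement recovers the planted amplitudes in µV
  exactly in expectation; cued targets differ from uncued by the planted
  modulation.
* **Noise** is 1/f (exponent 1, 8 µV RMS per channel) mixed spatially by
  a random orthonormal matrix per subject — giving the channels a
  covariance structure for the activation-map transform to act on — plus
  narrowband alpha (random frequency 8–13 Hz and phase per trial/channel,
  4 µV² variance).
* **Heterogeneity and couplings**: subject effect amplitudes are
  log-normal (right-skewed, strictly positive; σ = 0.4), onsets normal
  around the paradigm mean (SD 10 ms). The planted N1 modulation is
  `−(n1_coupling · amplitude) + ε` and trial RTs are Gaussian around a
  mean coupled to the target effect (`rt_coupling` ms/µV) — faster
  responses with stronger selection in the instructional design, a larger
  validity cost in the probabilistic design.
* One seeded generator per cohort with deterministic per-subject
  substreams: identical config and seed give bit-identical cohorts.

Two presets mirror the two cueing strategies: instructional-like
(30 subjects, onset 80 ms, amplitude 1.2 µV) and probabilistic-like
(26 subjects, onset 160 ms, amplitude 0.9 µV). **Calibration, not ground
truth**: the default amplitudes were chosen so the simulated
group-average decoding time course at full trial counts shows the
qualitative shape such experiments report — onset shortly after the
planted latency and a plateau around 0.7–0.9 — since published studies do
not state component SNRs. The slow 1/f background also reproduces a real
feature of trial-averaged decoding: per-subject accuracy stays coherent
over long stretches of the epoch, so individual subjects can sit visibly
above or below chance pre-cue while the expectation remains exactly 0.5.

What the generator does **not** emulate: no biophysical forward model or
measured electrode geometry (topographies are schematic Gaussian bumps),
no ocular dipole geometry (the optional frontal artifact is a ramped
deflection with opposite polarity on F7/F8 and an amplified HEOG copy),
no late target components beyond the N1, no trial-to-trial latency
jitter, and no ICA stage (the pipeline accepts already-corrected data;
component-removal bookkeeping is out of scope). Passing recovery tests
therefore show that the analysis chain is correct and calibrated under
its own assumptions — not that those assumptions hold for any particular
recording system.

## Validation experiments and problem sizes

The test suite and `scripts/acceptance.py` recompute, from scratch:

* structural constants (120 attempts per point; 100/55 retained samples;
  ±40 ms smoothing half-width);
* chance-level calibration: a zero-effect cohort of 20 subjects × 60
  trials/condition × 30 channels through the full pipeline; the grand
  mean smoothed accuracy is compared with 50% within its own 95%
  Monte-Carlo confidence interval;
* the cluster test's family-wise error: 500 replicates of 26 subjects ×
  60 autocorrelated time points with behavior drawn independently, 1,000
  permutations each — the fraction of replicates with any significant
  cluster should be 0.05 ± 0.02;
* oracle equivalence: exact signed-rank enumeration (n ≤ 12), a frozen
  normal-CDF fixture for the weighted-Z combination, a hand-worked
  BH + contiguity fixture, and exhaustive-window oracles for the artifact
  criteria;
* parameter recovery at high SNR (amplitude 8 µV, onset SD 0, 10 subjects
  × 60 trials/condition): bootstrap onset means within ±20 ms (one
  smoothed time step) of the planted 80 and 160 ms, with the early cohort
  significantly earlier; and planted decode–N1 couplings confined to
  460–660 ms recovered as significant negative-r clusters overlapping the
  window in ≥ 80% of 20 replicates;
* the confound check: a condition-locked frontal artifact drives
  F7/F8-only decoding far above chance in the late cue-target interval,
  and regenerating without it restores an empty significance mask.

Problem sizes (trials, subjects, iteration counts) in the recovery and
confound tests are scaled to what the checks need statistically; the
full-scale settings are used where a check is defined at full scale
(the null cohort and the FWER experiment).

## Known limitations

* Onset estimates carry a small detection lag at moderate SNR (the ramp
  must clear the noise floor) and the five-point smoothing can pull them
  one step earlier at very high SNR; the two effects were measured at
  within ±1 smoothed step under the high-SNR validation settings but are
  not separately corrected.
* The exact signed-rank distribution switches to the normal approximation
  above n = 25 or in the presence of rank ties; p values are then
  approximate.
* The generator's RT distributions are Gaussian (clipped at 150 ms),
  not the right-skewed distributions real RTs show; median and mean
  summaries are therefore nearly equivalent in simulation.
* `univariate_corr` evaluates per-channel clusters against the maximum
  over channels of the null largest-run — conservative for dense
  montages.
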