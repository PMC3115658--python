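# Methods

`cracklekit` re-implements a multichannel lung-sound crackle analysis as a
tested pipeline: synthesis of disease-profiled recordings with ground-truth
annotations, per-channel crackle detection, half-period waveform
decomposition, crackle-family grouping with a transmission coefficient and
source localization, per-breath aggregate features, and hierarchical
(crackle → breath → patient) majority-voting classification evaluated by
patient-level cross-validation.  This note records the model, the
parameters that matter, and the design choices made where the method left
them open.

## Crackle waveform model

A crackle is modelled as a train of `n ≥ 4` half-sine segments with
alternating sign.  The k-th half-period has duration `T_k` (ms) and
amplitude `A_k`; the first half-period carries the highest peak, later
durations equal `t2_over_t1 · T1`, and amplitudes decay geometrically
(`A_k = decay^(k−1)`).  The parameterization is chosen so the waveform
analysis is exactly invertible:

- pitch `= 2000 / (T1+T2+T3+T4)` (T in ms) by construction, so
  `T1 = 2000 / (pitch · (1 + 3·t2_over_t1))`;
- polarity is the sign of the first (highest) half-period;
- zero crossings fall exactly at segment boundaries.

Half-period durations receive multiplicative jitter (SD 0.30, clipped to
[0.4, 2]) in recordings, producing the ~35–40 % half-period duration
variability typical of measured crackles; the *realized* `2000/ΣT1..4` and
`T1` are stored in the annotation as ground truth.

Interpretation note: the waveform figure convention ("the half-period to
the left of the highest peak") is implemented as *the half-period
containing the highest peak*, enumerated rightward.  This is the only
reading consistent with A1 being the amplitude of the peak's half-period,
and it makes generator → decomposition round trips exact.

The zero-crossing count (ZXS) convention is `zxs = n + 1` for `n` retained
half-periods (the crossings bounding them); half-periods above the
amplitude floor on the *left* of T1 are included in the count (making ZXS
invariant to time reversal) but not in the duration features.

## Disease profiles and the two-level cohort model

Profiles for IPF, CHF, and PN carry: inspiratory/expiratory crackle rates,
pitch, T1, half-period count, `T2/T1`, amplitude decay, positive-polarity
fraction, transmission level, amplitude scale, spatial pattern, and noise
level.  Published group means ± SD are used for rates, pitch, T1, ZXS
(via `n = zxs − 1`), `T2/T1`, polarity, transmission and amplitude.

All profile SDs are treated as *between-patient*: each synthetic patient
draws latent means from the profile distributions (rates censored at zero,
bounded quantities clipped), and individual crackles scatter around the
patient's latent means (pitch CV 0.12, half-period count SD 1, log-normal
amplitude scatter 0.45, per-family transmission SD 0.04).  This two-level
structure is what makes group t-tests and patient-level classification
meaningful; a single-level generator would make every patient identical up
to sampling noise.

The geometric amplitude decay cannot reproduce the published `A2/A1 ≈ 1`,
`A3/A1 ≈ 0.4–0.5` *and* ZXS 6–9 simultaneously (amplitudes decaying that
fast drop below the 10 % retention floor long before 8 half-periods).
Decay factors (0.72 IPF, 0.58 CHF/PN) were chosen so the retained
half-period count reproduces the ZXS rows; consequently `A2/A1`,
`A3/A1`, and amplitude variability do not match their published group
values, and synthetic group differences in those features are smaller than
real ones.  Pitch, T1, ZXS, crackle rate, and CTC — the features the
evaluation relies on — are matched.

## Recording synthesis

A recording (default 20 s, 16 channels at 8 kHz, 3 breaths) contains:

- Gaussian background noise (RMS 0.12 arbitrary units per channel);
- a band-limited (40–250 Hz) breath-sound component amplitude-modulated by
  the breath phase (inspiration gain 1.0, expiration 0.55, `sin^0.7`
  envelope; in-phase RMS 0.18), with known phase boundaries (inspiration
  is 45 % of each cycle);
- crackles at 3-D sources drawn from the profile's spatial pattern:
  *uniform* over a two-lung box derived from the microphone bounding box;
  *basal* with a linear density gradient doubling toward the lowest third;
  *focal* with all sources in one seeded quadrant region (Gaussian spread
  2 cm, clipped to the region).

Each crackle's nearest ipsilateral microphone records the mother crackle;
other ipsilateral channels receive delayed (distance/sound-speed, default
3 cm/ms) and attenuated copies.  Child amplitudes are allocated directly
from the family's target transmission: a per-family CTC target `c` is
drawn around the patient's transmission level and the ratio budget
`c · (N−1)` is distributed over channels nearest the source first, each
child between 0.5 and 0.95 of the mother's amplitude, with the fractional
remainder realized as one floor-ratio child with matching probability.
The *expected measured* CTC therefore equals the target exactly, which is
the only aspect of transmission the published account constrains.  A
distance-decay model with a global gain was considered and rejected: it
cannot hit per-profile measured CTC without iterative calibration against
the detector, and sub-floor children would be inaudible anyway.

The mother amplitude floor (3.0 units) and noise RMS give the weakest
annotated event (a floor-ratio child of a floor-amplitude mother, 1.5
units) a detection score comfortably above threshold.  The resulting
crackle-peak SNR (≈ 30–37 dB for a typical mother) is deliberately higher
than bedside recordings; at lower SNR the detector's threshold, the
child-ratio floor, and the CTC calibration would have to be retuned
together.

## Detection

Per channel: a causal 100–2000 Hz band-pass scores each sample as
rectified amplitude over a trailing robust background (median of |signal|
per 50 ms block, median over the trailing 200 ms; causal filtering is
essential — zero-phase filtering pre-rings ahead of the transient and
defeats the rise-time criterion).  Candidate samples above threshold
(default 5.5) are reduced by non-maximum suppression with a 10 ms dead
time; each surviving peak must emerge from below 35 % of its own peak
envelope within 3 ms (rejecting slow swells and the ring tails of earlier
crackles).  Events are windowed (30 ms, centred on the peak, truncated at
breath boundaries) from a 60 Hz high-passed copy of the signal.

The threshold default of 5.5 is set by false-positive calibration: in the
100–2000 Hz band a 20 s channel contains ≈ 76 000 effectively independent
samples, so a threshold of 4 would fire several times per channel on pure
noise, while 5.5 gives an expected noise event count of ≈ 0.003 per 20 s
channel.  The background estimate is floored at 2×10⁻⁴ of the channel's
peak band-passed amplitude so that noiseless synthetic channels do not
score their own filter tails.

Breath segmentation uses the known boundaries when provided (the synthetic
annotation carries them; all cohort analyses use them).  The estimator for
unannotated audio low-passes at 150 Hz, smooths the RMS envelope (250 ms),
clips it at its 90th percentile (individual loud crackles must not set the
scale), splits at troughs, and pairs phases insp/exp by the louder-phase
convention.  It recovers 3/3 breaths with boundary errors ≲ 0.2 s on most
synthetic recordings but can mis-pair phases or over-segment when crackle
energy dominates the low band; it is a convenience for standalone WAV
input, not part of the validated cohort path.

## Families, CTC, localization

Detected events are grouped greedily: the largest-amplitude unassigned
event becomes a mother and attaches unassigned ipsilateral events within
±10 ms, one per channel (nearest in time).  The transmission coefficient
is `100/(N−1) · Σ min(A_c/A_mother, 1)` over the `N−1` non-mother
ipsilateral channels — the simplest monotone interpolation of the
published 0 %/100 % endpoints, used consistently by generator and
measurement, and to be read as an approximation of the original
instrument's definition.

Sources are localized by least squares on peak-time differences (delays
predicted as distance/sound-speed), bounded to a box around the array,
with a weak pull (0.02 per cm) toward the mother microphone pushed 8 cm
into the chest; families with fewer than 3 members take that fallback
directly.  With exact delays and ≥ 5 well-spread members the solver
recovers sources to < 1 cm; in the pipeline, peak times are quantized to
the 8 kHz grid and families are small, so typical errors are 2–5 cm —
adequate for the quadrant/distance aggregates, which only need the
uniform/basal/focal patterns to remain distinguishable.

## Aggregates, classification, statistics

Per breath: crackle count, counts per chest quadrant (a crackle belongs to
its mother channel's quadrant), the 6 pairwise quadrant percentage
differences `100·(n_i−n_j)/max(n_i+n_j, 1)` in a fixed pair order, and
maximum inter-crackle distances per axis and Euclidean, computed on both
source locations and mother-microphone positions.

Classification: per-crackle feature vectors (the full individual-feature
set including CTC) feed an RBF-kernel maximum-margin classifier or a
16-hidden-unit backpropagation network, standardized on training
statistics only.  Folds are split at the patient level, stratified by
class — crackles of one patient are correlated, and splitting them across
folds would inflate accuracy.  Held-out crackle labels are majority-voted
into breath labels and breath labels into patient labels (ties broken by
summed score, then class priority).  In aggregate mode a second-stage
ridge logistic model consumes the crackle vote fraction and mean score
concatenated with the aggregate vector; it is trained on *cross-fitted*
vote fractions (3 patient-level subfolds inside each training fold),
because the final model's in-sample votes are unrealistically clean.
Training sets are subsampled to 4000 crackles (seeded) to bound the kernel
fit.  Breaths with zero detected crackles cannot vote; they are excluded
and counted in the result's diagnostics.

Group statistics: per-patient medians per phase are compared with Welch's
unequal-variance t-test (group SDs differ; the pooled classic variant is
available by flag), two-sided, without multiple-testing correction; rows
at p < .05 are flagged.  Degenerate (zero-variance) comparisons report
p = 1 with a flag rather than NaN.

## What the synthetic tests do and do not show

The generator reproduces the *between-patient statistics* of the three
groups and the *spatial/transmission semantics* of crackle families.  It
does not emulate heart sounds, wheezes, electrode artifacts, airway-sound
spectra, inter-crackle waveform correlation within a patient, or low-SNR
acquisition.  Passing the cohort tests therefore shows that the pipeline
is internally consistent and recovers its own generative parameters at
study scale — not that the published patient-level accuracies would be
reproduced on real recordings.  Synthetic group separation on the retained
features is in fact cleaner than the published crackle-level accuracies
suggest for real data, so the cross-validated accuracies here
(≈ 0.9–1.0 at patient level) exceed the published 0.82–0.88 and are
checked only against the direction/threshold (> 0.8), not the printed
values.

## Problem sizes and numerical defaults

Cohort tests use one 20 s, 3-breath, 16-channel recording per patient at
8 kHz with the study's group sizes (39/95/123).  Key defaults: detector
threshold 5.5, dead time 10 ms, rise limit 3 ms, window 30 ms; family
window ±10 ms; decomposition floor 10 % of the peak with ≥ 4 half-periods;
sound speed 3 cm/ms; five-fold patient-stratified cross-validation.  All
stochastic stages take explicit seeds; identical seeds reproduce
bit-identical recordings and analyses.

## Known limitations

- `A2/A1`, `A3/A1`, and amplitude variability do not match the published
  group values (see the decay-model note above).
- The CTC formula is an endpoint-faithful approximation; the original
  device's channel weighting is not public.
- The breath-boundary estimator is heuristic and weaker than the
  annotated path.
- Localization accuracy is limited by the 8 kHz peak-time grid; distances
  between family arrivals of under ~0.4 cm are not resolvable.
- One recording per patient; breathing maneuvers and repeat sessions are
  out of scope.
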