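# Methods

This note records the scientific and numerical choices behind `fpvs`: the
stimulation model, the simulator, the preprocessing chain, the spectral
statistics, and the points where the procedure had to be pinned down beyond
what the published description fixes.

## Stimulation model

A sequence lasts 44 s: 2 s fade-in, 40 s stimulation, 2 s fade-out, with
items at the 6 Hz base rate throughout (264 items; 240 inside the analysed
40 s). In experimental sequences every 5th item (1-based positions 5, 10,
…) is a deviant, giving the 1.2 Hz oddball rate; standards carry magnitudes
{1,2,3,4} and deviants {6,7,8,9} (5 is excluded so the categories are
separated). Control sequences draw each item's magnitude at random from the
union of both sets (large with probability 0.5, exposed as
`control_large_fraction`), so category labels carry no periodicity. Both
formats of a notation pair are guaranteed to appear among standards and
among deviants. A session comprises 3 notation pairs × 2 conditions × 4
repetitions = 24 sequences, blocked by notation then condition, with
notation order taken from a cyclic 3×3 Latin square row selected by
participant index.

Stimulus contrast follows (1 − cos 2πFt)/2, so each item starts and ends at
0 % contrast and peaks mid-slot; the phase convention (zero at onsets) is
ours — the published figure shows the shape only. Fade-in/out apply a
linear gain ramp to the *response* amplitude in the simulator; the ramp
shape is unspecified in the source design and immaterial to the analysis,
which discards the fades. Fixation-cross colour changes are 8 draws uniform
in [1 s, 43 s] with a ≥2 s gap (rejection sampling). Font/dot-configuration
variant ids are sampled uniformly (4 fonts, 5 dot configurations) as
metadata only — no images are rendered.

A documented inconsistency: the source description mentions 40 s epochs
"containing 400 stimulus onsets", which matches a 10 Hz design from earlier
work, not 6 Hz × 40 s = 240. The package uses the 6 Hz arithmetic
throughout.

## Synthetic EEG

`simulate_recording` builds 64-channel recordings (MNE's standard
`biosemi64` montage, positions normalised to the unit sphere) at 2048 Hz by
default; tests and batch runs simulate at 512 Hz directly, which is
equivalent after the pipeline's resampling for all analysed frequencies.

Two response modes:

* **oscillatory** (default): the standard response is a sum of sinusoids at
  6 Hz harmonics with geometric amplitude decay (0.25 per harmonic, first
  harmonic dominant); the oddball response is a sum at 1.2 Hz harmonics
  with multiples of 6 Hz excluded and per-harmonic weights
  (1, 0.8, 0.6, 0.45, 0.3, 0.2).
* **event_based**: every item onset contributes a ~180 ms Hann-windowed
  biphasic kernel; deviant onsets add a distinct ~240 ms kernel, so the
  1.2 Hz periodicity *emerges* from the event train instead of being
  injected as a sinusoid.

Spatial structure: channel weight = exp(−d²/2σ²) of great-circle distance
from a profile centroid. The oddball topography follows the notation
(medial-occipital near Oz for digits–dots, left occipito-parietal near
P7/PO7 for words–digits, an LOP+MO blend for dots–words; σ = 0.45 rad).
The 6 Hz general visual response uses its own broad medial-occipital
profile (σ = 0.9 rad) for every notation, so the standard response is
significant at all three ROIs, matching the reported pattern. No generative
topography is published; these profiles emulate the qualitative ROI
pattern only.

Background noise is Gaussian 1/f^α noise (α = 1 by default), built in the
frequency domain with random phases and rescaled to a per-channel standard
deviation of 15 µV — a realistic broadband EEG scale. Ground-truth
amplitudes default to 2 µV (standard, 6 Hz) and 0.9 µV (oddball); the
source reports only SNR/z, never microvolts, so these are calibration
choices, fixed once so that ROI-level deviant z falls in the published
1.5–3 regime with 4 averaged repetitions (observed matched-ROI means
2.4–3.0 across notations) while control-condition z stays at 0. Optional
degradations: up to 3 bad channels (5 % of 64 — more is refused) replaced
by high-variance noise, and artifact repetitions injected with a
configurable probability.

What the simulator does **not** model: dipolar forward physics, eye/EMG
artifact morphology, nonstationary alpha, inter-channel noise correlation,
or between-participant amplitude variability. Passing tests therefore
demonstrate correctness and calibration of the *analysis*, not performance
guarantees on real child EEG.

## Preprocessing

Order of operations (as stated by the source procedure): resample
2048→512 Hz (polyphase), band-pass 0.1–100 Hz, segment into 44 s
sequences, interpolate bad channels, reject noisy repetitions,
common-average re-reference, crop to the 40 s stimulation phase
([2 s, 42 s), exactly 20,480 samples), average repetitions per condition
in the time domain, then FFT.

Choices the source leaves open, fixed here and exposed in
`PreprocessConfig`:

* Filter realisation: 4th-order Butterworth applied forward–backward
  (zero phase); passband amplitudes at the tagged frequencies are
  preserved within 1 %.
* Rejection criterion: peak-to-peak > 200 µV on any non-interpolated
  channel ("too noisy to correct" is not quantified in the source);
  rejections are logged per notation × condition cell.
* Interpolation: unweighted mean of the 3 nearest good channels by
  great-circle distance (no weights published); distance ties resolve in
  montage order.
* Crop alignment: the crop starts at the sample exactly 2.000 s after the
  sequence marker, half-open interval, 0-based indexing.

## Spectral statistics

The FFT uses a rectangular window — the 40 s epoch holds an integer number
of cycles of every tagged frequency, so their energy is bin-confined and a
taper would only leak it. Amplitudes are scaled as 2|X|/N (DC and Nyquist
not doubled): a unit sinusoid at an exact bin reads 1. SNR and z are
ratio/standardised quantities and are invariant to this convention (tested).

**Noise-bin selections.** The published description gives two phrasings:
"twenty surrounding bins (10 on each side) … excluding the immediately
adjacent bins and two most extreme bins" (SNR) and "twenty surrounding
bins (10 on each side)" (z). These cannot be one rule — 20 bins minus 4
exclusions is 16 — and the reconciliation was chosen by measuring the null
calibration of each candidate:

* **SNR**: candidates are the ±12-bin window minus the adjacent bin per
  side (22 bins); the two extremes — the local maximum and the local
  minimum, one from each tail — are dropped, leaving 20. Defining
  "extreme" instead as largest deviation from the median removes the two
  *largest* values of the positively skewed (Rayleigh) noise floor almost
  surely and biases white-noise SNR to ≈1.09; max+min trimming measures
  ≈1.03.
* **z**: the twenty surrounding bins proper — 10 per side, skipping the
  adjacent bin (offsets ±2…±11), with *no* extreme trimming. Any trimmed
  set clips the tails of the noise sample, underestimates its sd and
  inflates the null z (sd ≈ 1.3, false-positive rate 10–14 %). With the
  untrimmed set, z = √1.05·t₁₉ up to the skew of summed amplitudes.

**Null behaviour of z (measured).** Under a flat noise floor the exact
null exceedance P(z > 1.64) is 7.0 % (10⁷-draw Monte Carlo; sd 1.084) —
the 1.64 normal criterion is mildly anticonservative because the noise
parameters are estimated from 20 bins and spectral amplitudes are skewed.
Under the simulator's 1/f background the curvature of the floor biases z
slightly downward: exceedance 6.74 % ± 0.06, sd 1.062 (192,000 draws).
Practitioners applying the conventional 1.64 cutoff should be aware the
effective single-channel false-positive rate is closer to 6–7 % than 5 %.

Summed-harmonic quantification: 25-bin windows (±12) centred on each
retained harmonic are summed element-wise; the deviant set is the first
six multiples of 1.2 Hz with multiples of 6 Hz removed —
{1.2, 2.4, 3.6, 4.8, 7.2, 8.4} Hz — and the standard set is {6 Hz} only
(its first harmonic dominates). Edge bins without a full ±12-bin window
are excluded from SNR maps (NaN); all tagged frequencies sit far from the
edges (lowest target bin 48).

## ROI statistics

z is computed per channel, averaged over the 4 channels of each a-priori
ROI, then averaged over participants (mean ± SE) — matching an
"averaged z-scores" table. The alternative order (z on ROI-averaged
summed segments) is available as `roi_zscore_on_segments` for sensitivity
analysis. Averaging correlated channel z's changes the null sd of the ROI
statistic; the conventional 1.64 cutoff is applied to the averaged z
regardless, replicating the published procedure. Group tables are tidy
long-format (participant × notation × condition × ROI × target), ready for
external RM-ANOVA/Bayesian tooling; that group-level inference is out of
scope here.

## Reproducibility and problem sizes

All randomness flows from explicit seeds: a master seed derives
per-participant seeds via `numpy.random.SeedSequence(master, participant)`
and per-sequence seeds from a participant-level generator, so partial
re-runs are stable; every run writes a manifest with the config hash and
seed. The test suite's simulation sizes are chosen to make the statistical
assertions sharp at desk scale: null calibration uses 800 noise-only
recordings (51,200 channel-level z draws, ≈0.1 % standard error on the
exceedance), and parameter recovery uses 10 cohorts of 8 participants × 24
sequences simulated at 512 Hz. Recordings default to 2048 Hz when
simulating for export, mirroring the acquisition hardware.

## Known limitations

* The simulator's between-channel noise independence makes ROI averaging
  slightly more powerful than on real EEG, where neighbouring channels are
  strongly correlated; detection-rate results transfer qualitatively, not
  quantitatively.
* EDF/BDF files are read (via MNE) but not written; simulated recordings
  persist to an HDF5 container with a JSON sidecar carrying ground truth
  and seeds.
* The z criterion's mild anticonservatism (above) is a property of the
  published method itself, reproduced faithfully rather than corrected.
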