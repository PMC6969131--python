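# Methods

## Stimulation paradigm

Blocks of 20 s auditory stimulation followed by 40 s of silence. Each block
holds five trials of four syllables (SOA 600 ms, syllable duration 285 ms),
trials separated by a 1.6 s inter-trial interval measured from the last
syllable's offset to the next trial's first onset. With that convention a
trial spans 3 × 0.6 + 0.285 = 2.085 s, the trial period is 3.685 s, and the
last syllable of a block ends at 16.825 s — inside the 20-s stimulation
window, which fixes the otherwise unstated ITI convention. Three block
types (standard, deviant-phoneme, deviant-voice) are generated for realism
— deviant blocks replace a late syllable in three of the five trials — but
the analyses pool all blocks and trial types, so deviance never enters a
statistic. Timing is deterministic; the seed only draws block types and
syllable identities.

## Probe geometry

Each hemisphere carries a patch of 8 sources and 2 detectors on a hexagonal
("round") grid with 15 mm between neighbouring optodes. The two detectors
occupy adjacent grid sites; sources fill every remaining site at one grid
step from a detector. Two sources are equidistant from both detectors, so
each detector pairs with exactly 5 sources at 15 mm, giving 10 channels per
patch. Exact scalp coordinates are not published for this probe, so the
layout is canonicalized to reproduce the published counts and spacing;
geometry is planar per patch because only inter-channel distances feed the
analysis (cluster adjacency: midpoints within 20 mm, the next-nearest
midpoint distance on this grid; configurable). The "right-temporal" channel
used as the residual-coupling site in the IVH arm is the most inferior
channel of the right patch.

## Synthetic cohorts

The generator writes raw data in the acquisition units the real instruments
produce — two-wavelength detector intensities at 9.1912 Hz and scalp
microvolts at 2048 Hz — so both pipelines are exercised end to end.

**Hemodynamics.** Ground-truth Δ[HbO] per channel is a train of
block-onset-locked gamma-variate kernels, unit peak at 7 s (FWHM ≈ 8 s,
returning to ~0 well before the window end), scaled by
`coupling_gain × hbo_peak_amplitude` (defaults 1.0 and 0.5 µM);
Δ[Hb] = −⅓ Δ[HbO]. One kernel per block, matching the block-design
analysis window. Intensities follow the exact forward Beer-Lambert model
the conversion inverts (extinction coefficients from the standard
Gratzer/Cope compilation at 690/830 nm; DPF 4.99; 15-mm separation), with
three nuisance processes: multiplicative slow drift (< 0.01 Hz sinusoid
mixture, RMS 0.5 % of intensity), a cardiac oscillation at 164 BPM added in
the concentration domain (amplitude 10 % of the response peak — it lies
below the 4.6 Hz Nyquist of the 9.19 Hz system and inside the filter's
stopband), and white intensity noise (SD 0.1 %). Baseline absolute
concentrations (42 µM HbO, 21 µM Hb → StO2 ≈ 0.67, a typical preterm
value) feed only the StO2 computation.

**EEG.** Voltage is the sum of (i) band-limited (0.5–25 Hz) background noise
at ≈5 µV RMS emulating the low-voltage interburst activity; (ii) bursts:
Poisson arrivals at 6/min, 1–3 s Hann envelopes, 1–8 Hz content scaled to
≈300 µV peak, with a smooth random spatial profile, timed independently of
the stimulation; (iii) syllable-locked ERP components: four fixed dipolar
topographies (two-pole Gaussians on the projected 31-electrode 10-20
montage) times Gaussian temporal kernels (σ = 22 ms) at 84/244/378/576 ms,
amplitudes (2.0, 3.0, 2.5, 3.5) µV scaled by `habituation_ratio^(s−1)` for
syllable position s (default 0.8). Amplitudes are in the low-microvolt
range typical of neonatal syllable ERPs; the true scalp maps of this
population are unpublished, so topography realism is limited to repeatable,
distinct maps per peak. IVH subjects share the healthy neural parameters by
default (their ERP deficit is not quantified numerically in the source
material); an attenuation can be set explicitly.

**What the generator does not emulate.** Photon transport and skull/
fontanel conduction; lesion-induced distortion of scalp topographies;
non-stationary sleep-state changes; electrode impedance drift. Passing
tests therefore demonstrate correctness of the processing chain and
sensitivity under the stated generative assumptions, not performance on
clinical recordings.

## fNIRS pipeline

Order: MBLL → z-score block rejection → band-pass → segmentation → detrend
→ baseline → averaging → AUC.

- **MBLL.** ΔOD(λ,t) = −log10(I/Ī) per channel, Ī the channel's *geometric*
  temporal mean (the arithmetic mean of OD), making the conversion the
  exact inverse of the forward model; the arithmetic-mean-intensity dialect
  is available via `reference="mean"`. The 2 × 2 extinction system is
  solved channel-wise. Conversion errors name the offending channel and
  sample.
- **Rejection.** z computed per channel over the whole recording (the same
  normalization that puts subjects on a common scale), on both HbO and Hb;
  a block is rejected if |z| > 4 anywhere in its [−5, +25) s window on any
  channel. Symmetric |z| is the default reading of the threshold; a signed
  variant is a config switch.
- **Filtering.** Zero-phase (forward–backward) order-6 Butterworth
  band-pass 0.03–0.5 Hz, removing drifts and the cardiac line.
- **Segmentation.** Half-open [−5, +25) s windows; epoch length fixed at
  floor(30 × 9.1912) = 275 samples so every epoch shares the canonical grid
  −5 + k/fs (block onsets do not fall on the sampling grid; the ≤ half-
  sample phase offset is ignored, standard practice at this sampling rate).
  Least-squares linear detrend over the full segment, then subtraction of
  the [−5, 0) s baseline mean.
- **AUC.** Trapezoidal integral of the mean HbO epoch over [0, 10] s
  (the window in which the group difference is reported), window edges
  linearly interpolated onto the grid; the [0, 20] s whole-stimulation
  variant is always computed alongside. Hemisphere AUC = mean of channel
  AUCs per hemisphere.

The pipeline stays in µM after rejection (z-scores only gate blocks), so
AUC carries µM·s units; a z-scale analysis is a config option.

## EEG pipeline

1–20 Hz zero-phase order-4 Butterworth, then decimation by 4 to 512 Hz
(the 20 Hz cut-off is the anti-alias filter). Epochs [−0.5, +3.5) s locked
to each trial's first syllable, baseline [−0.2, 0) s. Artifact cascade in
the stated order: flag (trial, electrode) on max |V| > 50 µV or any
ten-successive-sample jump |V[t+9] − V[t]| > 30 µV (the simplest reading of
"jump between ten successive time-points"; span configurable); drop an
electrode for the session if flagged on > 70 % of trials; drop a trial if
> 15 % of the session-retained electrodes are flagged. Session-rejected
electrodes are stored as missing values, never zero-filled. Thresholds
apply to baseline-corrected, filtered epochs, as rejection follows
segmentation in the processing order.

**GFP.** Population SD across retained electrodes per time point. Peak
measures: GFP means over half-open 40-ms windows centred on each component
latency after each of the four syllable onsets (4 peaks × 4 repetitions).
GFP maxima are located with a prominence criterion (10 % of the window
maximum) to skip filter ripple. The repetition factor defaults to all four
syllables; the ANOVA can be restricted (e.g. omitting P1, whose window
overlaps the preceding syllable's P4 at this SOA — the package's ANOVAs on
peaks use P2–P4 for that reason).

**Templates.** For P2/P3/P4: healthy grand-average map in the 40-ms window
after S1, electrode-mean-centred, unit-normalized; leave-one-out folds
exclude the scored healthy subject so the similarity is never fit to its
own data. Projection similarity is the centred cosine (spatial Pearson r),
which yields the 1/0/−1 calibration points for proportional, orthogonal
and negated maps; an uncentred projection is a config option. Coefficients
average the similarity over 100-ms windows centred on each template's peak
after each syllable. Thin-plate interpolated 2-D maps are for display
only; no statistic consumes interpolated values.

## Group statistics

- **Cluster permutation test.** Per-cell two-sample Welch t on subject ×
  channel × 30-bin arrays (1-s bin means over [−5, +25) s). Cells with |t|
  above the two-sided critical value at α = 0.05 (Welch df per cell) enter
  clusters; connectivity = consecutive bins within a channel plus spatial
  adjacency within a bin, with sign agreement. Cluster statistic: mass
  (sum of t). Null: maximum |mass| over relabelings of subjects —
  exhaustive when the number of distinct relabelings does not exceed
  `n_perm`, otherwise seeded draws; p uses the add-one estimator so finite
  permutation counts never produce p = 0. Degenerate-variance cells get
  t = 0 and cannot enter clusters.
- **Hemisphere AUC.** Welch t per hemisphere plus medians/IQRs; the two
  tests are reported uncorrected (noted in the output metadata).
- **Mixed ANOVA.** Balanced split-plot decomposition (one between factor,
  one or two within factors) from cell means; each within effect is tested
  against its own subject-interaction stratum. Unbalanced cells raise —
  no imputation. Verified against R's `aov` with an
  `Error(subject/(A*B))` stratum and against pingouin for the one-within
  case.

## Problem sizes and numerical choices

Simulated sessions use 6–12 blocks per subject (clinical sessions hold
~75–108); recovery targets use 3 zero-noise subjects × 12 blocks (fNIRS)
and 2 blocks (EEG), sizes at which every quantity is stable to well within
its acceptance tolerance. The measured group-average HbO peak after the
full pipeline falls at 6.86 s (the 0.03 Hz high-pass and detrend pull the
7-s kernel peak slightly forward); the second GFP maximum falls at
244.14 ms, the grid point nearest 244 ms at 512 Hz. Calibration suites run
at 500 simulations × 200 permutations (cluster-test type-I error) and 100
cohort replicates (AUC-contrast power). All randomness flows through
per-subject seeds derived from one master seed; datasets are byte-
reproducible (HDF5 written without timestamps).

## Known limitations

- The extinction-coefficient table and DPF are conventional values, not
  instrument calibrations; absolute concentration scaling inherits their
  uncertainty (the group contrast does not, being within-instrument).
- GFP-based habituation ratios are biased toward 1 under additive noise
  (spatial SD has a variance floor); the noiseless recovery bound (5 %)
  does not transfer to noisy cohorts unchanged.
- The cluster test's forming threshold, statistic and permutation count
  are conventional defaults; the original toolbox settings for this
  dataset are unknown, so only calibration (type-I) and sensitivity are
  asserted, not numerical cluster identity.
- EEG epochs from different trials are averaged on a canonical grid,
  ignoring sub-sample onset phase (< 0.5 ms at 2048 Hz).
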