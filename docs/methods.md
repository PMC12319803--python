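# Methods

`tacsalpha` implements the analysis chain used to detect after-effects of
short-period transcranial alternating current stimulation (tACS) on
somatosensory alpha power, together with a synthetic-data generator that
reproduces the statistical structure the analysis assumes. This note
documents the model, the estimators, the numerical choices, and what the
synthetic validation does and does not establish.

## Study design being modelled

Each participant contributes two sessions (tACS and a no-stimulation
control) of two blocks each. A block is a 2-minute resting baseline
followed by 20 stimulation trains (10 s long in one block, 30 s in the
other) separated by 15 s intervals, sampled at 1000 Hz. Because the first
3.8 s after train offset are unusable (stimulator impedance artifacts) and
the last 5 s of each interval are contaminated by a vigilance task, the
usable post-stimulation window is 3.8–10 s after train offset, trimmed to
4.2–9.7 s to discard preprocessing edge effects: one 5.5 s epoch per train.
The last 10 s of the baseline are discarded and the remaining 110 s are cut
into 20 epochs of 5.5 s, matching the post-epoch count. Epochs follow a
half-open `[start, end)` sample convention, so a 5.5 s epoch holds exactly
5500 samples; this avoids duplicated boundary samples (the inclusive
alternative would give 5501).

Train offsets are treated as known event times; no trigger detection is
implemented. Artifact handling is a robust-z amplitude flagger
(median/MAD of the pooled samples; a trial is flagged when any sample
exceeds `zmax` robust standard deviations, default 8). Flagged trials are
skipped by downstream stages but never deleted, because the binning
analysis indexes trials by their position in the session.

## Synthetic signal model

For unit *u* at session time *t* the generator produces

```
x_u(t) = g_k · a_u · (1 + m · sin(2π f_mod t + φ)) · sin(2π f_ISF t + θ_u) + ε_u(t)
```

* `f_ISF` — the participant's alpha peak (integers 8–13 Hz by default,
  drawn uniformly per participant).
* `a_u` — alpha amplitude (`alpha_amp`, default 1). In tACS-session post
  epochs, units in the effect patch have `a_u` scaled by `sqrt(1 +
  tacs_gain)`, so the injected *power* gain at `f_ISF` equals `tacs_gain`
  exactly (default 0.30). The control session carries no gain.
* `m, f_mod` — slow amplitude modulation (defaults depth 0.3 at 0.4 Hz).
  The modulator phase φ is drawn once per participant and shared across
  units: the emulated phenomenon is a single region-wide slow fluctuation
  (plausibly a bodily rhythm), and a common driver modulates neighbouring
  units coherently. Per-unit random modulator phases would cancel in any
  unit-averaged power course and would make the modulation undetectable by
  construction. Carrier phases `θ_u` remain unit-specific. An optional
  `mod_depth_tacs` applies a different depth in tACS post epochs (used to
  emulate stimulation-enhanced rhythmicity).
* `g_k` — per-trial log-normal amplitude jitter (`exp(0.1·N(0,1))`),
  shared across units within a trial: a global excitability fluctuation
  that gives per-trial power estimates realistic variance.
* `ε_u(t)` — Gaussian background with amplitude spectrum ∝
  `max(f, 1 Hz)^(-exponent/2)` (default exponent 1), synthesised in the
  frequency domain with random phases. `noise_amp` (default 1.9)
  parametrises the standard deviation of the nominal full-band process;
  components above 150 Hz — the ceiling of the usual recording band-pass,
  invisible to every 4–40 Hz analysis — are not synthesised, so the
  realised std is `noise_amp · sqrt((1+ln 150)/(1+ln 500)) ≈ 0.91 ·
  noise_amp`. With the defaults, the alpha peak stands roughly a factor 7
  above the 1/f background at 1 Hz spectral resolution — a realistic
  MEG-like regime in which peak detection is reliable but single-trial
  power is noticeably noisy.

Units live on a rectangular lattice with 4-neighbour adjacency (default
8×8); the effect occupies a contiguous 3×3 patch labelled `somatosensory`,
optionally extended by a second `frontal` patch placed directly below it,
so that when both carry the effect they form one contiguous cluster
spanning the two regions — the configuration the region split dissects.
This is the smallest layout family on which spatial clustering is
meaningful.

Two generation modes exist. `continuous` synthesises the whole block
(baseline, trains, intervals) and runs the standard segmentation — used to
test the segmentation itself. `epochs` evaluates the same signal model
directly at the epochs' absolute session times with epoch-wise independent
noise; it is the default for cohort-scale simulation because it skips
synthesising data the analysis never touches. Cohort seeds derive from a
master seed via `numpy.random.SeedSequence.spawn`, checked for
distinctness.

## Spectral estimation

**ISF.** The individual stimulation frequency is the argmax of
Hanning-tapered FFT power on a 4–40 Hz, 1 Hz grid, restricted to the broad
alpha range 7–14 Hz, averaged over a declared unit subset (default: the
`somatosensory` region — synthetic layouts have no sensor names, so the
subset is a configuration field). The default tapers a single window over
the trial-concatenated baseline; a per-epoch variant is available. Exact
ties resolve to the lower frequency and are logged. Per-epoch mean and
linear trend are removed before every spectral estimate; an additional
4–150 Hz band-pass is unnecessary because the synthetic data are
band-limited by construction (a switch exists for real data).

**TFR.** Time–frequency power uses a Hanning taper on sliding windows
stepped every 100 ms: 7 cycles per window (window length 7/f) for the main
5–40 Hz analysis, and a fixed 400 ms window for the modulatory analysis,
where temporal resolution matters more than spectral resolution. Power is
normalised so a sinusoid of amplitude A yields A²/2. Time points whose
window does not fit inside the epoch are missing (NaN), never zero-filled.
Implementation detail: all frequencies sharing a window length are
evaluated in one windowed-segment gather and a single matrix product.

**Alignment.** TFR frequency axes are re-indexed as offsets relative to
each participant's ISF, spanning ISF−2 … ISF+26 (29 bins), so maps are
comparable across participants. A harmonic variant centres the axis on
2·ISF with offsets −4 … +16, chosen to keep all participants with ISF ≤ 12
inside the computed 5–40 Hz range; offsets falling outside that range are
missing, never extrapolated.

## Statistics

**Delta power.** Within a participant, at each (unit, offset, time)
element, a two-sample t statistic contrasts per-trial post power against
per-trial baseline power, the baseline values time-averaged first so each
baseline epoch contributes one value. The pooled-variance form is the
default with Welch's form available as a switch. The statistic is computed
from trial-level values (20 vs 20) — a t statistic requires trial-level
spread — and the 10 s and 30 s blocks are pooled by averaging the two
blocks' maps, which keeps exactly one map per participant and condition as
the paired group test requires.

**Cluster permutation tests.** Group inference is a paired comparison of
the per-participant tACS and control maps: element-wise one-sample t of
the differences, two-tailed cluster-forming threshold at p < 0.05,
clusters formed over the declared adjacency (the unit graph for the
spatial test; 4-neighbour grids over offset × time and modulation ×
carrier planes), positive and negative clusters evaluated separately, and
a minimum cluster size of two (the "two neighbouring channels" rule;
isolated suprathreshold elements never form clusters). The cluster
statistic is the summed t; the null is the distribution of each
permutation's maximum absolute summed statistic under random
condition-label exchanges (sign flips of the paired differences). With
`2^n ≤ n_permutations` all `2^n` assignments are enumerated (identity
included) and `p = #{max ≥ |observed|} / 2^n` is exact; otherwise
`n_permutations` random flips are drawn and `p = (1 + #{max ≥
|observed|}) / (n_permutations + 1)`, never exactly zero. Seeds are
mandatory and recorded. Sign-flip t maps are vectorised by exploiting that
the per-element sum of squares is flip-invariant.

**ISF-level (spatial) view.** The spatial test consumes the aligned maps
at offset 0, time-averaged over the post window. Region splits average
the per-participant maps over the cluster∩region units and rerun the
time–frequency cluster test per region. The train-duration contrast
computes, per block, the per-unit paired group t within the significant
cluster and compares the two sets of cluster-member t values with the
two-sided Wilcoxon rank-sum test (exact where scipy provides it; fully
tied inputs return p = 1 by convention).

**Binning.** Per post trial n, `power_difference(n) = (power_trial(n) −
avg_power_baseline) / avg_power_baseline` at ISF, computed per unit, then
averaged over cluster units and time; 20 trials partition into 5 bins of 4
consecutive trials. The bin effect across participants is Friedman's test
(mid-ranks; a table that is constant within every participant returns
χ² = 0, p = 1). The pairwise Conover post hoc,
`t = (R_i − R_j) / sqrt(2(n·A1 − ΣR_j²)/((n−1)(k−1)))` with
df = (n−1)(k−1), runs only when the omnibus p < 0.05, two-sided with
Bonferroni correction over the 10 pairs. Flagged trials contribute missing
values in the raw series and are mean-imputed within participant for the
ranks only, since Friedman requires complete blocks.

**Modulatory spectrum.** Per-trial power courses from the 400 ms TFR
(10 Hz sampling) are referenced to the preceding trial
(`power(n,t) − mean_t power(n−1)`; trial 1 has no predecessor and is
excluded), averaged over cluster units. Filtering a 0.1 Hz component
inside one 5.5 s trial is ill-posed, so the per-trial courses are
concatenated in trial order, mirror-padded by one series length at each
end, band-pass filtered once per filter-bank centre (0.1–0.5 Hz in 0.1 Hz
steps, then 0.75–2 Hz in 0.25 Hz steps), Hilbert-transformed, and the
envelope magnitude is segmented back and time-averaged per trial. Filters
are zero-phase forward–backward Butterworth band-passes with bandwidth
`max(0.1 Hz, centre/2)` and order chosen (via `buttord`) for ≥ 20 dB
stop-band attenuation at twice the centre; an optional
bandwidth-normalisation (divide by `sqrt(bandwidth/0.1 Hz)`) makes centres
comparable under white noise. The group contrast is the same cluster
machinery on the modulation × carrier plane.

## Validation experiments and their scope

The Monte-Carlo suites (`tacsalpha.experiments`) measure operating
characteristics at sizes chosen to finish on a single CPU in minutes:

* **Null calibration** — 200 cohorts, 8 participants, 4×4 layout, one
  block, 200 permutations: empirical type-I rate of the spatial test at
  α = 0.05 must fall within the 95 % binomial band [0.02, 0.09].
* **Effect recovery** — 50 cohorts, 12 participants, 5×5 layout with the
  3×3 effect patch, 1000 permutations: ≥ 90 % detection of a significant
  positive cluster overlapping the patch, and the recovered tACS power
  change within 10 points of the injected 30 %. The recovered change sits
  slightly below 30 % because raw power at the ISF bin includes a
  background-noise share that does not scale with the gain.
* **ISF recovery** — 50 single participants cycling ISF 8–13 Hz: exact
  recovery required in all runs.
* **Modulatory recovery** — 50 participants: modulatory-spectrum argmax at
  the 0.4 Hz centre (read at carrier offset 0, where the modulated carrier
  lives); and 25 six-participant cohorts with tACS/control modulation
  depths 0.6/0.3, requiring a significant contrast cluster containing the
  0.4 Hz row in ≥ 80 % of runs. For these single-purpose runs the known
  effect patch stands in for the significant spatial cluster.

What passing these suites shows: the estimators are unbiased at the scales
exercised, the permutation machinery is exact where enumerable and
calibrated where sampled, and the chain recovers effects of the size the
design targets. What it does not show: robustness to real MEG artifacts
(eye movements, SQUID jumps, head motion), to non-sinusoidal alpha
waveforms and their harmonics, to volume conduction or source-leakage
correlations between units (synthetic noise is unit-independent), or to
drifting alpha peak frequency. The generator makes no attempt at
biophysical forward modelling.

## Numerical and engineering choices

* Bulk synthetic arrays are float32 (as MEG pipelines typically store
  data); all statistics are accumulated in float64.
* Colored noise is synthesised at an FFT-friendly length and truncated.
* Degenerate inputs are defined, not accidental: zero pooled variance with
  unequal means is an error ("degenerate variance"); with equal means the
  statistic is 0. Fully tied rank-sum input gives p = 1. An all-zero
  alpha band is a "no alpha peak" error.
* The pipeline processes one participant at a time and regenerates
  participants deterministically from their seeds when the modulatory
  stage needs raw data again after the spatial cluster is known, keeping
  memory bounded at cohort scale.
* Reports are timestamp-free so a config + master seed reproduces an
  identical report byte-for-byte; timestamps live in the run manifest.
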