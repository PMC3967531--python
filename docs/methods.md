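# Methods

## The problem

Resting-state BOLD functional connectivity between two brain regions is
estimated as the Pearson correlation of their average time signals.  When
every subject's data are warped to a common template before region masks
are applied ("spatial normalization"), normalization error and spatial
smoothing mix signal across regional borders, which biases pairwise
correlations and erodes group contrasts.  The alternative implemented
here keeps the analysis in each subject's **native space**: regional
masks are defined on the subject's own anatomy, all localization
transforms are composed into a single matrix so labels are interpolated
exactly once, and connectivity is computed separately per hemisphere.

`nativefc` implements that analysis as a reusable pipeline and pairs it
with a synthetic cohort generator so every stage is testable without
access to any scanner data.

## Pipeline

Per subject, in order:

1. **Motion QC.** Framewise displacement from the six rigid-body
   parameters, `FD(i) = Σ|Δtrans| + r·Σ|Δrot|` with backward differences
   and rotation radius `r = 50 mm` (the usual convention for this
   statistic; exposed as a parameter).  Intensity RMSD is the RMS over
   brain voxels of the percent-signal difference between consecutive
   volumes, each voxel normalized by its own temporal mean.  Both series
   are 0 at frame 0 (no predecessor).
2. **Scrubbing.** A volume is contaminated when `FD > 0.5 mm` **or**
   `RMSD > 0.3 %` (strict inequalities).  Flagged volumes — including
   runs of them — are replaced by linear interpolation between the
   nearest clean volumes; flagged runs touching the series edge take the
   nearest clean value, since two-sided interpolation is undefined
   there.  Flags are computed once from the original QC series, not
   recomputed after replacement.
3. **Band-pass.** Zero-phase (forward-backward) 4th-order Butterworth,
   0.01–0.08 Hz at TR 2 s.  Zero-phase filtering matters: a causal
   filter would introduce frequency-dependent phase shifts identical in
   every channel only if the channels had identical spectra, and any
   differential phase corrupts lag-zero correlations.  The squared
   magnitude response gives ≥ 40 dB attenuation one octave outside
   either cut-off and < 1 dB ripple mid-band.  The first 5 volumes
   (about the filter order) are discarded afterwards, together with the
   aligned QC and nuisance series.
4. **Regional extraction.** Unweighted mean over all voxels of each
   gray-matter label; white-matter and ventricle compartments feed the
   nuisance set instead.  Columns are ordered by the canonical region
   list (Hi, En, IP, IC, MOF, PHi, PoC, PCu, SF, SM), left before right.
5. **Nuisance residualization.** OLS residual of each regional signal
   against an intercept plus FD, RMSD, left/right white-matter and
   ventricle signals.  The tissue regressors are extracted from the
   band-passed data, so they are frequency-matched to the signals.
   Collinear or constant columns are dropped with a warning.  The
   pipeline residualizes the 20 regional means rather than every voxel;
   because unweighted averaging and OLS residualization are both linear
   operators on the time axis, the two orders give identical results,
   and the regional order is orders of magnitude cheaper.
6. **Connectivity.** Pearson correlations of all 45 unordered pairs
   within each hemisphere (never across), Fisher-Z transformed
   (`z = atanh r`): 90 hemisphere-resolved values per subject.  The
   interhemispheric-averaging variant averages homologous left/right
   signals per time point first and yields 45 more.  `|r| ≥ 1 − 1e−12`
   raises (duplicated signals upstream) rather than storing infinities.
7. **Group statistics.** Per pair, a pooled-variance two-sample t-test
   on the Fisher-Z values (Welch available via `equal_var=False`);
   Bonferroni threshold `α/m` with `m` the whole family tested together
   (90 hemisphere-resolved, 45 averaged).  Cohen's d is the mean
   difference over the pooled SD.  The hemisphere-interaction model
   stacks two observations per subject and fits
   `z ~ group + hemisphere + group×hemisphere` by plain OLS — the
   within-subject pairing is deliberately ignored to match the simple
   regression formulation; a mixed model is out of scope.  Cognition
   regressions are fit within one group: `factor ~ z + age`.

## The synthetic cohort

The generator is first-class, tested code.  Its defaults encode the
study design the package targets: 25 young and 26 elder subjects, 285
volumes at TR 2 s (a 9.5-minute run), ten DMN regions per hemisphere.
Regional signals are multivariate Gaussian with a group-specific 20×20
population correlation matrix, band-passed to 0.01–0.08 Hz (identical
filtering of every channel preserves lag-zero correlations) and
standardized.  The default matrices are 0.2 within hemisphere and 0.1
between hemispheres everywhere, except the right SM–SF entry: 0.5 in the
young group, 0.04 in elders.  The background levels make the
cross-correlogram non-trivially structured while the SM–SF contrast
dominates; user-supplied matrices are repaired to the nearest
positive-definite correlation matrix by eigenvalue clipping at 1e−6 and
rescaling, with a logged warning.

Subjects are rendered onto a 24×24×18 grid at 2 mm: each of the 20 gray
regions plus per-hemisphere white-matter and ventricle compartments is a
3×3×3 block (unambiguous membership, ≥ 8 voxels each).  Voxel values are
`1000·(1 + a/100·s(t))` with `a = 0.2 %` the regional fluctuation
amplitude, plus white noise (SD 0.05 %), a shared slow drift (0.5 % at
0.003–0.008 Hz), a shared respiratory-band wave (0.05 % at
0.15–0.24 Hz), and a whole-brain intensity multiplication of 1 % at
spike frames.  These amplitudes were chosen once so a clean frame's RMSD
sits near 0.15 % — half the 0.3 % flagging threshold — while default
spikes exceed it by ~3×; the 2 s sampling places the respiratory wave
inside the measurable band (Nyquist 0.25 Hz), as aliased respiration is
in real acquisitions.  Motion traces carry a smooth six-parameter drift
(0.05 mm scale, below the FD threshold) plus a sustained 0.8 mm
translation step at each spike frame, so FD crosses 0.5 mm exactly
there.  Spikes are Bernoulli per volume (default rate 0.03) and avoid
the first/last three frames so interpolation replacement is always
well-defined.

Cognition scores are linear in the subject's realized right SM–SF
Fisher-Z: elders' memory and general-fluid scores and young subjects'
speed scores have slope 3.0 with residual SD 0.5; all other
group×factor slopes are zero and vocabulary is noise in both groups.
Ages are drawn at 25.36 ± 2.74 (young) and 65.11 ± 2.98 (elder) years.

What the generator does **not** emulate: anatomical realism (no cortical
surfaces or T1 contrast), EPI distortion, spatially correlated noise,
cardiac signals, and — importantly — **between-subject variability in the
population correlations themselves**.  Every subject in a group shares
the same population matrix, so group-level effect sizes are governed
purely by the sampling variance of a band-limited correlation
(≈ 1/(T_eff − 3) on the Z scale, T_eff ≈ T·2·bandwidth·TR ≈ 80 at the
defaults).  Passing tests therefore demonstrate that the pipeline's
inference machinery is calibrated and powerful under the stated design,
not that real cohorts, with their much larger between-subject spread,
would show effects of the same magnitude.

## Normalization-error emulation and overlay maps

`emulate_normalization` applies a small random rigid perturbation to the
label volume (translations N(0, jitter) mm per axis, rotations matched
in arc length at a 50 mm radius) and Gaussian-smooths the BOLD data
(default 6 mm FWHM, kernel truncated at 4 SD).  Overlay maps sum binary
region masks across subjects on a common grid; the containment fraction
is the share of overlay mass inside a reference mask.  With native
labels and zero jitter every region's containment is exactly 1 — the
native-space premise — and any jitter strictly degrades it in median.

## Numerical choices

- Label resampling is nearest-neighbour under a single composed
  world-to-world rigid transform; composing factors and resampling once
  preserves at least as many boundary voxels as sequential resampling.
- Quartiles use linear interpolation between order statistics (numpy's
  default, type 7); boxplot whiskers extend to the most extreme values
  within 1.5·IQR, outliers beyond.
- Geometry checks compare affines within 1e−6; voxel indices are
  0-based; world coordinates come from the NIfTI affine.
- Motion files are 6-column whitespace text, translations (mm) first and
  rotations in radians by default; rotations-first ordering and degrees
  are accepted via reader flags.
- Determinism: all randomness flows through `numpy` `SeedSequence`s
  derived from the cohort seed and subject index, so identical (spec,
  seed) reproduce bit-identical subjects and byte-identical run tables.

## Problem sizes in the test and acceptance runs

Statistical checks run on the fast path that simulates regional signals
directly (rendering voxel volumes only where the imaging stages are
under test): the headline contrast uses 100 reseeded full-size cohorts
(51 subjects, T = 285); null calibration uses 500 cohorts at T = 128
with identical group matrices; scrubbing efficacy uses 20 rendered
subjects at full T; overlay degradation uses 20 replicates of 8
jittered masks.  These sizes give Monte-Carlo error comfortably below
the margins asserted.

## Known limitations

- The pooled-variance t-test and the unpaired interaction OLS mirror the
  simple formulations they implement; neither models within-subject
  correlation between hemispheres.
- The Fisher-Z values of band-limited series are only approximately
  normal; at T_eff ≈ 80 the approximation is good (the null calibration
  test verifies the 5 % level empirically).
- No figure rendering: outputs are machine-readable tables (TSV/CSV/
  JSON) from which plots can be built.
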