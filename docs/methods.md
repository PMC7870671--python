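# Methods

## The VI score

A B-scan is a 2D intensity image with row 0 on the vitreous (anterior)
side. The Vitreous/RPE-relative intensity of a scan is

VI = (Σ preprocessed vitreous intensity / n_vitreous_px) / RPE signal,

computed in three stages.

**Pre-processing** (`vi.preprocess_bscan`). (i) Grayscale morphological
opening with a disc of radius 1 px removes isolated speckle spikes
smaller than the structuring element while preserving particles of
radius ≥ 2 px. (ii) Soft thresholding: the vitreous background level is
the median of the anterior 40% of rows after a second, coarser opening
(disc radius 6 px) that strips hyperreflective particles, so the
estimate remains a *background* level at any particle density; the
threshold is that median plus `threshold_k` (default 3) robust SDs
(1.4826 × MAD). Intensities below the threshold are zeroed. (iii) The
surviving range is linearly rescaled to [0, 1]. Every statistic in the
chain (median, MAD, maximum) scales with the image, so the preprocessed
image — and therefore VI — is *exactly* invariant under global
multiplicative rescaling of the raw scan. This is the media-opacity
property: attenuation by cataract or vitreous opacity cancels out. An
absolute-threshold mode (`threshold_mode="absolute"`) is provided for
sensitivity analysis; it trades the invariance for a fixed floor.

A constant (zero-variance) image pre-processes to all zeros with a
`DegenerateImageWarning` rather than an exception.

**Segmentation** (`vi.segment_retina`). Per column of the preprocessed
image, after Gaussian smoothing along depth (σ = 2 rows): the RPE row is
the brightest smoothed row (ties broken toward the deeper, posterior
row); the RPE band is that row ± 4 px. The ILM is found by walking *up*
from the RPE through the contiguous retinal band: the deepest row above
the RPE whose profile drops below `ilm_fraction` (default 0.2) of the
column peak marks the vitreoretinal gap, and the ILM is the next row
down. Searching upward from the RPE rather than downward from the top
makes the rule robust to bright vitreous particles, which are separated
from the retina by a sub-threshold gap. A column is valid only if its
peak is strong (≥ 0.3 after rescaling), ~20 rows of retina-like signal
sit directly above the RPE band, and the vitreous above the ILM averages
below 25% of the column peak (a dark-compartment check that rejects
structureless bright noise). Invalid columns are excluded from both the
numerator and the denominator — never imputed. If more than half the
columns are invalid the scan raises `SegmentationError` with
diagnostics; in volume scoring such scans are recorded as missing, not
silently dropped.

**The ratio** (`vi.compute_vi`). The numerator is the mean preprocessed
intensity over the vitreous mask (rows strictly above the ILM in valid
columns). Area normalisation is the default because the raw sum would
scale with vitreous depth and make scans with a shallow vitreous
incomparable; the raw-sum mode is kept as a config switch
(`area_normalised=False`) since either convention is defensible. The
denominator is the mean (or median, `rpe_statistic`) *raw* RPE-band
intensity mapped through the same global adjustment as the numerator. A
non-positive adjusted RPE signal raises `UndefinedScoreError`.

## Scan thinning and selection schemes

A study-conformant volume has 19 B-scans 243 µm apart. Every other scan
is analysed; with 19 scans the two parities give 10 or 9 scans, and only
the odd original indices {1, 3, …, 17} contain the central scan 9 while
yielding the 9 analysable scans of the study design, so the default
phase is the parity of the central scan (overridable). Even scan counts
have no central scan and are rejected rather than guessed.

Within the 9 analysable positions (center = 4): `1c` = {4},
`3c` = {3,4,5}, `5c` = {2..6}, `7c` = {1..7}, `9s` = {0..8},
`3w` = {0,4,8}. Mean adjacent-selected-scan distance is
(mean index gap) × 2 × 243 µm: 486 µm for `9s`, 1944 µm for `3w`.

## Reliability statistics

- **ICC**: two-way random-effects, absolute-agreement, single-measure
  (ICC(2,1)) from ANOVA mean squares. Scans are a random sample of
  "raters", and reliability of a score requires absolute agreement, not
  merely consistency; the consistency variant ICC(3,1) is available via
  `model="consistency"`. The 95% CI uses the published F-based formulas
  with Satterthwaite degrees of freedom. Degenerate inputs (zero residual
  and rater variance) return a point CI at the estimate.
- **Agreement**: per scheme, the median and IQR of absolute per-eye
  differences from the 9-scan reference, and 95% limits of agreement
  mean ± 1.96 × SD (sample SD) of the signed differences. Signed and
  absolute differences serve different summaries and both are reported.
- **Bland–Altman regression**: OLS of signed difference on pairwise
  mean, after excluding eyes whose pairwise mean exceeds 0.1 — outside
  the score's sensitivity range, where the vitreous saturates and the
  difference–mean relation is no longer informative. Fewer than 3
  remaining eyes raises `InsufficientDataError` (flagged, not fatal, in
  the full report).
- **Paired tests**: Wilcoxon signed-rank on per-eye absolute deviations
  (the paired design governs; the unpaired rank-sum is available via
  `paired=False`), Holm step-down adjustment over the comparison family.
  The default family is the two headline comparisons (3w vs 5c, 7c vs
  3w) plus the adjacent central-scheme pairs; it is configurable because
  the appropriate family depends on the question asked. An all-zero
  difference vector yields p = 1 with a `DegenerateTestWarning`.
- **ROC**: the state variable is reference ≥ split point (median by
  default, quartiles optionally; ties go to the positive class), the
  predictor is the scheme score. AUC is the tie-corrected normalized
  Mann–Whitney U; the 95% CI uses DeLong's structural-components
  variance. An empty class raises `UndefinedAUCError`.

The full report (`stats.run_reliability_analysis`) always carries the
`9s` row as a conservation check — its deviation from the reference is
identically zero because both are computed by the same code path — and
flags, rather than fails on, partial results.

## The synthetic generator

`synthetic.generate_volume` renders, top to bottom: a dark vitreous
(diffuse level 0 by default) with hyperreflective particles, the retina
from the ILM down (intensity 0.35), the brightest RPE band (1.0,
8 px thick at 80% depth with a slight lateral tilt), and dimmer sub-RPE
tissue (0.12). The ILM carries a smooth foveal dip. Particle count per
scan is Poisson with expectation `inflammation_level ×
gradient[scan] × vitreous_area / 1000` (particles per 1000 px²);
particles are Gaussian blobs (σ = 2.5 px, peak ~0.8) placed uniformly in
the vitreous with a 3σ margin above the ILM. All intensities scale by
`opacity_factor`; multiplicative log-normal speckle (scale 0.1 by
default) is applied last. Pixels stay float64 so the opacity model is
exact; `quantize_volume` converts to uint16 at a fixed scale for
lossless PNG storage.

The per-scan quality score is a dB-like SNR proxy — rendered RPE-band
mean over the model's true background-noise SD, clipped to [0, 40] —
mimicking device quality scores so the inclusion gate (score < 20 in
more than 3 scans excludes the volume) is exercisable. With the default
zero diffuse background the proxy clips at 40; gate behaviour is driven
through explicit quality values or a non-zero diffuse background.

**Cohorts** (`generate_cohort`): per eye, the inflammation level is
drawn log-normally (median 2 particles/1000 px², σ = 0.8), giving the
right-skewed severity distribution typical of uveitis cohorts, and the
cross-volume profile is quadratic in scan position,
g(i) = 1 + c·((i − center)/center)², with curvature c ~ U(−0.4, 0.8).
The quadratic profile is the design choice that makes the scan-density
question non-trivial: a *linear* profile is invisible to every symmetric
scheme (its mean over {0,4,8}, {2..6} or all 9 equals the central
value), whereas curvature biases each scheme by
|mean_scheme(u) − mean_9s(u)| with u the squared normalized distance
from the central scan — geometrically 7c < 3w < 5c < 3c < 1c. The wide
selection samples the periphery and therefore tracks the volume mean
under curvature; central selections cannot. Per-scan Poisson and speckle
noise adds a variance term that *decreases* with the number of averaged
scans, which is why the orderings flip at small scan sizes (see
`examples/04_reliability_study.py`).

## What passing tests do and do not show

The generator emulates compartment geometry, particle statistics,
speckle, media opacity and smooth spatial inflammation variation. It
does not emulate wave-optics speckle correlation, motion artefacts,
vessel shadows, posterior vitreous detachment membranes, snowballs or
layered retinal morphology. Passing tests therefore demonstrate the
pipeline's internal correctness and the geometric logic of scan
subsampling — not clinical validity on device data, which requires the
separately validated acquisition chain the score derives from.

## Problem sizes and determinism

The bundled study sizes are chosen to be statistically meaningful at
desk scale: 49-eye cohorts at full 19 × 512 × 496 geometry for the
cohort analyses, 200 replicates for ICC recovery, 30 seeds per density
level for monotonicity, 500 replicates for regression null calibration.
All randomness flows from a single seed through named `SeedSequence`
substreams (one per eye), so cohorts, scores and reports are
byte-reproducible; the acceptance script derives every stream from its
`--seed` argument.

## Known limitations

- The segmentation assumes a single dominant bright band (the RPE) and
  a dark vitreous; dense vitreous haze above ~25% of the RPE brightness
  per column would invalidate columns by design rather than mis-segment.
- The relative threshold adapts to the image; at extreme particle
  density the vitreous saturates and the score compresses (the
  sensitivity-range exclusion in the Bland–Altman regression reflects
  the same physics).
- The quality gate operates per volume (the inclusion rule), not per
  scan: a volume that passes contributes all its analysable scans, and
  scans are only dropped for segmentation failure.
- Test–retest (longitudinal) reliability is out of scope; the analysis
  concerns within-volume scan subsampling at a single visit.
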