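# Methods

## Image model and preprocessing

**Background subtraction.** The background of each channel is estimated by
the rolling-ball construction: a grayscale opening of the intensity surface
with a ball structuring element of radius 115 px (the default), implemented
with `scipy.ndimage.grey_opening` and a non-flat ball-height structure. For
radii above 16 px the image is first shrunk by block-minimum (factor 2/4/8
chosen by radius, the classic ImageJ speed-up), the ball rolled on the
shrunk image, and the background bilinearly interpolated back; the
background is clipped to `[0, image]` before subtraction so the residual is
always in `[0, image]`. Exact bit-compatibility with any particular ImageJ
build is not promised; the operation is specified by the opening contract
and tested against a brute-force double-loop opening. Note that
`skimage.restoration.rolling_ball` was deliberately not used: it returns
the ball-apex erosion rather than the full opening, and deviates from the
opening by several ADU on noisy images.

**Local threshold.** Segmentation of punctate structures uses a local-mean
("auto local threshold", mean method) rule: pixel `p` is foreground iff
`I(p) > mean(I; N_r(p)) + c` with neighborhood radius `r = 5` and offset
`c = 12` ADU by default. The ImageJ mean method thresholds at
`mean − C`; with its parameter `C = −12` this is `mean + 12`, which is the
sign convention adopted here (an offset a spot must rise *above* its
surroundings). The neighborhood is a disk by default (matching the ImageJ
kernel); a square window is selectable, and both are implemented as a
sum-then-divide convolution so that integer-valued images make exactly the
same threshold decisions as a per-pixel reference loop. Borders use
reflective (symmetric) padding. Which local method and sign convention the
original macro used is not recorded anywhere authoritative; both are
configurable.

**Patch detection.** Connected components are 8-connected; the patch size
filter defaults to 4–200 px, bracketing diffraction-limited puncta at the
simulated pixel scale. Centroids are unweighted means of member pixels.

**Photobleaching correction** for movies is model-free ratio normalization:
each frame is scaled so its whole-field mean equals that of frame 0. This
assumes the field-average signal is dominated by a pool whose true
abundance is constant over the movie.

## Colocalization scoring and hit calling

Per field, the score is `s = A_inter / A_red` where `A_inter` is the pixel
count of the green∧red mask intersection and `A_red` the red (anchor) mask
area. The anchor channel is unaffected by rapamycin, so `A_red` acts as a
per-field cell-number normalizer; `s ∈ [0, 1]` by construction.
Normalization is per field (each field yields one `s`) because the
statistical test operates across fields; a pooled mode (sum of
intersections over sum of red areas) is available through
`recruitment_ratio`'s pseudocount path and the per-strain ratio can be
computed either way.

Per strain, `ratio = mean(s|+RAP) / mean(s|−RAP)`. If the vehicle mean is
exactly zero, the ratio falls back to pooled intersection sums with a
one-pixel pseudocount and the record is flagged — this preserves ordering
and avoids infinities in screen tables.

Significance uses a one-tailed Welch (heteroscedastic) t-test with sample
variances and Welch–Satterthwaite degrees of freedom, alternative
"+RAP exceeds −RAP" (recruitment can only increase colocalization). The
cutoff is raw `p < 0.02` (`log10(1/p) > 1.699`; "log" must be base 10 for
those two numbers to agree). No multiple-testing correction is applied by
default, faithful to the original decision rule; Benjamini–Hochberg is
available via `call_hits(..., bh_correct=True)`.

**The negligible-recruitment filter.** Significance alone passes preys
whose absolute recruitment is tiny; the original workflow removed these by
visual inspection. The quantitative surrogate here is `ratio ≥ min_ratio`.
Calibration on the synthetic screen's study conditions (9 fields per
condition, chance colocalization from native membrane puncta): null-strain
ratios are centered at 1 with sd ≈ 0.13, and across a 221-strain panel
their sampling maximum reaches ≈ 1.6, while genuinely recruited preys score
≈ 8. The default is therefore `min_ratio = 2.0` — more than 5 null
standard deviations above the null mode and far below any true recruiter —
chosen as this package's own calibration of the visual-inspection
surrogate. It is a parameter, not a law; screens with weaker expected
recruitment should lower it consciously.

Degenerate inputs: `welch_one_tailed` rejects two zero-variance groups;
`run_screen` instead records such strains with `p = 1` (no evidence) and a
logged warning so one pathological strain cannot abort a screen. Strains
missing a condition or with fewer than two usable fields are skipped with
a warning. Fields whose red mask is empty cannot be normalized and are
skipped likewise.

## The synthetic-microscopy generator

The generator is the package's test bed: it emulates the assay's geometry
and camera, not any particular microscope.

- **Cells** are circles (interior = cytosol) with radius ~ N(18, 2²) px at
  256×256 field size, kept away from the border by a margin so PSF tails
  stay in frame; ~10 cells per field. Anchor puncta sit on the cell
  perimeter (eisosomes are plasma-membrane sites), Poisson-many per cell
  (mean 4, at least 1).
- **Photons.** Amplitudes are total photons per punctum (anchor 2000,
  native prey puncta 1200) or photons per cytosol pixel (prey expression
  5). Point and area sources are rendered then convolved with a Gaussian
  PSF, σ = 1.2 px (≈ 0.21·λ/NA for GFP at NA 1.45 and ~65 nm pixels).
- **Recruitment** in a +RAP field of an interactor strain relocates a
  fraction *e* (default 0.8) of each cell's prey photons — cytosolic and
  native-punctum alike — onto that cell's anchor coordinates, split
  equally. Relocation conserves photons exactly, so total green signal is
  invariant to *e*; this is a tested invariant.
- **Camera.** ADU = gain·Poisson(photons) + offset + N(0, read-noise²),
  with gain 2 ADU/photon, offset 100 ADU, read noise 3 ADU — a standard
  CCD model; the numbers are artifact choices, stated here once.
- **Screen layout.** 227 strains, the six exocyst preys (Sec3, Sec5, Sec6,
  Sec8, Sec15, Exo84) as planted interactors, 9 fields per condition. The
  default prey carries 3 native membrane puncta per cell placed
  independently of anchors — exocyst-like preys live in both cytosol and
  surface patches — which deliberately exercises chance colocalization and
  anchors the null ratio near 1. Every field's RNG stream derives from
  (master seed, strain index, condition index, field index), so any subset
  regenerates bit-identically.

What the generator does **not** model: realistic cell morphology and
crowding, Airy/defocus optics, flat-field inhomogeneity, stage drift,
rapamycin pharmacokinetics, or strain-to-strain expression variability.
Passing tests therefore demonstrate that the pipeline's decision rules
behave correctly under controlled, idealized imaging — not that any
particular biological screen would reach the same sensitivity.

## FRAP

The generative model for a bleached spot, relative to its pre-bleach
plateau and before the whole-field envelope `B(t) = exp(−β·t)`:

```
I(t)/I_pre = 1                                              t < t_b
I(t)/I_pre = 1 − d·( f_imm + (1 − f_imm)·exp(−k_off·(t−t_b)) )   t ≥ t_b
```

where `d` is the bleach depth, `f_imm` the immobile fraction and `k_off`
the exchange rate. The bleach removes a fraction `d` of the whole spot; the
mobile share re-equilibrates with the unbleached pool at `k_off` while the
bleached immobile share never recovers — the standard reaction-limited
FRAP form (anchor sites are static, so diffusion-coupled models are out of
scope). At `d = 1` this reduces to `f_imm + (1−f_imm)(1 − e^{−k t'})`
viewed from zero.

Normalization is double normalization with a full-scale rescale:
background-subtracted spot over background-subtracted whole field (removes
acquisition bleaching), scaled to pre-bleach mean 1, then affinely mapped
so the first post-bleach point is 0. Any affine distortion of the
underlying recovery (ROI size, partial spot capture) cancels exactly, and
the normalized curve is `(1 − f_imm)(1 − exp(−k_off·t'))` — the recovered
fraction. The no-rescale variant is available (`full_scale=False`). Whether
published recovery curves start at 0 depends on each study's convention;
this one is documented here, not asserted as universal.

Aggregation is pointwise mean ± sample SD over replicates on an identical
time grid (no resampling; mismatched grids are an error). Fitting uses
bounded least squares (`mobile ∈ [0,1]`, `k_app ∈ [0, 10] /s`) of
`mobile·(1 − e^{−k_app t'})` to the post-bleach mean curve, with a
half-recovery-time initial guess. For a flat curve the fit converges to
mobile ≈ 0 (stable complex); for `k_off = 0` simulations the observation
window (default 480 s ≈ the 7.5-minute stable-interaction window) shows no
recovery by construction. Parameter identifiability degrades when
`k_off·T ≪ 1` (rate and amplitude trade off along a ridge); the parameter-
recovery tests use grids where at least one time constant fits in the
window.

## Problem sizes and numerical choices

Defaults were chosen to keep a full 227-strain screen (4,086 two-channel
256×256 fields) a few minutes of desk-scale compute: background
subtraction downsamples by block-min for the 115 px ball, and the screen
generator streams fields instead of materializing ~1 GB of pixels. The
type-I-error calibration simulates 5,000 null preys at the score level
(per-field Gaussian scores with per-prey variance inflation up to 3× in
one group) with a vectorized Welch test. Ties in thresholding are broken
strictly (`>`); the manual-scoring cutoff is strict (`fraction > 0.9`);
patch membership uses the nearest-pixel centroid at tolerance 0 by default
(the strictest reading of "colocalized"), with a dilation tolerance
available.
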