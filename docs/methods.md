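# Methods

This note documents the algorithms, their assumptions, the tunable
parameters with defaults, the synthetic-data model behind the test suite,
and the limitations a user should know before trusting numbers on real data.

## Puncta segmentation chain

The chain assumes a single larva per analyzed field, imaged as a Z-stack
with bright, compact autophagosome puncta on a diffuse autofluorescent body.

1. **Maximum projection** over Z. Puncta are analyzed in 2D; no 3D
   segmentation is attempted.
2. **Smoothing**: a 3×3 median filter (despeckle) followed by a Gaussian
   blur, `smooth_sigma` = 10 px by default — on the order of the larva
   half-width at 20×, heavy enough that subtracting the smoothed image
   removes the body background while leaving puncta intact. The sigma is the
   single most consequential tunable: too small and puncta are subtracted
   away; too large and body edges bleed into the subtracted image.
3. **Body mask**: the smoothed image is binarized (Otsu by default; a fixed
   absolute threshold is available for fields where bimodality fails),
   components below `min_body_area` (5 000 px²) are discarded, the largest
   survivor is kept, and the mask is eroded by a disk of `shrink_radius`
   (5 px). A minimum image contrast (`min_contrast` = 10 intensity units)
   acts as the detection floor: blank wells raise a "no larva detected"
   signal that becomes a displaced-larva exclusion upstream.
4. **Puncta**: the subtracted image (projection − smoothed, clipped at 0) is
   thresholded at `threshold_factor` × mean(smoothed | body), with
   `threshold_factor` = 1.0 by default. The factor is exposed because real
   reporters vary in diffuse-to-punctate contrast. Components ≥
   `min_punctum_area` (4 px²) that satisfy the containment rule — fully
   inside the body mask by default, centroid-inside as a tolerant option —
   are labeled puncta.

Consequences of this design worth knowing:

- The threshold is proportional to the mean body signal, so puncta counts
  are invariant to detector gain, and detectability is governed by the
  punctum peak-to-body contrast, not by peak-to-noise. Puncta dimmer than
  the diffuse body signal are invisible to this algorithm by construction.
- The erosion step biases the relative puncta area upward (the denominator
  shrinks) by roughly the rim fraction of the body — about 9% at the default
  geometry. This is inherent to the shrink-then-measure chain and is left
  uncorrected; comparisons across groups are unaffected because the bias is
  common to all larvae.

**Larva localization** (low magnification) thresholds a lightly smoothed
well image, keeps up to `max_larvae` (3) silhouettes, takes the principal
axis of each, and anchors the analysis area `head_tail_offset` px inward
from the head- and tail-side extremes. The offset and the analysis-area
size have no literature-derived defaults; both are configuration values.
Silhouettes too short for the offset window are logged and skipped.

**Pre/post pairing.** Larvae from the two acquisitions (± NH₄Cl) are paired
greedily by nearest ROI centroid, ties broken by distance then lower index.
A larva undetectable in either acquisition voids the pair: both phase
records are emitted with the displaced flag and no metrics — absent, not
zero — and every exclusion is logged with its well and larva identity so
group n's are auditable.

## Screen analytics

Fold change is computed within (plate, phase) strata against the vehicle
group; the group summary is the mean by default (median available). Each
phase is normalized to its own vehicle; normalizing both phases to the
−NH₄Cl vehicle is a config option since either convention is defensible.
Excluded larvae never enter any mean.

Flux ratio is the ratio of raw group means (+NH₄Cl over −NH₄Cl), not of
fold changes, so the vehicle's own flux is meaningful.

E\_max is the maximum +NH₄Cl fold change over non-toxic doses. Toxicity is
an input flag on the plate map (a visual-inspection call), not computed.
All-toxic compounds are carried as excluded entries rather than dropped.
Hit calling (E\_max ≥ 1.5 by default) is explicitly threshold-dependent;
the threshold lives in config. Ranking ties break at the lower achieving
dose, then compound name, for determinism.

The 4PL fit uses least squares with a fixed, deterministic initialization:
top/bottom from the response extremes, IC₅₀ from the geometric mean of the
doses bracketing the half response, Hill = 1, with bounds IC₅₀ > 0 and
Hill ∈ [0.01, 20]. Responses spanning less than `no_transition_range` (0.2)
raise a "no transition" signal instead of returning a meaningless IC₅₀; an
ascending fitted curve is reported as a fit error since the model is an
inhibition titration. No inferential statistics (ANOVA, multiple
comparisons) are reimplemented; the module emits tidy tables for standard
statistics software.

## Ratiometric indices

The mito-QC index segments mitochondria on the mCherry channel (Otsu), then
calls mitolysosomes on the per-pixel log ratio log(mCherry/(GFP + ε)),
ε = 1 intensity unit to keep near-zero GFP pixels finite. The mitolysosome
cut is Otsu on the log ratio within the mitochondrial mask, accepted only
when the resulting classes straddle the absolute cutoff (ratio 2 by
default); unimodal fields — fully colocalized or fully quenched — fall back
to the absolute cutoff. Both area mode (mitolysosome area / mitochondrial
area, in [0, 1]; the default) and count mode (foci / mitochondrial objects)
are implemented because both definitions are in circulation; the foci count
is always reported. All intensity ratios are invariant to common gain on
both channels.

JC-10 channel-to-role mapping (monomer vs aggregate) is explicit
configuration and never inferred from emission wavelength, because
wavelength conventions are inconsistent across sources. Per-cell ROIs are
caller-supplied masks; automated cell segmentation is out of scope.

## Physiology traces

Basal OCR is the mean of the last three pre-FCCP points, exactly; earlier
points never enter it. Two maximal-OCR conventions coexist in practice and
disagree on real traces, so both are implemented — post-FCCP maximum, and
mean of the last three points before R+AA (the default, matching
figure-style summaries) — and the output labels the rule used.
Non-responders (post-FCCP OCR never above basal) are flagged with their
metrics retained. Control-chamber normalization matches timestamps within
half the median sampling interval by default.

The activity score counts t₀-worm pixels vacated at t₁ over t₀ worm area:
this is the only reading that gives the stated endpoints (identical masks
→ 0, complete departure → 1). A symmetric-difference variant is available.
Alive/dead calls are input flags; multiple 30-s windows per video are
aggregated by their mean.

## Synthetic-data model

The generators define the conditions every recovery test runs under.

- **Larva stacks**: an elongated elliptical body (default area 55 000 px²,
  aspect 2.75) of uniform autofluorescence (80 above a background of 20)
  present in all 26 planes; puncta are uniform-intensity disks (default
  diameter 4 px) each placed in one random Z plane, rejection-sampled to be
  non-overlapping and ≥ 14 px inside the body edge. The `snr` parameter is
  the punctum peak amplitude over the clean body plateau (signal-to-
  background contrast, default 3) — the quantity that governs detectability
  under a body-mean threshold. Noise is Poisson shot noise plus Gaussian
  read noise (sd 3). Disk profiles keep planted areas exact; a Gaussian
  profile is available but optics/PSF are deliberately not simulated.
- **mito-QC fields**: thickened random-walk curvilinear mitochondria in
  both channels; a connectivity-preserving subset of network pixels is made
  mCherry-only, trimmed to the requested area fraction by breadth-first
  carving; the truth records the exact post-trim fraction.
- **OCR traces**: three plateaus (basal 210, uncoupled 350, nonmitochondrial
  30 pmol O₂/min) sampled every 5 min with Gaussian noise (sd 5);
  non-responders plateau at 70% of basal. Titration pairs follow a 4PL
  truth (IC₅₀ 300 µM, Hill 1.5, 2 measurement cycles per step) with a flat
  control chamber.
- **Worm frames**: a rectangular blob whose trailing columns are vacated
  pixel-exactly to the requested fraction, with mass conserved ahead of the
  worm, so the planted activity score is exact.
- **Screens**: per-larva relative areas drawn lognormal (CV 20%) around
  group means implied by a sigmoidal dose dependence (EC₅₀ 25 µM, Hill 2)
  reaching the planted fold change (2.0) at the top dose in the +NH₄Cl
  phase and half the effect at baseline; vehicle flux ratio 1.5; doses
  10/50/100/250 µM, 15 larvae per group, 20 compounds with 2 actives.

What these fixtures do **not** emulate — and hence what passing tests do not
establish about real data: optical blur and axial crosstalk, intensity
gradients and vignetting, touching or overlapping larvae, autofluorescent
debris, photobleaching between the ± NH₄Cl acquisitions, plate spatial
effects, and motion artifacts other than complete displacement.

## Numerical and design notes

- Coordinates are 0-based (row, col); ROIs are half-open. Areas are
  reported in px² and µm² (px² × pixel\_size\_µm²).
- Pixel sizes are read from TIFF resolution metadata only when a physical
  unit is declared; unit-less resolution tags fall back to the configured
  default rather than being trusted.
- All generators are bit-deterministic for a fixed seed, and planted
  quantities are exposed in the returned ground truth so tests never
  hard-code expectations.
- The IC₅₀ Monte-Carlo validation uses 8 half-log doses × 2 measurement
  cycles × 4 replicate chambers per titration. At 5%-of-top measurement
  noise a single measurement per dose leaves a free 4PL fit with a
  Cramér–Rao lower bound on IC₅₀ error of roughly 20% — no estimator can do
  better — so replicate-chamber designs are the realistic setting in which
  ~3–5% median IC₅₀ error is achievable.
- Problem sizes in the validation scripts (20–50 stacks, 100–200 Monte-Carlo
  screens, 100 trace replicates) were chosen to make sampling error small
  relative to each tolerance band.

## Known limitations

- The puncta threshold couples detection to body brightness: dim puncta on
  a bright body are missed, and strongly autofluorescent debris inside the
  body mask is counted.
- Body-mask erosion biases relative puncta area upward (~9% at defaults);
  use identical settings across groups being compared.
- The mito-QC index assumes mitolysosomes are mCherry-bright; quenched and
  degraded reporters (dim in both channels) are invisible.
- Pre/post larva pairing is geometric only; it cannot recover identity if
  larvae swap positions between acquisitions.
- Toxicity and death calls are inputs, not inferences.
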