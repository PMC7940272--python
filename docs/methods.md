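# Methods

## Scope and model of the data

`punctaflux` quantifies single-section, multichannel fluorescence images of
pancreatic islets. Each image is a set of registered 2D intensity planes
(proinsulin/insulin, LC3, LAMP1, p62, optionally DAPI) with one physical
pixel size (μm/px) supplied by configuration. Z-stacks are rejected rather
than silently flattened: all quantities are defined on single confocal
sections. Pixel size is configuration-driven rather than parsed from TIFF
tags, avoiding tag-dialect fragility.

The unit of analysis is the islet: one image yields one row of densities
and colocalisation percentages. Subject identifiers are carried through so
users can aggregate per animal/donor, but the statistics operate on islets.

## Pipeline steps

**Background subtraction.** For each channel the 25th-percentile intensity
of *all* pixels (linear-interpolation estimator) is subtracted and the
result clamped at zero. The quantile is computed image-wide, before ROI
masking, so the estimate reflects the acinar/background field. Clamping
(rather than rescaling) was chosen because downstream thresholding is
scale-dependent; the applied quantile and the subtracted value are recorded
in the channel's provenance. The operation is idempotent once ≥ 25 % of
pixels are zero.

**Median smoothing.** Square-window median filter, window (2r+1)², default
r = 1, reflect padding. Reflection avoids darkening objects at borders.

**ROI.** Two modes. *Marker-derived* (human-tissue style): global Otsu on
the background-subtracted proinsulin channel, morphological closing
(disk, default radius 2 px), hole filling, and removal of components
< `min_area_px` (default 100). Proinsulin staining is granular, so closing
and hole filling turn it into a filled region. *Manual* (mouse-tissue
style): a binary mask image; non-zero = ROI; masks with more than two
values are an error, never guessed. An all-zero marker or mask produces an
*empty-ROI flag*, not an exception, and the islet is excluded from
normalised metrics.

**Puncta detection.** Median smooth → mask to ROI → global Otsu computed
over ROI pixels only (so extra-islet background cannot skew the threshold;
a fixed threshold is available per channel) → 8-connected labelling →
equivalent-diameter gate, d = 2·sqrt(area/π), default gate [2, 10] px,
configurable per channel. The gate defaults are sized for
diffraction-limited spots at ~0.1 μm/px sampling. Touching puncta are *not*
declumped — they merge into one object. This is a documented limitation and
drives the synthetic generator's separation constraint (below).

**Colocalisation.** Object-overlap, not pixel correlation. Every child
object is assigned to the parent object with the largest pixel overlap;
ties break to the lowest parent id (deterministic); children with zero
overlap stay unassigned. The reported statistic is
100 · (#assigned children)/(#children). A minimum-overlap fraction knob
exists (`coloc.min_overlap_frac`, default 0 = any shared pixel). Islets
with zero child puncta are flagged and excluded from group means rather
than scored 0 %, which would bias low-count groups downward.

**Statistics.** One-way ANOVA with Tukey HSD (all pairwise contrasts);
two-way ANOVA group × treatment with type-II sums of squares (robust to
unbalanced islet counts, switchable) and within-group treatment contrasts
using the pooled residual variance of the factorial model, Sidak-adjusted
over the number of groups (p_adj = 1 − (1 − p)^m); two-sided unpaired t
(pooled by default, Welch optional; two zero-variance samples with equal
means give p = 1 by convention). α = 0.05 throughout. Summaries are
mean ± SEM.

**Flux assessment.** A group's autophagic flux is *intact* iff its
chloroquine arm shows a Sidak-adjusted significant *increase* of the marker
density over its untreated arm; otherwise *impaired*. The biological logic:
a lysosomal blocker can only pile up autophagosomes/p62 if degradation was
running. Degenerate fits (zero residual variance, e.g. all-zero densities)
are flagged and called impaired unless the delta is positive with an exact
zero p. p62 fold change divides each chloroquine islet's density by its
group's baseline mean (per-islet; a per-subject option averages baseline
means per animal first); a zero baseline mean flags the fold as undefined.

**EM nitrogen rims.** Telolysosome identification from raw EM morphology is
upstream, manual, and out of scope; the module consumes object label masks
with a per-object kind (secondary lysosome vs telolysosome) plus aligned
N/P/Os elemental maps. The core is the object eroded by `shell_width`
(default 3 px); the shell is the remainder. The rim score,
mean N(shell)/mean N(core), is scale-invariant under linear rescaling of
the N map. Rim-positive requires score ≥ `ratio_cut` (default 1.5) *and* a
phosphorus-enriched core relative to the non-object background — the
phospholipid signature of the lysosome interior. Osmium is carried only as
a lipid-presence sanity channel. Objects too small for a non-empty core are
flagged unclassifiable and excluded from occupancy denominators. Both
thresholds are explicit configuration: ring presence in real data is
qualitative, so the classifier is parameterised, not asserted as ground
truth.

## Synthetic generator

The generator is the package's test bed and defines its study conditions.

*Geometry.* An islet is a smooth random blob (radial harmonics around a
centre, mean radius ≈ 1/3 of the frame) in a 192 × 192 px frame at
0.1 μm/px.

*Spots.* Isotropic Gaussians, σ = 1.2 px (diffraction-limited at this
sampling), amplitude 150 with 15 % CV. Per-channel counts are Poisson with
mean density × islet area; densities in the default cohort (0.001–0.006
spots/px², i.e. 0.1–0.6 puncta/μm²) sit in the range typical of islet
immunofluorescence. Same-channel centres keep a minimum separation of
5 σ = 6 px, enforced by grid-accelerated rejection sampling. This
separation is deliberate: detection performs no declumping, and the
Otsu-level footprint of a σ = 1.2 spot has radius ≈ 2 px, so centres closer
than ~4.5 σ merge into one object. The generator therefore emulates
resolvable fields; when a requested density approaches the packing limit,
sequential placement saturates below it and the ground truth records what
was actually planted. Requests above 0.2 spots/px² are rejected outright.

*Colocalisation.* A Binomial(n, f) subset of child spots is planted on
distinct parent centres with ≤ 1 px jitter — centre-sharing, the strongest
form of object overlap, so any-overlap detection recovers it. Remaining
children keep ≥ 3 σ distance from every parent, so accidental overlap does
not inflate the realised f.

*Noise.* Smooth background (offset 20 + directional gradient amplitude 10)
plus Poisson shot noise and additive Gaussian read noise (σ = 3) — the
standard fluorescence forward model. The proinsulin channel additionally
carries a granular plate (level 60, textured) filling the islet so the
marker-derived ROI is segmentable.

*Cohorts.* The default scenario is three groups × two treatments:
a control-like arm (f = 0.60, chloroquine doubles LC3 and p62 densities), a
pre-disease arm (f = 0.55, elevated baseline child density, LC3 but not p62
chloroquine response) and a disease arm (f = 0.25, no chloroquine response).
All randomness flows through one seeded generator; identical seeds give
bit-identical images.

*Record-level sampler.* The statistics/flux layer is additionally exercised
by a direct sampler of per-islet densities (gamma-distributed, CV 0.25
around arm means). This is the fast harness for decision-logic checks that
need many re-seeded replicates; the image path exercises detection and is
validated separately.

*EM objects.* Synthetic lysosomes are discs (radius 10–14 px) whose
nitrogen either concentrates in a 3-px peripheral shell (ringed) or spreads
uniformly (un-ringed), over a phosphorus-rich core, with Gaussian map noise.

**What the generator does not emulate:** tissue autofluorescence, immune
infiltrate morphology, anisotropic/Airyscan PSFs, chromatic misregistration,
clustered (non-Poisson-disc) puncta, partial-overlap colocalisation
geometries beyond the jitter knob, and EDX spectral artefacts. Passing
tests therefore demonstrate correctness of the measurement chain on
resolvable, well-registered fields — not robustness to every property of
real tissue.

## Problem sizes in the shipped checks

The test suite and reproduction script use sizes chosen to give tight
Monte-Carlo error while staying desk-scale: 20 images per planted-f arm for
colocalisation recovery; 5 images per density for detection fidelity;
100 re-seeded record-level runs (15 islets/arm) for flux calls; 1000
replicates for ANOVA type-I calibration; 100 objects for ring recovery;
8 images/arm for the full-cohort ordering run. At the planted fractions
0.60 vs 0.55 the two non-diabetic arms differ by only 5 points, so their
*ordering* in any single small cohort is noise-sensitive; the disease arm
(0.25) separates unambiguously.

## Numerical choices and edge cases

- Percentile estimator: linear interpolation (the common default).
- Otsu ties/constant regions: a constant ROI yields zero puncta rather
  than an arbitrary split.
- Assignment ties: lowest parent id wins, making outputs reproducible.
- Zero-child islets: colocalisation is NaN + flag, excluded from means.
- Zero-area ROI: density is an error; the islet row carries the empty flag.
- Sidak values are capped at 1; adjusted p is never below unadjusted.
- CSV output uses a fixed column order and `%.10g` floats, so identical
  runs are byte-identical.

## Known limitations

Merging of touching puncta (no declumping/watershed) biases counts down and
sizes up at high density; colocalisation of densely packed children is
correspondingly approximate. The ROI is a single region per image — no
per-cell segmentation. The flux call is a per-group binary at a fixed α; it
does not model dose, time courses, or subject-level random effects.
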