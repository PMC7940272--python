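# punctaflux

Quantitative image analysis of beta-cell autophagy in pancreatic islets.

Autophagy ships cytoplasmic cargo to lysosomes: LC3-positive autophagosomes
form, fuse with LAMP1-positive lysosomes, and their contents — including the
adaptor p62 and, via crinophagy, proinsulin granules — are degraded. In
immunofluorescence sections this process is read out as *puncta*: small,
diffraction-limited spots in each marker channel. `punctaflux` implements the
full quantification chain used for such studies:

1. **Background subtraction** — per channel, subtract the image-wide
   lower-quartile intensity, clamped at zero.
2. **ROI definition** — the analysis region is the proinsulin-positive area
   (Otsu threshold, closing, hole fill, size filter) or a supplied manual
   islet mask.
3. **Puncta detection** — median filtering, Otsu thresholding over ROI
   pixels, 8-connected labelling, then a pixel equivalent-diameter gate
   d ∈ [d_min, d_max] (default [2, 10] px); counts are normalised to ROI
   area (puncta/μm²).
4. **Object-overlap colocalisation** — each *child* punctum (LC3 or
   proinsulin) is assigned to the *parent* punctum (LAMP1) with the largest
   pixel overlap; the statistic is the percentage of children assigned:
   `pct = 100 · n_colocalised / n_child`.
5. **Group statistics** — one-way ANOVA with Tukey HSD, two-way ANOVA
   (type-II SS) with Sidak-adjusted within-group contrasts
   (`p_adj = 1 − (1 − p)^m`), unpaired t tests, mean ± SEM summaries.
6. **Autophagic-flux calls** — with a lysosomal blocker (chloroquine),
   marker puncta accumulate only if flux is running; a group is called
   *intact* iff its chloroquine-vs-baseline contrast shows a significant
   increase, else *impaired*. p62 fold change over the baseline group mean
   is reported alongside.
7. **EM/EDX nitrogen rims** — for annotated lysosomes/telolysosomes in
   electron micrographs with elemental maps, the rim score is
   mean N(shell) / mean N(core); objects with score ≥ 1.5 and a
   phosphorus-enriched core are rim-positive, and class occupancy
   (Lys−/Lys+/Tel−/Tel+) is tabulated.

Because real donor and mouse imaging data are not redistributable, the
package ships a first-class **synthetic generator**: islet-shaped fields
with Gaussian puncta, planted colocalisation fractions, Poisson + read
noise, cohort-level group effects, and full ground truth — so every stage
is testable end to end without any download.

## Worked example

```bash
punctaflux synth    --out demo/images --seed 1 --n-images 4
punctaflux quantify --manifest demo/images/manifest.csv --out demo/quant
punctaflux stats    --islets demo/quant/islets.csv --out demo/stats
```

This writes a 24-image cohort (three groups × baseline/chloroquine,
4 islets per arm), quantifies one row per islet, and runs the statistics.
`demo/quant/islets.csv` begins:

```
image_id,subject_id,group,treatment,roi_area_px,roi_area_um2,density_lc3_per_um2,...
NOR_none_000,NOR_s0,NOR,none,11941,119.41,0.2093626999,0.3098567959,...
```

Group means of LC3-in-LAMP1 colocalisation (`demo/stats/summary.csv`):

```
          group   treatment      mean      sem  n
   NOD_diabetic        none 20.485640 3.041295  4
NOD_nondiabetic        none 61.953939 0.797970  4
            NOR        none 48.051916 1.815064  4
```

i.e. the untreated disease arm shows far lower autophagosome–lysosome
overlap than the two non-diabetic arms (planted fractions 0.25 vs
0.55/0.60; at 4 islets/arm the two high arms are within noise of each
other). The flux calls (`demo/stats/flux_calls.csv`, LC3 density):

```
             metric           group  delta_puncta  p_adjusted     call
density_lc3_per_um2    NOD_diabetic      0.001935    0.999900 impaired
density_lc3_per_um2 NOD_nondiabetic      0.220885    0.000008   intact
density_lc3_per_um2             NOR      0.217298    0.000010   intact
```

Chloroquine roughly doubles LC3 density in the two flux-competent arms
(significant Sidak-adjusted increase → *intact*) and does nothing in the
disease arm (→ *impaired*), exactly as planted.

The library surface mirrors the CLI: `load_stack`, `subtract_lower_quartile`,
`segment_marker_roi`, `detect_puncta`, `percent_colocalized`,
`assess_flux`, `rim_classify`, `generate_islet_image`, … — see the module
docstrings under `src/punctaflux/`.

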