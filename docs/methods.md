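# Methods

## Model and assumptions

`thyquant` treats an H-DAB brightfield photomicrograph as a Beer–Lambert
absorbance image: each pixel's per-channel optical density
`OD_c = −log10(max(I_c, 1)/255)` is a nonnegative linear combination of
three unit-norm stain absorbance vectors (hematoxylin, DAB, residual).
Unmixing is the exact 3×3 inverse in OD space with negative concentrations
clipped to zero.  The white point is fixed at 255 — background subtraction
is folded into the white-reference transform rather than performed as a
separate rolling-ball step; a custom stain matrix can be supplied in config
(rows are renormalised automatically).  The default matrix uses the
standard published H-DAB absorbance vectors with the residual row completed
per channel as `sqrt(1 − h² − d²)` and renormalised, which keeps all
components nonnegative.

Segmentation is deliberately simple and global: one threshold set per run,
trading adaptivity for robustness to background-staining variation.  The
follicular-cell region is defined *geometrically*, not by cell detection:
colloid dilated by a band width and intersected with cellular tissue, minus
dilated nuclei.  This sidesteps the cell-phenotyping problem entirely and
is the core design idea of the protocol.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `median_radius_px` | 2 | px | smallest disc that kills impulse noise without eroding single-cell features |
| `bright_mean_rgb` | 232 | 8-bit | separates unstained lumen/glass (≳240) from stroma (≈195) and epithelium (≲210) |
| `nucleus_hema_od` | 0.35 | OD | between cytoplasmic hematoxylin (≈0.15) and chromatin (≈0.8) |
| `stroma_residual_min` / `_margin` | 0.08 / 0 | OD | stroma is the only class carrying residual-channel density; a pixel is stroma when residual OD clears the floor and exceeds hema+DAB |
| `min_area_um2` | 30 | µm² | below one small cell: specks are relabelled to their surround |
| `closing_radius_um` | 0 | µm | per-class closing is available (precedence nucleus > colloid > parenchyma > stroma) but off by default — at 1 µm/px it bridges the cytoplasmic slivers between rim nuclei |
| `band_width_um` | 8 | µm | typical thyroid epithelium height |
| `nucleus_dilation_um` | 1 | µm | guard ring against chromatin bleed into cytoplasm |
| `positivity_threshold` | 180 | 0–255 | gate between faint nonspecific DAB (≈228 at OD 0.05) and genuine signal (≈64 at OD 0.6) |
| `subroi_area_um2` / `n_subrois` | 2×10⁵ / 5 | µm² | the study's fixed sampling budget, 10⁶ µm² total |
| `surs_fraction` / `tile_um` | 0.03 / 100 | — / µm | the study's validated sampling fraction; tile geometry is unstated there, squares chosen |
| `bandwidth_um` | 50 | µm | heatmap smoothing ≈ a few cell rows; unstated upstream, chosen once |

Every geometric parameter is physical (µm) and converted through `mpp`
(microns per pixel), which must be given explicitly — there is no silent
pixel-unit fallback.

## Synthetic histology: what it emulates and what it does not

The generator renders colloid lumens (circles with low-frequency radial
perturbation) ringed by a one-cell epithelial rim carrying hematoxylin-dark
nuclei, embedded in stroma rendered via weak residual-channel density;
lymphocytes are small hematoxylin-only discs in stroma, providing the
lymphocytic-thyroiditis confounder.  Default frame 1392×1040 RGB; synthetic
calibration is 1 µm/px (real 20× captures are ≈0.46 µm/px) so the
multi-subROI geometries fit desk-scale frames — the calibration is explicit
everywhere, so nothing depends on this choice.  DAB positivity is assigned
by thresholding a smooth Gaussian random field (σ = 10 µm) at the quantile
matching the requested fraction, so the realised positive fraction equals
the target almost exactly while remaining spatially clumped like real
staining.  Rim nuclei are placed by arclength (default 8 per 100 µm,
radius 4 µm, rim 10 µm) as a monolayer: neighbours may come close but keep
a sliver of cytoplasm between them.

Not emulated: papillae and capsules, nuclear texture/chromatin patterns,
stain gradients across the slide, scanner artefacts, out-of-focus regions,
tissue folds.  Passing tests therefore demonstrate correctness of the
*algorithmic chain* (separation, segmentation-by-architecture, geometry,
quantitation, sampling, statistics) under controlled appearance — not
robustness to the full variability of clinical slides, which would require
stain normalisation the protocol deliberately leaves out of scope.

## Numerical choices

- **Quantisation.**  The forward renderer is exact in float; writing 8-bit
  images adds up to half a grey level, i.e. ~0.004 OD at mid densities.
  Round-trip accuracy of 10⁻³ OD is therefore asserted on the unquantised
  model; segmentation thresholds carry margins an order of magnitude wider
  than quantisation error.
- **Colloid vs glass.**  Both are bright; they are separated purely by
  border connectivity (4-connected components touching the frame border
  are background).
- **Nucleus splitting.**  Connected nucleus components larger than 1.5×
  the nominal nucleus area are split by distance-transform watershed with
  peaks at least one nucleus radius apart.  Rim nuclei are clipped by the
  band, so an abutting pair measures below twice the nominal area — a 2×
  threshold would never split pairs; the peak guard protects oversized
  singles.
- **Hotspot ties and determinism.**  Greedy hotspot selection takes the
  raster-first argmax on ties; suppression radius is max(two circle radii,
  `min_separation_um`), guaranteeing non-overlap.  Valid circle centres
  come from a Euclidean distance transform of the ROI (the frame border
  counts as outside).  All randomness (grid offsets, SURS phase, synthesis)
  flows from explicit seeds; two runs with equal config are byte-identical,
  which is the protocol's headline advantage over manual scoring
  (run-to-run Lin's CCC = 1).
- **SURS.**  Every k-th ROI-intersecting tile in raster order,
  k = round(1/fraction), with a seeded uniform random grid offset and
  phase; the selected area tracks the target fraction to within about one
  tile for grid-aligned ROIs (strong aliasing between tile rows and k can
  exceed this on contrived geometries).
- **Heatmaps.**  Gaussian KDE via reflective-boundary filtering, which
  conserves total mass, so the map integrates to the event count.
  Min-max normalisation before the product combination; a constant
  positive map normalises to ones, a zero map to zeros.
- **Empty regions.**  Empty quantitation masks yield `n_pixels = 0` with
  null metrics and a logged warning — never a division by zero; SURS tiles
  landing in stroma do this routinely.
- **Score binning.**  The percentage scale (0: ≤10, 1: >10–30, 2: >30–50,
  3: >50–70, 4: >70) leaves exact boundary values formally unassigned; they
  fall into the lower bin.  When emulating manual scores from DIA readouts,
  intensity grades 0–3 use mean-intensity cuts 220/160/110 (dark = strong).
- **Statistics.**  Moments in Lin's CCC use n-denominators; its CI uses the
  Fisher z transform with the asymptotic variance of the transformed
  estimate (degenerate and |rc| = 1 cases return a point interval).  ANOVA
  pairwise contrasts use the pooled MSE standard error; Tukey–Kramer p via
  the studentized range (Bonferroni and unadjusted LSD are alternatives —
  which correction produced the original tables is not stated upstream).
  Shapiro–Wilk delegates to SciPy.  AUC is the tie-averaged rank statistic;
  the operating point maximises Youden's J, lower threshold on ties.
- **Mean intensity** averages *all* quantified pixels, not only positives
  (`mean_over_positives=True` gives the alternative).

## Problem sizes

Tests and the acceptance script run on desk-scale synthetic frames
(256–640 px; 20-image cohorts at 320 px; the 80-case group-discrimination
cohort at 256 px; sampling-geometry checks on a 3000×2000 px ROI).  These
sizes give the segmentation and sampling oracles thousands-to-millions of
pixels while keeping the full suite under a minute; all algorithms are
resolution-independent through `mpp`.

## Known limitations

- Global thresholds presume consistent staining/scanning; batch-to-batch
  stain variation needs normalisation or stain-vector estimation
  (Macenko/NMF), both out of scope.
- The stroma/parenchyma rule keys on residual-channel density, which is a
  modelling stand-in for eosin-less connective-tissue colour; heavily
  eosinophilic or hemorrhagic stroma would need a retuned rule.
- Hotspot methods assume nucleus detection is reliable inside the ROI;
  dense lymphocytic infiltrate biases the nuclear heatmap toward
  inflammation (the same caveat applies to the original protocol, which is
  why percent positivity in lymphocytic-thyroiditis cases needs cautious
  reading).
- Percent positivity measured through the full pipeline can jitter a few
  points as staining strength shifts segmentation boundary pixels; the
  directional trend (positivity up, mean intensity strictly down with
  rising DAB density) is what the pipeline guarantees.
- Single-resolution processing: the low-resolution screening / high-
  resolution quantitation split of whole-slide platforms is reduced to
  mask-restricted computation at one scale, adequate at desk scale; a
  pyramid scheduler would slot in ahead of `analyze_case`.
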