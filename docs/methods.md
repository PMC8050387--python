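# Methods

## Overview

`neuritequant` quantifies neurite outgrowth in two-channel live-cell
fields: a DNA-dye (Hoechst) channel giving the cell count, and a
cell/neurite channel from which thin projections are segmented and
measured.  The statistical unit is the field, matching per-image
quantification on a screening microscope; per-cell distributions are
additionally derivable from the component-to-cell assignment.

## Physical calibration

All thresholds on object size and length are physical (µm, µm²) and are
converted to pixels through `pixel_size_um`.  The default of 0.65 µm/px is
a typical 10x sCMOS scale; it is a configurable assumption, not a
measured constant, and the resolved value is echoed into every metrics
row and into `config_resolved.yaml` so results are auditable.

## Nucleus segmentation

Pipeline: Gaussian smoothing (sigma 2 px) → illumination correction →
global threshold → hole filling → area filtering → watershed splitting →
optional border exclusion → relabelling 1..N.

- **Illumination correction** subtracts a grayscale-opening background
  with a disk of radius 25 px (must exceed the nucleus radius).  The disk
  is applied in decomposed form (scikit-image `decomposition="sequence"`),
  which deviates from the exact disk by well under 1% of the signal
  amplitude and is an order of magnitude faster; the unit tests bound the
  deviation against an exact-disk oracle.
- **Threshold**: Otsu on the corrected channel, plus an offset expressed
  in median-absolute-deviation (MAD) units so it transfers across bit
  depths.  A robust floor of median + 4 MAD guards the degenerate case of
  a structure-free field, where Otsu would otherwise split the noise
  itself; because the floor is an affine-equivariant statistic, counts
  remain invariant under intensity rescalings a·I + b (a > 0) with zero
  offset.
- **Area band**: nuclei outside [30, 500] µm² are rejected — plausible
  bounds for SH-SY5Y nuclei at 10x; both ends configurable.
- **Splitting touching nuclei**: candidate seeds are the strict 3x3 local
  maxima of the Euclidean distance transform.  Seeds are accepted
  greedily, deepest first, with a minimum spacing of 5 px (closer
  candidates are plateau/quantisation duplicates and are absorbed).  A
  watershed on the negated distance assigns pixels to seeds.  Finally,
  adjacent fragments are re-merged when their union has a major/minor
  axis ratio below 1.45 — still the shape of a single (possibly slightly
  elliptical) nucleus.  This last step is the load-bearing design choice:
  a plain minimum-seed-distance rule fails in both directions, because
  the distance maxima of fused nuclei drift toward the shared waist
  (under-splitting) while boundary noise can give one nucleus two
  well-separated maxima (over-splitting).  Shape of the union separates
  the two cases: fused pairs at up to 30% overlap form unions with axis
  ratio ≥ ~1.5, single nuclei stay below ~1.4.  On synthetic ground
  truth this yields exact counts on 100/100 disjoint-nuclei fields and
  ≤1 count error on ≥ 92% of touching-pair fields at SNR 5.
- **Border policy**: border-touching nuclei are excluded by default
  (partial nuclei bias both the count and the area distribution).
- Labelling is 8-connected throughout; ties between equal-distance
  watershed basins resolve to the lower raster-order label, so the
  segmentation is deterministic.

## Neurite segmentation

Pipeline: multi-scale tubeness → hysteresis threshold → morphological
cleanup → soma exclusion → skeletonization → spur pruning → component
length filter → topology extraction.

- **Ridge operator**: Sato Hessian-eigenvalue tubeness, maximum over
  scales {1, 2, 4} px, robust to the uneven contrast of live-cell
  imaging.  Default polarity is bright-on-dark with a config switch,
  since either contrast can occur in practice; dark-on-bright is computed
  on the inverted channel.
- **Threshold**: hysteresis in robust units — high threshold at
  median + 8 MAD of the response, low at half that.  Hysteresis keeps dim
  mid-sections of a neurite connected while rejecting isolated noise
  response.
- **Soma exclusion**: nucleus labels dilated by 5 µm are removed from the
  neurite mask, so only projections outside cell bodies are measured.
- **Skeleton**: scikit-image thinning, followed by a deterministic
  unit-width repair that deletes topology-preserving (simple) pixels of
  any fully set 2x2 block.  Terminal spurs shorter than 5 µm are pruned
  iteratively by walking from endpoints to the first branch point; a
  junction pixel left as a redundant bump is removed when its remaining
  neighbours are already mutually connected.  Components shorter than
  10 µm are dropped.  Crossing neurites are not disentangled; they count
  as one component.
- **Length convention**: the sum over unique 8-adjacent skeleton pixel
  pairs of 1 (orthogonal) or sqrt(2) (diagonal) times the pixel size,
  with no corner-cut or perimeter corrections.  On digitised curves of
  random orientation this convention overestimates true arc length by
  ~4% on average (0% at 0° and 45°, up to ~8% near 22.5°) — an intrinsic
  property of 8-connected chain length, visible in the recovery numbers
  below.

## Per-field morphometrics

Each skeleton component is assigned to the nucleus whose centroid is
nearest to the component's closest pixel (ties to the lower label).  A
cell is *neurite-positive* when its summed assigned length reaches
20 µm (≈ one to two SH-SY5Y soma diameters); the assay itself does not
define the term, so the threshold is exposed and echoed in the output.
Fields with zero nuclei have undefined per-cell quantities; they are
flagged (`excluded`) and dropped from statistics rather than imputed.

## Statistics

Group summaries are the median with a seeded percentile-bootstrap CI
(B = 10,000 by default; the CI method for this presentation is a package
choice).  Two conditions are compared with the Welch t test by default
(classical pooled t by flag); three or more with classical one-way ANOVA
plus each-treatment-vs-control t tests using the pooled within-group
mean square and Bonferroni correction — the post-hoc procedure is a
declared choice, and both raw and corrected p-values are available.  All
tests are two-sided.  Stars follow p < 0.05 / 0.01 / 0.001 / 0.0001 →
* / ** / *** / ****.

Calibration, measured by the acceptance script: null rejection rates at
alpha 0.05 of 0.047 (t) and 0.049 (ANOVA) over 5,000 simulated null
datasets (n = 30/group), and 94.2% coverage of the true median by the
95% bootstrap CI over 1,000 simulations (n = 50).

## Synthetic fields and ground truth

The generator emulates a screening-microscope field:

- **Nuclei**: ellipses with radius uniform in [3.5, 5.5] µm,
  eccentricity ≤ 0.15, Gaussian-blurred (sigma 1.2 px); placement by
  rejection sampling under a pairwise-overlap constraint, with a bounded
  retry budget (violations raise a generation error naming the
  constraint).
- **Somata**: one disk (radius 6 µm) per nucleus in the cell channel.
- **Neurites**: constant-width (3 px) strokes whose centerlines are
  chains of three circular arcs with curvature uniform in ±0.05 rad/µm —
  circular arcs have exact closed-form length, so the recorded ground
  truth is analytic, not an estimate.  Each neurite starts on the
  boundary of the anchor soma's exclusion disk (nucleus radius + 5 µm,
  mirroring the segmentation's soma dilation), with a cosmetic stem back
  to the soma; paths that would leave the field or graze another soma
  are re-drawn.  The recorded length is therefore exactly the length the
  segmentation is expected to measure.
- **Noise**: Poisson shot noise on the signal plus Gaussian read noise,
  each contributing half the variance at peak-signal pixels, calibrated
  so (peak − background)/SD equals the requested SNR (default 8; the
  recovery claims are validated at SNR 5).
- **Determinism**: one `numpy` generator per field, seeded from the
  spec; per-field seeds in an experiment derive from
  `SeedSequence((master, condition, field))`, so fields are independent
  yet bit-reproducible.

What the generator does **not** emulate: phase-contrast optics and halos,
uneven illumination across the field, cell debris and apoptotic bodies,
neurite fasciculation, intensity variation between cells, and focus
drift.  Passing the synthetic suite therefore demonstrates correctness of
the measurement chain under the stated image-formation model, not
robustness to every real-world artefact; on real data the robust (MAD)
thresholds and physical-size filters are the intended adjustment points.

## Measured performance (acceptance script, seed 1)

- nucleus count exact on 100% of 100 fields (10–40 nuclei, SNR 5);
  mean centroid error 0.19 px;
- touching-pair fields (≤30% overlap): count error ≤ 1 on 96% of 50
  fields;
- curved-neurite total length: median |relative error| 2.6% (50 fields,
  SNR 5); end-to-end fields 2.0%;
- a generator-built 2x difference in neurite length per cell
  (25 fields/condition) detected at p ≈ 1e-23;
- byte-identical metrics and comparison CSVs across repeated runs.

Problem sizes in the test and acceptance suites (256x256 px fields,
50–100 fields per property, B = 1,000 bootstrap inside simulations) were
chosen to give stable Monte-Carlo estimates at interactive runtimes; all
thresholds they are checked against were fixed beforehand by the
properties above.

## Known limitations

- The 8-connected step-weight convention overestimates curve length by
  up to ~8% at unfavourable orientations; comparisons between conditions
  are unaffected (the bias is common to both), but absolute lengths
  carry it.
- Touching nuclei beyond ~30% overlap, or pairs with very unequal radii,
  are not reliably separable by shape and may count as one.
- Crossing or fasciculating neurites are measured as shared skeleton
  pixels once, slightly undercounting dense arbors.
- The neurite-positive threshold (20 µm) is a convention; report it with
  any fraction-based result.
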