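# Methods

This note records the model, the tunable parameters, the conventions chosen
where the design was genuinely open, and what the synthetic benchmark does
and does not establish.

## The model

The pipeline treats a TMA core's DAPI channel as a landscape of nuclear
blobs and classifies *groups* of nuclei rather than single ones. The
biological signal it exploits is that tumor nuclei sit in tight nests
(nearest-neighbour pixel gaps of a few pixels) and stain *darker* than the
surrounding stromal nuclei, while stroma is sparser and brighter, with two
recognizable subtypes: elongated fibroblasts and small, bright, round
inflammatory cells (lymphocytes).

Two rules define the cell graph. Nuclei are **touching** when their pixel
sets, dilated with a diamond (city-block ball) of radius *r*, intersect —
for the diamond this is exactly "minimum L1 distance ≤ 2r", which is how
the property test checks it. Nuclei are **intensity-compatible** when their
mean pixel intensities differ by strictly less than a threshold, which
prevents dim tumor nuclei from linking to the brighter stromal cells that
may wrap a tumor nest. An edge requires both. Connected components with
≥ 2 nodes are classified by a subgraph SVM; degree-0 nuclei go to the
single-cell fallback.

## Parameters

| parameter | default | unit | origin |
|---|---|---|---|
| background floor | 25 | grey level | published constant |
| median kernel | 3×3 | px | published constant |
| min object area | 150 | px | published constant (strict <) |
| isolated-nucleus margin | 20 | px per side | published constant |
| overstain min area | 2000 | px | free (unstated); configurable |
| h (h-maxima) | 10 | grey levels | free (unstated; "empirically" tuned per dataset) |
| diamond radius | 2 | px | published constant |
| intensity-link threshold | 30 | grey levels | published constant (strict <) |
| top-k features | 15 | — | published constant |
| SVM C | 1.0 | — | free; standard default |
| RBF width γ | 1/k selected features | — | free; standard default |
| inflammatory area cap | 500 | px | published constant (strict <) |
| roundness threshold | 0.85 | — | free (unstated) |
| eccentricity threshold | 0.9 | — | free (unstated) |
| inflammatory intensity threshold | Otsu of nucleus means + 30 | grey levels | free; derived per core so it tracks staining variation |

Boundary conventions are literal readings: "below 25" → strict <,
"smaller than 150 px" → strict <, "lower than 30" → strict <. Component
labeling is 8-connected throughout. All of these are configurable.

## Numerical and procedural choices

* **Otsu thresholding** is an exhaustive search over the 256 candidate
  levels maximizing between-class variance, with pixels ≥ t mapped to
  foreground and ties broken toward the smallest t. The preprocessing
  binarization uses the full histogram (the split wanted there is
  background vs nuclei); the pre-segmentation brightness split ignores
  background pixels.
* **Brightness split granularity.** The bright/dark separation before
  seeding assigns whole connected mask components, not pixels, to a side
  (by their mean masked intensity against the Otsu level). A pixel-level
  cut slices every mid-intensity nucleus in two — its bright center and
  dim rim land in different partitions — and produced systematic
  over-segmentation; whole "objects with a brighter illumination" is also
  the more faithful reading of the method being reproduced.
* **h-maxima seeds** are the regional maxima of the morphological
  reconstruction (by dilation) of `image − h` under `image`. Taking the
  maxima of the reconstruction rather than the `residue ≥ h` set matters on
  noisy plateaus: the residue set fragments into scattered single pixels at
  the peak level and spawns spurious seeds. A constant image yields one
  seed covering it. Seeding and watershed run on a 3×3-median-smoothed
  copy of the corrected image; nucleus intensity statistics are computed on
  the shading-corrected, pre-median image.
* **Watershed** floods the inverted intensity from the seeds inside the
  mask (8-connectivity, deterministic priority queue); mask components
  containing no seed stay background.
* **Shading correction** divides by a clear-background field (supplied, or
  estimated as a smoothed block-wise 5th percentile) and rescales by the
  field's mean, so a flat field is an identity up to rounding. Saturated
  (255) pixels stay saturated so the overstain filter still sees them.
* **Segmentation scoring** matches result and truth nuclei by maximal
  pixel overlap: a truth nucleus whose best-covering result label is shared
  (or that nothing covers) counts under-segmented, one claimed by ≥ 2
  result labels counts over-segmented, the rest are correct; the three
  counts partition the total.
* **Isolated-nucleus removal** takes all its decisions in a single pass on
  the input mask. Because bounding boxes are not symmetric between objects
  of different sizes, "apply again" is not a theorem for this rule;
  idempotence is verified on generated cores, where the spacing makes it
  hold, and not claimed in general.
* **Hop-plot exponent**: P(h) counts unordered node pairs with shortest
  path ≤ h, h = 1..diameter; the exponent is the least-squares slope of
  log P vs log h; graphs of diameter < 2 return 0 with a warning. Nodes of
  degree < 2 contribute clustering coefficient 0.
* **Eq.-level ambiguity**: the mean intensity in the linking rule is taken
  over the nucleus's own pixel set, not over its bounding-box crop (the
  written form sums a rectangular cell image; including background pixels
  would make the mean depend on crop padding).
* **Subgraph truth labels** (for training/evaluation): tumor iff a strict
  majority of member-nucleus centroids falls inside the tumor-region mask;
  ties go to stroma. Mixed subgraphs are rare but possible.
* **Producer's accuracy aggregation** is per-core-then-averaged
  (mean ± sample sd over cores), with the pooled per-nucleus accuracy
  reported alongside; a core without nuclei of a class is excluded from
  that class's aggregate.
* **Model serialization** is versioned JSON holding the support vectors,
  dual coefficients, bias, γ, the selected feature names and the
  normalization bounds; prediction is evaluated from these arrays directly,
  so a save/load round-trip reproduces every decision value bit-for-bit.

## The synthetic generator

`SyntheticCoreSpec` states the world the tests run in: a 512×512 core disc
with 6 tumor clusters of 8 nuclei (mean level 95), 40 stromal nuclei (mean
165; 20% fibroblasts, 20% lymphocytes at ≥ 200 and < 500 px), per-nucleus
intensities N(class mean, 7), a multiplicative Gaussian-bump shading field
of relative amplitude 0.15, additive N(0, 3) noise, background level 10 and
one saturated blob. Within-cluster nearest-pixel gaps are kept in 2–4 px
(so the touching rule links them), tumor–stroma and solitary-stroma gaps
exceed 4 px. Nuclei are filled rotated ellipses with a smooth radial
profile (center +12%, rim −12%) — the single dominant peak per nucleus that
h-maxima seeding relies on in real DAPI images. Rendered nuclei cap at
grey level 254; 255 is reserved for overstained artifacts. One
`numpy.random.Generator` stream per core makes output bit-identical per
seed; impossible packings raise a capacity error after bounded retries.

Because no quantitative per-class size/intensity distributions are
published for this material, these defaults are the package's own choices,
set once to produce the qualitative structure described above and not tuned
against any test outcome.

A deliberate deviation: taken literally, "stromal gaps > 4 px" would make
*every* stromal nucleus isolated, so no stroma-class subgraph could ever
exist and the subgraph classifier could not be trained with both classes.
`fraction_clustered_stroma` (default 0.4) therefore places part of the
generic stroma in loose pairs/triples with linkable gaps, which is also
what fibrous stroma looks like in practice.

What a green benchmark does **not** establish: performance on real tissue.
The generator renders flat-profile ellipses without chromatin texture,
debris, out-of-focus sections, squashed core boundaries or staining
batch effects, and its class contrast (70 grey levels) is generous. The
synthetic end-to-end accuracy (~99–100%) is an internal-consistency check
of segmentation → graph → features → SVM → propagation, standing in for a
published real-data figure near 89% that cannot be reproduced without the
original cohort.

## Known limitations

* Single-channel 8-bit input only; no multi-channel (keratin/vimentin)
  rendering or evaluation.
* The watershed operates in 2-D; overlapping nuclei from 3-D sectioning are
  merged or split heuristically.
* The inflammatory-rule intensity threshold derived per core assumes both
  dim and bright nuclei are present; cores of one population fall back to
  the mean + offset.
* Whole-slide reading, core localization and de-arraying are out of scope;
  the input is one already-extracted core image.
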