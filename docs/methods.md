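# Methods

## The measurement model

A dual 2-nitroimidazole experiment yields, per tumour section, two registered
fluorescence channels: CCI-103F (baseline hypoxia, TRITC-range emission) and
pimonidazole (post-treatment hypoxia, FITC-range), plus a hand-drawn ROI
excluding skin and normal tissue. Both markers are bioreduced and retained
only below ~10 mmHg O₂, so after thresholding each channel inside the ROI the
set difference CCI \ Pimo is tissue that *was* hypoxic and no longer is. The
package treats the inputs as pre-registered; no image registration is
performed (serial-section comparisons in the original workflow are manual).

Coordinates are 0-based (x right, y down); a rasterised polygon contains a
pixel iff the pixel centre lies inside it (even-odd rule), so integer-vertex
rectangles have exact pixel areas. Acquisition-range images are mapped to the
8-bit analysis range by fixed nominal scaling (v·255/65535, round half-up),
*not* per-image min–max: per-image scaling would silently re-define a global
preset threshold from section to section.

## Thresholding

Two thresholding routes are exposed, mirroring the two tool chains such
studies use. `preset_threshold` applies one global intensity cut-off;
`otsu_threshold` maximises between-class variance over the 256-bin histogram
restricted to ROI pixels, with ties broken toward the lower threshold for
determinism. Positivity is `intensity ≥ threshold` everywhere — conventions
differ between tools, so this is fixed and documented rather than
configurable. A constant ROI has no Otsu threshold and is an error, not a
guess. The original acquisition software's "global preset intensity using
adaptive threshold" is internally ambiguous (global vs adaptive), so no
attempt is made to reverse-engineer it; both documented routes are provided
instead.

## Category arithmetic and scores

`classify_categories` is pure set arithmetic; the partition identity
(reoxygenated + new hypoxia + no change = CCI ∪ Pimo within the ROI) holds
exactly by construction and is enforced by exhaustive tests on all 2×2 mask
pairs. Optional minimum-object-size and hole-fill filters exist but default
to off, preserving the raw arithmetic.

The reoxygenation statistic is a log-ratio of integrated densities (sum of
8-bit CCI-channel intensities): numerator the full baseline mask, denominator
the overlap. The study wording ("the region stained only for CCI-103F, ...
subtracting the overlap region") supports either a full-mask or a
CCI-only numerator; the full-mask form is the default because it makes the
noiseless statistic exactly −log₂(1 − f) in the reoxygenated fraction f,
putting the published call thresholds (0 and 1) at f = 0 and f = 0.5; the
CCI-only variant is available via `numerator="cci_only"`. Both ratios are
ε-regularised only when a mask is empty (ε = 0.01 percentage points for the
area ratio, 1 intensity unit for densities), and activation is flagged in the
report rather than silent — empty pimonidazole masks are a real possibility
the original analysis never specifies. Call thresholds are strict
inequalities; both boundary values map to "indeterminate".

Group summaries use two-sided t-tests at the 5% level: Welch for unpaired
comparisons, exact pairing only when a pairing key is supplied.

## Foci scoring

Nuclei are segmented from the counterstain by Otsu + hole filling + a
distance-transform-seeded watershed (minimum area 30 px, configurable); the
original study scores manually, so the detector is a documented stand-in
whose parameters were set on the phantom. Foci are counted per nucleus by
Laplacian-of-Gaussian blob detection over a 1–3.5 px radius range with a
relative prominence floor of 0.08 of the intensity range; blobs dimmer than
the floor are deliberately not counted. ">5 foci" is read strictly as ≥6 and
the boundary is tested. CCI-103F status uses a majority-pixel rule (≥50% of
nucleus pixels inside the CCI mask, configurable). Aggregation follows the
study's sampling scheme — regions enriched for the reoxygenated category,
≥5 fields per region, ≥50 cells per field — with under-populated fields
flagged and excluded; because it is unstated whether published percentages
are pooled or per-field means, both aggregations are emitted, and an empty
stratum is reported as absent rather than 0%.

## Spheroid quantification

The proprietary well-cytometer segmentation is replaced by documented
Otsu-on-inverted-brightfield + hole filling; the largest component is taken,
with a second large object or low circularity (4πA/P² < 0.6, the
disaggregation signature at cytotoxic doses) recorded as QC warnings rather
than silent exclusions. Diameter is the equivalent-circle diameter;
"average fluorescence intensity" is the masked mean over the spheroid (the
alternative, whole-well mean, would dilute the signal with empty-well area).
Ratios are taken to the same-timepoint dose-0 control mean, so the control
ratio is identically 1.

## The phantom generator

The generator emulates the study conditions, not the optics. Hypoxic
geometry is the upper level set of a Gaussian-smoothed random field
(`blob_scale_px`, default 16 px), giving patchy, multi-component masks like
perfusion-limited hypoxia; the exact number of positive pixels is taken, so
requested fractions are met to within one pixel. Reoxygenation is carved
from the baseline mask greedily — whole blobs in a seed-determined order,
then boundary-erosion layers, then a field-value-ordered partial layer — so
the removed fraction is exact and geometrically contiguous. New hypoxia is an
independent level set drawn from the CCI-negative remainder. Channels are
rendered two-level (default 40000/5000 in 16-bit) with additive Gaussian
noise clipped to the intensity range; at zero noise each channel takes
exactly two values.

Foci phantoms place disc nuclei (default radius 10 px) on a jittered grid,
non-overlapping by construction, and render foci as Gaussian spots
(σ = radius/2) with centres inside the parent nucleus and a minimum
centre-to-centre separation of 2.5 focus radii — the separation at which
scale-space blob detection provably resolves neighbours, keeping counts
well defined at zero noise. When a Poisson draw exceeds what the nucleus can
hold at that separation, placement relaxes stepwise and the *placed* count is
recorded as truth, so ground truth always matches the rendered image.
Per-stratum Poisson means allow different foci burdens in CCI-positive and
-negative cells.

Spheroid phantoms draw diameters uniformly from 400–700 µm (default
4 µm/px), render a dark disc on bright brightfield and a concentric hypoxic
core (0.6 of the radius) in the red channel whose intensity is scaled by the
clearance multiplier

    m(d, t) = 1 − s(d) · exp(−max(t − 1, 0)/τ(d)),
    s(d) = d²/(d² + k₅₀²),  τ(d) = τ₀(1 + d/k₅₀),   k₅₀ = 1.2 mM, τ₀ = 8 h,

which is exactly 1 at dose 0, strictly decreasing in dose at fixed time, and
recovers toward 1 by 24 h at low doses (hypoxia re-emergence), with the
half-effect dose at the concentration where published dose responses become
significant. Because the core/spheroid area ratio is constant across sizes,
the control-normalised masked mean recovers m(d, t) directly.

What the phantoms do **not** emulate: point-spread blur, stitching and
illumination artefacts, autofluorescence gradients, nucleus shape
variability, marker intensity heterogeneity within hypoxic tissue, and
imperfect section registration. Passing tests therefore demonstrate the
correctness of the arithmetic, thresholds, detectors and statistics under
controlled conditions — not robustness to every artefact of real microscopy.

## Numerical choices and problem sizes

All randomness flows through `numpy.random.Generator` seeded per stage;
identical configuration and seeds reproduce byte-identical CSVs. Default
validation sizes — 192–256 px sections, 100–1000 nuclei, 14 spheroids per
condition over a 6-dose × 3-timepoint grid — were chosen so the full suite
exercises every code path on a laptop-class machine in well under a minute
while keeping sampling error far below the tolerances tested (e.g. the
Poisson-tail check at 1000 nuclei has a sampling SD of ~1.6 percentage points
against a ±5 pp band).

## Known limitations

- The pipeline assumes pre-registered channels; misregistration directly
  inflates the mismatch categories.
- The Otsu route presumes a bimodal ROI histogram; weakly stained sections
  may need the preset route.
- Foci counting saturates for very dense nuclei (>~15 foci at the default
  geometry) where spots physically merge.
- The normalised-image cross-check some workflows use for region selection
  is not implemented (under-specified); region selection here is by
  reoxygenated-category enrichment alone.
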