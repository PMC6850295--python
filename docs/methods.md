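# Methods

## Model and assumptions

Both methods assume a single-channel intensity image in which the objects
of interest differ in grey level from their local background, so that
object edges carry large gradient magnitude. Foreground polarity is
explicit: `dark_objects` thresholds the range [L_Min, L] (foreground =
pixels ≤ L, inclusive), `bright_objects` the range [L, L_Max]. L_Min and
L_Max are the observed extreme grey values, and the search always visits
every integer level in between — exhaustive by construction, with no
histogram shortcut or subsampling.

The **global method** scores each level L by the total or mean gradient
over the phase boundary E(L) and returns the argmax. The two statistics
differ in emphasis: `total` grows with boundary length and favours levels
where long edges are strong; `average` normalises by N(L) and is the more
selective of the two, often showing secondary maxima that correspond to
alternative or multiple thresholds. Both are exposed; `average` is the
default.

The **region-based method** applies the same score per 8-connected
boundary component and per level, then reduces the (level × image) stack
of score-labelled boundaries by a per-pixel maximum projection. Its
correctness rests on two observations: (i) a region's boundary score is
maximal at the level where the boundary sits on the object edge, and (ii)
after projection that boundary is a constant-valued plateau whose
neighbours (boundaries from non-optimal levels, or background) are
strictly lower, so the exact regional-maxima transform recovers it. Nearby
objects whose optimal boundaries touch can shadow one another (the
touching plateau has a higher neighbour); the object-specification filter
mitigates this by removing implausible competitor boundaries while the
stack is built.

## Border and connectivity conventions

Stated once and used everywhere:

- Greyscale morphology (Beucher gradient) and the Sobel filter use
  replicate padding at the frame.
- Binary erosion treats outside-the-image as background, so regions
  touching the frame acquire boundary pixels along the frame; every phase
  boundary is therefore a closed curve and hole-filling is well defined.
  Frame-touching regions are flagged `touches_border` so they can be
  excluded from analysis.
- Regions and boundary components are 8-connected (thin diagonal
  boundaries stay whole under 8-connectivity); the background in the
  filling step is 4-connected, the complementary connectivity.
- Sobel magnitudes are kept at full float precision internally; clipping
  to the bit-depth range would quantise the average statistic.

## Tunable parameters

| parameter | default | units | notes |
|---|---|---|---|
| polarity | dark_objects | — | which side of the level is foreground |
| gradient method | beucher | — | Sobel selectable; both give near-identical curves |
| statistic | average | gradient units | `total` also exposed |
| Gaussian radius | 0 (off) | px (σ) | radius 1 suppresses pixel noise before the gradient |
| min_circularity | 0.5 | — | 4πA/P², capped at 1 |
| min_area, max_area | 250, 3000 | px² | scale with expected object size |
| mode | cumulative | — | `stack` is bit-identical, O(levels) memory |

The default bounds (0.5, 250–3000 px²) suit nuclei of roughly 9–30 px
radius; the synthetic-scene tests scale the area bounds to their object
sizes (100–5000 px² for 8–16 px semi-axes).

## Numerical choices

- **Scores are exact floats.** Slice images are never quantised to the
  image bit depth; a component's score is constant across its pixels by
  construction, so plateau equality under the regional-maxima transform
  is exact, with no spurious splits or merges.
- **Ties.** Equal statistic values at different levels: the smallest level
  wins (deterministic output). Equal scores reaching the same projection
  pixel from different levels: the lower level keeps provenance; the
  projection value is unaffected. Exact score ties between *different*
  touching components are left implementation-defined (both plateaus
  survive if neither strictly dominates); float scores make this
  measure-zero in practice.
- **Degenerate inputs.** G_Average is defined 0 where N(L) = 0 and such
  levels are excluded from the argmax; an image where every level has an
  empty boundary raises `NoPhaseError`. A constant projection is one
  whole-image plateau (vacuously maximal); `segment_regions` guards this
  by returning an empty result when no boundary ever scored above 0 —
  e.g. on a constant image.
- **Local maxima of the curve.** Interior peaks only (a monotone curve
  has none), plateaus reported at their smallest level, optional
  prominence filter (default 0, no smoothing): the curves are smooth
  enough on realistic images that no peak-picking heuristics are needed.
- **Perimeter estimator.** 8-connected Moore contour walk through pixel
  centres, 1 per axial and √2 per diagonal step; a single pixel is
  defined as 4, a 10×10 square measures 36, a 1×100 bar 198. Chain-code
  estimators of this family overestimate smooth contours by ~4–5%
  depending on orientation, so digital disks plateau at circularity
  ≈ 0.90–0.92 rather than 1 (and the value wobbles slightly with radius).
  Circularity thresholds up to ~0.8 are unaffected; absolute values near
  0.9 should not be over-interpreted.
- **Half-pixel boundary offset.** E(L) is the *inner* boundary of B(L),
  so the optimum aligns a ring that sits ~0.5 px inside the mask edge
  with the true edge: the optimal mask is dilated by about half a pixel.
  For a convex object of radius r the attainable Jaccard against an ideal
  mask is ≈ (r/(r+0.5))² — about 0.92–0.94 at r = 8–16 px, above 0.95
  only for r ≳ 26 px. This is a property of the method's boundary
  definition, not an implementation artefact; the test thresholds follow
  this bound.

## Synthetic scenes

`generate_scene` emulates brightfield images of stained nuclei:
non-overlapping ellipses (semi-axes drawn from 8–16 px by default,
optional aspect-ratio control for elongated fixtures), per-object
foreground intensity 50–120 on background 200, optional linear
illumination ramp of ± a stated amplitude across the field, Gaussian edge
blur σ = 1, optional additive Gaussian noise (sd 1–15 covers the tested
range), all on a seeded `numpy` generator — identical parameters and seed
give bitwise-identical scenes. The gold standard is the ideal pre-blur
mask. `three_tone_scene` nests a darker nucleus (tone 60) inside a
cytoplasm ellipse (140) on background 220, with whole-cell and nucleus
label classes, for multi-threshold tests.

Not emulated: chromatin texture, clumped/touching nuclei, defocus, stain
colour. Passing tests on these scenes demonstrate correctness of the
algorithms on well-separated blob-like objects; they do not certify
performance on dense tissue, where clumping and the regional-maxima
shadowing effect matter.

Problem sizes used by the test-suite and the acceptance script — 192–320
px fields, 2–20 objects, 5 noise seeds — are the package's chosen
desk-scale defaults; all quantities recompute at larger sizes with the
same code paths.

## Design choices on open points

- Matching for evaluation is greatest-overlap, one-to-one, gold objects
  visited in label order (ties: larger Jaccard, then smaller region id);
  unmatched gold objects count 0 toward the mean. The matcher is a single
  function and can be swapped.
- Noise in the robustness harness is added to the clean scene first; any
  smoothing is part of the method under test (this mirrors evaluating a
  noisy acquisition).
- Provenance (winning level per pixel) is recorded during projection as
  diagnostic metadata; the output mask never depends on it. Each reported
  region's `source_level`, rethresholded inside the region's bounding
  box, reproduces the region (internal consistency asserted in tests).
- The object-specification filter evaluates circularity/area on the *filled* region of a
  boundary component, using the same fill rule as the final step.

## Known limitations

- Simple hole-filling: objects with genuine interior holes ("child"
  regions) are filled solid; a hole-preserving fill is out of scope.
- Touching objects with different scores can shadow each other's plateaus
  and drop out without an object specification.
- Without a spec, a closed frame ring from the level where the phase
  covers the whole image can become a (low-scoring) regional maximum on
  ramped backgrounds and flood the result; any sensible area bound
  removes it.
- 16-bit images are supported throughout, but the exhaustive level scan
  visits every integer level between the observed extremes; very wide
  dynamic ranges are correspondingly slow.
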