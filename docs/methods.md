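# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `vtlkit`, in the order data flows through the
package.

## Arena geometry and coordinates

All coordinates live in a normalised arena: the circular well (35 mm
physical diameter) maps to a circle of 430 px, the frame is 470 px square
with the circle centred, and the origin sits at the upper-left corner
outside the circle with x growing rightward and y downward. Frames are
0-based; object identities are 1-based in files. The default frame rate is
7.2 frames/s; the photoperiod is 12 h light : 12 h dark with recordings
conventionally starting at lights-on. The millimetre conversion, where
requested, is 35 mm / 430 px.

## Trajectory model (synthetic arena)

Each animal is a two-state semi-Markov process:

* **Dwell times** in the active and rest states are exponential
  (`mean_active_bout_s` = 300 s, `mean_rest_bout_s` = 600 s by default),
  rounded to whole frames with a one-frame minimum. During the dark phase
  the rest dwell mean is multiplied by `dark_rest_multiplier` (default 2),
  the minimal mechanism that consolidates night sleep and gives sleep
  latency something to measure.
* **Rest steps** are isotropic jitter with radius uniform in
  [0, `rest_jitter_px`), `rest_jitter_px` = 1 px < 3 px, so every
  rest-state frame satisfies the immobility rule by construction.
* **Active steps** follow a correlated random walk: a persistent heading
  with Gaussian turning noise (`heading_turn_sd` = 0.6 rad/frame) and a
  per-bout walking speed drawn as 3 px + Exp(`active_step_mean_px` − 3 px)
  with ±30 % uniform frame-to-frame jitter (`active_step_mean_px` = 12 px
  ≈ 7 mm/s, an ordinary walking pace). Step lengths are floored so the net
  displacement of an active frame is never below the 3 px rest threshold;
  the labels the simulator emits therefore agree *exactly* with the rest
  classifier run on its coordinates. We chose a correlated walk over
  frame-wise uniform headings deliberately: pure positional diffusion makes
  the identity of two touching identical animals unresolvable in principle,
  which neither real insect locomotion (runs with gradual turns) nor any
  plausibly accurate tracker corresponds to.
* **Social attraction**: with probability `social_attraction` (default
  0.2) an active step is aimed at the nearest neighbour instead of the
  persistent heading. This produces transient proximity bouts (sub-second
  to tens of seconds) rather than permanent pairing.
* **Rigid bodies**: animals cannot interpenetrate. A step may not bring
  two centroids closer than `min_separation_px` = 14 px (one body width,
  twice the 7 px ellipse semi-minor axis) unless they are already closer,
  in which case it may not decrease the distance further. Candidate
  headings violating this are redrawn; in a crowded corner physicality
  yields to the active-displacement guarantee so the label/metric
  agreement is never broken.
* **Boundary**: steps crossing the wall reflect specularly (the remaining
  segment mirrors across the tangent at the crossing point). Reflection
  preserves path length but can shorten the net chord, so a reflected
  *active* step whose net displacement would fall below 3 px triggers a
  heading redraw; rest steps can only shrink further below threshold, which
  is harmless. The containment radius is the arena radius minus the body
  semi-major axis, keeping the whole rendered body inside the well.
* The final frame's state label repeats the penultimate one, mirroring how
  the rest classifier extends its last flag.

**Rendering.** Bodies are filled dark ellipses (semi-axes 15 × 7 px ≈ 3 mm
at the 430 px / 35 mm scale) oriented along the instantaneous heading, on a
uniform background (gray 200) with the well rim drawn dark and additive
Gaussian sensor noise (SD 3 gray levels), quantised to 8 bits. All
generators are deterministic given their seeds.

**What the generator does not emulate**: uneven illumination, shadows and
reflections at the wall, body-posture changes (wing extension, grooming),
partial occlusion by the food surface, and camera artefacts. Passing tests
on synthetic data therefore validates the geometry, the assignment logic
and the metric definitions — not robustness to real-world photometric
nuisances, for which the segmentation thresholds are exposed.

## Tracker

Per frame: the well is located (explicit geometry, or a Hough circle
transform on Canny edges once per recording), the image is affine-warped so
the well is a centred 430 px circle, pixels outside the circle are replaced
by the interior median, and connected regions darker than the interior
median by `threshold_offset` (default 50 gray levels) with area in
[`min_area`, `max_area`] = [120, 1500] px² become detections at their
darkness-weighted centroids. The bounds fit the default 30 × 14 px body
(~330 px²) and are configuration for other species or optics.

When fewer detections than animals remain, oversized blobs (≥ 1.2× the
expected single-body area) are split by seeded Lloyd iteration on the blob
pixels — seeds are the animals' last known positions when they lie within
the blob's reach, otherwise the blob's principal-axis extremes — and the
pieces are marked as shared.

Identity linking is a per-frame global minimum-cost assignment
(`scipy.optimize.linear_sum_assignment`) between predicted positions and
detections. Predictions are per-identity anchors advanced by an
exponentially damped velocity (new estimate = ½ old + ½ last step);
identities sharing a blob keep their pre-merge relative offsets, translated
rigidly so the group mean follows the blob centroid, and their velocity
resets. Residuals are divided by a per-identity scale
σ = clip(0.5·speed + 2 px, 2 px, gate) before the Hungarian solve, so a
long-immobile animal — whose position is known tightly — outweighs a fast
mover when both could claim the same blob. Detections within a frame are
sorted canonically first, making the result invariant to detection order;
equal-cost ties resolve deterministically.

Flags: unmatched identities inherit their last coordinate (`missing`);
surplus identities attach to the nearest blob and both parties are flagged
`overlap` (as are identities on split pieces); matches beyond `gate_px`
(default 50 px) are `deviation`; detections outside the arena circle are
`mislocation`.

**Evaluation.** Tracker labels are arbitrary, so identities are aligned to
ground truth once per recording by minimum mean distance (Hungarian on the
mean-distance matrix). An object-frame is correct when the tracked
coordinate lies within `tol_px` (10 px, about one body width) of the true
coordinate of the aligned identity; incorrect frames are attributed to
overlap (flagged shared blob), mislocation (missing or outside the arena),
or deviation (everything else). The tolerance-based definition is this
package's own, standing in for manual frame checking.

**Known limitation.** During head-on contact with direction reversals, two
identical centroids are momentarily interchangeable; no appearance-free
tracker can resolve every such event, and occasional identity swaps after
deep contacts are the residual error mode (benchmark accuracy across seeds
is ~98–100 % for group sizes 1–5 at 10 px tolerance).

## VTL format

Commented `# key: value` header (format version, well id, fps, diameter,
object count, start timestamp, photoperiod; unknown keys round-trip), then
one tab-separated record per object-frame: `frame object x y flag`, frames
0-based, objects 1-based, coordinates printed with two decimals, missing
values as `NA`. Write∘read is the identity at two-decimal precision and a
second write is byte-identical. A full day at 7.2 fps is 622,080 records
per object.

## Behaviour metrics

* **Rest** is strict: displacement < 3 px; the final frame inherits the
  preceding flag. Missing (NaN) steps count as rest — an undetectable
  animal that held its last coordinate reads as immobile, matching the
  physics of an undetected resting fly; `summarize_behavior(...,
  mask_flagged=True)` instead excludes flagged frames from distance and
  social computations for users who prefer strictness.
* **Sleep bout threshold**: a rest run qualifies with ≥ ⌈300 s · fps⌉
  frames (2160 at 7.2 fps — a run of exactly five minutes counts; the
  ceiling is computed with a 1e-9 guard against binary rounding of
  300 × 7.2). Metrics are computed over a 24 h window aligned to
  lights-on; recordings of 24.5 h should discard the first half hour (the
  window helper takes any half-open frame range of exactly one day).
  Latency runs from lights-off (minute 720 of the window) to the onset of
  the first episode starting at or after it, and is censored at the
  720 min dark-phase length — with a flag, not dropped — when no such
  episode exists.
* **Social bouts** use ≤ 40 px inside and > 40 px outside, reconciling the
  mixed "within"/"less than"/"beyond" conventions in circulation; the
  boundary frame itself counts as interaction. Distances below 5 px count
  as interaction by default; `min_distance_px=5` activates the alternative
  lower cutoff. Well-level values are the mean over the unordered pairs in
  the well (not a per-fly renormalisation).
* **Performance index** for T-maze assays: (n_reference − n_stimulus) /
  total, in [−1, 1].

## Screen hit calling

Population statistics include the candidate line itself and use the sample
(n−1) SD; the sleep rule is strict (< mean − 2·SD), locomotor and social
rules are inclusive (≥ 1.5×, ≤ 0.5× the mean). Consequences worth knowing:
the −2·SD rule is affine-equivariant and therefore always has ~2 % of a
normal null population below threshold — planted strong effects are always
recovered, but tail lines of the null are legitimate additional calls, not
errors. Lines are called per line; `hits_to_genes` reduces to gene level
(a gene is a hit if any of its lines is).

## Enrichment

Direct annotations only (no ancestor propagation — counting annotated
proteins, not ontology closure), NOT-qualified GAF rows excluded, aspect
retained for optional filtering. The p-value is the exact hypergeometric
upper tail via `scipy.stats.hypergeom.sf`, which works in log space and is
stable at genome scale; results are reported for E-ratio ≥ 1, sorted by p,
with raw p-values by default and an optional Benjamini–Hochberg column.

## LLM response classification and evaluation

Texts are normalised before matching: case-folded, whitespace collapsed,
curly apostrophes and quotes straightened (normalisation is idempotent).
Interpretation responses are negative iff any of the 27 disclaimer phrases
occurs as a substring; reasoning responses are positive iff any of the 11
reasoning phrases occurs and the word "no" does not occur as a whole word
(substring matching would fire on "know" or "normal"). Metric conventions:
any zero denominator in Sn/Sp/Ac/Pr/MCC yields 0. Specificity against an
unreported-gene universe is estimated by 20 rounds of sampling a negative
set the size of the positive benchmark (1:1), without replacement, seeded;
under this balanced design per-round accuracy is identically
(Sn + Sp) / 2. Isoform-level calls reduce to gene level as "positive if
any isoform is positive".

## Signal web

Nodes carry exactly one of seven functional categories. Positive reasoned
pairs become one edge each: a directed regulation (optionally signed) when
the direction of information flow is a curated table column, an undirected
association otherwise. Direction and sign are never parsed from the
free-text answers — extracting them automatically would require an NLP
method with its own validation burden, so they remain curation inputs. PPI
overlays come from PSI-MI TAB 2.5 records (symbols from the alias/alt-id
columns, self-loops dropped, duplicates and reversals collapsed, malformed
rows skipped with counted warnings). Serialisation is node/edge TSV plus
GraphML; edge ordering is sorted, so rebuilding from the same inputs is
bit-identical.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on seconds-to-minutes of simulated data, with
daily metrics exercised at reduced frame rates (0.5–1 fps) so a 24 h
window is tens of thousands of frames; the sleep rule scales with fps by
construction. The tracking benchmark uses 6 seeds × group sizes 1–5 ×
120 rendered frames (10,800 object-frames, ≈ 17 s of video per well at
7.2 fps), chosen as the smallest protocol that exercises every merge/split
and crossing mode while keeping a full run in the low minutes on one CPU.
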