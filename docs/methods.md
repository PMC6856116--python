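# Methods

This note documents the models, rules and numerical choices behind
`colonytrack`, and what the synthetic benchmark does and does not show.

## Imaging model and detection

Phase-contrast images of adherent fibroblast-like cells show two coupled
cues: a bright halation rim along the cell edge and an interior darker
than the surrounding background, on top of a slowly varying illumination
gradient.

**Background correction.** The illumination field is estimated by
grayscale morphological opening followed by closing with a disc of radius
`kernel_radius_px` (default 25 px = 100 µm at 4 µm/px; it must exceed the
largest cell radius). The opening removes bright rims, the closing removes
dark interiors, and what survives is the smooth background, which is
subtracted and re-centred on its mean. Opening alone would keep the dark
cell bodies inside the estimate and cancel them on subtraction, which is
why the closing step is part of the estimator. Frames are padded by odd
reflection so local gradients continue across the border and the outermost
band is estimated without bias. A flat frame is a fixed point of the
operator, and a pure linear ramp is flattened to < 1 % of its amplitude.

**Shape restoration.** The response map is the sum of (a) darkness below
the median background level, Gaussian-smoothed at `interior_sigma_px`
(2 px), and (b) regions enclosed by rim pixels — pixels brighter than
median + 4·σ̂ (σ̂ from the median absolute deviation) — hole-filled,
smoothed at `halo_sigma_px` (1.5 px) and weighted by 20 gray levels.
The response is then zeroed on the rim pixels themselves. Because halation
follows every cell edge, the rim network partitions a dense colony into
per-cell regions, which keeps touching cells from fusing into one
thresholded component. An inverted-contrast blob (bright centre, dark rim)
produces almost no response, so the detector is specific to the
phase-contrast appearance of cells.

**Binarization.** The default threshold is a fixed absolute floor of
5 gray levels (`min_response`). The response is sparse and its positive
values form a one-sided continuum of Gaussian skirts around cell bodies;
a histogram-split criterion such as Otsu places its threshold in the
middle of that continuum and truncates small or faint cells (observed as
a 4–8 % per-frame recall loss), whereas the noise floor after smoothing
is far below 5. Otsu (computed on the positive support, with the same
absolute floor so a cell-free frame yields no objects) remains available
as `threshold_method: otsu`. Components are 8-connected; `min_area_px`
defaults to 10 px (160 µm²) — deliberately below a whole-cell body area
(~50 px) because the thresholded body excludes the halo ring and, in
dense colonies, neighbouring halos can slice a body further.

## Temporal persistence and debris rejection

Primary cultures contain debris as large as the cells, so size cannot
separate them; position stability over time can. Detections are linked
frame-to-frame by greedy nearest-neighbour assignment with a 10-px gate
(40 µm per 6-h step), ties broken by distance and then reading order.
A track is labelled a **living cell** iff it contains ≥ `min_frames` = 3
consecutive observations with every step ≤ `max_step_px` = 10 px;
otherwise it is noise. "Three frames" (18 h) and "10 px" quantify *in the
same position over several frames* for this pixel scale and frame
interval; both are configuration parameters.

Counting is per frame, not per track: every observation of a living track
counts as one cell in its frame (classification sees the whole sequence,
so a newborn cell's early observations count once its track proves
persistent). Two consequences are documented behaviour:

* Cells first appearing in the final two frames cannot accumulate three
  observations and are not yet counted — the final-day count of a
  fast-growing colony lags truth by the births of the last ~12 h.
* Greedy (not globally optimal) assignment is adequate at
  colony-assay sparsity; it is not designed for confluent fields.

## Colony rules

All geometry is in micrometres (px × `pixel_size_um`, default 4.0).

* **Grouping.** Living cells of a frame are partitioned by single linkage
  at `merge_distance_um` = 100 µm (strict `<`), so distinct groups are
  ≥ 100 µm apart by construction.
* **Confirmation.** A colony is confirmed when ≥ `min_cells` = 4 of its
  members fit inside a circle of diameter `colony_diameter_um` = 320 µm.
  The decision "some 4-subset has minimum enclosing circle ≤ 320 µm" is
  equivalent to "a circle of radius 160 µm covers ≥ 4 points" and is
  solved exactly: candidate centres are every point and the two centres
  determined by every point pair closer than one diameter (an O(n³)
  search), preceded by a sufficient quick test (a member with ≥ 4
  neighbours within 160 µm). The rule is a confirmation threshold only:
  a confirmed colony keeps all of its single-linkage members as it grows
  past 320 µm.
* **Identity.** A colony keeps its id while ≥ 1 member of a current group
  lies within `link_distance_um` = 40 µm (the tracking gate) of one of its
  previous members; a colony may own several groups in a frame, so a
  transient chain break (one member missed in one frame) does not spawn a
  new identity. A group overlapping several colonies — two colonies have
  approached within the linkage cutoff — is divided among the claimants by
  nearest previous membership.
* **Merging.** For every frame and every pair of colonies *confirmed by
  that frame*, the minimum cross-pair cell distance is computed; if it is
  strictly below 100 µm both are flagged merged from that frame onward (no
  un-merging) and excluded from growth-curve output, because clonality is
  lost. Restricting the test to confirmed colonies means a stray
  unconfirmed single-cell lineage brushing a colony does not void it; a
  colony that never violates the rule is non-merged.
* **Daily counts.** The reference frame of day *d* is the last frame at or
  before 24·*d* hours (frame 4·*d* at 6-h intervals) — one frame per day,
  not an aggregate. Counts before confirmation are reported from day 1
  (the founding lineage is tracked from its first appearance); a colony
  with no observation at a reference frame carries its last known count
  with a warning.

## Morphometrics

* **Long axis**: from the central second moments of a cell's pixel set
  with the 1/12 pixel-extent correction (each pixel is a unit square);
  long axis = 4·√λ_max · pixel size. A single pixel therefore measures
  4·√(1/12) ≈ 1.155 px, and a rasterized disc of radius r measures 2r
  (within rasterization error, < 2 % for r ≥ 10 px).
* **Inter-cell distance**: mean length of the unique edges of the Delaunay
  triangulation of the colony's cell centres of gravity; for 2 points or a
  collinear set (where no triangulation exists) the mean of consecutive
  distances along the line is used. Exactly cocircular 4-point sets have
  two valid triangulations; the library's tie-break decides, affecting
  only the diagonal choice, and test fixtures avoid exact cocircularity.
* Records are computed at the final day's reference frame (falling back to
  the colony's last observed frame), where end-of-culture colonies are
  compared.

## Growth-curve analysis

Counts span orders of magnitude by day 14, so curves are square-root
transformed before clustering (a variance-damping transform for
count-like data). Clustering is agglomerative with **complete linkage**
(furthest-neighbour) on Euclidean distances between the transformed
14-day vectors — Euclidean being the conventional default metric for this
method — and the dendrogram is cut into `k_groups` = 7 groups (two large,
four medium, one small is the typical structure of a 14-day MSC colony
assay; the cut criterion is a free parameter, so *k* is configurable).
Labels are canonicalised by descending group mean of the final-day count,
making group 1 "largest" in every run.

Prediction and validation use ordinary least squares on **raw counts**
(no log transform): `r2_by_day[d]` is the squared Pearson correlation of
day-14 counts with day-*d* counts across colonies, so day 14 gives exactly
1 and a zero-variance predictor day is reported missing with a warning.
`validate_counts` applies the same raw-scale R² to paired detected/
reference counts and adds the mean relative error.

## Synthetic data generator

The generator emulates a 14-day colony-forming assay imaged every 6 h
(57 frames including t = 0) at 4 µm/px on 1024² frames:

* **Division model.** Each colony is a pure-birth (Yule) process: after an
  exponential per-colony lag, every cell divides independently with
  exponential waiting times of archetype-specific mean — 64 h (large),
  96 h (medium), 168 h (small), i.e. population doublings of roughly
  1.8–4.9 days, realistic for primary synovial MSCs; lags 12/24/48 h;
  archetype mix 0.2/0.5/0.3. A deterministic mode (synchronous division
  every τ) exists for exact doubling fixtures.
* **Geometry.** Founders are placed with ≥ 200 px spacing and a 100-px
  edge margin; daughters settle ~1.8 cell diameters from their mother at
  the least crowded of 12 candidate angles, with the distance factor
  clipped to [0.75, 1.2] and a hard-core separation of 0.65× spacing
  (crowded daughters step outward) — cells are contact-inhibited physical
  objects and colonies stay contiguous monolayers. Cell sizes are
  lognormal around a 40-µm long axis with aspect ratio 0.45–0.7.
* **Rendering.** All interiors are drawn first (local background − 30 gray
  levels), then every cell's ~2-px halo ring on top (+40), so halation
  follows each cell edge even where cells touch; a static smooth
  background gradient (30 gray levels peak-to-peak) and Gaussian pixel
  noise (σ = 2) are added before clipping to uint8.
* **Debris.** Blobs with the same size distribution and contrast as cells
  whose positions are resampled independently every frame (≥ 20 px jump
  enforced) — rejectable only by temporal persistence, not by size.

What the generator does **not** emulate: cell migration and death,
mitotic rounding, focus drift, stage-stitching seams, intensity flicker,
out-of-focus debris, and genuinely overlapping (stacked) cells. Passing
the synthetic benchmark therefore demonstrates the correctness and
internal consistency of the pipeline under the stated imaging model, not
performance on any particular microscope's data.

## Benchmark problem sizes

The end-to-end benchmark uses the generator defaults (20 colonies,
57 rendered 1024² frames, 10 debris blobs); the prediction cohort uses
140 colonies at the same mix. On these conditions the pipeline reaches
per-frame detection precision/recall ≈ 1.0 at an 8-px match radius,
rejects all teleporting debris, reproduces ≥ 90 % of colony-by-day counts
exactly (the residual mismatches are the final-day persistence lag
described above), and the day-7 prediction R² exceeds 0.7 — the values
are recomputed, not stored, by `scripts/acceptance.py`.

## Known limitations

* Persistence classification needs three frames, so counts on the final
  day systematically exclude cells born in the last two frames.
* Greedy linking and single-linkage grouping assume low seeding density;
  neither is designed for confluent cultures.
* The fixed default threshold (5 gray levels) presumes roughly uint8-scale
  contrast after background correction; adjust `fixed_threshold` /
  `min_response` (or switch to Otsu) for other acquisition scales.
* Colonies that transiently split across the 100-µm linkage radius for
  several consecutive frames can still fragment identities; the
  single-frame case is handled.
* Exactly cocircular cell configurations make the Delaunay edge set
  ambiguous (diagonal choice only).
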