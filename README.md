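# colonytrack

Colony-level growth analysis of time-lapse phase-contrast microscopy for
low-density cultures of fibroblast-like cells (e.g. primary synovial
mesenchymal stromal cells in a colony-forming assay).

Clinical-scale MSC expansion needs early, non-invasive estimates of final
cell yield. At ~20 cells/cm², each seeded cell grows into a discrete
colony whose cell number can be followed in phase-contrast time-lapse
images — but phase-contrast cultures contain debris as large as the cells,
so objects cannot be classified by size alone. `colonytrack` implements the
full analysis chain:

1. **Detection** — the background brightness gradient is flattened with a
   morphological (opening∘closing) estimate; cell bodies are restored from
   the two phase-contrast cues (dark interior + bright halation rim) into a
   response map that is thresholded and decomposed into 8-connected objects.
2. **Debris rejection by temporal persistence** — objects are linked across
   frames by gated greedy nearest-neighbour matching; a track is a *living
   cell* only if it holds the same position (steps ≤ 10 px = 40 µm) for at
   least 3 consecutive 6-h frames. Everything else — in particular debris
   that moves between frames — is image noise.
3. **Colony model** — living cells are grouped per frame by single linkage
   at 100 µm; a group is a *confirmed colony* once ≥ 4 cells fit inside a
   circle of diameter 320 µm (80 px at 4 µm/px). Identity is tracked over
   time; if the closest cells of two confirmed colonies come within
   100 µm, both are flagged *merged* and excluded from growth analysis
   (clonality lost).
4. **Growth curves & morphometrics** — per-colony cell counts at the last
   frame of each culture day build a colony × day matrix; colony shape is
   summarised by the mean cell long axis (major axis of the
   equal-second-moments ellipse, with the 1/12 pixel-extent correction) and
   the mean Delaunay inter-cell distance of the cell centres of gravity.
5. **Classification & prediction** — growth curves are square-root
   transformed and clustered by complete linkage (furthest-neighbour
   method, Euclidean metric), cut into *k* groups (default 7: large-1/2,
   medium-1..4, small); predictability of the day-14 count is the per-day
   OLS R² of day-14 counts on day-*d* counts (raw scale).

A first-class synthetic generator (`colonytrack.simulate`) produces
ground-truthed image sequences — cells with dark interiors and bright halo
rims on a smooth brightness gradient, colonies growing by a pure-birth
division process with archetype-specific rates, and teleporting debris —
so every stage is testable without microscope data.

## Worked example

```python
import colonytrack as ct

# simulate a 14-day, 20-colony assay and render it (57 frames, 1024x1024)
sim = ct.SimulationConfig(n_colonies=20, seed=1)
truth = ct.simulate_ground_truth(sim)
seq = ct.render_sequence(truth, sim)

# run the full pipeline
results = ct.run_pipeline(seq, ct.PipelineConfig(seed=1))
print(results.growth_curves.iloc[:3, [0, 5, 10, 13]])
print({d: round(r, 3) for d, r in results.growth.r2_by_day.items() if d in (4, 7, 14)})
```

prints:

```
           day_1  day_6  day_11  day_14
colony_id
0              2      4      16      32
1              2      5      15      25
2              1      1       4      12
{4: 0.291, 7: 0.36, 14: 1.0}
```

i.e. the first three confirmed, non-merged colonies grew to 12–32 cells by
day 14 (day 14 regressed on itself gives R² = 1 by construction). With only
14 analysable colonies in a single rendered well the day-7 R² is noisy;
on a 140-colony simulated cohort
(`colonytrack.benchmark.prediction_study(140, seed=1)`) the day-wise R²
rises with culture time and reaches 0.91 at day 7 — the distribution of
colony sizes a week into culture already anticipates the final yield.

The same analyses are available from the shell:

```sh
colonytrack simulate --n-colonies 20 --seed 1 --out sim/
colonytrack analyze sim/sequence.tif --out results/ --k-groups 7
colonytrack cluster results/growth_curves.csv --k-groups 7
colonytrack validate results/growth_curves.csv sim/true_growth_curves.csv
```

`analyze` writes CSV tables (per-frame objects, labelled tracks, colonies,
growth-curve matrix, cluster labels, morphometrics, per-day R²), a JSON run
manifest, and optional per-frame PNG overlays with persistent colony
colours.

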