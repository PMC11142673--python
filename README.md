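# corridorscape

Least-cost **climate-adaptation corridor** modeling for regional
conservation planning: linking lowland protected areas to intact highland
forest — candidate climate-change refugia — across an elevational
gradient, and ranking the resulting corridors with a PCA-based priority
index.

## Who this is for

Landscape ecologists and conservation planners who need a tested,
reproducible implementation of the standard regional corridor workflow:

1. **Start nodes** — clean a protected-area polygon table (drop duplicated
   geometries, "proposed" records, UNESCO-MAB biosphere reserves, records
   with unreported area; keep the land portion of marine reserves), then
   select lowland reserves (mean elevation ≤ 500 m, area ≥ 5 km²), each
   represented by one interior point.
2. **End nodes** — contiguous (8-connected) montane forest patches:
   forest-class cells passing a forest-integrity cutoff, polygonized, kept
   when ≥ 5 km² with mean elevation ≥ 1500 m, protected or not. Patches
   get extra end points on a hexagonal lattice so paths need not travel
   deep into large patches.
3. **Conductance surface** — land-cover classes map to conductance
   (inverse resistance) through a lookup table; the forest class is
   modified by standing biomass, `m = min(b, 100)/100` (Mt C), penalizing
   degraded stands. No topographic or climate-dissimilarity adjustment.
4. **Least-cost paths** — the raster becomes a lattice graph (8-connected;
   step cost = distance / mean cell conductance; zero-conductance cells
   are hard barriers). Each start node is routed to its **k = 5 nearest
   end points** (Euclidean), one Dijkstra tree per start.
5. **Corridor metrics** — each polyline is buffered by 1000 m (a 2 km
   swath, the rule-of-thumb minimum corridor width for long-term gene
   flow); length, elevation range, percent protection (union-first, no
   double counting), counts of overlapping non-marine protected areas and
   KBAs, mean biomass, and countries crossed.
6. **Priority index** — corridor, start-node, and end-patch variables
   (corridor length inverted so short corridors score favorably) are
   screened for collinearity (|Spearman ρ| ≥ 0.7), standardized, and fed
   to a PCA. The index of corridor *i* is its distance from the origin in
   the space of the first three components,
   `index_i = sqrt(s_i1² + s_i2² + s_i3²)`, classed **low** (< 2),
   **medium** (2–4), **high** (> 4).
7. **Group statistics** — Kruskal–Wallis across the three classes, with
   Dunn's pairwise tests under Holm adjustment when the omnibus test is
   significant, plus Spearman correlations among corridor variables.

A seeded **synthetic-landscape generator** (elevation gradient, fragmented
forest/agriculture mosaic, biomass and integrity layers, reserve/KBA/
country polygon tables with deliberately pathological records) makes the
whole pipeline runnable and testable with no external data. Rasters are
read and written as Esri ASCII grids, vector layers as GeoJSON; all
coordinates are planar metric (real inputs must arrive in an equal-area
projection — the pipeline never reprojects).

## Worked example

```sh
cat > demo.yaml <<EOF
landscape:
  grid_rows: 300
  grid_cols: 300
  n_reserves: 40
  n_kbas: 12
  seed: 1
seed: 1
EOF
corridorscape run --config demo.yaml --out demo_out
```

prints

```
21 start nodes x k=5 -> 105 corridors (0 unreachable); classes {'low': 47, 'medium': 54, 'high': 4}; outputs in demo_out
```

Of the 40 synthetic reserves, 36 survive cleaning and 21 qualify as
lowland start nodes; the 30 km × 30 km world holds 4 montane forest
patches carrying 9 end points, so each start is routed to its
min(5, 9) = 5 nearest end points — 105 corridors, none unreachable. The
first three principal components explain 62.5 % of the feature variance
(`variance_explained_3pc` in `demo_out/manifest.json`), and the corridor
classes split 47/54/4 across low/medium/high. Per-corridor scores live in
`demo_out/priority.csv`:

```
corridor_id,pc1,pc2,pc3,index,priority_class
0,-0.8122963586,-1.517216455,-1.633904573,2.373060323,medium
1,-2.260615492,0.3660903944,-1.188096393,2.579918142,medium
```

`demo_out/manifest.json` records the full configuration, seed, and
per-stage counts; re-running with the same config reproduces every output
byte for byte.

The same stages are available individually (`corridorscape simulate`,
`nodes`, `conductance`, `prioritize`, `stats`) and as library functions
(`corridorscape.run_pipeline`, `clean_reserves`, `extract_end_patches`,
`build_conductance`, `batch_corridors`, `prioritize`, ...).

## Limitations

Synthetic landscapes emulate the *structure* of real inputs, not any real
region; the shipped conductance lookup is illustrative, not a
species-calibrated table. See `docs/methods.md` for the model's
assumptions, parameter defaults, and known caveats (including the
direction-blindness of a distance-from-origin index).
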