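# plotgrid

Georeferenced plot polygons for serpentine field trials.

Plant breeders and agronomists who extract per-plot data from UAV imagery
need a polygon layer — one rectangle per experimental plot — to intersect
with each orthomosaic. Drawing those rectangles by hand in a GIS is slow and
error-prone. `plotgrid` generates the layer directly from the trial's
description: it lays plots out in a serpentine (boustrophedon) pattern from
the bottom-left of the field, numbers them the way breeders do, removes
non-experimental *fill* plots and irrigation *wheel-track* ranges, shrinks
each rectangle by per-side buffers to capture only the canopy, joins
field-book attributes by plot number, and writes an ESRI Shapefile or
GeoJSON in a projected CRS.

## The layout model

The experiment extent is a fishnet of `rows x ranges` cells (rows across,
ranges deep; front range at the bottom). Plots fill cells along a serpentine
walk that reverses direction on each range. Replicated designs are numbered

```
plot = rep * 10^d + i,   d = max(2, digits(plots_per_rep)),  i = 1..plots_per_rep
```

so a 3-replicate, 20-plot trial is numbered 101–120, 201–220, 301–320 and a
200-plot trial 1001–1200, 2001–2200, 3001–3200. Unreplicated designs number
sequentially from a start to an end plot, optionally *indented* past cells a
preceding experiment occupies. Each plot's region of interest is its cell
with the total length and width reduced by twice the respective buffer:

```
final_length = plot_length - 2 * length_buffer
final_width  = plot_width  - 2 * width_buffer
```

A replicated spec must balance exactly:
`reps*plots_per_rep + fills + rows*wheel_track_ranges == rows*ranges`.

## Worked example

A replicated yield trial: 3 replicates of 30 plots on a 4 x 26 grid, two
fills after each replicate, wheel tracks in ranges 9 and 18, 20 x 10 ft
plots trimmed by 5 and 2.5 ft per side (`examples/replicated_yield_trial.py`):

```python
from plotgrid import (Placement, build_feature_table, build_matrix,
                      join_attributes, write_layer)
from plotgrid.examples import yield_trial

case = yield_trial()
matrix = build_matrix(case.spec)
table = build_feature_table(matrix, case.dims,
                            Placement(origin_x=277000, origin_y=3782000,
                                      crs="EPSG:32616"))
table = join_attributes(table, case.book)
write_layer(table, "yield_trial.shp", "shapefile")
```

prints, via the example script:

```
Specified plots: 104  (= 3 reps x 30 plots + 6 fills + 8 wheel-track cells)
Total possible plots: 104  (= 4 rows x 26 ranges)
Final plot size: 10 x 5 ft (length x width)
Wrote 90 plot polygons (fills and wheel tracks removed) to yield_trial.shp + 3 sidecar files
First feature: 101 {'name': 'LINE-1951-0001', 'pedigree': 'CHEROKEE x DILLON'}
```

104 grid cells balance exactly; the 6 fills and 8 wheel-track cells are
dropped, leaving 90 polygons of 10 x 5 ft, each carrying `plot`, `rep` and
the field-book's `name` and `pedigree`. The other scripts in `examples/`
cover unreplicated nurseries (indent, right-to-left start, an exactly filled
extent, one field book shared across two layers) and validation plus the
ASCII map preview.

The same run from the shell:

```
plotgrid replicated --name "Yield Test 1" --plots-per-rep 30 --reps 3 \
  --rows 4 --ranges 26 --fills 2,2,2 --wheel-tracks 9,18 \
  --plot-length 20 --plot-width 10 --length-buffer 5 --width-buffer 2.5 \
  --units english --crs EPSG:32616 \
  --fieldbook book.csv --plot-column plot --output yield_trial.shp
```

`--preview` prints the text field map instead of writing a file; `--config`
takes a flat YAML file with the same keys as the flags.

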