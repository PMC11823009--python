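"""Replicated yield trial, end to end: layout -> polygons -> field book -> shapefile.

Three replicates of 30 plots each on a 4 x 26 grid, two fill plots after
every replicate, irrigation wheel tracks in ranges 9 and 18.  Plots are
20 x 10 ft; buffers of 5 and 2.5 ft per side trim each region of interest to
the 10 x 5 ft canopy.  Fills and wheel-track cells never reach the output.
"""

from pathlib import Path

from plotgrid import (
    Placement, build_feature_table, build_matrix, final_dimensions,
    join_attributes, write_layer,
)
from plotgrid.examples import yield_trial

case = yield_trial()
print(f"Specified plots: {case.spec.specified_plots}  "
      f"(= {case.spec.reps} reps x {case.spec.plots_per_rep} plots "
      f"+ {sum(case.spec.fills_after_reps)} fills "
      f"+ {case.spec.rows * len(case.spec.wheel_track_ranges)} wheel-track cells)")
print(f"Total possible plots: {case.spec.total_possible_plots}  "
      f"(= {case.spec.rows} rows x {case.spec.ranges} ranges)")

fl, fw = final_dimensions(case.dims)
print(f"Final plot size: {fl:g} x {fw:g} ft (length x width)")

matrix = build_matrix(case.spec)
table = build_feature_table(matrix, case.dims,
                            Placement(origin_x=277000, origin_y=3782000,
                                      crs="EPSG:32616"))
table = join_attributes(table, case.book)
out = Path(__file__).parent / "output" / "yield_trial.shp"
paths = write_layer(table, out, "shapefile")
print(f"Wrote {len(table)} plot polygons "
      f"(fills and wheel tracks removed) to {paths[0].name} "
      f"+ {len(paths) - 1} sidecar files")
print("First feature:", table.features[0].plot, table.features[0].attributes)
# 90 features = 104 grid cells minus 6 fills and 8 wheel-track cells; each
# polygon is a 10 x 5 ft rectangle carrying plot, rep, name and pedigree.
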