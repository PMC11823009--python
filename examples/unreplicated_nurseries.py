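"""Unreplicated plant-row nurseries: sequential numbering, indent, shared book.

Set #1 is 701 single-row plots on a 52 x 14 grid (27 unused cells in the
last range).  Set #2 starts 25 plots into its first range — set #1 ends
mid-range — with numbers increasing right to left, runs 1,067 plots, and
continues as Part 2 with 1,716 plots exactly filling a 52 x 33 grid.  One
field book covers both parts of set #2.
"""

from pathlib import Path

from plotgrid import (
    CellRole, Placement, build_feature_table, build_matrix, join_attributes,
    write_layer,
)
from plotgrid.examples import plant_row_nurseries

out_dir = Path(__file__).parent / "output"
for case in plant_row_nurseries():
    matrix = build_matrix(case.spec)
    table = build_feature_table(matrix, case.dims, Placement(crs="EPSG:32616"))
    table = join_attributes(table, case.book)
    (path,) = write_layer(table, out_dir / f"{case.spec.experiment_name}.geojson",
                          "geojson")
    print(f"{case.spec.experiment_name}: {len(table)} plots "
          f"({case.spec.rows} x {case.spec.ranges} grid, "
          f"indent {case.spec.plot_indent}, "
          f"{matrix.role_count(CellRole.EXCLUDED)} excluded cells) "
          f"-> {path.name}")
# Each line reports how many polygons were written and how much of the grid
# is unused; Part 2's zero excluded cells show an exactly filled extent.
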