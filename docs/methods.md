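# Methods

## Problem and model

UAV high-throughput phenotyping pipelines extract per-plot spectral data from
orthomosaics by intersecting the imagery with a polygon layer of plot
boundaries. `plotgrid` generates that layer from a description of the trial
alone: the experiment extent is a fishnet of `rows x ranges` rectangular
cells (rows step across the x-axis by one plot width; ranges stack up the
y-axis by one plot length, front range at y = 0), and plots are assigned to
cells by a serpentine walk that starts at the bottom-left cell, covers the
front range, and reverses direction on each subsequent range. No manual
corner collection or scaling is involved; the extent follows from plot
counts and dimensions.

Two design types are supported.

**Replicated (balanced).** Each of `reps` replicates holds `plots_per_rep`
experimental plots, numbered `rep * 10^d + i` with
`d = max(2, digits(plots_per_rep))`: a 3-replicate, 20-plot trial is numbered
101–120, 201–220, 301–320; a 200-plot trial 1001–1200, 2001–2200, 3001–3200.
The `d = max(2, ...)` rule extends the two-or-three-digit convention
naturally (1,000-plot replicates get four digits) and guarantees numbers
never collide across replicates. Each replicate may be trailed by *fill*
plots (planted, non-experimental), and whole ranges may be *wheel-track*
ranges sacrificed to lateral-irrigation wheels. The walk passes physically
through wheel-track ranges without consuming a plot, so direction parity is
determined by the physical range index including wheel tracks — the walk
mirrors how a planter actually traverses the field. Fill cells continue
their replicate's numbering internally (131, 132 after 101–130) so every
planted cell has a unique label, but neither fills nor wheel-track cells
produce output polygons. A spec is accepted only when
`reps*plots_per_rep + sum(fills) + rows*|wheel_tracks| == rows*ranges`;
unbalanced replicates are rejected (lay each replicate out as its own
unreplicated run instead).

**Unreplicated.** Plots are numbered sequentially `start_plot..end_plot`. A
*plot indent* skips cells at the start of the first range (a preceding
experiment occupies them, which also means such layouts often start with the
right-to-left direction); trailing cells after the last plot are excluded.
Equality of `indent + plot_count` with `rows*ranges` is permitted — an
exactly filled extent is a legitimate layout — and `ranges` is treated as
capacity: a layout may occupy fewer ranges than declared, with the surplus
cells excluded.

## Geometry

Each plot's region of interest is its cell shrunk by per-side buffers: the
total length/width (which include alleyways and all crop rows) is reduced by
twice the respective buffer, trimming equally on both sides so the rectangle
stays centered in its cell. Buffers that leave a non-positive dimension are
rejected at construction. Dimensions are given in feet (`english`) or meters
(`metric`) and converted to CRS units with the exact international foot,
0.3048 m. Only projected CRSs with meter or foot linear units are accepted —
plots are meter-scale rectangles and degree units would be meaningless —
given as WKT or as an EPSG code from a small built-in table (WGS84/NAD83 UTM
zones, Web Mercator). Placement is an explicit origin (bottom-left corner of
cell (0,0), default (0,0)) plus an optional counter-clockwise rotation about
that origin; aligning the layer to imagery is the user's post-hoc step in
any GIS editor, exactly as in the interactive workflow this replaces.
Row-wise serpentine is not a native mode: rotate the layer 90° afterwards
and swap the length/width inputs.

## Field-book join

A field book is a CSV with a header row and one column containing every plot
number of the layout. Matching is numeric after integer parsing (so "0101"
matches 101, robust to spreadsheet zero-padding). Coverage of all layout
plots is mandatory — a missing plot raises rather than silently writing
nulls — while extra rows for plots outside the layout are ignored with a
warning, which lets one book serve an experiment split across several layers.
The join preserves geometry and feature order and is invariant to book row
order.

## Export

Shapefile is the default output (the `.shp`/`.shx`/`.dbf`/`.prj` set, CRS as
WKT in `.prj`); the writer and round-trip reader are implemented in-package
(polygon shape type 5, dBase III attributes, a fixed header date stamp for
byte stability). Outer rings are written clockwise per the Shapefile
convention even though in-memory rings are counter-clockwise. DBF limits
attribute names to 10 ASCII characters, so names are sanitized
deterministically (truncate to 10; collisions truncate to 8 plus a two-digit
suffix). `plot` and `rep` are integer fields; field-book columns are text
unless every value parses as a number. GeoJSON output is byte-deterministic
(fixed key order, 6-decimal coordinates) and records the projected CRS in a
non-standard `crs` member, since RFC 7946 assumes WGS84. An empty output
path writes to a fresh temporary directory under a name derived from the
experiment name — the scripted analogue of a temporary layer.

## Worked examples as test inputs

`plotgrid.examples` regenerates two realistic layouts deterministically
(seeded line names and pedigrees drawn from a fixed parent list; the books
are synthetic): a replicated yield trial (3 x 30 plots, fills `[2,2,2]`,
wheel tracks in ranges 9 and 18, 4 x 26 footprint, 20 x 10 ft plots trimmed
to 10 x 5 ft) and three plant-row nursery layouts (701 plots in 52 x 14;
1,067 plots with a 25-cell indent starting right-to-left in 52 x 34; 1,716
plots exactly filling 52 x 33, with one shared book for the latter two,
numbered continuously 1–2,783). These emulate the bookkeeping structure of
real trials, not their measurement content: passing tests show the layout,
geometry, join and export logic are correct, not that any particular field's
imagery will align — alignment remains a manual step against the orthomosaic.

## Numerical and testing choices

Geometry assertions use relative tolerance 1e-9 (areas, distances) and 1e-6
CRS units for round-trip coordinates, against shapely's double-precision
predicates. The serpentine order is property-tested against an independent
explicit enumeration for every grid up to 8 x 8, plus hypothesis-driven
mirror/coverage/adjacency properties; count conservation is checked over 200
randomly generated valid specs (fixed seed). Problem sizes follow the worked
examples (at most ~1,700 plots), which exercise every code path at
negligible cost.

## Known limitations

- Balanced replicates only; no randomization or design generation (the
  package lays out, it does not randomize).
- No geographic-CRS output and no reprojection; the built-in EPSG table is
  deliberately small (pass WKT for anything else).
- No GeoPackage/KML writers; no raster handling or imagery alignment.
- Multi-part or non-rectangular plots are out of scope; one rectangle per
  plot.
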