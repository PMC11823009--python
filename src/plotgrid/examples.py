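"""Worked example layouts with synthetic field books.

Two self-contained examples cover the package's scope end to end and double
as regenerable test inputs: a replicated yield trial (fills, wheel tracks,
canopy buffers) and a pair of unreplicated plant-row nurseries (indent,
right-to-left start, an exactly-filled extent, one shared field book).  All
generation is seeded and deterministic.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import pandas as pd

from .fieldbook import FieldBook
from .geometry import PlotDimensions, UnitSystem
from .layout import ReplicatedSpec, UnreplicatedSpec

_PARENTS = [
    "AG5335", "BENNING", "BOGGS", "CHEROKEE", "DILLON", "ELLIS", "G00-3213",
    "HAGOOD", "HUTCHESON", "MUSEN", "OSAGE", "PRICHARD", "ROANOKE", "WOODRUFF",
]


def _synthetic_book(plots: list[int], seed: int) -> FieldBook:
    """Field book with generated line name and pedigree per plot (synthetic)."""
    rng = random.Random(seed)
    names = [f"LINE-{rng.randrange(10**4):04d}-{i:04d}" for i, _ in enumerate(plots, 1)]
    pedigrees = [" x ".join(rng.sample(_PARENTS, 2)) for _ in plots]
    records = pd.DataFrame(
        {"plot": [str(p) for p in plots], "name": names, "pedigree": pedigrees}
    )
    return FieldBook(
        header=["plot", "name", "pedigree"],
        records=records,
        plot_column="plot",
        selected_columns=["name", "pedigree"],
    )


@dataclass
class ExampleCase:
    spec: ReplicatedSpec | UnreplicatedSpec
    dims: PlotDimensions
    book: FieldBook
    expected: dict


def yield_trial(seed: int = 2026) -> ExampleCase:
    """Replicated yield trial: 3 reps x 30 plots on a 4 x 26 footprint.

    Each replicate is trailed by two fill plots, and ranges 9 and 18 from the
    front are irrigation wheel tracks.  Plots are 20 x 10 ft (four 2.5 ft crop
    rows on 20 ft beds); buffers of 5 and 2.5 ft per side trim the region of
    interest to the 10 x 5 ft canopy.
    """
    spec = ReplicatedSpec(
        experiment_name="Yield Test 1",
        plots_per_rep=30,
        reps=3,
        rows=4,
        ranges=26,
        fills_after_reps=(2, 2, 2),
        wheel_track_ranges=(9, 18),
    )
    dims = PlotDimensions(
        plot_length=20.0,
        plot_width=10.0,
        length_buffer=5.0,
        width_buffer=2.5,
        unit_system=UnitSystem.ENGLISH,
    )
    plots = [r * 100 + i for r in (1, 2, 3) for i in range(1, 31)]
    return ExampleCase(
        spec=spec,
        dims=dims,
        book=_synthetic_book(plots, seed),
        expected={
            "features": 90,
            "fill_cells": 6,
            "wheel_track_cells": 8,
            "footprint": (4, 26),
            "final_size_ft": (10.0, 5.0),
        },
    )


def plant_row_nurseries(seed: int = 2026) -> tuple[ExampleCase, ExampleCase, ExampleCase]:
    """Unreplicated plant-row nurseries: set #1 and the two parts of set #2.

    Single-row plots spaced 2.5 ft apart on 12 ft beds, no buffers.  Set #1 is
    701 plots on a 52 x 14 extent.  Set #2 starts 25 plots into its first
    range (set #1 ends mid-range) with plot numbers increasing right to left,
    runs 1,067 plots over a 52 x 34 extent, then — around a washed-out area —
    continues as Part 2 with 1,716 plots exactly filling 52 x 33.  Parts 1 and
    2 are numbered continuously (1-1,067 then 1,068-2,783) and share one
    field book.
    """
    dims = PlotDimensions(
        plot_length=12.0, plot_width=2.5, unit_system=UnitSystem.ENGLISH
    )
    set1 = UnreplicatedSpec(
        experiment_name="Plant Rows set 1",
        start_plot=1, end_plot=701, rows=52, ranges=14,
    )
    part1 = UnreplicatedSpec(
        experiment_name="Plant Rows set 2 part 1",
        start_plot=1, end_plot=1067, rows=52, ranges=34,
        plot_indent=25, right_to_left=True,
    )
    part2 = UnreplicatedSpec(
        experiment_name="Plant Rows set 2 part 2",
        start_plot=1068, end_plot=2783, rows=52, ranges=33,
    )
    book1 = _synthetic_book(list(range(1, 702)), seed)
    book2 = _synthetic_book(list(range(1, 2784)), seed + 1)  # shared by both parts
    return (
        ExampleCase(set1, dims, book1,
                    {"features": 701, "excluded_cells": 52 * 14 - 701}),
        ExampleCase(part1, dims, book2,
                    {"features": 1067, "indent_cells": 25,
                     "excluded_cells": 52 * 34 - 25 - 1067}),
        ExampleCase(part2, dims, book2,
                    {"features": 1716, "excluded_cells": 0}),
    )
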