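"""Plot rectangles: buffered cell polygons positioned in a projected CRS.

Axis convention: *rows* step across the x-axis (one plot width per step) and
*ranges* stack up the y-axis (one plot length per step); the front of the
experiment is at y = 0 and cell (0, 0) has its corner at the placement
origin.  Each plot's region of interest is its cell shrunk by the buffers —
the same trim on both sides of an axis, so the total dimension shrinks by
twice its buffer — then optionally rotated about the origin.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from shapely import affinity
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient

from .crs import CRS, parse_crs
from .layout import CellRole, FieldMatrix

_FOOT = 0.3048


class DimensionError(ValueError):
    """Raised when buffers leave a plot with a non-positive dimension."""


class UnitSystem(enum.Enum):
    ENGLISH = "english"  # feet
    METRIC = "metric"  # meters

    @property
    def to_meters(self) -> float:
        return _FOOT if self is UnitSystem.ENGLISH else 1.0


@dataclass(frozen=True)
class PlotDimensions:
    """Total plot dimensions and the per-side buffers that trim them.

    ``plot_length`` is the along-range depth of a cell (bed length including
    alleyways); ``plot_width`` spans all crop rows of the plot.  Units are
    feet for ``english``, meters for ``metric``.
    """

    plot_length: float
    plot_width: float
    length_buffer: float = 0.0
    width_buffer: float = 0.0
    unit_system: UnitSystem = UnitSystem.ENGLISH

    def __post_init__(self) -> None:
        if isinstance(self.unit_system, str):
            object.__setattr__(self, "unit_system", UnitSystem(self.unit_system.lower()))
        if self.plot_length <= 0 or self.plot_width <= 0:
            raise DimensionError("plot length and width must be positive")
        if self.length_buffer < 0 or self.width_buffer < 0:
            raise DimensionError("buffers must be non-negative")
        final_dimensions(self)  # fails fast on over-large buffers


@dataclass(frozen=True)
class Placement:
    """Where the grid sits: origin of cell (0,0), rotation, and the CRS."""

    origin_x: float = 0.0
    origin_y: float = 0.0
    rotation_deg: float = 0.0
    crs: str = "EPSG:32616"

    def __post_init__(self) -> None:
        if not math.isfinite(self.rotation_deg):
            raise ValueError("rotation must be finite")

    @property
    def crs_info(self) -> CRS:
        return parse_crs(self.crs)


@dataclass
class PlotFeature:
    """One output polygon with its plot number and attributes."""

    plot: int
    geometry: Polygon
    rep: int | None = None
    attributes: dict[str, object] = field(default_factory=dict)


@dataclass
class PlotFeatureTable:
    """Ordered plot polygons plus their CRS, ready for export."""

    features: list[PlotFeature]
    crs: str
    experiment_name: str = ""

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def attribute_names(self) -> list[str]:
        names: list[str] = []
        for f in self.features:
            for k in f.attributes:
                if k not in names:
                    names.append(k)
        return names

    @property
    def has_rep(self) -> bool:
        return any(f.rep is not None for f in self.features)


def final_dimensions(dims: PlotDimensions) -> tuple[float, float]:
    """Plot size after trimming: each total dimension loses twice its buffer."""
    final_length = dims.plot_length - 2 * dims.length_buffer
    final_width = dims.plot_width - 2 * dims.width_buffer
    if final_length <= 0:
        raise DimensionError(
            f"length buffer {dims.length_buffer} leaves non-positive plot "
            f"length ({final_length})"
        )
    if final_width <= 0:
        raise DimensionError(
            f"width buffer {dims.width_buffer} leaves non-positive plot "
            f"width ({final_width})"
        )
    return final_length, final_width


def convert_units(value: float, unit_system: UnitSystem, crs_linear_unit: str) -> float:
    """Convert a dimension to CRS units (exact 0.3048 m/ft when systems differ)."""
    if isinstance(unit_system, str):
        unit_system = UnitSystem(unit_system.lower())
    if crs_linear_unit not in ("meter", "foot"):
        raise ValueError(f"unsupported CRS linear unit {crs_linear_unit!r}")
    crs_to_m = _FOOT if crs_linear_unit == "foot" else 1.0
    return value * unit_system.to_meters / crs_to_m


def cell_polygon(
    row_index: int,
    range_index: int,
    dims: PlotDimensions,
    placement: Placement,
) -> Polygon:
    """Buffered rectangle of one grid cell as a closed counter-clockwise ring.

    Before rotation the rectangle is centered in its cell: the cell spans one
    plot width in x and one plot length in y (converted to CRS units), and the
    buffers trim both sides equally.  ``rotation_deg`` then rotates the ring
    counter-clockwise about the placement origin.
    """
    if row_index < 0 or range_index < 0:
        raise ValueError("cell indices must be non-negative")
    unit = placement.crs_info.linear_unit
    w = convert_units(dims.plot_width, dims.unit_system, unit)
    length = convert_units(dims.plot_length, dims.unit_system, unit)
    wb = convert_units(dims.width_buffer, dims.unit_system, unit)
    lb = convert_units(dims.length_buffer, dims.unit_system, unit)
    final_dimensions(dims)
    x0 = placement.origin_x + row_index * w + wb
    x1 = placement.origin_x + (row_index + 1) * w - wb
    y0 = placement.origin_y + range_index * length + lb
    y1 = placement.origin_y + (range_index + 1) * length - lb
    ring = orient(Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)]), sign=1.0)
    if placement.rotation_deg:
        ring = affinity.rotate(
            ring,
            placement.rotation_deg,
            origin=(placement.origin_x, placement.origin_y),
        )
    return ring


def build_feature_table(
    matrix: FieldMatrix, dims: PlotDimensions, placement: Placement
) -> PlotFeatureTable:
    """One polygon feature per experimental cell, in serpentine plot order.

    Fill, wheel-track and excluded cells yield no feature — they are removed
    from the output layer exactly as they are removed in the field workflow.
    Replicated layouts carry a ``rep`` attribute alongside ``plot``.
    """
    features = [
        PlotFeature(
            plot=cell.plot_number,  # type: ignore[arg-type]
            rep=cell.rep_number if matrix.replicated else None,
            geometry=cell_polygon(r, g, dims, placement),
        )
        for (r, g), cell in matrix.experimental_cells()
    ]
    return PlotFeatureTable(
        features=features,
        crs=placement.crs,
        experiment_name=matrix.experiment_name,
    )
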