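"""Serpentine field-trial layouts: cell matrices, plot numbering, validation.

A field trial is laid out on a rectangular grid of *rows* x *ranges* cells.
Plots are numbered in a serpentine (boustrophedon) walk that starts at the
bottom-left cell of the front range and alternates direction on successive
ranges.  Replicated designs prefix each plot number with its replicate number;
unreplicated designs number sequentially between a start and an end plot.

Cells that hold no experimental plot are still part of the physical grid:
*fill* plots pad out the tail of each replicate, whole *wheel-track* ranges are
sacrificed to lateral-irrigation wheels, and an unreplicated layout may skip
leading (*indent*) or trailing cells entirely.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator


class LayoutError(ValueError):
    """Raised when a layout specification cannot produce a valid matrix."""


class CellRole(enum.Enum):
    """What a grid cell holds.

    EXPERIMENTAL cells become output polygons; FILL and WHEEL_TRACK cells are
    planted but removed from the output; EXCLUDED cells (indent or trailing
    slack in unreplicated layouts) are not part of the experiment at all.
    """

    EXPERIMENTAL = "experimental"
    FILL = "fill"
    WHEEL_TRACK = "wheel_track"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class Cell:
    role: CellRole
    plot_number: int | None = None
    rep_number: int | None = None


@dataclass(frozen=True)
class ReplicatedSpec:
    """Inputs of a balanced replicated serpentine design.

    ``rows`` is the number of plots across each range; ``ranges`` counts every
    physical range including skipped wheel-track ranges.  ``fills_after_reps``
    gives the number of fill plots trailing each replicate (one entry per
    replicate, zeros allowed).  ``wheel_track_ranges`` holds 1-based range
    numbers counted from the front of the experiment.
    """

    plots_per_rep: int
    reps: int
    rows: int
    ranges: int
    fills_after_reps: tuple[int, ...] = ()
    wheel_track_ranges: tuple[int, ...] = ()
    right_to_left: bool = False
    experiment_name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "fills_after_reps", tuple(self.fills_after_reps))
        object.__setattr__(self, "wheel_track_ranges", tuple(self.wheel_track_ranges))

    @property
    def specified_plots(self) -> int:
        """Experimental + fill + wheel-track plots implied by the inputs."""
        return (
            self.reps * self.plots_per_rep
            + sum(self.fills_after_reps)
            + self.rows * len(self.wheel_track_ranges)
        )

    @property
    def total_possible_plots(self) -> int:
        return self.rows * self.ranges


@dataclass(frozen=True)
class UnreplicatedSpec:
    """Inputs of a sequentially numbered unreplicated layout.

    Plots are numbered ``start_plot .. end_plot`` inclusive.  ``plot_indent``
    skips that many cells at the start of the first range (a preceding
    experiment occupies them); any cells left over after the last plot are
    likewise excluded.
    """

    start_plot: int
    end_plot: int
    rows: int
    ranges: int
    plot_indent: int = 0
    right_to_left: bool = False
    experiment_name: str = ""

    @property
    def plot_count(self) -> int:
        return self.end_plot - self.start_plot + 1


@dataclass
class FieldMatrix:
    """The rows x ranges grid of cells, each with a role and optional number."""

    rows: int
    ranges: int
    cells: dict[tuple[int, int], Cell] = field(default_factory=dict)
    right_to_left: bool = False
    experiment_name: str = ""
    replicated: bool = False

    def __getitem__(self, key: tuple[int, int]) -> Cell:
        return self.cells[key]

    def role_count(self, role: CellRole) -> int:
        return sum(1 for c in self.cells.values() if c.role is role)

    def experimental_cells(self) -> Iterator[tuple[tuple[int, int], Cell]]:
        """Yield ((row, range), cell) for experimental cells, serpentine order."""
        for rc in serpentine_cell_sequence(self.rows, self.ranges, self.right_to_left):
            cell = self.cells[rc]
            if cell.role is CellRole.EXPERIMENTAL:
                yield rc, cell

    def plot_numbers(self) -> list[int]:
        return [c.plot_number for _, c in self.experimental_cells()]  # type: ignore[misc]


def serpentine_cell_sequence(
    rows: int, ranges: int, right_to_left: bool = False
) -> list[tuple[int, int]]:
    """Order cells the way plots are numbered in the field.

    Returns ``rows * ranges`` distinct ``(row_index, range_index)`` pairs
    (0-based).  The walk starts in the front range (range 0) and covers it
    completely before stepping to the next; direction across rows alternates
    with range parity.  By default even ranges run left to right (ascending
    row index); ``right_to_left=True`` inverts the direction of every range.
    """
    if rows < 1 or ranges < 1:
        raise LayoutError(f"grid dimensions must be positive, got {rows}x{ranges}")
    seq: list[tuple[int, int]] = []
    for g in range(ranges):
        row_iter = range(rows) if g % 2 == 0 else range(rows - 1, -1, -1)
        for r in row_iter:
            seq.append((rows - 1 - r, g) if right_to_left else (r, g))
    return seq


def replicated_plot_number(rep: int, within_rep_index: int, plots_per_rep: int) -> int:
    """Replicate-prefixed plot number.

    The trailing digits carry the within-replicate index (two digits for fewer
    than 100 plots per replicate, three for 100-999, and so on); the leading
    digits carry the replicate number.  A 3-replicate, 20-plot design is thus
    numbered 101-120, 201-220, 301-320.
    """
    if not 1 <= within_rep_index <= plots_per_rep:
        raise LayoutError(
            f"within-replicate index {within_rep_index} outside 1..{plots_per_rep}"
        )
    digits = max(2, len(str(plots_per_rep)))
    return rep * 10**digits + within_rep_index


def validate_spec(spec: ReplicatedSpec | UnreplicatedSpec) -> list[str]:
    """Check a spec's invariants, returning one human-readable issue each.

    An empty list means the spec can be built into a matrix.
    """
    issues: list[str] = []
    if isinstance(spec, ReplicatedSpec):
        for name in ("plots_per_rep", "reps", "rows", "ranges"):
            if getattr(spec, name) < 1:
                issues.append(f"'{name}' must be a positive integer")
        if any(f < 0 for f in spec.fills_after_reps):
            issues.append("'Fills after reps' entries must be non-negative")
        if len(spec.fills_after_reps) != spec.reps:
            issues.append(
                f"'Fills after reps' has {len(spec.fills_after_reps)} entries; "
                f"its length must equal 'Reps' ({spec.reps})"
            )
        bad = [w for w in spec.wheel_track_ranges if not 1 <= w <= spec.ranges]
        if bad:
            issues.append(
                f"'Wheel track ranges' entries {bad} must be between 1 and "
                f"'Ranges' ({spec.ranges})"
            )
        if len(set(spec.wheel_track_ranges)) != len(spec.wheel_track_ranges):
            issues.append("'Wheel track ranges' entries must be unique")
        if not issues and spec.specified_plots != spec.total_possible_plots:
            issues.append(
                f"specified plots ({spec.specified_plots}) must match total "
                f"possible plots ({spec.total_possible_plots} = "
                f"{spec.rows} rows x {spec.ranges} ranges)"
            )
    else:
        for name in ("start_plot", "end_plot", "rows", "ranges"):
            if getattr(spec, name) < 1:
                issues.append(f"'{name}' must be a positive integer")
        if spec.end_plot < spec.start_plot:
            issues.append(
                f"'End plot' ({spec.end_plot}) must be at least "
                f"'Start plot' ({spec.start_plot})"
            )
        if spec.plot_indent < 0:
            issues.append("'Plot indent' must be non-negative")
        elif spec.rows >= 1 and spec.plot_indent >= spec.rows:
            issues.append(
                f"'Plot indent' ({spec.plot_indent}) must be smaller than "
                f"'Rows' ({spec.rows})"
            )
        if not issues:
            specified = spec.plot_indent + spec.plot_count
            possible = spec.rows * spec.ranges
            if specified > possible:
                issues.append(
                    f"indent plus plot count ({specified}) exceeds total "
                    f"possible plots ({possible} = {spec.rows} rows x "
                    f"{spec.ranges} ranges)"
                )
    return issues


def _require_valid(spec: ReplicatedSpec | UnreplicatedSpec) -> None:
    issues = validate_spec(spec)
    if issues:
        raise LayoutError("; ".join(issues))


def build_matrix_replicated(spec: ReplicatedSpec) -> FieldMatrix:
    """Assign roles and plot numbers to every cell of a replicated design.

    The serpentine walk skips nothing physically: cells in wheel-track ranges
    are marked WHEEL_TRACK without consuming a plot, and every other cell
    consumes the next item of the sequence (replicate 1's plots, then its
    fills, replicate 2's plots, then its fills, ...).  Fill cells continue
    their replicate's numbering (131, 132 after 101-130) so every planted
    cell has a unique label, but fills never reach the output layer.
    """
    _require_valid(spec)
    wheel = set(spec.wheel_track_ranges)
    digits = max(2, len(str(spec.plots_per_rep)))

    def queue() -> Iterator[Cell]:
        for rep in range(1, spec.reps + 1):
            for i in range(1, spec.plots_per_rep + 1):
                num = replicated_plot_number(rep, i, spec.plots_per_rep)
                yield Cell(CellRole.EXPERIMENTAL, num, rep)
            for j in range(1, spec.fills_after_reps[rep - 1] + 1):
                yield Cell(
                    CellRole.FILL, rep * 10**digits + spec.plots_per_rep + j, rep
                )

    items = queue()
    matrix = FieldMatrix(
        spec.rows,
        spec.ranges,
        right_to_left=spec.right_to_left,
        experiment_name=spec.experiment_name,
        replicated=True,
    )
    for r, g in serpentine_cell_sequence(spec.rows, spec.ranges, spec.right_to_left):
        if g + 1 in wheel:
            matrix.cells[(r, g)] = Cell(CellRole.WHEEL_TRACK)
        else:
            matrix.cells[(r, g)] = next(items)
    return matrix


def build_matrix_unreplicated(spec: UnreplicatedSpec) -> FieldMatrix:
    """Assign sequential plot numbers to an unreplicated layout.

    The first ``plot_indent`` cells of the serpentine walk are EXCLUDED, the
    next ``plot_count`` cells are numbered ``start_plot .. end_plot``, and any
    remaining cells (slack in the final range) are EXCLUDED.
    """
    _require_valid(spec)
    matrix = FieldMatrix(
        spec.rows,
        spec.ranges,
        right_to_left=spec.right_to_left,
        experiment_name=spec.experiment_name,
        replicated=False,
    )
    number = spec.start_plot
    for k, (r, g) in enumerate(
        serpentine_cell_sequence(spec.rows, spec.ranges, spec.right_to_left)
    ):
        if k < spec.plot_indent or number > spec.end_plot:
            matrix.cells[(r, g)] = Cell(CellRole.EXCLUDED)
        else:
            matrix.cells[(r, g)] = Cell(CellRole.EXPERIMENTAL, number)
            number += 1
    return matrix


def build_matrix(spec: ReplicatedSpec | UnreplicatedSpec) -> FieldMatrix:
    """Dispatch to the replicated or unreplicated builder."""
    if isinstance(spec, ReplicatedSpec):
        return build_matrix_replicated(spec)
    return build_matrix_unreplicated(spec)
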