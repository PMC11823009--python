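"""ASCII rendering of a field matrix, front range at the bottom.

Experimental cells show their plot number, fills show ``F``, wheel-track
cells ``W`` and excluded cells ``.``; columns are aligned so the text mirrors
the field map a crew would carry.
"""

from __future__ import annotations

from .layout import CellRole, FieldMatrix

_SYMBOL = {CellRole.FILL: "F", CellRole.WHEEL_TRACK: "W", CellRole.EXCLUDED: "."}


def render_preview(matrix: FieldMatrix) -> str:
    """One text line per range, last range first (front range at the bottom)."""
    def label(r: int, g: int) -> str:
        cell = matrix[(r, g)]
        if cell.role is CellRole.EXPERIMENTAL:
            return str(cell.plot_number)
        return _SYMBOL[cell.role]

    width = max(
        len(label(r, g))
        for r in range(matrix.rows)
        for g in range(matrix.ranges)
    )
    lines = [
        " ".join(label(r, g).rjust(width) for r in range(matrix.rows))
        for g in range(matrix.ranges - 1, -1, -1)
    ]
    return "\n".join(lines)
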