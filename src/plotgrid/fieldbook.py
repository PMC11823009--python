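"""Field-book CSV loading and attribute joins onto plot features.

A field book is the tabular record breeders keep per plot (line name,
pedigree, notes ...).  It must have a header row and one column whose values
are the plot numbers of the layout; selected columns are copied onto each
matching plot feature directly — no intermediate field-map file is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from os import PathLike

import pandas as pd

from .geometry import PlotFeatureTable

logger = logging.getLogger(__name__)


class FieldBookError(ValueError):
    """Raised for schema, duplication, or coverage problems in a field book."""


@dataclass
class FieldBook:
    """A parsed field book: records keyed by an integer plot column."""

    header: list[str]
    records: pd.DataFrame
    plot_column: str
    selected_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.plot_column not in self.header:
            raise FieldBookError(
                f"plot column {self.plot_column!r} not in header {self.header}"
            )
        missing = [c for c in self.selected_columns if c not in self.header]
        if missing:
            raise FieldBookError(f"selected columns not in header: {missing}")
        try:
            plots = self.records[self.plot_column].astype(int)
        except (ValueError, TypeError) as exc:
            raise FieldBookError(
                f"plot column {self.plot_column!r} has non-integer values"
            ) from exc
        dupes = sorted(plots[plots.duplicated()].unique().tolist())
        if dupes:
            raise FieldBookError(f"duplicate plot numbers in field book: {dupes}")
        self.records = self.records.assign(**{self.plot_column: plots})

    def plot_numbers(self) -> set[int]:
        return set(self.records[self.plot_column].tolist())


def load_fieldbook(
    path: str | PathLike,
    plot_column: str,
    selected_columns: list[str] | None = None,
) -> FieldBook:
    """Read a field-book CSV (header row mandatory).

    Plot numbers are matched numerically after integer parsing, so a
    zero-padded "0101" matches plot 101.  ``selected_columns`` defaults to
    every column except the plot column.
    """
    records = pd.read_csv(path, dtype=str, keep_default_na=False)
    header = list(records.columns)
    if plot_column not in header:
        raise FieldBookError(
            f"plot column {plot_column!r} not found; header is {header}"
        )
    if selected_columns is None:
        selected_columns = [c for c in header if c != plot_column]
    return FieldBook(
        header=header,
        records=records,
        plot_column=plot_column,
        selected_columns=list(selected_columns),
    )


def join_attributes(features: PlotFeatureTable, book: FieldBook) -> PlotFeatureTable:
    """Copy the book's selected columns onto each feature by plot number.

    Every feature's plot number must appear in the book (missing plots are an
    error); extra book rows for plots outside the layout are ignored with a
    warning, which lets one book serve an experiment split across several
    layers.  Geometry and feature order are untouched.
    """
    lookup = book.records.set_index(book.plot_column)
    missing = sorted(
        {f.plot for f in features} - set(lookup.index.tolist())
    )
    if missing:
        raise FieldBookError(
            f"field book is missing plot numbers present in the layout: {missing}"
        )
    extra = sorted(set(lookup.index.tolist()) - {f.plot for f in features})
    if extra:
        logger.warning(
            "field book has %d rows for plots not in this layout (ignored): %s%s",
            len(extra),
            extra[:10],
            " ..." if len(extra) > 10 else "",
        )
    joined = [
        replace(
            f,
            attributes={
                **f.attributes,
                **{c: lookup.at[f.plot, c] for c in book.selected_columns},
            },
        )
        for f in features
    ]
    return PlotFeatureTable(
        features=joined, crs=features.crs, experiment_name=features.experiment_name
    )
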