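"""ScoreTable: rectangular input data keyed by identifier columns.

A thin wrapper around a :class:`pandas.DataFrame` carrying the two pieces
of table-level context the engine and transforms need: which columns
identify a row (participant x study event) and, for longitudinal
operations, the total order over event labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd

from .errors import ConfigurationError, LoadError

DEFAULT_ID_COLUMNS = ("participant_id", "session_id")


@dataclass
class ScoreTable:
    """Tabular data with identifier columns and an optional event order.

    Attributes
    ----------
    data : pandas.DataFrame
        The rows; identifier columns plus item/score columns.
    id_columns : tuple of str
        Ordered identifier columns, conventionally
        ``(participant, event)``.
    event_order : tuple of str or None
        Total order over event labels (earliest first); required by
        longitudinal operations such as ``make_static``.
    """

    data: pd.DataFrame
    id_columns: tuple[str, ...] = DEFAULT_ID_COLUMNS
    event_order: tuple[str, ...] | None = None

    def __post_init__(self):
        self.id_columns = tuple(self.id_columns)
        if self.event_order is not None:
            self.event_order = tuple(self.event_order)
        absent = [c for c in self.id_columns if c not in self.data.columns]
        if absent:
            raise LoadError(
                "table lacks identifier column(s): " + ", ".join(absent)
            )
        if self.data.duplicated(subset=list(self.id_columns)).any():
            raise LoadError(
                "duplicate identifier tuples in "
                f"({', '.join(self.id_columns)})"
            )

    @property
    def participant_column(self) -> str:
        return self.id_columns[0]

    @property
    def event_column(self) -> str:
        if len(self.id_columns) < 2:
            raise ConfigurationError(
                "table has no event identifier column"
            )
        return self.id_columns[1]

    @property
    def value_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.id_columns]

    def with_data(self, data: pd.DataFrame) -> "ScoreTable":
        """Same configuration, new frame."""
        return replace(self, data=data)

    def copy(self) -> "ScoreTable":
        return self.with_data(self.data.copy())

    def __len__(self) -> int:
        return len(self.data)


def as_table(
    obj: ScoreTable | pd.DataFrame,
    id_columns: Sequence[str] = DEFAULT_ID_COLUMNS,
    event_order: Sequence[str] | None = None,
) -> ScoreTable:
    """Coerce a DataFrame (or pass through a ScoreTable) to a ScoreTable."""
    if isinstance(obj, ScoreTable):
        return obj
    return ScoreTable(
        obj,
        tuple(id_columns),
        tuple(event_order) if event_order is not None else None,
    )
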