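"""Column-level data-transformation utilities.

Four generic transforms used while curating tabulated cohort data before
(or after) scoring: value recoding, column coalescing, category collapsing,
and conversion of a longitudinal variable to a per-participant constant.
All transforms are pure — they return a new :class:`ScoreTable` and
preserve row count, row order and identifier columns exactly.
"""

from __future__ import annotations

import logging
from typing import Any, Hashable, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SpecificationError, ValidationFailure
from .model import Violation
from .table import ScoreTable

__all__ = [
    "recode_levels",
    "combine_cols",
    "combine_levels",
    "make_static",
    "TRANSFORMS",
]

logger = logging.getLogger("scorekit")

#: Sentinel for "recode this level to missing" in recode_levels mappings.
MISSING = None


def _require_columns(table: ScoreTable, *columns: str) -> None:
    absent = [c for c in columns if c not in table.data.columns]
    if absent:
        raise ValidationFailure(
            [
                Violation(
                    "missing-column", f"column {c!r} not present", field=c
                )
                for c in absent
            ]
        )


def recode_levels(
    table: ScoreTable,
    column: str,
    mapping: Mapping[Hashable, Any],
    default: str = "keep",
) -> ScoreTable:
    """Recode values in one column.

    Values found as keys in ``mapping`` are replaced by their mapped value
    (map to ``None`` to recode a level to missing).  Values not in the
    mapping follow ``default``: ``"keep"`` leaves them unchanged,
    ``"missing"`` recodes them to missing.  Missing stays missing either
    way.
    """
    if default not in ("keep", "missing"):
        raise SpecificationError(
            f"default must be 'keep' or 'missing', got {default!r}"
        )
    _require_columns(table, column)
    series = table.data[column]
    mapping = dict(mapping)
    keep = default == "keep"

    def _recode(value):
        if value in mapping:
            mapped = mapping[value]
            return np.nan if mapped is None else mapped
        return value if keep else np.nan

    data = table.data.copy()
    data[column] = series.map(_recode, na_action="ignore")
    return table.with_data(data)


def combine_cols(
    table: ScoreTable,
    first: str,
    second: str,
    out: str | None = None,
    overwrite: bool = False,
) -> ScoreTable:
    """Coalesce two columns into one, first argument wins.

    Typical use: merging mutually exclusive branching-logic columns (two
    survey paths writing to different variables).  The output takes
    ``first``'s value where observed and ``second``'s otherwise.  Rows
    where both are observed but unequal are conflicts — counted and
    logged, not errors, since ``first`` wins by position.
    """
    _require_columns(table, first, second)
    if out is None:
        out = first
    if out in table.data.columns and out not in (first, second) and not overwrite:
        raise SpecificationError(
            f"output column {out!r} already present (pass overwrite=True)"
        )
    a, b = table.data[first], table.data[second]
    conflicts = int((a.notna() & b.notna() & (a != b)).sum())
    if conflicts:
        logger.warning(
            "combine_cols(%s, %s): %d row(s) with conflicting observed "
            "values; kept %s",
            first,
            second,
            conflicts,
            first,
        )
    data = table.data.copy()
    data[out] = a.where(a.notna(), b)
    return table.with_data(data)


def combine_levels(
    table: ScoreTable,
    column: str,
    level_groups: Mapping[Hashable, Iterable[Hashable]],
) -> ScoreTable:
    """Collapse categories: each old level in a group maps to its new level.

    ``level_groups`` maps new level -> set of old levels; groups must be
    pairwise disjoint.  Levels in no group pass through unchanged.
    """
    seen: dict = {}
    for new, olds in level_groups.items():
        for old in olds:
            if old in seen:
                raise SpecificationError(
                    f"level {old!r} appears in groups {seen[old]!r} and "
                    f"{new!r}; groups must be disjoint"
                )
            seen[old] = new
    _require_columns(table, column)
    data = table.data.copy()
    data[column] = data[column].map(
        lambda v: seen.get(v, v), na_action="ignore"
    )
    return table.with_data(data)


def make_static(
    table: ScoreTable,
    column: str,
    rule: str = "first-observed",
) -> ScoreTable:
    """Convert a longitudinal variable into a per-participant constant.

    For each participant the selected value is propagated to all of that
    participant's rows.  ``rule="first-observed"`` (default) selects the
    value at the earliest event — by the table's ``event_order`` — where
    the column is observed; ``rule="baseline"`` takes the value at the
    first event in the order, observed or not.  Participants with no
    selectable value get missing everywhere.  Idempotent.
    """
    if rule not in ("first-observed", "baseline"):
        raise SpecificationError(
            f"unknown make_static rule {rule!r}"
        )
    _require_columns(table, column)
    if table.event_order is None:
        raise ConfigurationError(
            "make_static requires the table to define event_order"
        )
    part_col, event_col = table.participant_column, table.event_column
    rank = {label: i for i, label in enumerate(table.event_order)}
    unknown = set(table.data[event_col].dropna()) - set(rank)
    if unknown:
        raise ConfigurationError(
            "event label(s) absent from event_order: "
            + ", ".join(map(str, sorted(unknown)))
        )

    data = table.data.copy()
    order = data[event_col].map(rank)
    if rule == "baseline":
        base = data[order == 0]
        chosen = pd.Series(
            base[column].to_numpy(), index=base[part_col].to_numpy()
        )
    else:
        frame = pd.DataFrame(
            {"part": data[part_col], "order": order, "value": data[column]}
        ).sort_values("order", kind="stable")
        frame = frame[frame["value"].notna()]
        chosen = frame.groupby("part", sort=False)["value"].first()
    data[column] = data[part_col].map(chosen)
    return table.with_data(data)


#: Registry of the generic data-transformation utilities.
TRANSFORMS = {
    "recode_levels": recode_levels,
    "combine_cols": combine_cols,
    "combine_levels": combine_levels,
    "make_static": make_static,
}
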