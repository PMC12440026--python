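"""Execution engine: runs score definitions against tables.

The calling contract mirrors the field's convention for scoring functions:
``data`` (the input table), ``name`` (output column override) and
``combine`` (append the score to the input, default, or return identifiers
plus the score only).  Every run validates first — all violations are
collected and reported at once — then recodes sentinel missing codes,
executes the kernel, and derives the ``_nm`` (number-missing) companion
where declared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .errors import SpecificationError, ValidationFailure
from .kernels import SCORE_KERNELS, ss_nm
from .model import (
    Catalog,
    NormTable,
    ScoreDefinition,
    Violation,
    validate_definition,
)
from .table import ScoreTable, as_table

__all__ = ["ScoreResult", "compute_score", "compute_group", "validate_input"]

logger = logging.getLogger("scorekit")

_NUMERIC_KERNELS = ("sum", "mean", "prsum", "max", "mean_pos", "tscore")


@dataclass
class ScoreResult:
    """Outcome of a scoring run.

    Attributes
    ----------
    table : ScoreTable
        With ``combine=True``: the input columns plus the score column(s);
        with ``combine=False``: identifier columns plus the score
        column(s) only.  Row count and order match the input exactly.
    score_columns : list of str
        Names of the columns this run added, in emission order.
    provenance : dict
        Score column name -> definition hash and effective parameter
        values, for release reproducibility.
    """

    table: ScoreTable
    score_columns: list[str] = field(default_factory=list)
    provenance: dict[str, dict] = field(default_factory=dict)

    @property
    def data(self) -> pd.DataFrame:
        return self.table.data


def _coercible(series: pd.Series) -> bool:
    observed = series.dropna()
    if observed.empty or pd.api.types.is_numeric_dtype(series):
        return True
    try:
        pd.to_numeric(observed)
        return True
    except (ValueError, TypeError):
        return False


def _resolve_norms(
    defn: ScoreDefinition, catalog: Catalog | None
) -> NormTable | None:
    ref = defn.params.get("norm_ref")
    if isinstance(ref, NormTable):
        return ref
    if catalog is not None and ref in catalog.norms:
        return catalog.norms[ref]
    return None


def validate_input(
    data: ScoreTable | pd.DataFrame,
    defn: ScoreDefinition,
    catalog: Catalog | None = None,
) -> list[Violation]:
    """Validate a table against a definition; report, never raise.

    Checks that the definition itself is valid, that every required column
    is present, and that item columns are of the type the kernel requires.
    The report lists all violations at once; :func:`compute_score` raises
    exactly when this report is non-empty.
    """
    frame = data.data if isinstance(data, ScoreTable) else data
    report = list(validate_definition(defn))

    required = list(defn.items)
    if defn.kernel == "count_cond":
        required = sorted(
            set(required)
            | {c.column for c in defn.params.get("conditions", ())}
        )
    if defn.kernel == "tscore":
        required = required + list(defn.params.get("stratum_columns", ()))
        if len(defn.items) != 1:
            report.append(
                Violation(
                    "items",
                    "tscore takes exactly one raw-score item column, got "
                    f"{len(defn.items)}",
                    field="items",
                )
            )
        if _resolve_norms(defn, catalog) is None:
            report.append(
                Violation(
                    "norm-ref",
                    f"norm table {defn.params.get('norm_ref')!r} could not "
                    "be resolved",
                    field="norm_ref",
                )
            )
    absent = [c for c in required if c not in frame.columns]
    for col in absent:
        report.append(
            Violation(
                "missing-column",
                f"required column {col!r} is absent from the input data",
                field=col,
            )
        )
    if defn.kernel in _NUMERIC_KERNELS:
        for col in defn.items:
            if col in frame.columns and not _coercible(frame[col]):
                report.append(
                    Violation(
                        "type",
                        f"column {col!r} must be numeric for kernel "
                        f"{defn.kernel!r}",
                        field=col,
                    )
                )
    return report


def _recode_missing(frame: pd.DataFrame, missing_codes) -> pd.DataFrame:
    if not missing_codes:
        return frame
    return frame.mask(frame.isin(list(missing_codes)))


def _run_kernel(
    defn: ScoreDefinition,
    items: pd.DataFrame,
    full: pd.DataFrame,
    catalog: Catalog | None,
) -> pd.Series:
    k = defn.kernel
    params = defn.params
    if k in ("sum", "mean", "prsum", "max"):
        return SCORE_KERNELS[k](items, max_na=int(params.get("max_na", 0)))
    if k == "nm":
        return ss_nm(items)
    if k == "mean_pos":
        return SCORE_KERNELS[k](items)
    if k == "count":
        return SCORE_KERNELS[k](items, params["target_levels"])
    if k == "count_cond":
        return SCORE_KERNELS[k](full, params["conditions"])
    if k == "tscore":
        norms = _resolve_norms(defn, catalog)
        stratum_cols = list(params.get("stratum_columns", ()))
        stratum = full[stratum_cols] if stratum_cols else None
        return SCORE_KERNELS[k](items[defn.items[0]], norms, stratum)
    raise SpecificationError(f"unknown kernel {k!r}")  # pragma: no cover


def compute_score(
    data: ScoreTable | pd.DataFrame,
    defn: ScoreDefinition,
    name: str | None = None,
    combine: bool = True,
    catalog: Catalog | None = None,
    missing_codes=None,
    **param_overrides: Any,
) -> ScoreResult:
    """Compute one summary score (plus its ``_nm`` companion if declared).

    Parameters
    ----------
    data : ScoreTable or DataFrame
        Input containing every item column the definition requires.
    defn : ScoreDefinition
        The declarative score specification to execute.
    name : str, optional
        Output column name; defaults to the score's own name.
    combine : bool
        True (default): return the input with the score column(s)
        appended.  False: return identifier columns plus the score
        column(s) only.
    catalog : Catalog, optional
        Supplies identifier columns, sentinel missing codes and norm
        tables when the definition references them.
    missing_codes : iterable, optional
        Overrides the catalog's sentinel codes for this run.
    **param_overrides
        Kernel parameters overriding the definition's defaults
        (e.g. ``max_na=2``).

    Raises
    ------
    ValidationFailure
        If :func:`validate_input` reports any violation.
    SpecificationError
        If an output column name collides with an existing column.
    """
    if param_overrides:
        defn = ScoreDefinition(
            defn.name,
            defn.items,
            defn.kernel,
            {**defn.params, **param_overrides},
            defn.nm_companion,
        )
    id_columns = (
        catalog.id_columns
        if catalog is not None and not isinstance(data, ScoreTable)
        else None
    )
    table = (
        as_table(data, id_columns=id_columns)
        if id_columns is not None
        else as_table(data)
    )

    report = validate_input(table, defn, catalog)
    if report:
        raise ValidationFailure(report)

    out_name = name if name is not None else defn.name.render()
    new_columns = [out_name]
    if defn.nm_companion:
        nm_name = (
            f"{name}_nm"
            if name is not None
            else defn.name.with_suffix("nm").render()
        )
        new_columns.append(nm_name)
    collisions = [c for c in new_columns if c in table.data.columns]
    if collisions:
        raise SpecificationError(
            "score column name(s) already present in the input: "
            + ", ".join(collisions),
            kind="name-collision",
        )

    if missing_codes is None:
        missing_codes = catalog.missing_codes if catalog is not None else ()
    full = table.data
    if defn.kernel == "count_cond":
        cond_cols = sorted({c.column for c in defn.params["conditions"]})
        full = full.copy()
        full[cond_cols] = _recode_missing(full[cond_cols], missing_codes)
        items = full.reindex(columns=list(defn.items))
    else:
        items = _recode_missing(full[list(defn.items)], missing_codes)

    values = _run_kernel(defn, items, full, catalog)

    out = table.data.copy()
    out[out_name] = values
    if defn.nm_companion:
        out[new_columns[1]] = ss_nm(items)
    if not combine:
        out = out[list(table.id_columns) + new_columns]

    provenance = {
        out_name: {
            "score": defn.name.render(),
            "definition_hash": defn.definition_hash(),
            "kernel": defn.kernel,
            "params": dict(defn.params),
            "items": list(defn.items),
        }
    }
    if defn.nm_companion:
        provenance[new_columns[1]] = {
            "score": defn.name.with_suffix("nm").render(),
            "definition_hash": defn.definition_hash(),
            "kernel": "nm",
            "params": {},
            "items": list(defn.items),
        }
    logger.info(
        "computed %s over %d row(s); nm range [%d, %d]",
        out_name,
        len(out),
        int(ss_nm(items).min()) if len(out) else 0,
        int(ss_nm(items).max()) if len(out) else 0,
    )
    return ScoreResult(
        table.with_data(out), new_columns, provenance
    )


def compute_group(
    data: ScoreTable | pd.DataFrame,
    catalog: Catalog,
    group: str,
    combine: bool = True,
) -> ScoreResult:
    """Compute every score in a catalog group, in catalog order.

    Equivalent to folding :func:`compute_score` over the group members;
    ``_nm`` companions are emitted immediately after their parent score.
    """
    members = catalog.group_members(group)
    if not members:
        logger.warning("group %r is empty; no scores computed", group)
    table = (
        as_table(data)
        if isinstance(data, ScoreTable)
        else as_table(data, id_columns=catalog.id_columns)
    )
    current = table
    score_columns: list[str] = []
    provenance: dict[str, dict] = {}
    for defn in members:
        res = compute_score(current, defn, combine=True, catalog=catalog)
        current = res.table
        score_columns.extend(res.score_columns)
        provenance.update(res.provenance)
    out = current.data
    if not combine:
        out = out[list(table.id_columns) + score_columns]
    return ScoreResult(table.with_data(out), score_columns, provenance)
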