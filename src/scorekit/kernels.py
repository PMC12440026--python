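"""Row-wise score-computation kernels (the ``ss_*`` utilities).

Each kernel maps one row of item values to a scalar, vectorized over a
:class:`pandas.DataFrame` whose columns are the items of a score (one row
per observation): the input is an ``n_rows x n_items`` frame and the output
a length-``n_rows`` Series aligned on the input index.

Missingness contract
--------------------
``nm`` denotes the number of missing items in a row.  The value-producing
aggregations (:func:`ss_mean`, :func:`ss_sum`, :func:`ss_prsum`,
:func:`ss_max`) take a ``max_na`` bound — the maximum number of missing
items tolerated — and return missing for any row with ``nm > max_na``.
A row with *all* items missing is always missing, even when
``max_na >= n_items``: a score computed from zero items is undefined.
Sentinel missing codes (refuse/don't-know) must be recoded to missing
upstream (the engine does this from the catalog's ``missing_codes``).

No rounding is applied anywhere; consumers may format.
"""

from __future__ import annotations

from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .model import ConditionSpec, NormTable, Violation
from .errors import ValidationFailure

__all__ = [
    "ss_sum",
    "ss_mean",
    "ss_nm",
    "ss_count",
    "ss_count_cond",
    "ss_max",
    "ss_prsum",
    "ss_mean_pos",
    "ss_tscore",
    "SCORE_KERNELS",
]


def _as_items(items: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(items, pd.DataFrame):
        raise ParameterError("kernel input must be a pandas DataFrame")
    if items.shape[1] == 0:
        raise ParameterError("kernel input must have at least one item column")
    return items.apply(pd.to_numeric, errors="coerce")


def _gate(items: pd.DataFrame, max_na: int) -> tuple[pd.Series, pd.Series]:
    """Return (nm, row-is-computable) for a given missingness bound."""
    n = items.shape[1]
    if not isinstance(max_na, (int, np.integer)) or isinstance(max_na, bool):
        raise ParameterError(f"max_na must be an integer, got {max_na!r}")
    if not 0 <= max_na <= n:
        raise ParameterError(
            f"max_na out of range: expected 0 <= max_na <= {n} (the item "
            f"count), got {max_na}"
        )
    nm = items.isna().sum(axis=1)
    return nm, (nm <= max_na) & (nm < n)


def ss_nm(items: pd.DataFrame) -> pd.Series:
    """Number of missing items per row.  Always defined, never missing."""
    if not isinstance(items, pd.DataFrame):
        raise ParameterError("kernel input must be a pandas DataFrame")
    return items.isna().sum(axis=1).astype(int)


def ss_mean(items: pd.DataFrame, max_na: int = 0) -> pd.Series:
    """Arithmetic mean of the observed items; missing if ``nm > max_na``."""
    items = _as_items(items)
    _, ok = _gate(items, max_na)
    return items.mean(axis=1).where(ok)


def ss_sum(items: pd.DataFrame, max_na: int = 0) -> pd.Series:
    """Sum of the observed items (no proration); missing if ``nm > max_na``."""
    items = _as_items(items)
    _, ok = _gate(items, max_na)
    return items.sum(axis=1, min_count=1).where(ok)


def ss_prsum(items: pd.DataFrame, max_na: int = 0) -> pd.Series:
    """Prorated sum: observed sum scaled by ``n_items / (n_items - nm)``.

    The standard psychometric proration — estimates the full-scale sum
    under partial missingness by assuming unanswered items would have
    scored at the respondent's observed mean.  Missing if ``nm > max_na``.
    """
    items = _as_items(items)
    n = items.shape[1]
    nm, ok = _gate(items, max_na)
    answered = (n - nm).where(nm < n)  # avoid 0/0 on all-missing rows
    sums = items.sum(axis=1, min_count=1)
    # nm == 0 keeps the exact sum: the n/n factor must not perturb it
    prorated = sums.where(nm == 0, sums * n / answered)
    return prorated.where(ok)


def ss_max(items: pd.DataFrame, max_na: int = 0) -> pd.Series:
    """Maximum of the observed items; missing if ``nm > max_na``."""
    items = _as_items(items)
    _, ok = _gate(items, max_na)
    return items.max(axis=1).where(ok)


def ss_mean_pos(items: pd.DataFrame) -> pd.Series:
    """Mean of the observed items strictly greater than zero.

    Zeros and negatives are excluded from the mean; missing when a row has
    no positive observed value.
    """
    items = _as_items(items)
    return items.where(items > 0).mean(axis=1)


def ss_count(
    items: pd.DataFrame, target_levels: Iterable[Any]
) -> pd.Series:
    """Count of observed items that fall in ``target_levels``.

    Partially missing rows remain countable (missing items contribute 0),
    so counts are lower bounds by construction; only an all-missing row —
    which carries no information — yields missing.  Returns a nullable
    integer Series.
    """
    if not isinstance(items, pd.DataFrame):
        raise ParameterError("kernel input must be a pandas DataFrame")
    targets = list(target_levels)
    if not targets:
        raise ParameterError("target_levels must be non-empty")
    counts = (items.isin(targets) & items.notna()).sum(axis=1)
    all_missing = items.isna().all(axis=1)
    return counts.astype("Int64").mask(all_missing)


def _eval_condition(data: pd.DataFrame, cond: ConditionSpec) -> pd.Series:
    series = data[cond.column]
    op, ref = cond.comparator, cond.reference
    if op == "in":
        hit = series.isin(list(ref))
    elif op == "not-in":
        hit = ~series.isin(list(ref))
    elif op == "==":
        hit = series == ref
    elif op == "!=":
        hit = series != ref
    elif op == "<":
        hit = series < ref
    elif op == "<=":
        hit = series <= ref
    elif op == ">":
        hit = series > ref
    else:
        hit = series >= ref
    # comparisons on missing values are never trusted; the policy decides
    return hit.where(series.notna(), other=False).astype(bool)


def ss_count_cond(
    data: pd.DataFrame, conditions: Sequence[ConditionSpec]
) -> pd.Series:
    """Row-wise count of user-defined conditions evaluating true.

    Each condition is a :class:`~scorekit.model.ConditionSpec` predicate on
    one column of ``data``.  A condition applied to a missing value counts
    as false by default; with ``missing_policy="missing-propagates"`` the
    row's whole count becomes missing instead.  An empty condition list
    yields 0 everywhere.
    """
    if not isinstance(data, pd.DataFrame):
        raise ParameterError("kernel input must be a pandas DataFrame")
    absent = sorted({c.column for c in conditions} - set(data.columns))
    if absent:
        raise ValidationFailure(
            [
                Violation(
                    "missing-column",
                    f"condition column {col!r} not present in data",
                    field=col,
                )
                for col in absent
            ]
        )
    counts = pd.Series(0, index=data.index, dtype="Int64")
    propagate = pd.Series(False, index=data.index)
    for cond in conditions:
        counts = counts + _eval_condition(data, cond).astype(int)
        if cond.missing_policy == "missing-propagates":
            propagate |= data[cond.column].isna()
    return counts.mask(propagate)


def ss_tscore(
    raw: pd.Series | float,
    norms: NormTable,
    stratum: pd.DataFrame | tuple | None = None,
) -> pd.Series | float:
    """Normative t-score for raw score(s) by exact table lookup.

    ``stratum`` selects the norm stratum: ``None`` for a global (empty)
    stratum key, a tuple applied to every row, or a DataFrame of stratum
    columns aligned with ``raw``.  A missing raw score yields a missing
    t-score; a raw score outside the stratum's domain raises
    :class:`~scorekit.errors.NormDomainError`.
    """
    if np.isscalar(raw) or raw is None:
        key = () if stratum is None else tuple(np.atleast_1d(stratum))
        return norms.lookup(raw, key)
    raw = pd.to_numeric(raw, errors="coerce")
    out = []
    for idx, value in raw.items():
        if stratum is None:
            key: tuple = ()
        elif isinstance(stratum, pd.DataFrame):
            key = tuple(stratum.loc[idx])
        else:
            key = tuple(stratum)
        out.append(norms.lookup(value if pd.notna(value) else None, key))
    return pd.Series(out, index=raw.index, dtype=float)


#: Registry mapping catalog kernel identifiers to kernel callables.
SCORE_KERNELS = {
    "sum": ss_sum,
    "mean": ss_mean,
    "nm": ss_nm,
    "count": ss_count,
    "count_cond": ss_count_cond,
    "max": ss_max,
    "prsum": ss_prsum,
    "mean_pos": ss_mean_pos,
    "tscore": ss_tscore,
}
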