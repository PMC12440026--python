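"""Declarative score model: definitions, catalogs, norm tables, conditions.

A :class:`ScoreDefinition` states *what* a score is — its items, the kernel
that aggregates them, and kernel parameters — without computing anything.
A :class:`Catalog` collects definitions plus table-level configuration
(identifier columns, sentinel missing codes, named score groups).  The
engine (:mod:`scorekit.engine`) executes these declarations.

Validation here follows a report-not-raise contract:
:func:`validate_definition` and :meth:`Catalog.validate` return a list of
:class:`Violation` records (empty = valid) and never raise on bad input.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import NormDomainError, SpecificationError
from .names import ScoreName, parse_score_name

#: Kernel identifiers with built-in semantics (the ``ss_*`` utilities).
KERNEL_NAMES = (
    "sum",
    "mean",
    "nm",
    "count",
    "count_cond",
    "max",
    "prsum",
    "mean_pos",
    "tscore",
)

#: Required parameters per kernel, checked by :func:`validate_definition`.
KERNEL_REQUIRED_PARAMS: dict[str, tuple[str, ...]] = {
    "count": ("target_levels",),
    "count_cond": ("conditions",),
    "tscore": ("norm_ref",),
}

#: Kernels that accept a ``max_na`` missingness bound.
KERNELS_WITH_MAX_NA = ("sum", "mean", "prsum", "max")

#: Kernels whose scores carry an ``_nm`` companion by default.
NM_COMPANION_DEFAULT = ("sum", "mean", "prsum")

COMPARATORS = ("==", "!=", "<", "<=", ">", ">=", "in", "not-in")
_SET_COMPARATORS = ("in", "not-in")
MISSING_POLICIES = ("false", "missing-propagates")


@dataclass(frozen=True)
class Violation:
    """One validation finding: a machine-readable kind plus a message."""

    kind: str
    message: str
    field: str | None = None

    def __str__(self) -> str:  # pragma: no cover
        return f"[{self.kind}] {self.message}"


@dataclass(frozen=True)
class ConditionSpec:
    """A row-level predicate, ``column <comparator> reference``.

    ``missing_policy`` governs evaluation on a missing value:
    ``"false"`` (default) makes the condition false; ``"missing-propagates"``
    makes the whole row-wise count missing.
    """

    column: str
    comparator: str
    reference: Any
    missing_policy: str = "false"

    def __post_init__(self):
        if self.comparator not in COMPARATORS:
            raise SpecificationError(
                f"unknown comparator {self.comparator!r} "
                f"(expected one of {COMPARATORS})"
            )
        if self.missing_policy not in MISSING_POLICIES:
            raise SpecificationError(
                f"unknown missing policy {self.missing_policy!r}"
            )
        is_set = isinstance(self.reference, (set, frozenset, list, tuple))
        if self.comparator in _SET_COMPARATORS and not is_set:
            raise SpecificationError(
                f"comparator {self.comparator!r} requires a value set, got "
                f"scalar {self.reference!r}"
            )
        if self.comparator not in _SET_COMPARATORS and is_set:
            raise SpecificationError(
                f"comparator {self.comparator!r} requires a scalar, got a "
                "value set"
            )
        if is_set:
            object.__setattr__(self, "reference", frozenset(self.reference))


class NormTable:
    """Normative (stratum, raw score) -> t-score lookup.

    Strata are keyed by zero or more stratum columns (e.g. age band x sex);
    a table with no stratum columns has a single global stratum.  Lookup is
    exact: no interpolation, and a raw value outside a stratum's raw-score
    domain is a :class:`~scorekit.errors.NormDomainError`.
    """

    def __init__(
        self,
        entries: pd.DataFrame,
        stratum_columns: Sequence[str] = (),
        raw_column: str = "raw",
        t_column: str = "t",
    ):
        self.stratum_columns = tuple(stratum_columns)
        missing = [
            c
            for c in (*self.stratum_columns, raw_column, t_column)
            if c not in entries.columns
        ]
        if missing:
            raise SpecificationError(
                f"norm table lacks required column(s): {', '.join(missing)}"
            )
        key_cols = [*self.stratum_columns, raw_column]
        if entries.duplicated(subset=key_cols).any():
            raise SpecificationError(
                "norm table has duplicate (stratum, raw) entries"
            )
        t = pd.to_numeric(entries[t_column], errors="coerce")
        if not np.isfinite(t.to_numpy(dtype=float)).all():
            raise SpecificationError("norm table t-scores must be finite")
        self._map: dict[tuple, dict[Any, float]] = {}
        for _, row in entries.iterrows():
            stratum = tuple(row[c] for c in self.stratum_columns)
            self._map.setdefault(stratum, {})[row[raw_column]] = float(
                row[t_column]
            )
        self._frame = entries[key_cols + [t_column]].copy()
        self._frame.columns = [*self.stratum_columns, "raw", "t"]

    @property
    def strata(self) -> list[tuple]:
        return list(self._map)

    def raw_domain(self, stratum: tuple = ()) -> set:
        if stratum not in self._map:
            raise NormDomainError(f"unknown stratum {stratum!r}")
        return set(self._map[stratum])

    def lookup(self, raw: Any, stratum: tuple = ()) -> float:
        """T-score for one raw value; missing raw propagates to missing."""
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            return float("nan")
        if stratum not in self._map:
            raise NormDomainError(f"unknown stratum {stratum!r}")
        entries = self._map[stratum]
        if raw not in entries:
            raise NormDomainError(
                f"raw score {raw!r} outside norm domain for stratum "
                f"{stratum!r}"
            )
        return entries[raw]

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, NormTable)
            and self.stratum_columns == other.stratum_columns
            and self._map == other._map
        )


@dataclass
class ScoreDefinition:
    """Declarative specification of a single summary score.

    Parameters
    ----------
    name : ScoreName or str
        The score's canonical name; strings are parsed.
    items : sequence of str
        Ordered item (input column) names.
    kernel : str
        One of :data:`KERNEL_NAMES` (``"mean"``, ``"prsum"``, ...).
    params : mapping
        Kernel parameters (``max_na``, ``target_levels``, ``conditions``,
        ``norm_ref``/``stratum_columns``).
    nm_companion : bool, optional
        Whether an ``_nm`` (number-missing) sibling score is derived
        alongside.  Defaults to True for mean/sum/prsum kernels.
    """

    name: ScoreName
    items: tuple[str, ...]
    kernel: str
    params: dict[str, Any] = field(default_factory=dict)
    nm_companion: bool | None = None

    def __post_init__(self):
        if isinstance(self.name, str):
            self.name = parse_score_name(self.name)
        self.items = tuple(self.items)
        self.params = dict(self.params)
        if self.nm_companion is None:
            self.nm_companion = self.kernel in NM_COMPANION_DEFAULT

    @property
    def max_na(self) -> int | None:
        return self.params.get("max_na")

    def definition_hash(self) -> str:
        """Stable content hash used for provenance records."""
        payload = {
            "name": self.name.render(),
            "items": list(self.items),
            "kernel": self.kernel,
            "params": {
                k: sorted(v) if isinstance(v, (set, frozenset)) else repr(v)
                for k, v in sorted(self.params.items())
            },
            "nm_companion": self.nm_companion,
        }
        blob = json.dumps(payload, sort_keys=True, default=repr)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_score_name(defn: ScoreDefinition) -> str:
    """The output column name used when the caller does not override it:
    the score's own canonical name."""
    return defn.name.render()


def validate_definition(defn: ScoreDefinition) -> list[Violation]:
    """Check a definition against its invariants.

    Returns a (possibly empty) list of violations; never raises.
    """
    out: list[Violation] = []
    if not defn.items:
        out.append(
            Violation("items", "items list is empty", field="items")
        )
    dupes = sorted(
        {it for it in defn.items if list(defn.items).count(it) > 1}
    )
    if dupes:
        out.append(
            Violation(
                "items",
                f"duplicate item(s): {', '.join(dupes)}",
                field="items",
            )
        )
    if defn.kernel not in KERNEL_NAMES:
        out.append(
            Violation(
                "kernel",
                f"unknown kernel {defn.kernel!r} "
                f"(expected one of {KERNEL_NAMES})",
                field="kernel",
            )
        )
    max_na = defn.params.get("max_na")
    if max_na is not None:
        if not isinstance(max_na, (int, np.integer)) or max_na < 0:
            out.append(
                Violation(
                    "parameter",
                    f"max_na must be a non-negative integer, got {max_na!r}",
                    field="max_na",
                )
            )
        elif max_na > len(defn.items):
            out.append(
                Violation(
                    "parameter",
                    f"max_na exceeds item count ({max_na} > "
                    f"{len(defn.items)})",
                    field="max_na",
                )
            )
        if defn.kernel in KERNEL_NAMES and defn.kernel not in KERNELS_WITH_MAX_NA:
            out.append(
                Violation(
                    "parameter",
                    f"kernel {defn.kernel!r} does not accept max_na",
                    field="max_na",
                )
            )
    for param in KERNEL_REQUIRED_PARAMS.get(defn.kernel, ()):
        if param not in defn.params:
            out.append(
                Violation(
                    "parameter",
                    f"kernel {defn.kernel!r} requires parameter {param!r}",
                    field=param,
                )
            )
    conditions = defn.params.get("conditions")
    if conditions is not None:
        for i, cond in enumerate(conditions):
            if not isinstance(cond, ConditionSpec):
                out.append(
                    Violation(
                        "parameter",
                        f"conditions[{i}] is not a ConditionSpec",
                        field="conditions",
                    )
                )
    return out


@dataclass
class Catalog:
    """A collection of score definitions plus table-level configuration.

    Attributes
    ----------
    definitions : dict
        Score-name string -> :class:`ScoreDefinition`, in declaration order.
    groups : dict
        Group identifier (e.g. ``ph_y_bp``) -> ordered member score names;
        groups back the ``_all``-style convenience computations.
    missing_codes : frozenset
        Sentinel item values (refuse/don't-know codes) recoded to missing
        before any kernel runs.  Default: empty.
    id_columns : tuple of str
        Identifier columns expected in every input table.
    norms : dict
        Norm-table identifier -> :class:`NormTable`, referenced by
        t-score definitions via ``norm_ref``.
    """

    definitions: dict[str, ScoreDefinition] = field(default_factory=dict)
    groups: dict[str, list[str]] = field(default_factory=dict)
    missing_codes: frozenset = frozenset()
    id_columns: tuple[str, ...] = ("participant_id", "session_id")
    norms: dict[str, NormTable] = field(default_factory=dict)

    def __post_init__(self):
        self.missing_codes = frozenset(self.missing_codes)
        self.id_columns = tuple(self.id_columns)
        self.groups = {g: list(m) for g, m in self.groups.items()}

    @classmethod
    def from_definitions(
        cls, definitions: Iterable[ScoreDefinition], **kwargs
    ) -> "Catalog":
        defs: dict[str, ScoreDefinition] = {}
        for d in definitions:
            key = d.name.render()
            if key in defs:
                raise SpecificationError(f"duplicate score name {key!r}")
            defs[key] = d
        return cls(definitions=defs, **kwargs)

    def add(self, defn: ScoreDefinition) -> None:
        key = defn.name.render()
        if key in self.definitions:
            raise SpecificationError(f"duplicate score name {key!r}")
        self.definitions[key] = defn

    def __contains__(self, name: str) -> bool:
        return name in self.definitions

    def __getitem__(self, name: str) -> ScoreDefinition:
        return self.definitions[name]

    def score_names(self) -> list[str]:
        return list(self.definitions)

    def group_members(self, group: str) -> list[ScoreDefinition]:
        if group not in self.groups:
            raise SpecificationError(
                f"unknown group {group!r} (available: "
                f"{', '.join(sorted(self.groups)) or 'none'})"
            )
        return [self.definitions[n] for n in self.groups[group]]

    def validate(self) -> list[Violation]:
        """Catalog-closure validation: every definition valid, every group
        member present and prefix-consistent with its group."""
        out: list[Violation] = []
        for name, defn in self.definitions.items():
            for v in validate_definition(defn):
                out.append(
                    Violation(v.kind, f"{name}: {v.message}", field=v.field)
                )
            if defn.kernel == "tscore":
                ref = defn.params.get("norm_ref")
                if ref is not None and ref not in self.norms:
                    out.append(
                        Violation(
                            "norm-ref",
                            f"{name}: norm table {ref!r} not loaded",
                            field="norm_ref",
                        )
                    )
        for group, members in self.groups.items():
            for member in members:
                if member not in self.definitions:
                    out.append(
                        Violation(
                            "group-member",
                            f"group {group!r} member {member!r} has no "
                            "definition",
                            field=group,
                        )
                    )
                elif not member.startswith(group):
                    out.append(
                        Violation(
                            "group-prefix",
                            f"group {group!r} member {member!r} does not "
                            "share the group prefix",
                            field=group,
                        )
                    )
        return out
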