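"""Synthetic-data generators.

Emulates the kinds of tables the engine scores in a cohort study: a
Likert/binary questionnaire subscale with controlled per-row missingness
(the Family Environment Scale cohesion subscale, 9 items), a youth
blood-pressure measure with 3 replicate readings per vital sign, and a
simple longitudinal table for exercising ``make_static``.  All generators
are fully reproducible from their seed.

These fixtures target *behaviors* (missingness handling, grouping,
longitudinal selection), not the marginal distributions or covariance
structure of any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .table import DEFAULT_ID_COLUMNS, ScoreTable

__all__ = [
    "MissingnessPattern",
    "simulate_items",
    "simulate_fes",
    "simulate_bp",
    "simulate_longitudinal",
]

#: Columns of the blood-pressure fixture: 3 replicate measurements each of
#: systolic, diastolic and heart rate.
BP_ITEM_COLUMNS = tuple(
    f"ph_y_bp__{measure}_{i:03d}"
    for measure in ("sys", "dia", "hrate")
    for i in (1, 2, 3)
)

# plausible vitals for 9-12 year olds: mean, sd, floor, ceiling
_BP_RANGES = {
    "sys": (105.0, 10.0, 80, 160),
    "dia": (62.0, 8.0, 40, 110),
    "hrate": (78.0, 10.0, 50, 130),
}


@dataclass(frozen=True)
class MissingnessPattern:
    """Where missing items go: exact per-row counts, or a global rate.

    Exactly one of ``row_counts`` (cycled over rows; each count is placed
    at uniformly chosen item positions) and ``prob`` (independent
    per-cell missingness) should be set.  Neither set means fully
    observed.
    """

    row_counts: tuple[int, ...] | None = None
    prob: float | None = None

    def __post_init__(self):
        if self.row_counts is not None and self.prob is not None:
            raise ConfigurationError(
                "set either row_counts or prob, not both"
            )
        if self.row_counts is not None:
            object.__setattr__(self, "row_counts", tuple(self.row_counts))
            if any(c < 0 for c in self.row_counts):
                raise ConfigurationError("row_counts must be non-negative")
        if self.prob is not None and not 0 <= self.prob <= 1:
            raise ConfigurationError("prob must be in [0, 1]")


def _ids(n_rows: int, session: str = "s01") -> pd.DataFrame:
    return pd.DataFrame(
        {
            DEFAULT_ID_COLUMNS[0]: [f"P{i + 1:04d}" for i in range(n_rows)],
            DEFAULT_ID_COLUMNS[1]: session,
        }
    )


def _apply_missingness(
    values: np.ndarray, pattern: MissingnessPattern | None, rng
) -> np.ndarray:
    if pattern is None:
        return values
    n_rows, n_items = values.shape
    out = values.astype(float)
    if pattern.row_counts is not None:
        if max(pattern.row_counts, default=0) > n_items:
            raise ConfigurationError(
                f"row_counts exceed the item count ({n_items})"
            )
        for i in range(n_rows):
            count = pattern.row_counts[i % len(pattern.row_counts)]
            if count:
                positions = rng.choice(n_items, size=count, replace=False)
                out[i, positions] = np.nan
    else:
        out[rng.random(values.shape) < pattern.prob] = np.nan
    return out


def simulate_items(
    n_rows: int,
    n_items: int = 9,
    levels: Sequence = (0, 1),
    pattern: MissingnessPattern | None = None,
    prefix: str = "fc_p_fes__cohes",
    seed: int = 0,
) -> ScoreTable:
    """Simulate a questionnaire subscale table.

    Produces identifier columns plus item columns ``<prefix>_001`` ...
    ``_NNN`` (zero-padded, 3 digits) with values drawn uniformly from
    ``levels`` and missingness placed per ``pattern``.
    """
    if n_rows <= 0 or n_items <= 0:
        raise ConfigurationError("n_rows and n_items must be positive")
    rng = np.random.default_rng(seed)
    values = rng.choice(np.asarray(list(levels)), size=(n_rows, n_items))
    values = _apply_missingness(values.astype(float), pattern, rng)
    frame = _ids(n_rows)
    for j in range(n_items):
        frame[f"{prefix}_{j + 1:03d}"] = values[:, j]
    return ScoreTable(frame)


#: Default per-row missing-item counts of the FES preset, cycled over
#: rows: the third row carries 2 missing items, so the cohesion mean is
#: missing there under the default bound (max_na=1) and computed once the
#: bound is raised to 2.
FES_PATTERN = (0, 1, 2, 0, 0)


def simulate_fes(n_rows: int = 5, seed: int = 0) -> ScoreTable:
    """The 9-item binary cohesion-subscale fixture with the standard
    per-row missingness pattern (:data:`FES_PATTERN`)."""
    return simulate_items(
        n_rows,
        n_items=9,
        levels=(0, 1),
        pattern=MissingnessPattern(row_counts=FES_PATTERN),
        prefix="fc_p_fes__cohes",
        seed=seed,
    )


def simulate_bp(
    n_rows: int = 10, seed: int = 0, p_missing: float = 0.0
) -> ScoreTable:
    """Simulate a youth blood-pressure table.

    Three replicate readings each of systolic pressure, diastolic pressure
    (mmHg) and heart rate (bpm), in plausible pediatric ranges; replicates
    vary around a per-participant level.  ``p_missing`` places independent
    per-cell missingness (default fully observed).
    """
    if n_rows <= 0:
        raise ConfigurationError("n_rows must be positive")
    rng = np.random.default_rng(seed)
    frame = _ids(n_rows)
    for measure, (mu, sd, lo, hi) in _BP_RANGES.items():
        level = rng.normal(mu, sd, size=n_rows)
        for i in (1, 2, 3):
            reading = np.clip(np.round(level + rng.normal(0, 3, n_rows)), lo, hi)
            frame[f"ph_y_bp__{measure}_{i:03d}"] = reading
    if p_missing:
        pattern = MissingnessPattern(prob=p_missing)
        cols = list(BP_ITEM_COLUMNS)
        frame[cols] = _apply_missingness(
            frame[cols].to_numpy(dtype=float), pattern, rng
        )
    return ScoreTable(frame)


def simulate_longitudinal(
    n_participants: int = 5,
    events: Sequence[str] = ("ses-00a", "ses-01a", "ses-02a"),
    seed: int = 0,
) -> ScoreTable:
    """Simulate a participant x event longitudinal table.

    One row per participant and event.  ``height`` varies by event (it
    grows), and ``hand_pref`` is a trait observed only at a random single
    event per participant — the natural target for ``make_static``.
    """
    if n_participants <= 0 or not list(events):
        raise ConfigurationError(
            "n_participants and events must be non-empty"
        )
    rng = np.random.default_rng(seed)
    events = list(events)
    part = [f"P{i + 1:04d}" for i in range(n_participants)]
    rows = []
    for i, p in enumerate(part):
        base_height = rng.normal(140.0, 8.0)
        observed_at = int(rng.integers(len(events)))
        pref = rng.choice(["right", "left", "mixed"])
        for e_idx, event in enumerate(events):
            rows.append(
                {
                    DEFAULT_ID_COLUMNS[0]: p,
                    DEFAULT_ID_COLUMNS[1]: event,
                    "height": round(base_height + 5.5 * e_idx + rng.normal(0, 1), 1),
                    "hand_pref": pref if e_idx == observed_at else None,
                }
            )
    frame = pd.DataFrame(rows)
    return ScoreTable(frame, event_order=tuple(events))
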