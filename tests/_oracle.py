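"""Naive per-row reference implementations of the scoring kernels.

Pure-Python loops over lists, with ``None`` for missing — deliberately
independent of the vectorized pandas implementations they check.
"""

from __future__ import annotations


def observed(v):
    return [x for x in v if x is not None]


def o_nm(v):
    return sum(1 for x in v if x is None)


def _gated(v, max_na):
    obs = observed(v)
    nm = len(v) - len(obs)
    return obs if nm <= max_na and obs else None


def o_mean(v, max_na):
    obs = _gated(v, max_na)
    return None if obs is None else sum(obs) / len(obs)


def o_sum(v, max_na):
    obs = _gated(v, max_na)
    return None if obs is None else sum(obs)


def o_prsum(v, max_na):
    obs = _gated(v, max_na)
    if obs is None:
        return None
    return sum(obs) * len(v) / len(obs)


def o_max(v, max_na):
    obs = _gated(v, max_na)
    return None if obs is None else max(obs)


def o_mean_pos(v):
    pos = [x for x in observed(v) if x > 0]
    return sum(pos) / len(pos) if pos else None


def o_count(v, targets):
    obs = observed(v)
    if not obs:
        return None
    return sum(1 for x in obs if x in targets)


def o_count_cond(row, conditions):
    """row: dict column -> value (None = missing)."""
    total = 0
    for cond in conditions:
        value = row[cond.column]
        if value is None:
            if cond.missing_policy == "missing-propagates":
                return None
            continue
        ref = cond.reference
        op = cond.comparator
        hit = {
            "==": lambda: value == ref,
            "!=": lambda: value != ref,
            "<": lambda: value < ref,
            "<=": lambda: value <= ref,
            ">": lambda: value > ref,
            ">=": lambda: value >= ref,
            "in": lambda: value in ref,
            "not-in": lambda: value not in ref,
        }[op]()
        total += int(hit)
    return total
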