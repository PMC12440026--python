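"""The hierarchical score-naming grammar.

Summary scores in the tabulated cohort-data convention are named

    <domain>_<respondent>_<table>(__<scale_segment>)*_<suffix>

e.g. ``fc_p_fes__cohes_mean`` — the mean of the Family Environment Scale
(parent report) cohesion-subscale items — or ``ph_y_bp__sys_nm`` — the
number of missing systolic blood-pressure replicates.  Single underscores
separate the domain / respondent / table / suffix tokens; each *double*
underscore introduces one scale-path segment (subscales nest:
``..__a__b_mean`` has scale path ``[a, b]``).

:func:`parse_score_name` and :meth:`ScoreName.render` are exact inverses:
``render(parse(s)) == s`` for every valid name string.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import NameParseError

#: The seven research-domain codes: general, family/friends/community,
#: mental health, neurocognition, novel technologies, physical health,
#: substance use.
DOMAIN_CODES = frozenset({"ab", "fc", "mh", "nc", "nt", "ph", "su"})

#: Score-type suffixes with built-in kernel semantics.  Catalogs may
#: declare additional suffixes for custom kernels.
STANDARD_SUFFIXES = frozenset(
    {"mean", "sum", "nm", "count", "max", "prsum", "tscore"}
)

_TOKEN = re.compile(r"^[a-z0-9]+$")


def _check_token(token: str, role: str, raw: str) -> str:
    if not _TOKEN.match(token):
        shown = token if token else "<empty>"
        raise NameParseError(
            f"malformed score name {raw!r}: {role} segment {shown!r} is not "
            "a lowercase alphanumeric token"
        )
    return token


@dataclass(frozen=True)
class ScoreName:
    """Parsed representation of a score name.

    Attributes
    ----------
    domain : str
        One of the seven domain codes (:data:`DOMAIN_CODES`).
    respondent : str
        Who answered the instrument, e.g. ``p`` (parent) or ``y`` (youth).
    table : str
        Database-table code, e.g. ``fes`` or ``bp``.
    scale_path : tuple of str
        Scale/subscale segments, outermost first; may be empty.
    suffix : str
        Score-type suffix, e.g. ``mean``, ``nm``.
    """

    domain: str
    respondent: str
    table: str
    scale_path: tuple[str, ...] = field(default=())
    suffix: str = "mean"

    def __post_init__(self):
        raw = self.render_unchecked()
        if self.domain not in DOMAIN_CODES:
            raise NameParseError(
                f"malformed score name {raw!r}: unknown domain code "
                f"{self.domain!r} (expected one of {sorted(DOMAIN_CODES)})"
            )
        _check_token(self.respondent, "respondent", raw)
        _check_token(self.table, "table", raw)
        for seg in self.scale_path:
            _check_token(seg, "scale-path", raw)
        _check_token(self.suffix, "suffix", raw)
        object.__setattr__(self, "scale_path", tuple(self.scale_path))

    def render_unchecked(self) -> str:
        head = f"{self.domain}_{self.respondent}_{self.table}"
        scales = "".join(f"__{seg}" for seg in self.scale_path)
        return f"{head}{scales}_{self.suffix}"

    def render(self) -> str:
        """Serialize back to the canonical name string."""
        return self.render_unchecked()

    def with_suffix(self, suffix: str) -> "ScoreName":
        """Sibling score with a different suffix (e.g. the ``nm`` companion)."""
        return ScoreName(
            self.domain, self.respondent, self.table, self.scale_path, suffix
        )

    @property
    def table_prefix(self) -> str:
        """The ``domain_respondent_table`` prefix shared by a table's scores."""
        return f"{self.domain}_{self.respondent}_{self.table}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_score_name(raw: str) -> ScoreName:
    """Parse a score-name string into its components.

    Raises
    ------
    NameParseError
        If the name violates the grammar; the message names the offending
        segment.
    """
    if not isinstance(raw, str) or not raw:
        raise NameParseError("malformed score name: empty or not a string")
    chunks = raw.split("__")
    head = chunks[0].split("_")
    if chunks[1:]:
        # scale-path form: head is exactly domain_respondent_table; the
        # final chunk is "<segment>_<suffix>".
        if len(head) != 3:
            raise NameParseError(
                f"malformed score name {raw!r}: expected "
                "'domain_respondent_table' before the first '__', got "
                f"{chunks[0]!r}"
            )
        domain, respondent, table = head
        tail = chunks[-1].rsplit("_", 1)
        if len(tail) != 2:
            raise NameParseError(
                f"malformed score name {raw!r}: final segment {chunks[-1]!r} "
                "lacks a '_<suffix>'"
            )
        segments = list(chunks[1:-1]) + [tail[0]]
        for seg in segments:
            if "_" in seg:
                raise NameParseError(
                    f"malformed score name {raw!r}: scale-path segment "
                    f"{seg!r} contains a single underscore"
                )
        suffix = tail[1]
        scale_path = tuple(segments)
    else:
        # flat form: domain_respondent_table_suffix
        if len(head) != 4:
            raise NameParseError(
                f"malformed score name {raw!r}: expected exactly "
                "'domain_respondent_table_suffix', got "
                f"{len(head)} single-underscore tokens"
            )
        domain, respondent, table, suffix = head
        scale_path = ()
    return ScoreName(domain, respondent, table, scale_path, suffix)
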