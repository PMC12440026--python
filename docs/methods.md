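# Methods

## Scope and design

scorekit separates *what a score is* from *how it is computed*. A
`ScoreDefinition` declares a score's items, kernel and parameters; a
`Catalog` collects definitions plus table-level configuration (identifier
columns, sentinel missing codes, score groups, norm tables); the engine
(`compute_score` / `compute_group`) validates, recodes sentinels, runs the
kernel and emits the score column(s). Every scoring run follows
validate → compute → return: validation collects *all* violations into a
structured report (machine-readable `kind` + message) and raises once, so a
catalog-scale run surfaces every problem in one pass rather than failing
piecemeal.

The calling contract is `(data, name, combine)`: `data` is the input
table, `name` overrides the output column (default: the score's own name),
and `combine=True` (default) appends the score to the input while
`combine=False` returns identifier columns plus the score only — the two
are join-consistent by construction and tested as such.

## The naming grammar

`<domain>_<respondent>_<table>(__<scale_segment>)*_<suffix>` with a
seven-code domain vocabulary (`ab`, `fc`, `mh`, `nc`, `nt`, `ph`, `su`).
Exactly one double underscore introduces each scale segment; the suffix is
the final single-underscore token. Parsing and rendering are exact
inverses (property-tested). This grammar is the one consistent with every
published score name the package emulates; suffixes beyond
{mean, sum, nm, count, max, prsum, tscore} can be declared by catalogs.

## Kernels and missing-data contracts

For a row with `n` items and `nm` missing:

| kernel | value | missing when |
|---|---|---|
| `ss_mean` | mean of observed | `nm > max_na` or all missing |
| `ss_sum` | sum of observed (no proration) | same |
| `ss_prsum` | `Σobs · n/(n − nm)` | same |
| `ss_max` | max of observed | same |
| `ss_nm` | `nm` | never |
| `ss_mean_pos` | mean of observed values > 0 | no positive observed value |
| `ss_count` | #observed in target set | all items missing |
| `ss_count_cond` | #conditions true | a condition with `missing-propagates` hits a missing value |
| `ss_tscore` | exact lookup (stratum, raw) → t | raw missing |

Choices the published material leaves open, fixed here once:

- **All-missing rows are always missing** for value-producing kernels,
  even when `max_na ≥ n`: a score from zero items is 0/0.
- **`ss_prsum`** uses the standard psychometric proration factor
  `n/(n − nm)` on the observed sum. At `nm = 0` the kernel returns the
  plain sum unmultiplied, so `ss_prsum == ss_sum` holds *exactly* in
  floating point, not merely to rounding.
- **`ss_mean_pos`** means over observed values strictly greater than
  zero; zeros and negatives are excluded. This is a stand-in semantics
  isolated behind the kernel interface.
- **`ss_count`** treats partially missing rows as countable (missing
  items contribute 0), so counts are lower bounds; it takes no `max_na`.
  `ss_max` does take `max_na`.
- **`ss_tscore`** is exact lookup only — no interpolation — and norms are
  always user-supplied (normative tables for the emulated instruments are
  proprietary and do not ship). An out-of-domain raw score is an error
  naming the raw value and stratum, not a silent missing.
- **No rounding anywhere**; consumers format.
- `max_na` must satisfy `0 ≤ max_na ≤ n`; anything else is a parameter
  error echoing the bound.

Invariants under test: `nm + #observed = n` (conservation); raising
`max_na` never changes a computed value and only converts missing →
computed (monotonicity); mean/sum scale equivariance on fully observed
rows; and equivalence of every vectorized kernel with a naive per-row
Python loop on randomized inputs.

## Transforms

- `recode_levels`: mapped values replaced (map to `None` for missing);
  unmapped values follow `default` ∈ {keep, missing}; missing stays
  missing.
- `combine_cols`: positional coalesce — the first column wins where both
  are observed. Conflicting observed values are counted and logged, not
  raised, because the common use is merging mutually exclusive
  branching-logic columns where conflicts indicate upstream issues worth a
  warning, not a crash.
- `combine_levels`: collapses categories by disjoint groups; overlap is a
  specification error.
- `make_static`: default rule is **first observed by event order** —
  the earliest study event at which the variable is observed supplies the
  per-participant constant; `rule="baseline"` restricts selection to the
  first event in the order (missing if unobserved there). The default was
  chosen because traits collected once per participant are administered at
  different events for different participants; it is idempotent and
  row-preserving by construction.

## Sentinel missing codes and identifiers

Numeric response codes meaning "refused"/"don't know" are catalog-level
configuration (`missing_codes`, default empty) recoded to missing on the
kernel's working copy only — the raw item columns pass through to the
output unchanged. Identifier columns default to
`(participant_id, session_id)` and are configurable per catalog.

## The shipped catalog

Exemplars only: the Family Environment Scale (parent) cohesion and
conflict subscale means (9 items each, `max_na = 1`), the youth
blood-pressure group (3 replicate readings each of systolic, diastolic,
heart rate; means with `max_na = 1`, i.e. a score from ≥ 2 of 3
replicates), and one mental-health exemplar, the emotion-regulation
attunement subscale mean (5 items — the item count is this package's
choice of a plausible short subscale; the emulated release's count is not
public in the material used). Mean-type scores carry `_nm` companions,
emitted immediately after their parent.

## Synthetic data

The generators state a fixed world; they target *behaviors*, not any real
cohort's distributions:

- `simulate_items` / `simulate_fes`: binary {0,1} items (true/false-style
  family-environment questions), item columns `<prefix>_001…_NNN`.
  Missingness is either an exact per-row count pattern (counts cycled over
  rows, positions uniform) or i.i.d. per-cell with probability `p`. The
  FES preset cycles per-row missing counts `(0, 1, 2, 0, 0)` so every
  fifth-row block contains one row with two missing items — the case that
  distinguishes `max_na = 1` from `max_na = 2`.
- `simulate_bp`: per-participant vital level (systolic ~ N(105, 10²) mmHg,
  diastolic ~ N(62, 8²) mmHg, heart rate ~ N(78, 10²) bpm — plausible for
  9–12-year-olds) plus N(0, 3²) replicate noise, rounded to integers and
  clipped to physiologic ranges; fully observed by default.
- `simulate_longitudinal`: one row per participant × event; `height`
  grows across events, `hand_pref` is observed at exactly one random event
  per participant (the natural `make_static` target).

All generators are deterministic given their seed. A green test on these
fixtures establishes the engine's contracts (missingness handling,
naming, grouping, ordering); it does not establish anything about real
cohort data, real norms, or instrument psychometrics.

## Numerical and degenerate-input choices

- Kernel arithmetic is float64 pandas; counts are nullable integers
  (`Int64`) so a missing count is representable without casting to float.
- Output column-name collisions are errors, not overwrites — protects
  release reproducibility.
- An empty score group computes nothing and logs a warning.
- CSV dialect is fixed: comma-separated, UTF-8, header row, empty string
  = missing. CLI and programmatic runs produce byte-identical outputs.
- Provenance: every result carries a 16-hex-digit content hash of the
  executed definition plus the effective parameter values.

## Known limitations

- Only exemplar scores ship; the full instrument catalogs of any real
  release must be authored as catalog files.
- Proprietary-norm instruments (e.g. ASEBA-style raw→t conversion) are out
  of scope; `ss_tscore` provides the mechanism once a user supplies norms.
- Timeline-followback-style interview scoring is out of scope.
- `ss_tscore` matches raw scores exactly; real half-point or banded norm
  tables must be expanded to explicit entries by the user.
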