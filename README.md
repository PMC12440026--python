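# scorekit

Catalog-driven computation of assessment **summary scores** from tabulated
cohort-study data.

Longitudinal cohort studies collect hundreds of questionnaires, interviews
and physical measures as item-level columns (`fc_p_fes__cohes_001` …
`_009`, three replicate blood-pressure readings, …). Analyses work with
*summary scores* — means, sums, counts, prorated sums, normative t-scores —
derived from those items under explicit missing-data rules. scorekit is for
data teams and researchers who need those scores computed reproducibly:
scores are *declared* in a catalog (items + kernel + parameters) and a
small engine executes them, so the scoring algorithm for every released
variable is inspectable and re-runnable.

## The model

A score is a row-wise aggregation of an item vector
x = (x₁, …, xₙ) with *nm* = #missing items and a tolerance `max_na`:

- `ss_mean` / `ss_sum` / `ss_max`: mean / sum / max of the observed items if
  `nm ≤ max_na` (and at least one item observed), otherwise missing;
- `ss_prsum`: prorated sum `Σ observed · n/(n − nm)` — the standard
  psychometric estimate of the full-scale sum under partial missingness;
- `ss_nm`: *nm* itself (the companion `*_nm` score released next to most
  means and sums);
- `ss_count`: number of observed items in a target level set;
- `ss_count_cond`: number of user-defined row-level conditions that hold;
- `ss_mean_pos`: mean of the observed items > 0;
- `ss_tscore`: exact normative table lookup (stratum, raw) → t-score.

Four column transforms support curation around scoring: `recode_levels`,
`combine_cols` (coalesce, first wins), `combine_levels` (collapse
categories) and `make_static` (propagate a participant's first observed
value across study events). Score names follow the hierarchical grammar
`<domain>_<respondent>_<table>(__<scale>)*_<suffix>`, e.g.
`ph_y_bp__sys_mean`.

## Worked example

```python
import scorekit as sk

table = sk.simulate_fes(5, seed=7)          # 9 binary cohesion items
cat = sk.default_catalog()
res = sk.compute_score(table, cat["fc_p_fes__cohes_mean"], catalog=cat)
print(res.data[["participant_id", "fc_p_fes__cohes_mean",
                "fc_p_fes__cohes_nm"]])
```

```
participant_id  fc_p_fes__cohes_mean  fc_p_fes__cohes_nm
         P0001              0.777778                   0
         P0002              0.500000                   1
         P0003                   NaN                   2
         P0004              0.777778                   0
         P0005              0.555556                   0
```

The score column is appended under the score's own name; `*_nm` records how
many items were missing per row. P0003 has 2 missing items, which exceeds
the catalog default `max_na = 1`, so its mean is missing. Relaxing the
bound computes that row and changes nothing else:

```python
res2 = sk.compute_score(table, cat["fc_p_fes__cohes_mean"],
                        catalog=cat, max_na=2)
# P0003 -> 0.285714 (mean of its 7 observed items); other rows unchanged
```

Group computation mirrors the `_all`-style convenience functions: the youth
blood-pressure group scores three replicate readings each of systolic,
diastolic and heart rate into 6 columns (`ph_y_bp__sys_mean`,
`ph_y_bp__sys_nm`, `ph_y_bp__dia_mean`, `ph_y_bp__dia_nm`,
`ph_y_bp__hrate_mean`, `ph_y_bp__hrate_nm`):

```python
bp = sk.simulate_bp(50, seed=1)
sk.compute_group(bp, cat, "ph_y_bp", combine=False).score_columns
```

The same is available from a shell:

```sh
scorekit simulate --preset bp --n 50 --seed 1 --output bp.csv
scorekit compute --input bp.csv --group ph_y_bp --output scores.csv
scorekit list
```

## Acceptance script

`scripts/acceptance.py` regenerates the blood-pressure fixture with
`simulate_bp`, runs the `ph_y_bp` catalog group with `combine=False`, and
writes the number of score columns produced to JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the scoring kernels, their missing-data
contracts, the synthetic-data generators and the package's numerical and
design choices in detail.
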