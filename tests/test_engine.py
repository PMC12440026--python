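"""Engine: the data/name/combine contract, validation, groups."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scorekit import (
    Catalog,
    NormTable,
    ScoreDefinition,
    SpecificationError,
    ValidationFailure,
    compute_group,
    compute_score,
    simulate_bp,
    simulate_items,
    validate_input,
    MissingnessPattern,
)


def test_defaults_append_single_named_column(fes_frame, catalog):
    defn = catalog["fc_p_fes__cohes_mean"]
    res = compute_score(fes_frame, defn, catalog=catalog)
    assert list(res.data.columns) == list(fes_frame.columns) + [
        "fc_p_fes__cohes_mean",
        "fc_p_fes__cohes_nm",
    ]
    # default max_na = 1: row with 2 missing items is not computed
    assert list(res.data["fc_p_fes__cohes_nm"]) == [0, 1, 2, 0]
    assert pd.isna(res.data["fc_p_fes__cohes_mean"].iloc[2])
    assert res.data["fc_p_fes__cohes_mean"].iloc[0] == pytest.approx(6 / 9)


def test_name_override_changes_column_not_values(fes_frame, catalog):
    defn = catalog["fc_p_fes__cohes_mean"]
    default = compute_score(fes_frame, defn, catalog=catalog)
    renamed = compute_score(fes_frame, defn, name="my_score", catalog=catalog)
    assert "my_score" in renamed.data.columns
    assert "fc_p_fes__cohes_mean" not in renamed.data.columns
    pd.testing.assert_series_equal(
        renamed.data["my_score"],
        default.data["fc_p_fes__cohes_mean"],
        check_names=False,
    )


def test_raising_max_na_computes_previously_missing_row(fes_frame, catalog):
    """The Fig-2-style customization: max_na 1 -> 2 fills in the 2-missing
    row and changes nothing else."""
    defn = catalog["fc_p_fes__cohes_mean"]
    strict = compute_score(fes_frame, defn, catalog=catalog)
    relaxed = compute_score(fes_frame, defn, catalog=catalog, max_na=2)
    s = strict.data["fc_p_fes__cohes_mean"]
    r = relaxed.data["fc_p_fes__cohes_mean"]
    assert pd.isna(s.iloc[2]) and not pd.isna(r.iloc[2])
    assert r.iloc[2] == pytest.approx(5 / 7)
    pd.testing.assert_series_equal(s.drop(index=2), r.drop(index=2))


def test_missing_item_column_error_names_it(fes_frame, catalog):
    broken = fes_frame.drop(columns=["fc_p_fes__cohes_004"])
    with pytest.raises(ValidationFailure, match="fc_p_fes__cohes_004"):
        compute_score(broken, catalog["fc_p_fes__cohes_mean"], catalog=catalog)


def test_validate_input_reports_all_violations(fes_frame, catalog):
    defn = catalog["fc_p_fes__cohes_mean"]
    assert validate_input(fes_frame, defn, catalog) == []
    broken = fes_frame.drop(columns=["fc_p_fes__cohes_004"]).copy()
    broken["fc_p_fes__cohes_001"] = "often"
    report = validate_input(broken, defn, catalog)
    kinds = {v.kind for v in report}
    assert kinds == {"missing-column", "type"}


def test_name_collision_is_error(fes_frame, catalog):
    defn = catalog["fc_p_fes__cohes_mean"]
    res = compute_score(fes_frame, defn, catalog=catalog)
    with pytest.raises(SpecificationError, match="already present") as err:
        compute_score(res.data, defn, catalog=catalog)
    assert err.value.kind == "name-collision"


def test_sentinel_missing_codes_recoded_before_kernel(fes_frame, catalog):
    coded = fes_frame.copy()
    # refuse-to-answer code in an otherwise complete row
    coded.loc[0, "fc_p_fes__cohes_001"] = 777.0
    defn = catalog["fc_p_fes__cohes_mean"]
    res = compute_score(coded, defn, catalog=catalog, missing_codes={777})
    assert res.data["fc_p_fes__cohes_nm"].iloc[0] == 1
    assert res.data["fc_p_fes__cohes_mean"].iloc[0] == pytest.approx(5 / 8)
    # the raw input column is not mutated in the combined output
    assert res.data["fc_p_fes__cohes_001"].iloc[0] == 777.0


def test_combine_false_returns_ids_plus_scores(fes_frame, catalog):
    defn = catalog["fc_p_fes__cohes_mean"]
    res = compute_score(fes_frame, defn, combine=False, catalog=catalog)
    assert list(res.data.columns) == [
        "participant_id",
        "session_id",
        "fc_p_fes__cohes_mean",
        "fc_p_fes__cohes_nm",
    ]


def test_combine_consistency_join(fes_frame, catalog):
    """Joining the combine=False output onto the input equals combine=True."""
    defn = catalog["fc_p_fes__cohes_mean"]
    combined = compute_score(fes_frame, defn, catalog=catalog).data
    separate = compute_score(
        fes_frame, defn, combine=False, catalog=catalog
    ).data
    joined = fes_frame.merge(
        separate, on=["participant_id", "session_id"], how="left"
    )
    pd.testing.assert_frame_equal(joined, combined)


def test_determinism(fes_frame, catalog):
    defn = catalog["fc_p_fes__cohes_mean"]
    a = compute_score(fes_frame, defn, catalog=catalog).data
    b = compute_score(fes_frame, defn, catalog=catalog).data
    pd.testing.assert_frame_equal(a, b)


def test_provenance_records_hash_and_params(fes_frame, catalog):
    res = compute_score(
        fes_frame, catalog["fc_p_fes__cohes_mean"], catalog=catalog, max_na=2
    )
    prov = res.provenance["fc_p_fes__cohes_mean"]
    assert prov["params"]["max_na"] == 2
    assert prov["kernel"] == "mean"
    assert len(prov["definition_hash"]) == 16


class TestComputeGroup:
    def test_bp_group_emits_six_scores_in_order(self, catalog):
        table = simulate_bp(8, seed=3)
        res = compute_group(table, catalog, "ph_y_bp", combine=False)
        assert res.score_columns == [
            "ph_y_bp__sys_mean",
            "ph_y_bp__sys_nm",
            "ph_y_bp__dia_mean",
            "ph_y_bp__dia_nm",
            "ph_y_bp__hrate_mean",
            "ph_y_bp__hrate_nm",
        ]
        non_id = [
            c
            for c in res.data.columns
            if c not in ("participant_id", "session_id")
        ]
        assert len(non_id) == 6

    def test_group_equals_fold_of_single_scores(self, catalog):
        table = simulate_items(
            12,
            n_items=9,
            pattern=MissingnessPattern(row_counts=(0, 1, 2)),
            prefix="fc_p_fes__cohes",
            seed=5,
        )
        frame = table.data.copy()
        confl = simulate_items(
            12,
            n_items=9,
            pattern=MissingnessPattern(row_counts=(1, 0)),
            prefix="fc_p_fes__confl",
            seed=6,
        )
        for c in confl.data.columns:
            if c.startswith("fc_p_fes__confl"):
                frame[c] = confl.data[c]
        grouped = compute_group(frame, catalog, "fc_p_fes").data
        folded = frame
        for member in catalog.groups["fc_p_fes"]:
            folded = compute_score(
                folded, catalog[member], catalog=catalog
            ).data
        pd.testing.assert_frame_equal(grouped, folded)

    def test_unknown_group_lists_available(self, catalog):
        with pytest.raises(SpecificationError, match="ph_y_bp"):
            compute_group(simulate_bp(3), catalog, "nope")

    def test_empty_group_warns_and_adds_nothing(self, catalog, caplog):
        cat = Catalog.from_definitions(
            catalog.definitions.values(), groups={"ph_y_bp": []}
        )
        table = simulate_bp(3, seed=0)
        with caplog.at_level("WARNING", logger="scorekit"):
            res = compute_group(table, cat, "ph_y_bp")
        assert "empty" in caplog.text
        assert res.score_columns == []
        pd.testing.assert_frame_equal(res.data, table.data)

    def test_row_preservation(self, catalog):
        table = simulate_bp(20, seed=7)
        res = compute_group(table, catalog, "ph_y_bp")
        assert len(res.data) == 20
        pd.testing.assert_frame_equal(
            res.data[["participant_id", "session_id"]],
            table.data[["participant_id", "session_id"]],
        )


def test_tscore_definition_through_engine():
    norms = NormTable(
        pd.DataFrame({"raw": [0.0, 1.0, 2.0], "t": [40.0, 50.0, 60.0]})
    )
    defn = ScoreDefinition(
        "mh_y_scale__anx_tscore",
        ("mh_y_scale__anx_sum",),
        "tscore",
        {"norm_ref": norms},
        nm_companion=False,
    )
    frame = pd.DataFrame(
        {
            "participant_id": ["P1", "P2", "P3"],
            "session_id": "s01",
            "mh_y_scale__anx_sum": [0.0, 2.0, np.nan],
        }
    )
    res = compute_score(frame, defn)
    out = res.data["mh_y_scale__anx_tscore"]
    assert list(out[:2]) == [40.0, 60.0]
    assert pd.isna(out.iloc[2])


def test_count_cond_definition_through_engine():
    from scorekit import ConditionSpec

    defn = ScoreDefinition(
        "su_y_use__any_count",
        ("su_y_use__alc", "su_y_use__nic"),
        "count_cond",
        {
            "conditions": [
                ConditionSpec("su_y_use__alc", ">", 0),
                ConditionSpec("su_y_use__nic", ">", 0),
            ]
        },
        nm_companion=False,
    )
    frame = pd.DataFrame(
        {
            "participant_id": ["P1", "P2"],
            "session_id": "s01",
            "su_y_use__alc": [1.0, 0.0],
            "su_y_use__nic": [2.0, np.nan],
        }
    )
    res = compute_score(frame, defn)
    assert list(res.data["su_y_use__any_count"]) == [2, 0]


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    seed=st.integers(0, 2**20),
    max_na=st.integers(0, 9),
    n_rows=st.integers(1, 15),
)
def test_engine_matches_direct_kernel(seed, max_na, n_rows, catalog):
    """compute_score is a thin, faithful wrapper over the kernel."""
    from scorekit import ss_mean

    table = simulate_items(
        n_rows,
        n_items=9,
        pattern=MissingnessPattern(prob=0.2),
        seed=seed,
    )
    defn = catalog["fc_p_fes__cohes_mean"]
    res = compute_score(table, defn, catalog=catalog, max_na=max_na)
    direct = ss_mean(table.data[list(defn.items)], max_na)
    pd.testing.assert_series_equal(
        res.data["fc_p_fes__cohes_mean"], direct, check_names=False
    )
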