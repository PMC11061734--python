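import json

import numpy as np
import pytest

from goafs.preprocess import (
    RULE_MEAN,
    RULE_MODE,
    ImputationError,
    ImputationPlan,
    before_after_report,
    default_rules,
    fit_imputer,
    impute,
)
from goafs.schema import missingness_report
from goafs.synthetic import default_spec, generate, inject_missing

from conftest import build_dataset


def test_default_rule_assignment_follows_feature_kind(schema):
    rules = default_rules(schema)
    mean_feats = {n for n, r in rules.items() if r == RULE_MEAN}
    assert mean_feats == {"Age", "Trestbps", "Chol", "Fbs", "Thalach", "OldPeak"}
    assert all(rules[n] == RULE_MODE
               for n in ("Sex", "CP", "Restecg", "Exang", "Slope", "Ca", "Thal"))


class TestFit:
    def test_numeric_mean_fill(self):
        ds = build_dataset(n=3, overrides={"Chol": [205.0, 0.0, 207.0]},
                           missing={"Chol": [False, True, False]},
                           labels=[1, 1, 1])
        plan = fit_imputer(ds, similarity="global")
        assert plan.global_values["Chol"] == 206.0

    def test_nominal_mode_fill(self):
        ds = build_dataset(n=4, overrides={"Thal": [3, 3, 3, 6]},
                           missing={"Thal": [False, False, True, False]},
                           labels=[0, 0, 0, 0])
        plan = fit_imputer(ds, similarity="global")
        assert plan.global_values["Thal"] == 3.0

    def test_per_label_groups_get_distinct_fills(self):
        # label 0 rows observe {101}, label 1 rows observe {109, 109}
        ds = build_dataset(
            n=5,
            overrides={"Trestbps": [101.0, 0.0, 109.0, 109.0, 0.0]},
            missing={"Trestbps": [False, True, False, False, True]},
            labels=[0, 0, 1, 1, 1],
        )
        plan = fit_imputer(ds)
        assert plan.group_values["Trestbps"][0] == 101.0
        assert plan.group_values["Trestbps"][1] == 109.0
        out = impute(ds, plan)
        j = ds.schema.index("Trestbps")
        assert out.values[1, j] == 101.0
        assert out.values[4, j] == 109.0

    def test_mode_tie_broken_by_lowest_code(self):
        ds = build_dataset(n=5, overrides={"Slope": [3, 3, 1, 1, 2]},
                           missing={"Slope": [False] * 4 + [True]},
                           labels=[0, 0, 0, 0, 0])
        plan = fit_imputer(ds, similarity="global")
        assert plan.global_values["Slope"] == 1.0

    def test_fully_unobserved_feature_is_an_error(self):
        ds = build_dataset(n=2, missing={"Ca": [True, True]})
        with pytest.raises(ImputationError, match="Ca"):
            fit_imputer(ds)

    def test_rule_overrides_validated(self):
        ds = build_dataset(n=2)
        with pytest.raises(ImputationError):
            fit_imputer(ds, plan_overrides={"Nope": RULE_MEAN})


class TestImpute:
    def test_clean_dataset_unchanged(self):
        ds = build_dataset(n=3)
        out = impute(ds, fit_imputer(ds))
        np.testing.assert_array_equal(out.values, ds.values)
        assert out.n_missing == 0

    def test_completeness_on_injected_missingness(self):
        ds = inject_missing(generate(default_spec(seed=1), 200), 0.15, seed=2)
        assert ds.n_missing > 0
        out = impute(ds, fit_imputer(ds))
        rep = missingness_report(out)
        assert (rep["missing"] == 0).all()

    def test_idempotence(self):
        ds = inject_missing(generate(default_spec(seed=3), 100), 0.2, seed=4)
        plan = fit_imputer(ds)
        once = impute(ds, plan)
        twice = impute(once, plan)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_observed_cells_untouched(self):
        ds = inject_missing(generate(default_spec(seed=5), 100), 0.2, seed=6)
        out = impute(ds, fit_imputer(ds))
        obs = ~ds.missing
        np.testing.assert_array_equal(out.values[obs], ds.values[obs])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_numeric_fills_within_observed_group_range(self, seed):
        ds = inject_missing(generate(default_spec(seed=seed), 150), 0.25,
                            seed=seed + 10)
        plan = fit_imputer(ds)
        out = impute(ds, plan)
        for j, desc in enumerate(ds.schema.features):
            for g in (0, 1):
                sel = ~ds.missing[:, j] & (ds.labels == g)
                if not sel.any():
                    continue
                lo, hi = ds.values[sel, j].min(), ds.values[sel, j].max()
                filled = ds.missing[:, j] & (ds.labels == g)
                assert ((out.values[filled, j] >= lo)
                        & (out.values[filled, j] <= hi)).all(), desc.name

    def test_nominal_fills_are_valid_codes(self):
        ds = inject_missing(generate(default_spec(seed=7), 120), 0.3, seed=8)
        out = impute(ds, fit_imputer(ds))
        for j, desc in enumerate(ds.schema.features):
            if desc.kind != "nominal":
                continue
            assert all(v in desc.categories for v in out.values[ds.missing[:, j], j])

    def test_knn_similarity_completes_the_table(self):
        ds = inject_missing(generate(default_spec(seed=9), 60), 0.2, seed=10)
        out = impute(ds, fit_imputer(ds, similarity="knn", k=3))
        assert out.n_missing == 0
        obs = ~ds.missing
        np.testing.assert_array_equal(out.values[obs], ds.values[obs])


def test_plan_json_round_trip():
    ds = inject_missing(generate(default_spec(seed=11), 80), 0.1, seed=12)
    plan = fit_imputer(ds)
    back = ImputationPlan.from_json(plan.to_json())
    assert back.rules == plan.rules
    assert back.global_values == plan.global_values
    assert back.group_values == plan.group_values
    a = impute(ds, plan)
    b = impute(ds, back)
    np.testing.assert_array_equal(a.values, b.values)


def test_before_after_report_shows_zero_after(tmp_path):
    ds = inject_missing(generate(default_spec(seed=13), 90), 0.1, seed=14)
    out = impute(ds, fit_imputer(ds))
    rep = before_after_report(ds, out)
    assert rep["missing_before"].sum() == ds.n_missing
    assert (rep["missing_after"] == 0).all()
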