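import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import retroclock as rc
from retroclock.exceptions import ValidationError


def _model(coefficients, intercept=10.0, transform=None, means=None):
    if means is None:
        means = {k: 0.5 for k in coefficients}
    return rc.ClockModel(
        name="m", platform="custom", intercept=intercept,
        coefficients=coefficients,
        transform=transform or rc.AgeTransform("identity"),
        training_means=means,
    )


def _beta(data: dict, samples) -> rc.BetaMatrix:
    return rc.BetaMatrix(pd.DataFrame(data, index=samples).T)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def test_prediction_arithmetic_forced_example():
    model = _model({"cg1": 20.0, "cg2": -5.0}, intercept=10.0)
    beta = _beta({"cg1": [0.5], "cg2": [0.2]}, ["s1"])
    pred = rc.predict_age(beta, model)
    assert pred.loc["s1", "predicted_age"] == pytest.approx(19.0)
    assert pred.loc["s1", "n_missing_probes"] == 0


def test_empty_coefficient_model_predicts_intercept():
    model = _model({}, intercept=42.0, means={})
    beta = _beta({"cgX": [0.1, 0.9, 0.4]}, ["s1", "s2", "s3"])
    pred = rc.predict_age(beta, model)
    assert (pred["predicted_age"] == 42.0).all()


def test_prediction_invariant_to_row_and_column_order():
    rng = np.random.default_rng(2)
    probes = [f"cg{i}" for i in range(20)]
    samples = [f"s{j}" for j in range(6)]
    df = pd.DataFrame(rng.uniform(size=(20, 6)), index=probes, columns=samples)
    model = _model({p: float(rng.normal()) for p in probes[:10]},
                   means={p: 0.5 for p in probes[:10]})
    base = rc.predict_age(rc.BetaMatrix(df), model)
    shuffled = df.iloc[rng.permutation(20), rng.permutation(6)]
    other = rc.predict_age(rc.BetaMatrix(shuffled), model)
    for s in samples:
        assert other.loc[s, "predicted_age"] == pytest.approx(
            base.loc[s, "predicted_age"], rel=1e-12
        )


def test_missing_model_cpgs_imputed_at_training_mean():
    model = _model({"cg1": 10.0, "cg2": 10.0},
                   means={"cg1": 0.5, "cg2": 0.3})
    beta = _beta({"cg1": [0.5]}, ["s1"])  # cg2 absent entirely
    with pytest.warns(UserWarning, match="imputed"):
        pred = rc.predict_age(beta, model)
    assert pred.loc["s1", "predicted_age"] == pytest.approx(10 + 5 + 3)
    assert pred.loc["s1", "n_missing_probes"] == 1
    assert pred.loc["s1", "imputed_fraction"] == pytest.approx(0.5)


def test_missing_cpgs_with_imputation_disabled_is_error():
    model = rc.ClockModel("m", "custom", 10.0, {"cg1": 10.0, "cg2": 10.0},
                          rc.AgeTransform("identity"), None)
    beta = _beta({"cg1": [0.5]}, ["s1"])
    with pytest.raises(ValidationError, match="cg2"):
        rc.predict_age(beta, model)


def test_prediction_linearity_on_response_scale():
    rng = np.random.default_rng(4)
    probes = [f"cg{i}" for i in range(8)]
    model = _model({p: float(rng.normal()) for p in probes})
    b1, b2 = rng.uniform(size=8), rng.uniform(size=8)
    lam = 0.3
    mix = lam * b1 + (1 - lam) * b2
    df = pd.DataFrame({"a": b1, "b": b2, "mix": mix}, index=probes)
    pred = rc.predict_age(rc.BetaMatrix(df), model)
    expected = lam * pred.loc["a", "predicted_age"] + \
        (1 - lam) * pred.loc["b", "predicted_age"]
    assert pred.loc["mix", "predicted_age"] == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _pred_frame(values, ids=None):
    ids = ids or [f"s{i}" for i in range(len(values))]
    return pd.DataFrame(
        {"predicted_age": values, "n_missing_probes": 0, "imputed_fraction": 0.0},
        index=pd.Index(ids, name="sample_id"),
    )


def _age_frame(values, ids=None):
    ids = ids or [f"s{i}" for i in range(len(values))]
    return pd.DataFrame({"age": values}, index=pd.Index(ids, name="sample_id"))


def test_perfect_predictions_have_zero_mae_unit_r():
    summary = rc.evaluate_predictions(_pred_frame([10, 40, 70]),
                                      _age_frame([10, 40, 70]))
    assert summary.mae == 0.0
    assert summary.pearson_r == pytest.approx(1.0)


def test_mae_is_the_median_absolute_error():
    # abs errors [0, 0, 4]: the median (0), not the mean (1.33)
    summary = rc.evaluate_predictions(_pred_frame([10, 20, 30]),
                                      _age_frame([10, 20, 34]))
    assert summary.mae == 0.0
    # abs errors [0, 2, 4] -> median 2
    summary = rc.evaluate_predictions(_pred_frame([10, 22, 30]),
                                      _age_frame([10, 20, 34]))
    assert summary.mae == 2.0


def test_affine_predictions_keep_unit_correlation():
    ages = np.array([20.0, 35.0, 50.0, 65.0])
    summary = rc.evaluate_predictions(_pred_frame(2 * ages + 7), _age_frame(ages))
    assert summary.pearson_r == pytest.approx(1.0)
    assert summary.mae == pytest.approx(np.median(np.abs(ages + 7)))


def test_zero_variance_gives_nan_r_but_mae():
    summary = rc.evaluate_predictions(_pred_frame([50, 50, 50]),
                                      _age_frame([40, 50, 60]))
    assert np.isnan(summary.pearson_r)
    assert summary.mae == 10.0


# ---------------------------------------------------------------------------
# age acceleration
# ---------------------------------------------------------------------------

def test_difference_acceleration_is_exact():
    accel = rc.age_acceleration(_pred_frame([52.8]), _age_frame([50.0]))
    assert accel.loc["s0", "acceleration"] == pytest.approx(2.8)


def test_acceleration_zero_when_prediction_matches_age():
    ages = [30.0, 45.0, 60.0, 75.0]
    for method in ("difference", "residual"):
        accel = rc.age_acceleration(_pred_frame(ages), _age_frame(ages), method)
        assert np.allclose(accel["acceleration"], 0.0, atol=1e-10)


def test_residual_accelerations_sum_to_zero():
    rng = np.random.default_rng(1)
    ages = rng.uniform(20, 80, 40)
    pred = 0.9 * ages + 5 + rng.normal(0, 3, 40)
    accel = rc.age_acceleration(_pred_frame(pred), _age_frame(ages), "residual")
    assert accel["acceleration"].sum() == pytest.approx(0.0, abs=1e-8)
    with pytest.raises(ValidationError, match="3 samples"):
        rc.age_acceleration(_pred_frame(pred[:2]), _age_frame(ages[:2]), "residual")


# ---------------------------------------------------------------------------
# group contrasts
# ---------------------------------------------------------------------------

def test_identical_pre_post_gives_null_paired_test():
    values = [1.0, -2.0, 0.5, 3.0]
    accel = _pred_frame(values * 2, ids=[f"s{i}" for i in range(8)])
    accel = accel.rename(columns={"predicted_age": "acceleration"})
    meta = pd.DataFrame({
        "age": 50.0,
        "donor_id": [f"d{i}" for i in range(4)] * 2,
        "group": ["pre"] * 4 + ["post"] * 4,
    }, index=accel.index)
    report = rc.group_difference_test(accel, meta, "paired",
                                      levels=("pre", "post"))
    assert report.t == 0.0 and report.p == 1.0 and report.estimate == 0.0


def test_constant_paired_change_detected_exactly():
    pre = [10.0, 12.0, 9.0]
    post = [v - 1.5 for v in pre]
    accel = pd.DataFrame({"acceleration": pre + post},
                         index=[f"s{i}" for i in range(6)])
    meta = pd.DataFrame({
        "age": 50.0,
        "donor_id": ["d0", "d1", "d2"] * 2,
        "group": ["pre"] * 3 + ["post"] * 3,
    }, index=accel.index)
    report = rc.group_difference_test(accel, meta, "paired",
                                      levels=("pre", "post"))
    assert report.estimate == pytest.approx(-1.5)
    assert report.p == 0.0


def test_unmatched_pairs_error_names_donor():
    accel = pd.DataFrame({"acceleration": [1.0, 2.0, 3.0]},
                         index=["s0", "s1", "s2"])
    meta = pd.DataFrame({
        "age": 50.0,
        "donor_id": ["d0", "d0", "d1"],
        "group": ["pre", "post", "pre"],
    }, index=accel.index)
    with pytest.raises(ValidationError, match="d1"):
        rc.group_difference_test(accel, meta, "paired", levels=("pre", "post"))


def test_two_group_shift_recovered():
    rng = np.random.default_rng(6)
    n1, n2, shift = 44, 185, 2.99
    vals = np.r_[rng.normal(-0.19, 4, n1), rng.normal(2.8, 4, n2)]
    accel = pd.DataFrame({"acceleration": vals},
                         index=[f"s{i}" for i in range(n1 + n2)])
    meta = pd.DataFrame({"age": 50.0,
                         "group": ["ctrl"] * n1 + ["case"] * n2},
                        index=accel.index)
    report = rc.group_difference_test(accel, meta, "two_group",
                                      levels=("ctrl", "case"))
    assert report.estimate == pytest.approx(shift, abs=2.0)
    assert report.p < 0.01
    assert report.ci_low < report.estimate < report.ci_high


# ---------------------------------------------------------------------------
# clock CpG intersections
# ---------------------------------------------------------------------------

def test_upset_counts_worked_example():
    table = rc.compare_clock_cpg_sets({"A": {"a", "b", "c"}, "B": {"b", "c", "d"}})
    assert table.exclusive == {
        frozenset({"A"}): 1, frozenset({"B"}): 1, frozenset({"A", "B"}): 2,
    }
    assert table.pairwise.loc["A", "B"] == 2
    assert table.union_size == 4


def test_disjoint_sets_have_zero_overlaps():
    table = rc.compare_clock_cpg_sets({"A": {"a1", "a2"}, "B": {"b1"},
                                       "C": {"c1", "c2", "c3"}})
    off_diag = table.pairwise.to_numpy()[~np.eye(3, dtype=bool)]
    assert (off_diag == 0).all()
    assert sum(table.exclusive.values()) == 6


@given(
    st.lists(
        st.sets(st.integers(min_value=0, max_value=30), min_size=0, max_size=15),
        min_size=2, max_size=4,
    )
)
def test_upset_counts_partition_the_union(families):
    sets = {f"set{i}": {f"cg{x}" for x in s} for i, s in enumerate(families)}
    if not any(sets.values()):
        sets["set0"] = {"cg0"}
    table = rc.compare_clock_cpg_sets(sets)
    union = set().union(*sets.values())
    assert sum(table.exclusive.values()) == len(union)
    # brute-force membership-vector enumeration
    expected = {}
    for cpg in union:
        combo = frozenset(n for n, s in sets.items() if cpg in s)
        expected[combo] = expected.get(combo, 0) + 1
    assert table.exclusive == expected
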