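import numpy as np
import pandas as pd
import pytest

import retroclock as rc
from retroclock.clock_training import _path_coefs, _standardize
from retroclock.exceptions import ValidationError


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _meta(n, donors=None):
    idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    df = pd.DataFrame({"age": np.linspace(20, 80, n)}, index=idx)
    if donors is not None:
        df["donor_id"] = donors
    return df


def test_ungrouped_split_sizes_and_disjointness():
    meta = _meta(10)
    train, test = rc.split_samples(meta, rc.TrainingConfig(seed=1))
    assert len(train) == 8 and len(test) == 2
    assert set(train) | set(test) == set(meta.index)
    assert set(train) & set(test) == set()


def test_grouped_split_never_straddles_donors():
    meta = _meta(10, donors=["a"] * 3 + ["b"] * 3 + ["c"] * 4)
    cfg = rc.TrainingConfig(seed=0, group_by_donor=True)
    train, test = rc.split_samples(meta, cfg)
    donors_train = set(meta.loc[train, "donor_id"])
    donors_test = set(meta.loc[test, "donor_id"])
    assert donors_train & donors_test == set()
    assert set(train) | set(test) == set(meta.index)


def test_grouped_split_over_many_seeds_zero_leakage_and_near_target():
    rng = np.random.default_rng(77)
    for seed in range(100):
        n_donors = int(rng.integers(5, 20))
        sizes = rng.integers(1, 6, size=n_donors)
        donors = [f"d{i}" for i in range(n_donors) for _ in range(sizes[i])]
        meta = _meta(len(donors), donors=donors)
        cfg = rc.TrainingConfig(seed=seed, group_by_donor=True)
        train, test = rc.split_samples(meta, cfg)
        assert set(meta.loc[train, "donor_id"]) & set(meta.loc[test, "donor_id"]) == set()
        # achieved share within one (largest) donor of the target
        largest = sizes.max() / len(donors)
        achieved = len(train) / len(donors)
        assert abs(achieved - cfg.split_fraction) <= largest + 1e-9


def test_grouped_split_requires_donor_ids_and_multiple_donors():
    with pytest.raises(ValidationError, match="donor_id"):
        rc.split_samples(_meta(6), rc.TrainingConfig(group_by_donor=True))
    meta = _meta(6, donors=["a"] * 6)
    with pytest.raises(ValidationError, match="donors"):
        rc.split_samples(meta, rc.TrainingConfig(group_by_donor=True))


def test_split_reproducible_from_seed():
    meta = _meta(50)
    cfg = rc.TrainingConfig(seed=4)
    assert rc.split_samples(meta, cfg) == rc.split_samples(meta, cfg)


# ---------------------------------------------------------------------------
# elastic net
# ---------------------------------------------------------------------------

def test_constant_response_gives_intercept_only_model():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 10))
    y = np.full(40, 37.0)
    with pytest.warns(UserWarning, match="constant"):
        fit, cv = rc.fit_elastic_net_cv(X, y, rc.TrainingConfig(seed=0))
    assert fit.intercept == 37.0
    assert fit.coefficients == {}


def test_all_zero_solution_at_and_above_lambda_max():
    rng = np.random.default_rng(8)
    for _ in range(5):
        n, p = int(rng.integers(20, 80)), int(rng.integers(5, 40))
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        lmax = rc.lambda_max(X, y, alpha=1.0)
        Xs, _, _ = _standardize(X)
        yc = y - y.mean()
        coefs = _path_coefs(Xs, yc, np.array([lmax * 2, lmax * 1.000001]),
                            1.0, 1e-12, 100_000)
        assert np.count_nonzero(coefs) == 0
        below = _path_coefs(Xs, yc, np.array([lmax * 0.5]), 1.0, 1e-12, 100_000)
        assert np.count_nonzero(below) > 0


def test_kkt_stationarity_on_random_problems():
    rng = np.random.default_rng(21)
    for i in range(5):
        n, p = 80, 40
        X = rng.normal(size=(n, p))
        y = X[:, :8] @ rng.normal(size=8) + rng.normal(size=n)
        alpha = float(rng.uniform(0.2, 1.0))
        cfg = rc.TrainingConfig(alpha=alpha, seed=i, n_lambda=30, n_folds=5,
                                tol=1e-12, max_iter=100_000)
        fit, _ = rc.fit_elastic_net_cv(X, y, cfg)
        v = rc.kkt_violation(X, y, fit.intercept, fit.coef_vector(),
                             fit.lambda_, alpha)
        assert v < 1e-6


def test_fitted_solution_beats_random_perturbations():
    rng = np.random.default_rng(31)
    n, p = 60, 25
    X = rng.normal(size=(n, p))
    y = X[:, :5] @ rng.normal(size=5) + 0.5 * rng.normal(size=n)
    alpha = 0.5
    cfg = rc.TrainingConfig(alpha=alpha, seed=3, n_lambda=30, n_folds=5,
                            tol=1e-12, max_iter=100_000)
    fit, _ = rc.fit_elastic_net_cv(X, y, cfg)
    Xs, mu, sd = _standardize(X)
    yc = y - y.mean()
    b = fit.coef_vector() * sd

    def objective(beta):
        r = yc - Xs @ beta
        return (r @ r) / (2 * n) + fit.lambda_ * (
            alpha * np.abs(beta).sum() + (1 - alpha) / 2 * beta @ beta
        )

    base = objective(b)
    for _ in range(1000):
        assert base <= objective(b + rng.normal(scale=1e-3, size=p)) + 1e-12


def test_cv_lambda_path_shape_and_selection():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(60, 20))
    y = X[:, 0] * 3 + rng.normal(size=60)
    cfg = rc.TrainingConfig(seed=2, n_lambda=40, n_folds=5)
    fit, cv = rc.fit_elastic_net_cv(X, y, cfg)
    assert len(cv.lambda_path) == 40
    assert np.all(np.diff(cv.lambda_path) < 0)
    assert cv.chosen_lambda in cv.lambda_path
    assert fit.lambda_ == cv.chosen_lambda
    cfg_1se = rc.TrainingConfig(seed=2, n_lambda=40, n_folds=5,
                                selection_rule="lambda_1se")
    _, cv_1se = rc.fit_elastic_net_cv(X, y, cfg_1se)
    assert cv_1se.chosen_lambda >= cv.chosen_lambda


# ---------------------------------------------------------------------------
# end-to-end training
# ---------------------------------------------------------------------------

def test_recovery_experiment_accuracy_and_selection(recovery_run):
    result = recovery_run["result"]
    assert result.test_summary.pearson_r >= 0.9
    assert result.test_summary.mae <= 3.0
    selected = set(result.model.cpgs)
    causal_fraction = len(selected & recovery_run["causal"]) / len(selected)
    assert causal_fraction >= 0.7


def test_training_is_deterministic_byte_identical(tmp_path):
    cfg_sim = rc.SyntheticConfig(n_samples=120, n_probes=300, n_causal=30, seed=2)
    beta, meta, _ = rc.simulate_methylation_cohort(cfg_sim)
    files = []
    for run in range(2):
        res = rc.train_clock(beta, meta, rc.AgeTransform("identity"),
                             rc.TrainingConfig(seed=2, n_lambda=40))
        path = tmp_path / f"clock{run}.csv"
        rc.write_clock_model(res.model, path)
        files.append(path)
    assert files[0].read_bytes() == files[1].read_bytes()


def test_null_cohort_yields_no_spurious_age_signal():
    rs = []
    for seed in range(20):
        cfg = rc.SyntheticConfig(n_samples=80, n_probes=120, n_causal=10,
                                 effect_scale=0.0, seed=seed)
        beta, meta, _ = rc.simulate_methylation_cohort(cfg)
        res = rc.train_clock(beta, meta, rc.AgeTransform("identity"),
                             rc.TrainingConfig(seed=seed, n_lambda=30, n_folds=5))
        r = res.test_summary.pearson_r
        rs.append(0.0 if np.isnan(r) else r)
    rs = np.array(rs)
    # mean held-out r must not be significantly positive
    from scipy import stats
    t, p = stats.ttest_1samp(rs, 0.0)
    assert not (t > 0 and p / 2 < 0.01)


def test_missing_betas_imputed_and_heavily_missing_samples_excluded():
    cfg = rc.SyntheticConfig(n_samples=100, n_probes=200, n_causal=30, seed=6)
    beta, meta, _ = rc.simulate_methylation_cohort(cfg)
    df = beta.data.copy()
    rng = np.random.default_rng(0)
    mask = rng.random(df.shape) < 0.02
    df = df.mask(mask)
    df.iloc[:, 0] = np.nan
    df.iloc[: int(0.5 * len(df)), 1] = np.nan  # sample 2: 50% missing
    df.iloc[0, 0] = 0.5  # leave one value so every probe has a training mean
    beta2 = rc.BetaMatrix(df)
    with pytest.warns(UserWarning, match="excluding"):
        res = rc.train_clock(beta2, meta, rc.AgeTransform("identity"),
                             rc.TrainingConfig(seed=6, n_lambda=30, n_folds=5))
    excluded = set(res.excluded_samples)
    assert beta.sample_ids[0] in excluded and beta.sample_ids[1] in excluded
    assert set(res.train_ids) | set(res.test_ids) == set(beta.sample_ids) - excluded


def test_log_offset_training_reports_years(multispecies_run):
    result = multispecies_run["result"]
    assert result.model.transform.kind == "log_offset"
    # evaluation happens in years: median error must be on the year scale
    assert 0 <= result.test_summary.mae < 20


# ---------------------------------------------------------------------------
# expression preprocessing
# ---------------------------------------------------------------------------

def test_expression_cpm_log_transform_forced_value():
    counts = pd.DataFrame(
        {"s1": [100, 999_900]}, index=["locusA", "locusB"]
    )
    feats = rc.preprocess_expression(counts, min_prevalence=0.0)
    # library size 1e6: locusA count 100 -> CPM 100 -> ln(101)
    assert feats.loc["s1", "locusA"] == pytest.approx(np.log(101), rel=1e-12)


def test_expression_filtering_and_validation():
    counts = pd.DataFrame(
        {"s1": [5, 0, 1], "s2": [7, 0, 0], "s3": [1, 0, 0]},
        index=["keep", "allzero", "rare"],
    )
    feats = rc.preprocess_expression(counts, min_prevalence=0.5)
    assert list(feats.columns) == ["keep"]
    with pytest.raises(ValidationError, match="non-negative"):
        rc.preprocess_expression(counts - 3)
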