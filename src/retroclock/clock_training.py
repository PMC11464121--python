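"""Penalized linear age-clock training.

The clock is an elastic-net linear model of the (possibly transformed) age
response on CpG beta values:

    minimize  (1/2n) * sum_i (y_i - b0 - x_i' b)^2
              + lambda * [ alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2 ]

Features are standardized internally (mean 0, unit variance) for the
penalty to act evenly; returned coefficients are on the original beta
scale.  The regularization path runs from

    lambda_max = max_j | x~_j' (y - ybar) | / (n * alpha)

(the smallest lambda with an all-zero solution, computed on standardized
x~) down to ``lambda_max * lambda_min_ratio``, log-spaced.  lambda is
chosen by 10-fold cross-validation, either at the CV-error minimizer
(``lambda_min``) or the one-standard-error rule (``lambda_1se``).

Solver: scikit-learn coordinate descent (the same algorithm family as
glmnet); this module owns standardization, the lambda path, fold
construction, selection and back-transformation, and exposes a KKT
stationarity check (:func:`kkt_violation`) used to verify solutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import enet_path

from .age_transforms import AgeTransform
from .exceptions import ValidationError

_ALPHA_FLOOR = 1e-3  # clamp for the lambda_max formula when alpha -> 0


# ---------------------------------------------------------------------------
# configuration and model containers
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    """Knobs for clock training.

    alpha is the elastic-net mixing parameter (1 = lasso, 0 = ridge);
    0.5 is the default used throughout.  split_fraction is the training
    share of the cohort; group_by_donor keeps all samples of a donor on one
    side of the split (no leakage across tissues/timepoints of the same
    individual).
    """

    alpha: float = 0.5
    n_folds: int = 10
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    split_fraction: float = 0.8
    group_by_donor: bool = False
    selection_rule: str = "lambda_min"  # or "lambda_1se"
    seed: int = 0
    tol: float = 1e-4
    max_iter: int = 1000
    max_missing_fraction: float = 0.2  # per-sample probe missingness cutoff

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must be in [0, 1]")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValidationError("split_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if self.selection_rule not in ("lambda_min", "lambda_1se"):
            raise ValidationError("selection_rule must be lambda_min or lambda_1se")


@dataclass
class ClockModel:
    """A trained clock: intercept + sparse CpG coefficients (response
    scale), the age transform, and per-CpG training means used to impute
    missing betas at prediction time."""

    name: str
    platform: str
    intercept: float
    coefficients: dict[str, float]
    transform: AgeTransform
    training_means: dict[str, float] | None
    n_train: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        zero = [k for k, v in self.coefficients.items() if v == 0.0]
        if zero:
            raise ValidationError(
                f"coefficients must be sparse (no zero entries); got zeros for "
                f"{zero[:5]}"
            )
        if self.training_means is not None:
            missing = [k for k in self.coefficients if k not in self.training_means]
            if missing:
                raise ValidationError(
                    f"training_means missing for coefficient CpGs: {missing[:5]}"
                )

    @property
    def cpgs(self) -> list[str]:
        return list(self.coefficients)

    @property
    def imputation_enabled(self) -> bool:
        return self.training_means is not None


@dataclass
class CVResult:
    """Cross-validation trace along the lambda path."""

    lambda_path: np.ndarray          # strictly decreasing
    cv_mean_error: np.ndarray        # MSE on the response scale
    cv_se: np.ndarray
    chosen_lambda: float
    fold_assignments: np.ndarray     # fold label per training sample


@dataclass
class LinearFit:
    """Elastic-net solution at the chosen lambda, original feature scale."""

    intercept: float
    coefficients: dict[str, float]   # nonzero only
    lambda_: float
    alpha: float
    feature_names: list[str] = field(default_factory=list)

    def coef_vector(self) -> np.ndarray:
        return np.array([self.coefficients.get(f, 0.0) for f in self.feature_names])

    def predict(self, X) -> np.ndarray:
        """Linear predictor for rows of X (columns = feature_names)."""
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coef_vector()


# ---------------------------------------------------------------------------
# sample splitting
# ---------------------------------------------------------------------------

def split_samples(
    metadata: pd.DataFrame, config: TrainingConfig
) -> tuple[list[str], list[str]]:
    """Split sample ids into disjoint, exhaustive train/test sets.

    Ungrouped: a seeded permutation assigns ``round(split_fraction * n)``
    samples to training.  Grouped (``group_by_donor``): whole donors are
    packed greedily, in seeded random order, into the training side until
    it reaches the target share, so no donor ever straddles the split; the
    achieved share can deviate from the target by up to one donor.
    """
    ids = list(metadata.index.astype(str))
    n = len(ids)
    if n < 2:
        raise ValidationError("need at least 2 samples to split")
    rng = np.random.default_rng(config.seed)

    if not config.group_by_donor:
        n_train = int(round(config.split_fraction * n))
        n_train = min(max(n_train, 1), n - 1)
        perm = rng.permutation(n)
        train = [ids[i] for i in sorted(perm[:n_train])]
        test = [ids[i] for i in sorted(perm[n_train:])]
        return train, test

    if "donor_id" not in metadata.columns or metadata["donor_id"].isna().any():
        raise ValidationError(
            "group_by_donor requires a donor_id for every sample"
        )
    donors = metadata.groupby("donor_id", sort=True).size()
    if len(donors) < 2:
        raise ValidationError(
            "grouped splitting needs >= 2 donors so both sides are non-empty; "
            "reduce grouping or change split_fraction"
        )
    order = rng.permutation(len(donors))
    target = config.split_fraction * n
    train_donors: list = []
    size = 0
    for k in order:
        if size >= target:
            break
        train_donors.append(donors.index[k])
        size += int(donors.iloc[k])
    if size == n:  # everything landed in train; move the last donor out
        moved = train_donors.pop()
        size -= int(donors[moved])
    train_set = set(train_donors)
    train = [s for s in ids if metadata.loc[s, "donor_id"] in train_set]
    test = [s for s in ids if metadata.loc[s, "donor_id"] not in train_set]
    if not train or not test:
        raise ValidationError(
            "grouped split produced an empty side; a donor is larger than the "
            "test side can hold — change split_fraction or donor structure"
        )
    return train, test


# ---------------------------------------------------------------------------
# elastic net with internal standardization
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0, glmnet convention
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd_safe


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest lambda whose solution is all-zero, on standardized
    features.  With alpha -> 0 the formula diverges; alpha is clamped at
    1e-3 for this computation only."""
    Xs, _, _ = _standardize(np.asarray(X, dtype=float))
    yc = y - np.mean(y)
    n = len(y)
    a = max(alpha, _ALPHA_FLOOR)
    return float(np.max(np.abs(Xs.T @ yc)) / (n * a))


def make_lambda_path(lmax: float, n_lambda: int, lambda_min_ratio: float) -> np.ndarray:
    return np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)


def _path_coefs(Xs, yc, lambdas, alpha, tol, max_iter) -> np.ndarray:
    """Standardized-scale coefficients for every lambda (p x n_lambda)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter at tiny lambdas
        _, coefs, _ = enet_path(
            Xs, yc, l1_ratio=alpha, alphas=lambdas,
            tol=tol, max_iter=max_iter,
        )
    return coefs


def age_stratified_folds(y: np.ndarray, n_folds: int, rng) -> np.ndarray:
    """Fold labels stratified on the response: samples are sorted by y and
    fold labels permuted within consecutive blocks of ``n_folds``, keeping
    the response distribution balanced across folds."""
    n = len(y)
    order = np.argsort(y, kind="stable")
    folds = np.empty(n, dtype=int)
    for start in range(0, n, n_folds):
        block = order[start:start + n_folds]
        labels = rng.permutation(n_folds)[: len(block)]
        folds[block] = labels
    return folds


def kkt_violation(
    X: np.ndarray,
    y: np.ndarray,
    intercept: float,
    coef: np.ndarray,
    lambda_: float,
    alpha: float,
) -> float:
    """Maximum violation of the elastic-net stationarity conditions.

    ``coef`` is on the original feature scale; the check standardizes X
    exactly as the solver does and verifies, at the solution (b0, b):

    * active j:   (1/n) x~_j' r  =  lambda*alpha*sign(b_j) + lambda*(1-alpha)*b_j
    * inactive j: |(1/n) x~_j' r| <= lambda*alpha
    * intercept:  mean residual = 0

    Returns the largest absolute discrepancy across all conditions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xs, mu, sd = _standardize(X)
    b_std = np.asarray(coef, dtype=float) * sd
    b0_std = intercept + float(mu @ coef) - np.mean(y)
    yc = y - np.mean(y)
    r = yc - b0_std - Xs @ b_std
    n = len(y)
    g = Xs.T @ r / n
    viol = abs(np.mean(r))
    active = b_std != 0
    if np.any(active):
        lhs = g[active] - lambda_ * (1 - alpha) * b_std[active]
        viol = max(viol, float(np.max(np.abs(lhs - lambda_ * alpha * np.sign(b_std[active])))))
    if np.any(~active):
        slack = np.abs(g[~active]) - lambda_ * alpha
        viol = max(viol, float(max(0.0, np.max(slack))))
    return viol


def fit_elastic_net_cv(
    X,
    y,
    config: TrainingConfig,
    feature_names: list[str] | None = None,
) -> tuple[LinearFit, CVResult]:
    """Cross-validated elastic net over the lambda path.

    X is samples x features, fully observed (impute upstream); y is the
    response (transformed age).  Returns the solution at the selected
    lambda with coefficients on the original feature scale, plus the CV
    trace.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValidationError(f"X has {n} rows but y has {len(y)} values")
    if n < config.n_folds:
        raise ValidationError(
            f"need at least n_folds={config.n_folds} samples, got {n}"
        )
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]

    if np.ptp(y) == 0.0:
        warnings.warn(
            "response is constant; returning an intercept-only model",
            stacklevel=2,
        )
        fit = LinearFit(float(y[0]) if n else 0.0, {}, float("nan"),
                        config.alpha, list(feature_names))
        cv = CVResult(np.array([]), np.array([]), np.array([]),
                      float("nan"), np.zeros(n, dtype=int))
        return fit, cv

    lmax = lambda_max(X, y, config.alpha)
    lambdas = make_lambda_path(lmax, config.n_lambda, config.lambda_min_ratio)

    rng = np.random.default_rng(config.seed)
    folds = age_stratified_folds(y, config.n_folds, rng)
    fold_err = np.full((config.n_folds, len(lambdas)), np.nan)
    for k in range(config.n_folds):
        tr, va = folds != k, folds == k
        if va.sum() == 0 or tr.sum() < 2:
            continue
        Xs, mu, sd = _standardize(X[tr])
        ybar = float(np.mean(y[tr]))
        coefs = _path_coefs(Xs, y[tr] - ybar, lambdas, config.alpha,
                            config.tol, config.max_iter)
        Xva = (X[va] - mu) / sd
        pred = ybar + Xva @ coefs  # (n_va, n_lambda)
        fold_err[k] = np.mean((pred - y[va][:, None]) ** 2, axis=0)

    cv_mean = np.nanmean(fold_err, axis=0)
    n_eff = np.sum(~np.isnan(fold_err), axis=0)
    cv_se = np.nanstd(fold_err, axis=0, ddof=1) / np.sqrt(np.maximum(n_eff, 1))

    i_min = int(np.argmin(cv_mean))
    if config.selection_rule == "lambda_min":
        i_sel = i_min
    else:  # lambda_1se: largest lambda within one SE of the minimum
        threshold = cv_mean[i_min] + cv_se[i_min]
        i_sel = int(np.argmax(cv_mean <= threshold))  # path is decreasing in lambda
    chosen = float(lambdas[i_sel])

    Xs, mu, sd = _standardize(X)
    ybar = float(np.mean(y))
    coefs = _path_coefs(Xs, y - ybar, lambdas, config.alpha,
                        config.tol, config.max_iter)
    b_std = coefs[:, i_sel]
    b = b_std / sd
    intercept = ybar - float(mu @ b)
    coefficients = {
        feature_names[j]: float(b[j]) for j in np.nonzero(b_std)[0]
    }
    fit = LinearFit(intercept, coefficients, chosen, config.alpha,
                    list(feature_names))
    cv = CVResult(lambdas, cv_mean, cv_se, chosen, folds)
    return fit, cv


# ---------------------------------------------------------------------------
# end-to-end clock training
# ---------------------------------------------------------------------------

@dataclass
class TrainingResult:
    model: ClockModel
    cv: CVResult
    train_summary: "EvaluationSummary"
    test_summary: "EvaluationSummary"
    train_ids: list[str]
    test_ids: list[str]
    excluded_samples: list[str]


def train_clock(
    beta,
    metadata: pd.DataFrame,
    transform: AgeTransform,
    config: TrainingConfig,
    *,
    annotations=None,
    classes: set[str] | None = None,
    name: str = "retroelement-clock",
    platform: str = "custom",
) -> TrainingResult:
    """Full training pipeline.

    split -> transform ages -> mean-impute missing betas (training means
    only) -> cross-validated elastic net on the training side -> evaluate
    on train and held-out test in years (via the deployment prediction
    path, so imputation behaves identically at train and predict time).

    ``beta`` should already be restricted to the retroelement universe;
    passing ``annotations`` applies :func:`select_retro_probes` first.
    Samples missing more than ``config.max_missing_fraction`` of probes are
    excluded with a warning.
    """
    from .clock_application import evaluate_predictions, predict_age
    from .retro_annotation import select_retro_probes

    if annotations is not None:
        beta = select_retro_probes(beta, annotations, classes)

    usable = [s for s in beta.sample_ids
              if s in metadata.index and pd.notna(metadata.loc[s, "age"])]
    if len(usable) < len(beta.sample_ids):
        raise ValidationError(
            "every beta-matrix sample needs an age in metadata; missing: "
            f"{sorted(set(beta.sample_ids) - set(usable))[:5]}"
        )

    missing_frac = beta.data.isna().mean(axis=0)
    excluded = [s for s in usable if missing_frac[s] > config.max_missing_fraction]
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} sample(s) missing more than "
            f"{config.max_missing_fraction:.0%} of probes: {excluded[:5]}",
            stacklevel=2,
        )
        usable = [s for s in usable if s not in set(excluded)]

    meta = metadata.loc[usable]
    train_ids, test_ids = split_samples(meta, config)
    if not test_ids:
        raise ValidationError("test set is empty; adjust split_fraction")

    train_df = beta.data[train_ids]
    training_means_all = train_df.mean(axis=1, skipna=True)
    if training_means_all.isna().any():
        bad = training_means_all.index[training_means_all.isna()].tolist()
        raise ValidationError(
            f"probes with no observed training values: {bad[:5]}"
        )
    X_train = train_df.T.fillna(training_means_all).to_numpy()
    ages_train = meta.loc[train_ids, "age"].to_numpy(dtype=float)
    y_train = np.asarray(transform.forward(ages_train), dtype=float)

    fit, cv = fit_elastic_net_cv(X_train, y_train, config,
                                 feature_names=beta.probe_ids)

    model = ClockModel(
        name=name,
        platform=platform,
        intercept=fit.intercept,
        coefficients=fit.coefficients,
        transform=transform,
        training_means={k: float(training_means_all[k]) for k in fit.coefficients},
        n_train=len(train_ids),
        seed=config.seed,
    )

    from .io_formats import BetaMatrix
    pred_train = predict_age(BetaMatrix(beta.data[train_ids]), model)
    pred_test = predict_age(BetaMatrix(beta.data[test_ids]), model)
    train_summary = evaluate_predictions(pred_train, meta)
    test_summary = evaluate_predictions(pred_test, meta)
    return TrainingResult(model, cv, train_summary, test_summary,
                          train_ids, test_ids, excluded)


# ---------------------------------------------------------------------------
# retroelement expression features
# ---------------------------------------------------------------------------

def preprocess_expression(
    counts: pd.DataFrame, min_prevalence: float = 0.1
) -> pd.DataFrame:
    """Turn a loci x samples count matrix into clock features.

    Per-sample counts-per-million scaling followed by log(x + 1); loci with
    zero counts in at least ``1 - min_prevalence`` of samples are removed.
    Returns samples x loci, ready for :func:`fit_elastic_net_cv`.
    """
    values = counts.to_numpy()
    if np.any(values < 0):
        raise ValidationError("expression counts must be non-negative")
    if not np.allclose(values, np.round(values)):
        raise ValidationError("expression counts must be integers")
    zero_frac = (counts == 0).mean(axis=1)
    keep = zero_frac < (1.0 - min_prevalence)
    filtered = counts.loc[keep]
    lib = filtered.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = lib.index[lib == 0].tolist()
        raise ValidationError(f"samples with zero library size: {bad[:5]}")
    cpm = filtered / lib * 1e6
    return np.log1p(cpm).T
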