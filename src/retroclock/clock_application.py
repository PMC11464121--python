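"""Applying a trained clock: age prediction, evaluation, age acceleration,
group contrasts and cross-clock CpG intersections.

Evaluation follows epigenetic-clock conventions: accuracy is summarized by
Pearson's r and the MEDIAN absolute error in years (the field's "MAE").
Age acceleration is by default the simple difference predicted minus
chronological age; the residual method (residuals of predicted regressed
on chronological within a cohort) is available for cross-cohort work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clock_training import ClockModel
from .exceptions import ValidationError
from .io_formats import BetaMatrix


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_age(
    beta: BetaMatrix,
    model: ClockModel,
    *,
    impute_missing: bool = True,
    warn_imputed_fraction: float = 0.2,
) -> pd.DataFrame:
    """Predict age in years for every sample of a beta matrix.

    The linear predictor is ``intercept + sum_j coef_j * beta_j`` on the
    response scale, mapped to years by the model's inverse transform.
    Model CpGs absent from the matrix (or NA in a sample) are imputed at
    their training mean and counted per sample; with imputation disabled
    any missing CpG is an error.

    Returns a DataFrame indexed by sample id with columns
    ``predicted_age``, ``n_missing_probes``, ``imputed_fraction``.
    """
    cpgs = model.cpgs
    coef = np.array([model.coefficients[c] for c in cpgs])
    present = [c for c in cpgs if c in beta.data.index]
    absent = [c for c in cpgs if c not in beta.data.index]

    can_impute = impute_missing and model.imputation_enabled
    if absent and not can_impute:
        raise ValidationError(
            f"{len(absent)} model CpGs missing from the beta matrix and "
            f"imputation is disabled: {absent[:5]}"
        )

    # matrix restricted to model CpGs, absent rows as NaN, model CpG order
    sub = beta.data.reindex(cpgs)
    missing_mask = sub.isna()
    if missing_mask.to_numpy().any():
        if not can_impute:
            bad = sorted(missing_mask.index[missing_mask.any(axis=1)])
            raise ValidationError(
                f"missing beta values for model CpGs with imputation "
                f"disabled: {bad[:5]}"
            )
        means = pd.Series({c: model.training_means[c] for c in cpgs})
        sub = sub.apply(lambda col: col.fillna(means))

    response = model.intercept + coef @ sub.to_numpy()
    predicted = model.transform.inverse(response)
    n_missing = missing_mask.sum(axis=0).to_numpy()
    frac = n_missing / len(cpgs) if cpgs else np.zeros(len(beta.sample_ids))
    if np.any(frac > warn_imputed_fraction):
        worst = [s for s, f in zip(beta.sample_ids, frac) if f > warn_imputed_fraction]
        warnings.warn(
            f"{len(worst)} sample(s) had more than "
            f"{warn_imputed_fraction:.0%} of clock CpGs imputed: {worst[:5]}",
            stacklevel=2,
        )
    return pd.DataFrame(
        {
            "predicted_age": np.atleast_1d(predicted),
            "n_missing_probes": n_missing,
            "imputed_fraction": frac,
        },
        index=pd.Index(beta.sample_ids, name="sample_id"),
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationSummary:
    """Clock accuracy on one cohort: n, Pearson r, median absolute error
    (years)."""

    n: int
    pearson_r: float  # NaN when undefined (zero variance)
    mae: float        # MEDIAN of |predicted - chronological|, years


def evaluate_predictions(
    predictions: pd.DataFrame, metadata: pd.DataFrame
) -> EvaluationSummary:
    """Summarize predictions against chronological age.

    ``predictions`` is the output of :func:`predict_age`; ``metadata`` is
    indexed by sample id with an ``age`` column.  r needs >= 3 pairs and
    non-degenerate variance, otherwise it is NaN; the median absolute
    error is always computed.
    """
    common = [s for s in predictions.index if s in metadata.index]
    if not common:
        raise ValidationError("no overlap between predictions and metadata")
    pred = predictions.loc[common, "predicted_age"].to_numpy(dtype=float)
    age = metadata.loc[common, "age"].to_numpy(dtype=float)
    ok = ~(np.isnan(pred) | np.isnan(age))
    pred, age = pred[ok], age[ok]
    mae = float(np.median(np.abs(pred - age))) if len(pred) else float("nan")
    if len(pred) >= 3 and np.ptp(pred) > 0 and np.ptp(age) > 0:
        r = float(stats.pearsonr(pred, age).statistic)
    else:
        r = float("nan")
    return EvaluationSummary(n=len(pred), pearson_r=r, mae=mae)


# ---------------------------------------------------------------------------
# age acceleration
# ---------------------------------------------------------------------------

def age_acceleration(
    predictions: pd.DataFrame,
    metadata: pd.DataFrame,
    method: str = "difference",
) -> pd.DataFrame:
    """Per-sample age acceleration in years.

    ``difference``: predicted - chronological, exactly.  ``residual``:
    residuals of the least-squares regression of predicted on
    chronological within this cohort (sums to zero by construction).
    """
    if method not in ("difference", "residual"):
        raise ValidationError("method must be 'difference' or 'residual'")
    common = [s for s in predictions.index if s in metadata.index]
    pred = predictions.loc[common, "predicted_age"].to_numpy(dtype=float)
    age = metadata.loc[common, "age"].to_numpy(dtype=float)
    if method == "difference":
        accel = pred - age
    else:
        if len(common) < 3:
            raise ValidationError("residual method needs at least 3 samples")
        slope, intercept = np.polyfit(age, pred, 1)
        accel = pred - (intercept + slope * age)
    return pd.DataFrame(
        {"acceleration": accel, "method": method},
        index=pd.Index(common, name="sample_id"),
    )


# ---------------------------------------------------------------------------
# group contrasts
# ---------------------------------------------------------------------------

@dataclass
class TestReport:
    """A t-test on accelerations: mean difference with 95% CI, t, df, p."""

    design: str
    estimate: float
    ci_low: float
    ci_high: float
    t: float
    df: float
    p: float
    n1: int
    n2: int


def group_difference_test(
    accel: pd.DataFrame,
    metadata: pd.DataFrame,
    design: str,
    *,
    group_col: str = "group",
    levels: tuple[str, str] | None = None,
    welch: bool = False,
) -> TestReport:
    """Test age-acceleration differences between groups.

    ``two_group``: Student's two-sample t (pooled variance by default,
    Welch optional) of acceleration between the two levels of
    ``group_col``; the estimate is mean(level2) - mean(level1).
    ``paired``: one-sample t on within-donor differences (level2 - level1),
    pairing on ``donor_id``; donors without exactly one sample per level
    are an error.  Two-sided p-values throughout.
    """
    common = [s for s in accel.index if s in metadata.index]
    df_all = metadata.loc[common].copy()
    df_all["acceleration"] = accel.loc[common, "acceleration"]
    if group_col not in df_all.columns:
        raise ValidationError(f"metadata lacks group column {group_col!r}")
    found = sorted(df_all[group_col].dropna().unique())
    if levels is None:
        if len(found) != 2:
            raise ValidationError(
                f"{group_col!r} must have exactly 2 levels, found {found}"
            )
        levels = (found[0], found[1])

    if design == "two_group":
        a = df_all.loc[df_all[group_col] == levels[0], "acceleration"].to_numpy()
        b = df_all.loc[df_all[group_col] == levels[1], "acceleration"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValidationError("each group needs n >= 2")
        res = stats.ttest_ind(b, a, equal_var=not welch)
        est = float(np.mean(b) - np.mean(a))
        dof = float(res.df)
        if welch:
            se = float(np.sqrt(np.var(a, ddof=1) / len(a) + np.var(b, ddof=1) / len(b)))
        else:
            sp2 = ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1)) \
                / (len(a) + len(b) - 2)
            se = float(np.sqrt(sp2 * (1 / len(a) + 1 / len(b))))
        tcrit = stats.t.ppf(0.975, dof) if dof > 0 else np.nan
        return TestReport("two_group", est, est - tcrit * se, est + tcrit * se,
                          float(res.statistic), dof, float(res.pvalue),
                          len(a), len(b))

    if design == "paired":
        if "donor_id" not in df_all.columns:
            raise ValidationError("paired design requires donor_id")
        wide = df_all.pivot_table(index="donor_id", columns=group_col,
                                  values="acceleration", aggfunc="count")
        bad = wide.index[(wide.reindex(columns=list(levels)).fillna(0) != 1)
                         .any(axis=1)].tolist()
        if bad:
            raise ValidationError(
                f"donors without exactly one sample per level: {bad[:5]}"
            )
        piv = df_all.pivot(index="donor_id", columns=group_col,
                           values="acceleration")
        diffs = (piv[levels[1]] - piv[levels[0]]).to_numpy(dtype=float)
        n = len(diffs)
        if n < 2:
            raise ValidationError("paired design needs >= 2 donors")
        est = float(np.mean(diffs))
        sd = float(np.std(diffs, ddof=1))
        if sd == 0.0:
            # degenerate: identical change in every donor
            t_stat = 0.0 if est == 0.0 else float(np.inf) * np.sign(est)
            p = 1.0 if est == 0.0 else 0.0
            return TestReport("paired", est, est, est, t_stat, n - 1, p, n, n)
        se = sd / np.sqrt(n)
        t_stat = est / se
        p = float(2 * stats.t.sf(abs(t_stat), n - 1))
        tcrit = stats.t.ppf(0.975, n - 1)
        return TestReport("paired", est, est - tcrit * se, est + tcrit * se,
                          float(t_stat), float(n - 1), p, n, n)

    raise ValidationError("design must be 'two_group' or 'paired'")


# ---------------------------------------------------------------------------
# cross-clock CpG intersections (UpSet semantics)
# ---------------------------------------------------------------------------

@dataclass
class IntersectionTable:
    """Exclusive intersection counts over a family of CpG sets."""

    exclusive: dict[frozenset, int]   # combination of set names -> count
    pairwise: pd.DataFrame            # symmetric overlap matrix
    union_size: int

    def to_frame(self) -> pd.DataFrame:
        names = list(self.pairwise.index)
        rows = []
        for combo, count in sorted(
            self.exclusive.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0]))
        ):
            row = {name: (name in combo) for name in names}
            row["count"] = count
            rows.append(row)
        return pd.DataFrame(rows, columns=names + ["count"])


def compare_clock_cpg_sets(sets: Mapping[str, set]) -> IntersectionTable:
    """Exclusive-intersection (UpSet) counts and pairwise overlaps.

    For every non-empty subset S of clock names, counts the CpGs belonging
    to exactly the clocks in S; these counts partition the union.
    """
    if len(sets) < 2:
        raise ValidationError("need at least 2 CpG sets to intersect")
    names = list(sets)
    exclusive: dict[frozenset, int] = {}
    union = set().union(*sets.values())
    for cpg in union:
        combo = frozenset(n for n in names if cpg in sets[n])
        exclusive[combo] = exclusive.get(combo, 0) + 1
    pairwise = pd.DataFrame(
        [[len(sets[a] & sets[b]) for b in names] for a in names],
        index=names, columns=names,
    )
    return IntersectionTable(exclusive, pairwise, len(union))
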