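"""Test-retest reliability of clock predictions via the intraclass
correlation coefficient.

Technical replicates of the same biological sample should yield nearly
identical predicted ages.  The one-way random-effects model

    y_ij = mu + u_i + e_ij,   u_i ~ N(0, sigma2_between),
                              e_ij ~ N(0, sigma2_within)

decomposes prediction variance into a between-subject and a within-subject
(replicate) component; reliability is

    ICC = sigma2_between / (sigma2_between + sigma2_within).

Primary estimation is restricted maximum likelihood (REML, via a linear
mixed model); the classical one-way ANOVA moment estimator ICC(1,1) is the
cross-check and fallback.  Negative variance estimates are truncated at
zero and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError


@dataclass
class ICCResult:
    icc: float
    sigma2_between: float
    sigma2_within: float
    n_subjects: int
    n_replicates: dict[str, int]
    method: str               # "reml" or "anova"
    truncated: bool = False   # a negative variance component was clipped to 0


def _anova_icc(values: np.ndarray, subjects: np.ndarray) -> tuple[float, float, bool]:
    """One-way ANOVA moment estimator of (sigma2_between, sigma2_within).

    Handles unbalanced designs through the mean group size correction
    k0 = (N - sum(k_i^2) / N) / (a - 1).
    """
    groups = pd.Series(values).groupby(pd.Series(subjects))
    k = groups.size().to_numpy(dtype=float)
    a = len(k)
    n_total = k.sum()
    grand = values.mean()
    means = groups.mean().to_numpy()
    ssb = float(np.sum(k * (means - grand) ** 2))
    ssw = float(np.sum((values - groups.transform("mean").to_numpy()) ** 2))
    msb = ssb / (a - 1)
    dfw = n_total - a
    msw = ssw / dfw if dfw > 0 else 0.0
    k0 = (n_total - np.sum(k ** 2) / n_total) / (a - 1)
    s2b = (msb - msw) / k0
    truncated = s2b < 0
    return max(s2b, 0.0), msw, truncated


def _reml_icc(values: np.ndarray, subjects: np.ndarray) -> tuple[float, float]:
    """REML variance components from a random-intercept mixed model."""
    from statsmodels.regression.mixed_linear_model import MixedLM

    exog = np.ones((len(values), 1))
    model = MixedLM(values, exog, groups=subjects)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary-convergence chatter
        fit = model.fit(reml=True, method="lbfgs")
    s2b = float(np.asarray(fit.cov_re)[0, 0])
    s2w = float(fit.scale)
    return s2b, s2w


def estimate_icc(values, subjects, method: str = "reml") -> ICCResult:
    """Estimate the one-way random-effects ICC of replicate measurements.

    Parameters
    ----------
    values
        Measurement per replicate (e.g. predicted age in years).
    subjects
        Subject label per replicate, aligned with ``values``.
    method
        ``"reml"`` (default; falls back to the ANOVA estimator if the
        mixed-model fit fails) or ``"anova"``.

    Requires >= 2 subjects and at least one subject with >= 2 replicates.
    """
    values = np.asarray(values, dtype=float)
    subjects = np.asarray(subjects)
    if len(values) != len(subjects):
        raise ValidationError("values and subjects must have equal length")
    counts = pd.Series(subjects).value_counts()
    if len(counts) < 2:
        raise ValidationError("need >= 2 subjects to estimate an ICC")
    if (counts >= 2).sum() == 0:
        raise ValidationError(
            "every subject has a single replicate; within-subject variance "
            "is not estimable"
        )
    if method not in ("reml", "anova"):
        raise ValidationError("method must be 'reml' or 'anova'")

    groups = pd.Series(values).groupby(pd.Series(subjects))
    ssw = float(np.sum((values - groups.transform("mean").to_numpy()) ** 2))
    if ssw == 0.0:
        # replicates identical within every subject: perfect reliability
        s2b = float(np.var(groups.mean().to_numpy(), ddof=1))
        return ICCResult(1.0 if s2b > 0 else 0.0, s2b, 0.0, len(counts),
                         counts.to_dict(), method)

    truncated = False
    used = method
    if method == "reml":
        try:
            s2b, s2w = _reml_icc(values, subjects)
        except Exception:
            s2b, s2w, truncated = _anova_icc(values, subjects)
            used = "anova"
    else:
        s2b, s2w, truncated = _anova_icc(values, subjects)

    if s2b < 0:
        s2b, truncated = 0.0, True
    total = s2b + s2w
    icc = s2b / total if total > 0 else 0.0
    icc = float(min(max(icc, 0.0), 1.0))
    return ICCResult(icc, float(s2b), float(s2w), len(counts),
                     counts.to_dict(), used, truncated)


def icc_from_predictions(
    predictions: pd.DataFrame,
    metadata: pd.DataFrame,
    subject_col: str = "replicate_of",
    method: str = "reml",
) -> ICCResult:
    """Convenience wrapper: group predicted ages by subject and estimate
    the ICC.

    ``subject_col`` names the metadata column carrying the subject label;
    with the default ``replicate_of`` convention a sample maps to its
    ``replicate_of`` target when set, else to its own id.
    """
    common = [s for s in predictions.index if s in metadata.index]
    if not common:
        raise ValidationError("no overlap between predictions and metadata")
    values = predictions.loc[common, "predicted_age"].to_numpy(dtype=float)
    if subject_col == "replicate_of" and "replicate_of" in metadata.columns:
        col = metadata.loc[common, "replicate_of"]
        subjects = np.where(col.notna(), col.astype(str), np.asarray(common))
    else:
        if subject_col not in metadata.columns:
            raise ValidationError(f"metadata lacks column {subject_col!r}")
        subjects = metadata.loc[common, subject_col].astype(str).to_numpy()
    return estimate_icc(values, subjects, method=method)
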