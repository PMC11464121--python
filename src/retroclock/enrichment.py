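"""CpG set enrichment against genomic feature sets.

Each clock's CpG set is tested against feature sets (transcription-factor
binding sites, ChromHMM chromatin states, histone marks, ...) with a
one-sided Fisher's exact test on the 2x2 table

                in feature   not in feature
    in clock        a              b
    not in clock    c              d

where the margins are taken within a stated probe universe.  Under the
null the overlap ``a`` is hypergeometric, so the one-sided (enrichment)
p-value is the upper hypergeometric tail.  Fold enrichment is
``(a / |clock|) / (|feature| / |universe|)``.  p-values are adjusted by
Benjamini-Hochberg within each feature database (TFBS, ChromHMM and
histone panels are separate families).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError


@dataclass
class FeatureSet:
    """A named set of probe ids from one feature database."""

    name: str
    members: set
    database: str = "default"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"feature set {self.name!r} has no members")


@dataclass
class EnrichmentResult:
    """One clock-vs-feature 2x2 test."""

    feature: str
    database: str
    overlap: int
    fold_enrichment: float
    odds_ratio: float
    p_value: float
    q_value: float | None = None


def fisher_enrichment(
    query: set,
    feature: FeatureSet,
    universe: set,
    alternative: str = "greater",
) -> EnrichmentResult:
    """Fisher's exact test of a CpG query set against one feature set.

    The feature is intersected with the universe before testing; the query
    must be contained in the universe.  ``alternative="greater"`` (the
    default, enrichment only) uses the exact upper hypergeometric tail,
    ``P(X >= a)``; ``"two-sided"`` uses Fisher's exact test.
    """
    if not universe:
        raise ValidationError("universe must be non-empty")
    query = set(query)
    if not query <= set(universe):
        stray = sorted(query - set(universe))
        raise ValidationError(f"query CpGs outside the universe: {stray[:5]}")
    feat = feature.members & set(universe)
    a = len(query & feat)
    b = len(query) - a
    c = len(feat) - a
    d = len(universe) - len(query) - c
    if alternative == "greater":
        # X ~ Hypergeom(N=|U|, K=|feat|, n=|query|); p = P(X >= a)
        p = float(stats.hypergeom.sf(a - 1, len(universe), len(feat), len(query)))
    elif alternative == "two-sided":
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    else:
        raise ValidationError("alternative must be 'greater' or 'two-sided'")
    expected = len(feat) / len(universe)
    fold = (a / len(query)) / expected if query and expected > 0 else float("nan")
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return EnrichmentResult(
        feature=feature.name, database=feature.database,
        overlap=a, fold_enrichment=fold, odds_ratio=odds, p_value=min(p, 1.0),
    )


def adjust_fdr_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q(i) = min_{j >= i} m * p(j) / j`` on the sorted p-values, mapped
    back to the input order; monotone in p and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_clock(
    query,
    databases: Iterable[FeatureSet],
    universe: set,
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """Test a clock's CpG set against every feature set.

    ``query`` may be a ClockModel (its coefficient CpGs are used) or any
    iterable of probe ids.  BH adjustment is applied within each database
    group; feature sets with no members in the universe are skipped with a
    warning.  Results are sorted by q, then by descending fold enrichment.
    """
    cpgs = set(getattr(query, "cpgs", query))
    universe = set(universe)

    results: list[EnrichmentResult] = []
    for fs in databases:
        if not (fs.members & universe):
            warnings.warn(
                f"feature set {fs.name!r} ({fs.database}) has no members in "
                "the universe; skipped",
                stacklevel=2,
            )
            continue
        results.append(fisher_enrichment(cpgs, fs, universe, alternative))

    by_db: dict[str, list[EnrichmentResult]] = {}
    for res in results:
        by_db.setdefault(res.database, []).append(res)
    for group in by_db.values():
        qvals = adjust_fdr_bh([r.p_value for r in group])
        for res, q in zip(group, qvals):
            res.q_value = float(q)
    results.sort(key=lambda r: (r.q_value, -r.fold_enrichment, r.feature))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature, "database": r.database,
                "overlap": r.overlap, "fold_enrichment": r.fold_enrichment,
                "odds_ratio": r.odds_ratio, "p_value": r.p_value,
                "q_value": r.q_value,
            }
            for r in results
        ]
    )


def read_feature_sets(path) -> list[FeatureSet]:
    """Read feature sets from a CSV with columns feature, probe_id and
    optionally database."""
    df = pd.read_csv(path, dtype=str)
    required = {"feature", "probe_id"}
    if not required <= set(df.columns):
        raise ValidationError(
            f"feature CSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    if "database" not in df.columns:
        df["database"] = "default"
    out = []
    for (db, name), grp in df.groupby(["database", "feature"], sort=True):
        out.append(FeatureSet(name=name, members=set(grp["probe_id"]), database=db))
    return out
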