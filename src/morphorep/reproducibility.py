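"""Cross-analysis reproducibility scoring of per-feature effect sizes.

Two analyses (two cohorts, two software versions, or two processing streams)
each yield a Cohen's d with 95% CI per feature.  For every shared feature the
composite reproducibility score is

    S = sigma + omega + epsilon

where sigma = 1 iff the effect direction agrees, omega = 1 iff the 95%
confidence intervals overlap (closed intervals: touching endpoints count),
and epsilon = min(|d_A|, |d_B|).  S is symmetric in the two analyses and
ranges over [0, 2 + epsilon]; higher values flag features whose group
difference replicates.

Zero-effect handling (``zero_sign_rule``): with the default ``"conservative"``
rule a single exactly-zero d cannot confirm a direction (sigma = 0) while two
zero effects agree trivially (sigma = 1); the ``"lenient"`` rule counts any
zero as agreeing.  Rounded published tables can produce exact zeros, so the
choice is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .effects import EffectSizeRecord, effect_sizes
from .io_tables import CohortSummaryTable

__all__ = ["ReproRecord", "ConcordanceSummary", "repro_record", "concordance"]


@dataclass(frozen=True)
class ReproRecord:
    """Reproducibility of one feature's effect across two analyses."""

    feature: str
    d_a: float
    d_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    sigma: int
    omega: int
    epsilon: float
    score: float


@dataclass
class ConcordanceSummary:
    """Whole-panel agreement between two analyses' effect-size profiles."""

    correlation: float
    correlation_p: float
    fraction_directionally_consistent: float
    fraction_ci_overlap: float
    records: list[ReproRecord]  # ranked by S descending, ties by feature label

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": [r.feature for r in self.records],
                "d_a": [r.d_a for r in self.records],
                "d_b": [r.d_b for r in self.records],
                "sigma": [r.sigma for r in self.records],
                "omega": [r.omega for r in self.records],
                "epsilon": [r.epsilon for r in self.records],
                "score": [r.score for r in self.records],
            }
        )

    def top_features(self, k: int = 5) -> list[str]:
        return [r.feature for r in self.records[:k]]


def _sigma(d_a: float, d_b: float, zero_sign_rule: str) -> int:
    sa, sb = np.sign(d_a), np.sign(d_b)
    if zero_sign_rule == "conservative":
        if sa == 0 and sb == 0:
            return 1
        if sa == 0 or sb == 0:
            return 0
        return int(sa == sb)
    if zero_sign_rule == "lenient":
        return int(sa * sb >= 0)
    raise ValueError(f"unknown zero_sign_rule {zero_sign_rule!r}")


def repro_record(
    rec_a: EffectSizeRecord,
    rec_b: EffectSizeRecord,
    zero_sign_rule: str = "conservative",
) -> ReproRecord:
    """Combine one feature's effect sizes from two analyses into S = sigma+omega+epsilon."""
    if rec_a.feature != rec_b.feature:
        raise ValueError(f"feature mismatch: {rec_a.feature!r} vs {rec_b.feature!r}")
    sigma = _sigma(rec_a.d, rec_b.d, zero_sign_rule)
    omega = int(rec_a.ci_lo <= rec_b.ci_hi and rec_b.ci_lo <= rec_a.ci_hi)
    epsilon = min(abs(rec_a.d), abs(rec_b.d))
    return ReproRecord(
        feature=rec_a.feature,
        d_a=rec_a.d, d_b=rec_b.d,
        ci_a=(rec_a.ci_lo, rec_a.ci_hi), ci_b=(rec_b.ci_lo, rec_b.ci_hi),
        sigma=sigma, omega=omega, epsilon=float(epsilon),
        score=float(sigma + omega + epsilon),
    )


def concordance(
    table_a: CohortSummaryTable,
    table_b: CohortSummaryTable,
    method: str = "pearson",
    zero_sign_rule: str = "conservative",
) -> ConcordanceSummary:
    """Full-panel concordance between two cohort summary tables.

    Effect sizes are computed per shared region in each table; the summary
    holds the correlation of the two d vectors, the fractions of regions with
    direction agreement and CI overlap, and the ranked per-region records.
    Exchanging the two tables leaves every S and both fractions unchanged.
    """
    eff_a = effect_sizes(table_a)
    eff_b = effect_sizes(table_b)
    shared = [r for r in table_a.regions if r in eff_b]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared features, got {len(shared)}")
    records = [repro_record(eff_a[f], eff_b[f], zero_sign_rule) for f in shared]
    d_a = np.array([r.d_a for r in records])
    d_b = np.array([r.d_b for r in records])
    if method == "pearson":
        r, p = stats.pearsonr(d_a, d_b)
    elif method == "spearman":
        r, p = stats.spearmanr(d_a, d_b)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    records.sort(key=lambda rec: (-rec.score, rec.feature))
    return ConcordanceSummary(
        correlation=float(r),
        correlation_p=float(p),
        fraction_directionally_consistent=float(np.mean([r.sigma for r in records])),
        fraction_ci_overlap=float(np.mean([r.omega for r in records])),
        records=records,
    )
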