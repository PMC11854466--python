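"""Per-feature two-group statistics.

Cohen's d with its large-sample 95% CI, computed from summary statistics so
that published tables (means/SDs/n) can be compared without subject-level
data; Cliff's delta from rank comparisons with Mann-Whitney p-values;
Bonferroni adjustment; strength-band labels; Spearman association matrices.

Sign convention: d and delta are positive when the healthy-control group is
larger.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import CohortSummaryTable, RegionSummary, SubjectTable

__all__ = [
    "EffectSizeRecord",
    "CliffResult",
    "BandLabel",
    "pooled_sd",
    "cohens_d",
    "cohens_d_from_stats",
    "effect_sizes",
    "cliffs_delta",
    "bonferroni",
    "band_label",
    "spearman_matrix",
    "group_compare",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class EffectSizeRecord:
    """Standardized mean difference with pooled SD and 95% CI."""

    feature: str
    d: float
    sp: float
    ci_lo: float
    ci_hi: float
    n1: int
    n2: int


@dataclass(frozen=True)
class CliffResult:
    feature: str
    delta: float
    u_stat: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class BandLabel:
    name: str
    scheme: str


def pooled_sd(n1: int, s1: float, n2: int, s2: float) -> float:
    """Pooled standard deviation sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2))."""
    if n1 + n2 <= 2:
        raise ValueError("pooled SD requires n1 + n2 > 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be >= 0")
    return float(np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)))


def cohens_d_from_stats(
    feature: str,
    n1: int, mean1: float, s1: float,
    n2: int, mean2: float, s2: float,
) -> EffectSizeRecord:
    """Cohen's d = (mean1 - mean2) / sp with the large-sample 95% CI.

    CI half-width: z * sqrt((n1+n2)/(n1*n2) + d^2 / (2*(n1+n2))).
    Antisymmetric under swapping the two groups.  sp = 0 with equal means
    yields d = 0 by convention; sp = 0 with unequal means is an error (the
    standardized effect would be infinite).
    """
    sp = pooled_sd(n1, s1, n2, s2)
    diff = mean1 - mean2
    if sp == 0:
        if diff != 0:
            raise ZeroDivisionError(
                f"{feature}: zero pooled SD with unequal means gives an infinite effect"
            )
        d = 0.0
    else:
        d = diff / sp
    n = n1 + n2
    half = Z_95 * np.sqrt(n / (n1 * n2) + d**2 / (2 * n))
    return EffectSizeRecord(feature, float(d), sp, float(d - half), float(d + half), n1, n2)


def cohens_d(summary: RegionSummary) -> EffectSizeRecord:
    """Effect size HC vs IBS from a region summary (positive = larger in HC)."""
    return cohens_d_from_stats(
        summary.region,
        summary.hc.n, summary.hc.mean, summary.hc.sd,
        summary.ibs.n, summary.ibs.mean, summary.ibs.sd,
    )


def effect_sizes(table: CohortSummaryTable) -> dict[str, EffectSizeRecord]:
    """Cohen's d per region for a whole cohort summary table."""
    return {rec.region: cohens_d(rec) for rec in table.records}


def cliffs_delta(x, y, feature: str = "", m_correction: int = 1) -> CliffResult:
    """Cliff's delta between samples x and y, with the Mann-Whitney p-value.

    delta = (#{x_i > y_j} - #{x_i < y_j}) / (n_x n_y) = 2U/(n_x n_y) - 1,
    where U counts ties as 0.5.  delta = +1 iff every x strictly exceeds every
    y; antisymmetric in (x, y).  The two-sided p uses exact enumeration for
    small tie-free samples and the tie-corrected normal approximation
    otherwise (group sizes above 20 sit in the asymptotic regime).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "asymptotic" if (has_ties or max(x.size, y.size) > 20) else "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)
    delta = 2.0 * u / (x.size * y.size) - 1.0
    p = float(res.pvalue)
    p_adj = bonferroni([p], m=m_correction)[0]
    return CliffResult(feature, float(delta), u, p, p_adj)


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment p_adj = min(1, m * p); order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return list(np.minimum(1.0, m * p))


# Printed bands are closed on their endpoints; values falling in the unprinted
# gaps between bands (e.g. 0.145 on the Cliff scheme) go to the nearer band,
# which the midpoint cut-offs below implement.  Below the lowest labelled band
# everything is negligible.
_CLIFF_CUTS = [(0.145, "negligible"), (0.335, "small"), (0.475, "medium")]
_SPEARMAN_CUTS = [(0.395, "weak"), (0.595, "moderate"), (0.795, "strong")]


def band_label(value: float, scheme: str) -> BandLabel:
    """Strength-band label for an absolute Cliff's delta or Spearman rho."""
    a = abs(float(value))
    if a > 1:
        raise ValueError(f"|value| must be <= 1, got {value}")
    if scheme == "cliff":
        cuts, top = _CLIFF_CUTS, "large"
    elif scheme == "spearman":
        if a < 0.20:  # weak band's closed lower endpoint
            return BandLabel("negligible", scheme)
        cuts, top = _SPEARMAN_CUTS, "very strong"
    else:
        raise ValueError(f"unknown scheme {scheme!r}; use 'cliff' or 'spearman'")
    for upper, name in cuts:
        if a <= upper:
            return BandLabel(name, scheme)
    return BandLabel(top, scheme)


def spearman_matrix(table: SubjectTable | pd.DataFrame, features: list[str]) -> pd.DataFrame:
    """Symmetric Spearman rank-correlation matrix over the named features.

    Invariant under strictly monotone transforms of any feature.  A constant
    feature yields NaN entries and a warning, never a silent zero.
    """
    df = table.features(features) if isinstance(table, SubjectTable) else table[features]
    if len(df.dropna()) < 3:
        raise ValueError("need at least 3 complete observations")
    constant = [c for c in features if df[c].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(f"constant features yield undefined correlations: {constant}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=stats.ConstantInputWarning)
        rho, _ = stats.spearmanr(df.to_numpy(), nan_policy="omit")
    if np.ndim(rho) == 0:  # scipy collapses the two-feature case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    out = pd.DataFrame(np.atleast_2d(rho), index=features, columns=features)
    np.fill_diagonal(out.values, [np.nan if c in constant else 1.0 for c in features])
    return out


def group_compare(
    table: SubjectTable,
    features: list[str],
    m_correction: int | None = None,
) -> pd.DataFrame:
    """Per-feature HC-vs-IBS comparison: medians/IQRs, U, p, Cliff's delta, band.

    The Bonferroni factor defaults to the number of features tested.
    """
    hc = table.data[table.data["group"] == "HC"]
    ibs = table.data[table.data["group"] == "IBS"]
    m = m_correction if m_correction is not None else len(features)
    rows = []
    for feat in features:
        x = hc[feat].dropna().to_numpy()
        y = ibs[feat].dropna().to_numpy()
        res = cliffs_delta(x, y, feature=feat, m_correction=m)
        q1x, q3x = np.percentile(x, [25, 75])
        q1y, q3y = np.percentile(y, [25, 75])
        rows.append({
            "feature": feat,
            "hc_median": float(np.median(x)), "hc_iqr": float(q3x - q1x),
            "ibs_median": float(np.median(y)), "ibs_iqr": float(q3y - q1y),
            "u_stat": res.u_stat,
            "p_raw": res.p_raw,
            "p_adj": res.p_adjusted,
            "delta": res.delta,
            "band": band_label(res.delta, "cliff").name,
        })
    return pd.DataFrame(rows)
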