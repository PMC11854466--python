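"""Synthetic two-group cohort generator.

Emulates the statistical structure of a morphometry-plus-cognition case/
control study so that every downstream analysis is testable without any
data download: eTIV-normalized regional volumes drawn from a multivariate
normal whose per-group means/SDs default to the shipped Bergen summary
table, strong bilateral correlations (hippocampus ~0.8, amygdala ~0.7,
putamen ~0.9) over a mild global dependence (0.3), age-corrected cognitive
index scores around mean 100 / SD 15, symptom-severity scores in the
screening bands (controls < 75, patients >= 175), sex at the study's
proportions, and raw volumes produced by multiplying by a per-subject eTIV
near 1.5e6 mm^3 so that eTIV normalization recovers the target scale.

The echoed config plus seed regenerate the table bit-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import (
    COGNITIVE_INDICES,
    FeaturePanel,
    SubjectTable,
    load_fixture_summary,
)

__all__ = [
    "SimConfig",
    "GeneratedCohort",
    "generate",
    "impute_sss",
    "null_config",
    "nearest_pd_correlation",
]

_BILATERAL_DEFAULT = {
    ("Left Hippocampus", "Right Hippocampus"): 0.8,
    ("Left Amygdala", "Right Amygdala"): 0.7,
    ("Left Putamen", "Right Putamen"): 0.9,
}

# Group shifts of the cognitive indices in index points (HC minus IBS),
# chosen to land the rank-based effect sizes near the reported small-band
# values (full-scale delta ~0.2).
_COGNITIVE_SHIFT_DEFAULT = {
    "Full-scale RBANS": 6.0,
    "Memory Index": 4.0,
    "Visuospatial Index": 1.0,
    "Verbal Skills Index": 3.0,
    "Attention Index": 3.0,
    "Recall Index": 5.0,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort draw."""

    n_hc: int = 29
    n_ibs: int = 49
    #: per-region (hc_mean, hc_sd, ibs_mean, ibs_sd) of normalized volume;
    #: None loads the Bergen summary-table columns.
    region_params: tuple[tuple[str, float, float, float, float], ...] | None = None
    bilateral_rho: tuple[tuple[str, str, float], ...] = tuple(
        (a, b, r) for (a, b), r in _BILATERAL_DEFAULT.items()
    )
    base_region_rho: float = 0.3
    #: overrides the whole group-difference structure when given: for every
    #: feature, IBS mean = HC mean - d * SD with d = effect_vector.get(f, 0).
    effect_vector: tuple[tuple[str, float], ...] | None = None
    cognitive_mean: float = 100.0
    cognitive_sd: float = 15.0
    cognitive_rho: float = 0.5
    recall_memory_rho: float = 0.67
    cognitive_shift: tuple[tuple[str, float], ...] = tuple(_COGNITIVE_SHIFT_DEFAULT.items())
    #: severity bands: controls truncated to [0, 74], patients to [175, 500]
    sss_hc: tuple[float, float] = (25.0, 15.0)  # (mean, sd) before truncation
    sss_ibs: tuple[float, float] = (264.0, 71.0)
    missing_rate_sss: float = 0.08
    sex_frac_f: tuple[float, float] = (0.69, 0.776)  # (HC, IBS)
    age_mean: float = 34.0
    age_sd: float = 10.0
    etiv_mean: float = 1.5e6
    etiv_sd: float = 1.5e5
    seed: int = 0


@dataclass
class GeneratedCohort:
    table: SubjectTable
    truth: SimConfig


def nearest_pd_correlation(corr: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Repair a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues are clipped at ``eps`` and the result rescaled to unit
    diagonal; a matrix that is already PD passes through (up to symmetry).
    """
    corr = (corr + corr.T) / 2
    w, v = np.linalg.eigh(corr)
    if w.min() <= 0:
        w = np.clip(w, eps, None)
        corr = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        corr = (corr + corr.T) / 2
    if np.linalg.eigvalsh(corr).min() <= 0:
        raise ValueError("correlation matrix not positive definite after repair")
    return corr


def _feature_params(config: SimConfig) -> pd.DataFrame:
    """Per-feature (hc_mean, hc_sd, ibs_mean, ibs_sd, kind) under the config."""
    if config.region_params is None:
        bergen = load_fixture_summary("bergen")
        region_rows = [
            (r.region, r.hc.mean, r.hc.sd, r.ibs.mean, r.ibs.sd) for r in bergen.records
        ]
    else:
        region_rows = list(config.region_params)
    rows = [
        {"feature": f, "hc_mean": m1, "hc_sd": s1, "ibs_mean": m2, "ibs_sd": s2, "kind": "region"}
        for f, m1, s1, m2, s2 in region_rows
    ]
    shift = dict(config.cognitive_shift)
    for idx in COGNITIVE_INDICES:
        s = shift.get(idx, 0.0)
        rows.append({
            "feature": idx,
            "hc_mean": config.cognitive_mean + s / 2,
            "hc_sd": config.cognitive_sd,
            "ibs_mean": config.cognitive_mean - s / 2,
            "ibs_sd": config.cognitive_sd,
            "kind": "cognitive",
        })
    params = pd.DataFrame(rows)
    if (params["hc_sd"] <= 0).any() or (params["ibs_sd"] <= 0).any():
        raise ValueError("feature SDs must be > 0")
    if config.effect_vector is not None:
        d = dict(config.effect_vector)
        params["ibs_mean"] = params["hc_mean"] - params["feature"].map(
            lambda f: d.get(f, 0.0)
        ) * params["hc_sd"]
        params["ibs_sd"] = params["hc_sd"]
    return params


def _correlation(config: SimConfig, params: pd.DataFrame) -> np.ndarray:
    k = len(params)
    kinds = params["kind"].to_numpy()
    corr = np.eye(k)
    region = kinds == "region"
    cognitive = kinds == "cognitive"
    corr[np.ix_(region, region)] = config.base_region_rho
    corr[np.ix_(cognitive, cognitive)] = config.cognitive_rho
    # cognitive-morphometry cross-correlations stay at 0: the study found
    # structure-function associations to be negligible-to-weak
    index = {f: i for i, f in enumerate(params["feature"])}
    for a, b, r in config.bilateral_rho:
        if a in index and b in index:
            corr[index[a], index[b]] = corr[index[b], index[a]] = r
    rm = ("Recall Index", "Memory Index")
    if rm[0] in index and rm[1] in index:
        i, j = index[rm[0]], index[rm[1]]
        corr[i, j] = corr[j, i] = config.recall_memory_rho
    np.fill_diagonal(corr, 1.0)
    return nearest_pd_correlation(corr)


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate(config: SimConfig | None = None) -> GeneratedCohort:
    """Draw one cohort under the configured study conditions.

    Deterministic given ``config.seed``: the echoed config regenerates the
    table bit-identically.
    """
    config = config or SimConfig()
    params = _feature_params(config)
    corr = _correlation(config, params)
    chol = np.linalg.cholesky(corr)
    rng = np.random.default_rng(config.seed)
    features = list(params["feature"])
    region_cols = list(params.loc[params["kind"] == "region", "feature"])

    frames = []
    for group, n in (("HC", config.n_hc), ("IBS", config.n_ibs)):
        mean = params[f"{'hc' if group == 'HC' else 'ibs'}_mean"].to_numpy()
        sd = params[f"{'hc' if group == 'HC' else 'ibs'}_sd"].to_numpy()
        Z = rng.standard_normal((n, len(features)))
        X = mean + (Z @ chol.T) * sd
        df = pd.DataFrame(X, columns=features)
        df.insert(0, "group", group)
        frac_f = config.sex_frac_f[0 if group == "HC" else 1]
        df.insert(1, "sex", np.where(rng.random(n) < frac_f, "F", "M"))
        df.insert(2, "age", np.round(_truncnorm(rng, config.age_mean, config.age_sd, 18, 70, n), 1))
        if group == "HC":
            sss = _truncnorm(rng, *config.sss_hc, 0, 74, n)
        else:
            sss = _truncnorm(rng, *config.sss_ibs, 175, 500, n)
        sss = np.round(sss, 0)
        sss[rng.random(n) < config.missing_rate_sss] = np.nan
        df.insert(3, "ibs_sss", sss)
        etiv = _truncnorm(rng, config.etiv_mean, config.etiv_sd, 1.1e6, 1.9e6, n)
        df.insert(4, "eTIV", etiv)
        # store raw mm^3 volumes; eTIV normalization recovers the drawn scale
        df[region_cols] = df[region_cols].mul(etiv, axis=0)
        frames.append(df)

    data = pd.concat(frames, ignore_index=True)
    data.insert(0, "subject_id", [f"SYN_{i:03d}" for i in range(len(data))])
    panel = FeaturePanel(
        region_columns=tuple(region_cols),
        cognitive_columns=COGNITIVE_INDICES,
        include_etiv=True,
    )
    return GeneratedCohort(table=SubjectTable(data, panel), truth=config)


def impute_sss(table: SubjectTable, m: int = 5, seed: int = 0) -> list[SubjectTable]:
    """Multiple imputation of missing severity scores, stratified by group and sex.

    Each missing cell is drawn from the empirical distribution of observed
    scores within the same (group, sex) stratum, independently in each of the
    ``m`` completed copies.  An empty stratum falls back to the group-only
    stratum with a warning.  Because strata never mix groups, imputed control
    values stay below 75 and imputed patient values at or above 175 whenever
    the observed data respect those bands.
    """
    df = table.data
    missing_idx = df.index[df["ibs_sss"].isna()]
    if len(missing_idx) == 0:
        return [SubjectTable(df.copy(), table.panel) for _ in range(m)]
    rng = np.random.default_rng(seed)
    completed = []
    for _ in range(m):
        out = df.copy()
        for i in missing_idx:
            group, sex = df.loc[i, "group"], df.loc[i, "sex"]
            pool = df.loc[
                (df["group"] == group) & (df["sex"] == sex), "ibs_sss"
            ].dropna().to_numpy()
            if pool.size == 0:
                warnings.warn(
                    f"empty ({group}, {sex}) stratum; falling back to group-only pool"
                )
                pool = df.loc[df["group"] == group, "ibs_sss"].dropna().to_numpy()
            if pool.size == 0:
                raise ValueError(f"no observed severity scores in group {group}")
            out.loc[i, "ibs_sss"] = rng.choice(pool)
        completed.append(SubjectTable(out, table.panel))
    return completed


def null_config(n_per_group: int = 100, seed: int = 0, **overrides) -> SimConfig:
    """A convenience config with no true group differences anywhere."""
    return replace(
        SimConfig(n_hc=n_per_group, n_ibs=n_per_group, effect_vector=(), seed=seed),
        **overrides,
    )
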