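"""Per-table transforms and outlier filters applied before association testing.

Pipeline orders:

* microbial features: zeros_to_missing -> arcsine_sqrt -> grubbs_filter
  (per feature) -> standardize
* metabolites: below-detection -> missing, runday_median_scale,
  log_transform, then standardize for faecal metabolites only.

All transforms preserve table shape and sample/feature identity; only
values change.  Sample standard deviation (n-1 denominator) is used
throughout.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "zeros_to_missing",
    "arcsine_sqrt",
    "grubbs_filter",
    "standardize",
    "pca_sample_outliers",
    "runday_median_scale",
    "log_transform",
    "inverse_normal_transform",
    "sd_outlier_mask",
    "preprocess_features",
    "preprocess_metabolites",
]


def zeros_to_missing(t: pd.DataFrame) -> pd.DataFrame:
    """Exact zeros become missing (zero abundance = not detected)."""
    return t.mask(t == 0)


def arcsine_sqrt(t: pd.DataFrame) -> pd.DataFrame:
    """Arcsine square-root transform for relative abundances in [0, 1]."""
    vals = t.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (vals < 0) | (vals > 1)
    if np.any(bad & ~np.isnan(vals)):
        raise ValueError("arcsine_sqrt requires values in [0, 1]")
    return pd.DataFrame(np.arcsin(np.sqrt(vals)), index=t.index, columns=t.columns)


def _grubbs_critical(n: int, alpha: float) -> float:
    t_crit = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t_crit**2 / (n - 2 + t_crit**2))


def grubbs_filter(values: pd.Series, alpha: float = 0.05) -> pd.Series:
    """Iterative two-sided Grubbs outlier removal; outliers set to missing.

    Repeatedly removes the single most extreme point while
    G = max|x - mean| / sd exceeds the critical value at ``alpha``.  Hard
    stop at floor(n/2) removals.  Fewer than 3 non-missing values: returned
    unchanged with a warning.
    """
    out = values.astype(float).copy()
    n_orig = int(out.notna().sum())
    if n_orig < 3:
        warnings.warn("grubbs_filter: fewer than 3 non-missing values; unchanged",
                      stacklevel=2)
        return out
    max_removals = n_orig // 2
    removed = 0
    while removed < max_removals:
        x = out.dropna()
        n = len(x)
        if n < 3:
            break
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            break
        dev = (x - x.mean()).abs()
        g = dev.max() / sd
        if g <= _grubbs_critical(n, alpha):
            break
        out[dev.idxmax()] = np.nan
        removed += 1
    return out


def standardize(values: pd.Series) -> pd.Series:
    """Center to mean 0 and scale to unit sample SD; missing preserved."""
    x = values.astype(float)
    obs = x.dropna()
    if obs.nunique() < 2:
        raise ValueError("standardize requires >= 2 distinct non-missing values")
    return (x - obs.mean()) / obs.std(ddof=1)


def pca_sample_outliers(
    t: pd.DataFrame, n_pcs: int = 10, sd_mult: float = 3.0
) -> list:
    """Samples with |score| > sd_mult * SD(score) on any of the first n_pcs PCs.

    Single pass, centred (not variance-scaled) PCA; zero-variance components
    are skipped.  Missing entries are treated as zero abundance (the filter
    runs before zeros are recoded as missing).
    """
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    if len(t) < 2:
        raise ValueError("need more than one sample")
    X = t.to_numpy(dtype=float)
    X = np.nan_to_num(X, nan=0.0)
    X = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U * s  # n x rank
    k = min(n_pcs, scores.shape[1])
    flagged = np.zeros(len(t), dtype=bool)
    for j in range(k):
        sc = scores[:, j]
        sd = sc.std(ddof=1)
        if sd <= 1e-12 * max(1.0, np.abs(sc).max(), 1e-300):
            continue
        flagged |= np.abs(sc) > sd_mult * sd
    return list(t.index[flagged])


def runday_median_scale(t: pd.DataFrame, runday: pd.Series) -> pd.DataFrame:
    """Divide each value by the median of its metabolite within its run-day."""
    rd = runday.reindex(t.index)
    if rd.isna().any():
        raise ValueError("runday labels missing for some samples")
    med = t.groupby(rd).transform("median")
    return t / med


def log_transform(t: pd.DataFrame) -> pd.DataFrame:
    """Natural log; requires strictly positive present values."""
    vals = t.to_numpy(dtype=float)
    if np.any((vals <= 0) & ~np.isnan(vals)):
        raise ValueError("log_transform requires positive values")
    with np.errstate(invalid="ignore"):
        return pd.DataFrame(np.log(vals), index=t.index, columns=t.columns)


def inverse_normal_transform(values: pd.Series) -> pd.Series:
    """Rank-based inverse-normal transform: rank r of n maps to
    Phi^-1((r - 0.5)/n); ties share the average rank."""
    x = values.astype(float)
    obs = x.dropna()
    if obs.nunique() < 2:
        raise ValueError("inverse_normal_transform requires >= 2 distinct values")
    ranks = stats.rankdata(obs)
    z = stats.norm.ppf((ranks - 0.5) / len(obs))
    out = pd.Series(np.nan, index=x.index, dtype=float)
    out.loc[obs.index] = z
    return out


def sd_outlier_mask(values: pd.Series, sd_mult: float = 3.0) -> pd.Series:
    """Single-pass mask: values further than sd_mult SDs from the mean become
    missing (the adiposity-phenotype exclusion rule)."""
    x = values.astype(float).copy()
    obs = x.dropna()
    if len(obs) < 2:
        return x
    sd = obs.std(ddof=1)
    if sd == 0:
        return x
    return x.mask((x - obs.mean()).abs() > sd_mult * sd)


def preprocess_features(t: pd.DataFrame, alpha: float = 0.05,
                        min_distinct: int = 2) -> pd.DataFrame:
    """Full microbial-feature pipeline: zeros->NA, arcsine-sqrt, per-feature
    Grubbs filtering and standardization.

    Features left with fewer than 2 distinct values are set entirely missing
    rather than raising (they are dropped later by the min-n rule).
    """
    out = arcsine_sqrt(zeros_to_missing(t))
    cols = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for c in out.columns:
            v = grubbs_filter(out[c], alpha=alpha)
            if v.dropna().nunique() < min_distinct:
                cols[c] = pd.Series(np.nan, index=out.index)
            else:
                cols[c] = standardize(v)
    return pd.DataFrame(cols, index=out.index)


def preprocess_metabolites(
    t: pd.DataFrame, runday: pd.Series | None = None, scale: bool = False
) -> pd.DataFrame:
    """Metabolite pipeline: run-day median scaling (when labels are given),
    natural log, and — for faecal metabolites only — standardization."""
    out = t.mask(t == 0)
    if runday is not None:
        out = runday_median_scale(out, runday)
    out = log_transform(out)
    if scale:
        cols = {}
        for c in out.columns:
            if out[c].dropna().nunique() < 2:
                cols[c] = pd.Series(np.nan, index=out.index)
            else:
                cols[c] = standardize(out[c])
        out = pd.DataFrame(cols, index=out.index)
    return out
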