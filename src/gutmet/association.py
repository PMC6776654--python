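"""Variance-component mixed-model association screen with Storey FDR.

The model is y ~ N(X beta, sigma_g^2 K + sigma_e^2 I), fit by maximum
likelihood via a 1-D profile over h = sigma_g^2 / (sigma_g^2 + sigma_e^2)
after a single eigendecomposition of K restricted to complete cases.
Association is tested by a likelihood-ratio test of the feature's fixed
effect against a chi-square with 1 degree of freedom; both fits use the
complete-case set of the full model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VCFit",
    "fit_vc",
    "lrt_association",
    "storey_qvalues",
    "run_screen",
    "covariate_sensitivity",
    "bonferroni_threshold",
]

_H_MAX = 1.0 - 1e-6


def _drop_constant(C: np.ndarray) -> np.ndarray:
    """Drop covariate columns that are constant on the complete-case subset
    (they are collinear with the intercept)."""
    if C.ndim == 1:
        C = C[:, None]
    keep = np.ptp(C, axis=0) > 0
    return C[:, keep]


@dataclass
class VCFit:
    """ML fit of y ~ N(X beta, sigma_g^2 K + sigma_e^2 I)."""

    beta_hat: np.ndarray
    se: np.ndarray
    sigma_g2: float
    sigma_e2: float
    loglik: float
    n: int
    h: float
    boundary: bool = False


def _profile_ml(h: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    """Profile ML pieces at heritability fraction h.

    Returns (negative log-likelihood, beta, XtWiX inverse, sigma2).
    """
    n, p = Xt.shape
    w = h * d + (1.0 - h)
    wi = 1.0 / w
    XtW = Xt * wi[:, None]
    A = XtW.T @ Xt
    b = XtW.T @ yt
    try:
        beta = np.linalg.solve(A, b)
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise ValueError("design matrix is rank-deficient") from exc
    r = yt - Xt @ beta
    sigma2 = float(np.sum(r * r * wi) / n)
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    ll = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + np.sum(np.log(w)))
    return -ll, beta, Ainv, sigma2


def fit_vc(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    n_grid: int = 21,
) -> VCFit:
    """Maximum-likelihood variance-component fit.

    Parameters
    ----------
    y, X
        Complete-case response and fixed-effect design (caller drops rows
        with missing values).
    K
        Expected-relatedness matrix; PSD but possibly singular (MZ blocks).
    eig
        Optional precomputed ``(eigenvalues, eigenvectors)`` of K; callers
        testing many pairs on the same complete-case pattern should cache
        this.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank-deficient")
    if eig is None:
        if K is None:
            d = np.ones(n)
            U = None
        else:
            d, U = np.linalg.eigh(np.asarray(K, dtype=float))
            d = np.clip(d, 0.0, None)
    else:
        d, U = eig
    if U is None:
        yt, Xt = y, X
    else:
        yt = U.T @ y
        Xt = U.T @ X

    # coarse grid then bounded Brent around the best point; the profile
    # likelihood in h is cheap to evaluate and rarely multimodal
    grid = np.linspace(0.0, _H_MAX, n_grid)
    nlls = [_profile_ml(h, d, yt, Xt)[0] for h in grid]
    i = int(np.argmin(nlls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda h: _profile_ml(h, d, yt, Xt)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        h_hat = float(res.x) if res.fun <= nlls[i] else float(grid[i])
    else:
        h_hat = float(grid[i])
    nll, beta, Ainv, sigma2 = _profile_ml(h_hat, d, yt, Xt)
    se = np.sqrt(np.clip(np.diag(Ainv), 0, None) * sigma2)
    boundary = h_hat <= 1e-8 or h_hat >= _H_MAX - 1e-8
    return VCFit(
        beta_hat=beta,
        se=se,
        sigma_g2=h_hat * sigma2,
        sigma_e2=(1.0 - h_hat) * sigma2,
        loglik=-nll,
        n=n,
        h=h_hat,
        boundary=boundary,
    )


def lrt_association(
    metabolite: pd.Series,
    feature: pd.Series,
    covariates: pd.DataFrame | None,
    K: pd.DataFrame,
    min_n: int = 50,
    eig_cache: dict | None = None,
) -> dict | None:
    """One feature-metabolite association test.

    Returns a record dict (n, beta, se, p, loglik_null, loglik_full) or
    ``None`` when fewer than ``min_n`` complete observations remain.  The
    complete-case set is defined by the full model's variables and shared
    by both fits.
    """
    idx = metabolite.index
    parts = [metabolite, feature.reindex(idx)]
    if covariates is not None:
        cov = covariates.reindex(idx)
        parts.append(cov)
    frame = pd.concat(parts, axis=1)
    mask = frame.notna().all(axis=1)
    n = int(mask.sum())
    if n < min_n:
        return None
    ids = idx[mask]
    y = metabolite[mask].to_numpy(dtype=float)
    x = feature[mask].to_numpy(dtype=float)
    ones = np.ones(n)
    if covariates is not None:
        C = covariates.loc[ids].to_numpy(dtype=float)
        C = _drop_constant(C)
        X_null = np.column_stack([ones, C]) if C.shape[1] else ones[:, None]
    else:
        X_null = ones[:, None]
    if np.ptp(x) == 0:
        return None  # feature constant on the complete-case set: untestable
    X_full = np.column_stack([X_null, x])

    eig = None
    if eig_cache is not None:
        key = mask.to_numpy().tobytes()
        eig = eig_cache.get(key)
    if eig is None:
        Ksub = K.loc[ids, ids].to_numpy(dtype=float)
        d, U = np.linalg.eigh(Ksub)
        eig = (np.clip(d, 0.0, None), U)
        if eig_cache is not None:
            eig_cache[key] = eig

    full = fit_vc(y, X_full, eig=eig)
    null = fit_vc(y, X_null, eig=eig)
    stat = 2.0 * (full.loglik - null.loglik)
    if stat < -1e-6:
        # numerical slip: re-fit the null on a finer grid before giving up
        null2 = fit_vc(y, X_null, eig=eig, n_grid=101)
        full2 = fit_vc(y, X_full, eig=eig, n_grid=101)
        stat = 2.0 * (max(full.loglik, full2.loglik) - max(null.loglik, null2.loglik))
        if stat < -1e-6:
            raise ArithmeticError(f"negative LRT statistic {stat:g}")
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df=1))
    return {
        "n": n,
        "beta": float(full.beta_hat[-1]),
        "se": float(full.se[-1]),
        "p": max(p, np.finfo(float).tiny),
        "loglik_null": null.loglik,
        "loglik_full": full.loglik,
    }


def storey_qvalues(p, pi0: float | None = None) -> np.ndarray:
    """Storey q-values.

    pi0 is estimated by evaluating #{p > lambda} / (m (1 - lambda)) on the
    grid lambda = 0.05, 0.10, ..., 0.90, smoothing with a cubic polynomial
    and taking the value at the largest lambda, capped at 1.  For fewer than
    100 P values the smoother is unstable and pi0 falls back to 1 (with a
    warning), which makes the q-values identical to Benjamini-Hochberg.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty P value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("P values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if m < 100:
            warnings.warn(
                "storey_qvalues: fewer than 100 P values; using pi0 = 1",
                stacklevel=2,
            )
            pi0 = 1.0
        else:
            lam = np.arange(0.05, 0.905, 0.05)
            pi0_lam = np.array(
                [np.mean(p > l) / (1.0 - l) for l in lam]
            )
            coef = np.polyfit(lam, pi0_lam, deg=3)
            pi0 = float(np.polyval(coef, lam[-1]))
            pi0 = min(pi0, 1.0)
            if pi0 <= 0:
                pi0 = float(max(pi0_lam.min(), 1.0 / m))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    # op order mirrors the usual BH implementation so that pi0 = 1
    # reproduces Benjamini-Hochberg bit-for-bit
    q = pi0 * (ranked / (np.arange(1, m + 1) / m))
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def run_screen(
    metabolites: pd.DataFrame,
    features: pd.DataFrame,
    covariates: pd.DataFrame | None,
    K: pd.DataFrame,
    min_n: int = 50,
) -> pd.DataFrame:
    """Test every (feature, metabolite) pair; one Storey FDR batch.

    Tables must share their sample index.  Returns a record per tested pair
    with columns feature_id, metabolite_id, n, beta, se, p, q.
    """
    if not metabolites.index.equals(features.index):
        features = features.reindex(metabolites.index)
    eig_cache: dict = {}
    rows = []
    for f in features.columns:
        feat = features[f]
        for met in metabolites.columns:
            rec = lrt_association(
                metabolites[met], feat, covariates, K, min_n=min_n,
                eig_cache=eig_cache,
            )
            if rec is None:
                continue
            rows.append(
                {"feature_id": f, "metabolite_id": met, "n": rec["n"],
                 "beta": rec["beta"], "se": rec["se"], "p": rec["p"]}
            )
    if not rows:
        raise ValueError("no testable feature-metabolite pairs")
    out = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["q"] = storey_qvalues(out["p"].to_numpy())
    return out


def covariate_sensitivity(
    screen_a: pd.DataFrame, screen_b: pd.DataFrame, fdr: float = 0.05
) -> dict:
    """Compare two screens of the same pairs run with different covariates.

    Reports pairs significant in both with concordant effect signs, pairs
    significant in only one screen, and sign-discordant pairs.
    """
    key = ["feature_id", "metabolite_id"]
    a = screen_a.set_index(key)
    b = screen_b.set_index(key)
    if set(a.index) != set(b.index):
        raise ValueError("screens cover different pair sets")
    b = b.reindex(a.index)
    sig_a = a["q"] <= fdr
    sig_b = b["q"] <= fdr
    both = sig_a & sig_b
    concordant = both & (np.sign(a["beta"]) == np.sign(b["beta"]))
    n_both = int(both.sum())
    return {
        "n_pairs": len(a),
        "n_significant_a": int(sig_a.sum()),
        "n_significant_b": int(sig_b.sum()),
        "n_significant_both": n_both,
        "n_concordant": int(concordant.sum()),
        "n_discordant": int((both & ~concordant).sum()),
        "n_only_one": int((sig_a ^ sig_b).sum()),
        "concordance": float(concordant.sum() / n_both) if n_both else float("nan"),
    }


def bonferroni_threshold(alpha: float, n_tests: int, sig_digits: int = 2) -> float:
    """Per-test Bonferroni threshold alpha / n_tests, rounded to
    ``sig_digits`` significant digits."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    t = alpha / n_tests
    if t == 0:
        return 0.0
    exp = int(np.floor(np.log10(abs(t))))
    return round(t, -exp + sig_digits - 1)
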