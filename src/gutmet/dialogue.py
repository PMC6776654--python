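"""Gut-host metabolic dialogue detection.

Stages:

1. faecal and blood metabolites significantly associated with the same
   microbial feature are paired into co-association trios;
2. mediation plausibility is tested by comparing metabolite-pair
   correlations where the feature is present against matched random pairs
   imposed on the same presence patterns (missingness-based simulation);
3. each trio is quantified with the P-gain statistic — the ratio between
   the smaller of the two single-metabolite mixed-model P values and the P
   value of the log-ratio model — against an empirically calibrated
   threshold (95th percentile of P-gains from correlation- and
   sample-size-matched metabolite pairs associated with different
   features).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .association import _drop_constant, fit_vc
from scipy import stats as _stats

__all__ = [
    "find_co_associations",
    "pairwise_r",
    "presence_correlation_test",
    "log_ratio",
    "lmm_family_p",
    "pgain",
    "pgain_records",
    "build_null_pool",
    "match_null_pairs",
    "null_pgains",
    "empirical_pgain_threshold",
    "dialogue_summary",
]

P_FLOOR = 1e-300
TOL_R = 0.05
TOL_N = 0.10


def pairwise_r(a: pd.Series, b: pd.Series, mask: np.ndarray | None = None):
    """Pearson r and n on pairwise-complete observations (optionally within
    a boolean subset)."""
    x = a.to_numpy(dtype=float)
    y = b.reindex(a.index).to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if mask is not None:
        ok &= mask
    n = int(ok.sum())
    if n < 3 or x[ok].std() == 0 or y[ok].std() == 0:
        return float("nan"), n
    return float(np.corrcoef(x[ok], y[ok])[0, 1]), n


def _presence(feature: pd.Series) -> np.ndarray:
    """Detection indicator that works on raw abundances (0 = absent) and on
    transformed tables (absent already recoded as missing, values signed)."""
    return (feature.notna() & (feature != 0)).to_numpy()


def find_co_associations(
    faecal_assoc: pd.DataFrame,
    blood_assoc: pd.DataFrame,
    faecal: pd.DataFrame,
    blood: pd.DataFrame,
    features: pd.DataFrame,
    min_complete: int = 100,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Cartesian pairing of each feature's significant faecal and blood
    metabolites; trios with fewer than ``min_complete`` samples having the
    feature plus both metabolites observed are dropped.

    Returns columns feature_id, faecal_met_id, blood_met_id, n_complete,
    r_observed (Pearson r of the metabolite pair, pairwise complete).
    """
    sig_f = faecal_assoc[faecal_assoc["q"] <= fdr]
    sig_b = blood_assoc[blood_assoc["q"] <= fdr]
    rows = []
    common = set(sig_f["feature_id"]) & set(sig_b["feature_id"])
    blood_al = blood.reindex(faecal.index)
    for f in sorted(common):
        present = _presence(features[f].reindex(faecal.index))
        for fm in sig_f.loc[sig_f["feature_id"] == f, "metabolite_id"]:
            fvec = faecal[fm]
            for bm in sig_b.loc[sig_b["feature_id"] == f, "metabolite_id"]:
                bvec = blood_al[bm]
                ok = fvec.notna().to_numpy() & bvec.notna().to_numpy() & present
                n_complete = int(ok.sum())
                if n_complete < min_complete:
                    continue
                r, _ = pairwise_r(fvec, bvec)
                rows.append({
                    "feature_id": f,
                    "faecal_met_id": fm,
                    "blood_met_id": bm,
                    "n_complete": n_complete,
                    "r_observed": r,
                })
    return pd.DataFrame(
        rows, columns=["feature_id", "faecal_met_id", "blood_met_id",
                       "n_complete", "r_observed"],
    )


def build_null_pool(
    faecal_assoc: pd.DataFrame,
    blood_assoc: pd.DataFrame,
    faecal: pd.DataFrame,
    blood: pd.DataFrame,
    features: pd.DataFrame,
    min_complete: int = 100,
    fdr: float = 0.05,
    exclude: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Candidate null pairs: a significant faecal metabolite and a
    significant blood metabolite associated with two DIFFERENT features
    (conservative no-interplay assumption).

    Each pool record carries the faecal metabolite's feature (used for the
    P-gain regressions), the pair's correlation and complete sample size.
    """
    sig_f = faecal_assoc[faecal_assoc["q"] <= fdr]
    sig_b = blood_assoc[blood_assoc["q"] <= fdr]
    excl = set()
    if exclude is not None and len(exclude):
        excl = set(zip(exclude["faecal_met_id"], exclude["blood_met_id"]))
    blood_al = blood.reindex(faecal.index)
    rows = []
    for frow in sig_f.itertuples():
        present = _presence(features[frow.feature_id].reindex(faecal.index))
        fvec = faecal[frow.metabolite_id]
        for brow in sig_b.itertuples():
            if brow.feature_id == frow.feature_id:
                continue
            if (frow.metabolite_id, brow.metabolite_id) in excl:
                continue
            bvec = blood_al[brow.metabolite_id]
            ok = fvec.notna().to_numpy() & bvec.notna().to_numpy() & present
            n_complete = int(ok.sum())
            if n_complete < min_complete:
                continue
            r, _ = pairwise_r(fvec, bvec)
            if np.isnan(r):
                continue
            rows.append({
                "feature_id": frow.feature_id,
                "faecal_met_id": frow.metabolite_id,
                "blood_met_id": brow.metabolite_id,
                "n_complete": n_complete,
                "r_observed": r,
            })
    return pd.DataFrame(
        rows, columns=["feature_id", "faecal_met_id", "blood_met_id",
                       "n_complete", "r_observed"],
    )


def match_null_pairs(
    targets: pd.DataFrame,
    pool: pd.DataFrame,
    n_draws: int,
    rng: np.random.Generator,
    tol_r: float = TOL_R,
    tol_n: float = TOL_N,
    on_unmatched: str = "error",
) -> pd.DataFrame:
    """Sample ``n_draws`` pool pairs matched 1-to-1 to targets by
    |correlation| (within ``tol_r``, absolute) and sample size (within
    ``tol_n``, relative), with replacement, cycling through targets.

    A target with an empty tolerance neighbourhood triggers one
    widen-and-warn doubling of the tolerances; if still empty, an error
    names the unmatched targets (``on_unmatched="error"``) or the targets
    are dropped from the cycle (``on_unmatched="drop"``).
    """
    if pool.empty:
        raise ValueError("empty null pool")
    pr = np.abs(pool["r_observed"].to_numpy())
    pn = pool["n_complete"].to_numpy()
    t_r = np.abs(targets["r_observed"].to_numpy())
    t_n = targets["n_complete"].to_numpy()

    def neighbourhood(i, fr, fn):
        return np.flatnonzero(
            (np.abs(pr - t_r[i]) <= fr) & (np.abs(pn - t_n[i]) <= fn * t_n[i])
        )

    neigh = []
    widened = False
    unmatched = []
    for i in range(len(targets)):
        cand = neighbourhood(i, tol_r, tol_n)
        if cand.size == 0:
            if not widened:
                warnings.warn(
                    "match_null_pairs: widening tolerances (x2) for targets "
                    "with empty neighbourhoods", stacklevel=2,
                )
                widened = True
            cand = neighbourhood(i, 2 * tol_r, 2 * tol_n)
            if cand.size == 0:
                unmatched.append(i)
        neigh.append(cand)
    usable = list(range(len(targets)))
    if unmatched:
        ids = targets.iloc[unmatched][
            ["feature_id", "faecal_met_id", "blood_met_id"]
        ].to_records(index=False).tolist()
        if on_unmatched == "error" or len(unmatched) == len(targets):
            raise ValueError(f"no matchable pool pairs for targets: {ids}")
        warnings.warn(
            f"match_null_pairs: dropping {len(unmatched)} unmatched targets",
            stacklevel=2,
        )
        usable = [i for i in usable if i not in set(unmatched)]
    out = []
    for d in range(n_draws):
        i = usable[d % len(usable)]
        j = int(rng.choice(neigh[i]))
        rec = pool.iloc[j].to_dict()
        rec["target_index"] = i
        out.append(rec)
    return pd.DataFrame(out)


def presence_correlation_test(
    trios: pd.DataFrame,
    pool: pd.DataFrame,
    features: pd.DataFrame,
    faecal: pd.DataFrame,
    blood: pd.DataFrame,
    n_datasets: int = 1000,
    n_pairs: int = 1000,
    min_missing: int = 30,
    rng: np.random.Generator | None = None,
    tol_r: float = TOL_R,
    tol_n: float = TOL_N,
    on_unmatched: str = "error",
) -> dict:
    """Missingness-based mediation test.

    Observed statistic: mean over trios (restricted to features missing in
    at least ``min_missing`` samples) of the metabolite-pair Pearson r
    computed on samples where the feature is present.  Null: ``n_datasets``
    datasets of ``n_pairs`` matched random metabolite pairs imposed on the
    same feature-presence patterns.  Empirical P uses the add-one
    convention.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    n_samples = len(faecal)
    blood_al = blood.reindex(faecal.index)

    presence = {}
    for f in trios["feature_id"].unique():
        presence[f] = _presence(features[f].reindex(faecal.index))
    missing_enough = {
        f: (n_samples - int(p.sum())) >= min_missing for f, p in presence.items()
    }
    kept = trios[trios["feature_id"].map(missing_enough)].reset_index(drop=True)
    if kept.empty:
        raise ValueError(
            f"no trios whose feature is missing in >= {min_missing} samples"
        )

    def subset_r(fm, bm, f):
        r, _ = pairwise_r(faecal[fm], blood_al[bm], mask=presence[f])
        return r

    obs = np.array([
        subset_r(t.faecal_met_id, t.blood_met_id, t.feature_id)
        for t in kept.itertuples()
    ])
    observed = float(np.nanmean(obs))

    matched = match_null_pairs(kept, pool, n_datasets * n_pairs, rng,
                               tol_r=tol_r, tol_n=tol_n,
                               on_unmatched=on_unmatched)
    cache: dict = {}
    null_means = np.empty(n_datasets)
    k = 0
    for d in range(n_datasets):
        vals = []
        for _ in range(n_pairs):
            row = matched.iloc[k]
            k += 1
            f = kept.iloc[int(row["target_index"])]["feature_id"]
            key = (row["faecal_met_id"], row["blood_met_id"], f)
            if key not in cache:
                cache[key] = subset_r(*key)
            vals.append(cache[key])
        null_means[d] = np.nanmean(vals)
    exceed = int(np.sum(null_means >= observed))
    return {
        "observed_mean_r": observed,
        "empirical_p": (1 + exceed) / (1 + n_datasets),
        "n_trios": int(len(kept)),
        "n_datasets": n_datasets,
        "n_pairs": n_pairs,
        "null_means": null_means,
    }


def log_ratio(m1: pd.Series, m2: pd.Series) -> pd.Series:
    """Element-wise difference of two log-intensity vectors (the log of the
    intensity ratio); missing wherever either is missing."""
    return m1 - m2.reindex(m1.index)


def lmm_family_p(
    y: pd.Series,
    feature: pd.Series,
    covariates: pd.DataFrame | None,
    family_ids: pd.Series,
    min_complete: int = 100,
    eig_cache: dict | None = None,
    mask: np.ndarray | None = None,
) -> float:
    """LRT P value for the feature's fixed effect under a
    random-intercept-per-family Gaussian LMM (ML fit).

    When every family is a singleton the family variance collapses and the
    test equals the OLS likelihood-ratio test.
    """
    idx = y.index
    parts = [y, feature.reindex(idx)]
    if covariates is not None:
        parts.append(covariates.reindex(idx))
    frame = pd.concat(parts, axis=1)
    ok = frame.notna().all(axis=1).to_numpy()
    if mask is not None:
        ok &= mask
    n = int(ok.sum())
    if n < min_complete:
        raise ValueError(f"only {n} complete observations (< {min_complete})")
    ids = idx[ok]
    yv = y[ok].to_numpy(dtype=float)
    xv = feature.reindex(idx)[ok].to_numpy(dtype=float)
    if np.ptp(xv) == 0:
        raise ValueError("feature constant on the complete-case set")
    ones = np.ones(n)
    if covariates is not None:
        C = _drop_constant(covariates.reindex(idx).loc[ids].to_numpy(dtype=float))
        X_null = np.column_stack([ones, C]) if C.shape[1] else ones[:, None]
    else:
        X_null = ones[:, None]
    X_full = np.column_stack([X_null, xv])

    fam = family_ids.reindex(ids).to_numpy()
    eig = None
    if eig_cache is not None:
        key = ok.tobytes()
        eig = eig_cache.get(key)
    if eig is None:
        same = (fam[:, None] == fam[None, :]).astype(float)
        d, U = np.linalg.eigh(same)
        eig = (np.clip(d, 0.0, None), U)
        if eig_cache is not None:
            eig_cache[key] = eig
    full = fit_vc(yv, X_full, eig=eig)
    null = fit_vc(yv, X_null, eig=eig)
    stat = max(2.0 * (full.loglik - null.loglik), 0.0)
    return float(max(_stats.chi2.sf(stat, df=1), P_FLOOR))


def pgain(p_faecal: float, p_blood: float, p_ratio: float) -> float:
    """min(p_faecal, p_blood) / p_ratio, with the denominator floored at
    1e-300 to stay finite."""
    for p in (p_faecal, p_blood, p_ratio):
        if not 0.0 < p <= 1.0:
            raise ValueError("P values must lie in (0, 1]")
    return min(p_faecal, p_blood) / max(p_ratio, P_FLOOR)


def pgain_records(
    trios: pd.DataFrame,
    faecal_log: pd.DataFrame,
    blood_log: pd.DataFrame,
    features: pd.DataFrame,
    covariates: pd.DataFrame | None,
    family_ids: pd.Series,
    min_complete: int = 100,
    eig_cache: dict | None = None,
) -> pd.DataFrame:
    """P-gain for each trio: single-metabolite and log-ratio mixed-model P
    values on the shared complete-case set.

    ``faecal_log``/``blood_log`` must be on the log scale; ``features`` is
    the transformed abundance table (absent = missing).
    """
    if eig_cache is None:
        eig_cache = {}
    rows = []
    blood_al = blood_log.reindex(faecal_log.index)
    for t in trios.itertuples():
        x = features[t.feature_id].reindex(faecal_log.index)
        yf = faecal_log[t.faecal_met_id]
        yb = blood_al[t.blood_met_id]
        ratio = log_ratio(yf, yb)
        # one complete-case mask for all three regressions
        both = yf.notna().to_numpy() & yb.notna().to_numpy()
        try:
            p_f = lmm_family_p(yf, x, covariates, family_ids,
                               min_complete=min_complete,
                               eig_cache=eig_cache, mask=both)
            p_b = lmm_family_p(yb, x, covariates, family_ids,
                               min_complete=min_complete,
                               eig_cache=eig_cache, mask=both)
            p_r = lmm_family_p(ratio, x, covariates, family_ids,
                               min_complete=min_complete,
                               eig_cache=eig_cache, mask=both)
        except ValueError:
            continue
        rec = {
            "feature_id": t.feature_id,
            "faecal_met_id": t.faecal_met_id,
            "blood_met_id": t.blood_met_id,
            "n_complete": t.n_complete,
            "r_observed": t.r_observed,
            "p_faecal": p_f,
            "p_blood": p_b,
            "p_ratio": p_r,
            "pgain": pgain(p_f, p_b, p_r),
        }
        rows.append(rec)
    return pd.DataFrame(
        rows, columns=["feature_id", "faecal_met_id", "blood_met_id",
                       "n_complete", "r_observed", "p_faecal", "p_blood",
                       "p_ratio", "pgain"],
    )


def null_pgains(
    targets: pd.DataFrame,
    pool: pd.DataFrame,
    faecal_log: pd.DataFrame,
    blood_log: pd.DataFrame,
    features: pd.DataFrame,
    covariates: pd.DataFrame | None,
    family_ids: pd.Series,
    n_draws: int,
    rng: np.random.Generator,
    min_complete: int = 100,
    tol_r: float = TOL_R,
    tol_n: float = TOL_N,
    on_unmatched: str = "error",
) -> np.ndarray:
    """P-gains of matched null pairs (different-feature metabolite pairs),
    each evaluated against its faecal metabolite's feature."""
    matched = match_null_pairs(targets, pool, n_draws, rng,
                               tol_r=tol_r, tol_n=tol_n,
                               on_unmatched=on_unmatched)
    matched = matched.drop(columns=["target_index"])
    unique = matched.drop_duplicates().reset_index(drop=True)
    eig_cache: dict = {}
    recs = pgain_records(unique, faecal_log, blood_log, features,
                         covariates, family_ids, min_complete=min_complete,
                         eig_cache=eig_cache)
    # P-gain of a given (pair, feature) is deterministic: compute once per
    # unique record, then expand back to the full draw sequence
    key = ["feature_id", "faecal_met_id", "blood_met_id"]
    lut = recs.set_index(key)["pgain"]
    vals = matched.set_index(key).index.map(lut)
    return np.asarray(vals, dtype=float)[~pd.isna(vals)]


def empirical_pgain_threshold(null_pgains_: np.ndarray, q: float = 0.95) -> float:
    """The q-quantile of the null P-gain distribution by the higher
    order-statistic convention: the smallest null value with at least a
    fraction q of nulls at or below it."""
    vals = np.sort(np.asarray(null_pgains_, dtype=float))
    n = vals.size
    if n < 100:
        raise ValueError(f"need >= 100 null P-gains, got {n}")
    k = int(np.ceil(q * n)) - 1
    return float(vals[k])


def dialogue_summary(
    records: pd.DataFrame,
    threshold: float,
    n_faecal_total: int,
    n_blood_total: int,
    n_features_total: int,
) -> dict:
    """Fractions of distinct faecal metabolites, blood metabolites and
    features appearing in at least one P-gain record passing the
    threshold."""
    passing = records[records["pgain"] >= threshold] if len(records) else records
    n_pass = int(len(passing))
    return {
        "threshold": float(threshold),
        "n_records": int(len(records)),
        "n_passing": n_pass,
        "frac_faecal_mets": (passing["faecal_met_id"].nunique() / n_faecal_total
                             if n_faecal_total else 0.0) if n_pass else 0.0,
        "frac_blood_mets": (passing["blood_met_id"].nunique() / n_blood_total
                            if n_blood_total else 0.0) if n_pass else 0.0,
        "frac_features": (passing["feature_id"].nunique() / n_features_total
                          if n_features_total else 0.0) if n_pass else 0.0,
    }
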