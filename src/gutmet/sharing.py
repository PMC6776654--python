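"""Presence/absence sharing statistics and metabolome temporal stability.

Presence is coded 1 when a feature is detected (abundance > 0) and 0
otherwise.  Sharing between two individuals is the ratio between the number
of features present in both and the number present in at least one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree
from .preprocess import sd_outlier_mask, standardize

__all__ = [
    "presence_matrix",
    "sharing_fraction",
    "unrelated_pairs",
    "compare_sharing",
    "prevalence_bins",
    "prevalence_redundancy_correlation",
    "contribution_fraction",
    "temporal_stability",
]

PREVALENCE_EDGES = (0.01, 0.25, 0.50, 0.75)
BIN_LABELS = ("<1%", "1-25%", "25-50%", "50-75%", ">75%")


def presence_matrix(t: pd.DataFrame) -> pd.DataFrame:
    """Binary detection indicators from an abundance table (NA counts as
    absent)."""
    return ((t > 0) & t.notna()).astype(int)


def sharing_fraction(a, b) -> float:
    """|a AND b| / |a OR b|; NaN when the union is empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("presence vectors differ in length")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return float("nan")
    return float(np.logical_and(a, b).sum() / union)


def unrelated_pairs(ped: Pedigree) -> np.ndarray:
    """Index pairs (i, j), i < j, of individuals from different families."""
    fam = ped.records["family_id"].to_numpy()
    n = len(fam)
    ii, jj = np.triu_indices(n, k=1)
    keep = fam[ii] != fam[jj]
    return np.column_stack([ii[keep], jj[keep]])


def _pairwise_sharing(P: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    inter = P @ P.T
    counts = P.sum(axis=1)
    ii, jj = pairs[:, 0], pairs[:, 1]
    union = counts[ii] + counts[jj] - inter[ii, jj]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(union > 0, inter[ii, jj] / union, np.nan)


def compare_sharing(
    species: pd.DataFrame, pathways: pd.DataFrame, ped: Pedigree
) -> dict:
    """Species vs pathway sharing over all unrelated (cross-family) pairs,
    compared with a paired two-sided Wilcoxon signed-rank test."""
    if ped.records["family_id"].nunique() < 2:
        raise ValueError("need at least 2 families")
    order = ped.individual_ids
    S = presence_matrix(species.loc[order]).to_numpy()
    P = presence_matrix(pathways.loc[order]).to_numpy()
    pairs = unrelated_pairs(ped)
    fs = _pairwise_sharing(S, pairs)
    fp = _pairwise_sharing(P, pairs)
    ok = ~(np.isnan(fs) | np.isnan(fp))
    fs, fp = fs[ok], fp[ok]
    d = fp - fs
    if np.all(d == 0):
        p = 1.0
    else:
        method = "exact" if (len(d) <= 50 and np.all(d != 0)
                             and len(np.unique(np.abs(d))) == len(d)) else "approx"
        p = float(stats.wilcoxon(d, zero_method="zsplit", correction=True,
                                 alternative="two-sided", method=method).pvalue)
    return {
        "n_pairs": int(len(d)),
        "mean_species": float(np.mean(fs)),
        "mean_pathways": float(np.mean(fp)),
        "wilcoxon_p": p,
        "species_fractions": fs,
        "pathway_fractions": fp,
    }


def prevalence_bins(
    t: pd.DataFrame, edges: tuple = PREVALENCE_EDGES
) -> pd.Series:
    """Fraction of features per prevalence bin [0,1%), [1,25%), [25,50%),
    [50,75%), [75,100%]."""
    if t.shape[1] == 0:
        raise ValueError("empty presence matrix")
    prev = t.mean(axis=0).to_numpy()
    bins = np.concatenate([[0.0], edges, [1.0 + 1e-12]])
    counts, _ = np.histogram(prev, bins=bins)
    return pd.Series(counts / counts.sum(), index=list(BIN_LABELS))


def prevalence_redundancy_correlation(
    pathways: pd.DataFrame, contribution_map: dict
) -> tuple[float, float]:
    """Spearman correlation between pathway prevalence and contributor
    count, with its asymptotic P value."""
    ids = [p for p in pathways.columns if p in contribution_map]
    if len(ids) < 3:
        raise ValueError("need at least 3 pathways with contributor counts")
    prev = pathways[ids].pipe(lambda d: ((d > 0) & d.notna()).mean(axis=0))
    counts = np.array([len(contribution_map[p]) for p in ids], dtype=float)
    if np.ptp(counts) == 0:
        raise ValueError("contributor count is constant; rho undefined")
    rho, p = stats.spearmanr(prev.to_numpy(), counts)
    return float(rho), float(p)


def contribution_fraction(
    pathway_id: str,
    species_id: str,
    species: pd.DataFrame,
    contribution_map: dict,
) -> float:
    """Mean share of a pathway's abundance attributable to one species.

    Per sample, the species' share of the known-member mass is
    w_s a_s / sum_m w_m a_m, scaled by the total known-member weight
    (1 minus the unclassified residual), and averaged over samples where
    the pathway is present (any member contribution > 0).  A
    single-contributor pathway therefore scores 1 minus the residual share;
    two equal contributors with equal abundances and no residual score 0.5
    each.
    """
    if pathway_id not in contribution_map:
        raise KeyError(f"unknown pathway {pathway_id!r}")
    weights = contribution_map[pathway_id]
    member_ids = list(weights)
    wvec = np.array([weights[s] for s in member_ids], dtype=float)
    contrib = species[member_ids].to_numpy() @ wvec
    present = contrib > 0
    if not present.any():
        raise ValueError(f"pathway {pathway_id!r} never present")
    w = float(weights.get(species_id, 0.0))
    if w == 0.0:
        return 0.0
    own = w * species.loc[:, species_id].to_numpy()[present]
    share = own / contrib[present]
    known_mass = float(wvec.sum())
    return float(np.mean(share) * known_mass)


def temporal_stability(
    profiles_t1: pd.DataFrame,
    profiles_t2: pd.DataFrame,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Intra-individual metabolome stability with a random-pairing null.

    Rows of the two tables are matched by position (pair i = row i of each
    table).  Each metabolite is 3-SD outlier-masked and standardized, then
    the per-pair Pearson correlation across metabolites is computed.  The
    null re-pairs the second-timepoint profiles at random ``n_perm`` times;
    the empirical P uses the add-one convention and is therefore in (0, 1].
    """
    if len(profiles_t1) != len(profiles_t2):
        raise ValueError("tables must have the same number of matched rows")
    n_pairs = len(profiles_t1)
    if n_pairs < 10:
        raise ValueError("need at least 10 matched pairs")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(0) if rng is None else rng

    def clean(df: pd.DataFrame) -> np.ndarray:
        cols = []
        for c in df.columns:
            v = sd_outlier_mask(df[c])
            if v.dropna().nunique() < 2:
                cols.append(np.full(len(df), np.nan))
            else:
                cols.append(standardize(v).to_numpy())
        return np.column_stack(cols)

    A = clean(profiles_t1)
    B = clean(profiles_t2)

    def mean_pair_r(Bm: np.ndarray) -> float:
        rs = []
        for i in range(n_pairs):
            a, b = A[i], Bm[i]
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() < 3 or a[ok].std() == 0 or b[ok].std() == 0:
                continue
            rs.append(np.corrcoef(a[ok], b[ok])[0, 1])
        return float(np.mean(rs)) if rs else float("nan")

    observed = mean_pair_r(B)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_pairs)
        if mean_pair_r(B[perm]) >= observed:
            exceed += 1
    return {
        "mean_r": observed,
        "empirical_p": (1 + exceed) / (1 + n_perm),
        "n_pairs": n_pairs,
        "n_perm": n_perm,
    }
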