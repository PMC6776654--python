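"""PAGE enrichment of association effect directions over metabolite
super-pathways.

The Z score for a set of size m with mean S_m against a background with
mean mu and SD delta is z = (S_m - mu) sqrt(m) / delta.  Significance is
assessed by label permutation (two-tailed, add-one convention) and adjusted
across sets with Benjamini-Hochberg.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["SUPER_PATHWAYS", "page_z", "metabolite_statistics", "page_test"]

SUPER_PATHWAYS = (
    "amino acid",
    "carbohydrate",
    "cofactors and vitamins",
    "energy",
    "lipid",
    "nucleotide",
    "peptide",
    "xenobiotics",
)


def page_z(set_values, background) -> float:
    """(set mean - background mean) * sqrt(m) / background SD."""
    s = np.asarray(set_values, dtype=float)
    b = np.asarray(background, dtype=float)
    if s.size < 1:
        raise ValueError("empty set")
    delta = b.std(ddof=1)
    if delta == 0 or not np.isfinite(delta):
        raise ValueError("background SD is zero")
    return float((s.mean() - b.mean()) * np.sqrt(s.size) / delta)


def metabolite_statistics(assoc: pd.DataFrame, fdr: float = 0.05) -> pd.Series:
    """Per-metabolite signed count of significant associations
    (positive minus negative beta at q <= fdr).

    Metabolites tested but with no significant association score 0.  This
    is the statistic fed to the PAGE Z score.
    """
    sig = assoc[assoc["q"] <= fdr]
    pos = sig[sig["beta"] > 0].groupby("metabolite_id").size()
    neg = sig[sig["beta"] < 0].groupby("metabolite_id").size()
    mets = assoc["metabolite_id"].unique()
    stat = pd.Series(0.0, index=pd.Index(mets, name="metabolite_id"))
    stat = stat.add(pos.astype(float), fill_value=0.0)
    stat = stat.sub(neg.astype(float), fill_value=0.0)
    return stat.reindex(mets)


def page_test(
    assoc: pd.DataFrame,
    annotation: pd.Series,
    n_perm: int = 10_000,
    fdr: float = 0.05,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """PAGE enrichment per super-pathway.

    Parameters
    ----------
    assoc
        Association records (feature_id, metabolite_id, beta, q).
    annotation
        metabolite_id -> super-pathway label.
    n_perm
        Label permutations for the empirical two-tailed P value.

    Returns one row per non-empty set with columns set_id, m, z, direction,
    p_perm, p_adj.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    stats_ = metabolite_statistics(assoc, fdr=fdr)
    ann = annotation.reindex(stats_.index)
    keep = ann.notna()
    stats_, ann = stats_[keep], ann[keep]
    if stats_.empty:
        raise ValueError("no annotated metabolites")
    background = stats_.to_numpy()
    delta = background.std(ddof=1)
    rows = []
    for set_id, members in stats_.groupby(ann):
        m = len(members)
        if m == 0:
            continue
        if delta == 0:
            z = 0.0
            p_perm = 1.0
        else:
            z = page_z(members.to_numpy(), background)
            draws = np.array([
                background[rng.choice(len(background), size=m, replace=False)].mean()
                for _ in range(n_perm)
            ])
            z_perm = (draws - background.mean()) * np.sqrt(m) / delta
            p_perm = (1 + int(np.sum(np.abs(z_perm) >= abs(z)))) / (1 + n_perm)
        rows.append({
            "set_id": set_id,
            "m": m,
            "z": z,
            "direction": "increase" if z > 0 else ("decrease" if z < 0 else "none"),
            "p_perm": p_perm,
        })
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_perm"], method="fdr_bh")[1]
    return out
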