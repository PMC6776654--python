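"""Join metabolite compound identifiers to pathway membership tables and
count associations linked to pathways that produce or consume their
metabolite."""

from __future__ import annotations

import pandas as pd

__all__ = ["normalize_key", "link_metabolites", "functional_link_fraction"]


def normalize_key(key) -> str | None:
    """Canonical compound key: trimmed, upper-cased; empty/NA -> None."""
    if key is None or (isinstance(key, float) and pd.isna(key)):
        return None
    s = str(key).strip().upper()
    return s or None


def link_metabolites(
    metabolite_annotations: pd.Series, cmap: pd.DataFrame
) -> dict[str, set]:
    """Inner-join metabolite compound keys against a compound -> pathway map.

    Parameters
    ----------
    metabolite_annotations
        metabolite_id -> compound key (e.g. InChIKey); missing keys allowed.
    cmap
        DataFrame with columns ``compound_key`` and ``pathway_id``;
        duplicate rows are collapsed.

    Returns metabolite_id -> set of pathway ids (empty set when the
    metabolite has no key or no match).
    """
    table: dict[str, set] = {}
    for _, row in cmap.iterrows():
        k = normalize_key(row["compound_key"])
        if k is None:
            continue
        table.setdefault(k, set()).add(row["pathway_id"])
    out: dict[str, set] = {}
    for met_id, key in metabolite_annotations.items():
        k = normalize_key(key)
        out[met_id] = set(table.get(k, set())) if k else set()
    return out


def functional_link_fraction(
    assoc: pd.DataFrame, links: dict[str, set], fdr: float = 0.05
) -> tuple[int, int, float]:
    """Fraction of significant pathway associations whose metabolite belongs
    to the associated pathway.

    Counted over unique (metabolite, pathway) pairs with q <= fdr.
    Returns (n_linked, n_total, fraction).
    """
    sig = assoc[assoc["q"] <= fdr]
    pairs = sig[["metabolite_id", "feature_id"]].drop_duplicates()
    n_total = len(pairs)
    if n_total == 0:
        raise ValueError("no significant associations to link")
    linked = [
        row.feature_id in links.get(row.metabolite_id, set())
        for row in pairs.itertuples()
    ]
    n_linked = int(sum(linked))
    return n_linked, n_total, n_linked / n_total
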