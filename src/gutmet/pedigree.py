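"""Pedigrees of twin pairs and singletons, and their expected-relatedness matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_ZYGOSITY = {"MZ", "DZ", "NA"}

# expected relatedness (2x kinship): MZ co-twins 1, DZ co-twins 0.5
RELATEDNESS = {"MZ": 1.0, "DZ": 0.5}


@dataclass(frozen=True)
class Pedigree:
    """Twin-cohort pedigree: families of MZ pairs, DZ pairs or singletons.

    ``records`` has columns ``family_id``, ``individual_id``, ``zygosity``
    (one of MZ, DZ, NA).
    """

    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        req = ["family_id", "individual_id", "zygosity"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise ValueError(f"pedigree missing columns: {missing}")
        ids = self.records["individual_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate individual_id: {dup!r}")
        bad = set(self.records["zygosity"]) - VALID_ZYGOSITY
        if bad:
            raise ValueError(f"invalid zygosity values: {sorted(bad)}")
        for fam, grp in self.records.groupby("family_id"):
            zyg = set(grp["zygosity"])
            if zyg & {"MZ", "DZ"}:
                if len(grp) != 2:
                    raise ValueError(
                        f"twin family {fam!r} has {len(grp)} members, expected 2"
                    )
                if len(zyg) != 1:
                    raise ValueError(f"family {fam!r} mixes zygosity labels {zyg}")

    @property
    def individual_ids(self) -> list[str]:
        return list(self.records["individual_id"])

    @property
    def family_ids(self) -> pd.Series:
        """family_id per individual, indexed by individual_id."""
        return self.records.set_index("individual_id")["family_id"]

    def __len__(self) -> int:
        return len(self.records)


def kinship_matrix(ped: Pedigree) -> pd.DataFrame:
    """Expected-relatedness matrix K (2x kinship coefficients).

    K[i, i] = 1; K[i, j] = 1 for MZ co-twins, 0.5 for DZ co-twins and 0
    across families.  Symmetric, PSD (singular within MZ blocks, which the
    variance-component solver tolerates via eigendecomposition).
    """
    ids = ped.individual_ids
    n = len(ids)
    K = np.eye(n)
    pos = {iid: i for i, iid in enumerate(ids)}
    for _, grp in ped.records.groupby("family_id"):
        zyg = grp["zygosity"].iloc[0]
        if zyg in RELATEDNESS and len(grp) == 2:
            i, j = (pos[x] for x in grp["individual_id"])
            K[i, j] = K[j, i] = RELATEDNESS[zyg]
    return pd.DataFrame(K, index=ids, columns=ids)


def family_block_matrix(family_ids: pd.Series) -> pd.DataFrame:
    """Block-of-ones covariance structure for a random intercept per family.

    Entry (i, j) is 1 when i and j belong to the same family, else 0.  Used
    by the random-intercept LMM of the dialogue stage.
    """
    ids = list(family_ids.index)
    fam = np.asarray(family_ids)
    same = (fam[:, None] == fam[None, :]).astype(float)
    return pd.DataFrame(same, index=ids, columns=ids)
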