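"""Synthetic twin-cohort generator.

Produces pedigrees, zero-inflated compositional feature tables (species and
pathways, where pathway abundance is a weighted sum of contributing species
plus an unclassified residual), log-scale metabolite tables with planted
feature effects, family covariance, run-day batches and planted mediated
faecal-blood metabolite trios — everything the downstream analysis assumes,
with ground-truth labels, so every stage is testable without any download.

Determinism contract: the same :class:`CohortSpec` (including ``seed``)
yields byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "Cohort",
    "generate_pedigree",
    "generate_species_table",
    "plan_truth",
    "derive_pathway_table",
    "generate_metabolites",
    "plant_dialogue",
    "generate_cohort",
    "planted_predictor",
]

SEX_EFFECT = 0.1
AGE_EFFECT = 0.1
FEMALE_FRACTION = 0.96
AGE_MEAN, AGE_SD, AGE_MIN, AGE_MAX = 65.0, 8.0, 18.0, 90.0


@dataclass(frozen=True)
class CohortSpec:
    n_mz_pairs: int = 30
    n_dz_pairs: int = 30
    n_singletons: int = 40
    n_species: int = 40
    n_pathways: int = 20
    contribution_density: float = 0.2
    prevalence_range: tuple[float, float] = (0.3, 0.95)
    n_faecal_mets: int = 30
    n_blood_mets: int = 30
    n_planted_effects: int = 10
    effect_size: float = 0.6
    heritability: float = 0.4
    n_planted_trios: int = 5
    mediation_strength: float = 0.7
    n_rundays: int = 4
    runday_sd: float = 0.3
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mz_pairs", "n_dz_pairs", "n_singletons", "n_species",
                     "n_pathways", "n_faecal_mets", "n_blood_mets",
                     "n_planted_effects", "n_planted_trios", "n_rundays"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("contribution_density", "heritability", "missing_rate",
                     "mediation_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.prevalence_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("prevalence_range must be within (0, 1]")


@dataclass
class GroundTruth:
    """Planted structure: what the downstream analysis should recover."""

    planted_effects: list = field(default_factory=list)  # (feature, met, slope)
    planted_trios: list = field(default_factory=list)    # (feature, f_met, b_met, strength)
    contribution_map: dict = field(default_factory=dict)  # pathway -> {species: w}

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            planted_effects=[tuple(e) for e in d["planted_effects"]],
            planted_trios=[tuple(t) for t in d["planted_trios"]],
            contribution_map=d["contribution_map"],
        )


@dataclass
class Cohort:
    spec: CohortSpec
    pedigree: Pedigree
    species: pd.DataFrame
    pathways: pd.DataFrame
    faecal: pd.DataFrame
    blood: pd.DataFrame
    covariates: pd.DataFrame
    truth: GroundTruth


def generate_pedigree(spec: CohortSpec) -> Pedigree:
    """MZ pairs, DZ pairs and singletons, each in their own family."""
    total = spec.n_mz_pairs + spec.n_dz_pairs + spec.n_singletons
    if total == 0:
        raise ValueError("empty cohort: all counts are zero")
    rows = []
    fam = 0
    ind = 0

    def new_id():
        nonlocal ind
        ind += 1
        return f"I{ind:05d}"

    for zyg, n_pairs in (("MZ", spec.n_mz_pairs), ("DZ", spec.n_dz_pairs)):
        for _ in range(n_pairs):
            fam += 1
            fid = f"FAM{fam:05d}"
            rows.append((fid, new_id(), zyg))
            rows.append((fid, new_id(), zyg))
    for _ in range(spec.n_singletons):
        fam += 1
        rows.append((f"FAM{fam:05d}", new_id(), "NA"))
    df = pd.DataFrame(rows, columns=["family_id", "individual_id", "zygosity"])
    return Pedigree(df)


def _close_rows(values: np.ndarray) -> np.ndarray:
    sums = values.sum(axis=1, keepdims=True)
    return values / sums


def generate_species_table(
    spec: CohortSpec, pedigree: Pedigree, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Zero-inflated compositional species abundances.

    Log-normal intensities masked by per-feature Bernoulli detection, then
    closed to sum 1 over detected features per sample.  Undetected entries
    are exactly 0.
    """
    if spec.n_species == 0:
        raise ValueError("n_species must be positive")
    if len(pedigree) == 0:
        raise ValueError("pedigree is empty")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    samples = pedigree.individual_ids
    n, m = len(samples), spec.n_species
    lo, hi = spec.prevalence_range
    prev = rng.uniform(lo, hi, size=m)
    detected = rng.random((n, m)) < prev
    intensity = rng.lognormal(mean=0.0, sigma=1.0, size=(n, m))
    vals = np.where(detected, intensity, 0.0)
    # a sample with nothing detected: force the most prevalent feature on
    empty = vals.sum(axis=1) == 0
    if empty.any():
        j = int(np.argmax(prev))
        vals[empty, j] = rng.lognormal(0.0, 1.0, size=int(empty.sum()))
    vals = _close_rows(vals)
    cols = [f"SP{j + 1:04d}" for j in range(m)]
    return pd.DataFrame(vals, index=pd.Index(samples, name="sample_id"),
                        columns=cols)


def plan_truth(
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
    species: pd.DataFrame | None = None,
) -> GroundTruth:
    """Draw the planted structure: contribution map, effects and trios.

    Feature/metabolite identifiers follow the deterministic naming used by
    the table generators, so the plan can be drawn before the tables exist.
    When the species table is supplied, trio mediators are taken from the
    most prevalent features so that downstream complete-case thresholds
    remain attainable.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    species_ids = [f"SP{j + 1:04d}" for j in range(spec.n_species)]
    faecal_ids = [f"FMET{j + 1:04d}" for j in range(spec.n_faecal_mets)]
    blood_ids = [f"BMET{j + 1:04d}" for j in range(spec.n_blood_mets)]

    cmap: dict = {}
    for k in range(spec.n_pathways):
        pid = f"PWY{k + 1:04d}"
        members = [s for s in species_ids
                   if rng.random() < spec.contribution_density]
        if not members:
            members = [species_ids[int(rng.integers(spec.n_species))]]
        raw = rng.random(len(members))
        total = rng.uniform(0.5, 0.9)  # leaves 10-50% unclassified residual
        w = raw / raw.sum() * total
        cmap[pid] = dict(zip(members, np.round(w, 10)))

    effects = []
    trios = []
    # trios first: each plants the same feature on one faecal and one blood
    # metabolite, then the dialogue redraw couples them where the feature is
    # present
    n_trios = min(spec.n_planted_trios, spec.n_faecal_mets, spec.n_blood_mets)
    feat_pool = [str(s) for s in rng.permutation(species_ids)]
    if species is not None:
        # trio mediators in a mid-high prevalence window: present often
        # enough for complete-case thresholds, missing often enough for the
        # missingness-based correlation test
        counts = (species > 0).sum(axis=0)
        target = 0.76 * len(species)
        trio_pool = list((counts - target).abs().sort_values().index)
    else:
        trio_pool = feat_pool
    for t in range(n_trios):
        f = trio_pool[t % len(trio_pool)]
        fm, bm = faecal_ids[t], blood_ids[t]
        # opposite-sign effects (production in one compartment, depletion in
        # the other): the log-ratio then cancels the shared residual but
        # keeps the feature signal, which is what the P-gain rewards
        effects.append((f, fm, spec.effect_size))
        effects.append((f, bm, -spec.effect_size))
        trios.append((f, fm, bm, spec.mediation_strength))
    # remaining planted effects on metabolites untouched by trios, paired on
    # shared non-trio features with EQUAL signs: coincident co-associations
    # whose log-ratio cancels the signal — designed negatives for the
    # dialogue stage (no mediation planted)
    trio_features = set(trio_pool[t % len(trio_pool)] for t in range(n_trios))
    extra_pool = [f for f in trio_pool if f not in trio_features] or feat_pool
    free_f = faecal_ids[n_trios:]
    free_b = blood_ids[n_trios:]
    placed = 0
    k = 0
    while placed < spec.n_planted_effects and (free_f or free_b):
        f = extra_pool[k % len(extra_pool)]
        k += 1
        if free_f and placed < spec.n_planted_effects:
            effects.append((f, free_f.pop(0), spec.effect_size))
            placed += 1
        if free_b and placed < spec.n_planted_effects:
            effects.append((f, free_b.pop(0), spec.effect_size))
            placed += 1
    return GroundTruth(planted_effects=effects, planted_trios=trios,
                       contribution_map=cmap)


def derive_pathway_table(
    species: pd.DataFrame,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    residuals: dict | None = None,
) -> pd.DataFrame:
    """Pathway abundances as weighted sums of contributing species plus an
    unclassified residual, renormalized over present pathways per sample.

    The residual behaves like one extra unobserved contributor: it is
    detected with probability equal to the mean prevalence of the pathway's
    known contributors, with log-normal intensity scaled by the mean
    detected species abundance.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    n = len(species)
    cols = {}
    mean_abund = float(species.to_numpy().mean())
    for pid, weights in truth.contribution_map.items():
        members = list(weights)
        missing = [s for s in members if s not in species.columns]
        if missing:
            raise ValueError(f"pathway {pid}: unknown species {missing}")
        w = np.array([weights[s] for s in members], dtype=float)
        residual = 1.0 - w.sum()
        if residuals is not None and pid in residuals:
            residual = float(residuals[pid])
        if not members and residual <= 0:
            raise ValueError(f"pathway {pid}: no contributors and no residual")
        vals = species[members].to_numpy() @ w if members else np.zeros(n)
        if residual > 0:
            member_prev = (
                (species[members].to_numpy() > 0).mean() if members else 0.5
            )
            det = rng.random(n) < member_prev
            res_val = residual * rng.lognormal(0.0, 1.0, n) * mean_abund
            vals = vals + np.where(det, res_val, 0.0)
        cols[pid] = vals
    out = pd.DataFrame(cols, index=species.index)
    present = out.to_numpy() > 0
    sums = out.to_numpy().sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    out = pd.DataFrame(out.to_numpy() / sums, index=out.index,
                       columns=out.columns)
    return out


def planted_predictor(values: pd.Series | np.ndarray) -> np.ndarray:
    """The transformed feature used when planting effects: arcsine-sqrt with
    zeros kept, standardized (sample SD)."""
    x = np.arcsin(np.sqrt(np.asarray(values, dtype=float)))
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _family_effects(spec: CohortSpec, pedigree: Pedigree,
                    rng: np.random.Generator) -> np.ndarray:
    """Per-individual family/genetic random effect with variance
    ``heritability``: MZ co-twins share one draw, DZ co-twins are
    correlation-0.5 bivariate, singletons independent."""
    h = spec.heritability
    g = np.zeros(len(pedigree))
    sd = np.sqrt(h)
    pos = {iid: i for i, iid in enumerate(pedigree.individual_ids)}
    for _, grp in pedigree.records.groupby("family_id", sort=False):
        idx = [pos[i] for i in grp["individual_id"]]
        zyg = grp["zygosity"].iloc[0]
        if zyg == "MZ":
            g[idx] = sd * rng.standard_normal()
        elif zyg == "DZ":
            shared = rng.standard_normal()
            for i in idx:
                g[i] = sd * (np.sqrt(0.5) * shared
                             + np.sqrt(0.5) * rng.standard_normal())
        else:
            for i in idx:
                g[i] = sd * rng.standard_normal()
    return g


def generate_metabolites(
    spec: CohortSpec,
    species: pd.DataFrame,
    pathways: pd.DataFrame,
    pedigree: Pedigree,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Log-linear metabolite model.

    log-metabolite = intercept + planted slopes x transformed feature
    + sex effect + age effect + family random effect (variance =
    heritability) + run-day shift + residual; intensities are the exponent.
    A ``missing_rate`` fraction of entries is removed at random.

    Returns (faecal table, blood table, covariates with sex/age/runday).
    """
    rng = np.random.default_rng(spec.seed + 2) if rng is None else rng
    samples = pedigree.individual_ids
    n = len(samples)

    sex = (rng.random(n) < FEMALE_FRACTION).astype(float)  # 1 = female
    age = np.clip(rng.normal(AGE_MEAN, AGE_SD, n), AGE_MIN, AGE_MAX)
    runday = rng.integers(0, max(spec.n_rundays, 1), n)
    cov = pd.DataFrame(
        {"sex": sex, "age": np.round(age, 2), "runday": runday},
        index=pd.Index(samples, name="sample_id"),
    )
    age_z = (age - age.mean()) / age.std(ddof=1)

    effects_by_met: dict[str, list] = {}
    for f, m, slope in truth.planted_effects:
        effects_by_met.setdefault(m, []).append((f, slope))

    feature_tables = {"SP": species, "PWY": pathways}

    def build(met_ids: list[str]) -> pd.DataFrame:
        cols = {}
        for m in met_ids:
            planted = effects_by_met.get(m, [])
            planted_var = sum(s**2 for _, s in planted)
            resid_var = 1.0 - spec.heritability - planted_var
            if resid_var <= 0:
                raise ValueError(
                    f"metabolite {m}: heritability + planted variance "
                    f"{spec.heritability + planted_var:.3f} >= 1"
                )
            y = np.zeros(n)
            for f, slope in planted:
                table = feature_tables[f[:2] if f.startswith("SP") else "PWY"]
                y += slope * planted_predictor(table[f])
            y += SEX_EFFECT * sex + AGE_EFFECT * age_z
            y += _family_effects(spec, pedigree, rng)
            shifts = rng.normal(0.0, spec.runday_sd, max(spec.n_rundays, 1))
            y += shifts[runday]
            y += np.sqrt(resid_var) * rng.standard_normal(n)
            cols[m] = np.exp(y)
        df = pd.DataFrame(cols, index=pd.Index(samples, name="sample_id"))
        if spec.missing_rate > 0:
            mask = rng.random(df.shape) < spec.missing_rate
            df = df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns))
        return df

    faecal = build([f"FMET{j + 1:04d}" for j in range(spec.n_faecal_mets)])
    blood = build([f"BMET{j + 1:04d}" for j in range(spec.n_blood_mets)])
    return faecal, blood, cov


def plant_dialogue(
    faecal: pd.DataFrame,
    blood: pd.DataFrame,
    mediator: pd.Series,
    faecal_met: str,
    blood_met: str,
    strength: float,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Re-draw a blood metabolite so that, among samples where the mediator
    feature is present, its log-scale correlation with the faecal metabolite
    equals ``strength``; absent-subset values are left untouched.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    out = blood.copy()
    if strength == 0.0:
        return out
    rng = np.random.default_rng(0) if rng is None else rng
    present = (mediator.reindex(blood.index).fillna(0) > 0).to_numpy()
    usable = present & faecal[faecal_met].notna().to_numpy() \
        & blood[blood_met].notna().to_numpy()
    n_pres = int(usable.sum())
    if n_pres < 10:
        raise ValueError(
            f"mediator present in only {n_pres} usable samples (< 10)"
        )
    bl = np.log(blood.loc[usable, blood_met].to_numpy(dtype=float))
    fl = np.log(faecal.loc[usable, faecal_met].to_numpy(dtype=float))
    # partial out the mediator so the induced correlation is the partial
    # correlation given the feature: both metabolites keep their own
    # feature effects while sharing residual ("absorbed") variation
    t = planted_predictor(mediator.reindex(blood.index)[usable])
    X = np.column_stack([np.ones(n_pres), t])
    coef_f, *_ = np.linalg.lstsq(X, fl, rcond=None)
    coef_b, *_ = np.linalg.lstsq(X, bl, rcond=None)
    resid_f = fl - X @ coef_f
    fitted_b = X @ coef_b
    resid_b_sd = (bl - fitted_b).std(ddof=1)
    z = resid_f / resid_f.std(ddof=1)
    eps = rng.standard_normal(n_pres)
    new_log = fitted_b + resid_b_sd * (
        strength * z + np.sqrt(1.0 - strength**2) * eps
    )
    col = out[blood_met].copy()
    col.loc[out.index[usable]] = np.exp(new_log)
    out[blood_met] = col
    return out


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Full deterministic cohort draw from a single seeded stream."""
    rng = np.random.default_rng(spec.seed)
    ped = generate_pedigree(spec)
    species = generate_species_table(spec, ped, rng)
    truth = plan_truth(spec, rng, species=species)
    pathways = derive_pathway_table(species, truth, rng)
    faecal, blood, cov = generate_metabolites(spec, species, pathways, ped,
                                              truth, rng)
    for f, fm, bm, strength in truth.planted_trios:
        table = species if f.startswith("SP") else pathways
        blood = plant_dialogue(faecal, blood, table[f], fm, bm, strength, rng)
    return Cohort(spec=spec, pedigree=ped, species=species, pathways=pathways,
                  faecal=faecal, blood=blood, covariates=cov, truth=truth)
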