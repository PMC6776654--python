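"""End-to-end orchestrator: simulate -> preprocess -> associate (x4) ->
share -> enrich -> dialogue -> link, with a deterministic JSON manifest per
stage (inputs/outputs hashed, parameters and seeds recorded; no timestamps,
so identical configs produce hash-identical artifacts)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, dialogue, enrichment, linking, preprocess, sharing
from .io import write_table
from .pedigree import kinship_matrix
from .synthetic import CohortSpec, generate_cohort

log = logging.getLogger("gutmet.pipeline")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    out_dir: str = "gutmet_run"
    cohort: dict = field(default_factory=dict)   # CohortSpec overrides
    seed: int = 0
    min_n: int = 50
    fdr: float = 0.05
    enrich_n_perm: int = 1000
    dialogue_n_null: int = 2000
    dialogue_n_datasets: int = 200
    dialogue_n_pairs: int = 50
    dialogue_min_missing: int = 30
    dialogue_min_complete: int = 100
    tol_r: float = 0.05
    tol_n: float = 0.10
    # optional pre-existing inputs; when unset the synthetic cohort is used
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def validate(self) -> None:
        for name, p in (self.inputs or {}).items():
            if not Path(p).exists():
                raise FileNotFoundError(f"input {name!r} does not exist: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Stages:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir

    def manifest(self, stage: str, params: dict, inputs: list, outputs: list):
        man = {
            "stage": stage,
            "params": params,
            "inputs": {str(Path(p).name): _sha256(Path(p)) for p in inputs},
            "outputs": {str(Path(p).name): _sha256(Path(p)) for p in outputs},
        }
        path = self.out_dir / f"manifest_{stage}.json"
        path.write_text(json.dumps(man, indent=1, sort_keys=True))
        return path


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns a report of per-stage artifacts."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = _Stages(out)
    report: dict = {"stages": []}

    def done(stage, params, inputs, outputs, t0):
        stages.manifest(stage, params, inputs, outputs)
        log.info("stage=%s wall_time=%.2fs n_outputs=%d",
                 stage, time.monotonic() - t0, len(outputs))
        report["stages"].append(stage)

    # ---- simulate -------------------------------------------------------
    t0 = time.monotonic()
    spec = CohortSpec(**{**cfg.cohort, "seed": cfg.seed})
    cohort = generate_cohort(spec)
    rng = np.random.default_rng(cfg.seed + 10)
    ped_path = out / "pedigree.tsv"
    cohort.pedigree.records.to_csv(ped_path, sep="\t", index=False)
    paths = {}
    for name, df in (("species", cohort.species), ("pathways", cohort.pathways),
                     ("faecal_mets", cohort.faecal), ("blood_mets", cohort.blood),
                     ("covariates", cohort.covariates)):
        paths[name] = out / f"{name}.tsv"
        write_table(df, paths[name])
    truth_path = out / "truth.json"
    truth_path.write_text(cohort.truth.to_json())
    # synthetic annotation: super-pathway labels and compound keys for the
    # enrichment and linking stages
    all_mets = list(cohort.faecal.columns) + list(cohort.blood.columns)
    ann = pd.DataFrame({
        "metabolite_id": all_mets,
        "super_pathway": [enrichment.SUPER_PATHWAYS[i % 8]
                          for i in range(len(all_mets))],
        "compound_key": [f"KEY-{m}" for m in all_mets],
    })
    ann_path = out / "annotation.tsv"
    ann.to_csv(ann_path, sep="\t", index=False)
    pwy_ids = list(cohort.pathways.columns)
    cmap_rows = [
        {"compound_key": f"KEY-{m}",
         "pathway_id": pwy_ids[int(rng.integers(len(pwy_ids)))]}
        for m in all_mets if rng.random() < 0.5
    ]
    cmap = pd.DataFrame(cmap_rows, columns=["compound_key", "pathway_id"])
    cmap_path = out / "compound_map.tsv"
    cmap.to_csv(cmap_path, sep="\t", index=False)
    done("simulate", {"spec": dataclasses.asdict(spec)}, [],
         [ped_path, truth_path, ann_path, cmap_path, *paths.values()], t0)

    # ---- preprocess -----------------------------------------------------
    t0 = time.monotonic()
    species_t = preprocess.preprocess_features(cohort.species)
    pathways_t = preprocess.preprocess_features(cohort.pathways)
    runday = cohort.covariates["runday"]
    faecal_t = preprocess.preprocess_metabolites(cohort.faecal, runday, scale=True)
    blood_t = preprocess.preprocess_metabolites(cohort.blood, runday, scale=False)
    proc_paths = []
    for name, df in (("species_proc", species_t), ("pathways_proc", pathways_t),
                     ("faecal_proc", faecal_t), ("blood_proc", blood_t)):
        p = out / f"{name}.tsv"
        write_table(df, p)
        proc_paths.append(p)
    done("preprocess", {}, list(paths.values()), proc_paths, t0)

    # ---- associate (4 screens) -----------------------------------------
    t0 = time.monotonic()
    K = kinship_matrix(cohort.pedigree)
    cov = cohort.covariates[["sex", "age"]]
    screens = {}
    screen_paths = []
    for feat_name, feat in (("species", species_t), ("pathways", pathways_t)):
        for met_name, met in (("faecal", faecal_t), ("blood", blood_t)):
            key = f"{feat_name}_{met_name}"
            try:
                rec = association.run_screen(met, feat, cov, K, min_n=cfg.min_n)
            except ValueError as exc:
                if "no testable" not in str(exc):
                    raise RuntimeError(f"stage associate ({key}) failed") from exc
                rec = pd.DataFrame(
                    columns=["feature_id", "metabolite_id", "n", "beta",
                             "se", "p", "q"])
            screens[key] = rec
            p = out / f"assoc_{key}.tsv"
            write_table(rec, p, index_label=None)
            screen_paths.append(p)
    done("associate", {"min_n": cfg.min_n, "fdr": cfg.fdr}, proc_paths,
         screen_paths, t0)

    # ---- share ----------------------------------------------------------
    t0 = time.monotonic()
    sp_pres = sharing.presence_matrix(cohort.species)
    pw_pres = sharing.presence_matrix(cohort.pathways)
    cmp = sharing.compare_sharing(cohort.species, cohort.pathways,
                                  cohort.pedigree)
    try:
        rho, rho_p = sharing.prevalence_redundancy_correlation(
            cohort.pathways, cohort.truth.contribution_map)
    except ValueError:
        rho, rho_p = float("nan"), float("nan")
    share_summary = {
        "mean_species_sharing": cmp["mean_species"],
        "mean_pathway_sharing": cmp["mean_pathways"],
        "wilcoxon_p": cmp["wilcoxon_p"],
        "n_unrelated_pairs": cmp["n_pairs"],
        "species_prevalence_bins": sharing.prevalence_bins(sp_pres).to_dict(),
        "pathway_prevalence_bins": sharing.prevalence_bins(pw_pres).to_dict(),
        "prevalence_redundancy_spearman": rho,
        "prevalence_redundancy_p": rho_p,
    }
    share_path = out / "sharing_summary.json"
    share_path.write_text(json.dumps(share_summary, indent=1, sort_keys=True))
    done("share", {}, [ped_path], [share_path], t0)

    # ---- enrich ---------------------------------------------------------
    t0 = time.monotonic()
    ann_map = ann.set_index("metabolite_id")["super_pathway"]
    enrich_paths = []
    for key in ("species_faecal", "species_blood"):
        rec = screens[key]
        p = out / f"enrichment_{key}.tsv"
        if len(rec):
            res = enrichment.page_test(
                rec, ann_map, n_perm=cfg.enrich_n_perm, fdr=cfg.fdr,
                rng=np.random.default_rng(cfg.seed + 20))
        else:
            res = pd.DataFrame(columns=["set_id", "m", "z", "direction",
                                        "p_perm", "p_adj"])
        write_table(res, p, index_label=None)
        enrich_paths.append(p)
    done("enrich", {"n_perm": cfg.enrich_n_perm}, [ann_path], enrich_paths, t0)

    # ---- dialogue (species class) --------------------------------------
    t0 = time.monotonic()
    fam = cohort.pedigree.family_ids
    trios = dialogue.find_co_associations(
        screens["species_faecal"], screens["species_blood"],
        faecal_t, blood_t, species_t,
        min_complete=cfg.dialogue_min_complete, fdr=cfg.fdr)
    trio_path = out / "trios.tsv"
    write_table(trios, trio_path, index_label=None)
    dlg: dict = {"n_trios": int(len(trios))}
    pg_path = out / "pgain.tsv"
    if len(trios):
        pool = dialogue.build_null_pool(
            screens["species_faecal"], screens["species_blood"],
            faecal_t, blood_t, species_t,
            min_complete=cfg.dialogue_min_complete, fdr=cfg.fdr,
            exclude=trios)
        rng_d = np.random.default_rng(cfg.seed + 30)
        try:
            pres = dialogue.presence_correlation_test(
                trios, pool, species_t, faecal_t, blood_t,
                n_datasets=cfg.dialogue_n_datasets,
                n_pairs=cfg.dialogue_n_pairs,
                min_missing=cfg.dialogue_min_missing,
                rng=rng_d, tol_r=cfg.tol_r, tol_n=cfg.tol_n,
                on_unmatched="drop")
            dlg["presence_correlation"] = {
                "observed_mean_r": pres["observed_mean_r"],
                "empirical_p": pres["empirical_p"],
                "n_trios": pres["n_trios"],
            }
        except ValueError as exc:
            dlg["presence_correlation"] = {"skipped": str(exc)}
        recs = dialogue.pgain_records(
            trios, faecal_t, blood_t, species_t, cov, fam,
            min_complete=cfg.dialogue_min_complete)
        try:
            nulls = dialogue.null_pgains(
                trios, pool, faecal_t, blood_t, species_t, cov, fam,
                n_draws=cfg.dialogue_n_null, rng=rng_d,
                min_complete=cfg.dialogue_min_complete,
                tol_r=cfg.tol_r, tol_n=cfg.tol_n, on_unmatched="drop")
            thr = dialogue.empirical_pgain_threshold(nulls)
            recs["passes"] = recs["pgain"] >= thr
            dlg.update(dialogue.dialogue_summary(
                recs, thr, cohort.faecal.shape[1], cohort.blood.shape[1],
                cohort.species.shape[1]))
        except ValueError as exc:
            dlg["pgain_threshold"] = {"skipped": str(exc)}
        write_table(recs, pg_path, index_label=None)
    else:
        write_table(pd.DataFrame(columns=["feature_id", "faecal_met_id",
                                          "blood_met_id", "pgain"]),
                    pg_path, index_label=None)
    dlg_path = out / "dialogue_summary.json"
    dlg_path.write_text(json.dumps(dlg, indent=1, sort_keys=True))
    done("dialogue",
         {"n_null": cfg.dialogue_n_null, "n_datasets": cfg.dialogue_n_datasets,
          "n_pairs": cfg.dialogue_n_pairs, "min_missing": cfg.dialogue_min_missing,
          "min_complete": cfg.dialogue_min_complete, "tol_r": cfg.tol_r,
          "tol_n": cfg.tol_n, "seed": cfg.seed},
         [trio_path], [trio_path, pg_path, dlg_path], t0)

    # ---- link -----------------------------------------------------------
    t0 = time.monotonic()
    links = linking.link_metabolites(
        ann.set_index("metabolite_id")["compound_key"], cmap)
    link_summary = {}
    for key in ("pathways_faecal", "pathways_blood"):
        rec = screens[key]
        try:
            n_linked, n_total, frac = linking.functional_link_fraction(
                rec, links, fdr=cfg.fdr)
        except ValueError:
            n_linked, n_total, frac = 0, 0, float("nan")
        link_summary[key] = {"n_linked": n_linked, "n_total": n_total,
                             "fraction": frac}
    link_path = out / "link_summary.json"
    link_path.write_text(json.dumps(link_summary, indent=1, sort_keys=True))
    done("link", {}, [ann_path, cmap_path], [link_path], t0)

    report["out_dir"] = str(out)
    return report
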