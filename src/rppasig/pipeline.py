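"""End-to-end orchestration: simulate -> quantify -> harmonize -> associate ->
cluster -> survival -> HARPS, with a run manifest.

Stages communicate only through the documented files in the run directory, so
any stage can be re-run on externally exported matrices.  All randomness
derives from the single configured seed; two runs with the same inputs and
seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .associate import association_screen
from .cluster import SignalingClusterer, cluster_means, cluster_summary
from .core import (PipelineConfig, config_hash, read_clinical, read_spots,
                   write_clinical, write_matrix, write_spots)
from .harmonize import harmonize
from .harps import derive_harps, harps_classify, harps_response_table
from .quantify import quantify
from .simulate import SimulationConfig, simulate_cohort, simulate_spots
from .survival import analyte_survival_screen, drfs_by_cluster

logger = logging.getLogger("rppasig")

__all__ = ["run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig = None, out_dir="run",
            sim_config: SimulationConfig = None,
            spots_path=None, clinical_path=None,
            split_cluster_id=None, harps_filter=None) -> dict:
    """Run the full analysis chain and return the manifest.

    Either ``sim_config`` (synthetic inputs are generated and written) or
    both ``spots_path`` and ``clinical_path`` must be provided.  Every
    stage's table is written under ``out_dir``; ``manifest.json`` records the
    package version, seed, config hash, per-stage shapes and output hashes.
    """
    config = (config or PipelineConfig()).validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": config_hash(config),
        "stages": {},
        "outputs": {},
    }
    logger.info("run_all: resolved config %s (seed=%d)",
                dataclasses.asdict(config), config.seed)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    # --- inputs -----------------------------------------------------------
    if sim_config is not None:
        def _simulate():
            clin, truth = simulate_cohort(sim_config)
            spots = simulate_spots(sim_config, clin, truth)
            write_clinical(clin, out / "clinical.csv")
            write_spots(spots, out / "spots.tsv")
            truth.to_json(out / "truth.json")
            return clin, spots
        clinical, spots = stage("simulate", _simulate)
    elif spots_path is not None and clinical_path is not None:
        clinical = stage("read", lambda: read_clinical(clinical_path))
        spots = stage("read", lambda: read_spots(spots_path))
    else:
        raise StageError("stage 'inputs' failed: provide sim_config or "
                         "spots_path + clinical_path")
    manifest["stages"]["inputs"] = {"patients": int(len(clinical)),
                                    "spot_rows": int(len(spots))}

    # --- quantify ---------------------------------------------------------
    def _quantify():
        matrices = quantify(spots)
        for arr, m in matrices.items():
            write_matrix(m, out / f"endpoint_{arr.replace('/', '_')}.tsv")
        return matrices
    matrices = stage("quantify", _quantify)
    manifest["stages"]["quantify"] = {
        arr: {"patients": int(m.shape[0]), "analytes": int(m.shape[1])}
        for arr, m in matrices.items()}

    # --- harmonize --------------------------------------------------------
    def _harmonize():
        z, model = harmonize(matrices, clinical, config)
        write_matrix(z, out / "harmonized.tsv")
        model.to_json(out / "harmonization_model.json")
        return z
    harmonized = stage("harmonize", _harmonize)
    manifest["stages"]["harmonize"] = {
        "patients": int(harmonized.shape[0]),
        "analytes": int(harmonized.shape[1]),
        "arrays": int(clinical["array_id"].nunique()),
    }

    # --- associate --------------------------------------------------------
    def _associate():
        scopes = ["population"]
        scopes += [f"arm:{a}" for a in sorted(clinical["arm"].unique())]
        scopes += [f"subtype:{s}" for s in sorted(clinical["subtype"].unique())]
        tables = [association_screen(harmonized, clinical, scope,
                                     bh_alpha=config.bh_alpha)
                  for scope in scopes]
        tables = [t for t in tables if len(t)]
        assoc = (pd.concat(tables, ignore_index=True) if tables
                 else association_screen(harmonized, clinical, "population"))
        assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
        return assoc
    assoc = stage("associate", _associate)
    pop = assoc[assoc["scope"] == "population"]
    manifest["stages"]["associate"] = {
        "records": int(len(assoc)),
        "population_significant": int(pop["significant"].sum()),
    }

    # --- cluster ----------------------------------------------------------
    def _cluster():
        est = SignalingClusterer(cut_height=config.cut_height,
                                 split=split_cluster_id).fit(harmonized)
        est.labels_.rename("cluster").to_frame().to_csv(
            out / "clusters.tsv", sep="\t", index_label="patient_id")
        est.model_.to_json(out / "tree.json")
        means = cluster_means(harmonized.loc[est.labels_.index], est.labels_)
        write_matrix(means.rename_axis("patient_id"), out / "cluster_means.tsv")
        summary = cluster_summary(
            est.labels_,
            clinical.set_index("patient_id").loc[est.labels_.index].reset_index())
        summary.to_csv(out / "cluster_summary.tsv", sep="\t", index=False)
        return est
    clust = stage("cluster", _cluster)
    manifest["stages"]["cluster"] = {
        "clusters": int(clust.labels_.nunique()),
        "patients": int(len(clust.labels_)),
        "excluded": len(clust.excluded_),
    }

    # --- survival ---------------------------------------------------------
    def _survival():
        clin_sub = clinical.set_index("patient_id").loc[clust.labels_.index].reset_index()
        forest = drfs_by_cluster(clin_sub, clust.labels_.to_numpy())
        forest.to_csv(out / "survival_clusters.tsv", sep="\t", index=False)
        screen = analyte_survival_screen(
            harmonized.loc[clust.labels_.index], clin_sub, clust.labels_.to_numpy())
        screen.to_csv(out / "survival_analytes.tsv", sep="\t", index=False)
        return forest, screen
    forest, surv_screen = stage("survival", _survival)
    manifest["stages"]["survival"] = {
        "cluster_fits": int(len(forest)),
        "screen_records": int(len(surv_screen)),
    }

    # --- harps ------------------------------------------------------------
    def _harps():
        model = derive_harps(harmonized, clinical, harps_filter)
        model.to_json(out / "harps.json")
        tn = clinical.set_index("patient_id")["subtype"] == "TN"
        status = harps_classify(harmonized.loc[tn.reindex(harmonized.index,
                                                          fill_value=False)], model)
        status.to_frame().to_csv(out / "harps_status.tsv", sep="\t",
                                 index_label="patient_id")
        table = harps_response_table(status, clinical)
        table.to_csv(out / "harps_response.tsv", sep="\t", index=False)
        return model, status
    model, status = stage("harps", _harps)
    manifest["stages"]["harps"] = {
        "cut_egfr_y1173": model.cut_egfr_y1173,
        "cut_erbb2_y1248": model.cut_erbb2_y1248,
        "derivation_n": model.derivation["n"],
        "n_positive": int((status == "HARPS+").sum()),
    }

    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
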