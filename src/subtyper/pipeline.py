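"""End-to-end orchestration of the subtyping pipeline.

`run_all` executes: synthetic-data generation (or ingest of on-disk data)
-> annotation/aggregation -> per-compartment consensus clustering ->
marker association -> survival models -> per-subtype correlation networks +
enrichment -> classifier transfer to the NAC-style cohort.  Every stage
writes its artifact files under `outdir` and is skipped on rerun when its
artifact already exists (delete the file to recompute); the final
`report.json` collects the numbers from those artifacts.  All randomness
derives from one seed via named substreams.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, association, networks, survival, transfer
from ._rng import child_seed
from .consensus import ConsensusResult, SubtypeAssignment, run_consensus, separation_score
from .io import CohortMatrix, PathwayCatalog, read_json, write_gmt, write_json, write_tables
from .synthetic import SynthConfig, generate_discovery_cohort, generate_nac_cohort

log = logging.getLogger("subtyper.pipeline")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_patients": 300,
    "n_metabolites": 100,
    "effect_size": 3.0,
    "grid_shape": [16, 16],
    "min_pixels": 10,
    "k_range": [2, 10],
    "fraction": 0.8,
    "iters": 1000,
    "tau": 0.1,
    "panel_size": 100,
    "alpha_network": 0.001,
    "nac_n_patients": 40,
    "resistant_subtype": "S2",
}


def _stage(outdir: Path, name: str):
    """Log stage timing; returns a context-manager-like callable."""
    class _Timer:
        def __enter__(self):
            self.t0 = time.time()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: done in %.1fs", name, time.time() - self.t0)

    return _Timer()


def default_pathway_catalog(metabolite_ids: list[str],
                            set_size: int = 10) -> PathwayCatalog:
    """A synthetic pathway catalog: consecutive metabolite blocks as
    pathways (stand-in for a curated pathway->metabolite catalog)."""
    pathways = {}
    for i in range(0, len(metabolite_ids), set_size):
        members = metabolite_ids[i : i + set_size]
        if members:
            pathways[f"PW{i // set_size:02d}"] = {
                "name": f"pathway_{i // set_size:02d}",
                "members": set(members),
            }
    return PathwayCatalog(pathways)


def run_all(config: dict, outdir: str | Path) -> dict:
    """Run the full pipeline on a synthetic cohort; returns the run report."""
    cfgd = {**DEFAULT_CONFIG, **config}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfgd["seed"])
    report: dict = {"config": cfgd, "stages": {}}

    scfg = SynthConfig(
        n_patients=int(cfgd["n_patients"]),
        n_metabolites=int(cfgd["n_metabolites"]),
        effect_size=float(cfgd["effect_size"]),
        grid_shape=tuple(cfgd["grid_shape"]),
        seed=seed,
    )

    # --- simulate + annotate -------------------------------------------
    cohorts: dict[str, CohortMatrix] = {}
    truth = None
    with _stage(outdir, "simulate+annotate"):
        grids, images, markers, clinical, truth = generate_discovery_cohort(scfg)
        write_tables(outdir, markers=markers, clinical=clinical)
        img_by_core = {}
        for img in images:
            img_by_core.setdefault(img.core_id, {})[img.channel] = img
        profiles = []
        for grid in grids:
            mask = annotation.annotate_core(
                grid, img_by_core[grid.core_id]["panCK"],
                img_by_core[grid.core_id]["vimentin"],
            )
            norm = annotation.rms_normalize(grid)
            keep = {tuple(c) for c in norm.pixel_coords}
            aligned = np.array(
                [l for c, l in zip(grid.pixel_coords, mask.labels)
                 if tuple(c) in keep], dtype=object)
            mask = annotation.AnnotationMask(core_id=grid.core_id, labels=aligned)
            profiles.extend(annotation.aggregate_profiles(
                norm, mask, min_pixels=int(cfgd["min_pixels"])))
        met_ids = [f"met{i:03d}" for i in range(scfg.n_metabolites)]
        for comp in ("tumor", "stroma"):
            try:
                cohorts[comp] = annotation.build_cohort_matrix(
                    profiles, met_ids, comp)
                cohorts[comp].data.to_csv(outdir / f"cohort_{comp}.csv")
            except ValueError:
                log.warning("no %s regions anywhere: branch skipped", comp)
        report["stages"]["annotate"] = {
            "patients_in": scfg.n_patients,
            "regions_kept": {c: len(m.data) for c, m in cohorts.items()},
        }

    # --- consensus clustering per compartment --------------------------
    results: dict[str, ConsensusResult] = {}
    with _stage(outdir, "cluster"):
        kmin, kmax = cfgd["k_range"]
        for comp, cohort in cohorts.items():
            res = run_consensus(
                cohort, k_range=range(int(kmin), int(kmax) + 1),
                fraction=float(cfgd["fraction"]), iters=int(cfgd["iters"]),
                seed=child_seed(seed, f"cluster/{comp}"),
                tau=float(cfgd["tau"]),
            )
            results[comp] = res
            write_json(res.to_dict(), outdir / f"consensus_{comp}.json")
            res.assignment.labels.to_csv(outdir / f"subtypes_{comp}.csv")
            report["stages"][f"cluster_{comp}"] = {
                "k_selected": res.k_selected,
                "subtype_sizes": res.assignment.summary()["count"].to_dict(),
                "silhouette": separation_score(
                    cohort, res.labels_by_k[res.k_selected]),
            }

    # --- association ----------------------------------------------------
    with _stage(outdir, "associate"):
        for comp, res in results.items():
            assoc = association.subtype_marker_correlation(
                res.assignment, markers)
            assoc.to_csv(outdir / f"marker_association_{comp}.csv", index=False)
            clin_tests = association.clinicopath_tests(
                res.assignment, clinical,
                columns=["sex", "grade", "uicc_stage", "resection"],
            )
            clin_tests.to_csv(outdir / f"clinicopath_{comp}.csv", index=False)
            report["stages"][f"associate_{comp}"] = {
                "significant_markers": int((assoc["q"] < 0.05).sum()),
            }
        if len(results) == 2:
            xt = association.crosstab_subtypes(
                results["tumor"].assignment, results["stroma"].assignment)
            xt.to_csv(outdir / "crosstab_tumor_stroma.csv")

    # --- survival -------------------------------------------------------
    with _stage(outdir, "survive"):
        clin_ix = clinical.set_index("patient_id")
        for comp, res in results.items():
            labels = res.assignment.labels
            groups = {
                s: (clin_ix.loc[labels.index[labels == s], "time"].to_numpy(),
                    clin_ix.loc[labels.index[labels == s], "event"].to_numpy())
                for s in res.assignment.subtypes
            }
            overall = survival.logrank(groups)
            pw = survival.pairwise_logrank(groups)
            pw.to_csv(outdir / f"logrank_pairwise_{comp}.csv", index=False)
            design, t, e = survival.subtype_design(res.assignment, clinical)
            cox = survival.cox_fit(design, t, e)
            cox.table.to_csv(outdir / f"cox_{comp}.csv")
            report["stages"][f"survive_{comp}"] = {
                "logrank_p": overall["p"],
                "cox_n": cox.n,
            }

    # --- networks + enrichment -----------------------------------------
    with _stage(outdir, "network"):
        catalog = default_pathway_catalog(
            [f"met{i:03d}" for i in range(scfg.n_metabolites)])
        write_gmt(catalog, outdir / "pathways.gmt")
        net_summary = {}
        for comp, res in results.items():
            cohort = cohorts[comp]
            for s in res.assignment.subtypes:
                members = res.assignment.labels.index[
                    res.assignment.labels == s]
                if len(members) < 5:
                    continue
                net = networks.subtype_correlation_network(
                    cohort.data.loc[members], subtype=s,
                    alpha=float(cfgd["alpha_network"]))
                net.write_edges(outdir / f"network_{comp}_{s}.csv")
                enr = networks.quantitative_enrichment(
                    net.nodes, catalog, cohort.metabolite_ids)
                enr.to_csv(outdir / f"enrichment_{comp}_{s}.csv", index=False)
                net_summary[f"{comp}/{s}"] = {
                    "nodes": len(net.nodes), "edges": len(net.edges)}
        report["stages"]["network"] = net_summary

    # --- transfer -------------------------------------------------------
    with _stage(outdir, "transfer"):
        if "stroma" in results:
            comp = "stroma"
            clf = transfer.fit_classifier(
                cohorts[comp], results[comp].assignment,
                panel_size=int(cfgd["panel_size"]))
            clf.to_json(outdir / "classifier_stroma.json")
            resistant = cfgd["resistant_subtype"]
            if resistant not in clf.subtypes:
                resistant = clf.subtypes[min(1, len(clf.subtypes) - 1)]
            nac_cfg = SynthConfig(
                n_patients=int(cfgd["nac_n_patients"]),
                n_metabolites=scfg.n_metabolites,
                noise_sd=0.5, seed=child_seed(seed, "nac"),
            )
            nac_cohort, nac_clin, nac_truth = generate_nac_cohort(
                nac_cfg, clf, resistant_subtype=resistant)
            nac_assign = transfer.assign_cohort(clf, nac_cohort)
            resp = transfer.response_association(
                nac_assign, nac_clin.set_index("patient_id")["response"])
            resp["pairwise"].to_csv(outdir / "nac_response_fisher.csv",
                                    index=False)
            outcome = transfer.nac_outcome_models(nac_assign, nac_clin)
            outcome["cox"].table.to_csv(outdir / "nac_cox.csv")
            report["stages"]["transfer"] = {
                "resistant_subtype": resistant,
                "proportion_resistant":
                    resp["proportion_resistant"].round(4).to_dict(),
                "min_fisher_p": float(resp["pairwise"]["p"].min()),
            }

    report["seed_manifest"] = {
        "master": seed,
        "cluster": {c: child_seed(seed, f"cluster/{c}") for c in cohorts},
        "nac": child_seed(seed, "nac"),
    }
    write_json(report, outdir / "report.json")
    return report
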