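"""Canned study-condition experiments used by the acceptance script and the
recovery tests: generate a synthetic cohort at the default conditions, run
the full annotation + consensus path, and report what the elbow rule chose
and how well the planted subtypes were recovered."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import annotation
from ._rng import child_seed
from .consensus import ConsensusResult, run_consensus
from .io import CohortMatrix
from .synthetic import GroundTruth, SynthConfig, generate_discovery_cohort


def annotate_cohort(cfg: SynthConfig, compartment: str = "tumor") -> tuple[
    CohortMatrix, GroundTruth
]:
    """Generate a discovery cohort and run the annotation stage for one
    compartment, returning the clustering-ready matrix plus ground truth."""
    grids, images, _markers, _clinical, truth = generate_discovery_cohort(cfg)
    img_by_core: dict[str, dict] = {}
    for img in images:
        img_by_core.setdefault(img.core_id, {})[img.channel] = img
    profiles = []
    for grid in grids:
        mask = annotation.annotate_core(
            grid, img_by_core[grid.core_id]["panCK"],
            img_by_core[grid.core_id]["vimentin"])
        norm = annotation.rms_normalize(grid)
        if norm.n_pixels != grid.n_pixels:  # all-zero pixels dropped
            keep = {tuple(c) for c in norm.pixel_coords}
            labels = np.array(
                [l for c, l in zip(grid.pixel_coords, mask.labels)
                 if tuple(c) in keep], dtype=object)
            mask = annotation.AnnotationMask(core_id=grid.core_id, labels=labels)
        profiles.extend(annotation.aggregate_profiles(norm, mask))
    met_ids = [f"met{i:03d}" for i in range(cfg.n_metabolites)]
    return annotation.build_cohort_matrix(profiles, met_ids, compartment), truth


def k_selection_run(
    seed: int,
    n_patients: int = 300,
    n_metabolites: int = 100,
    effect_size: float = 3.0,
    iters: int = 500,
    compartment: str = "tumor",
    k_range: range = range(2, 11),
    fraction: float = 0.8,
    tau: float = 0.1,
) -> tuple[int, float, ConsensusResult]:
    """One seed of the K-selection experiment at the study conditions.

    Returns (K selected by the delta-area rule, ARI of the final labels
    against the planted subtypes, full result).
    """
    cfg = SynthConfig(n_patients=n_patients, n_metabolites=n_metabolites,
                      effect_size=effect_size, seed=seed)
    cohort, truth = annotate_cohort(cfg, compartment)
    res = run_consensus(cohort, k_range=k_range, fraction=fraction,
                        iters=iters, seed=child_seed(seed, "consensus"),
                        tau=tau)
    planted = (truth.tumor_subtype if compartment == "tumor"
               else truth.stroma_subtype)
    ari = adjusted_rand_score(planted.loc[res.sample_ids].to_numpy(),
                              res.assignment.labels.to_numpy())
    return res.k_selected, float(ari), res


def k_selection_majority(
    seeds: list[int], iters: int = 500, **kwargs
) -> tuple[int, list[int]]:
    """Majority K over several seeds; returns (majority K, per-seed Ks)."""
    ks = [k_selection_run(s, iters=iters, **kwargs)[0] for s in seeds]
    values, counts = np.unique(ks, return_counts=True)
    return int(values[np.argmax(counts)]), ks
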