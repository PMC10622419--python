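"""Synthetic discovery and NAC-style cohorts with known ground truth.

Generates everything the pipeline consumes — per-core pixel grids, IF channel
images, marker and clinical tables — from a small set of planted parameters,
so every downstream stage can be tested against a known truth without any
external data.

The intensity model is log-normal: each metabolite has a cohort-level
baseline log-intensity; metabolites in a subtype's informative block gain a
standardized shift (`effect_size`) in that subtype's compartment pixels;
patient-level biology adds `between_patient_sd` of log-noise and each pixel
adds `noise_sd` more; intensities are the exponentials.  Each patient
carries one core whose first `tumor_fraction` rows of pixels are tumor
(panCK-high) and the rest stroma (vimentin-high) in the IF images.

Marker scores come from a Gaussian latent shifted per planted subtype
(`marker_assoc` holds the signed shifts), then pushed through monotone maps
into each marker's native range — so planted Spearman signs survive.
Survival times are exponential with per-subtype multiplicative hazards and
independent uniform censoring calibrated to the target censoring rate.

Defaults mirror the study conditions the pipeline is meant to recover:
300 patients, 100 metabolites, 4 subtypes per compartment, effect size 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._rng import substream
from .io import (
    CohortMatrix,
    FluorescenceImage,
    PixelSpectrumGrid,
    validate_clinical,
    validate_markers,
)
from .transfer import CentroidClassifier

#: default signed latent shifts of each marker per subtype (index = subtype-1),
#: mirroring the discovery-cohort pattern: subtype 1 immune-cold (all
#: negative), subtype 2 immune-hot (all positive), subtype 3 neutral,
#: subtype 4 PD-L1-high with elevated DNA damage.
DEFAULT_MARKER_ASSOC: dict[str, tuple[float, ...]] = {
    "CD3": (-0.5, 0.5, 0.0, 0.0),
    "CD8": (-0.5, 0.5, 0.0, 0.0),
    "PDL1": (-0.5, 0.5, 0.0, 0.5),
    "gH2AX": (-0.4, 0.4, 0.0, 0.3),
}

#: default per-subtype multiplicative hazards: subtype 3 protective (the
#: favorable-prognosis subtype), subtype 4 slightly adverse.
DEFAULT_HAZARD_RATIOS: tuple[float, ...] = (1.0, 0.8, 0.45, 1.2)


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohorts (defaults = study conditions)."""

    n_patients: int = 300
    n_metabolites: int = 100
    n_subtypes: int = 4
    effect_size: float = 3.0
    frac_informative: float = 0.3
    grid_shape: tuple[int, int] = (16, 16)
    tumor_fraction: float = 0.6
    noise_sd: float = 1.0
    between_patient_sd: float = 0.5
    marker_assoc: dict[str, tuple[float, ...]] | None = None
    hazard_ratios: tuple[float, ...] | None = None
    base_median_survival: float = 30.0  # months
    censor_rate: float = 0.3
    subtype_coupling: float = 0.7  # P(stroma subtype mirrors tumor subtype)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subtypes < 2:
            raise ValueError("n_subtypes must be >= 2")
        if self.n_patients < self.n_subtypes:
            raise ValueError("n_patients must be >= n_subtypes")
        if self.n_metabolites < self.n_subtypes:
            raise ValueError("n_metabolites must be >= n_subtypes")
        if not 0 < self.tumor_fraction < 1:
            raise ValueError("tumor_fraction must lie in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 < self.frac_informative <= 1:
            raise ValueError("frac_informative must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if not 0 <= self.subtype_coupling <= 1:
            raise ValueError("subtype_coupling must lie in [0, 1]")
        if self.marker_assoc is None:
            self.marker_assoc = {
                m: _pad(v, self.n_subtypes) for m, v in DEFAULT_MARKER_ASSOC.items()
            }
        else:
            for m, v in self.marker_assoc.items():
                if len(v) != self.n_subtypes:
                    raise ValueError(
                        f"marker_assoc[{m!r}] needs {self.n_subtypes} entries"
                    )
        if self.hazard_ratios is None:
            self.hazard_ratios = _pad(DEFAULT_HAZARD_RATIOS, self.n_subtypes)
        elif len(self.hazard_ratios) != self.n_subtypes:
            raise ValueError(f"hazard_ratios needs {self.n_subtypes} entries")
        if any(h <= 0 for h in self.hazard_ratios):
            raise ValueError("hazard_ratios must be > 0")


def _pad(values: tuple[float, ...], n: int) -> tuple[float, ...]:
    v = tuple(values)
    if len(v) >= n:
        return v[:n]
    return v + (v[-1],) * (n - len(v))


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    tumor_subtype: pd.Series  # patient id -> 1-based subtype index
    stroma_subtype: pd.Series
    informative_metabolites: list[str]
    subtype_blocks: dict[int, list[str]]  # subtype index -> metabolite block
    hazard_ratios: tuple[float, ...]
    marker_assoc: dict[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        for name, s in (("tumor", self.tumor_subtype),
                        ("stroma", self.stroma_subtype)):
            if s.nunique() != len(self.hazard_ratios):
                raise ValueError(
                    f"{name} labels do not cover all {len(self.hazard_ratios)} subtypes"
                )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _metabolite_ids(n: int) -> list[str]:
    return [f"met{i:03d}" for i in range(n)]


def _informative_blocks(cfg: SynthConfig) -> tuple[list[str], dict[int, list[str]]]:
    ids = _metabolite_ids(cfg.n_metabolites)
    n_inf = max(cfg.n_subtypes, round(cfg.frac_informative * cfg.n_metabolites))
    informative = ids[:n_inf]
    blocks = {
        k + 1: list(informative[k::cfg.n_subtypes]) for k in range(cfg.n_subtypes)
    }
    return informative, blocks


def _draw_subtypes(cfg: SynthConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """1-based tumor and stroma subtype labels; every subtype occurs at least
    once in each compartment; stroma mirrors tumor with prob subtype_coupling."""
    n, k = cfg.n_patients, cfg.n_subtypes
    while True:
        tumor = rng.integers(1, k + 1, size=n)
        if len(np.unique(tumor)) == k:
            break
    mirror = rng.random(n) < cfg.subtype_coupling
    stroma = np.where(mirror, tumor, rng.integers(1, k + 1, size=n))
    # guarantee coverage of all stroma subtypes
    for s in range(1, k + 1):
        if not np.any(stroma == s):
            stroma[rng.integers(0, n)] = s
    return tumor, stroma


def _censor_horizon(lambdas: np.ndarray, target: float) -> float:
    """Horizon tau of the U(0, tau) censoring time achieving the target
    overall censoring probability for exponential event times."""
    if target <= 0:
        return np.inf

    def frac_censored(tau: float) -> float:
        # P(C < T) averaged over the cohort's hazards, C ~ U(0, tau)
        return float(np.mean((1 - np.exp(-lambdas * tau)) / (lambdas * tau)))

    lo, hi = 1e-6, 1e6
    return brentq(lambda t: frac_censored(t) - target, lo, hi)


def _survival_times(
    lambdas: np.ndarray, censor_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    t_event = rng.exponential(1.0 / lambdas)
    if censor_rate <= 0:
        times, events = t_event, np.ones(len(lambdas), dtype=int)
    else:
        tau = _censor_horizon(lambdas, censor_rate)
        c = rng.uniform(0, tau, size=len(lambdas))
        events = (t_event <= c).astype(int)
        times = np.minimum(t_event, c)
    return np.maximum(times, 1e-3), events


def _marker_table(
    cfg: SynthConfig, tumor_subtype: np.ndarray, patient_ids: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = {"patient_id": patient_ids}
    for marker, shifts in cfg.marker_assoc.items():
        latent = np.array([shifts[s - 1] for s in tumor_subtype]) + rng.normal(
            0, 1, size=cfg.n_patients
        )
        if marker == "PDL1":
            rows[marker] = 100 / (1 + np.exp(-latent))
        elif marker == "gH2AX":
            rows[marker] = 1 / (1 + np.exp(-latent))
        else:  # CD3 / CD8 style non-negative scores
            rows[marker] = np.exp(0.8 * latent + 3)
    return validate_markers(pd.DataFrame(rows))


def _clinical_table(
    cfg: SynthConfig, tumor_subtype: np.ndarray, patient_ids: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = cfg.n_patients
    base_lambda = np.log(2) / cfg.base_median_survival
    lambdas = base_lambda * np.array(
        [cfg.hazard_ratios[s - 1] for s in tumor_subtype]
    )
    times, events = _survival_times(lambdas, cfg.censor_rate, rng)
    # staging drawn independently of subtype (no planted clinical link),
    # with marginals shaped like a resected cohort
    df = pd.DataFrame({
        "patient_id": patient_ids,
        "time": times,
        "event": events,
        "uicc_stage": rng.choice(["I", "II", "III", "IV"], size=n,
                                 p=[0.30, 0.34, 0.33, 0.03]),
        "pT": rng.choice(["T1", "T2", "T3", "T4"], size=n,
                         p=[0.22, 0.48, 0.22, 0.08]),
        "pN": rng.choice(["N0", "N1", "N2"], size=n, p=[0.57, 0.32, 0.11]),
        "M": rng.choice(["M0", "M1"], size=n, p=[0.97, 0.03]),
        "grade": rng.choice(["G1", "G2", "G3"], size=n, p=[0.02, 0.49, 0.49]),
        "sex": rng.choice(["male", "female"], size=n, p=[0.85, 0.15]),
        "age": rng.integers(43, 86, size=n),
        "resection": rng.choice(["R0", "R1", "R2"], size=n,
                                p=[0.87, 0.12, 0.01]),
    })
    return validate_clinical(df)


# ---------------------------------------------------------------------------
# discovery cohort
# ---------------------------------------------------------------------------

def generate_discovery_cohort(cfg: SynthConfig) -> tuple[
    list[PixelSpectrumGrid], list[FluorescenceImage], pd.DataFrame,
    pd.DataFrame, GroundTruth,
]:
    """Generate the full discovery cohort: one core per patient.

    Returns (grids, if_images, markers, clinical, truth); `if_images` holds
    the panCK and vimentin channel per core at twice the grid resolution.
    """
    met_ids = _metabolite_ids(cfg.n_metabolites)
    informative, blocks = _informative_blocks(cfg)
    block_idx = {k: np.array([met_ids.index(m) for m in v])
                 for k, v in blocks.items()}

    rng_struct = substream(cfg.seed, "discovery/structure")
    tumor_sub, stroma_sub = _draw_subtypes(cfg, rng_struct)
    patient_ids = [f"P{i:04d}" for i in range(cfg.n_patients)]

    baseline = rng_struct.normal(3.0, 1.0, size=cfg.n_metabolites)

    rows, cols = cfg.grid_shape
    n_px = rows * cols
    n_tumor_rows = int(round(cfg.tumor_fraction * rows))
    coords = np.array([(r, c) for r in range(rows) for c in range(cols)])
    is_tumor_px = coords[:, 0] < n_tumor_rows

    rng_px = substream(cfg.seed, "discovery/pixels")
    rng_if = substream(cfg.seed, "discovery/ifimages")
    grids: list[PixelSpectrumGrid] = []
    images: list[FluorescenceImage] = []
    mz_channels = 200.0 + 2.0 * np.arange(cfg.n_metabolites)

    for i, pid in enumerate(patient_ids):
        shift = np.zeros((n_px, cfg.n_metabolites))
        shift[np.ix_(is_tumor_px, block_idx[tumor_sub[i]])] += cfg.effect_size
        shift[np.ix_(~is_tumor_px, block_idx[stroma_sub[i]])] += cfg.effect_size
        patient_noise = rng_px.normal(0, cfg.between_patient_sd,
                                      size=cfg.n_metabolites)
        pixel_noise = rng_px.normal(0, cfg.noise_sd,
                                    size=(n_px, cfg.n_metabolites))
        log_int = baseline + patient_noise + shift + pixel_noise
        grids.append(PixelSpectrumGrid(
            core_id=pid, pixel_coords=coords.copy(),
            mz_channels=mz_channels, intensities=np.exp(log_int),
        ))
        # IF channels at 2x grid resolution; positives bright, negatives dim
        up = np.repeat(np.repeat(is_tumor_px.reshape(rows, cols), 2, axis=0),
                       2, axis=1)
        panck = np.abs(np.where(up, 1.0, 0.05)
                       + rng_if.normal(0, 0.05, size=up.shape))
        vim = np.abs(np.where(up, 0.05, 1.0)
                     + rng_if.normal(0, 0.05, size=up.shape))
        images.append(FluorescenceImage(core_id=pid, channel="panCK", values=panck))
        images.append(FluorescenceImage(core_id=pid, channel="vimentin", values=vim))

    markers = _marker_table(cfg, tumor_sub, patient_ids,
                            substream(cfg.seed, "discovery/markers"))
    clinical = _clinical_table(cfg, tumor_sub, patient_ids,
                               substream(cfg.seed, "discovery/clinical"))
    truth = GroundTruth(
        tumor_subtype=pd.Series(tumor_sub, index=patient_ids, name="tumor_subtype"),
        stroma_subtype=pd.Series(stroma_sub, index=patient_ids, name="stroma_subtype"),
        informative_metabolites=informative,
        subtype_blocks=blocks,
        hazard_ratios=tuple(cfg.hazard_ratios),
        marker_assoc=dict(cfg.marker_assoc),
    )
    return grids, images, markers, clinical, truth


def generate_profile_cohort(cfg: SynthConfig, compartment: str = "tumor") -> tuple[
    CohortMatrix, GroundTruth
]:
    """Shortcut: region profiles drawn directly at the patient level
    (baseline + block shift + patient noise, exponentiated), skipping the
    pixel stage.  Useful for fast statistical tests of downstream stages."""
    met_ids = _metabolite_ids(cfg.n_metabolites)
    informative, blocks = _informative_blocks(cfg)
    block_idx = {k: np.array([met_ids.index(m) for m in v])
                 for k, v in blocks.items()}
    rng_struct = substream(cfg.seed, "discovery/structure")
    tumor_sub, stroma_sub = _draw_subtypes(cfg, rng_struct)
    sub = tumor_sub if compartment == "tumor" else stroma_sub
    patient_ids = [f"P{i:04d}" for i in range(cfg.n_patients)]
    baseline = rng_struct.normal(3.0, 1.0, size=cfg.n_metabolites)
    rng = substream(cfg.seed, f"profiles/{compartment}")
    log_int = (baseline
               + rng.normal(0, cfg.between_patient_sd,
                            size=(cfg.n_patients, cfg.n_metabolites)))
    for i in range(cfg.n_patients):
        log_int[i, block_idx[sub[i]]] += cfg.effect_size
    data = pd.DataFrame(np.exp(log_int), index=patient_ids, columns=met_ids)
    data.index.name = "sample_id"
    truth = GroundTruth(
        tumor_subtype=pd.Series(tumor_sub, index=patient_ids, name="tumor_subtype"),
        stroma_subtype=pd.Series(stroma_sub, index=patient_ids, name="stroma_subtype"),
        informative_metabolites=informative,
        subtype_blocks=blocks,
        hazard_ratios=tuple(cfg.hazard_ratios),
        marker_assoc=dict(cfg.marker_assoc),
    )
    return CohortMatrix(data=data, compartment=compartment), truth


# ---------------------------------------------------------------------------
# NAC-style transfer cohort
# ---------------------------------------------------------------------------

def generate_nac_cohort(
    cfg: SynthConfig,
    classifier: CentroidClassifier,
    resistant_subtype: str,
    resistant_enrichment: float = 0.9,
    baseline_resistance: float = 0.3,
    resistant_hr: float = 3.0,
) -> tuple[CohortMatrix, pd.DataFrame, GroundTruth]:
    """Chemotherapy-treated cohort drawn around the classifier's centroids.

    Each patient gets a true subtype (uniform over the classifier's
    subtypes), a z-space profile = centroid + N(0, noise_sd), and a response
    label: resistant with probability `resistant_enrichment` in the
    designated `resistant_subtype`, else `baseline_resistance`.  Survival is
    exponential with hazard multiplied by `resistant_hr` for resistant
    patients, uniform independent censoring as in the discovery cohort.
    """
    if resistant_subtype not in classifier.subtypes:
        raise ValueError(
            f"unknown resistant_subtype {resistant_subtype!r}; "
            f"classifier knows {classifier.subtypes}"
        )
    rng = substream(cfg.seed, "nac")
    n = cfg.n_patients
    subtypes = classifier.subtypes
    true_sub = rng.choice(len(subtypes), size=n)
    for s in range(len(subtypes)):  # cover every subtype
        if not np.any(true_sub == s):
            true_sub[rng.integers(0, n)] = s
    patient_ids = [f"N{i:04d}" for i in range(n)]

    C = classifier.centroids.to_numpy(dtype=float)
    z = C[true_sub] + rng.normal(0, cfg.noise_sd, size=(n, len(classifier.panel)))
    raw = z * classifier.feature_sds.to_numpy() + classifier.feature_means.to_numpy()
    raw = np.maximum(raw, 0.0)  # intensities are non-negative
    data = pd.DataFrame(raw, index=patient_ids, columns=classifier.panel)
    data.index.name = "sample_id"
    cohort = CohortMatrix(data=data, compartment=classifier.compartment)

    p_resist = np.where(
        np.asarray(subtypes)[true_sub] == resistant_subtype,
        resistant_enrichment, baseline_resistance,
    )
    resistant = rng.random(n) < p_resist
    base_lambda = np.log(2) / cfg.base_median_survival
    lambdas = np.where(resistant, base_lambda * resistant_hr, base_lambda)
    times, events = _survival_times(lambdas, cfg.censor_rate, rng)

    clinical = pd.DataFrame({
        "patient_id": patient_ids,
        "time": times,
        "event": events,
        "uicc_stage": rng.choice(["I", "II", "III", "IV"], size=n,
                                 p=[0.25, 0.35, 0.35, 0.05]),
        "pT": rng.choice(["T1", "T2", "T3", "T4"], size=n,
                         p=[0.22, 0.48, 0.22, 0.08]),
        "pN": rng.choice(["N0", "N1", "N2"], size=n, p=[0.5, 0.35, 0.15]),
        "M": rng.choice(["M0", "M1"], size=n, p=[0.97, 0.03]),
        "grade": rng.choice(["G1", "G2", "G3"], size=n, p=[0.02, 0.49, 0.49]),
        "sex": rng.choice(["male", "female"], size=n, p=[0.85, 0.15]),
        "age": rng.integers(43, 86, size=n),
        "resection": rng.choice(["R0", "R1", "R2"], size=n,
                                p=[0.87, 0.12, 0.01]),
        "MPR": np.where(resistant,
                        rng.random(n) < 0.15, rng.random(n) < 0.55).astype(int),
        "response": np.where(resistant, "resistant", "sensitive"),
    })
    validate_clinical(clinical)

    k = len(subtypes)
    labels_1based = pd.Series(true_sub + 1, index=patient_ids)
    truth = GroundTruth(
        tumor_subtype=labels_1based.rename("tumor_subtype"),
        stroma_subtype=labels_1based.rename("stroma_subtype"),
        informative_metabolites=list(classifier.panel),
        subtype_blocks={i + 1: [] for i in range(k)},
        hazard_ratios=tuple(
            resistant_hr if subtypes[i] == resistant_subtype else 1.0
            for i in range(k)
        ),
        marker_assoc={},
    )
    return cohort, clinical, truth
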