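"""Immunophenotype-guided annotation of imaging-MS pixels.

Implements the SPACiAL-style steps that turn raw per-core data into
compartment profiles ready for clustering:

1. RMS-normalize every pixel spectrum (divide by its root mean square).
2. Co-register each IF channel onto the MALDI pixel grid by area-weighted
   block-mean pooling.
3. Label pixels: pan-cytokeratin-positive -> tumor; panCK-negative but
   vimentin-positive -> stroma; otherwise unassigned.  Positivity thresholds
   default to Otsu's method per channel per core and can be overridden.
4. Aggregate RMS-normalized spectra into one mean profile per
   patient x compartment, dropping compartments with too few pixels.
5. Annotate m/z channels by accurate-mass matching against a metabolite
   reference ([M-H]- in negative-ion mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .io import (
    CohortMatrix,
    FluorescenceImage,
    MetaboliteReference,
    PixelSpectrumGrid,
    PROTON_MASS,
)

log = logging.getLogger("subtyper.annotation")

TUMOR, STROMA, UNASSIGNED = "tumor", "stroma", "unassigned"


@dataclass
class AnnotationMask:
    """Per-pixel semantic label for one core, aligned with a grid's pixels."""

    core_id: str
    labels: np.ndarray  # (n_pixels,) array of {tumor, stroma, unassigned}

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels) - {TUMOR, STROMA, UNASSIGNED}
        if bad:
            raise ValueError(f"unknown pixel labels: {sorted(map(str, bad))}")

    def to_frame(self, coords: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {"core_id": self.core_id, "row": coords[:, 0], "col": coords[:, 1],
             "label": self.labels}
        )


@dataclass
class RegionProfile:
    """Mean normalized intensity per metabolite for one patient compartment."""

    patient_id: str
    compartment: str
    intensities: np.ndarray
    n_pixels: int


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def rms_normalize(grid: PixelSpectrumGrid) -> PixelSpectrumGrid:
    """Divide each pixel spectrum by its root mean square.

    All-zero pixels cannot be normalized; they are dropped from the returned
    grid (and logged), which is equivalent to labeling them unassigned.
    """
    rms = np.sqrt(np.mean(grid.intensities**2, axis=1))
    keep = rms > 0
    if not keep.all():
        log.warning("core %s: excluding %d all-zero pixel(s)", grid.core_id,
                    int((~keep).sum()))
    return PixelSpectrumGrid(
        core_id=grid.core_id,
        pixel_coords=grid.pixel_coords[keep],
        mz_channels=grid.mz_channels,
        intensities=grid.intensities[keep] / rms[keep, None],
    )


# ---------------------------------------------------------------------------
# co-registration
# ---------------------------------------------------------------------------

def _overlap_weights(n_src: int, n_dst: int) -> np.ndarray:
    """(n_dst, n_src) row-stochastic matrix of fractional interval overlaps.

    Destination cell j covers [j*n_src/n_dst, (j+1)*n_src/n_dst) in source
    coordinates; weights are the overlap lengths (proportional-area rule),
    normalized to sum to 1 per destination cell.
    """
    w = np.zeros((n_dst, n_src))
    step = n_src / n_dst
    for j in range(n_dst):
        lo, hi = j * step, (j + 1) * step
        for i in range(int(np.floor(lo)), int(np.ceil(hi))):
            w[j, i] = min(hi, i + 1) - max(lo, i)
    return w / w.sum(axis=1, keepdims=True)


def coregister(image: FluorescenceImage, grid_shape: tuple[int, int]) -> np.ndarray:
    """Downscale an IF image to the MALDI grid by block-mean pooling.

    Each grid pixel receives the (area-weighted) mean lightness of the image
    block it maps onto.  Identity when resolutions already match.
    """
    rows, cols = grid_shape
    h, w = image.resolution
    if rows <= 0 or cols <= 0:
        raise ValueError("grid_shape must be positive")
    if h < rows or w < cols:
        raise ValueError(
            f"image resolution {h}x{w} below grid resolution {rows}x{cols}"
        )
    if (h, w) == (rows, cols):
        return image.values.copy()
    wr = _overlap_weights(h, rows)
    wc = _overlap_weights(w, cols)
    return wr @ image.values @ wc.T


# ---------------------------------------------------------------------------
# pixel labeling
# ---------------------------------------------------------------------------

def otsu_threshold(values: np.ndarray) -> float:
    """Otsu threshold for an IF channel; degenerate (constant) channels get
    a threshold above the maximum so no pixel is called positive."""
    flat = np.asarray(values, dtype=float).ravel()
    if np.allclose(flat, flat[0]):
        return float(flat[0]) + 1.0
    return float(threshold_otsu(flat))


def annotate_pixels(
    panck: np.ndarray,
    vimentin: np.ndarray,
    t_panck: float,
    t_vim: float,
) -> np.ndarray:
    """Label each grid position: tumor if panCK >= t_panck, else stroma if
    vimentin >= t_vim, else unassigned.  Total function, shape-preserving."""
    panck = np.asarray(panck, dtype=float)
    vimentin = np.asarray(vimentin, dtype=float)
    if panck.shape != vimentin.shape:
        raise ValueError("panCK and vimentin matrices must share shape")
    labels = np.full(panck.shape, UNASSIGNED, dtype=object)
    labels[vimentin >= t_vim] = STROMA
    labels[panck >= t_panck] = TUMOR  # panCK positivity wins
    return labels


def annotate_core(
    grid: PixelSpectrumGrid,
    panck_img: FluorescenceImage,
    vim_img: FluorescenceImage,
    t_panck: float | None = None,
    t_vim: float | None = None,
) -> AnnotationMask:
    """Co-register both IF channels to the grid and label the grid's pixels.

    Thresholds default to Otsu's method per channel per core.
    """
    shape = grid.grid_shape
    panck = coregister(panck_img, shape)
    vim = coregister(vim_img, shape)
    if t_panck is None:
        t_panck = otsu_threshold(panck)
    if t_vim is None:
        t_vim = otsu_threshold(vim)
    label_img = annotate_pixels(panck, vim, t_panck, t_vim)
    labels = label_img[grid.pixel_coords[:, 0], grid.pixel_coords[:, 1]]
    return AnnotationMask(core_id=grid.core_id, labels=labels)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_profiles(
    grid: PixelSpectrumGrid,
    mask: AnnotationMask,
    min_pixels: int = 10,
    patient_id: str | None = None,
) -> list[RegionProfile]:
    """Mean spectrum per compartment; compartments with fewer than
    `min_pixels` member pixels are omitted (and logged)."""
    if len(mask.labels) != grid.n_pixels:
        raise ValueError("mask not aligned with grid pixels")
    pid = patient_id if patient_id is not None else grid.core_id
    profiles: list[RegionProfile] = []
    for comp in (TUMOR, STROMA):
        member = mask.labels == comp
        n = int(member.sum())
        if n == 0:
            continue
        if n < min_pixels:
            log.info("core %s: %s region dropped (%d < %d pixels)",
                     grid.core_id, comp, n, min_pixels)
            continue
        profiles.append(RegionProfile(
            patient_id=pid, compartment=comp,
            intensities=grid.intensities[member].mean(axis=0), n_pixels=n,
        ))
    if not profiles:
        log.warning("core %s: no labeled pixels at all", grid.core_id)
    return profiles


def build_cohort_matrix(
    profiles: list[RegionProfile],
    metabolite_ids: list[str],
    compartment: str,
) -> CohortMatrix:
    """Stack one compartment's region profiles into a samples x metabolites
    matrix.  Multiple cores of one patient are averaged with equal weight."""
    rows = [p for p in profiles if p.compartment == compartment]
    if not rows:
        raise ValueError(f"no {compartment} profiles to assemble")
    df = pd.DataFrame(
        [p.intensities for p in rows],
        index=[p.patient_id for p in rows],
        columns=metabolite_ids,
    )
    df = df.groupby(level=0, sort=True).mean()
    df.index.name = "sample_id"
    return CohortMatrix(data=df, compartment=compartment)


# ---------------------------------------------------------------------------
# peak annotation
# ---------------------------------------------------------------------------

def annotate_peaks(
    mz_channels: np.ndarray,
    ref: MetaboliteReference,
    tol_ppm: float = 5.0,
) -> dict[int, list[tuple[str, float]]]:
    """Accurate-mass matching of observed m/z channels to [M-H]- ions.

    Returns channel index -> list of (metabolite id, ppm error), sorted by
    absolute error; channels with no match within `tol_ppm` are omitted.
    """
    if tol_ppm < 0:
        raise ValueError("tol_ppm must be >= 0")
    if len(ref.table) == 0:
        log.warning("empty metabolite reference: nothing annotated")
        return {}
    theo = ref.table["mass"].to_numpy(dtype=float) - PROTON_MASS  # [M-H]-
    ids = np.asarray(ref.table.index)
    out: dict[int, list[tuple[str, float]]] = {}
    for ci, mz in enumerate(np.asarray(mz_channels, dtype=float)):
        ppm = (mz - theo) / theo * 1e6
        hit = np.abs(ppm) <= tol_ppm
        if hit.any():
            matches = sorted(
                zip(ids[hit], ppm[hit]), key=lambda t: (abs(t[1]), t[0])
            )
            out[ci] = [(str(m), float(e)) for m, e in matches]
    return out
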