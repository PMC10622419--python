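"""Shared data model and file formats.

In-memory containers for one imaging-MS tissue core (:class:`PixelSpectrumGrid`),
its immunofluorescence channels (:class:`FluorescenceImage`), cohort-level tables
(markers, clinical), the metabolite reference used for accurate-mass annotation
and the pathway catalog used for enrichment.

On disk, pixel grids use either standard imzML (read-only, via pyimzml) or a
plain-text long-format CSV dialect ("imzml-lite") with columns
``core_id,row,col,mz,intensity`` — greppable and diff-friendly.  Pixel
coordinates are 0-based, row-major, everywhere in the package.  Tables are CSV
with fixed headers; the pathway catalog is GMT-style text.  Every reader
validates its schema before anything downstream consumes the data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("subtyper.io")

#: closed vocabularies for the clinical table
UICC_STAGES = ("I", "II", "III", "IV")
PT_STAGES = ("T1", "T2", "T3", "T4")
PN_STAGES = ("N0", "N1", "N2")
M_STAGES = ("M0", "M1")
GRADES = ("G1", "G2", "G3")
SEXES = ("male", "female")
RESECTIONS = ("R0", "R1", "R2")
RESPONSES = ("sensitive", "resistant")

MARKER_COLUMNS = ("CD3", "CD8", "PDL1", "gH2AX")

#: mass of a proton (Da); negative mode observes [M-H]- = M - PROTON_MASS
PROTON_MASS = 1.007276


class SchemaError(ValueError):
    """A file or table violates its declared schema."""


# ---------------------------------------------------------------------------
# pixel-level containers
# ---------------------------------------------------------------------------

@dataclass
class PixelSpectrumGrid:
    """Pixel-resolved intensity matrix for one tissue core.

    Parameters
    ----------
    core_id : str
        Identifier of the tissue core (one core per patient by convention).
    pixel_coords : (n_pixels, 2) int array
        0-based (row, col) pairs, unique, row-major ordering not required but
        produced by all writers in this package.
    mz_channels : (n_channels,) float array
        Strictly increasing m/z values in Da, shared by all pixels.
    intensities : (n_pixels, n_channels) float array
        Non-negative intensities.
    """

    core_id: str
    pixel_coords: np.ndarray
    mz_channels: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.pixel_coords = np.asarray(self.pixel_coords, dtype=int)
        self.mz_channels = np.asarray(self.mz_channels, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.pixel_coords.ndim != 2 or self.pixel_coords.shape[1] != 2:
            raise SchemaError("pixel_coords must be an (n, 2) array")
        if self.intensities.shape != (len(self.pixel_coords), len(self.mz_channels)):
            raise SchemaError(
                "intensities shape %s does not match %d pixels x %d channels"
                % (self.intensities.shape, len(self.pixel_coords), len(self.mz_channels))
            )
        coords = {tuple(c) for c in self.pixel_coords}
        if len(coords) != len(self.pixel_coords):
            raise SchemaError(f"core {self.core_id}: duplicate pixel coordinates")
        if len(self.mz_channels) > 1 and not np.all(np.diff(self.mz_channels) > 0):
            raise SchemaError(f"core {self.core_id}: m/z channels not strictly increasing")
        if np.any(self.intensities < 0):
            raise SchemaError(f"core {self.core_id}: negative intensities")

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_coords)

    @property
    def n_channels(self) -> int:
        return len(self.mz_channels)

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(rows, cols) bounding shape implied by the pixel coordinates."""
        return (int(self.pixel_coords[:, 0].max()) + 1, int(self.pixel_coords[:, 1].max()) + 1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PixelSpectrumGrid):
            return NotImplemented
        return (
            self.core_id == other.core_id
            and np.array_equal(self.pixel_coords, other.pixel_coords)
            and np.allclose(self.mz_channels, other.mz_channels)
            and np.allclose(self.intensities, other.intensities)
        )


@dataclass
class FluorescenceImage:
    """One IF channel of a core: lightness values at native resolution."""

    core_id: str
    channel: str  # 'panCK' or 'vimentin'
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.channel not in ("panCK", "vimentin"):
            raise SchemaError(f"unknown IF channel {self.channel!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise SchemaError("IF image must be a non-empty 2-D matrix")
        if np.any(self.values < 0):
            raise SchemaError("IF lightness values must be non-negative")

    @property
    def resolution(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# cohort-level containers
# ---------------------------------------------------------------------------

@dataclass
class CohortMatrix:
    """Samples (= patient . compartment) x annotated-metabolite intensities."""

    data: pd.DataFrame  # index: sample ids; columns: metabolite ids
    compartment: str  # 'tumor' or 'stroma'

    def __post_init__(self) -> None:
        if self.compartment not in ("tumor", "stroma"):
            raise SchemaError(f"compartment must be tumor or stroma, got {self.compartment!r}")
        if self.data.isna().any().any():
            raise SchemaError("cohort matrix contains missing values")
        if self.data.index.duplicated().any():
            raise SchemaError("duplicate sample ids in cohort matrix")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class PathwayCatalog:
    """pathway id -> {name, member metabolite ids}."""

    pathways: dict[str, dict]

    def __post_init__(self) -> None:
        for pid, entry in self.pathways.items():
            members = entry.get("members", set())
            if not members:
                raise SchemaError(f"pathway {pid} has an empty member set")
            entry["members"] = set(members)
            entry.setdefault("name", pid)

    def __len__(self) -> int:
        return len(self.pathways)

    def items(self):
        return self.pathways.items()


@dataclass
class MetaboliteReference:
    """Reference table for accurate-mass peak annotation."""

    table: pd.DataFrame  # index: metabolite id; columns: name, mass

    def __post_init__(self) -> None:
        missing = {"name", "mass"} - set(self.table.columns)
        if missing:
            raise SchemaError(f"metabolite reference missing columns: {sorted(missing)}")
        if (self.table["mass"] <= 0).any():
            raise SchemaError("metabolite monoisotopic masses must be > 0")


# ---------------------------------------------------------------------------
# imzml-lite CSV dialect
# ---------------------------------------------------------------------------

def write_grid(grid: PixelSpectrumGrid, path: str | Path) -> Path:
    """Write a grid in the long-format imzml-lite CSV dialect."""
    path = Path(path)
    n_px, n_ch = grid.intensities.shape
    rows = np.repeat(grid.pixel_coords[:, 0], n_ch)
    cols = np.repeat(grid.pixel_coords[:, 1], n_ch)
    mzs = np.tile(grid.mz_channels, n_px)
    df = pd.DataFrame(
        {
            "core_id": grid.core_id,
            "row": rows,
            "col": cols,
            "mz": mzs,
            "intensity": grid.intensities.ravel(),
        }
    )
    df.to_csv(path, index=False)
    return path


def _read_grid_csv(path: Path) -> PixelSpectrumGrid:
    df = pd.read_csv(path)
    required = ["core_id", "row", "col", "mz", "intensity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    core_ids = df["core_id"].unique()
    if len(core_ids) != 1:
        raise SchemaError(f"{path}: expected exactly one core_id, found {len(core_ids)}")
    dup = df.duplicated(subset=["row", "col", "mz"])
    if dup.any():
        first = df[dup].iloc[0]
        raise SchemaError(
            f"{path}: duplicate record for pixel ({int(first.row)},{int(first.col)}) "
            f"at m/z {first.mz}"
        )
    wide = df.pivot_table(index=["row", "col"], columns="mz", values="intensity")
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)][0]
        raise SchemaError(f"{path}: pixel {bad} does not cover the shared m/z axis")
    coords = np.array(list(wide.index), dtype=int)
    return PixelSpectrumGrid(
        core_id=str(core_ids[0]),
        pixel_coords=coords,
        mz_channels=np.asarray(wide.columns, dtype=float),
        intensities=wide.to_numpy(dtype=float),
    )


def _read_grid_imzml(path: Path) -> PixelSpectrumGrid:
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    coords = []
    spectra = []
    mz_axis = None
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mzs, ints = parser.getspectrum(i)
        if mz_axis is None:
            mz_axis = np.asarray(mzs, dtype=float)
        elif len(mzs) != len(mz_axis) or not np.allclose(mzs, mz_axis):
            raise SchemaError(
                f"{path}: spectrum {i} does not share the continuous m/z axis"
            )
        # imzML coordinates are 1-based (x=col, y=row)
        coords.append((int(y) - 1, int(x) - 1))
        spectra.append(np.asarray(ints, dtype=float))
    if mz_axis is None:
        raise SchemaError(f"{path}: no spectra")
    return PixelSpectrumGrid(
        core_id=Path(path).stem,
        pixel_coords=np.array(coords, dtype=int),
        mz_channels=mz_axis,
        intensities=np.vstack(spectra),
    )


def read_grid(path: str | Path, dialect: str = "imzml_lite_csv") -> PixelSpectrumGrid:
    """Read a pixel grid from `imzml` or `imzml_lite_csv` files."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "imzml_lite_csv":
        return _read_grid_csv(path)
    if dialect == "imzml":
        return _read_grid_imzml(path)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# marker / clinical tables
# ---------------------------------------------------------------------------

def validate_markers(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the per-patient immunomarker table (CD3, CD8, PDL1, gH2AX)."""
    missing = [c for c in ("patient_id", *MARKER_COLUMNS) if c not in df.columns]
    if missing:
        raise SchemaError(f"marker table missing column(s): {missing}")
    if df["patient_id"].duplicated().any():
        raise SchemaError("marker table: duplicate patient_id")
    if ((df["PDL1"] < 0) | (df["PDL1"] > 100)).any():
        raise SchemaError("PDL1 must lie in [0, 100] (% positive tumor cells)")
    if ((df["gH2AX"] < 0) | (df["gH2AX"] > 1)).any():
        raise SchemaError("gH2AX must lie in [0, 1] (proportion of positive cells)")
    if (df[["CD3", "CD8"]] < 0).any().any():
        raise SchemaError("CD3/CD8 scores must be non-negative")
    return df


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the clinical table (survival + staging; optional NAC columns)."""
    required = ["patient_id", "time", "event", "uicc_stage", "pT", "pN", "M",
                "grade", "sex", "age", "resection"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical table missing column(s): {missing}")
    if df["patient_id"].duplicated().any():
        raise SchemaError("clinical table: duplicate patient_id")
    if (df["time"] <= 0).any():
        raise SchemaError("survival time must be > 0 months")
    if not df["event"].isin([0, 1]).all():
        raise SchemaError("event must be 0/1 (disease-specific death)")
    vocab = {
        "uicc_stage": UICC_STAGES, "pT": PT_STAGES, "pN": PN_STAGES,
        "M": M_STAGES, "grade": GRADES, "sex": SEXES, "resection": RESECTIONS,
    }
    for col, allowed in vocab.items():
        bad = set(df[col].dropna()) - set(allowed)
        if bad:
            raise SchemaError(f"clinical column {col}: values {sorted(bad)} "
                              f"outside closed vocabulary {allowed}")
    if "response" in df.columns:
        bad = set(df["response"].dropna()) - set(RESPONSES)
        if bad:
            raise SchemaError(f"response values {sorted(bad)} not in {RESPONSES}")
    if "MPR" in df.columns and not df["MPR"].dropna().isin([0, 1]).all():
        raise SchemaError("MPR must be 0/1")
    return df


def write_tables(outdir: str | Path, markers: pd.DataFrame | None = None,
                 clinical: pd.DataFrame | None = None,
                 catalog: PathwayCatalog | None = None) -> dict[str, Path]:
    """Write validated cohort tables to `outdir`; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if markers is not None:
        validate_markers(markers)
        p = outdir / "markers.csv"
        markers.to_csv(p, index=False)
        written["markers"] = p
    if clinical is not None:
        validate_clinical(clinical)
        p = outdir / "clinical.csv"
        clinical.to_csv(p, index=False)
        written["clinical"] = p
    if catalog is not None:
        p = outdir / "pathways.gmt"
        write_gmt(catalog, p)
        written["catalog"] = p
    return written


def read_markers(path: str | Path) -> pd.DataFrame:
    return validate_markers(pd.read_csv(path))


def read_clinical(path: str | Path) -> pd.DataFrame:
    return validate_clinical(pd.read_csv(path))


# ---------------------------------------------------------------------------
# pathway catalog (GMT) and metabolite reference
# ---------------------------------------------------------------------------

def write_gmt(catalog: PathwayCatalog, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for pid, entry in sorted(catalog.items()):
            members = "\t".join(sorted(entry["members"]))
            fh.write(f"{pid}\t{entry['name']}\t{members}\n")
    return path


def read_gmt(path: str | Path) -> PathwayCatalog:
    pathways: dict[str, dict] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise SchemaError(f"{path}:{ln}: GMT line needs id, name and >=1 member")
            pathways[parts[0]] = {"name": parts[1], "members": set(parts[2:])}
    return PathwayCatalog(pathways)


def read_metabolite_reference(path: str | Path) -> MetaboliteReference:
    df = pd.read_csv(path)
    if "metabolite_id" not in df.columns:
        raise SchemaError("metabolite reference needs a metabolite_id column")
    return MetaboliteReference(df.set_index("metabolite_id"))


def write_metabolite_reference(ref: MetaboliteReference, path: str | Path) -> Path:
    path = Path(path)
    ref.table.rename_axis("metabolite_id").reset_index().to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# ground truth / misc JSON
# ---------------------------------------------------------------------------

def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_default)
    return path


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
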