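"""NIfTI volume and CSV manifest I/O with validation.

Inputs are assumed already aligned on a common voxel grid (registration
and tensor fitting are upstream of this package); volumes are read and
written in on-disk axis order with an identity-scaled affine and no
reorientation.  Malformed inputs are rejected, never silently repaired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: Canonical order of the five diffusion-tensor-derived maps.
MAP_NAMES = ("FA", "MD", "AxD", "RD", "MO")

#: Five binary vascular risk factors, in scoring order.
RISK_FACTORS = (
    "hypertension",
    "diabetes",
    "hypercholesterolemia",
    "obesity",
    "smoking",
)

#: Seven cognitive test raw-score columns.
COGNITION_TESTS = (
    "reaction_time",
    "trail_making_a",
    "symbol_digit",
    "numeric_memory",
    "pairs_matching",
    "trail_making_b",
    "fluid_intelligence",
)

#: Columns every participant manifest must carry.  Sex is coded
#: female=0 / male=1; scanner is an integer site code in {0, 1, 2};
#: missing values are empty CSV cells.
MANDATORY_COLUMNS = (
    "participant_id",
    "timepoint",
    "age",
    "sex",
    "scanner",
    "icv",
    *RISK_FACTORS,
    "apoe_e4_count",
    "education_college",
    "health_status",
)

#: Optional columns that are understood without a warning.
KNOWN_OPTIONAL_COLUMNS = (
    *COGNITION_TESTS,
    *(f"path_{m}" for m in MAP_NAMES),
    "split",
)


class ManifestError(ValueError):
    """Raised when a manifest violates its contract."""


@dataclass
class DwiMapSet:
    """Five aligned 3D scalar maps for one participant-timepoint."""

    participant_id: str
    timepoint: str
    volumes: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        missing = [m for m in MAP_NAMES if m not in self.volumes]
        if missing:
            raise ValueError(f"map set is missing maps: {', '.join(missing)}")
        extra = [m for m in self.volumes if m not in MAP_NAMES]
        if extra:
            raise ValueError(f"unexpected maps: {', '.join(extra)}")
        shapes = {m: v.shape for m, v in self.volumes.items()}
        if len({s for s in shapes.values()}) != 1:
            raise ValueError(f"maps disagree on grid shape: {shapes}")
        for m, v in self.volumes.items():
            if v.ndim != 3:
                raise ValueError(f"map {m} is not a 3D volume (shape {v.shape})")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"map {m} contains non-finite voxels")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return next(iter(self.volumes.values())).shape

    def stacked(self) -> np.ndarray:
        """Volumes stacked in canonical map order, shape (5, *grid)."""
        return np.stack([self.volumes[m] for m in MAP_NAMES])


def volume_filename(participant_id: str, timepoint: str, map_name: str) -> str:
    return f"{participant_id}_{timepoint}_{map_name}.nii.gz"


def save_map_set(map_set: DwiMapSet, outdir: str | Path) -> dict[str, Path]:
    """Write the five volumes as .nii.gz with an identity affine.

    Returns the path written per map (keys in canonical map order).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for m in MAP_NAMES:
        p = outdir / volume_filename(map_set.participant_id, map_set.timepoint, m)
        img = nib.Nifti1Image(
            np.asarray(map_set.volumes[m], dtype=np.float32), np.eye(4)
        )
        nib.save(img, p)
        paths[m] = p
    return paths


def load_map_set(row: pd.Series | dict) -> DwiMapSet:
    """Load the five volumes referenced by one manifest row.

    The row must carry ``path_FA`` ... ``path_MO``.  A missing column,
    an empty cell, or a vanished file raises an error naming the map.
    """
    row = dict(row)
    volumes = {}
    for m in MAP_NAMES:
        key = f"path_{m}"
        path = row.get(key)
        if path is None or (isinstance(path, float) and np.isnan(path)):
            raise ManifestError(f"manifest row lacks a volume path for map {m!r}")
        path = Path(path)
        if not path.exists():
            raise ManifestError(f"volume for map {m!r} not found: {path}")
        volumes[m] = np.asarray(nib.load(path).get_fdata(), dtype=np.float64)
    return DwiMapSet(
        participant_id=str(row["participant_id"]),
        timepoint=str(row.get("timepoint", "baseline")),
        volumes=volumes,
    )


def write_manifest(records: pd.DataFrame, path: str | Path) -> Path:
    """Write a participant manifest as CSV (missing values = empty cells)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    missing = [c for c in MANDATORY_COLUMNS if c not in records.columns]
    if missing:
        raise ManifestError(f"manifest is missing mandatory columns: {missing}")
    records.to_csv(path, index=False)
    return path


def read_manifest(path: str | Path, check_paths: bool = True) -> pd.DataFrame:
    """Read and validate a participant manifest.

    Unknown columns raise a warning; missing mandatory columns, or a
    duplicated participant_id x timepoint pair, raise ``ManifestError``.
    An empty (header-only) manifest is returned as an empty frame.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest {path} is missing mandatory columns: {missing}")
    unknown = [
        c
        for c in df.columns
        if c not in MANDATORY_COLUMNS and c not in KNOWN_OPTIONAL_COLUMNS
    ]
    if unknown:
        warnings.warn(f"manifest {path} has unknown columns: {unknown}", stacklevel=2)
    if len(df):
        dup = df.duplicated(subset=["participant_id", "timepoint"])
        if dup.any():
            bad = df.loc[dup, ["participant_id", "timepoint"]].iloc[0].tolist()
            raise ManifestError(
                f"duplicate participant_id x timepoint in manifest: {bad}"
            )
    if check_paths:
        path_cols = [c for c in df.columns if c.startswith("path_")]
        for c in path_cols:
            for p in df[c].dropna():
                if not Path(p).exists():
                    raise ManifestError(f"referenced file does not exist: {p}")
    return df
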