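"""Readers/writers for the standard formats the pipeline touches.

Conventions (fixed, documented here once):

* Gradient tables are FSL-dialect whitespace-delimited text: one row of
  b-values in ``.bval``, three rows (x, y, z) in ``.bvec``.  Directions are
  interpreted in the image coordinate frame, 0-based voxel indexing,
  RAS-oriented affines.  The b=0 convention is a (0,0,0) direction.
* Volumes are NIfTI-1 (.nii/.nii.gz) via nibabel.
* Cohort tables are CSV with columns
  ``subject_id, group, age, sex, scanner, plate, gpx, gr, delay``.
  ``group`` is HC/PT, ``sex`` is M/F; the GPx/GR ratio is always derived
  (``ratio`` property), never stored.  GPx and GR activities are in
  nmoles NADPH used/min/g hemoglobin; delay is days between MRI and blood
  draw.  Rows with missing gpx/gr/delay are dropped with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("redoxdmri")

__all__ = [
    "FormatError",
    "GradientScheme",
    "Volume4D",
    "CohortTable",
    "read_dwi",
    "truncate_shells",
    "read_cohort",
    "write_dwi",
    "write_cohort",
]


class FormatError(ValueError):
    """Malformed or mutually inconsistent input files."""


@dataclass
class GradientScheme:
    """Multi-shell acquisition: b-values (s/mm^2) and unit directions.

    b-values within ``shell_tolerance`` (s/mm^2) of a shell centre are
    treated as one shell (acquisition jitter).
    """

    bvals: np.ndarray
    bvecs: np.ndarray  # (N, 3), unit rows for b > 0, zero rows allowed at b=0
    shell_tolerance: float = 50.0

    def __post_init__(self):
        self.bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (len(self.bvals), 3):
            raise FormatError(
                f"bvecs shape {self.bvecs.shape} does not match {len(self.bvals)} bvals"
            )
        if not (np.all(np.isfinite(self.bvals)) and np.all(np.isfinite(self.bvecs))):
            raise FormatError("non-finite entries in gradient table")
        if np.any(self.bvals < 0):
            raise FormatError("negative b-value")
        nz = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[nz], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-3):
            raise FormatError("non-unit direction at b > 0")

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= self.shell_tolerance

    def shells(self) -> np.ndarray:
        """Cluster b-values into shell centres within ``shell_tolerance``."""
        centres: list[float] = []
        for b in np.sort(self.bvals):
            if not centres or b - centres[-1] > self.shell_tolerance:
                centres.append(float(b))
        return np.array(centres)


@dataclass
class Volume4D:
    """A 4-D diffusion-weighted image with affine and binary mask."""

    data: np.ndarray  # (X, Y, Z, N)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise FormatError(f"expected 4-D data, got ndim={self.data.ndim}")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.data.shape[:3]:
                raise FormatError("mask shape does not match spatial shape")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


def _normalize_sex(s) -> str:
    s = str(s).strip().upper()
    if s in {"M", "MALE"}:
        return "M"
    if s in {"F", "FEMALE"}:
        return "F"
    raise ValueError(f"sex value {s!r} outside {{M, F}}")


def _normalize_group(g) -> str:
    g = str(g).strip().upper()
    if g in {"HC", "CONTROL"}:
        return "HC"
    if g in {"PT", "PATIENT"}:
        return "PT"
    raise ValueError(f"group value {g!r} outside {{HC, PT}}")


class CohortTable:
    """Typed cohort table; thin wrapper over a pandas DataFrame.

    The GPx/GR ratio is a derived quantity (``ratio``), never a stored
    column, so it can never drift out of sync with gpx and gr.
    """

    REQUIRED = ["subject_id", "group", "age", "sex", "scanner", "plate", "gpx", "gr", "delay"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"cohort table missing columns: {missing}")
        df = df.copy()
        n_in = len(df)
        df = df.dropna(subset=["gpx", "gr", "delay"])
        if len(df) < n_in:
            logger.warning("dropped %d cohort rows with missing gpx/gr/delay", n_in - len(df))
        df["subject_id"] = df["subject_id"].astype(str)
        df["group"] = df["group"].map(_normalize_group)
        df["sex"] = df["sex"].map(_normalize_sex)
        df["age"] = df["age"].astype(float)
        df["gpx"] = df["gpx"].astype(float)
        df["gr"] = df["gr"].astype(float)
        df["delay"] = df["delay"].astype(float)
        if np.any(df["gr"].to_numpy() <= 0):
            raise ValueError("gr must be strictly positive")
        if np.any(df["delay"].to_numpy() < 0):
            raise ValueError("delay must be non-negative")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ratio(self) -> pd.Series:
        """GPx/GR ratio, computed on access."""
        return self.df["gpx"] / self.df["gr"]

    def subset(self, mask) -> "CohortTable":
        return CohortTable(self.df.loc[np.asarray(mask)].reset_index(drop=True))

    def __repr__(self) -> str:
        n_hc = int((self.df["group"] == "HC").sum())
        return f"CohortTable(n={len(self)}, HC={n_hc}, PT={len(self) - n_hc})"


def read_dwi(image_path, bval_path, bvec_path) -> tuple[Volume4D, GradientScheme]:
    """Load a 4-D NIfTI plus FSL-dialect bval/bvec gradient table.

    Volume count, bval count and bvec count must agree; directions at
    b > 0 are re-normalized to unit length.
    """
    img = nib.load(str(image_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"{image_path}: expected a 4-D image, got ndim={data.ndim}")
    bvals = np.loadtxt(str(bval_path), ndmin=1).ravel()
    bvecs = np.loadtxt(str(bvec_path), ndmin=2)
    # FSL dialect: three rows (x, y, z) by N columns
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if len(bvals) != data.shape[3] or bvecs.shape[0] != data.shape[3]:
        raise FormatError(
            f"count mismatch: {data.shape[3]} volumes, {len(bvals)} bvals, "
            f"{bvecs.shape[0]} bvecs"
        )
    if not (np.all(np.isfinite(bvals)) and np.all(np.isfinite(bvecs))):
        raise FormatError("non-finite entries in gradient table")
    nz = bvals > 0
    norms = np.linalg.norm(bvecs[nz], axis=1)
    if np.any(norms == 0):
        raise FormatError("zero direction at b > 0")
    bvecs = bvecs.copy()
    bvecs[nz] /= norms[:, None]
    scheme = GradientScheme(bvals=bvals, bvecs=bvecs)
    return Volume4D(data=data.astype(np.float64), affine=np.asarray(img.affine)), scheme


def write_dwi(volume: Volume4D, scheme: GradientScheme, image_path, bval_path, bvec_path) -> None:
    """Write NIfTI (float32) + FSL bval/bvec; inverse of :func:`read_dwi`."""
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    nib.save(img, str(image_path))
    np.savetxt(str(bval_path), scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(str(bvec_path), scheme.bvecs.T, fmt="%.8f")


def truncate_shells(volume: Volume4D, scheme: GradientScheme, bmax: float) -> tuple[Volume4D, GradientScheme]:
    """Keep only volumes with b <= bmax (b=0 volumes always retained).

    The DKI cumulant expansion is only valid at moderate weighting, so
    acquisitions with very high shells are truncated before fitting
    (here at b <= 2500 s/mm^2 by pipeline default).
    """
    if bmax <= 0:
        raise ValueError("bmax must be positive")
    keep = scheme.bvals <= bmax
    if not np.any(scheme.bvals[keep] <= scheme.shell_tolerance):
        raise FormatError("truncation would leave no b=0 volume; fit impossible")
    new_scheme = GradientScheme(
        bvals=scheme.bvals[keep], bvecs=scheme.bvecs[keep], shell_tolerance=scheme.shell_tolerance
    )
    new_vol = Volume4D(data=volume.data[..., keep], affine=volume.affine, mask=volume.mask)
    return new_vol, new_scheme


def read_cohort(csv_path) -> CohortTable:
    """Read the cohort CSV (see module docstring for the schema)."""
    try:
        df = pd.read_csv(csv_path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{csv_path}: empty cohort file") from exc
    return CohortTable(df)


def write_cohort(cohort: CohortTable, csv_path) -> None:
    cohort.df.to_csv(csv_path, index=False)
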