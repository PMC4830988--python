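"""Readers, writers and container types for diffusion MRI artifacts.

All spatial data live on a plain 0-based voxel grid with an identity
orientation; world-space transforms are deliberately not modelled (the
synthetic volumes this package analyses are pre-aligned by construction).
Units: b-values in s/mm^2, diffusivities in mm^2/s throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: b-values below this (s/mm^2) are treated as unweighted (b = 0) volumes —
#: a standard tolerance for scanner-reported near-zero shells.
B0_THRESHOLD = 50.0

GROUP_LABELS = ("control", "simple_T2h", "complex_T2h_HIE")
TERM_LABELS = ("preterm", "fullterm")
ROI_NAMES = ("PLIC", "SCR", "CC", "EC")


class FormatError(ValueError):
    """Artifact on disk does not match the expected layout."""


class SchemeError(ValueError):
    """Gradient scheme violates an acquisition invariant."""


@dataclass(frozen=True)
class GradientScheme:
    """A multi-shell acquisition: b-values and unit gradient directions.

    Parameters
    ----------
    bvalues : (M,) array
        b-values in s/mm^2.  Entries below ``B0_THRESHOLD`` are snapped
        to exactly 0.
    directions : (M, 3) array
        Gradient directions.  Renormalized to unit length for b > 0;
        the direction of b = 0 entries is arbitrary and left as given.
    """

    bvalues: np.ndarray
    directions: np.ndarray

    def __post_init__(self):
        bvals = np.asarray(self.bvalues, dtype=float).ravel()
        dirs = np.asarray(self.directions, dtype=float)
        if dirs.shape != (bvals.size, 3):
            raise SchemeError(
                f"directions shape {dirs.shape} does not match {bvals.size} b-values"
            )
        if np.any(bvals < 0):
            raise SchemeError("negative b-values")
        bvals = np.where(bvals < B0_THRESHOLD, 0.0, bvals)
        if not np.any(bvals == 0):
            raise SchemeError("scheme has no b=0 entry")
        dwi = bvals > 0
        norms = np.linalg.norm(dirs[dwi], axis=1)
        if np.any(norms < 1e-12):
            raise SchemeError("zero-length direction at b > 0")
        dirs = dirs.copy()
        dirs[dwi] /= norms[:, None]
        object.__setattr__(self, "bvalues", bvals)
        object.__setattr__(self, "directions", dirs)
        self.bvalues.setflags(write=False)
        self.directions.setflags(write=False)

    def __len__(self) -> int:
        return self.bvalues.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues == 0

    @property
    def shells(self) -> np.ndarray:
        """Distinct nonzero b-values, ascending."""
        return np.unique(self.bvalues[self.bvalues > 0])

    @property
    def bmax(self) -> float:
        return float(self.bvalues.max())

    def unique_directions(self, tol: float = 1e-6) -> np.ndarray:
        """Unique b > 0 directions up to antipodal symmetry, (K, 3)."""
        dirs = self.directions[self.bvalues > 0]
        uniq: list[np.ndarray] = []
        for d in dirs:
            if not any(min(np.linalg.norm(d - u), np.linalg.norm(d + u)) < tol for u in uniq):
                uniq.append(d)
        return np.array(uniq)

    def validate_for_kurtosis(self) -> None:
        """Kurtosis fitting needs >= 3 distinct nonzero shells."""
        if self.shells.size < 3:
            raise SchemeError(
                f"kurtosis fitting requires >= 3 nonzero b-shells, got {self.shells.size}"
            )


@dataclass
class DWIVolume:
    """A 4-D diffusion-weighted dataset on a voxel grid.

    ``signal`` is X x Y x Z x M in arbitrary scanner units, ``scheme``
    has length M, ``mask`` selects the voxels every downstream fit
    operates on.
    """

    signal: np.ndarray
    scheme: GradientScheme
    mask: np.ndarray | None = None
    voxel_size_mm: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise FormatError(f"signal must be 4-D, got ndim={self.signal.ndim}")
        if self.signal.shape[-1] != len(self.scheme):
            raise FormatError(
                f"signal has {self.signal.shape[-1]} volumes but scheme has "
                f"{len(self.scheme)} entries"
            )
        if np.any(self.signal < 0):
            raise FormatError("negative signal values")
        if self.mask is None:
            self.mask = np.ones(self.spatial_shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.spatial_shape:
            raise FormatError(
                f"mask shape {self.mask.shape} != spatial shape {self.spatial_shape}"
            )
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    def masked_signal(self) -> np.ndarray:
        """(N_voxels, M) signal rows for masked voxels, C-order."""
        return self.signal[self.mask]


@dataclass
class LabelAtlas:
    """Integer-labelled ROI volume; label 0 is background."""

    labels: np.ndarray
    name_map: dict[int, str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("atlas labels must be integers")
        if 0 in self.name_map:
            raise FormatError("label 0 is reserved for background")
        present = set(np.unique(self.labels).tolist())
        missing = [l for l in self.name_map if l not in present]
        if missing:
            raise FormatError(f"name_map labels absent from volume: {missing}")

    def region_mask(self, name: str) -> np.ndarray:
        for lab, nm in self.name_map.items():
            if nm == name:
                return self.labels == lab
        raise KeyError(f"unknown ROI name {name!r}")


# ---------------------------------------------------------------------------
# gradient tables

def read_bval_bvec(bval_path, bvec_path) -> GradientScheme:
    """Read FSL-dialect .bval (1 x M) and .bvec (3 x M) text tables."""
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.loadtxt(bvec_path, dtype=float)
    if bvecs.ndim != 2 or 3 not in bvecs.shape:
        raise FormatError(f"bvec table must be 3 x M, got shape {bvecs.shape}")
    if bvecs.shape[0] != 3:  # tolerate M x 3 transposes
        bvecs = bvecs.T
    if bvecs.shape[1] != bvals.size:
        raise FormatError(
            f"{bvals.size} b-values but {bvecs.shape[1]} direction columns"
        )
    return GradientScheme(bvals, bvecs.T)


def write_bval_bvec(scheme: GradientScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.bvalues[None, :], fmt="%.1f")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.10f")


# ---------------------------------------------------------------------------
# volumes

def _identity_img(data: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0)) -> nib.Nifti1Image:
    affine = np.diag([*voxel_size_mm, 1.0])
    return nib.Nifti1Image(np.asarray(data), affine)


def read_dwi(volume_path, bval_path, bvec_path, mask_path=None) -> DWIVolume:
    """Load a 4-D NIfTI with its FSL gradient tables into a :class:`DWIVolume`."""
    img = nib.load(str(volume_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{volume_path}: expected a 4-D volume, got ndim={data.ndim}")
    scheme = read_bval_bvec(bval_path, bvec_path)
    if data.shape[-1] != len(scheme):
        raise FormatError(
            f"{volume_path}: {data.shape[-1]} volumes but gradient tables have "
            f"{len(scheme)} entries"
        )
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return DWIVolume(data, scheme, mask=mask, voxel_size_mm=voxel_size)


def write_dwi(dwi: DWIVolume, volume_path, bval_path=None, bvec_path=None) -> None:
    _identity_img(dwi.signal, dwi.voxel_size_mm).to_filename(str(volume_path))
    if bval_path is not None:
        write_bval_bvec(dwi.scheme, bval_path, bvec_path)


def write_scalar_map(map3d: np.ndarray, reference: DWIVolume, path) -> None:
    """Write a 3-D scalar map aligned to ``reference``'s grid."""
    map3d = np.asarray(map3d, dtype=np.float64)
    if map3d.shape != reference.spatial_shape:
        raise FormatError(
            f"map shape {map3d.shape} != reference spatial shape "
            f"{reference.spatial_shape}"
        )
    if not np.all(np.isfinite(map3d)):
        logger.warning("scalar map %s contains non-finite values", path)
    _identity_img(map3d, reference.voxel_size_mm).to_filename(str(path))


def read_scalar_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)


# ---------------------------------------------------------------------------
# atlases

def write_atlas(atlas: LabelAtlas, volume_path, names_path=None) -> None:
    _identity_img(atlas.labels.astype(np.int32)).to_filename(str(volume_path))
    if names_path is None:
        names_path = Path(str(volume_path)).with_suffix("").with_suffix("")  # strip .nii(.gz)
        names_path = Path(str(names_path) + "_labels.json")
    Path(names_path).write_text(
        json.dumps({str(k): v for k, v in atlas.name_map.items()}, indent=1)
    )


def read_atlas(volume_path, names_path) -> LabelAtlas:
    labels = np.asarray(nib.load(str(volume_path)).dataobj).astype(np.int32)
    name_map = {int(k): v for k, v in json.loads(Path(names_path).read_text()).items()}
    return LabelAtlas(labels, name_map)


# ---------------------------------------------------------------------------
# cohort tables

REQUIRED_COHORT_COLUMNS = (
    "subject_id",
    "group",
    "term_status",
    "GA_weeks",
    "PMA_weeks",
    "BW_grams",
)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check cohort invariants; raise with the offending row index."""
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cohort table missing columns: {missing}")
    if len(df) == 0:
        raise FormatError("cohort table is empty")
    bad_group = ~df["group"].isin(GROUP_LABELS)
    if bad_group.any():
        i = int(np.flatnonzero(bad_group.to_numpy())[0])
        raise FormatError(
            f"row {i}: unknown group label {df['group'].iloc[i]!r} "
            f"(expected one of {GROUP_LABELS})"
        )
    bad_term = ~df["term_status"].isin(TERM_LABELS)
    if bad_term.any():
        i = int(np.flatnonzero(bad_term.to_numpy())[0])
        raise FormatError(f"row {i}: unknown term_status {df['term_status'].iloc[i]!r}")
    ga_gt_pma = df["GA_weeks"].to_numpy(float) > df["PMA_weeks"].to_numpy(float)
    if ga_gt_pma.any():
        i = int(np.flatnonzero(ga_gt_pma)[0])
        raise FormatError(f"row {i}: GA > PMA ({df['GA_weeks'].iloc[i]} > {df['PMA_weeks'].iloc[i]})")
    bad_bw = df["BW_grams"].to_numpy(float) <= 0
    if bad_bw.any():
        i = int(np.flatnonzero(bad_bw)[0])
        raise FormatError(f"row {i}: BW must be positive, got {df['BW_grams'].iloc[i]}")
    return df


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a per-subject covariate/metric CSV.

    Columns beyond the required six are treated as ``<ROI>_<metric>``
    measurement columns.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty cohort file") from exc
    return validate_cohort(df)


def write_cohort(df: pd.DataFrame, path) -> None:
    validate_cohort(df)
    df.to_csv(path, index=False)
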