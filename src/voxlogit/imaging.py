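"""Volume I/O, smoothing, relative-CBF derivation and mask bookkeeping.

All per-case volumes live on a common voxel grid (the cases are assumed
co-registered in a shared space). Axis 0 is the left-right axis; the
mid-sagittal plane splits the grid into a "left" half (low indices) and a
"right" half (high indices). Masks are stored as uint8 arrays of {0, 1}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

#: Imaging modalities every case must provide, in manifest order.
MODALITIES = ("ncct", "cta", "cbv", "cbf", "tmax")

#: mTICI grades that count as successful recanalization (mTICI > 2a).
SUCCESSFUL_MTICI = frozenset({"2b", "2c", "3"})

#: Gaussian kernel truncation, in standard deviations.
KERNEL_TRUNCATE = 4.0

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class AlignmentError(ValueError):
    """Volumes of one case disagree in shape or affine."""


@dataclass
class VolumeGrid:
    """A 3D scalar volume with voxel geometry.

    Parameters
    ----------
    data
        3D array; float volumes are kept as float32, masks as uint8.
    voxel_size
        Physical voxel edge lengths in mm per axis.
    affine
        Optional 4x4 voxel-to-world affine. When absent, a diagonal
        affine built from ``voxel_size`` is used for I/O.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def default_affine(self) -> np.ndarray:
        if self.affine is not None:
            return self.affine
        aff = np.diag([*self.voxel_size, 1.0])
        return aff


def voxel_volume_ml(grid: VolumeGrid) -> float:
    """Volume of one voxel in ml (product of edge lengths in mm^3 / 1000)."""
    return float(np.prod(grid.voxel_size)) / 1000.0


@dataclass
class PatientCase:
    """One subject: co-registered volumes, masks and clinical covariates."""

    case_id: str
    volumes: dict[str, VolumeGrid]
    coverage: np.ndarray
    lesion: np.ndarray
    age: float
    sex: int
    nihss: int
    onset_to_image: float
    mtici: str
    occlusion_side: str
    cohort: str = ""
    exclusion: np.ndarray | None = None
    cbf_rel: VolumeGrid | None = None
    #: smoothing cache: fwhm -> {map name -> smoothed 3D array}
    _smoothed: dict[float, dict[str, np.ndarray]] = field(default_factory=dict, repr=False)

    @property
    def recanalization(self) -> bool:
        """Successful recanalization iff mTICI > 2a (grades 2b, 2c, 3)."""
        return str(self.mtici) in SUCCESSFUL_MTICI

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.coverage.shape

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return next(iter(self.volumes.values())).voxel_size

    def validate(self) -> None:
        shapes = {v.data.shape for v in self.volumes.values()}
        shapes |= {self.coverage.shape, self.lesion.shape}
        if self.exclusion is not None:
            shapes.add(self.exclusion.shape)
        if len(shapes) != 1:
            raise AlignmentError(f"case {self.case_id}: inconsistent shapes {shapes}")
        if self.occlusion_side not in ("left", "right"):
            raise ValueError(f"case {self.case_id}: occlusion side {self.occlusion_side!r}")

    def enforce_masks(self) -> int:
        """Clip the lesion mask to coverage (minus exclusion); return the
        number of lesion voxels dropped."""
        cov = self.coverage.astype(bool)
        if self.exclusion is not None:
            cov &= ~self.exclusion.astype(bool)
        les = self.lesion.astype(bool)
        dropped = int(np.count_nonzero(les & ~cov))
        if dropped:
            log.info("case %s: dropped %d lesion voxels outside coverage", self.case_id, dropped)
        self.lesion = (les & cov).astype(np.uint8)
        self.coverage = cov.astype(np.uint8)
        return dropped

    def effective_coverage(self) -> np.ndarray:
        """Coverage minus exclusion, as bool."""
        cov = self.coverage.astype(bool)
        if self.exclusion is not None:
            cov &= ~self.exclusion.astype(bool)
        return cov

    def smoothed(self, fwhm_mm: float) -> dict[str, np.ndarray]:
        """Smoothed imaging maps (including cbf_rel) at a given FWHM, cached.

        Smoothing is mask-aware, restricted to the coverage support.
        """
        key = float(fwhm_mm)
        if key not in self._smoothed:
            support = self.effective_coverage()
            maps: dict[str, np.ndarray] = {}
            for name, vol in self.volumes.items():
                maps[name] = gaussian_smooth(vol, key, support=support).data
            if self.cbf_rel is None:
                compute_cbf_rel(self)
            maps["cbf_rel"] = gaussian_smooth(self.cbf_rel, key, support=support).data
            self._smoothed[key] = maps
        return self._smoothed[key]


def gaussian_smooth(vol: VolumeGrid, fwhm_mm: float, support: np.ndarray | None = None) -> VolumeGrid:
    """Mask-aware separable Gaussian smoothing at a given FWHM (mm).

    sigma = fwhm / (2 sqrt(2 ln 2)) per axis, converted to voxels. Inside
    the support mask the kernel is renormalized over the supported
    neighbourhood, so values outside the support never bleed in. fwhm 0 is
    the identity.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return VolumeGrid(vol.data.copy(), vol.voxel_size, vol.affine)
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / s for s in vol.voxel_size]
    data = np.asarray(vol.data, dtype=np.float64)
    if support is None:
        out = ndimage.gaussian_filter(data, sigma_vox, truncate=KERNEL_TRUNCATE, mode="constant")
        # renormalize by the smoothed all-ones field to undo boundary loss
        ones = np.ones_like(data)
        norm = ndimage.gaussian_filter(ones, sigma_vox, truncate=KERNEL_TRUNCATE, mode="constant")
        out = out / norm
    else:
        m = support.astype(np.float64)
        num = ndimage.gaussian_filter(data * m, sigma_vox, truncate=KERNEL_TRUNCATE, mode="constant")
        den = ndimage.gaussian_filter(m, sigma_vox, truncate=KERNEL_TRUNCATE, mode="constant")
        out = np.zeros_like(data)
        inside = support.astype(bool) & (den > 0)
        out[inside] = num[inside] / den[inside]
    return VolumeGrid(out.astype(np.float32), vol.voxel_size, vol.affine)


def hemisphere_masks(shape: tuple[int, int, int], occlusion_side: str) -> tuple[np.ndarray, np.ndarray]:
    """(affected, unaffected) boolean hemisphere masks split at the
    mid-sagittal plane of the grid (axis 0)."""
    if occlusion_side not in ("left", "right"):
        raise ValueError(f"occlusion side must be 'left' or 'right', got {occlusion_side!r}")
    nx = shape[0]
    left = np.zeros(shape, dtype=bool)
    left[: nx // 2] = True
    right = ~left
    if occlusion_side == "left":
        return left, right
    return right, left


def compute_cbf_rel(case: PatientCase) -> VolumeGrid:
    """CBF as % of the mean CBF over covered voxels of the unaffected
    hemisphere; stored on the case."""
    cbf = case.volumes["cbf"]
    _, unaffected = hemisphere_masks(cbf.data.shape, case.occlusion_side)
    ref = unaffected & case.effective_coverage()
    if not ref.any():
        raise ValueError(f"case {case.case_id}: no coverage on the unaffected hemisphere")
    mean_ref = float(np.asarray(cbf.data, dtype=np.float64)[ref].mean())
    if mean_ref == 0:
        raise ValueError(f"case {case.case_id}: zero mean CBF on the unaffected hemisphere")
    rel = 100.0 * np.asarray(cbf.data, dtype=np.float64) / mean_ref
    case.cbf_rel = VolumeGrid(rel.astype(np.float32), cbf.voxel_size, cbf.affine)
    return case.cbf_rel


# ---------------------------------------------------------------------------
# NIfTI + manifest I/O


def save_volume(vol: VolumeGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data), vol.default_affine())
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> VolumeGrid:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(np.asarray(img.dataobj), zooms, np.asarray(img.affine))


#: Manifest columns referencing per-case NIfTI files.
MANIFEST_PATH_COLS = {
    "ncct": "path_ncct",
    "cta": "path_cta",
    "cbv": "path_cbv",
    "cbf": "path_cbf",
    "tmax": "path_tmax",
    "lesion": "path_lesion",
    "coverage": "path_coverage",
    "exclusion": "path_exclusion",
}


def read_case(manifest_row: Mapping, root: str | Path | None = None) -> PatientCase:
    """Build a PatientCase from one manifest row (paths + covariates).

    Raises AlignmentError on shape/affine mismatch between volumes and
    KeyError on a missing covariate.
    """
    root = Path(root) if root is not None else Path(".")

    def _load(col: str) -> VolumeGrid:
        p = Path(str(manifest_row[col]))
        if not p.is_absolute():
            p = root / p
        return load_volume(p)

    volumes = {mod: _load(MANIFEST_PATH_COLS[mod]) for mod in MODALITIES}
    coverage = _load(MANIFEST_PATH_COLS["coverage"])
    lesion = _load(MANIFEST_PATH_COLS["lesion"])
    exclusion = None
    exc_col = MANIFEST_PATH_COLS["exclusion"]
    if exc_col in manifest_row and str(manifest_row[exc_col]) not in ("", "nan", "None"):
        exclusion = _load(exc_col).data.astype(np.uint8)

    ref = volumes["ncct"]
    for name, vol in [*volumes.items(), ("coverage", coverage), ("lesion", lesion)]:
        if vol.data.shape != ref.data.shape:
            raise AlignmentError(f"{name}: shape {vol.data.shape} != {ref.data.shape}")
        if vol.affine is not None and ref.affine is not None:
            if not np.allclose(vol.affine, ref.affine, atol=1e-4):
                raise AlignmentError(f"{name}: affine mismatch")

    case = PatientCase(
        case_id=str(manifest_row["case_id"]),
        volumes=volumes,
        coverage=np.asarray(coverage.data).astype(np.uint8),
        lesion=np.asarray(lesion.data).astype(np.uint8),
        exclusion=exclusion,
        age=float(manifest_row["age"]),
        sex=int(manifest_row["sex"]),
        nihss=int(manifest_row["nihss"]),
        onset_to_image=float(manifest_row["onset_to_image_min"]),
        mtici=str(manifest_row["mtici"]),
        occlusion_side=str(manifest_row["occlusion_side"]),
        cohort=str(manifest_row.get("cohort", "")),
    )
    case.validate()
    case.enforce_masks()
    compute_cbf_rel(case)
    return case


def read_cohort(manifest_path: str | Path) -> list[PatientCase]:
    import pandas as pd

    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    return [read_case(row, root=manifest_path.parent) for _, row in df.iterrows()]
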