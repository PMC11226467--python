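"""Synthetic stroke-cohort generator with a known voxelwise generative model.

Each phantom patient carries multimodal CT-like maps (NCCT, CT-A source,
CBV, CBF, Tmax) on a common grid, a spherical core-plus-penumbra perfusion
deficit with smooth radial transitions, Gaussian voxel noise, clinical
covariates, and a binary infarct mask drawn voxelwise from
Bernoulli(logistic(eta)) where eta is the linear predictor of a known
logistic model over the realized (noisy) maps and covariates. Because the
infarct labels are sampled from the same maps the downstream model sees,
voxelwise maximum-likelihood refits of the generating predictor set are
consistent, which is what makes the phantoms usable as a parameter-recovery
testbed.

Perfusion maps are generated on a relative scale (background = 100% for CBF
and CBV), so deriving CBF relative to the unaffected hemisphere is exercised
non-trivially. NCCT and CT-A are weakly structured nuisance maps (small core
hypodensity plus noise) that carry no weight in the generative model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .imaging import MODALITIES, PatientCase, VolumeGrid, compute_cbf_rel, save_volume

#: Default true coefficients (log-odds units, raw predictor scales: CBV/CBF
#: in % of contralateral, Tmax in seconds, recanalization 0/1). The
#: recanalization terms make recanalization protective everywhere, with a
#: larger benefit in the penumbra (moderate CBF, preserved CBV) than in the
#: deeply hypoperfused core, and every coefficient carries a detectable
#: standardized effect at desk-scale cohorts.
DEFAULT_TRUE_BETA: dict[str, float] = {
    "intercept": 2.0,
    "cbv": -0.03,
    "cbf": -0.025,
    "tmax": 0.2,
    "recan": 1.0,
    "recan:cbv": -0.06,
    "recan:cbf": 0.04,
}

#: map name -> (core, penumbra, background) plateau values.
DEFAULT_CONTRAST: dict[str, tuple[float, float, float]] = {
    "tmax": (12.0, 8.0, 0.5),       # seconds
    "cbf": (25.0, 45.0, 100.0),     # % of contralateral
    "cbv": (40.0, 90.0, 100.0),     # % of contralateral; core-weighted drop
    "ncct": (33.0, 34.0, 35.0),     # HU-like; small core hypodensity
    "cta": (37.0, 39.0, 40.0),      # HU-like source image
}

DEFAULT_NOISE_SD: dict[str, float] = {
    "tmax": 0.75,
    "cbf": 8.0,
    "cbv": 8.0,
    "ncct": 2.0,
    "cta": 2.0,
}


class PhantomConfigError(ValueError):
    """Invalid phantom geometry or parameters."""


@dataclass
class GroundTruthModel:
    """The known voxelwise logistic model behind a phantom cohort."""

    beta: dict[str, float]

    @property
    def predictors(self) -> tuple[str, ...]:
        return tuple(self.beta)

    def linear_predictor(self, features: dict[str, np.ndarray | float], recan: int) -> np.ndarray:
        """eta = sum_j beta_j x_j with interaction columns recan * map."""
        eta = None
        for name, b in self.beta.items():
            if name == "intercept":
                x = 1.0
            elif name.startswith("recan:"):
                x = recan * np.asarray(features[name.split(":", 1)[1]], dtype=np.float64)
            elif name == "recan":
                x = float(recan)
            else:
                x = np.asarray(features[name], dtype=np.float64)
            term = b * x
            eta = term if eta is None else eta + term
        return np.asarray(eta, dtype=np.float64)

    def probability(self, features: dict[str, np.ndarray | float], recan: int) -> np.ndarray:
        p = expit(self.linear_predictor(features, recan))
        return np.clip(p, 1e-12, 1 - 1e-12)


@dataclass
class PhantomParams:
    """Generative parameters of a phantom cohort (see module docstring)."""

    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_BETA))
    core_radius_mm: float = 8.0
    penumbra_radius_mm: float = 16.0
    center_jitter_mm: float = 2.0
    #: per-case multiplicative jitter of both radii (lesion-size variability)
    radius_scale_range: tuple[float, float] = (0.8, 1.25)
    #: per-case multiplicative jitter of the perfusion-deficit depth
    severity_range: tuple[float, float] = (0.75, 1.25)
    #: additional per-case, per-map severity jitter: the deficit depths of
    #: CBF, CBV and Tmax co-vary but are not deterministic copies of each
    #: other, which keeps the voxelwise design identifiable
    map_severity_range: tuple[float, float] = (0.8, 1.2)
    coverage_margin_mm: float = 8.0
    transition_mm: float = 2.0
    contrast: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_CONTRAST.items()}
    )
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    #: correlation length of the map noise fields (mm, FWHM of the shaping
    #: kernel); perfusion-map errors are spatially smooth, not white
    noise_smoothness_mm: float = 6.0
    recan_fraction: float = 0.83
    age_mean: float = 74.0
    age_sd: float = 12.0
    sex_p_female: float = 0.57
    nihss_range: tuple[int, int] = (2, 30)
    onset_to_image_range: tuple[float, float] = (45.0, 480.0)
    #: "random": sample left/right per case; "left"/"right": fixed side
    occlusion_side: str = "random"
    seed: int = 0
    cohort_label: str = "phantom"

    def validate(self) -> None:
        if self.core_radius_mm >= self.penumbra_radius_mm:
            raise PhantomConfigError("core radius must be smaller than penumbra radius")
        extent_mm = min(n * v for n, v in zip(self.shape, self.voxel_size))
        max_radius = self.penumbra_radius_mm * max(self.radius_scale_range)
        if max_radius >= extent_mm / 2:
            raise PhantomConfigError(
                f"maximal penumbra radius {max_radius} mm must be below half "
                f"the smallest grid extent ({extent_mm / 2} mm)"
            )
        if not (0.0 <= self.recan_fraction <= 1.0):
            raise PhantomConfigError("recanalization fraction must lie in [0, 1]")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise PhantomConfigError("noise SDs must be non-negative")
        if "intercept" not in self.beta:
            raise PhantomConfigError("true beta must include an intercept")
        if self.occlusion_side not in ("random", "left", "right"):
            raise PhantomConfigError(f"occlusion_side must be random/left/right, got {self.occlusion_side!r}")

    @property
    def ground_truth(self) -> GroundTruthModel:
        return GroundTruthModel(dict(self.beta))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shape"] = list(self.shape)
        d["voxel_size"] = list(self.voxel_size)
        d["contrast"] = {k: list(v) for k, v in self.contrast.items()}
        d["nihss_range"] = list(self.nihss_range)
        d["onset_to_image_range"] = list(self.onset_to_image_range)
        d["radius_scale_range"] = list(self.radius_scale_range)
        d["severity_range"] = list(self.severity_range)
        d["map_severity_range"] = list(self.map_severity_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomParams":
        d = dict(d)
        for key in ("shape", "voxel_size", "nihss_range", "onset_to_image_range", "radius_scale_range", "severity_range", "map_severity_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "contrast" in d:
            d["contrast"] = {k: tuple(v) for k, v in d["contrast"].items()}
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomParams":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomParams":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _case_rng(seed: int, case_index: int) -> np.random.Generator:
    """Per-case RNG stream; cohorts are order-independent."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(case_index,)))


def _noise_field(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    sd: float,
    smoothness_mm: float,
    voxel_size: tuple[float, float, float],
) -> np.ndarray:
    """Gaussian random field with unit-correct SD: white noise shaped by a
    Gaussian kernel (FWHM = smoothness_mm) and rescaled to the target SD."""
    white = rng.normal(0.0, 1.0, size=shape)
    if smoothness_mm <= 0:
        return sd * white
    sigma_vox = [smoothness_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v for v in voxel_size]
    field = ndimage.gaussian_filter(white, sigma_vox, truncate=4.0, mode="wrap")
    # wrap mode keeps the field stationary, so a global rescale is exact
    field /= field.std()
    return sd * field


def _radial_profile(r_mm: np.ndarray, core: float, pen: float, bg: float, r_core: float, r_pen: float, w: float) -> np.ndarray:
    """Smooth two-step radial profile: core plateau -> penumbra plateau ->
    background, with logistic transitions of width w (mm)."""
    s1 = expit((r_mm - r_core) / w)
    s2 = expit((r_mm - r_pen) / w)
    return core + (pen - core) * s1 + (bg - pen) * s2


def generate_case(params: PhantomParams, case_index: int) -> PatientCase:
    """Generate one phantom patient; pure function of (params.seed, case_index)."""
    params.validate()
    if case_index < 0:
        raise ValueError("case_index must be >= 0")
    rng = _case_rng(params.seed, case_index)
    nx, ny, nz = params.shape
    vx, vy, vz = params.voxel_size

    if params.occlusion_side == "random":
        occlusion_side = "left" if rng.random() < 0.5 else "right"
    else:
        occlusion_side = params.occlusion_side
    # lesion center: middle of the affected hemisphere along x, grid center
    # along y/z, plus jitter
    cx = nx * vx * (0.25 if occlusion_side == "left" else 0.75)
    center = np.array([cx, ny * vy / 2.0, nz * vz / 2.0])
    center += rng.uniform(-params.center_jitter_mm, params.center_jitter_mm, size=3)

    ii, jj, kk = np.meshgrid(
        (np.arange(nx) + 0.5) * vx,
        (np.arange(ny) + 0.5) * vy,
        (np.arange(nz) + 0.5) * vz,
        indexing="ij",
    )
    r = np.sqrt((ii - center[0]) ** 2 + (jj - center[1]) ** 2 + (kk - center[2]) ** 2)

    # per-case lesion size and perfusion-deficit severity
    radius_scale = rng.uniform(*params.radius_scale_range)
    severity = rng.uniform(*params.severity_range)
    r_core = params.core_radius_mm * radius_scale
    r_pen = params.penumbra_radius_mm * radius_scale

    volumes: dict[str, VolumeGrid] = {}
    for name in MODALITIES:
        core, pen, bg = params.contrast[name]
        if name in ("ncct", "cta"):
            # early hypodensity depth varies idiosyncratically: independent
            # of the perfusion severity, so these maps carry no information
            # about infarction beyond what the perfusion maps already carry
            map_sev = rng.uniform(*params.severity_range) * rng.uniform(*params.map_severity_range)
        else:
            map_sev = severity * rng.uniform(*params.map_severity_range)
        core = bg - (bg - core) * map_sev
        pen = bg - (bg - pen) * map_sev
        vol = _radial_profile(r, core, pen, bg, r_core, r_pen, params.transition_mm)
        sd = params.noise_sd.get(name, 0.0)
        if sd > 0:
            vol = vol + _noise_field(rng, vol.shape, sd, params.noise_smoothness_mm, params.voxel_size)
        volumes[name] = VolumeGrid(vol.astype(np.float32), params.voxel_size)

    # coverage: lesion ball plus margin, plus its mirror across the
    # mid-sagittal plane (perfusion maps cover both hemispheres, and the
    # contralateral ball provides the CBF_rel reference region)
    cov_radius = r_pen + params.coverage_margin_mm
    mirror_center = center.copy()
    mirror_center[0] = nx * vx - center[0]
    r_mirror = np.sqrt((ii - mirror_center[0]) ** 2 + (jj - mirror_center[1]) ** 2 + (kk - mirror_center[2]) ** 2)
    coverage = ((r <= cov_radius) | (r_mirror <= cov_radius)).astype(np.uint8)

    recan = int(rng.random() < params.recan_fraction)
    mtici = str(rng.choice(["2b", "2c", "3"])) if recan else str(rng.choice(["0", "1", "2a"]))

    lo, hi = params.nihss_range
    case = PatientCase(
        case_id=f"case_{case_index:04d}",
        volumes=volumes,
        coverage=coverage,
        lesion=np.zeros(params.shape, dtype=np.uint8),
        age=float(np.round(rng.normal(params.age_mean, params.age_sd), 1)),
        sex=int(rng.random() < params.sex_p_female),
        nihss=int(rng.integers(lo, hi + 1)),
        onset_to_image=float(np.round(rng.uniform(*params.onset_to_image_range), 1)),
        mtici=mtici,
        occlusion_side=occlusion_side,
        cohort=params.cohort_label,
    )

    # infarct labels: Bernoulli(logistic(eta)) on covered voxels, with eta
    # computed from the realized (noisy) maps so refits are consistent
    truth = params.ground_truth
    features: dict[str, np.ndarray | float] = {name: volumes[name].data for name in MODALITIES}
    features.update(age=case.age, sex=case.sex, nihss=case.nihss, ttoimg=case.onset_to_image)
    p = truth.probability(features, recan)
    lesion = (rng.random(size=params.shape) < p) & coverage.astype(bool)
    case.lesion = lesion.astype(np.uint8)
    compute_cbf_rel(case)
    return case


def generate_cohort(params: PhantomParams, n: int, out_dir: str | Path | None = None) -> list[PatientCase]:
    """Generate n phantom patients; optionally write NIfTI files + manifest."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    cohort = [generate_case(params, i) for i in range(n)]
    if out_dir is not None:
        write_cohort(cohort, out_dir, params=params)
    return cohort


def write_cohort(cohort: list[PatientCase], out_dir: str | Path, params: PhantomParams | None = None) -> Path:
    """Write per-case NIfTI volumes and the manifest CSV; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cohort:
        case_dir = out_dir / case.case_id
        case_dir.mkdir(exist_ok=True)
        row: dict[str, object] = {"case_id": case.case_id}
        for name in MODALITIES:
            rel = f"{case.case_id}/{name}.nii.gz"
            save_volume(case.volumes[name], out_dir / rel)
            row[f"path_{name}"] = rel
        for name, arr in (("lesion", case.lesion), ("coverage", case.coverage)):
            rel = f"{case.case_id}/{name}.nii.gz"
            save_volume(VolumeGrid(arr.astype(np.uint8), case.voxel_size), out_dir / rel)
            row[f"path_{name}"] = rel
        if case.exclusion is not None:
            rel = f"{case.case_id}/exclusion.nii.gz"
            save_volume(VolumeGrid(case.exclusion.astype(np.uint8), case.voxel_size), out_dir / rel)
            row["path_exclusion"] = rel
        else:
            row["path_exclusion"] = ""
        row.update(
            age=case.age,
            sex=case.sex,
            nihss=case.nihss,
            onset_to_image_min=case.onset_to_image,
            mtici=case.mtici,
            occlusion_side=case.occlusion_side,
            cohort=case.cohort,
        )
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    if params is not None:
        params.to_json(out_dir / "phantom_params.json")
    return manifest
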