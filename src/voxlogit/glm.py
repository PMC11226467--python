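"""Mass-univariate voxelwise logistic regression and dual risk-map prediction.

One independent logistic model is fitted per voxel over the patients whose
perfusion coverage includes that voxel. The linear predictor combines
smoothed imaging values at the voxel, scalar clinical covariates,
recanalization status, and recanalization-by-perfusion interaction terms.
Continuous design columns are standardized with training-cohort statistics
for IRLS conditioning; this leaves t-values, pseudo-R^2 and predicted
probabilities unchanged, and the standardization constants are stored so
predictions and coefficient back-transforms are exact.

A fitted model predicts, for any patient, two probability-of-infarction
maps: one with recanalization forced to successful and one forced to
unsuccessful — the patient's actual status is never used at prediction
time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .imaging import PatientCase, VolumeGrid, save_volume, load_volume

log = logging.getLogger(__name__)

#: The 14 predictors of the full model, in canonical order (used for
#: deterministic tie-breaking during elimination).
FULL_PREDICTORS: tuple[str, ...] = (
    "intercept",
    "ncct",
    "cta",
    "cbv",
    "cbf",
    "tmax",
    "age",
    "sex",
    "nihss",
    "ttoimg",
    "recan",
    "recan:cbv",
    "recan:cbf",
    "recan:tmax",
)

#: Predictors that the step-down elimination may never remove: the
#: parameters of the thresholding baseline (CBF, Tmax, recanalization)
#: plus the intercept.
PROTECTED_PREDICTORS: frozenset[str] = frozenset({"intercept", "cbf", "tmax", "recan"})

#: Columns that are left unstandardized (constant or binary indicators).
_UNSTANDARDIZED: frozenset[str] = frozenset({"intercept", "sex", "recan"})

_IMAGING = frozenset({"ncct", "cta", "cbv", "cbf", "tmax"})
_SCALAR = frozenset({"age", "sex", "nihss", "ttoimg"})

#: |beta| bound (standardized scale) beyond which a fit is flagged separated.
BETA_CLIP = 25.0


class EmptyMaskError(ValueError):
    """No voxel satisfies the GLM mask rule."""


@dataclass(frozen=True)
class PredictorSet:
    """An ordered predictor selection with its smoothing level."""

    names: tuple[str, ...]
    protected: frozenset[str] = PROTECTED_PREDICTORS
    fwhm: float = 9.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        unknown = set(self.names) - set(FULL_PREDICTORS)
        if unknown:
            raise ValueError(f"unknown predictors: {sorted(unknown)}")
        if "intercept" not in self.names:
            raise ValueError("intercept must always be present")
        for name in self.names:
            if ":" in name:
                left, right = name.split(":", 1)
                if left not in self.names or right not in self.names:
                    raise ValueError(f"interaction {name} requires main effects {left} and {right}")
        if not self.protected <= set(FULL_PREDICTORS):
            raise ValueError("protected set contains unknown predictors")

    def __len__(self) -> int:
        return len(self.names)

    def drop(self, name: str) -> "PredictorSet":
        if name not in self.names:
            raise KeyError(name)
        return PredictorSet(tuple(n for n in self.names if n != name), self.protected, self.fwhm)

    def with_fwhm(self, fwhm: float) -> "PredictorSet":
        return PredictorSet(self.names, self.protected, fwhm)

    @classmethod
    def full(cls, fwhm: float = 9.0) -> "PredictorSet":
        return cls(FULL_PREDICTORS, PROTECTED_PREDICTORS, fwhm)


def build_glm_mask(
    cohort: Sequence[PatientCase],
    n_params: int,
    min_lesion_frac: float = 0.05,
) -> np.ndarray:
    """Voxels eligible for fitting: covered by at least 10 * n_params
    patients and lesioned in at least min_lesion_frac of the covered
    patients. Per-case exclusion masks are subtracted from coverage.
    Returns a boolean 3D mask (possibly empty)."""
    if not cohort:
        raise ValueError("cohort must be nonempty")
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    shape = cohort[0].shape
    cov_count = np.zeros(shape, dtype=np.int32)
    les_count = np.zeros(shape, dtype=np.int32)
    for case in cohort:
        cov = case.effective_coverage()
        cov_count += cov
        les_count += case.lesion.astype(bool) & cov
    mask = (cov_count >= 10 * n_params) & (les_count >= min_lesion_frac * cov_count) & (cov_count > 0)
    return mask


# ---------------------------------------------------------------------------
# design assembly


def _raw_feature(case: PatientCase, name: str, smoothed: dict[str, np.ndarray]):
    """Per-case raw predictor value: a 3D array for imaging terms, a scalar
    otherwise."""
    if name == "intercept":
        return 1.0
    if name in _IMAGING:
        return smoothed[name]
    if name == "age":
        return float(case.age)
    if name == "sex":
        return float(case.sex)
    if name == "nihss":
        return float(case.nihss)
    if name == "ttoimg":
        return float(case.onset_to_image)
    if name == "recan":
        return float(case.recanalization)
    if ":" in name:
        left, right = name.split(":", 1)
        return _raw_feature(case, left, smoothed) * _raw_feature(case, right, smoothed)
    raise KeyError(name)


@dataclass
class _CohortDesign:
    """Raw per-voxel main-effect columns for one cohort at one smoothing
    level. Interaction columns are formed after standardization."""

    predictors: PredictorSet
    mask_idx: np.ndarray           # flat voxel indices, shape (M,)
    shape: tuple[int, int, int]
    coverage: np.ndarray           # (n, M) bool
    labels: np.ndarray             # (n, M) uint8
    raw_main: np.ndarray           # (n, M, p) float64; interaction slots unused
    case_ids: tuple[str, ...]


def _build_design(cohort: Sequence[PatientCase], predictors: PredictorSet, mask: np.ndarray) -> _CohortDesign:
    shape = cohort[0].shape
    mask_idx = np.flatnonzero(mask.ravel())
    n, M, p = len(cohort), mask_idx.size, len(predictors)
    coverage = np.zeros((n, M), dtype=bool)
    labels = np.zeros((n, M), dtype=np.uint8)
    raw_main = np.zeros((n, M, p), dtype=np.float64)
    for i, case in enumerate(cohort):
        smoothed = case.smoothed(predictors.fwhm)
        coverage[i] = case.effective_coverage().ravel()[mask_idx]
        labels[i] = case.lesion.ravel()[mask_idx]
        for j, name in enumerate(predictors.names):
            if ":" in name:
                continue
            val = _raw_feature(case, name, smoothed)
            if np.isscalar(val):
                raw_main[i, :, j] = val
            else:
                raw_main[i, :, j] = np.asarray(val, dtype=np.float64).ravel()[mask_idx]
    return _CohortDesign(predictors, mask_idx, shape, coverage, labels, raw_main, tuple(c.case_id for c in cohort))


def build_design_matrix(
    raw_main: np.ndarray,
    names: Sequence[str],
    mean: np.ndarray | None = None,
    sd: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardized design matrix from raw main-effect columns.

    ``raw_main`` holds one column per predictor name; interaction slots are
    ignored on input. Continuous main effects are standardized by training
    mean/SD (computed here unless supplied); binary/constant columns are
    untouched (mean 0, SD 1). Interaction columns are then formed as
    elementwise products of their transformed parent columns, which keeps
    the design well conditioned. Returns (X, mean, sd) with mean/sd aligned
    to the predictor order (interaction entries fixed at 0/1)."""
    X = np.array(raw_main, dtype=np.float64)
    p = X.shape[1]
    if mean is None:
        mean = np.zeros(p)
        sd = np.ones(p)
        for j, name in enumerate(names):
            if name in _UNSTANDARDIZED or ":" in name:
                continue
            mean[j] = X[:, j].mean()
            s = X[:, j].std(ddof=0)
            sd[j] = s if s > 0 else 1.0
    X = (X - mean) / sd
    idx = {name: j for j, name in enumerate(names)}
    for j, name in enumerate(names):
        if ":" in name:
            left, right = name.split(":", 1)
            X[:, j] = X[:, idx[left]] * X[:, idx[right]]
    return X, mean, sd


def raw_to_standardized_beta(
    beta_raw: dict[str, float],
    names: Sequence[str],
    mean: np.ndarray,
    sd: np.ndarray,
) -> np.ndarray:
    """Express raw-scale coefficients in the standardized design basis.

    Exact linear map implied by ``build_design_matrix``: a continuous main
    effect g maps to beta_g * sd_g (its centering shifts the intercept by
    beta_g * mean_g); an interaction a:g (binary a, continuous g) maps to
    beta_{a:g} * sd_g, shifting the coefficient of a by beta_{a:g} *
    mean_g. Supports per-voxel mean/sd arrays of shape (..., p)."""
    mean = np.asarray(mean, dtype=np.float64)
    sd = np.asarray(sd, dtype=np.float64)
    p = len(names)
    idx = {name: j for j, name in enumerate(names)}
    out = np.zeros(mean.shape[:-1] + (p,))
    for j, name in enumerate(names):
        b = beta_raw.get(name, 0.0)
        if ":" in name:
            left, right = name.split(":", 1)
            if left in _UNSTANDARDIZED or ":" in left:
                a, g = left, right
            else:
                a, g = right, left
            if g in _UNSTANDARDIZED:
                raise ValueError(f"interaction {name} must have one continuous parent")
            out[..., j] += b * sd[..., idx[g]]
            out[..., idx[a]] += b * mean[..., idx[g]]
        else:
            out[..., j] += b * sd[..., j]
            out[..., idx["intercept"]] += b * mean[..., j] if name != "intercept" else 0.0
    return out


def assemble_design(
    cohort: Sequence[PatientCase],
    predictors: PredictorSet,
    voxel: tuple[int, int, int],
    standardization: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Design matrix and outcome vector for one voxel.

    Rows are the patients whose coverage includes the voxel; columns follow
    ``predictors.names``. Continuous main effects are standardized by
    training mean/SD (computed here unless supplied); interactions are
    products of the transformed parents. Returns (X, y, (mean, sd))."""
    rows_X, rows_y = [], []
    for case in cohort:
        if not case.effective_coverage()[voxel]:
            continue
        smoothed = case.smoothed(predictors.fwhm)
        row = []
        for name in predictors.names:
            if ":" in name:
                row.append(0.0)
                continue
            val = _raw_feature(case, name, smoothed)
            row.append(float(val if np.isscalar(val) else val[voxel]))
        rows_X.append(row)
        rows_y.append(int(case.lesion[voxel]))
    X = np.asarray(rows_X, dtype=np.float64)
    y = np.asarray(rows_y, dtype=np.float64)
    if standardization is None:
        Xs, mean, sd = build_design_matrix(X, predictors.names)
    else:
        mean, sd = standardization
        Xs, mean, sd = build_design_matrix(X, predictors.names, mean, sd)
    return Xs, y, (mean, sd)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class VoxelFit:
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    dfe: int
    converged: bool
    deviance: float
    n_iter: int


def fit_voxel(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-8,
    beta_clip: float = BETA_CLIP,
) -> VoxelFit:
    """IRLS maximum-likelihood logistic fit with an optional tiny ridge
    stabilizer. Convergence is declared when the deviance changes by less
    than ``tol``; separation (a coefficient reaching ``beta_clip`` on the
    standardized scale) or an ill-conditioned information matrix clears the
    converged flag instead of raising."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    beta = np.zeros(p)
    ybar = min(max(y.mean(), 1e-6), 1 - 1e-6)
    if np.all(X[:, 0] == 1.0):
        beta[0] = np.log(ybar / (1 - ybar))
    eye = np.eye(p)

    def _deviance(b: np.ndarray) -> tuple[float, np.ndarray]:
        mu = expit(np.clip(X @ b, -35, 35))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        return -2.0 * float(y @ np.log(mu) + (1 - y) @ np.log1p(-mu)), mu

    dev, mu = _deviance(beta)
    converged = False
    clipped = False
    ill = False
    it = 0
    for it in range(1, max_iter + 1):
        w = np.maximum(mu * (1 - mu), 1e-10)
        score = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        if ridge > 0:
            H = H + ridge * eye
        try:
            delta = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            ill = True
            delta = np.linalg.solve(H + 1e-6 * eye, score)
        # Newton step with deviance-guarded halving
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            dev_new, mu_new = _deviance(cand)
            if dev_new <= dev + 1e-12:
                break
            step *= 0.5
        beta, dev_old = cand, dev
        dev, mu = dev_new, mu_new
        if np.any(np.abs(beta) > beta_clip):
            # separation: the likelihood keeps improving as |beta| grows
            beta = np.clip(beta, -beta_clip, beta_clip)
            dev, mu = _deviance(beta)
            clipped = True
            break
        if abs(dev_old - dev) < tol:
            converged = True
            break
    # observed information at the final estimate
    w = np.maximum(mu * (1 - mu), 1e-10)
    H = (X * w[:, None]).T @ X
    if ridge > 0:
        H = H + ridge * eye
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.inv(H + 1e-6 * eye)
        ill = True
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    ok = converged and not clipped and not ill
    return VoxelFit(beta=beta, se=se, t=t, dfe=n - p, converged=ok, deviance=dev, n_iter=it)


def _fit_voxels_batched(
    X: np.ndarray,
    y: np.ndarray,
    row_mask: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-8,
    beta_clip: float = BETA_CLIP,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS over many voxels at once.

    X: (M, n, p) standardized designs with uncovered rows zeroed;
    y: (M, n); row_mask: (M, n) marking covered rows. Semantics match
    fit_voxel (deviance-guarded steps, separation clip + flag); a property
    test pins the two implementations against each other.
    Returns (beta, se, converged, deviance)."""
    M, n, p = X.shape
    y = np.asarray(y, dtype=np.float64)
    w_mask = row_mask.astype(np.float64)
    n_rows = w_mask.sum(axis=1)
    beta = np.zeros((M, p))
    has_icpt = np.all(X[:, :, 0] * w_mask == w_mask, axis=1)  # intercept column of ones
    ybar = np.clip((y * w_mask).sum(axis=1) / np.maximum(n_rows, 1.0), 1e-6, 1 - 1e-6)
    beta[has_icpt, 0] = np.log(ybar[has_icpt] / (1 - ybar[has_icpt]))
    eye = np.eye(p)

    def _dev_of(Xa, ya, wa, b) -> np.ndarray:
        eta = np.clip(np.matmul(Xa, b[..., None])[..., 0], -35, 35)
        mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        ll = ya * np.log(mu) + (1 - ya) * np.log1p(-mu)
        return -2.0 * (ll * wa).sum(axis=1)

    dev = _dev_of(X, y, w_mask, beta)
    converged = np.zeros(M, dtype=bool)
    clipped = np.zeros(M, dtype=bool)
    ill = np.zeros(M, dtype=bool)
    active = np.arange(M)
    Xa, ya, wa = X, y, w_mask
    beta_a, dev_a = beta.copy(), dev.copy()
    for _ in range(max_iter):
        if active.size == 0:
            break
        eta = np.clip(np.matmul(Xa, beta_a[..., None])[..., 0], -35, 35)
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-10) * wa
        score = np.matmul(Xa.transpose(0, 2, 1), ((ya - mu) * wa)[..., None])[..., 0]
        H = np.matmul(Xa.transpose(0, 2, 1), Xa * w[..., None])
        if ridge > 0:
            H = H + ridge * eye
        try:
            delta = np.linalg.solve(H, score[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.empty_like(score)
            for k in range(active.size):
                try:
                    delta[k] = np.linalg.solve(H[k], score[k])
                except np.linalg.LinAlgError:
                    delta[k] = np.linalg.solve(H[k] + 1e-6 * eye, score[k])
                    ill[active[k]] = True
        # deviance-guarded step with vectorized halving
        step = np.ones(active.size)
        cand = beta_a + delta
        dev_new = _dev_of(Xa, ya, wa, cand)
        for _h in range(30):
            worse = dev_new > dev_a + 1e-12
            if not worse.any():
                break
            step[worse] *= 0.5
            cand[worse] = beta_a[worse] + step[worse, None] * delta[worse]
            dev_new[worse] = _dev_of(Xa[worse], ya[worse], wa[worse], cand[worse])
        dev_old_a = dev_a
        beta_a, dev_a = cand, dev_new

        over = np.abs(beta_a).max(axis=1) > beta_clip
        if over.any():
            beta_a[over] = np.clip(beta_a[over], -beta_clip, beta_clip)
            dev_a[over] = _dev_of(Xa[over], ya[over], wa[over], beta_a[over])
            clipped[active[over]] = True
        done = np.abs(dev_old_a - dev_a) < tol
        beta[active] = beta_a
        dev[active] = dev_a
        drop = done | over
        converged[active[done & ~over]] = True
        active = active[~drop]
        if drop.any():
            keepm = ~drop
            Xa, ya, wa = Xa[keepm], ya[keepm], wa[keepm]
            beta_a, dev_a = beta_a[keepm], dev_a[keepm]

    # observed information at the final estimates
    eta = np.clip(np.matmul(X, beta[..., None])[..., 0], -35, 35)
    mu = expit(eta)
    w = np.maximum(mu * (1 - mu), 1e-10) * w_mask
    H = np.matmul(X.transpose(0, 2, 1), X * w[..., None])
    if ridge > 0:
        H = H + ridge * eye
    se = np.empty((M, p))
    try:
        cov = np.linalg.inv(H)
        se[:] = np.sqrt(np.maximum(np.einsum("mpp->mp", cov), 0.0))
    except np.linalg.LinAlgError:
        for k in range(M):
            try:
                c = np.linalg.inv(H[k])
            except np.linalg.LinAlgError:
                c = np.linalg.inv(H[k] + 1e-6 * eye)
                ill[k] = True
            se[k] = np.sqrt(np.maximum(np.diag(c), 0.0))
    ok = converged & ~clipped & ~ill
    return beta, se, ok, dev


def pseudo_r2(t, dfe):
    """Partial variance-explained transform of a t-statistic:
    t^2 / (t^2 + dfe). Monotone in |t| and bounded in [0, 1]."""
    t = np.asarray(t, dtype=np.float64)
    dfe = np.asarray(dfe, dtype=np.float64)
    if np.any(dfe <= 0):
        raise ValueError("residual degrees of freedom must be positive")
    t2 = t * t
    return t2 / (t2 + dfe)


# ---------------------------------------------------------------------------
# voxelwise map fitting


@dataclass
class VoxelModelMap:
    """Per-voxel fit results for one predictor set on one training cohort."""

    predictors: PredictorSet
    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    mask_idx: np.ndarray          # (M,) flat indices into the grid
    beta: np.ndarray              # (M, p)
    se: np.ndarray                # (M, p)
    t: np.ndarray                 # (M, p)
    r2: np.ndarray                # (M, p) pseudo-R^2
    dfe: np.ndarray               # (M,)
    converged: np.ndarray         # (M,) bool
    col_mean: np.ndarray          # (M, p) standardization means
    col_sd: np.ndarray            # (M, p) standardization SDs
    training_case_ids: tuple[str, ...] = ()
    fold_id: int | None = None

    @property
    def glm_mask(self) -> np.ndarray:
        mask = np.zeros(int(np.prod(self.shape)), dtype=bool)
        mask[self.mask_idx] = True
        return mask.reshape(self.shape)

    def field_volume(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        out = np.full(int(np.prod(self.shape)), fill, dtype=np.float64)
        out[self.mask_idx] = values
        return out.reshape(self.shape)

    def mean_pseudo_r2(self) -> dict[str, float]:
        """Mean pseudo-R^2 per predictor over all mask voxels."""
        return {name: float(self.r2[:, j].mean()) for j, name in enumerate(self.predictors.names)}

    # -- serialization -----------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        vs = self.voxel_size
        for j, name in enumerate(self.predictors.names):
            tag = name.replace(":", "_x_")
            for stem, arr in (("beta", self.beta), ("t", self.t), ("r2", self.r2)):
                save_volume(VolumeGrid(self.field_volume(arr[:, j]).astype(np.float32), vs), out_dir / f"{stem}_{tag}.nii.gz")
        save_volume(VolumeGrid(self.glm_mask.astype(np.uint8), vs), out_dir / "glm_mask.nii.gz")
        save_volume(VolumeGrid(self.field_volume(self.dfe, fill=0).astype(np.float32), vs), out_dir / "dfe.nii.gz")
        save_volume(VolumeGrid(self.field_volume(self.converged, fill=0).astype(np.uint8), vs), out_dir / "converged.nii.gz")
        sidecar = {
            "predictors": list(self.predictors.names),
            "protected": sorted(self.predictors.protected),
            "fwhm": self.predictors.fwhm,
            "shape": list(self.shape),
            "voxel_size": list(vs),
            "mask_idx": self.mask_idx.tolist(),
            "col_mean": self.col_mean.tolist(),
            "col_sd": self.col_sd.tolist(),
            "se": self.se.tolist(),
            "training_case_ids": list(self.training_case_ids),
            "fold_id": self.fold_id,
        }
        (out_dir / "model.json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, out_dir: str | Path) -> "VoxelModelMap":
        out_dir = Path(out_dir)
        meta = json.loads((out_dir / "model.json").read_text())
        predictors = PredictorSet(tuple(meta["predictors"]), frozenset(meta["protected"]), float(meta["fwhm"]))
        mask_idx = np.asarray(meta["mask_idx"], dtype=np.int64)
        shape = tuple(meta["shape"])
        M, p = mask_idx.size, len(predictors)
        beta = np.empty((M, p))
        t = np.empty((M, p))
        r2 = np.empty((M, p))
        for j, name in enumerate(predictors.names):
            tag = name.replace(":", "_x_")
            beta[:, j] = load_volume(out_dir / f"beta_{tag}.nii.gz").data.ravel()[mask_idx]
            t[:, j] = load_volume(out_dir / f"t_{tag}.nii.gz").data.ravel()[mask_idx]
            r2[:, j] = load_volume(out_dir / f"r2_{tag}.nii.gz").data.ravel()[mask_idx]
        dfe = load_volume(out_dir / "dfe.nii.gz").data.ravel()[mask_idx]
        converged = load_volume(out_dir / "converged.nii.gz").data.ravel()[mask_idx].astype(bool)
        return cls(
            predictors=predictors,
            shape=shape,
            voxel_size=tuple(meta["voxel_size"]),
            mask_idx=mask_idx,
            beta=beta,
            se=np.asarray(meta["se"], dtype=np.float64),
            t=t,
            r2=r2,
            dfe=np.asarray(dfe, dtype=np.float64),
            converged=converged,
            col_mean=np.asarray(meta["col_mean"], dtype=np.float64),
            col_sd=np.asarray(meta["col_sd"], dtype=np.float64),
            training_case_ids=tuple(meta["training_case_ids"]),
            fold_id=meta["fold_id"],
        )


def fit_voxelwise(
    cohort: Sequence[PatientCase],
    predictors: PredictorSet,
    glm_mask: np.ndarray | None = None,
    min_lesion_frac: float = 0.05,
    ridge: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-8,
    fold_id: int | None = None,
) -> VoxelModelMap:
    """Fit the logistic model independently at every GLM-mask voxel."""
    if glm_mask is None:
        glm_mask = build_glm_mask(cohort, len(predictors), min_lesion_frac)
    if not glm_mask.any():
        raise EmptyMaskError("GLM mask is empty")
    cd = _build_design(cohort, predictors, glm_mask)
    n, M, p = cd.raw_main.shape
    names = predictors.names

    # vectorized per-voxel standardization over covered rows
    cov = cd.coverage.astype(np.float64)            # (n, M)
    nrows = cov.sum(axis=0)                         # (M,)
    raw = cd.raw_main                               # (n, M, p)
    mean = np.einsum("nm,nmp->mp", cov, raw) / nrows[:, None]
    var = np.einsum("nm,nmp->mp", cov, (raw - mean) ** 2) / nrows[:, None]
    sd = np.sqrt(np.maximum(var, 0.0))
    keep = np.array([(name in _UNSTANDARDIZED) or (":" in name) for name in names])
    mean[:, keep] = 0.0
    sd[:, keep] = 1.0
    sd[sd == 0] = 1.0
    Xs = (raw - mean) / sd
    idx = {name: j for j, name in enumerate(names)}
    for j, name in enumerate(names):
        if ":" in name:
            left, right = name.split(":", 1)
            Xs[:, :, j] = Xs[:, :, idx[left]] * Xs[:, :, idx[right]]
    Xs = np.ascontiguousarray(np.swapaxes(Xs * cov[:, :, None], 0, 1))   # (M, n, p)
    yb = cd.labels.T.astype(np.float64)             # (M, n)
    rm = cd.coverage.T                              # (M, n)

    beta, se, conv, _ = _fit_voxels_batched(Xs, yb, rm, ridge=ridge, max_iter=max_iter, tol=tol)
    dfe = nrows - p
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    r2 = pseudo_r2(t, dfe[:, None])
    n_bad = int(np.count_nonzero(~conv))
    if n_bad:
        log.info("fit_voxelwise: %d / %d voxels flagged non-converged", n_bad, M)
    return VoxelModelMap(
        predictors=predictors,
        shape=cd.shape,
        voxel_size=cohort[0].voxel_size,
        mask_idx=cd.mask_idx,
        beta=beta,
        se=se,
        t=t,
        r2=r2,
        dfe=dfe,
        converged=conv,
        col_mean=mean,
        col_sd=sd,
        training_case_ids=cd.case_ids,
        fold_id=fold_id,
    )


# ---------------------------------------------------------------------------
# prediction


@dataclass
class RiskMapPair:
    """Two infarction-probability volumes: recanalization assumed successful
    vs unsuccessful; NaN outside the support mask."""

    p_success: np.ndarray
    p_failure: np.ndarray
    support: np.ndarray
    voxel_size: tuple[float, float, float]

    def scenario(self, recanalization: bool) -> np.ndarray:
        return self.p_success if recanalization else self.p_failure


def predict_risk_maps(model: VoxelModelMap, case: PatientCase) -> RiskMapPair:
    """Evaluate the fitted model on one case under both recanalization
    scenarios; the case's actual status is not consulted."""
    for mod in ("ncct", "cta", "cbv", "cbf", "tmax"):
        if mod not in case.volumes:
            raise KeyError(f"case {case.case_id}: missing modality {mod}")
    support_flat = case.effective_coverage().ravel()[model.mask_idx]
    sel = np.flatnonzero(support_flat)
    smoothed = case.smoothed(model.predictors.fwhm)
    names = model.predictors.names
    p = len(names)
    idx = {name: j for j, name in enumerate(names)}
    voxel_idx = model.mask_idx[sel]
    out = {}
    for recan in (0, 1):
        Xs = np.empty((sel.size, p))
        for j, name in enumerate(names):
            if ":" in name:
                continue
            if name == "intercept":
                col = np.ones(sel.size)
            elif name == "recan":
                col = np.full(sel.size, float(recan))
            elif name in _IMAGING:
                col = np.asarray(smoothed[name], dtype=np.float64).ravel()[voxel_idx]
            else:
                col = np.full(sel.size, float(_raw_feature(case, name, smoothed)))
            Xs[:, j] = (col - model.col_mean[sel, j]) / model.col_sd[sel, j]
        for j, name in enumerate(names):
            if ":" in name:
                left, right = name.split(":", 1)
                Xs[:, j] = Xs[:, idx[left]] * Xs[:, idx[right]]
        eta = np.einsum("ij,ij->i", Xs, model.beta[sel])
        probs = expit(eta)
        vol = np.full(int(np.prod(model.shape)), np.nan)
        vol[voxel_idx] = probs
        out[recan] = vol.reshape(model.shape)
    support = np.zeros(int(np.prod(model.shape)), dtype=bool)
    support[voxel_idx] = True
    return RiskMapPair(
        p_success=out[1],
        p_failure=out[0],
        support=support.reshape(model.shape),
        voxel_size=model.voxel_size,
    )
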