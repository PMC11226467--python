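"""Single-parameter thresholding baseline.

The conventional clinical rules — ischemic core where relative CBF falls
below ~30% of the unaffected hemisphere, hypoperfused tissue where Tmax
exceeds ~6 s — define the shape of this predictor, but the actual
thresholds are calibrated by cross-validation on the training data,
because optimal values depend on smoothing and acquisition. The core rule
(applied when recanalization is assumed successful) is trained on patients
with actual successful recanalization, whose final lesion approximates the
core; the Tmax rule (unsuccessful scenario) is trained on patients without
recanalization. Both rules use strict inequalities.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .glm import build_glm_mask
from .imaging import PatientCase, VolumeGrid, voxel_volume_ml
from .metrics import eval_mask
from .selection import FoldAssignment

log = logging.getLogger(__name__)

#: Literature defaults, provided as configuration fallbacks only.
LITERATURE_CBF_THRESHOLD = 30.0   # % of unaffected hemisphere
LITERATURE_TMAX_THRESHOLD = 6.0   # seconds


@dataclass
class ThresholdModel:
    """Calibrated thresholding predictor: core where cbf_rel < cbf_threshold
    (successful-recanalization scenario), lesion where tmax > tmax_threshold
    (unsuccessful scenario), on maps smoothed at ``fwhm`` mm."""

    cbf_threshold: float = LITERATURE_CBF_THRESHOLD
    tmax_threshold: float = LITERATURE_TMAX_THRESHOLD
    fwhm: float = 5.0

    def __post_init__(self) -> None:
        if self.cbf_threshold <= 0 or self.tmax_threshold <= 0:
            raise ValueError("thresholds must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(vars(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdModel":
        return cls(**json.loads(Path(path).read_text()))


def predict_threshold(
    case: PatientCase,
    model: ThresholdModel,
    scenario: str,
    support: np.ndarray | None = None,
) -> np.ndarray:
    """Binary lesion prediction under a recanalization scenario.

    'success' -> cbf_rel < cbf_threshold; 'failure' -> tmax >
    tmax_threshold (both strict). Restricted to the given support mask
    (typically coverage AND glm_mask minus exclusions), else to the case's
    effective coverage."""
    if scenario not in ("success", "failure"):
        raise ValueError(f"scenario must be 'success' or 'failure', got {scenario!r}")
    smoothed = case.smoothed(model.fwhm)
    if "cbf_rel" not in smoothed:
        raise KeyError("cbf_rel not available; run compute_cbf_rel first")
    if scenario == "success":
        pred = smoothed["cbf_rel"] < model.cbf_threshold
    else:
        pred = smoothed["tmax"] > model.tmax_threshold
    sup = case.effective_coverage() if support is None else np.asarray(support).astype(bool)
    return pred & sup


def _scan_threshold(
    values: Sequence[np.ndarray],
    truth_counts: np.ndarray,
    voxel_vol: float,
    rule: str,
) -> tuple[float, float]:
    """Exhaustive scan over observed map values minimizing the mean
    |predicted - truth| volume. rule 'less': mask = value < theta;
    rule 'greater': mask = value > theta. Ties resolve to the smallest
    theta."""
    flat = [np.sort(np.asarray(v, dtype=np.float64).ravel()) for v in values]
    candidates = np.unique(np.concatenate(flat))
    total = np.zeros(candidates.size)
    for vs, tc in zip(flat, truth_counts):
        if rule == "less":
            counts = np.searchsorted(vs, candidates, side="left")
        else:
            counts = vs.size - np.searchsorted(vs, candidates, side="right")
        total += np.abs(counts - tc)
    objective = total * voxel_vol / len(flat)
    best = int(np.argmin(objective))
    return float(candidates[best]), float(objective[best])


def _fit_thresholds(
    cohort: Sequence[PatientCase],
    glm_mask: np.ndarray,
    fwhm: float,
    voxel_vol: float,
) -> ThresholdModel:
    """Calibrate both thresholds on one training set at one smoothing level,
    stratified by actual recanalization status."""
    strata = {"success": [], "failure": []}
    for case in cohort:
        strata["success" if case.recanalization else "failure"].append(case)
    for name, cases in strata.items():
        if not cases:
            raise ValueError(f"no patients in the {name!r} recanalization stratum")
    params = {}
    for name, map_name, rule in (
        ("success", "cbf_rel", "less"),
        ("failure", "tmax", "greater"),
    ):
        vals, tcs = [], []
        for case in strata[name]:
            support = eval_mask(case, glm_mask)
            vals.append(case.smoothed(fwhm)[map_name][support])
            tcs.append(int((case.lesion.astype(bool) & support).sum()))
        theta, obj = _scan_threshold(vals, np.asarray(tcs), voxel_vol, rule)
        params[name] = theta
        log.info("threshold calibration (%s, fwhm %.0f): theta=%.3f, objective %.2f ml", map_name, fwhm, theta, obj)
    return ThresholdModel(cbf_threshold=params["success"], tmax_threshold=params["failure"], fwhm=fwhm)


def calibrate_thresholds(
    cohort: Sequence[PatientCase],
    folds: FoldAssignment,
    fwhm_list: Sequence[float] = (0.0, 5.0, 9.0, 13.0),
    glm_mask: np.ndarray | None = None,
) -> tuple[ThresholdModel, dict[float, float]]:
    """Cross-validated threshold calibration with a smoothing sweep.

    Per smoothing level, fold-training thresholds are scored on the
    held-out patients (actual-scenario rule, mean |dV| in ml); the level
    with the lowest cross-validated objective wins and the final
    thresholds are refitted on the whole cohort at that level. Returns the
    model and the per-fwhm CV objective table."""
    vv = voxel_volume_ml(VolumeGrid(np.zeros((1, 1, 1)), cohort[0].voxel_size))
    if glm_mask is None:
        glm_mask = build_glm_mask(cohort, n_params=2)
    cv_objective: dict[float, float] = {}
    for fwhm in (float(f) for f in fwhm_list):
        diffs = []
        for f in range(folds.k):
            train = [cohort[i] for i in folds.train_indices(f)]
            test = [cohort[i] for i in folds.test_indices(f)]
            model = _fit_thresholds(train, glm_mask, fwhm, vv)
            for case in test:
                support = eval_mask(case, glm_mask)
                truth = case.lesion.astype(bool) & support
                scenario = "success" if case.recanalization else "failure"
                pred = predict_threshold(case, model, scenario, support=support)
                diffs.append(abs(int(pred.sum()) - int(truth.sum())) * vv)
        cv_objective[fwhm] = float(np.mean(diffs))
    best_fwhm = min(cv_objective, key=lambda k: (cv_objective[k], k))
    final = _fit_thresholds(cohort, glm_mask, best_fwhm, vv)
    log.info(
        "thresholding baseline: fwhm %.0f mm, cbf_rel < %.2f%%, tmax > %.2f s",
        best_fwhm,
        final.cbf_threshold,
        final.tmax_threshold,
    )
    return final, cv_objective
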