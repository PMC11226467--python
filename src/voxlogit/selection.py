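"""Cross-validated step-down predictor elimination and cutoff calibration.

Starting from the full 14-predictor model, the predictor with the lowest
mean pseudo-R^2 across mask voxels and folds (computed at the intermediate
smoothing level, FWHM = 9 mm) is eliminated, subject to two constraints:
the protected set (intercept, CBF, Tmax, recanalization — the parameters
of the thresholding baseline) may never leave, and an interaction must
leave before either of its main effects. At every model size the current
model is cross-validated at every smoothing level in the sweep list, and
the final (model, FWHM) pair is the one with the lowest cross-validated
mean absolute volume difference.

The binarization cutoff for a risk map is calibrated by exhaustive scan
over the observed in-sample risk values, minimizing the mean absolute
volume difference between binarized prediction and ground-truth lesion.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .glm import (
    FULL_PREDICTORS,
    PredictorSet,
    VoxelModelMap,
    fit_voxelwise,
    predict_risk_maps,
)
from .imaging import PatientCase, VolumeGrid, voxel_volume_ml
from .metrics import abs_volume_difference, dice, eval_mask, roc_auc

log = logging.getLogger(__name__)

DEFAULT_FWHM_LIST: tuple[float, ...] = (0.0, 5.0, 9.0, 13.0)
DEFAULT_SEED = 20160101


@dataclass(frozen=True)
class FoldAssignment:
    """A balanced random partition of a cohort into k folds."""

    k: int
    fold_index: tuple[int, ...]
    seed: int

    def train_indices(self, fold: int) -> list[int]:
        return [i for i, f in enumerate(self.fold_index) if f != fold]

    def test_indices(self, fold: int) -> list[int]:
        return [i for i, f in enumerate(self.fold_index) if f == fold]


def make_folds(n_or_cohort, k: int, seed: int = DEFAULT_SEED) -> FoldAssignment:
    """Balanced random folds (sizes differ by at most 1), deterministic
    given the seed."""
    n = n_or_cohort if isinstance(n_or_cohort, int) else len(n_or_cohort)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"cannot split {n} cases into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_index = np.empty(n, dtype=int)
    for pos, case in enumerate(order):
        fold_index[case] = pos % k
    return FoldAssignment(k=k, fold_index=tuple(int(f) for f in fold_index), seed=seed)


def eliminate_next(mean_r2: dict[str, float], current: PredictorSet) -> str | None:
    """The eligible predictor with the lowest mean pseudo-R^2, or None when
    no predictor may be eliminated (termination of the step-down).

    Eligible: not protected, not the intercept, and not a main effect with
    a dependent interaction still in the model. Ties break by the canonical
    predictor order (first listed wins)."""
    eligible = []
    for name in current.names:
        if name == "intercept" or name in current.protected:
            continue
        has_dependent = any(
            ":" in other and name in other.split(":") for other in current.names if other != name
        )
        if has_dependent:
            continue
        eligible.append(name)
    if not eligible:
        return None
    choice = min(eligible, key=lambda nm: (mean_r2[nm], FULL_PREDICTORS.index(nm)))
    tied = [nm for nm in eligible if mean_r2[nm] == mean_r2[choice]]
    if len(tied) > 1:
        log.info("elimination tie among %s broken by canonical order -> %s", tied, choice)
    return choice


# ---------------------------------------------------------------------------
# cutoff calibration


@dataclass
class Calibration:
    """A trained binarization cutoff (or baseline parameter threshold)."""

    kind: str                 # logistic-cutoff | cbf-threshold | tmax-threshold
    value: float
    objective_ml: float
    fingerprint: str = ""

    def __post_init__(self) -> None:
        if self.kind == "logistic-cutoff" and not (0.0 <= self.value <= 1.0):
            raise ValueError(f"logistic cutoff must lie in [0, 1], got {self.value}")
        if self.kind in ("cbf-threshold", "tmax-threshold") and self.value <= 0:
            raise ValueError(f"{self.kind} must be positive, got {self.value}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(vars(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Calibration":
        return cls(**json.loads(Path(path).read_text()))


def _fingerprint(case_ids: Sequence[str]) -> str:
    return hashlib.sha256("|".join(sorted(case_ids)).encode()).hexdigest()[:16]


def calibrate_cutoff(
    risks: Sequence[np.ndarray],
    truths: Sequence[np.ndarray],
    voxel_vol: float,
    fingerprint: str = "",
) -> Calibration:
    """Cutoff c* minimizing the mean over patients of
    |vol(risk > c) - vol(truth)|, searched over the sorted unique observed
    risk values plus {0, 1}; ties resolve to the smallest cutoff."""
    if len(risks) == 0 or len(risks) != len(truths):
        raise ValueError("need one risk array and one truth array per patient")
    flat = [np.asarray(r, dtype=np.float64).ravel() for r in risks]
    truth_counts = np.array([int(np.asarray(t).astype(bool).sum()) for t in truths])
    candidates = np.unique(np.concatenate([np.concatenate(flat), [0.0, 1.0]]))
    total = np.zeros(candidates.size)
    for r, tc in zip(flat, truth_counts):
        rs = np.sort(r)
        # count of voxels with risk strictly greater than each candidate
        counts = rs.size - np.searchsorted(rs, candidates, side="right")
        total += np.abs(counts - tc)
    objective = total * voxel_vol / len(flat)
    best = int(np.argmin(objective))  # first minimum -> smallest candidate
    return Calibration(
        kind="logistic-cutoff",
        value=float(candidates[best]),
        objective_ml=float(objective[best]),
        fingerprint=fingerprint,
    )


# ---------------------------------------------------------------------------
# step-down


@dataclass
class StepRecord:
    predictors: tuple[str, ...]
    eliminated: str | None
    mean_r2: dict[str, float]
    #: fwhm -> {"vol_diff", "auc", "dice", "fold_cutoffs", "full_cutoff"}
    metrics: dict[float, dict]


@dataclass
class SelectionTrace:
    steps: list[StepRecord]
    folds: FoldAssignment
    final_predictors: PredictorSet = None
    final_fwhm: float = None
    final_cutoff: Calibration | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, rec in enumerate(self.steps):
            for fwhm, m in rec.metrics.items():
                rows.append(
                    {
                        "step": s,
                        "n_predictors": len(rec.predictors),
                        "eliminated": rec.eliminated or "",
                        "predictors": "+".join(rec.predictors),
                        "fwhm": fwhm,
                        "mean_abs_vol_diff_ml": m["vol_diff"],
                        "mean_auc": m["auc"],
                        "mean_dice": m["dice"],
                        "mean_fold_cutoff": float(np.mean(m["fold_cutoffs"])),
                        "full_cutoff": m.get("full_cutoff", ""),
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def final_to_json(self, path: str | Path) -> None:
        d = {
            "predictors": list(self.final_predictors.names),
            "fwhm": self.final_fwhm,
            "cutoff": vars(self.final_cutoff) if self.final_cutoff else None,
        }
        Path(path).write_text(json.dumps(d, indent=2))


def _cv_metrics_at_fwhm(
    cohort: Sequence[PatientCase],
    folds: FoldAssignment,
    pset: PredictorSet,
    fold_models: list[VoxelModelMap],
    voxel_vol: float,
) -> dict:
    """Out-of-fold |dV|/AUC/Dice at one smoothing level, binarizing with the
    fold-training in-sample cutoff; predictions use each patient's actual
    recanalization scenario."""
    per_patient = {"vol_diff": [], "auc": [], "dice": []}
    fold_cutoffs = []
    for f, model in enumerate(fold_models):
        train = [cohort[i] for i in folds.train_indices(f)]
        test = [cohort[i] for i in folds.test_indices(f)]
        glm_mask = model.glm_mask
        risks, truths = [], []
        for case in train:
            support = eval_mask(case, glm_mask)
            pair = predict_risk_maps(model, case)
            risks.append(pair.scenario(case.recanalization)[support])
            truths.append(case.lesion.astype(bool)[support])
        calib = calibrate_cutoff(risks, truths, voxel_vol, fingerprint=_fingerprint(model.training_case_ids))
        fold_cutoffs.append(calib.value)
        for case in test:
            if case.case_id in model.training_case_ids:
                raise RuntimeError("out-of-fold prediction would reuse a training patient")
            support = eval_mask(case, glm_mask)
            truth = case.lesion.astype(bool) & support
            pair = predict_risk_maps(model, case)
            risk = pair.scenario(case.recanalization)
            risk_filled = np.where(support, np.nan_to_num(risk, nan=0.0), 0.0)
            pred = support & (risk_filled > calib.value)
            per_patient["vol_diff"].append(abs_volume_difference(pred, truth, voxel_vol))
            per_patient["auc"].append(roc_auc(risk_filled, truth, support))
            per_patient["dice"].append(dice(pred, truth))
    return {
        "vol_diff": float(np.nanmean(per_patient["vol_diff"])),
        "auc": float(np.nanmean(per_patient["auc"])),
        "dice": float(np.nanmean(per_patient["dice"])),
        "fold_cutoffs": fold_cutoffs,
    }


def _full_training_cutoff(
    cohort: Sequence[PatientCase],
    pset: PredictorSet,
    voxel_vol: float,
    min_lesion_frac: float,
    ridge: float,
) -> tuple[Calibration, VoxelModelMap]:
    model = fit_voxelwise(cohort, pset, min_lesion_frac=min_lesion_frac, ridge=ridge)
    glm_mask = model.glm_mask
    risks, truths = [], []
    for case in cohort:
        support = eval_mask(case, glm_mask)
        pair = predict_risk_maps(model, case)
        risks.append(pair.scenario(case.recanalization)[support])
        truths.append(case.lesion.astype(bool)[support])
    calib = calibrate_cutoff(risks, truths, voxel_vol, fingerprint=_fingerprint(model.training_case_ids))
    return calib, model


def run_step_down(
    cohort: Sequence[PatientCase],
    folds: FoldAssignment,
    fwhm_list: Sequence[float] = DEFAULT_FWHM_LIST,
    elimination_fwhm: float = 9.0,
    start: PredictorSet | None = None,
    min_lesion_frac: float = 0.05,
    ridge: float = 0.0,
    record_full_cutoffs: bool = False,
) -> SelectionTrace:
    """Step-down elimination with a smoothing-level sweep.

    Elimination pseudo-R^2 is the unweighted mean over mask voxels and
    folds at ``elimination_fwhm``. Cross-validated metrics are recorded for
    every (model, fwhm); the final choice minimizes the mean absolute
    volume difference. The whole-training in-sample cutoff is always
    computed for the final choice; set ``record_full_cutoffs`` to record it
    for every (model, fwhm) as well."""
    fwhm_list = [float(f) for f in fwhm_list]
    vv = voxel_volume_ml(VolumeGrid(np.zeros((1, 1, 1)), cohort[0].voxel_size))
    current = start if start is not None else PredictorSet.full(fwhm=elimination_fwhm)
    steps: list[StepRecord] = []
    eliminated: str | None = None
    while True:
        # one voxelwise fit per fold at the elimination smoothing level
        elim_pset = current.with_fwhm(elimination_fwhm)
        elim_models = [
            fit_voxelwise(
                [cohort[i] for i in folds.train_indices(f)],
                elim_pset,
                min_lesion_frac=min_lesion_frac,
                ridge=ridge,
                fold_id=f,
            )
            for f in range(folds.k)
        ]
        mean_r2 = {
            name: float(np.mean([m.mean_pseudo_r2()[name] for m in elim_models]))
            for name in current.names
        }
        metrics: dict[float, dict] = {}
        for fwhm in fwhm_list:
            pset = current.with_fwhm(fwhm)
            if fwhm == elimination_fwhm:
                fold_models = elim_models
            else:
                fold_models = [
                    fit_voxelwise(
                        [cohort[i] for i in folds.train_indices(f)],
                        pset,
                        min_lesion_frac=min_lesion_frac,
                        ridge=ridge,
                        fold_id=f,
                    )
                    for f in range(folds.k)
                ]
            m = _cv_metrics_at_fwhm(cohort, folds, pset, fold_models, vv)
            if record_full_cutoffs:
                calib, _ = _full_training_cutoff(cohort, pset, vv, min_lesion_frac, ridge)
                m["full_cutoff"] = calib.value
            metrics[fwhm] = m
        steps.append(StepRecord(current.names, eliminated, mean_r2, metrics))
        log.info(
            "step-down: %d predictors, eliminated=%s, best |dV| %.2f ml",
            len(current),
            eliminated,
            min(m["vol_diff"] for m in metrics.values()),
        )
        nxt = eliminate_next(mean_r2, current)
        if nxt is None:
            break
        eliminated = nxt
        current = current.drop(nxt)

    # final choice: minimum cross-validated mean |dV| over (step, fwhm)
    best = None
    for rec in steps:
        for fwhm in fwhm_list:
            v = rec.metrics[fwhm]["vol_diff"]
            if best is None or v < best[0]:
                best = (v, rec, fwhm)
    _, best_rec, best_fwhm = best
    final_pset = PredictorSet(best_rec.predictors, current.protected, best_fwhm)
    final_cutoff, _ = _full_training_cutoff(cohort, final_pset, vv, min_lesion_frac, ridge)
    trace = SelectionTrace(
        steps=steps,
        folds=folds,
        final_predictors=final_pset,
        final_fwhm=best_fwhm,
        final_cutoff=final_cutoff,
    )
    log.info(
        "step-down finished: final model %s at FWHM %.0f mm (CV |dV| %.2f ml, cutoff %.3f)",
        "+".join(final_pset.names),
        best_fwhm,
        best[0],
        final_cutoff.value,
    )
    return trace
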