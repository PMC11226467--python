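"""Evaluation metrics and statistics.

Volumetric accuracy (absolute volume difference in ml), topographic
accuracy (per-patient ROC AUC in the Mann-Whitney formulation), spatial
accuracy (Dice), mismatch compartments and tissue-to-infarct conversion
rates, paired and unpaired rank tests, Fisher's exact test, and the mixed
2-within x 1-between ANOVA used for the conversion-rate analysis.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

log = logging.getLogger(__name__)


class TestResult(NamedTuple):
    statistic: float
    pvalue: float
    flagged: bool = False


# ---------------------------------------------------------------------------
# masks and per-patient metrics


def eval_mask(case, glm_mask: np.ndarray) -> np.ndarray:
    """Evaluation support: coverage AND glm_mask minus the case exclusion
    mask. Empty results are allowed but logged."""
    if case.coverage.shape != glm_mask.shape:
        raise ValueError("masks must share the grid")
    out = case.effective_coverage() & glm_mask.astype(bool)
    if not out.any():
        log.warning("case %s: empty evaluation mask", case.case_id)
    return out


def abs_volume_difference(pred: np.ndarray, truth: np.ndarray, voxel_vol: float) -> float:
    """| #pred - #truth | * voxel volume, in ml."""
    return abs(int(np.count_nonzero(pred)) - int(np.count_nonzero(truth))) * voxel_vol


def roc_auc(scores: np.ndarray, truth: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Probability that a random lesioned voxel outscores a random
    non-lesioned one, ties counted 1/2 (Mann-Whitney formulation).
    Returns NaN when the mask holds a single class."""
    scores = np.asarray(scores, dtype=np.float64)
    t = np.asarray(truth).astype(bool)
    if mask is not None:
        m = np.asarray(mask).astype(bool)
        scores, t = scores[m], t[m]
    else:
        scores, t = scores.ravel(), t.ravel()
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        log.warning("roc_auc: single-class mask (pos=%d, neg=%d)", n_pos, n_neg)
        return float("nan")
    ranks = rankdata(scores)
    u = ranks[t].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """2|A^B| / (|A|+|B|); defined as 1 when both masks are empty (logged)."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share the grid")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        log.warning("dice: both masks empty, returning 1")
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def mismatch_maps(bin_success: np.ndarray, bin_failure: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Core = prediction under successful recanalization; penumbra =
    prediction under unsuccessful AND NOT under successful (the
    "thrombectomy mismatch")."""
    s = np.asarray(bin_success).astype(bool)
    f = np.asarray(bin_failure).astype(bool)
    if s.shape != f.shape:
        raise ValueError("masks must share the grid")
    return s, f & ~s


def conversion_rates(core: np.ndarray, penumbra: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Fraction of each compartment's voxels inside the ground-truth
    infarct; NaN for an empty compartment."""
    truth = np.asarray(truth).astype(bool)
    out = []
    for comp in (np.asarray(core).astype(bool), np.asarray(penumbra).astype(bool)):
        n = int(comp.sum())
        out.append(float("nan") if n == 0 else int((comp & truth).sum()) / n)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# rank tests


def _signed_rank_exact_p(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided exact p for the signed-rank statistic by enumeration of all
    sign assignments (midranks allowed)."""
    n = ranks.size
    mu = ranks.sum() / 2.0
    d_obs = abs(w_obs - mu)
    count = 0
    total = 1 << n
    # enumerate W+ over all 2^n subsets via bit tricks
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    count = int(np.count_nonzero(np.abs(sums - mu) >= d_obs - 1e-12))
    return count / total


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded. Exact enumeration when at most 12
    nonzero differences remain; otherwise a normal approximation with tie
    and continuity corrections. All-zero differences give p = 1 flagged."""
    d = np.asarray(x, dtype=np.float64) - np.asarray(y, dtype=np.float64)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, flagged=True)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 12:
        p = _signed_rank_exact_p(ranks, w_plus)
        return TestResult(w_plus, min(p, 1.0))
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    diff = w_plus - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(sigma2) if sigma2 > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(w_plus, min(p, 1.0))


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration over rank assignments when n_a + n_b <= 12 (valid
    with ties via midranks); otherwise tie-corrected normal approximation
    with continuity correction."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_obs = float(ranks[:na].sum()) - na * (na + 1) / 2.0
    mu = na * nb / 2.0
    if na + nb <= 12:
        d_obs = abs(u_obs - mu)
        count = 0
        total = 0
        for comb in itertools.combinations(range(na + nb), na):
            u = float(ranks[list(comb)].sum()) - na * (na + 1) / 2.0
            total += 1
            if abs(u - mu) >= d_obs - 1e-12:
                count += 1
        return TestResult(u_obs, count / total)
    n = na + nb
    _, counts = np.unique(ranks, return_counts=True)
    tie = float((counts**3 - counts).sum())
    sigma2 = na * nb / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    diff = u_obs - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(sigma2) if sigma2 > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(u_obs, min(p, 1.0))


def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table: the sum of
    hypergeometric probabilities of all tables with the observed margins
    whose point probability does not exceed the observed one (within 1e-12
    relative slack). A zero margin gives the degenerate p = 1, flagged."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative integer counts")
    a = int(t[0, 0])
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return TestResult(float(a), 1.0, flagged=True)
    hg = stats.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - r2), min(c1, r1) + 1)
    pmf = hg.pmf(support)
    p_obs = hg.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())
    if p > 1.0 - 1e-12:
        p = 1.0
    return TestResult(float(a), min(p, 1.0))


# ---------------------------------------------------------------------------
# mixed ANOVA (2 within x 2 within x 1 between)


@dataclass
class AnovaEffect:
    effect: str
    F: float
    df1: int
    df2: int
    pvalue: float
    flagged: bool = False


def _contrast_test(z: np.ndarray, groups: np.ndarray, kind: str) -> tuple[float, int, int, float, bool]:
    """Test on per-subject contrast scores z with a 2-level between factor.

    kind 'mean': H0 that the unweighted grand mean of group means is zero
    (a within main effect or within-within interaction). kind 'diff': H0
    that group means are equal (interaction with the between factor)."""
    labels = np.unique(groups)
    g = labels.size
    means = np.array([z[groups == lab].mean() for lab in labels])
    ns = np.array([(groups == lab).sum() for lab in labels])
    sse = float(sum(((z[groups == lab] - m) ** 2).sum() for lab, m in zip(labels, means)))
    df2 = int(z.size - g)
    if df2 <= 0:
        raise ValueError("each between-group needs at least 2 subjects")
    mse = sse / df2
    if kind == "mean":
        est = means.mean()
        var = (1.0 / ns).sum() / g**2
    else:
        est = means[0] - means[1]
        var = 1.0 / ns[0] + 1.0 / ns[1]
    if mse == 0:
        flagged = True
        F = math.inf if est != 0 else 0.0
    else:
        flagged = False
        F = est**2 / (mse * var)
    p = float(stats.f.sf(F, 1, df2)) if math.isfinite(F) else 0.0
    if F == 0.0:
        p = 1.0
    return F, 1, df2, p, flagged


def mixed_anova_2w1b(cells: np.ndarray, between: Sequence) -> pd.DataFrame:
    """Mixed-design ANOVA with two 2-level within factors (compartment,
    method) and one 2-level between factor (recanalization).

    ``cells``: array (n_subjects, 2, 2) of per-subject conversion rates,
    axis 1 = compartment (core, penumbra), axis 2 = method (logistic,
    thresholding). Subjects with any NaN cell are excluded listwise.
    Returns a table of F, df and p for the three main effects, the three
    two-way interactions and the three-way interaction. With all factors
    at 2 levels, each effect reduces to a test on per-subject contrast
    scores; between-group imbalance is handled with unweighted (Type-III
    style) means, and sphericity is moot."""
    cells = np.asarray(cells, dtype=np.float64)
    groups = np.asarray(between)
    if cells.ndim != 3 or cells.shape[1:] != (2, 2):
        raise ValueError("cells must have shape (n_subjects, 2, 2)")
    if groups.shape[0] != cells.shape[0]:
        raise ValueError("between labels must match the number of subjects")
    keep = ~np.isnan(cells).any(axis=(1, 2))
    n_drop = int(np.count_nonzero(~keep))
    if n_drop:
        log.info("mixed_anova_2w1b: excluded %d subjects with undefined cells", n_drop)
    cells = cells[keep]
    groups = groups[keep]
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"between factor must have exactly 2 levels, got {labels.size}")
    for lab in labels:
        if (groups == lab).sum() < 2:
            raise ValueError(f"between group {lab!r} has fewer than 2 subjects")

    subj_mean = cells.mean(axis=(1, 2))
    z_comp = cells[:, 1, :].mean(axis=1) - cells[:, 0, :].mean(axis=1)
    z_meth = cells[:, :, 1].mean(axis=1) - cells[:, :, 0].mean(axis=1)
    z_cm = (cells[:, 1, 1] - cells[:, 1, 0]) - (cells[:, 0, 1] - cells[:, 0, 0])

    rows: list[AnovaEffect] = []

    # between main effect: one-way ANOVA on subject means
    means = np.array([subj_mean[groups == lab].mean() for lab in labels])
    ns = np.array([(groups == lab).sum() for lab in labels])
    grand = subj_mean.mean()
    ss_a = float((ns * (means - grand) ** 2).sum())
    ss_s = float(sum(((subj_mean[groups == lab] - m) ** 2).sum() for lab, m in zip(labels, means)))
    df2 = int(subj_mean.size - 2)
    if ss_s == 0:
        F = math.inf if ss_a > 0 else 0.0
        p = 0.0 if ss_a > 0 else 1.0
        rows.append(AnovaEffect("recanalization", F, 1, df2, p, flagged=True))
    else:
        F = ss_a / 1 / (ss_s / df2)
        rows.append(AnovaEffect("recanalization", F, 1, df2, float(stats.f.sf(F, 1, df2))))

    for name, z, kind in [
        ("compartment", z_comp, "mean"),
        ("compartment x recanalization", z_comp, "diff"),
        ("method", z_meth, "mean"),
        ("method x recanalization", z_meth, "diff"),
        ("compartment x method", z_cm, "mean"),
        ("compartment x method x recanalization", z_cm, "diff"),
    ]:
        F, df1, df2, p, flagged = _contrast_test(z, groups, kind)
        rows.append(AnovaEffect(name, F, df1, df2, p, flagged))

    order = [
        "compartment",
        "method",
        "recanalization",
        "compartment x method",
        "compartment x recanalization",
        "method x recanalization",
        "compartment x method x recanalization",
    ]
    df = pd.DataFrame([vars(r) for r in rows]).set_index("effect").loc[order].reset_index()
    return df


# ---------------------------------------------------------------------------
# cohort-level evaluation


def mean_ci(values: Iterable[float], method: str = "normal", n_boot: int = 2000, seed: int = 0) -> tuple[float, float, float]:
    """Mean with a 95% CI: normal approximation (mean +/- 1.96 SE, the
    default) or a seeded percentile bootstrap."""
    v = np.asarray([x for x in values if not math.isnan(x)], dtype=np.float64)
    m = float(v.mean())
    if method == "bootstrap" and v.size > 1:
        rng = np.random.default_rng(seed)
        boots = rng.choice(v, size=(n_boot, v.size), replace=True).mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        return m, float(lo), float(hi)
    se = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else 0.0
    return m, m - 1.96 * se, m + 1.96 * se


def evaluate_cohort(
    model,
    cutoff,
    threshold_model,
    cohort,
    in_sample: bool = False,
    ci_method: str = "normal",
) -> dict:
    """Full evaluation of a frozen logistic model + cutoff and a frozen
    thresholding baseline on a cohort.

    Per patient and method: absolute volume difference (ml), AUC and Dice
    under the patient's actual recanalization scenario; mismatch
    compartments and conversion rates for both methods; paired Wilcoxon
    signed-rank comparisons; Table-style summary with mean (95% CI); and
    the mixed conversion-rate ANOVA. Refuses to score patients that were
    in the training set unless ``in_sample`` is set."""
    from .baseline import predict_threshold
    from .glm import predict_risk_maps
    from .imaging import voxel_volume_ml, VolumeGrid

    train_ids = set(model.training_case_ids)
    overlap = [c.case_id for c in cohort if c.case_id in train_ids]
    if overlap and not in_sample:
        raise ValueError(
            f"{len(overlap)} evaluation cases were used for training "
            "(pass in_sample=True to evaluate in-sample on purpose)"
        )

    glm_mask = model.glm_mask
    vv = voxel_volume_ml(VolumeGrid(np.zeros((1, 1, 1)), model.voxel_size))
    eval_rows = []
    mismatch_rows = []
    anova_cells = []
    anova_groups = []
    for case in cohort:
        support = eval_mask(case, glm_mask)
        truth = case.lesion.astype(bool) & support
        pair = predict_risk_maps(model, case)
        risk = pair.scenario(case.recanalization)
        risk_m = np.where(support, np.nan_to_num(risk, nan=0.0), 0.0)
        bin_succ_log = support & (np.nan_to_num(pair.p_success, nan=0.0) > cutoff.value)
        bin_fail_log = support & (np.nan_to_num(pair.p_failure, nan=0.0) > cutoff.value)
        bin_log = bin_succ_log if case.recanalization else bin_fail_log

        bin_succ_thr = predict_threshold(case, threshold_model, "success", support=support)
        bin_fail_thr = predict_threshold(case, threshold_model, "failure", support=support)
        bin_thr = bin_succ_thr if case.recanalization else bin_fail_thr
        smoothed = case.smoothed(threshold_model.fwhm)
        thr_score = -smoothed["cbf_rel"] if case.recanalization else smoothed["tmax"]

        for method, pred_bin, scores in (
            ("logistic", bin_log, risk_m),
            ("thresholding", bin_thr, thr_score),
        ):
            eval_rows.append(
                {
                    "case_id": case.case_id,
                    "method": method,
                    "recanalization": case.recanalization,
                    "abs_vol_diff_ml": abs_volume_difference(pred_bin, truth, vv),
                    "auc": roc_auc(scores, truth, support),
                    "dice": dice(pred_bin, truth),
                    "eval_voxels": int(support.sum()),
                }
            )

        cell = np.full((2, 2), np.nan)
        for mj, (bin_s, bin_f) in enumerate(((bin_succ_log, bin_fail_log), (bin_succ_thr, bin_fail_thr))):
            core, penumbra = mismatch_maps(bin_s, bin_f)
            r_core, r_pen = conversion_rates(core, penumbra, truth)
            cell[0, mj] = r_core
            cell[1, mj] = r_pen
            mismatch_rows.append(
                {
                    "case_id": case.case_id,
                    "method": ("logistic", "thresholding")[mj],
                    "recanalization": case.recanalization,
                    "core_volume_ml": int(core.sum()) * vv,
                    "penumbra_volume_ml": int(penumbra.sum()) * vv,
                    "rate_core": r_core,
                    "rate_penumbra": r_pen,
                }
            )
        anova_cells.append(cell)
        anova_groups.append(case.recanalization)

    eval_df = pd.DataFrame(eval_rows)
    mismatch_df = pd.DataFrame(mismatch_rows)

    # paired comparisons and Table-style summary
    summary_rows = []
    tests = {}
    piv = eval_df.pivot(index="case_id", columns="method", values=["abs_vol_diff_ml", "auc", "dice"])
    for metric, scale in (("abs_vol_diff_ml", 1.0), ("auc", 100.0), ("dice", 100.0)):
        x = piv[(metric, "logistic")].to_numpy() * scale
        y = piv[(metric, "thresholding")].to_numpy() * scale
        ok = ~(np.isnan(x) | np.isnan(y))
        res = wilcoxon_signed_rank(x[ok], y[ok])
        tests[metric] = res
        for method, vals in (("logistic", x[ok]), ("thresholding", y[ok])):
            m, lo, hi = mean_ci(vals, method=ci_method)
            summary_rows.append(
                {"method": method, "metric": metric, "mean": m, "ci_low": lo, "ci_high": hi, "p_vs_other": res.pvalue}
            )
    summary_df = pd.DataFrame(summary_rows)

    anova_df = None
    try:
        anova_df = mixed_anova_2w1b(np.stack(anova_cells), np.asarray(anova_groups))
    except ValueError as exc:
        log.warning("conversion-rate ANOVA skipped: %s", exc)

    return {
        "eval": eval_df,
        "mismatch": mismatch_df,
        "summary": summary_df,
        "tests": tests,
        "anova": anova_df,
    }
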