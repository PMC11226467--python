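import itertools
import math

import numpy as np
import pytest
from scipy import stats

from voxlogit.metrics import (
    abs_volume_difference,
    conversion_rates,
    dice,
    eval_mask,
    fisher_exact,
    mean_ci,
    mismatch_maps,
    mixed_anova_2w1b,
    roc_auc,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)


class TestVolumeAndOverlap:
    def test_abs_volume_difference_cases(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a.ravel()[:10] = True
        b.ravel()[:4] = True
        assert abs_volume_difference(a, a, 0.008) == 0.0
        assert abs_volume_difference(a, b, 0.008) == pytest.approx(0.048)
        signed = (int(a.sum()) - int(b.sum())) * 0.008
        assert abs_volume_difference(a, b, 0.008) == abs(signed)

    def test_dice_cases(self):
        a = np.zeros(10, bool); a[:4] = True
        b = np.zeros(10, bool); b[2:8] = True
        assert dice(a, a) == 1.0
        assert dice(a, ~a) == 0.0
        assert dice(a, b) == pytest.approx(2 * 2 / (4 + 6))
        assert dice(b, a) == dice(a, b)
        assert dice(np.zeros(5, bool), np.zeros(5, bool)) == 1.0  # flagged degenerate

    def test_eval_mask_is_set_intersection_minus_exclusion(self, rng):
        from voxlogit.imaging import PatientCase, VolumeGrid

        shape = (5, 5, 5)
        cov = rng.random(shape) < 0.7
        glm = rng.random(shape) < 0.6
        exc = rng.random(shape) < 0.2
        vols = {n: VolumeGrid(np.zeros(shape, np.float32), (2, 2, 2)) for n in ("ncct", "cta", "cbv", "cbf", "tmax")}
        case = PatientCase("t", vols, cov.astype(np.uint8), np.zeros(shape, np.uint8),
                           70, 1, 5, 60, "2b", "left", exclusion=exc.astype(np.uint8))
        out = eval_mask(case, glm)
        for v in np.ndindex(shape):
            assert out[v] == (cov[v] and glm[v] and not exc[v])


class TestRocAuc:
    def test_perfect_and_constant(self):
        truth = np.array([0, 0, 1, 1], bool)
        assert roc_auc(truth.astype(float), truth) == 1.0
        assert roc_auc(np.zeros(4), truth) == 0.5

    def test_six_voxel_toy_matches_pair_counting(self):
        scores = np.array([0.1, 0.4, 0.4, 0.35, 0.8, 0.05])
        truth = np.array([0, 1, 0, 1, 1, 0], bool)
        total = hits = 0
        for i in np.flatnonzero(truth):
            for j in np.flatnonzero(~truth):
                total += 1
                hits += 1.0 if scores[i] > scores[j] else (0.5 if scores[i] == scores[j] else 0.0)
        assert roc_auc(scores, truth) == pytest.approx(hits / total, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(200)
        truth = rng.random(200) < 0.3
        a1 = roc_auc(scores, truth)
        a2 = roc_auc(np.exp(5 * scores) - 2, truth)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_is_nan(self):
        assert math.isnan(roc_auc(np.ones(4), np.ones(4, bool)))


class TestMismatchAndConversion:
    def test_penumbra_is_set_difference(self, rng):
        s = rng.random((6, 6, 6)) < 0.4
        f = rng.random((6, 6, 6)) < 0.6
        core, pen = mismatch_maps(s, f)
        np.testing.assert_array_equal(core, s)
        np.testing.assert_array_equal(pen, f & ~s)
        assert not (core & pen).any()
        core2, pen2 = mismatch_maps(s, s)
        assert pen2.sum() == 0

    def test_conversion_rates(self):
        core = np.zeros(16, bool); core[:8] = True
        pen = np.zeros(16, bool); pen[8:12] = True
        truth = np.zeros(16, bool); truth[:3] = True
        rc, rp = conversion_rates(core, pen, truth)
        assert rc == pytest.approx(3 / 8)
        assert rp == 0.0
        rc2, _ = conversion_rates(core, pen, np.ones(16, bool))
        assert rc2 == 1.0
        _, rp3 = conversion_rates(core, np.zeros(16, bool), truth)
        assert math.isnan(rp3)

    def test_union_rate_is_weighted_mean_of_compartment_rates(self, rng):
        core = rng.random(300) < 0.3
        pen = (rng.random(300) < 0.4) & ~core
        truth = rng.random(300) < 0.5
        rc, rp = conversion_rates(core, pen, truth)
        r_union = (core | pen)[truth].sum() / (core | pen).sum()
        w = core.sum() / (core.sum() + pen.sum())
        assert r_union == pytest.approx(w * rc + (1 - w) * rp, abs=1e-12)


class TestWilcoxonSignedRank:
    def test_degenerate_all_equal(self):
        res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.pvalue == 1.0 and res.flagged

    def test_exact_matches_full_sign_enumeration(self, rng):
        for _ in range(5):
            x = rng.normal(size=8)
            y = x + rng.normal(size=8)
            d = x - y
            d = d[d != 0]
            ranks = stats.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            mu = ranks.sum() / 2
            count = sum(
                abs(sum(r for r, s in zip(ranks, signs) if s) - mu) >= abs(w_obs - mu) - 1e-12
                for signs in itertools.product([0, 1], repeat=d.size)
            )
            expected = count / 2 ** d.size
            res = wilcoxon_signed_rank(x, y)
            assert res.pvalue == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        ours = wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(x, y, method="exact")
        assert ours.pvalue == pytest.approx(ref.pvalue, abs=1e-12)

    def test_swap_symmetry(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        assert wilcoxon_signed_rank(x, y).pvalue == pytest.approx(
            wilcoxon_signed_rank(y, x).pvalue, abs=1e-12
        )

    def test_large_sample_approximation_close_to_scipy(self, rng):
        x = rng.normal(size=60)
        y = x + 0.3 + rng.normal(size=60)
        ours = wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(x, y, method="approx", correction=True)
        assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-6)


class TestWilcoxonRankSum:
    def test_separated_samples_exact_enumeration(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        # 2 of C(6,3)=20 arrangements are as extreme two-sided
        assert res.pvalue == pytest.approx(2 / 20, abs=1e-12)

    def test_exact_matches_enumeration_with_ties(self, rng):
        a = rng.integers(0, 4, size=5).astype(float)
        b = rng.integers(0, 4, size=5).astype(float)
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        na = a.size
        u_obs = ranks[:na].sum() - na * (na + 1) / 2
        mu = na * b.size / 2
        arrangements = list(itertools.combinations(range(10), na))
        count = sum(
            abs(ranks[list(c)].sum() - na * (na + 1) / 2 - mu) >= abs(u_obs - mu) - 1e-12
            for c in arrangements
        )
        res = wilcoxon_rank_sum(a, b)
        assert res.pvalue == pytest.approx(count / len(arrangements), abs=1e-12)

    def test_scale_invariance(self, rng):
        a = rng.normal(size=20)
        b = rng.normal(size=25)
        r1 = wilcoxon_rank_sum(a, b)
        r2 = wilcoxon_rank_sum(a * 10, b * 10)
        assert r1 == r2

    def test_identical_samples_null_center(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0, 4.0] * 4, [1.0, 2.0, 3.0, 4.0] * 4)
        assert res.pvalue == pytest.approx(1.0)

    def test_large_sample_close_to_scipy(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(loc=0.5, size=35)
        ours = wilcoxon_rank_sum(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestFisherExact:
    def test_printed_contingency_table_worked_example(self):
        # premorbid independence: 268/304 vs 51/51
        res = fisher_exact([[268, 36], [51, 0]])
        assert round(res.pvalue, 3) == 0.005

    def test_symmetric_table(self):
        assert fisher_exact([[1, 1], [1, 1]]).pvalue == 1.0

    def test_zero_margin_degenerate(self):
        res = fisher_exact([[0, 0], [3, 4]])
        assert res.pvalue == 1.0 and res.flagged

    def test_matches_scipy_and_enumeration_on_random_tables(self, rng):
        for _ in range(25):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum(axis=1).min() == 0 or t.sum(axis=0).min() == 0:
                continue
            ours = fisher_exact(t).pvalue
            ref = stats.fisher_exact(t).pvalue
            assert ours == pytest.approx(ref, rel=1e-9)
            # direct hypergeometric enumeration
            r1, c1, n = t[0].sum(), t[:, 0].sum(), t.sum()
            probs = {
                k: math.comb(r1, k) * math.comb(n - r1, c1 - k) / math.comb(n, c1)
                for k in range(max(0, c1 - (n - r1)), min(c1, r1) + 1)
            }
            p_obs = probs[t[0, 0]]
            manual = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))
            assert ours == pytest.approx(manual, rel=1e-9)


def _balanced_anova_oracle(cells, groups):
    """Closed-form balanced mixed-design SS decomposition (from cell
    means), independent of the implementation under test. Requires equal
    group sizes."""
    labels = np.unique(groups)
    n_per = [(groups == g).sum() for g in labels]
    assert len(set(n_per)) == 1
    n = n_per[0]
    # reindex: Y[g, s, b, c]
    Y = np.stack([cells[groups == g] for g in labels])  # (2, n, 2, 2)
    N = 2 * n
    grand = Y.mean()
    mg = Y.mean(axis=(1, 2, 3))
    mb = Y.mean(axis=(0, 1, 3))
    mc = Y.mean(axis=(0, 1, 2))
    mgb = Y.mean(axis=(1, 3))
    mgc = Y.mean(axis=(1, 2))
    mbc = Y.mean(axis=(0, 1))
    mgbc = Y.mean(axis=1)
    ms = Y.mean(axis=(2, 3))        # subject means
    msb = Y.mean(axis=3)            # subject x b
    msc = Y.mean(axis=2)            # subject x c

    ss_a = 4 * n * ((mg - grand) ** 2).sum()
    ss_s = 4 * ((ms - mg[:, None]) ** 2).sum()
    ss_b = 4 * n * ((mb - grand) ** 2).sum()
    ss_ab = 2 * n * ((mgb - mg[:, None] - mb[None, :] + grand) ** 2).sum()
    ss_bs = 2 * ((msb - ms[:, :, None] - mgb[:, None, :] + mg[:, None, None]) ** 2).sum()
    ss_c = 4 * n * ((mc - grand) ** 2).sum()
    ss_ac = 2 * n * ((mgc - mg[:, None] - mc[None, :] + grand) ** 2).sum()
    ss_cs = 2 * ((msc - ms[:, :, None] - mgc[:, None, :] + mg[:, None, None]) ** 2).sum()
    ss_bc = 2 * n * ((mbc - mb[:, None] - mc[None, :] + grand) ** 2).sum()
    ss_abc = n * ((mgbc - mgb[:, :, None] - mgc[:, None, :] - mbc[None, :, :]
                   + mg[:, None, None] + mb[None, :, None] + mc[None, None, :] - grand) ** 2).sum()
    ss_bcs = ((Y - msb[:, :, :, None] - msc[:, :, None, :] - mgbc[:, None, :, :]
               + ms[:, :, None, None] + mgb[:, None, :, None] + mgc[:, None, None, :]
               - mg[:, None, None, None]) ** 2).sum()
    df_err = N - 2
    return {
        "recanalization": (ss_a / 1) / (ss_s / df_err),
        "compartment": (ss_b / 1) / (ss_bs / df_err),
        "compartment x recanalization": (ss_ab / 1) / (ss_bs / df_err),
        "method": (ss_c / 1) / (ss_cs / df_err),
        "method x recanalization": (ss_ac / 1) / (ss_cs / df_err),
        "compartment x method": (ss_bc / 1) / (ss_bcs / df_err),
        "compartment x method x recanalization": (ss_abc / 1) / (ss_bcs / df_err),
    }


class TestMixedAnova:
    def test_constant_cells_give_zero_F(self):
        cells = np.full((8, 2, 2), 0.4)
        groups = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        table = mixed_anova_2w1b(cells, groups)
        assert (table["F"] == 0).all()
        assert (table["pvalue"] == 1).all()

    def test_pure_compartment_effect_zero_noise(self):
        cells = np.zeros((6, 2, 2))
        cells[:, 1, :] = 0.5
        groups = np.array([0, 0, 0, 1, 1, 1])
        table = mixed_anova_2w1b(cells, groups).set_index("effect")
        assert math.isinf(table.loc["compartment", "F"])
        assert table.loc["compartment", "flagged"]
        assert table.loc["compartment x method", "F"] == 0

    def test_matches_balanced_closed_form_oracle(self, rng):
        cells = rng.random((12, 2, 2))
        groups = np.repeat([0, 1], 6)
        table = mixed_anova_2w1b(cells, groups).set_index("effect")
        oracle = _balanced_anova_oracle(cells, groups)
        for effect, F in oracle.items():
            assert table.loc[effect, "F"] == pytest.approx(F, rel=1e-9), effect

    def test_between_and_within_match_pingouin(self, rng):
        """Collapsing the method factor reduces the design to 1 within x 1
        between, which pingouin's mixed_anova covers independently."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        cells = rng.random((14, 2, 2))
        groups = np.repeat([0, 1], 7)
        collapsed = cells.mean(axis=2)  # subjects x compartment
        rows = []
        for s in range(14):
            for b in range(2):
                rows.append({"subject": s, "compartment": b, "group": groups[s], "y": collapsed[s, b]})
        df = pd.DataFrame(rows)
        ref = pg.mixed_anova(data=df, dv="y", within="compartment", subject="subject", between="group")
        ours = mixed_anova_2w1b(cells, groups).set_index("effect")
        ref = ref.set_index("Source")
        assert ours.loc["recanalization", "F"] == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert ours.loc["compartment", "F"] == pytest.approx(ref.loc["compartment", "F"], rel=1e-6)
        assert ours.loc["compartment x recanalization", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6
        )

    def test_listwise_exclusion_of_undefined_cells(self, rng):
        cells = rng.random((10, 2, 2))
        groups = np.repeat([0, 1], 5)
        cells_nan = cells.copy()
        cells_nan[0, 1, 1] = np.nan
        t1 = mixed_anova_2w1b(cells_nan, groups)
        t2 = mixed_anova_2w1b(cells[1:], groups[1:])
        np.testing.assert_allclose(t1["F"], t2["F"], rtol=1e-12)

    def test_small_group_rejected(self):
        cells = np.random.default_rng(0).random((3, 2, 2))
        with pytest.raises(ValueError):
            mixed_anova_2w1b(cells, np.array([0, 0, 1]))


def test_mean_ci_normal_approximation(rng):
    x = rng.normal(size=50)
    m, lo, hi = mean_ci(x)
    se = x.std(ddof=1) / math.sqrt(50)
    assert m == pytest.approx(x.mean())
    assert hi - m == pytest.approx(1.96 * se, rel=1e-9)


class TestEvaluateCohort:
    def test_single_patient_aggregation_identity(self, small_cohort, fitted_model):
        """Cohort-level means over one patient equal the per-patient
        operations applied directly."""
        from voxlogit.baseline import ThresholdModel
        from voxlogit.glm import predict_risk_maps
        from voxlogit.metrics import evaluate_cohort
        from voxlogit.selection import Calibration

        case = small_cohort[0]
        cut = Calibration("logistic-cutoff", 0.4, 0.0)
        thr = ThresholdModel(cbf_threshold=40.0, tmax_threshold=6.0, fwhm=0.0)
        res = evaluate_cohort(fitted_model, cut, thr, [case], in_sample=True)
        row = res["eval"].set_index("method").loc["logistic"]
        support = eval_mask(case, fitted_model.glm_mask)
        truth = case.lesion.astype(bool) & support
        pair = predict_risk_maps(fitted_model, case)
        risk = pair.scenario(case.recanalization)
        riskf = np.where(support, np.nan_to_num(risk, nan=0.0), 0.0)
        pred = support & (riskf > 0.4)
        assert row["abs_vol_diff_ml"] == pytest.approx(abs_volume_difference(pred, truth, 0.008))
        assert row["auc"] == pytest.approx(roc_auc(riskf, truth, support))
        assert row["dice"] == pytest.approx(dice(pred, truth))

    def test_training_overlap_guard(self, small_cohort, fitted_model):
        from voxlogit.baseline import ThresholdModel
        from voxlogit.metrics import evaluate_cohort
        from voxlogit.selection import Calibration

        with pytest.raises(ValueError, match="training"):
            evaluate_cohort(
                fitted_model, Calibration("logistic-cutoff", 0.4, 0.0),
                ThresholdModel(fwhm=0.0), small_cohort[:2],
            )
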