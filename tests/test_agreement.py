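import numpy as np
import pytest

from tdluquant.agreement import (
    association_tests,
    dice,
    fleiss_kappa,
    icc_3_1,
    match_detections,
    mean_sd,
    ratings_to_counts,
)
from tdluquant.slide_model import BinaryMask, PointSet, SlideFrame

FRAME = SlideFrame(1000, 1000, 1.0)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def icc_oracle(x):
    """ICC(3,1) from first principles: explicit ANOVA sums of squares."""
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i][j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ss_total = sum(
        (x[i][j] - grand) ** 2 for i in range(n) for j in range(k)
    )
    ss_rows = k * sum((r - grand) ** 2 for r in row)
    ss_cols = n * sum((c - grand) ** 2 for c in col)
    ms_rows = ss_rows / (n - 1)
    ms_err = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)


def kappa_oracle(counts):
    """Fleiss' kappa by direct transcription of the defining formula."""
    counts = np.asarray(counts, dtype=float)
    n, _ = counts.shape
    k = counts[0].sum()
    p_j = counts.sum(axis=0) / (n * k)
    p_i = [
        (sum(c * (c - 1) for c in row)) / (k * (k - 1)) for row in counts
    ]
    p_bar = sum(p_i) / n
    p_e = sum(p ** 2 for p in p_j)
    return (p_bar - p_e) / (1 - p_e)


# ---------------------------------------------------------------------------
# point matching
# ---------------------------------------------------------------------------

class TestMatchDetections:
    def test_identical_sets_are_perfect(self, rng):
        pts = PointSet(FRAME, rng.uniform(0, 900, size=(50, 2)))
        m = match_detections(pts, pts, radius_um=15)
        assert m.f1 == 1.0 and m.tp == 50 and m.fp == 0 and m.fn == 0

    def test_empty_predictions_score_zero(self, rng):
        gt = PointSet(FRAME, rng.uniform(0, 900, size=(10, 2)))
        m = match_detections(PointSet(FRAME, np.zeros((0, 2))), gt, 15)
        assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)
        assert m.fn == 10

    def test_planted_eight_of_ten(self, rng):
        # 10 true points on a wide grid; 8 predictions on top of the first
        # 8, plus 2 far away
        gt_pts = np.stack(
            [np.arange(10) * 90.0 + 50, np.full(10, 500.0)], axis=1
        )
        pred_pts = np.vstack(
            [gt_pts[:8] + rng.normal(0, 2, size=(8, 2)), [[5, 5], [990, 990]]]
        )
        m = match_detections(
            PointSet(FRAME, pred_pts), PointSet(FRAME, gt_pts), radius_um=15
        )
        assert m.tp == 8 and m.precision == 0.8 and m.recall == 0.8
        assert m.f1 == pytest.approx(0.8)

    def test_swap_symmetry(self, rng):
        a = PointSet(FRAME, rng.uniform(0, 900, size=(30, 2)))
        b = PointSet(FRAME, rng.uniform(0, 900, size=(40, 2)))
        ab = match_detections(a, b, radius_um=40)
        ba = match_detections(b, a, radius_um=40)
        assert ab.tp == ba.tp
        assert ab.precision == ba.recall and ab.recall == ba.precision
        assert ab.f1 == pytest.approx(ba.f1)

    def test_permutation_invariant_counts(self, rng):
        gt = PointSet(FRAME, rng.uniform(0, 900, size=(25, 2)))
        pred_pts = rng.uniform(0, 900, size=(25, 2))
        m1 = match_detections(PointSet(FRAME, pred_pts), gt, 50)
        perm = rng.permutation(25)
        m2 = match_detections(PointSet(FRAME, pred_pts[perm]), gt, 50)
        assert (m1.tp, m1.fp, m1.fn) == (m2.tp, m2.fp, m2.fn)

    def test_radius_is_physical(self):
        # two points 10 px apart at 2 um/px are 20 um apart
        f = SlideFrame(100, 100, 2.0)
        a = PointSet(f, [(10.0, 10.0)])
        b = PointSet(f, [(20.0, 10.0)])
        assert match_detections(a, b, radius_um=15).tp == 0
        assert match_detections(a, b, radius_um=25).tp == 1


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------

class TestDice:
    def test_equal_nonempty_is_one(self, tiny_frame, rng):
        pix = rng.random(tiny_frame.shape) > 0.5
        m = BinaryMask(tiny_frame, pix)
        assert dice(m, m) == 1.0

    def test_disjoint_is_zero(self, tiny_frame):
        a = np.zeros(tiny_frame.shape, bool)
        b = np.zeros(tiny_frame.shape, bool)
        a[:10], b[20:30] = True, True
        assert dice(BinaryMask(tiny_frame, a), BinaryMask(tiny_frame, b)) == 0.0

    def test_half_overlapping_squares(self):
        f = SlideFrame(40, 40, 1.0)
        a = np.zeros(f.shape, bool)
        b = np.zeros(f.shape, bool)
        a[0:10, 0:10] = True
        b[0:10, 5:15] = True
        assert dice(BinaryMask(f, a), BinaryMask(f, b)) == 0.5

    def test_both_empty_is_one(self, tiny_frame):
        e = BinaryMask(tiny_frame, np.zeros(tiny_frame.shape, bool))
        assert dice(e, e) == 1.0

    def test_frame_mismatch_rejected(self, tiny_frame):
        other = SlideFrame(64, 64, 2.0)
        with pytest.raises(ValueError):
            dice(
                BinaryMask(tiny_frame, np.zeros(tiny_frame.shape, bool)),
                BinaryMask(other, np.zeros(other.shape, bool)),
            )

    def test_dice_equals_f1_on_pixel_sets(self, rng):
        # the segmentation metric is exactly the detection metric applied
        # to pixel sets
        f = SlideFrame(32, 32, 1.0)
        for _ in range(25):
            a = rng.random(f.shape) > 0.6
            b = rng.random(f.shape) > 0.6
            tp = int((a & b).sum())
            fp = int((a & ~b).sum())
            fn = int((~a & b).sum())
            f1 = 2 * tp / (2 * tp + fp + fn) if (tp + fp + fn) else 1.0
            assert dice(BinaryMask(f, a), BinaryMask(f, b)) == pytest.approx(
                f1, abs=1e-12
            )


def test_mean_sd_aggregation():
    m, sd = mean_sd([0.8, 0.7, 0.9])
    assert m == pytest.approx(0.8)
    assert sd == pytest.approx(0.1)


# ---------------------------------------------------------------------------
# ICC(3,1)
# ---------------------------------------------------------------------------

class TestIcc:
    def test_rater_offset_gives_one(self, rng):
        r1 = rng.normal(size=20)
        res = icc_3_1(np.stack([r1, r1 + 5.0], axis=1))
        assert res.statistic == pytest.approx(1.0, abs=1e-12)

    def test_matches_anova_oracle_on_random_tables(self, rng):
        for _ in range(200):
            x = rng.normal(size=(6, 3))
            assert icc_3_1(x).statistic == pytest.approx(
                icc_oracle(x), abs=1e-10
            )

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(500, 2))
        assert abs(icc_3_1(x).statistic) < 0.1

    def test_affine_invariance(self, rng):
        x = rng.normal(size=(12, 3))
        a = icc_3_1(x)
        b = icc_3_1(2.5 * x + 7.0)
        c = icc_3_1(x + np.array([1.0, -3.0, 10.0]))  # per-rater constants
        assert b.statistic == pytest.approx(a.statistic, abs=1e-12)
        assert c.statistic == pytest.approx(a.statistic, abs=1e-12)

    def test_matches_pingouin_with_ci(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(loc=5, scale=2, size=(15, 3)) + rng.normal(
            size=(15, 1)
        ) * 1.5
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 3),
                "rater": np.tile(np.arange(3), 15),
                "score": x.ravel(),
            }
        )
        icc_tbl = pingouin.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        row = icc_tbl.loc["ICC(C,1)"]  # consistency, single rater
        res = icc_3_1(x)
        assert res.statistic == pytest.approx(row["ICC"], abs=1e-9)
        ci_col = "CI95%" if "CI95%" in icc_tbl.columns else "CI95"
        lo, hi = row[ci_col]
        assert res.ci_low == pytest.approx(lo, abs=5e-3)
        assert res.ci_high == pytest.approx(hi, abs=5e-3)

    def test_ci_brackets_statistic(self, rng):
        x = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1))
        res = icc_3_1(x)
        assert res.ci_low <= res.statistic <= res.ci_high

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            icc_3_1(np.ones((5, 3)))


# ---------------------------------------------------------------------------
# Fleiss' kappa
# ---------------------------------------------------------------------------

class TestFleissKappa:
    def test_unanimous_is_one(self):
        counts = np.array([[3, 0], [0, 3], [3, 0], [0, 3]])
        res = fleiss_kappa(counts, 3)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)
        assert res.p_value < 0.05

    def test_matches_formula_oracle_on_random_tables(self, rng):
        for _ in range(200):
            labels = rng.integers(0, 3, size=(8, 4))
            counts, _ = ratings_to_counts(labels, categories=[0, 1, 2])
            res = fleiss_kappa(counts, 4)
            assert res.statistic == pytest.approx(
                kappa_oracle(counts), abs=1e-12
            )

    def test_matches_statsmodels(self, rng):
        sm_ir = pytest.importorskip("statsmodels.stats.inter_rater")
        labels = rng.integers(0, 3, size=(30, 5))
        counts, _ = ratings_to_counts(labels, categories=[0, 1, 2])
        assert fleiss_kappa(counts, 5).statistic == pytest.approx(
            sm_ir.fleiss_kappa(counts), abs=1e-12
        )

    def test_uniform_random_raters_near_zero(self):
        rng = np.random.default_rng(11)
        labels = rng.integers(0, 3, size=(1000, 4))
        counts, _ = ratings_to_counts(labels, categories=[0, 1, 2])
        res = fleiss_kappa(counts, 4)
        assert abs(res.statistic) < 0.05
        assert res.p_value > 0.01  # no evidence of agreement

    def test_classic_worked_example(self):
        # Fleiss (1971) Table 1: 30 subjects, 6 raters, 5 categories;
        # kappa = 0.430
        counts = np.array([
            [0, 0, 0, 0, 6], [0, 3, 0, 0, 3], [0, 1, 4, 0, 1],
            [0, 0, 0, 0, 6], [0, 3, 0, 3, 0], [2, 0, 4, 0, 0],
            [0, 0, 4, 0, 2], [2, 0, 3, 1, 0], [2, 0, 0, 4, 0],
            [0, 0, 0, 0, 6], [1, 0, 0, 5, 0], [1, 1, 0, 4, 0],
            [0, 3, 3, 0, 0], [1, 0, 0, 5, 0], [0, 2, 0, 3, 1],
            [0, 0, 5, 0, 1], [3, 0, 0, 1, 2], [5, 1, 0, 0, 0],
            [0, 2, 0, 4, 0], [1, 0, 2, 0, 3], [0, 0, 0, 0, 6],
            [0, 1, 0, 5, 0], [0, 2, 0, 1, 3], [2, 0, 0, 4, 0],
            [1, 0, 0, 4, 1], [0, 5, 0, 1, 0], [4, 0, 0, 0, 2],
            [0, 2, 0, 4, 0], [1, 0, 5, 0, 0], [0, 0, 0, 0, 6],
        ])
        res = fleiss_kappa(counts, 6)
        assert res.statistic == pytest.approx(0.430, abs=0.002)

    def test_row_sum_violation_named(self):
        counts = np.array([[2, 1], [3, 1]])
        with pytest.raises(ValueError, match=r"rows \[1\]"):
            fleiss_kappa(counts, 3)

    def test_single_category_undefined(self):
        with pytest.raises(ValueError, match="single category"):
            fleiss_kappa(np.array([[3, 0], [3, 0]]), 3)

    def test_intra_observer_two_sessions(self):
        # same computation applies to one observer's two sessions
        counts = np.array([[2, 0], [0, 2], [2, 0], [1, 1]])
        res = fleiss_kappa(counts, 2)
        assert res.n_raters == 2
        assert -1.0 <= res.statistic <= 1.0


# ---------------------------------------------------------------------------
# association tests
# ---------------------------------------------------------------------------

class TestAssociations:
    def test_monotone_pairs_have_rho_one(self):
        x = [1, 2, 3, 4, 5]
        stat, p = association_tests(x, [v ** 3 for v in x], test="spearman")
        assert stat == pytest.approx(1.0)

    def test_identical_groups_not_significant(self):
        g = list(range(20))
        _, p = association_tests(g, g, test="mann_whitney_u")
        assert p > 0.9

    def test_diagonal_contingency_is_significant(self):
        stat, p = association_tests(
            np.array([[20, 0], [0, 20]]), test="chi_squared"
        )
        assert p < 0.01

    def test_kruskal_separated_groups(self):
        _, p = association_tests(
            None,
            test="kruskal_wallis",
            groups=[[1, 2, 3, 4], [10, 11, 12, 13], [20, 21, 22, 23]],
        )
        assert p < 0.01

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError):
            association_tests([1], [2], test="anova")
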