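"""Validation statistics: detection F1, Dice, ICC(3,1), Fleiss' kappa.

These are the statistics used to validate automated involution measures
against manual assessment:

* point-detection agreement via maximum-cardinality one-to-one matching
  within a distance threshold, summarized by precision/recall/F1;
* segmentation agreement via the Dice similarity coefficient, which is
  exactly the F1 score computed on pixel sets;
* agreement between continuous measures via the two-way mixed-effects,
  consistency, single-rater intraclass correlation ICC(3,1) with its
  F-distribution 95% confidence interval;
* agreement between categorical ratings via Fleiss' kappa with the
  large-sample z-test against kappa = 0.

ICC and kappa are computed from their ANOVA / Fleiss formulations here
(they are part of the validated surface of the package); the generic
association tests (Spearman, Mann-Whitney U, Kruskal-Wallis,
chi-squared) delegate to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .slide_model import BinaryMask, PointSet

#: Default hit radius for point matching, on the order of an acinus radius.
DEFAULT_MATCH_RADIUS_UM = 15.0


@dataclass
class MatchResult:
    """Outcome of one-to-one point matching between detections and truth."""

    tp: int
    fp: int
    fn: int
    pairs: List[Tuple[int, int]]  # (pred index, gt index)
    precision: float
    recall: float
    f1: float


@dataclass
class AgreementResult:
    """An agreement statistic with its uncertainty and design metadata."""

    statistic: float
    method: str  # "icc_3_1" or "fleiss_kappa"
    n_subjects: int
    n_raters: int
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_value: float = float("nan")


def match_detections(
    pred: PointSet, gt: PointSet, radius_um: float = DEFAULT_MATCH_RADIUS_UM
) -> MatchResult:
    """Match predicted to ground-truth points within a physical radius.

    Maximum-cardinality one-to-one matching (Hungarian algorithm on the
    distance matrix with pairs beyond ``radius_um`` disallowed).  The
    matched-pair *count* — hence precision/recall/F1 — is deterministic
    under any permutation of the inputs.  Precision = TP / (TP + FP),
    recall = TP / (TP + FN); each is 0 when its denominator is 0, and F1
    is their harmonic mean (0 when both are 0).
    """
    if radius_um <= 0:
        raise ValueError("match radius must be positive")
    if pred.frame != gt.frame:
        raise ValueError("pred and gt point sets must share a frame")
    n_pred, n_gt = len(pred), len(gt)
    pairs: List[Tuple[int, int]] = []
    if n_pred and n_gt:
        d = cdist(pred.coords_um(), gt.coords_um())
        feasible = d <= radius_um
        # big-M cost for disallowed pairs keeps the assignment square-free
        big = radius_um * (n_pred + n_gt + 1.0) + 1.0
        cost = np.where(feasible, d, big)
        rows, cols = linear_sum_assignment(cost)
        pairs = [
            (int(i), int(j)) for i, j in zip(rows, cols) if feasible[i, j]
        ]
    tp = len(pairs)
    fp = n_pred - tp
    fn = n_gt - tp
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    return MatchResult(tp, fp, fn, pairs, precision, recall, f1)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∧B| / (|A| + |B|).

    Identical to the F1 score computed on the two pixel sets.  Two empty
    masks score 1 by convention (perfect agreement on absence).
    """
    if a.frame != b.frame:
        raise ValueError("masks must share a frame")
    na, nb = a.count, b.count
    if na == 0 and nb == 0:
        return 1.0
    inter = int((a.pixels & b.pixels).sum())
    return 2.0 * inter / (na + nb)


def mean_sd(values: Sequence[float]) -> Tuple[float, float]:
    """Aggregate per-slide scores as mean and sample SD (ddof=1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def icc_3_1(
    ratings: np.ndarray, confidence: float = 0.95
) -> AgreementResult:
    """Two-way mixed-effects, consistency, single-rater ICC(3,1).

    ``ratings`` is an (n_subjects x k_raters) table with no missing
    cells.  From the two-way ANOVA decomposition,

        ICC(3,1) = (MS_R - MS_E) / (MS_R + (k - 1) MS_E)

    where MS_R is the between-subjects mean square and MS_E the residual
    (subject x rater interaction) mean square.  Rater main effects are
    removed, so adding a constant to one rater's column leaves the ICC
    unchanged.  The confidence interval uses the F-distribution bounds
    F = MS_R / MS_E with (n-1, (n-1)(k-1)) degrees of freedom.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters table")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ss_rows = float(k * ((row_means - grand) ** 2).sum())
    ss_cols = float(n * ((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols

    df_rows = n - 1
    df_err = (n - 1) * (k - 1)
    ms_rows = ss_rows / df_rows
    ms_err = ss_err / df_err
    if ms_rows == 0.0 and ms_err == 0.0:
        raise ValueError("ICC undefined: zero total variance")

    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)

    if ms_err > 0:
        alpha = 1.0 - confidence
        f_obs = ms_rows / ms_err
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df_rows, df_err)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df_err, df_rows)
        ci_low = (fl - 1.0) / (fl + (k - 1.0))
        ci_high = (fu - 1.0) / (fu + (k - 1.0))
    else:
        ci_low = ci_high = 1.0  # perfect consistency, degenerate F

    return AgreementResult(
        statistic=float(icc),
        method="icc_3_1",
        n_subjects=n,
        n_raters=k,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
    )


def ratings_to_counts(
    labels: np.ndarray, categories: Optional[Sequence] = None
) -> Tuple[np.ndarray, list]:
    """Convert an (n_subjects x k_raters) label table to a count table.

    Returns the (n_subjects x n_categories) count matrix expected by
    :func:`fleiss_kappa` plus the category order used.
    """
    labels = np.asarray(labels)
    if categories is None:
        categories = sorted(set(labels.ravel().tolist()))
    cats = list(categories)
    index = {c: j for j, c in enumerate(cats)}
    n = labels.shape[0]
    counts = np.zeros((n, len(cats)), dtype=int)
    for i in range(n):
        for lab in labels[i]:
            counts[i, index[lab]] += 1
    return counts, cats


def fleiss_kappa(
    counts: np.ndarray, raters_per_subject: Optional[int] = None
) -> AgreementResult:
    """Fleiss' kappa for categorical agreement among a fixed rater count.

    ``counts`` is an (n_subjects x n_categories) table of how many
    raters placed each subject in each category; every row must sum to
    the same number of raters.  kappa = (P̄ - P̄_e) / (1 - P̄_e), and the
    p-value is from the large-sample null z = kappa / SE0(kappa)
    (two-sided), with the Fleiss null standard error

        SE0 = sqrt(2 / (N k (k-1))) *
              sqrt((Σ p_j q_j)^2 - Σ p_j q_j (q_j - p_j)) / Σ p_j q_j .
    """
    c = np.asarray(counts)
    if c.ndim != 2:
        raise ValueError("counts must be a 2-D subjects x categories table")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    row_sums = c.sum(axis=1)
    if raters_per_subject is None:
        raters_per_subject = int(row_sums[0])
    k = int(raters_per_subject)
    if k < 2:
        raise ValueError("need at least 2 raters per subject")
    if not (row_sums == k).all():
        bad = np.nonzero(row_sums != k)[0]
        raise ValueError(
            f"rows {bad.tolist()} do not sum to {k} raters"
        )
    n = c.shape[0]

    p_j = c.sum(axis=0) / (n * k)  # category proportions
    p_i = ((c * (c - 1)).sum(axis=1)) / (k * (k - 1))  # per-subject agreement
    p_bar = float(p_i.mean())
    p_e = float((p_j ** 2).sum())
    if p_e >= 1.0:
        raise ValueError(
            "kappa undefined: all ratings fall in a single category"
        )
    kappa = (p_bar - p_e) / (1.0 - p_e)

    q_j = 1.0 - p_j
    s = float((p_j * q_j).sum())
    var0 = (
        2.0
        / (n * k * (k - 1))
        * (s ** 2 - float((p_j * q_j * (q_j - p_j)).sum()))
        / (s ** 2)
    )
    se0 = np.sqrt(var0)
    z = kappa / se0 if se0 > 0 else np.inf * np.sign(kappa)
    p_value = 2.0 * (1.0 - stats.norm.cdf(abs(z)))

    return AgreementResult(
        statistic=float(kappa),
        method="fleiss_kappa",
        n_subjects=n,
        n_raters=k,
        p_value=float(p_value),
    )


def association_tests(
    x, y=None, test: str = "spearman", groups: Optional[Sequence] = None
) -> Tuple[float, float]:
    """Thin wrappers over the standard nonparametric association tests.

    ``spearman``: x, y paired numeric -> (rho, p).
    ``mann_whitney_u``: x, y two samples -> (U, p), two-sided.
    ``kruskal_wallis``: ``groups`` = list of samples -> (H, p).
    ``chi_squared``: x = contingency table -> (chi2, p).
    Ties are handled by midranks throughout (scipy defaults).
    """
    if test == "spearman":
        if y is None:
            raise ValueError("spearman requires paired x, y")
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    if test == "mann_whitney_u":
        if y is None:
            raise ValueError("mann_whitney_u requires two samples")
        if len(x) < 1 or len(y) < 1:
            raise ValueError("both groups must be nonempty")
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if test == "kruskal_wallis":
        samples = groups if groups is not None else x
        if len(samples) < 2 or any(len(s) < 1 for s in samples):
            raise ValueError("need >= 2 nonempty groups")
        res = stats.kruskal(*samples)
        return float(res.statistic), float(res.pvalue)
    if test == "chi_squared":
        table = np.asarray(x)
        res = stats.chi2_contingency(table)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")
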