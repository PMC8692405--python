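"""Evaluation statistics: AUC with DeLong variance, paired AUC comparison,
exact McNemar, Fisher's exact test, Dice coefficient, sensitivity/specificity.

Conventions used throughout: the malignant class is the positive class;
labels are 0 (benign) / 1 (malignant); scores are probabilities of
malignancy. All tests are two-sided and return plain-float p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "AucEstimate",
    "DelongResult",
    "ContingencyTable2x2",
    "SensSpec",
    "roc_auc",
    "delong_test",
    "mcnemar_exact",
    "fisher_exact_2x2",
    "dice_coefficient",
    "sens_spec",
]


@dataclass(frozen=True)
class AucEstimate:
    auc: float
    variance: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class DelongResult:
    z: float
    p: float
    auc1: float
    auc2: float
    var1: float
    var2: float
    cov: float


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Correct/incorrect counts by class (rows benign, malignant)."""

    benign_correct: int
    benign_incorrect: int
    malignant_correct: int
    malignant_incorrect: int

    def __post_init__(self) -> None:
        for v in (self.benign_correct, self.benign_incorrect,
                  self.malignant_correct, self.malignant_incorrect):
            if v < 0 or int(v) != v:
                raise ValueError("cells must be non-negative integers")

    def as_array(self) -> np.ndarray:
        return np.array([[self.benign_correct, self.benign_incorrect],
                         [self.malignant_correct, self.malignant_incorrect]])


@dataclass(frozen=True)
class SensSpec:
    sensitivity: float
    specificity: float
    tp: int
    fn: int
    tn: int
    fp: int

    def format(self) -> tuple[str, str]:
        return (f"{100 * self.sensitivity:.0f}% ({self.tp}/{self.tp + self.fn})",
                f"{100 * self.specificity:.0f}% ({self.tn}/{self.tn + self.fp})")


def _check_binary(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos, neg = labels == 1, labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    return pos, neg


def _placements(scores: np.ndarray, pos: np.ndarray, neg: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components V10 (per positive) and V01 (per negative).

    psi(x, y) = 1 if x > y, 1/2 if x == y, 0 otherwise; V10_i averages psi
    over negatives, V01_j over positives. mean(V10) = mean(V01) = AUC.
    """
    x = np.asarray(scores, dtype=np.float64)[pos]
    y = np.asarray(scores, dtype=np.float64)[neg]
    gt = (x[:, None] > y[None, :]).astype(np.float64)
    eq = (x[:, None] == y[None, :]).astype(np.float64)
    psi = gt + 0.5 * eq
    return psi.mean(axis=1), psi.mean(axis=0)


def roc_auc(scores, labels) -> AucEstimate:
    """Mann-Whitney AUC (half credit for ties) with DeLong variance.

    The 95% confidence interval is Wald on the DeLong standard error,
    clipped to [0, 1].
    """
    pos, neg = _check_binary(labels)
    v10, v01 = _placements(np.asarray(scores), pos, neg)
    auc = float(v10.mean())
    m, n = v10.size, v01.size
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    return AucEstimate(auc=auc, variance=var,
                       ci_low=float(max(0.0, auc - half)),
                       ci_high=float(min(1.0, auc + half)))


def delong_test(scores_arm1, scores_arm2, labels) -> DelongResult:
    """DeLong test for two correlated ROC curves on the same cases.

    z = (AUC1 - AUC2) / sqrt(var1 + var2 - 2 cov), with variances and the
    covariance estimated from the shared placement values; the p-value is
    two-sided standard normal. Identical score vectors (zero-variance
    difference) return p = 1 by convention.
    """
    s1, s2 = np.asarray(scores_arm1), np.asarray(scores_arm2)
    if s1.shape != s2.shape:
        raise ValueError("arms must score the same cases (paired design)")
    pos, neg = _check_binary(labels)
    v10_1, v01_1 = _placements(s1, pos, neg)
    v10_2, v01_2 = _placements(s2, pos, neg)
    auc1, auc2 = float(v10_1.mean()), float(v10_2.mean())
    m, n = v10_1.size, v01_1.size
    s10 = np.cov(np.stack([v10_1, v10_2]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_1, v01_2]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov_mat = s10 / m + s01 / n
    var_diff = cov_mat[0, 0] + cov_mat[1, 1] - 2 * cov_mat[0, 1]
    if var_diff <= 0:
        z = 0.0
        p = 1.0
    else:
        z = (auc1 - auc2) / np.sqrt(var_diff)
        p = float(2 * sps.norm.sf(abs(z)))
    return DelongResult(z=float(z), p=p, auc1=auc1, auc2=auc2,
                        var1=float(cov_mat[0, 0]), var2=float(cov_mat[1, 1]),
                        cov=float(cov_mat[0, 1]))


def mcnemar_exact(b: int, c: int) -> float:
    """Exact McNemar test on discordant pair counts.

    Binomial(n = b + c, 1/2) two-sided: p = min(1, 2 * P(X <= min(b, c)));
    no discordant pairs gives p = 1.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    return float(min(1.0, 2.0 * sps.binom.cdf(min(b, c), n, 0.5)))


def fisher_exact_2x2(table: ContingencyTable2x2 | np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table (point-probability method).

    Sums hypergeometric probabilities of all tables with the observed
    margins whose point probability does not exceed the observed one.
    """
    arr = table.as_array() if isinstance(table, ContingencyTable2x2) else np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(np.asarray(arr).dtype, np.integer):
        arr = np.asarray(arr)
        if np.any(arr != np.round(arr)) or np.any(arr < 0):
            raise ValueError("cells must be non-negative integers")
        arr = arr.astype(np.int64)
    if arr.sum() == 0:
        raise ValueError("all-zero table")
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity 2|A ∩ B| / (|A| + |B|) between two binary masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must have the same shape")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        raise ValueError("Dice undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / (sa + sb)


def sens_spec(scores, labels, threshold: float = 0.5) -> SensSpec:
    """Sensitivity/specificity at an operating point on the malignancy score.

    A case is called malignant when its score is >= ``threshold``.
    """
    pos, neg = _check_binary(labels)
    called = np.asarray(scores) >= threshold
    tp = int(np.sum(called & pos))
    fn = int(np.sum(~called & pos))
    tn = int(np.sum(~called & neg))
    fp = int(np.sum(called & neg))
    return SensSpec(sensitivity=tp / (tp + fn), specificity=tn / (tn + fp),
                    tp=tp, fn=fn, tn=tn, fp=fp)
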