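"""Diagnostic-performance statistics: ROC/AUC, Youden cutoff, group tests.

The ROC curve is built over distinct score thresholds with the
"predicted case when score > t" rule and ties grouped; the trapezoidal
AUC is then algebraically identical to the Mann–Whitney pairwise
statistic with half credit for tied case–control pairs. The optimal
cutoff maximizes Youden's J = sensitivity + specificity − 1 over
midpoints between adjacent distinct scores. Two-group comparison uses
Welch's t-test when both groups pass a Shapiro–Wilk normality check,
otherwise a Mann–Whitney rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LabeledScores",
    "DiagnosticResult",
    "roc_curve",
    "auc",
    "youden_threshold",
    "evaluate_scores",
    "stage_summary",
    "compare_groups",
]


@dataclass(frozen=True)
class LabeledScores:
    """Scores with case/control labels.

    ``labels`` may be the strings "case"/"control" or booleans
    (True = case). At least one of each class is required.
    """

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=np.float64)
        raw = np.asarray(self.labels)
        if raw.dtype == np.bool_:
            is_case = raw
        else:
            lab = np.asarray([str(x) for x in raw.ravel()])
            bad = set(lab) - {"case", "control"}
            if bad:
                raise ValueError(f"labels must be 'case'/'control', got extra {sorted(bad)}")
            is_case = lab == "case"
        if scores.ndim != 1 or is_case.ndim != 1 or scores.size != is_case.size:
            raise ValueError("scores and labels must be 1-D and of equal length")
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores must be finite")
        if is_case.all() or (~is_case).all():
            raise ValueError("need at least one case and one control")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", is_case)

    @property
    def case_scores(self) -> np.ndarray:
        return self.scores[self.labels]

    @property
    def control_scores(self) -> np.ndarray:
        return self.scores[~self.labels]


@dataclass(frozen=True)
class DiagnosticResult:
    """ROC points, AUC and the Youden-optimal operating point."""

    roc_points: list
    auc: float
    threshold: float
    sensitivity: float
    specificity: float


def roc_curve(data: LabeledScores) -> list[tuple[float, float]]:
    """ROC points (fpr, tpr) from (0, 0) to (1, 1), higher score = case.

    One point per distinct threshold under the "score > t" rule; tied
    scores are grouped at a single threshold.
    """
    cases = data.case_scores
    controls = data.control_scores
    n_pos, n_neg = cases.size, controls.size
    points = [(0.0, 0.0)]
    tp = fp = 0
    # descending distinct score values; all scores > t for t just below each value
    for v in np.unique(data.scores)[::-1]:
        tp += int(np.sum(cases == v))
        fp += int(np.sum(controls == v))
        points.append((fp / n_neg, tp / n_pos))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points


def auc(roc_points) -> float:
    """Trapezoidal area under the ROC curve.

    Equals the Mann–Whitney statistic (fraction of case–control pairs with
    the case scored higher, ties counted 1/2) for curves produced by
    :func:`roc_curve`.
    """
    pts = list(roc_points)
    if len(pts) < 2 or pts[0] != (0.0, 0.0) or pts[-1] != (1.0, 1.0):
        raise ValueError("malformed ROC curve: endpoints must be (0,0) and (1,1)")
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    if np.any(np.diff(fpr) < 0) or np.any(np.diff(tpr) < 0):
        raise ValueError("malformed ROC curve: fpr/tpr must be nondecreasing")
    return float(np.trapezoid(tpr, fpr))


def youden_threshold(data: LabeledScores) -> tuple[float, float, float]:
    """Cutoff maximizing J = sensitivity + specificity − 1.

    Candidates are midpoints between adjacent distinct sorted scores plus
    the two trivial cutoffs (everything / nothing predicted case, J = 0),
    so the result always matches an exhaustive search over all cutoffs
    (predicted case when score > t). Ties in J break toward the smallest
    threshold.
    """
    cases = data.case_scores
    controls = data.control_scores
    distinct = np.unique(data.scores)
    midpoints = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate(([distinct[0] - 1.0], midpoints, [distinct[-1]]))
    best = None
    for t in candidates:
        sens = float(np.mean(cases > t))
        spec = float(np.mean(controls <= t))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-15:
            best = (j, float(t), sens, spec)
    assert best is not None
    return best[1], best[2], best[3]


def evaluate_scores(data: LabeledScores) -> DiagnosticResult:
    """Full diagnostic evaluation: ROC curve, AUC and Youden operating point."""
    pts = roc_curve(data)
    t, sens, spec = youden_threshold(data)
    return DiagnosticResult(
        roc_points=pts, auc=auc(pts), threshold=t, sensitivity=sens, specificity=spec
    )


def stage_summary(counts: dict) -> pd.DataFrame:
    """Lesion-stage table (stage, count, percent to two decimals)."""
    items = list(counts.items())
    if any(c < 0 for _, c in items):
        raise ValueError("counts must be nonnegative")
    total = sum(c for _, c in items)
    if total <= 0:
        raise ValueError("total count must be positive")
    rows = [
        {"stage": s, "count": int(c), "percent": round(100.0 * c / total, 2)}
        for s, c in items
    ]
    return pd.DataFrame(rows, columns=["stage", "count", "percent"])


def compare_groups(a, b, alpha_normality: float = 0.05) -> tuple[float, float, str]:
    """Two-group comparison: Welch's t if both groups look normal, else rank-sum.

    Normality is a per-group Shapiro–Wilk test at ``alpha_normality``;
    groups too small to assess (n < 3) or degenerate (zero variance) fall
    back to the rank-sum branch. Returns (statistic, p_value, method).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")

    def looks_normal(x: np.ndarray) -> bool:
        if x.size < 3 or np.ptp(x) == 0:
            return False
        return stats.shapiro(x).pvalue > alpha_normality

    if looks_normal(a) and looks_normal(b):
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue), "welch_t"
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), "rank_sum"
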