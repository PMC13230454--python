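"""Segmentation metrics and method-agreement statistics.

Overlap metrics (Dice, IoU) and boundary metrics (Hausdorff, average
Hausdorff) score predicted LV regions against reference masks; the
agreement statistics (ICC, Bland-Altman, Spearman, ROC) compare
model-derived GLS against expert measurements.

Conventions: Dice/IoU of two empty masks is 1.0 and of one empty mask
0.0; Hausdorff distances are computed between foreground pixel centres
and are undefined when either foreground is empty; the ICC variant is
two-way mixed-effects, absolute-agreement, single-measurement
(ICC(A,1)); limits of agreement are +/-1.96 x SD of the paired
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import directed_hausdorff
from scipy.stats import spearmanr
from skimage.draw import polygon as _sk_polygon

from .contours import N_POINTS

#: reference range of normal LVGLS, percent
GLS_NORMAL_THRESHOLD = -18.0
GLS_IMPAIRED_THRESHOLD = -16.0

__all__ = [
    "AgreementReport",
    "contour_to_mask",
    "dice",
    "iou",
    "hausdorff",
    "avg_hausdorff",
    "icc_agreement",
    "bland_altman",
    "spearman",
    "roc_auc",
    "classify_lv_function",
    "agreement_report",
]


@dataclass
class AgreementReport:
    """Paired model-vs-reference statistics for one strain method."""

    n: int
    icc: float
    icc_ci: tuple
    bias: float
    loa: float
    spearman_rho: float
    auc: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# masks


def contour_to_mask(points: np.ndarray, shape) -> np.ndarray:
    """Rasterise a 49-point contour, closed by the basal segment.

    The polygon runs point 0 ... point 48 and closes with the straight
    basal segment back to point 0; pixels whose centres fall inside are
    foreground (even-odd rule, which also handles self-intersections).
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape != (N_POINTS, 2):
        raise ValueError(f"expected ({N_POINTS}, 2) contour")
    x, y = pts[:, 0], pts[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area < 0.5:  # degenerate (e.g. collinear) contour encloses no pixel
        return np.zeros(shape, dtype=bool)
    rr, cc = _sk_polygon(pts[:, 1], pts[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _check_masks(a, b):
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dice(a, b) -> float:
    """2|A∩B| / (|A|+|B|); both-empty = 1.0."""
    a, b = _check_masks(a, b)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def iou(a, b) -> float:
    """|A∩B| / |A∪B|; both-empty = 1.0."""
    a, b = _check_masks(a, b)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def _foreground(a, b):
    a, b = _check_masks(a, b)
    pa = np.argwhere(a).astype(float)
    pb = np.argwhere(b).astype(float)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("Hausdorff distances undefined for empty foreground")
    return pa, pb


def hausdorff(a, b) -> float:
    """Symmetric Hausdorff distance between foreground pixel centres."""
    pa, pb = _foreground(a, b)
    return float(max(directed_hausdorff(pa, pb)[0],
                     directed_hausdorff(pb, pa)[0]))


def avg_hausdorff(a, b) -> float:
    """Mean of the two directed mean nearest-neighbour distances."""
    pa, pb = _foreground(a, b)
    d_ab = cKDTree(pb).query(pa)[0].mean()
    d_ba = cKDTree(pa).query(pb)[0].mean()
    return float((d_ab + d_ba) / 2.0)


# ----------------------------------------------------------------------
# agreement statistics


def icc_agreement(x, y):
    """ICC(A,1) with its 95% CI for two paired raters/methods.

    Two-way mixed-effects, absolute-agreement, single-measurement
    intraclass correlation from the ANOVA mean squares (computed via
    pingouin); systematic offsets between methods lower the value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 pairs of equal length")
    if np.var(np.concatenate([x, y])) == 0:
        raise ValueError("ICC undefined for zero-variance data")
    import pingouin as pg

    n = len(x)
    df = pd.DataFrame({
        "subject": np.tile(np.arange(n), 2),
        "rater": np.repeat(["a", "b"], n),
        "score": np.concatenate([x, y]),
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        table = pg.intraclass_corr(df, targets="subject", raters="rater",
                                   ratings="score")
    row = table[table["Type"] == "ICC(A,1)"].iloc[0]
    icc = float(row["ICC"])
    lo, hi = (float(v) for v in row["CI95"])
    # a perfect-agreement sample has zero residual MS; its CI is degenerate
    lo = icc if not np.isfinite(lo) else lo
    hi = icc if not np.isfinite(hi) else hi
    return icc, (lo, hi)


def bland_altman(x, y):
    """(bias, loa): mean difference and 1.96 x sample SD of differences.

    Also returns the plotting data (pair means, differences) so callers
    can draw the classic plot.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need >= 2 pairs of equal length")
    diff = x - y
    bias = float(diff.mean())
    loa = float(1.96 * diff.std(ddof=1))
    return bias, loa, {"mean": (x + y) / 2.0, "diff": diff}


def spearman(x, y) -> float:
    """Rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 pairs of equal length")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman undefined for a constant vector")
    return float(spearmanr(x, y).statistic)


def classify_lv_function(expert_gls: float) -> str:
    """Label against the -16%/-18% reference range.

    > -16%: impaired; < -18%: normal; in between: borderline (excluded
    from either ROC arm).
    """
    if expert_gls > GLS_IMPAIRED_THRESHOLD:
        return "impaired"
    if expert_gls < GLS_NORMAL_THRESHOLD:
        return "normal"
    return "borderline"


def roc_auc(scores, labels) -> float:
    """AUC by the rank (Mann-Whitney) method; labels are 0/1."""
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _roc_arm(model, expert, arm: str) -> float | None:
    """AUC of one ROC analysis arm, borderline cases excluded."""
    cls = np.array([classify_lv_function(e) for e in expert])
    keep = cls != "borderline"
    if arm == "impaired":
        labels = (cls[keep] == "impaired").astype(int)
        scores = np.asarray(model)[keep]  # higher (less negative) = impaired
    else:
        labels = (cls[keep] == "normal").astype(int)
        scores = -np.asarray(model)[keep]
    try:
        return roc_auc(scores, labels)
    except ValueError:
        return None


def agreement_report(model_gls, expert_gls) -> AgreementReport:
    """All paired statistics for one model-vs-expert strain comparison."""
    model = np.asarray(model_gls, dtype=float)
    expert = np.asarray(expert_gls, dtype=float)
    icc, ci = icc_agreement(model, expert)
    bias, loa, _ = bland_altman(model, expert)
    rho = spearman(model, expert)
    auc = {arm: _roc_arm(model, expert, arm) for arm in ("impaired", "normal")}
    return AgreementReport(len(model), icc, ci, bias, loa, rho, auc)
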