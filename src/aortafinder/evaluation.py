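"""Evaluation machinery: confusion matrices, ROC/PR analysis, rank tests.

Covers both levels of assessment used for the detector: per-ROI (did the
forest assign each candidate the right class?) and per-scan (was each
vessel correctly detected and localized?), plus the threshold analysis
(ROC and precision-recall curves with Youden-J and F1 operating points)
and the nonparametric tests relating the QC probability to observer image
quality.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import NOT_VISIBLE, GroundTruth, ROILabel, circle_mask, dice_coefficient
from .detect import DetectionResult

__all__ = [
    "roi_confusion",
    "scan_detection_confusion",
    "RocPrResult",
    "roc_pr",
    "precision_baseline",
    "dsc_summary",
    "rank_tests",
]

#: Default per-vessel posterior operating thresholds for scan-level
#: detection (data-dependent; these maximize Youden's J on a large test
#: cohort and are exposed as configuration).
AA_THRESHOLD = 0.18
PDA_THRESHOLD = 0.09

_CLASS_ORDER = (ROILabel.NA, ROILabel.PDA, ROILabel.AA)


def roi_confusion(
    predicted: Sequence[ROILabel], actual: Sequence[ROILabel]
) -> tuple[np.ndarray, float]:
    """3x3 confusion matrix (rows predicted, cols actual) and error rate.

    Class order is (NA, PDA, AA); the error is the off-diagonal fraction.
    """
    predicted = list(predicted)
    actual = list(actual)
    if len(predicted) != len(actual):
        raise ValueError("label vectors must have equal length")
    idx = {c: i for i, c in enumerate(_CLASS_ORDER)}
    m = np.zeros((3, 3), dtype=int)
    for p, a in zip(predicted, actual):
        m[idx[ROILabel(p)], idx[ROILabel(a)]] += 1
    total = m.sum()
    error = float((total - np.trace(m)) / total) if total else 0.0
    return m, error


@dataclasses.dataclass
class VesselConfusion:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    dscs: list[float] = dataclasses.field(default_factory=list)  # TP cases

    @property
    def error(self) -> float:
        n = self.tp + self.tn + self.fp + self.fn
        return (self.fp + self.fn) / n if n else 0.0


def scan_detection_confusion(
    results: Mapping[str, DetectionResult],
    gts: Mapping[str, GroundTruth],
    shape: tuple[int, int],
    pixel_spacing_mm: tuple[float, float],
    dsc_threshold: float = 0.75,
    aa_threshold: float = AA_THRESHOLD,
    pda_threshold: float = PDA_THRESHOLD,
) -> dict[str, VesselConfusion]:
    """Per-vessel scan-level confusion over matched result/truth sets.

    A vessel is "detected" when its winning posterior reaches the vessel's
    operating threshold.  TP: visible, detected, Dice > ``dsc_threshold``
    against truth; FP: detected but the vessel is invisible or mislocated
    (Dice ≤ threshold); FN: visible but not detected; TN: invisible and
    not detected.
    """
    if set(results) != set(gts):
        raise ValueError("result and ground-truth scan sets differ")
    out = {"aa": VesselConfusion(), "pda": VesselConfusion()}
    for scan_id, res in results.items():
        gt = gts[scan_id]
        for vessel, thr in (("aa", aa_threshold), ("pda", pda_threshold)):
            entry = getattr(res, vessel)
            truth = getattr(gt, vessel)
            conf = out[vessel]
            detected = entry is not None and entry[1] >= thr
            if truth is NOT_VISIBLE:
                if detected:
                    conf.fp += 1
                else:
                    conf.tn += 1
                continue
            if not detected:
                conf.fn += 1
                continue
            d = dice_coefficient(
                circle_mask(entry[0], *shape, pixel_spacing_mm),
                circle_mask(truth, *shape, pixel_spacing_mm),
            )
            if d > dsc_threshold:
                conf.tp += 1
                conf.dscs.append(d)
            else:
                conf.fp += 1
    return out


@dataclasses.dataclass
class RocPrResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    precision: np.ndarray
    roc_auc: float
    pr_auc: float
    youden_threshold: float
    youden_j: float
    f1_threshold: float
    f1: float
    precision_baseline: float


def roc_pr(scores: Sequence[float], labels: Sequence[bool]) -> RocPrResult:
    """ROC and precision-recall analysis of a binary score.

    Sweeps the distinct observed scores (plus ±∞ endpoints, predicted
    positive meaning score ≥ threshold), computes trapezoidal AUCs, and
    returns the thresholds maximizing Youden's J = sensitivity +
    specificity − 1 and F1 = 2·precision·recall / (precision + recall).
    The precision-recall endpoint at recall 0 uses precision 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    thr = np.concatenate(([np.inf], np.unique(scores)[::-1], [-np.inf]))
    pred = scores[None, :] >= thr[:, None]
    tp = (pred & labels[None, :]).sum(axis=1)
    fp = (pred & ~labels[None, :]).sum(axis=1)
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 1.0)
    fpr = 1.0 - spec
    roc_auc = float(np.trapezoid(sens, fpr))
    pr_auc = float(np.trapezoid(prec, sens))
    j = sens + spec - 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(prec + sens > 0, 2 * prec * sens / np.maximum(prec + sens, 1e-300), 0.0)
    i_j = int(np.argmax(j))
    i_f1 = int(np.argmax(f1))
    return RocPrResult(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        roc_auc=roc_auc,
        pr_auc=pr_auc,
        youden_threshold=float(thr[i_j]),
        youden_j=float(j[i_j]),
        f1_threshold=float(thr[i_f1]),
        f1=float(f1[i_f1]),
        precision_baseline=n_pos / (n_pos + n_neg),
    )


def precision_baseline(labels: Sequence[bool]) -> float:
    """Positive prevalence: the horizontal reference of a PR curve."""
    labels = np.asarray(labels, dtype=bool)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    return float(labels.mean())


def dsc_summary(dscs: Sequence[float], threshold: float = 0.9) -> dict[str, float]:
    """Mean ± SD of true-positive Dice scores and the fraction ≥ threshold."""
    dscs = np.asarray(dscs, dtype=float)
    if dscs.size == 0:
        raise ValueError("no true positives to summarize")
    return {
        "mean": float(dscs.mean()),
        "sd": float(dscs.std()),
        "fraction_ge_threshold": float((dscs >= threshold).mean()),
    }


def rank_tests(groups: Mapping[str, Sequence[float]]) -> dict:
    """Kruskal-Wallis across groups plus Bonferroni-corrected pairwise tests.

    Groups are QC scores stratified by image quality.  Pairwise
    comparisons use the Mann-Whitney-Wilcoxon test (two-sided, tie
    corrected); Bonferroni multiplies each pairwise p by the number of
    comparisons, capped at 1.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 samples")
    h, p = stats.kruskal(*arrays.values())
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    pairwise = {}
    for a, b in pairs:
        u, p_pair = stats.mannwhitneyu(arrays[a], arrays[b], alternative="two-sided")
        pairwise[(a, b)] = {
            "U": float(u),
            "p": float(p_pair),
            "p_bonferroni": float(min(1.0, p_pair * m)),
        }
    return {"kruskal_H": float(h), "kruskal_p": float(p), "pairwise": pairwise}
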