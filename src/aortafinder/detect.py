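"""Best-candidate selection, the QC probability, and the rule-based baseline.

Per scan, the forest assigns each candidate a posterior over
{NA, PDA, AA}.  The detection keeps the candidate with the highest AA
posterior and, independently, the one with the highest PDA posterior.  The
product of the two winning posteriors is the scan's quality-control score:
confident detection of both vessels is only possible on a scan of usable
quality, so a low product flags the scan for human review.

The rule-based baseline reproduces the heuristic used before learned
classifiers: among candidate pairs, the ascending aorta must be bigger,
anterior and to the subject's right of the descending aorta, with centres
at least 18 mm apart.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .cht import CandidateROI
from .core import CircleROI

__all__ = ["DetectionResult", "select_best", "qc_flag", "rule_based_baseline"]

#: Default QC threshold: the operating point maximizing F1 for separating
#: usable from severely corrupted scans; 0.95 is the stricter preset.
QC_THRESHOLD = 0.75


@dataclasses.dataclass
class DetectionResult:
    """Best AA/PDA circles with posteriors and the combined QC decision."""

    aa: tuple[CircleROI, float] | None
    pda: tuple[CircleROI, float] | None
    qc_score: float
    qc_pass: bool
    posteriors: np.ndarray  # n_candidates x 3, columns (NA, PDA, AA)
    conflict: bool = False  # same candidate won both vessels

    def to_json(self) -> dict:
        def circ(entry):
            if entry is None:
                return None
            c, p = entry
            return {
                "row": c.centre_rc[0],
                "col": c.centre_rc[1],
                "radius_mm": c.radius_mm,
                "posterior": p,
            }

        return {
            "aa": circ(self.aa),
            "pda": circ(self.pda),
            "qc_score": self.qc_score,
            "qc_pass": self.qc_pass,
            "conflict": self.conflict,
        }


def select_best(
    candidates: Sequence[CandidateROI],
    posteriors: np.ndarray,
    qc_threshold: float = QC_THRESHOLD,
) -> DetectionResult:
    """Pick the maximum-posterior candidate for each vessel independently.

    The QC score is the product of the two winning posteriors (0 if there
    are no candidates).  If one candidate maximizes both posteriors the
    result carries a conflict flag — anatomically the two vessels can
    never coincide.
    """
    posteriors = np.asarray(posteriors, dtype=float)
    if len(candidates) == 0:
        return DetectionResult(
            aa=None, pda=None, qc_score=0.0, qc_pass=qc_flag(0.0, qc_threshold),
            posteriors=np.zeros((0, 3)),
        )
    if posteriors.shape != (len(candidates), 3):
        raise ValueError("posteriors must align with candidates (n x 3)")
    i_aa = int(np.argmax(posteriors[:, 2]))
    i_pda = int(np.argmax(posteriors[:, 1]))
    p_aa = float(posteriors[i_aa, 2])
    p_pda = float(posteriors[i_pda, 1])
    score = p_aa * p_pda
    return DetectionResult(
        aa=(candidates[i_aa].circle, p_aa),
        pda=(candidates[i_pda].circle, p_pda),
        qc_score=score,
        qc_pass=qc_flag(score, qc_threshold),
        posteriors=posteriors,
        conflict=i_aa == i_pda,
    )


def qc_flag(qc_score: float, threshold: float = QC_THRESHOLD) -> bool:
    """True when the scan passes QC; the boundary value itself passes."""
    if not (0.0 <= qc_score <= 1.0):
        raise ValueError("qc_score must lie in [0, 1]")
    return qc_score >= threshold


def rule_based_baseline(
    candidates: Sequence[CandidateROI],
    pixel_spacing_mm: tuple[float, float],
    min_distance_mm: float = 18.0,
) -> tuple[CircleROI | None, CircleROI | None]:
    """Heuristic AA/PDA assignment from candidate geometry alone.

    Scans all ordered candidate pairs for one where the AA is strictly
    bigger, anterior (smaller row) and to the subject's right (smaller
    col) of the PDA with centres at least 18 mm apart, and returns the
    admissible pair with the highest summed Hough peak magnitude.
    """
    best = None
    best_score = -np.inf
    for a in candidates:
        for p in candidates:
            if a is p:
                continue
            ca, cp = a.circle, p.circle
            if not (ca.radius_mm > cp.radius_mm):
                continue
            if not (ca.centre_rc[0] < cp.centre_rc[0] and ca.centre_rc[1] < cp.centre_rc[1]):
                continue
            d = math.hypot(
                (ca.centre_rc[0] - cp.centre_rc[0]) * pixel_spacing_mm[0],
                (ca.centre_rc[1] - cp.centre_rc[1]) * pixel_spacing_mm[1],
            )
            if d < min_distance_mm:
                continue
            score = a.cht_metric + p.cht_metric
            if score > best_score:
                best_score = score
                best = (ca, cp)
    if best is None:
        return None, None
    return best
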