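"""Core domain types and geometry shared by every pipeline stage.

The package works on transverse cine cardiac MR series: a stack of 2-D
frames over one cardiac cycle in which the ascending aorta (AA) and the
proximal descending aorta (PDA) appear as bright, pulsatile, near-circular
cross-sections.  This module holds the types those stages exchange
(:class:`CineSeries`, :class:`CircleROI`, :class:`GroundTruth`,
:class:`ROILabel`), the Dice similarity coefficient used both to label
training candidates and to score detections, circle rasterization, and the
annotation / model file I/O.

Coordinate conventions
----------------------
Images are indexed ``(row, col)``, 0-based.  Rows increase posteriorly and
columns increase toward the subject's left (the radiological transverse
display convention), so "anterior" means a smaller row index and "the
subject's right" a smaller column index.  Circle centres are stored in
pixels of the grid the circle lives on; radii are stored in millimetres and
converted through the pixel spacing.
"""

from __future__ import annotations

import dataclasses
import json
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping

import joblib
import numpy as np

__all__ = [
    "NOT_VISIBLE",
    "CineSeries",
    "CircleROI",
    "GroundTruth",
    "ROILabel",
    "circle_mask",
    "dice_coefficient",
    "read_annotations",
    "write_annotations",
    "save_model",
    "load_model",
]

#: Radius search range of the circle detector, in millimetres.
RADIUS_RANGE_MM = (6.0, 36.0)


class _NotVisible:
    """Sentinel for a vessel an observer could not identify on the slice.

    Distinct from any circle: a scan where the AA is obscured by artefact
    or the slice misses the aortic arch has no AA annotation at all, which
    is different from an annotation with zero radius.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "NOT_VISIBLE"

    def __reduce__(self):
        return (_NotVisible, ())


NOT_VISIBLE = _NotVisible()


class ROILabel(IntEnum):
    """Class of a candidate ROI: not-aorta, proximal descending, ascending."""

    NA = 1
    PDA = 2
    AA = 3


@dataclasses.dataclass(frozen=True)
class CircleROI:
    """A circular region of interest: centre in grid pixels, radius in mm."""

    centre_rc: tuple[float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.radius_mm) or self.radius_mm <= 0:
            raise ValueError(f"radius_mm must be positive, got {self.radius_mm}")

    def centre_mm(self, pixel_spacing_mm: tuple[float, float]) -> tuple[float, float]:
        """Centre coordinates in millimetres from the grid origin."""
        return (
            self.centre_rc[0] * pixel_spacing_mm[0],
            self.centre_rc[1] * pixel_spacing_mm[1],
        )


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Observer annotation for one scan.

    ``aa`` and ``pda`` are either a :class:`CircleROI` (time-averaged lumen
    circle) or :data:`NOT_VISIBLE`.  ``iq`` is the observer image-quality
    score in [0, 3]: 0 unusable, 1 major issues, 2 minor issues, 3 good.
    """

    aa: CircleROI | _NotVisible
    pda: CircleROI | _NotVisible
    iq: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.iq <= 3.0):
            raise ValueError(f"iq must lie in [0, 3], got {self.iq}")


@dataclasses.dataclass
class CineSeries:
    """One cine acquisition: ``pixels`` has shape (rows, cols, frames)."""

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    scan_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be rows x cols x frames")
        if self.pixels.shape[2] < 2:
            raise ValueError("a cine series needs at least 2 frames")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")
        sr, sc = self.pixel_spacing_mm
        if sr <= 0 or sc <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    def frame(self, index: int) -> np.ndarray:
        return self.pixels[:, :, index]


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) of two binary masks.

    Measures spatial overlap in [0, 1]; 1 for identical non-empty masks,
    0 for disjoint masks.  Two empty masks score 0 by convention — absence
    of both prediction and truth is bookkept separately via
    :data:`NOT_VISIBLE`, never through mask overlap.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 0.0
    return 2.0 * int(np.logical_and(a, b).sum()) / total


def circle_mask(
    roi: CircleROI,
    rows: int,
    cols: int,
    pixel_spacing_mm: tuple[float, float] | float,
) -> np.ndarray:
    """Rasterize a circle: pixel is set iff its centre lies within the radius.

    The test is Euclidean in millimetres, so anisotropic pixel spacing
    yields the correct physical disc.
    """
    if np.isscalar(pixel_spacing_mm):
        spacing = (float(pixel_spacing_mm), float(pixel_spacing_mm))
    else:
        spacing = (float(pixel_spacing_mm[0]), float(pixel_spacing_mm[1]))
    if roi.radius_mm <= 0:
        raise ValueError("radius must be positive")
    r0, c0 = roi.centre_rc
    rr = (np.arange(rows) - r0) * spacing[0]
    cc = (np.arange(cols) - c0) * spacing[1]
    dist2 = rr[:, None] ** 2 + cc[None, :] ** 2
    return dist2 <= roi.radius_mm**2


# ---------------------------------------------------------------------------
# Annotation I/O: JSON lines, one object per scan.  The null value is the
# on-disk form of NOT_VISIBLE, which keeps it unambiguous (a CSV would need
# a magic number).


def _circle_to_json(c: CircleROI | _NotVisible) -> dict | None:
    if c is NOT_VISIBLE:
        return None
    return {"row": c.centre_rc[0], "col": c.centre_rc[1], "radius_mm": c.radius_mm}


def _circle_from_json(obj, scan_id: str, field: str) -> CircleROI | _NotVisible:
    if obj is None:
        return NOT_VISIBLE
    try:
        return CircleROI((float(obj["row"]), float(obj["col"])), float(obj["radius_mm"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"scan {scan_id!r}: malformed {field} annotation: {exc}") from exc


def write_annotations(path: str | Path, annotations: Mapping[str, GroundTruth]) -> None:
    """Write scan annotations as JSON lines (one object per scan)."""
    with open(path, "w") as fh:
        for scan_id, gt in annotations.items():
            rec = {
                "scan_id": scan_id,
                "aa": _circle_to_json(gt.aa),
                "pda": _circle_to_json(gt.pda),
                "iq": gt.iq,
            }
            fh.write(json.dumps(rec) + "\n")


def read_annotations(path: str | Path) -> dict[str, GroundTruth]:
    """Read JSON-lines annotations; raises naming the offending scan/field."""
    out: dict[str, GroundTruth] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"line {line_no}: invalid JSON: {exc}") from exc
            scan_id = rec.get("scan_id")
            if not isinstance(scan_id, str):
                raise ValueError(f"line {line_no}: missing or non-string scan_id")
            if "iq" not in rec:
                raise ValueError(f"scan {scan_id!r}: missing field iq")
            iq = float(rec["iq"])
            if not (0.0 <= iq <= 3.0):
                raise ValueError(f"scan {scan_id!r}: iq {iq} outside [0, 3]")
            gt = GroundTruth(
                aa=_circle_from_json(rec.get("aa"), scan_id, "aa"),
                pda=_circle_from_json(rec.get("pda"), scan_id, "pda"),
                iq=iq,
            )
            out[scan_id] = gt
    return out


# ---------------------------------------------------------------------------
# Model archive.  One file holding the trained forest plus everything needed
# to reproduce and audit it: canonical feature names, priors, OOB statistics
# and the training seed.


def save_model(path: str | Path, model) -> None:
    joblib.dump(model, path)


def load_model(path: str | Path):
    return joblib.load(path)
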