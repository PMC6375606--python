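"""Foreground segmentation and the subject-specific reference frame.

First stage of the pipeline: segment the axial body cross-section from the
dark background, interpolate image and mask to a standard grid, derive the
body reference frame (intensity-weighted centroid plus diagonal axes of a
square box sized by the anterior-posterior body extent), and define the
elliptical core of the body inside which circular structures are searched.
Because the reference frame is anchored to the body itself, everything
derived from it is independent of where the body sits in the field of view.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage import filters, morphology, transform

__all__ = [
    "BodyFrame",
    "EllipseRegion",
    "PreprocessConfig",
    "segment_foreground",
    "to_standard_grid",
    "body_reference_frame",
    "search_region",
]


@dataclasses.dataclass
class PreprocessConfig:
    """Tunables of the segmentation / standardization stage.

    ``sigma_px`` and ``close_radius_px`` apply on the original acquisition
    grid (segmentation precedes interpolation); ``ellipse_factors`` are the
    fractions of the anterior-posterior body extent assigned to the
    (AP, LR) axes of the search ellipse.
    """

    sigma_px: float = 5.0
    close_radius_px: int = 10
    standard_shape: tuple[int, int] = (480, 392)
    ellipse_factors: tuple[float, float] = (0.6, 0.7)
    detection_frame: int = 0


@dataclasses.dataclass(frozen=True)
class BodyFrame:
    """Body-anchored reference frame on the standard grid.

    ``diag_axes`` are the two orthonormal unit vectors at ±45° to the image
    rows; spatial ROI coordinates are projections onto these diagonals,
    normalized by half the box side.
    """

    centroid_rc: tuple[float, float]
    box_side_px: float
    diag_axes: tuple[tuple[float, float], tuple[float, float]] = (
        (np.sqrt(0.5), np.sqrt(0.5)),
        (-np.sqrt(0.5), np.sqrt(0.5)),
    )


@dataclasses.dataclass(frozen=True)
class EllipseRegion:
    centre_rc: tuple[float, float]
    semi_axis_ap_px: float
    semi_axis_lr_px: float

    def contains(self, rc: tuple[float, float]) -> bool:
        u = (rc[0] - self.centre_rc[0]) / self.semi_axis_ap_px
        v = (rc[1] - self.centre_rc[1]) / self.semi_axis_lr_px
        return u * u + v * v <= 1.0


def segment_foreground(frame: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Segment the body from the background of a single frame.

    Gaussian smoothing (sigma = 5 px), Otsu threshold, largest connected
    component, morphological closing with a circular structuring element
    (radius 10 px) and finally the convex hull.  The result is a convex
    mask covering the thorax cross-section.  Invariant to affine intensity
    rescaling (a property of the Otsu threshold).
    """
    config = config or PreprocessConfig()
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if np.ptp(frame) == 0:
        raise ValueError("constant frame: foreground threshold is undefined")
    smoothed = ndimage.gaussian_filter(frame, sigma=config.sigma_px)
    mask = smoothed > filters.threshold_otsu(smoothed)
    labels, n_lab = ndimage.label(mask)
    if n_lab == 0:  # pragma: no cover - cannot happen after a valid Otsu split
        raise ValueError("no foreground component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_lab + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    mask = morphology.closing(mask, morphology.disk(config.close_radius_px))
    return morphology.convex_hull_image(mask)


def to_standard_grid(
    frame: np.ndarray,
    mask: np.ndarray,
    pixel_spacing_mm: tuple[float, float],
    config: PreprocessConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float], tuple[float, float]]:
    """Interpolate frame (bilinear) and mask (nearest) to the standard grid.

    Returns ``(frame', mask', pixel_spacing', zoom_factors)`` where the
    spacing is rescaled by the true per-axis zoom factors so millimetre
    geometry stays exact.
    """
    config = config or PreprocessConfig()
    target = config.standard_shape
    if frame.shape != mask.shape:
        raise ValueError("frame and mask shapes differ")
    if frame.shape[0] > target[0] or frame.shape[1] > target[1]:
        raise ValueError("input larger than the standard grid")
    zoom = (target[0] / frame.shape[0], target[1] / frame.shape[1])
    frame_std = transform.resize(
        np.asarray(frame, dtype=float), target, order=1, anti_aliasing=False,
        preserve_range=True,
    )
    mask_std = transform.resize(
        np.asarray(mask, dtype=bool), target, order=0, anti_aliasing=False,
        preserve_range=True,
    ).astype(bool)
    spacing = (pixel_spacing_mm[0] / zoom[0], pixel_spacing_mm[1] / zoom[1])
    return frame_std, mask_std, spacing, zoom


def body_reference_frame(frame_std: np.ndarray, mask_std: np.ndarray) -> BodyFrame:
    """Centroid and box side of the body on the standard grid.

    The centroid is weighted by image intensity restricted to the body
    mask; the box side is the maximum extent of the mask along the
    anterior-posterior (row) axis.  Translating frame and mask together
    translates the centroid by the same amount.
    """
    mask_std = np.asarray(mask_std, dtype=bool)
    if not mask_std.any():
        raise ValueError("empty body mask")
    w = np.asarray(frame_std, dtype=float) * mask_std
    total = w.sum()
    if total <= 0:
        raise ValueError("non-positive total intensity inside the mask")
    rows_idx, cols_idx = np.nonzero(mask_std)
    centroid = (
        float((w * np.arange(w.shape[0])[:, None]).sum() / total),
        float((w * np.arange(w.shape[1])[None, :]).sum() / total),
    )
    box_side = float(rows_idx.max() - rows_idx.min() + 1)
    return BodyFrame(centroid_rc=centroid, box_side_px=box_side)


def search_region(
    body: BodyFrame, config: PreprocessConfig | None = None
) -> EllipseRegion:
    """Elliptical core of the body in which candidate circles are accepted.

    Centred on the intensity-weighted centroid, with full axes equal to
    (0.6, 0.7) times the anterior-posterior body extent: 0.6 on the AP
    (row) axis and 0.7 left-right, so the ellipse hugs the mediastinum and
    excludes the chest wall and spine.
    """
    config = config or PreprocessConfig()
    f_ap, f_lr = config.ellipse_factors
    return EllipseRegion(
        centre_rc=body.centroid_rc,
        semi_axis_ap_px=f_ap * body.box_side_px / 2.0,
        semi_axis_lr_px=f_lr * body.box_side_px / 2.0,
    )
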