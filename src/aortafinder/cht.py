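"""Phase-coded circular Hough transform (CHT) for bright-blood lumina.

Strong Sobel edges vote into a complex accumulator: each edge pixel casts,
for every radius r on a 1-pixel ladder within the search range, a
unit-magnitude vote ``exp(i φ(r))`` at the point r millimetres along the
gradient direction.  The phase code ``φ(r) = 2π (r − r_min)/(r_max − r_min + Δ)``
is linear and invertible, so the radius of a circle can be read back from
the phase of its accumulator peak while all radii share a single 2-D
array.  Votes are cast both along and against the gradient so that rims
with locally inverted contrast (artefacted vessels) still vote towards
their centre.  Peaks of the magnitude-normalized accumulator inside the
body-core ellipse become candidate ROIs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage import filters

from .core import CircleROI
from .preprocess import EllipseRegion

__all__ = [
    "CHTConfig",
    "CHTAccumulator",
    "CandidateROI",
    "gradient_edges",
    "phase_coded_accumulate",
    "find_candidates",
]


@dataclasses.dataclass
class CHTConfig:
    r_min_mm: float = 6.0
    r_max_mm: float = 36.0
    min_magnitude: float = 0.1
    smooth_sigma: float = 2.0


@dataclasses.dataclass
class CHTAccumulator:
    """Complex vote array plus the phase code needed to decode radii.

    ``grid`` holds the smoothed, magnitude-normalized votes used for peak
    detection; ``raw`` keeps the unsmoothed vote sums, from which radii
    are decoded.  Smoothing mixes the phases of neighbouring cells, and
    near the lower end of the radius ladder that mix is one-sided (there
    are no votes below ``r_min``), which would bias small decoded radii
    upward by up to a millimetre.
    """

    grid: np.ndarray
    r_min_mm: float
    r_max_mm: float
    step_mm: float
    raw: np.ndarray | None = None

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.grid)

    def decode_radius(self, rc: tuple[int, int]) -> float:
        """Radius (mm) encoded in the accumulator phase at a peak."""
        source = self.raw if self.raw is not None and self.raw[rc] != 0 else self.grid
        phase = float(np.angle(source[rc])) % (2 * np.pi)
        span = self.r_max_mm - self.r_min_mm + self.step_mm
        r = self.r_min_mm + phase / (2 * np.pi) * span
        return float(np.clip(r, self.r_min_mm, self.r_max_mm))


@dataclasses.dataclass(frozen=True)
class CandidateROI:
    circle: CircleROI
    cht_metric: float


def gradient_edges(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strong-edge mask and gradient direction field of a frame.

    Gradient by Sobel convolution; edges kept where the gradient magnitude
    exceeds its Otsu threshold.  Directions are ``atan2(g_row, g_col)``,
    i.e. the angle of the (row, col) gradient measured from the +col axis.
    """
    frame = np.asarray(frame, dtype=float)
    if np.ptp(frame) == 0:
        raise ValueError("constant frame has no edges")
    g_r = ndimage.sobel(frame, axis=0)
    g_c = ndimage.sobel(frame, axis=1)
    mag = np.hypot(g_r, g_c)
    edges = mag > filters.threshold_otsu(mag)
    directions = np.arctan2(g_r, g_c)
    return edges, directions


def phase_coded_accumulate(
    edges: np.ndarray,
    directions: np.ndarray,
    pixel_spacing_mm: tuple[float, float],
    config: CHTConfig | None = None,
) -> CHTAccumulator:
    """Cast phase-coded votes for every edge pixel and every ladder radius.

    The radius ladder steps by one grid pixel (the mean in-plane spacing);
    finer steps would exceed the phase resolution of the accumulator.  The
    accumulator is smoothed (sigma = 2 px, real and imaginary parts
    separately) so that one coherent peak survives per circular structure,
    then its magnitude is normalized to a maximum of 1.
    """
    config = config or CHTConfig()
    if config.r_min_mm >= config.r_max_mm:
        raise ValueError("r_min must be below r_max")
    edges = np.asarray(edges, dtype=bool)
    shape = edges.shape
    step_mm = float(np.mean(pixel_spacing_mm))
    radii = np.arange(config.r_min_mm, config.r_max_mm + 1e-9, step_mm)
    acc = np.zeros(shape, dtype=complex)

    er, ec = np.nonzero(edges)
    if er.size == 0:
        return CHTAccumulator(acc, config.r_min_mm, config.r_max_mm, step_mm, raw=acc.copy())
    theta = directions[er, ec]
    u_r = np.sin(theta)
    u_c = np.cos(theta)
    span = config.r_max_mm - config.r_min_mm + step_mm
    phases = 2 * np.pi * (radii - config.r_min_mm) / span
    votes = np.exp(1j * phases)

    flat = np.zeros(shape[0] * shape[1], dtype=complex)
    for sign in (1.0, -1.0):
        # vote positions: edge pixel displaced r mm along ±gradient
        rr = np.rint(er[:, None] + sign * radii[None, :] * u_r[:, None] / pixel_spacing_mm[0])
        cc = np.rint(ec[:, None] + sign * radii[None, :] * u_c[:, None] / pixel_spacing_mm[1])
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        idx = (rr[ok].astype(np.intp) * shape[1] + cc[ok].astype(np.intp))
        np.add.at(flat, idx, np.broadcast_to(votes, rr.shape)[ok])
    raw = flat.reshape(shape)

    if config.smooth_sigma > 0:
        acc = ndimage.gaussian_filter(raw.real, config.smooth_sigma) + 1j * ndimage.gaussian_filter(
            raw.imag, config.smooth_sigma
        )
    else:
        acc = raw.copy()
    peak = np.abs(acc).max()
    if peak > 0:
        acc = acc / peak
    return CHTAccumulator(acc, config.r_min_mm, config.r_max_mm, step_mm, raw=raw)


def _subpixel(mag: np.ndarray, r: int, c: int, axis: int) -> float:
    """Parabolic sub-pixel offset of a peak along one axis, clamped to ±0.5."""
    if axis == 0:
        if r == 0 or r == mag.shape[0] - 1:
            return 0.0
        lo, mid, hi = mag[r - 1, c], mag[r, c], mag[r + 1, c]
    else:
        if c == 0 or c == mag.shape[1] - 1:
            return 0.0
        lo, mid, hi = mag[r, c - 1], mag[r, c], mag[r, c + 1]
    denom = lo - 2 * mid + hi
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (lo - hi) / denom, -0.5, 0.5))


def find_candidates(
    acc: CHTAccumulator,
    region: EllipseRegion | None = None,
    min_magnitude: float = 0.1,
) -> list[CandidateROI]:
    """Local accumulator maxima above threshold, restricted to the region.

    Maxima are 8-neighbourhood peaks of the magnitude; plateau ties keep
    the smallest (row, col) pixel.  Peak centres are refined to sub-pixel
    precision by a separable parabolic fit of the magnitude (a 1-pixel
    centre error already costs ~0.06 Dice on a 9 mm vessel).  Concentric
    and overlapping candidates are deliberately not suppressed — the
    classifier downstream handles near-duplicates.  Result is sorted by
    descending peak magnitude.
    """
    mag = acc.magnitude
    if mag.max() == 0:
        return []
    local_max = mag == ndimage.maximum_filter(mag, size=3, mode="constant")
    local_max &= mag > min_magnitude
    # collapse plateaus to their lexicographically smallest pixel
    labels, n_lab = ndimage.label(local_max)
    cands: list[CandidateROI] = []
    for lab in range(1, n_lab + 1):
        rr, cc = np.nonzero(labels == lab)
        order = np.lexsort((cc, rr))
        r, c = int(rr[order[0]]), int(cc[order[0]])
        if region is not None and not region.contains((r, c)):
            continue
        radius = acc.decode_radius((r, c))
        cands.append(
            CandidateROI(
                circle=CircleROI(
                    centre_rc=(r + _subpixel(mag, r, c, 0), c + _subpixel(mag, r, c, 1)),
                    radius_mm=radius,
                ),
                cht_metric=float(mag[r, c]),
            )
        )
    cands.sort(key=lambda c: (-c.cht_metric, c.circle.centre_rc))
    return cands
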