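"""The 18 local features extracted for every candidate ROI.

Each candidate circle is described by an ordered 18-vector of interpretable
features, named A-R in canonical order:

==  ==================  ==============================================
A   diagBodyRFcentreX   ROI centre on the first body-frame diagonal
B   diagBodyRFcentreY   ROI centre on the second body-frame diagonal
C   normDistMask        mean normalized distance-to-body-boundary
D   intensityMean       mean ROI intensity
E   intensityVar        ROI intensity variance
F   intensitySkewness   ROI intensity skewness
G   intensityKurtosis   ROI intensity kurtosis (non-excess)
H   imageEntropy        Shannon entropy of the 256-bin ROI histogram
I   roiCorrelation      2-D correlation of the ROI patch with its circle
J   SIFTorientation     dominant gradient orientation at the ROI scale
K   MPmaskDSC           overlap with circles found on the motion map
L   CHTmetric           normalized Hough peak magnitude
M   CHTradius           Hough-estimated radius (mm)
N   MSERregions         number of maximally stable extremal regions
O   MSERmaskDSC         best MSER-vs-ROI Dice overlap
P   MSERnotOverlap      fraction of the best MSER outside the ROI
Q   MSERsolidity        convexity of the best MSER
R   MSEReccentricity    eccentricity of the best MSER's moment ellipse
==  ==================  ==============================================

Spatial features are measured in the body reference frame so they are
independent of where the body sits in the field of view.  The motion
feature exploits that the aortic wall distends and recoils once per
cardiac cycle, which no static structure does.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage import measure

from .cht import CandidateROI, CHTAccumulator, CHTConfig, find_candidates, phase_coded_accumulate
from .core import CineSeries, CircleROI, circle_mask, dice_coefficient
from .preprocess import BodyFrame

__all__ = [
    "FEATURE_NAMES",
    "FeatureConfig",
    "spatial_features",
    "histogram_features",
    "roi_correlation",
    "sift_orientation",
    "motion_periodicity_map",
    "motion_periodicity_circles",
    "motion_periodicity_feature",
    "mser_features",
    "extract_feature_vector",
]

FEATURE_NAMES = (
    "diagBodyRFcentreX",
    "diagBodyRFcentreY",
    "normDistMask",
    "intensityMean",
    "intensityVar",
    "intensitySkewness",
    "intensityKurtosis",
    "imageEntropy",
    "roiCorrelation",
    "SIFTorientation",
    "MPmaskDSC",
    "CHTmetric",
    "CHTradius",
    "MSERregions",
    "MSERmaskDSC",
    "MSERnotOverlap",
    "MSERsolidity",
    "MSEReccentricity",
)


@dataclasses.dataclass
class FeatureConfig:
    """Tunables of the feature extractors.

    ``mp_threshold`` is the minimum fraction of non-DC temporal power the
    cardiac-frequency harmonic must carry for a voxel to count as
    periodically moving; ``mser_delta_frac`` is the intensity step between
    level sets as a fraction of the window maximum; ``mser_max_variation``
    is the maximum relative area change for a region to count as stable.
    """

    entropy_bins: int = 256
    sift_bins: int = 36
    sift_sigma_factor: float = 1.5
    mp_threshold: float = 0.3
    mser_delta_frac: float = 0.01
    mser_max_variation: float = 0.5
    mser_min_area_px: int = 9
    mser_window_factor: float = 6.0


# ---------------------------------------------------------------------------
# Spatial features (A, B, C)


def spatial_features(
    roi: CircleROI,
    body: BodyFrame,
    body_mask: np.ndarray,
    pixel_spacing_mm: tuple[float, float],
    edt: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """ROI centre in the diagonal body frame plus normalized boundary depth.

    A and B are the projections of (centre − centroid) onto the two
    diagonal axes, normalized by half the box side; C is the mean, over the
    ROI disc, of the Euclidean distance transform of the body mask
    normalized by its image-wide maximum (≈0 at the boundary, ≈1 at the
    deepest interior point).
    """
    body_mask = np.asarray(body_mask, dtype=bool)
    if not body_mask.any():
        raise ValueError("empty body mask")
    d = np.array(roi.centre_rc) - np.array(body.centroid_rc)
    half = body.box_side_px / 2.0
    ax0, ax1 = np.array(body.diag_axes[0]), np.array(body.diag_axes[1])
    a = float(d @ ax0 / half)
    b = float(d @ ax1 / half)
    if edt is None:
        edt = ndimage.distance_transform_edt(body_mask)
    m = edt.max()
    disc = circle_mask(roi, *body_mask.shape, pixel_spacing_mm)
    if m == 0 or not disc.any():
        return a, b, 0.0
    c = float(edt[disc].mean() / m)
    return a, b, c


# ---------------------------------------------------------------------------
# Histogram features (D-H)


def histogram_features(
    values: np.ndarray,
    hist_range: tuple[float, float] | None = None,
    n_bins: int = 256,
) -> tuple[float, float, float, float, float]:
    """Mean, variance, skewness, kurtosis and Shannon entropy of ROI pixels.

    Kurtosis is the raw fourth standardized moment (3 for a Gaussian).
    Entropy uses the normalized ``n_bins``-bin histogram over
    ``hist_range`` (default: the sample's own range) with 0·log0 = 0.
    Constant input takes the degenerate convention F = G = H = 0.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need at least 2 pixels")
    mean = float(values.mean())
    var = float(values.var())
    if var == 0:
        skew = kurt = 0.0
    else:
        z = (values - mean) / np.sqrt(var)
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
    if hist_range is None:
        hist_range = (float(values.min()), float(values.max()))
    if hist_range[0] == hist_range[1]:
        entropy = 0.0
    else:
        hist, _ = np.histogram(values, bins=n_bins, range=hist_range)
        p = hist / hist.sum()
        p = p[p > 0]
        entropy = float(-(p * np.log2(p)).sum())
    return mean, var, skew, kurt, entropy


# ---------------------------------------------------------------------------
# Shape features (I, J)


def _square_patch(frame: np.ndarray, roi: CircleROI, radius_px: float) -> tuple[slice, slice]:
    r0, c0 = roi.centre_rc
    half = max(1, int(round(radius_px)))
    rs = slice(max(0, int(round(r0)) - half), min(frame.shape[0], int(round(r0)) + half + 1))
    cs = slice(max(0, int(round(c0)) - half), min(frame.shape[1], int(round(c0)) + half + 1))
    return rs, cs


def roi_correlation(
    frame: np.ndarray, roi: CircleROI, pixel_spacing_mm: tuple[float, float]
) -> float:
    """Pearson correlation of the ROI patch with its own circle mask.

    The patch is the square of side 2·radius around the centre.  A bright
    circular lumen on darker surroundings correlates strongly with the
    rasterized disc; a zero-variance patch is flagged as 0.
    """
    radius_px = roi.radius_mm / float(np.mean(pixel_spacing_mm))
    rs, cs = _square_patch(frame, roi, radius_px)
    patch = np.asarray(frame, dtype=float)[rs, cs]
    disc = circle_mask(roi, *frame.shape, pixel_spacing_mm)[rs, cs].astype(float)
    if patch.std() == 0 or disc.std() == 0:
        return 0.0
    return float(np.corrcoef(patch.ravel(), disc.ravel())[0, 1])


def sift_orientation(
    frame: np.ndarray,
    centre_rc: tuple[float, float],
    scale_px: float,
    n_bins: int = 36,
    sigma_factor: float = 1.5,
) -> float:
    """Dominant local gradient orientation at the ROI scale, in [0, 2π).

    Orientation histogram with ``n_bins`` bins over 2π, each gradient pixel
    weighted by its magnitude times a Gaussian window of SD = 1.5·scale
    centred on the ROI.  Returns the centre angle of the maximal bin; a
    gradient-free window is flagged as 0.
    """
    if scale_px < 1:
        raise ValueError("scale must be at least 1 px")
    frame = np.asarray(frame, dtype=float)
    sigma = sigma_factor * scale_px
    half = int(np.ceil(3 * sigma))
    r0, c0 = centre_rc
    rs = slice(max(0, int(round(r0)) - half), min(frame.shape[0], int(round(r0)) + half + 1))
    cs = slice(max(0, int(round(c0)) - half), min(frame.shape[1], int(round(c0)) + half + 1))
    patch = frame[rs, cs]
    if patch.size < 4 or np.ptp(patch) == 0:
        return 0.0
    g_r = ndimage.sobel(patch, axis=0)
    g_c = ndimage.sobel(patch, axis=1)
    mag = np.hypot(g_r, g_c)
    if mag.max() == 0:
        return 0.0
    rr = np.arange(rs.start, rs.stop)[:, None] - r0
    cc = np.arange(cs.start, cs.stop)[None, :] - c0
    w = np.exp(-(rr**2 + cc**2) / (2 * sigma**2))
    angles = np.mod(np.arctan2(g_r, g_c), 2 * np.pi)
    bins = np.minimum((angles / (2 * np.pi) * n_bins).astype(int), n_bins - 1)
    hist = np.bincount(bins.ravel(), weights=(mag * w).ravel(), minlength=n_bins)
    if hist.max() == 0:
        return 0.0
    j = int(np.argmax(hist))
    return float((j + 0.5) * 2 * np.pi / n_bins)


# ---------------------------------------------------------------------------
# Motion periodicity (K)


def motion_periodicity_map(
    stack: np.ndarray, threshold: float = 0.3
) -> np.ndarray:
    """Binary map of boundary voxels moving at the cardiac frequency.

    Per voxel, the discrete Fourier transform of the intensity time series
    is taken; the voxel is marked periodic if, DC excluded, the dominant
    harmonic is 1 cycle/series and carries more than ``threshold`` of the
    non-DC power.  The marked set is then boundary-filtered (marked voxels
    with at least one unmarked 4-neighbour), leaving rings around
    pulsating structures.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[2] < 8:
        raise ValueError("need a rows x cols x frames stack with >= 8 frames")
    spec = np.fft.rfft(stack, axis=2)
    power = np.abs(spec) ** 2
    non_dc = power[:, :, 1:]
    total = non_dc.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac1 = np.where(total > 0, non_dc[:, :, 0] / np.where(total > 0, total, 1), 0.0)
    dominant = non_dc.argmax(axis=2) == 0
    marked = dominant & (frac1 > threshold) & (total > 0)
    interior = ndimage.binary_erosion(
        marked, structure=ndimage.generate_binary_structure(2, 1)
    )
    return marked & ~interior


def motion_periodicity_circles(
    mp_map: np.ndarray,
    pixel_spacing_mm: tuple[float, float],
    cht_config: CHTConfig | None = None,
) -> list[CandidateROI]:
    """Circles fitted to the motion-periodicity map by the phase-coded CHT."""
    mp_map = np.asarray(mp_map, dtype=bool)
    if not mp_map.any():
        return []
    smooth = ndimage.gaussian_filter(mp_map.astype(float), 1.0)
    g_r = ndimage.sobel(smooth, axis=0)
    g_c = ndimage.sobel(smooth, axis=1)
    directions = np.arctan2(g_r, g_c)
    acc = phase_coded_accumulate(mp_map, directions, pixel_spacing_mm, cht_config)
    return find_candidates(acc, region=None, min_magnitude=0.1)


def motion_periodicity_feature(
    series_std: np.ndarray,
    roi: CircleROI,
    pixel_spacing_mm: tuple[float, float],
    threshold: float = 0.3,
    mp_circles: list[CandidateROI] | None = None,
) -> float:
    """Best Dice overlap between the candidate and any motion-map circle.

    0 for a temporally constant series or when no circular structure is
    found on the motion map.  ``mp_circles`` may be precomputed once per
    series and shared across candidates.
    """
    rows, cols = series_std.shape[:2]
    if mp_circles is None:
        mp = motion_periodicity_map(series_std, threshold)
        mp_circles = motion_periodicity_circles(mp, pixel_spacing_mm)
    if not mp_circles:
        return 0.0
    roi_disc = circle_mask(roi, rows, cols, pixel_spacing_mm)
    best = 0.0
    for c in mp_circles:
        disc = circle_mask(c.circle, rows, cols, pixel_spacing_mm)
        best = max(best, dice_coefficient(disc, roi_disc))
    return best


# ---------------------------------------------------------------------------
# MSER features (N-R)


def _mser_regions(
    window: np.ndarray,
    delta_frac: float,
    max_variation: float,
    min_area: int,
) -> list[np.ndarray]:
    """Bright-on-dark maximally stable extremal regions of a window.

    Extremal regions are connected components of the upper level sets
    {I >= t}; thresholds descend from the window maximum in steps of
    ``delta_frac`` times that maximum.  A region is maximally stable when
    its relative area variation between the neighbouring levels is a local
    minimum along its component chain and does not exceed
    ``max_variation``.
    """
    window = np.asarray(window, dtype=float)
    vmax = window.max()
    vmin = window.min()
    if vmax <= vmin:
        return []
    delta = delta_frac * vmax
    if delta <= 0:
        return []
    levels = np.arange(vmax - delta, vmin - delta, -delta)
    if levels.size < 3:
        return []
    labs = []
    nlabs = []
    counts = []
    for t in levels:
        lab, n_lab = ndimage.label(window >= t)
        labs.append(lab)
        nlabs.append(n_lab)
        counts.append(np.bincount(lab.ravel()))
    n_levels = len(levels)
    # lineage: component at level i -> containing component at level i+1,
    # found through one representative pixel per component (level sets are
    # nested, so any pixel works); entry 0 is background
    parents: list[np.ndarray] = []
    for i in range(n_levels - 1):
        flat_i = labs[i].ravel()
        flat_j = labs[i + 1].ravel()
        reps = np.zeros(nlabs[i] + 1, dtype=np.intp)
        reps[flat_i] = np.arange(flat_i.size)
        par = flat_j[reps]
        par[0] = 0
        parents.append(par)
    # largest child of each component (the shrinking side of the chain)
    children_best: list[np.ndarray] = [np.zeros(n + 1, dtype=np.intp) for n in nlabs]
    for i in range(n_levels - 1):
        child_ids = np.arange(1, nlabs[i] + 1)
        par = parents[i][1:]
        areas = counts[i][1:]
        order = np.argsort(areas)  # later (larger) assignments win
        np.put(children_best[i + 1], par[order], child_ids[order])

    # relative area variation per component: (A_parent - A_best_child) / A
    variation: list[np.ndarray] = []
    for i in range(n_levels):
        a_i = counts[i].astype(float)
        a_plus = counts[i + 1][parents[i]] if i + 1 < n_levels else counts[i]
        child = children_best[i]
        a_minus = np.where(
            child > 0, counts[i - 1][child] if i >= 1 else counts[i], counts[i]
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            v = (a_plus - a_minus) / np.maximum(a_i, 1)
        variation.append(v)

    selected: list[np.ndarray] = []
    for i in range(1, n_levels - 1):
        area = counts[i][1:]
        q = variation[i][1:]
        keep = (area >= min_area) & (area <= 0.9 * window.size) & (q <= max_variation)
        # local minimum of variation along the chain: no strictly better
        # parent above, no better (admissible) child below
        par = parents[i][1:]
        if i + 1 < n_levels - 1:
            keep &= ~((par > 0) & (variation[i + 1][par] < q))
        child = children_best[i][1:]
        if i - 1 >= 1:
            child_better = (child > 0) & (variation[i - 1][child] <= q) & (
                counts[i - 1][child] >= min_area
            )
            keep &= ~child_better
        for lab_id in np.nonzero(keep)[0] + 1:
            selected.append(labs[i] == lab_id)
    return selected


def mser_features(
    frame: np.ndarray,
    roi: CircleROI,
    pixel_spacing_mm: tuple[float, float],
    config: FeatureConfig | None = None,
) -> tuple[float, float, float, float, float]:
    """MSER count and shape statistics of the best-overlapping region.

    MSERs are detected in a square window of side 6·radius around the ROI
    centre (bright-on-dark polarity, intensity step 1% of the window
    maximum, maximum area variation 50%, minimum region 9 px).  O is the
    best Dice overlap of any MSER with the ROI disc; the argmax region
    (OMSER) then yields P = |OMSER ∩ ROIᶜ| / |ROI| (the ROI disc is the
    denominator, so P can exceed 1 for a large OMSER), Q its solidity and
    R the eccentricity of its second-moment-equivalent ellipse.  With no
    MSER the degenerate defaults are (0, 0, 0, 1, 0).
    """
    config = config or FeatureConfig()
    frame = np.asarray(frame, dtype=float)
    radius_px = roi.radius_mm / float(np.mean(pixel_spacing_mm))
    half = max(2, int(round(config.mser_window_factor * radius_px / 2)))
    r0, c0 = int(round(roi.centre_rc[0])), int(round(roi.centre_rc[1]))
    rs = slice(max(0, r0 - half), min(frame.shape[0], r0 + half + 1))
    cs = slice(max(0, c0 - half), min(frame.shape[1], c0 + half + 1))
    window = frame[rs, cs]
    regions = _mser_regions(
        window, config.mser_delta_frac, config.mser_max_variation, config.mser_min_area_px
    )
    n = float(len(regions))
    if n == 0:
        return 0.0, 0.0, 0.0, 1.0, 0.0
    disc = circle_mask(roi, *frame.shape, pixel_spacing_mm)[rs, cs]
    disc_area = int(disc.sum())
    best_dsc, best_region = 0.0, regions[0]
    for reg in regions:
        d = dice_coefficient(reg, disc)
        if d > best_dsc:
            best_dsc, best_region = d, reg
    if disc_area > 0:
        not_overlap = float(np.logical_and(best_region, ~disc).sum() / disc_area)
    else:
        not_overlap = 0.0
    props = measure.regionprops(best_region.astype(int))[0]
    return n, best_dsc, not_overlap, float(props.solidity), float(props.eccentricity)


# ---------------------------------------------------------------------------
# Full vector


def extract_feature_vector(
    candidate: CandidateROI,
    frame_std: np.ndarray,
    body: BodyFrame,
    body_mask_std: np.ndarray,
    pixel_spacing_mm: tuple[float, float],
    series_std: np.ndarray | None = None,
    mp_circles: list[CandidateROI] | None = None,
    config: FeatureConfig | None = None,
    body_edt: np.ndarray | None = None,
) -> np.ndarray:
    """Ordered A-R feature vector for one candidate ROI.

    ``series_std`` (standard-grid cine stack) or precomputed ``mp_circles``
    feed the motion feature; passing neither sets K to 0.  ``body_edt``
    may hold the precomputed distance transform of the body mask (shared
    across the candidates of one scan).
    """
    config = config or FeatureConfig()
    roi = candidate.circle
    a, b, c = spatial_features(roi, body, body_mask_std, pixel_spacing_mm, edt=body_edt)
    disc = circle_mask(roi, *frame_std.shape, pixel_spacing_mm)
    values = np.asarray(frame_std, dtype=float)[disc]
    frame_range = (float(frame_std.min()), float(frame_std.max()))
    d, e, f, g, h = histogram_features(values, frame_range, config.entropy_bins)
    i = roi_correlation(frame_std, roi, pixel_spacing_mm)
    radius_px = max(1.0, roi.radius_mm / float(np.mean(pixel_spacing_mm)))
    j = sift_orientation(
        frame_std, roi.centre_rc, radius_px, config.sift_bins, config.sift_sigma_factor
    )
    if mp_circles is not None or series_std is not None:
        k = motion_periodicity_feature(
            series_std if series_std is not None else frame_std[..., None],
            roi,
            pixel_spacing_mm,
            config.mp_threshold,
            mp_circles=mp_circles,
        )
    else:
        k = 0.0
    n, o, p, q, r = mser_features(frame_std, roi, pixel_spacing_mm, config)
    return np.array(
        [a, b, c, d, e, f, g, h, i, j, k, candidate.cht_metric, roi.radius_mm, n, o, p, q, r]
    )
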