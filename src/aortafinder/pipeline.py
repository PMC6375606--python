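"""End-to-end orchestration: series in, detection + QC out.

Ties the stages together for one scan:

I.   segment the body and interpolate to the standard grid;
II.  phase-coded circular Hough transform inside the body-core ellipse;
III. extract the A-R feature vector for every candidate;
IV.  forest posteriors per candidate;
V.   best AA/PDA selection and the QC probability.

``process_scan`` runs I-III and is shared by training (where candidates
are then labelled against ground truth) and inference.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from . import cht as _cht
from . import features as _features
from . import preprocess as _pre
from .cht import CandidateROI, CHTConfig
from .core import CineSeries, GroundTruth, ROILabel
from .detect import QC_THRESHOLD, DetectionResult, select_best
from .features import FEATURE_NAMES, FeatureConfig
from .forest import RFModel, label_candidates, predict_posteriors, train_forest

__all__ = ["PipelineConfig", "ScanFeatures", "process_scan", "detect_scan", "train_from_cohort"]


@dataclasses.dataclass
class PipelineConfig:
    preprocess: _pre.PreprocessConfig = dataclasses.field(default_factory=_pre.PreprocessConfig)
    cht: CHTConfig = dataclasses.field(default_factory=CHTConfig)
    features: FeatureConfig = dataclasses.field(default_factory=FeatureConfig)
    qc_threshold: float = QC_THRESHOLD


@dataclasses.dataclass
class ScanFeatures:
    """Everything stage III produces for one scan."""

    scan_id: str
    candidates: list[CandidateROI]
    X: np.ndarray  # n_candidates x 18, canonical A-R order
    shape: tuple[int, int]  # standard grid
    pixel_spacing_mm: tuple[float, float]  # on the standard grid
    labels: list[ROILabel] | None = None


def process_scan(series: CineSeries, config: PipelineConfig | None = None) -> ScanFeatures:
    """Run segmentation, CHT candidate detection and feature extraction.

    Static processing uses the configured detection frame (default: the
    first frame of the cycle).  The motion-periodicity analysis runs on
    the original acquisition grid — interpolation adds no temporal
    information — and its circles are mapped onto the standard grid before
    the overlap feature is computed.
    """
    config = config or PipelineConfig()
    frame = series.frame(config.preprocess.detection_frame)
    mask = _pre.segment_foreground(frame, config.preprocess)
    frame_std, mask_std, spacing_std, zoom = _pre.to_standard_grid(
        frame, mask, series.pixel_spacing_mm, config.preprocess
    )
    body = _pre.body_reference_frame(frame_std, mask_std)
    region = _pre.search_region(body, config.preprocess)
    edges, directions = _cht.gradient_edges(frame_std)
    acc = _cht.phase_coded_accumulate(edges, directions, spacing_std, config.cht)
    candidates = _cht.find_candidates(acc, region, config.cht.min_magnitude)

    mp = _features.motion_periodicity_map(series.pixels, config.features.mp_threshold)
    mp_circles = _features.motion_periodicity_circles(mp, series.pixel_spacing_mm, config.cht)
    # pixel-centre convention of the grid interpolation:
    # std = (orig + 1/2) * zoom - 1/2
    mp_circles_std = [
        CandidateROI(
            circle=dataclasses.replace(
                c.circle,
                centre_rc=(
                    (c.circle.centre_rc[0] + 0.5) * zoom[0] - 0.5,
                    (c.circle.centre_rc[1] + 0.5) * zoom[1] - 0.5,
                ),
            ),
            cht_metric=c.cht_metric,
        )
        for c in mp_circles
    ]

    body_edt = ndimage.distance_transform_edt(mask_std)
    X = np.empty((len(candidates), len(FEATURE_NAMES)))
    for i, cand in enumerate(candidates):
        X[i] = _features.extract_feature_vector(
            cand,
            frame_std,
            body,
            mask_std,
            spacing_std,
            series_std=frame_std[..., None],  # shape source only; K uses mp_circles
            mp_circles=mp_circles_std,
            config=config.features,
            body_edt=body_edt,
        )
    return ScanFeatures(
        scan_id=series.scan_id,
        candidates=candidates,
        X=X,
        shape=frame_std.shape,
        pixel_spacing_mm=spacing_std,
    )


def detect_scan(
    series: CineSeries, model: RFModel, config: PipelineConfig | None = None
) -> tuple[DetectionResult, ScanFeatures]:
    """Full inference for one scan: detection result plus the stage-III record."""
    config = config or PipelineConfig()
    sf = process_scan(series, config)
    if len(sf.candidates) == 0:
        return select_best([], np.zeros((0, 3)), config.qc_threshold), sf
    posteriors = predict_posteriors(model, sf.X)
    return select_best(sf.candidates, posteriors, config.qc_threshold), sf


def train_from_cohort(
    cohort: Iterable[tuple[CineSeries, GroundTruth]],
    n_trees: int = 1000,
    mtry: int = 6,
    seed: int = 0,
    config: PipelineConfig | None = None,
    dsc_threshold: float = 0.75,
) -> tuple[RFModel, list[ScanFeatures]]:
    """Process and label a training cohort, then fit the forest.

    Candidates scoring Dice > ``dsc_threshold`` against the annotated AA
    (PDA) circle become AA (PDA) training rows; all others are NA.
    Returns the trained model and the per-scan records (with labels).
    """
    config = config or PipelineConfig()
    records: list[ScanFeatures] = []
    for series, gt in cohort:
        sf = process_scan(series, config)
        sf.labels = label_candidates(
            sf.candidates, gt, sf.shape, sf.pixel_spacing_mm, dsc_threshold
        )
        records.append(sf)
    X = np.vstack([sf.X for sf in records if len(sf.candidates)])
    y = np.concatenate(
        [[int(l) for l in sf.labels] for sf in records if len(sf.candidates)]
    )
    model = train_forest(X, y, n_trees=n_trees, mtry=mtry, seed=seed)
    return model, records
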