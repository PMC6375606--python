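"""Synthetic transverse cine-MR phantom of the thoracic aorta.

The generator emulates the image structure the detection pipeline relies
on, so the whole pipeline can be trained and validated without clinical
data: an elliptical mid-intensity "body" on a dark background, two bright
pulsatile circular vessels (the ascending aorta, larger, anterior and to
the subject's right; the proximal descending aorta, smaller, posterior and
to the left), a handful of circular distractor structures (pulmonary
trunk, superior vena cava, a left-sided pulmonary branch, spinal canal),
sinusoidal radius modulation with one period per cardiac cycle, additive
Gaussian noise, and graded artefact corruption mapped onto the observer
image-quality (IQ) scale 0-3.

Default geometry matches a typical acquisition: 240x196 matrix at
1.6x1.6 mm in-plane resolution, 50 frames per cycle, AA mean radius 15 mm,
PDA 9 mm, AA-PDA centre distance well above 18 mm.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import NOT_VISIBLE, CineSeries, CircleROI, GroundTruth

__all__ = ["Distractor", "PhantomConfig", "generate_phantom", "generate_cohort"]

#: Standard grid every downstream stage works on; ground-truth circle
#: centres are expressed in pixels of this grid (radii stay in mm).
STANDARD_SHAPE = (480, 392)

#: Cohort image-quality mix modelled on a large population cohort where
#: roughly 4% of scans are unusable, ~22% have major issues, ~54% minor
#: issues and ~20% are artefact-free.
DEFAULT_IQ_MIX = (0.04, 0.22, 0.54, 0.20)


@dataclasses.dataclass(frozen=True)
class Distractor:
    """A non-aortic circular structure: offset from body centre (mm), radius,
    intensity, and fractional pulsatile radius amplitude."""

    offset_mm: tuple[float, float]
    radius_mm: float
    intensity: float
    pulsatility: float = 0.0


def _default_distractors() -> tuple[Distractor, ...]:
    return (
        # pulmonary trunk: bright, mildly pulsatile, near midline
        Distractor((5.0, 30.0), 12.0, 0.9, 0.03),
        # superior vena cava: to the right of the AA
        Distractor((-8.0, -45.0), 6.0, 0.85, 0.0),
        # left pulmonary branch
        Distractor((32.0, 32.0), 5.0, 0.8, 0.0),
        # spinal canal: posterior, outside the core search region
        Distractor((70.0, 0.0), 8.0, 0.7, 0.0),
    )


@dataclasses.dataclass
class PhantomConfig:
    rows: int = 240
    cols: int = 196
    pixel_spacing_mm: float = 1.6
    n_frames: int = 50
    body_semiaxes_mm: tuple[float, float] = (95.0, 140.0)  # (AP, LR)
    body_intensity: float = 0.45
    background_intensity: float = 0.02
    aa_offset_mm: tuple[float, float] = (-10.0, -20.0)
    aa_radius_mm: float = 15.0
    pda_offset_mm: tuple[float, float] = (25.0, 10.0)
    pda_radius_mm: float = 9.0
    vessel_intensity: float = 1.0
    distractors: Sequence[Distractor] = dataclasses.field(
        default_factory=_default_distractors
    )
    pulsatility: float = 0.08
    noise_sd: float = 0.03
    artefact: str = "none"  # none | blur | ghosting | wrong_slice
    artefact_severity: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.artefact not in ("none", "blur", "ghosting", "wrong_slice"):
            raise ValueError(f"unknown artefact kind {self.artefact!r}")
        if not (0.0 <= self.artefact_severity <= 1.0):
            raise ValueError("artefact severity must lie in [0, 1]")
        if self.aa_radius_mm <= self.pda_radius_mm:
            raise ValueError("AA radius must exceed PDA radius")
        if not (self.aa_offset_mm[0] < self.pda_offset_mm[0]):
            raise ValueError("AA must be anterior to (smaller row than) PDA")
        if not (self.aa_offset_mm[1] < self.pda_offset_mm[1]):
            raise ValueError("AA must be to the subject's right of PDA")
        d = math.hypot(
            self.aa_offset_mm[0] - self.pda_offset_mm[0],
            self.aa_offset_mm[1] - self.pda_offset_mm[1],
        )
        if d < 18.0:
            raise ValueError(f"AA-PDA centre distance {d:.1f} mm < 18 mm")
        ap, lr = self.body_semiaxes_mm
        for off, radius in self._structures_mm():
            # structure must sit fully inside the body ellipse
            margin = (off[0] / (ap - radius)) ** 2 + (off[1] / (lr - radius)) ** 2
            if margin >= 1.0:
                raise ValueError(
                    f"structure at offset {off} mm, radius {radius} mm escapes the body"
                )

    def _structures_mm(self) -> list[tuple[tuple[float, float], float]]:
        out = [
            (self.aa_offset_mm, self.aa_radius_mm),
            (self.pda_offset_mm, self.pda_radius_mm),
        ]
        out.extend((d.offset_mm, d.radius_mm) for d in self.distractors)
        return out


def _soft_disc(rr_mm, cc_mm, centre_mm, radius_mm, edge_mm=0.8):
    """Anti-aliased disc: 1 inside, 0 outside, smooth ramp over ``edge_mm``."""
    d = np.hypot(rr_mm - centre_mm[0], cc_mm - centre_mm[1])
    return np.clip((radius_mm + edge_mm / 2 - d) / edge_mm, 0.0, 1.0)


def _body_ellipse(rr_mm, cc_mm, centre_mm, semiaxes_mm, edge_mm=2.0):
    u = (rr_mm - centre_mm[0]) / semiaxes_mm[0]
    v = (cc_mm - centre_mm[1]) / semiaxes_mm[1]
    d = np.sqrt(u**2 + v**2)
    # approximate signed distance in mm near the boundary
    scale = min(semiaxes_mm)
    return np.clip((1.0 - d) * scale / edge_mm + 0.5, 0.0, 1.0)


def _iq_from_artefact(kind: str, severity: float) -> float:
    if kind == "wrong_slice" or severity >= 0.9:
        return 0.0
    if kind == "none" or severity == 0.0:
        return 3.0
    if severity <= 0.45:
        return 2.0
    return 1.0


def generate_phantom(cfg: PhantomConfig) -> tuple[CineSeries, GroundTruth]:
    """Render one cine phantom and its ground-truth annotation.

    Vessel radii follow an area-centred sinusoid ``r(t) = r0 (1 + a sin ωt)``
    with one period per series (the breath-hold cine assumption: a single
    cardiac cycle, AA and PDA in phase).  The ground truth records the
    time-averaged circles, with centres on the standard 480x392 grid, and
    an IQ score derived from the artefact grade; a wrong-slice phantom has
    no vessels and both annotations are NOT_VISIBLE.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sp = cfg.pixel_spacing_mm
    rows, cols, n = cfg.rows, cfg.cols, cfg.n_frames
    rr_mm = np.arange(rows)[:, None] * sp
    cc_mm = np.arange(cols)[None, :] * sp
    body_centre = ((rows - 1) / 2 * sp, (cols - 1) / 2 * sp)

    body = _body_ellipse(rr_mm, cc_mm, body_centre, cfg.body_semiaxes_mm)
    base = cfg.background_intensity + (cfg.body_intensity - cfg.background_intensity) * body

    wrong = cfg.artefact == "wrong_slice" or cfg.artefact_severity >= 0.9
    phases = 2 * np.pi * np.arange(n) / n

    structures: list[tuple[tuple[float, float], float, float, float]] = []
    if not wrong:
        structures.append(
            (cfg.aa_offset_mm, cfg.aa_radius_mm, cfg.vessel_intensity, cfg.pulsatility)
        )
        structures.append(
            (cfg.pda_offset_mm, cfg.pda_radius_mm, cfg.vessel_intensity, cfg.pulsatility)
        )
        for d in cfg.distractors:
            structures.append((d.offset_mm, d.radius_mm, d.intensity, d.pulsatility))
    else:
        # off-anatomy content: a few static blobs that are not a plausible
        # AA/PDA pair, mimicking an incorrectly located slice
        for _ in range(4):
            off = (rng.uniform(-50, 60), rng.uniform(-90, 90))
            structures.append((off, rng.uniform(4, 10), rng.uniform(0.5, 0.8), 0.0))

    frames = np.empty((rows, cols, n), dtype=float)
    for k in range(n):
        frame = base.copy()
        for off, radius, intensity, puls in structures:
            r_k = radius * (1.0 + puls * np.sin(phases[k]))
            centre = (body_centre[0] + off[0], body_centre[1] + off[1])
            disc = _soft_disc(rr_mm, cc_mm, centre, r_k)
            frame = frame + (intensity - frame) * disc
        frames[:, :, k] = frame

    if cfg.artefact == "blur" and cfg.artefact_severity > 0:
        sigma = 6.0 * cfg.artefact_severity
        frames = ndimage.gaussian_filter(frames, sigma=(sigma, sigma, 0))
    elif cfg.artefact == "ghosting" and cfg.artefact_severity > 0:
        shift = max(4, int(0.15 * cols * cfg.artefact_severity))
        w = 0.5 * cfg.artefact_severity
        frames = (1 - w) * frames + (w / 2) * (
            np.roll(frames, shift, axis=1) + np.roll(frames, -shift, axis=1)
        )

    if cfg.noise_sd > 0:
        frames = frames + rng.normal(0.0, cfg.noise_sd, frames.shape)
    frames = np.clip(frames, 0.0, None)

    series = CineSeries(frames, (sp, sp), scan_id=f"phantom-{cfg.seed}")

    iq = _iq_from_artefact(cfg.artefact, cfg.artefact_severity)
    if wrong:
        gt = GroundTruth(aa=NOT_VISIBLE, pda=NOT_VISIBLE, iq=iq)
    else:
        zoom_r = STANDARD_SHAPE[0] / rows
        zoom_c = STANDARD_SHAPE[1] / cols

        def std_circle(off, radius):
            # pixel-centre convention of the grid interpolation:
            # std = (orig + 1/2) * zoom - 1/2
            r_px = ((body_centre[0] + off[0]) / sp + 0.5) * zoom_r - 0.5
            c_px = ((body_centre[1] + off[1]) / sp + 0.5) * zoom_c - 0.5
            return CircleROI((r_px, c_px), radius)

        gt = GroundTruth(
            aa=std_circle(cfg.aa_offset_mm, cfg.aa_radius_mm),
            pda=std_circle(cfg.pda_offset_mm, cfg.pda_radius_mm),
            iq=iq,
        )
    return series, gt


_IQ_TO_ARTEFACT = {
    3: ("none", 0.0),
    2: ("blur", 0.3),
    1: ("blur", 0.6),
    0: ("wrong_slice", 1.0),
}


def generate_cohort(
    n: int,
    iq_mix: Sequence[float] = DEFAULT_IQ_MIX,
    seed: int = 0,
    n_frames: int = 50,
) -> list[tuple[CineSeries, GroundTruth]]:
    """Generate ``n`` phantoms with jittered geometry and a graded IQ mix.

    ``iq_mix`` gives the multinomial proportions of IQ classes (0, 1, 2, 3).
    Per-phantom vessel centres are jittered by up to ±10 mm and radii by
    ±20%; draws violating the anatomical invariants (AA bigger, anterior,
    to the right, ≥ 18 mm apart, inside the body) are rejected and redrawn.
    Deterministic for a given seed.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    mix = np.asarray(iq_mix, dtype=float)
    if mix.shape != (4,) or not math.isclose(mix.sum(), 1.0, abs_tol=1e-8):
        raise ValueError("iq_mix must be 4 proportions summing to 1")
    rng = np.random.default_rng(seed)
    iq_classes = rng.choice(4, size=n, p=mix)
    base = PhantomConfig()
    out = []
    for i in range(n):
        kind, severity = _IQ_TO_ARTEFACT[int(iq_classes[i])]
        for _attempt in range(100):
            cfg = dataclasses.replace(
                base,
                aa_offset_mm=tuple(np.asarray(base.aa_offset_mm) + rng.uniform(-10, 10, 2)),
                pda_offset_mm=tuple(np.asarray(base.pda_offset_mm) + rng.uniform(-10, 10, 2)),
                aa_radius_mm=base.aa_radius_mm * rng.uniform(0.8, 1.2),
                pda_radius_mm=base.pda_radius_mm * rng.uniform(0.8, 1.2),
                n_frames=n_frames,
                artefact=kind,
                artefact_severity=severity,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            try:
                cfg.validate()
                break
            except ValueError:
                continue
        else:  # pragma: no cover - vanishingly unlikely with default geometry
            raise RuntimeError("could not draw valid phantom geometry")
        series, gt = generate_phantom(cfg)
        series.scan_id = f"phantom-{seed}-{i:04d}"
        out.append((series, gt))
    return out
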