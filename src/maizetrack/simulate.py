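"""Synthetic detection streams emulating a UAV pass over rows of plants.

The generator models the statistical structure the tracker assumes, not
imagery: a nadir camera translating at constant speed over a field, so that
plants enter at the top of the frame and scroll downward at a uniform pixel
velocity.  Plants are laid out in rows (rows run across the image, i.e.
perpendicular to the flight direction) starting just above the first
frame's field of view, so every plant is visible for many frames before it
reaches the counting line.

Detector imperfections are injected per frame:

* each visible plant's box is independently dropped with probability
  ``p_miss`` (missed detection);
* a Poisson-distributed number of spurious boxes (``fp_rate`` expected per
  frame) appears at uniform positions; by default each lives one frame, or
  ``fp_persist_frames`` frames to emulate weed-like persistent clutter that
  scrolls with the field;
* surviving box centers receive Gaussian jitter of ``jitter_sd`` pixels and
  sizes receive a matching log-normal perturbation.

Everything is driven by one seeded generator, so a clip is a pure function
of its configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .counter import check_crossing
from .geometry import Box
from .tracker import FrameDetections


@dataclass
class SimConfig:
    """Scene geometry, motion, noise rates, and the seed for one clip.

    Image geometry defaults to the 960x540 working resolution typical of
    cropped UAV footage; ``camera_velocity`` is the apparent downward plant
    motion in pixels per frame.  ``n_frames <= 0`` auto-sizes the clip so
    that every plant clears the counting line with a 10-frame margin.
    """

    image_width: float = 960.0
    image_height: float = 540.0
    n_plants: int = 24
    row_spacing: float = 90.0  # between rows, along the flight line (px)
    plant_spacing: float = 110.0  # within a row (px)
    camera_velocity: float = 4.0  # px/frame, downward in the image
    box_size_mean: float = 42.0
    box_size_sd: float = 4.0
    p_miss: float = 0.0
    fp_rate: float = 0.0
    fp_persist_frames: int = 1
    jitter_sd: float = 0.0
    baseline_fraction: float = 0.5
    n_frames: int = 0  # <= 0: auto
    seed: int = 0

    def __post_init__(self) -> None:
        if self.row_spacing <= 0 or self.plant_spacing <= 0:
            raise ValueError("row_spacing and plant_spacing must be positive")
        if self.camera_velocity <= 0:
            raise ValueError("camera_velocity must be positive")
        if not 0.0 <= self.p_miss <= 1.0:
            raise ValueError(f"p_miss must lie in [0, 1], got {self.p_miss}")
        if self.fp_rate < 0 or self.jitter_sd < 0:
            raise ValueError("fp_rate and jitter_sd must be non-negative")
        if self.n_plants < 0:
            raise ValueError("n_plants must be non-negative")
        if self.fp_persist_frames < 1:
            raise ValueError("fp_persist_frames must be >= 1")


@dataclass(frozen=True)
class Plant:
    """A plant's fixed field position (frame-1 image coordinates) and box size."""

    id: int
    u: float  # center column, constant over the pass
    v0: float  # center row at frame 1 (negative: above the image)
    w: float
    h: float

    def center_v(self, frame: int, velocity: float) -> float:
        return self.v0 + velocity * (frame - 1)


@dataclass
class GroundTruth:
    """Per-frame true boxes with persistent plant ids, plus the true count.

    ``true_count`` is the number of plants whose true center trajectory
    crosses the counting baseline within the clip — the quantity a manual
    counter scoring the same pass would report.  ``frames[f - 1]`` lists
    ``(plant_id, Box)`` pairs for the plants visible in frame ``f``.
    """

    config: SimConfig
    plants: list[Plant]
    frames: list[list[tuple[int, Box]]]
    true_count: int
    baseline_row: float

    def to_detections(
        self, hide: dict[int, set[int]] | None = None
    ) -> list[FrameDetections]:
        """Noiseless detection stream from the truth.

        ``hide`` maps plant id -> set of frame indices in which that plant's
        detection is suppressed (used to script occlusion episodes).
        """
        hide = hide or {}
        out = []
        for f, boxes in enumerate(self.frames, start=1):
            kept = [b for pid, b in boxes if f not in hide.get(pid, ())]
            out.append(FrameDetections(frame_index=f, boxes=kept))
        return out


def _layout_plants(cfg: SimConfig, rng: np.random.Generator) -> list[Plant]:
    # rows are stacked upward from just above the first frame's view, with a
    # small positional scatter so boxes are not perfectly gridded
    per_row = max(1, int(cfg.image_width // cfg.plant_spacing))
    plants = []
    pid = 0
    row = 0
    top_margin = cfg.box_size_mean  # keep frame-1 boxes fully out of view
    while pid < cfg.n_plants:
        v_row = -top_margin - row * cfg.row_spacing
        for j in range(per_row):
            if pid >= cfg.n_plants:
                break
            u = (j + 0.5) * cfg.image_width / per_row + rng.normal(
                0.0, 0.06 * cfg.plant_spacing
            )
            v = v_row + rng.normal(0.0, 0.06 * cfg.row_spacing)
            v = min(v, -cfg.box_size_mean / 2.0)  # never visible at frame 1
            w = max(8.0, rng.normal(cfg.box_size_mean, cfg.box_size_sd))
            h = max(8.0, rng.normal(cfg.box_size_mean, cfg.box_size_sd))
            plants.append(Plant(id=pid, u=u, v0=v, w=w, h=h))
            pid += 1
        row += 1
    return plants


def _auto_frames(cfg: SimConfig, plants: list[Plant]) -> int:
    baseline = cfg.baseline_fraction * cfg.image_height
    deepest = min((p.v0 for p in plants), default=0.0)
    return int(math.ceil((baseline - deepest) / cfg.camera_velocity)) + 11


def generate_clip(cfg: SimConfig) -> tuple[list[FrameDetections], GroundTruth]:
    """Generate one clip: noisy detections plus ground truth.

    Deterministic for a given configuration (the seed is part of it).
    """
    rng = np.random.default_rng(cfg.seed)
    plants = _layout_plants(cfg, rng)
    n_frames = cfg.n_frames if cfg.n_frames > 0 else _auto_frames(cfg, plants)
    baseline_row = cfg.baseline_fraction * cfg.image_height
    # relative size jitter tied to the center jitter scale
    size_log_sd = cfg.jitter_sd / cfg.box_size_mean

    truth_frames: list[list[tuple[int, Box]]] = []
    det_frames: list[FrameDetections] = []
    clutter: list[tuple[float, float, float, float, int]] = []  # u, v, w, h, frames left
    for f in range(1, n_frames + 1):
        visible: list[tuple[int, Box]] = []
        for p in plants:
            v = p.center_v(f, cfg.camera_velocity)
            if 0.0 <= v < cfg.image_height:
                visible.append(
                    (p.id, Box(x=p.u - p.w / 2, y=v - p.h / 2, w=p.w, h=p.h))
                )
        truth_frames.append(visible)

        boxes: list[Box] = []
        for _, b in visible:
            if cfg.p_miss > 0 and rng.random() < cfg.p_miss:
                continue
            cu, cv = b.center
            w, h = b.w, b.h
            if cfg.jitter_sd > 0:
                cu += rng.normal(0.0, cfg.jitter_sd)
                cv += rng.normal(0.0, cfg.jitter_sd)
                w *= math.exp(rng.normal(0.0, size_log_sd))
                h *= math.exp(rng.normal(0.0, size_log_sd))
            boxes.append(
                Box(x=cu - w / 2, y=cv - h / 2, w=w, h=h, confidence=rng.uniform(0.5, 1.0))
            )
        # clutter scrolls with the field, like a weed the detector mistakes
        # for a plant; with fp_persist_frames == 1 it is one-shot noise
        clutter = [
            (u, v + cfg.camera_velocity, w, h, left - 1)
            for (u, v, w, h, left) in clutter
            if left > 1
        ]
        if cfg.fp_rate > 0:
            for _ in range(rng.poisson(cfg.fp_rate)):
                fu = rng.uniform(0.0, cfg.image_width)
                fv = rng.uniform(0.0, cfg.image_height)
                fw = max(8.0, rng.normal(cfg.box_size_mean, cfg.box_size_sd))
                fh = max(8.0, rng.normal(cfg.box_size_mean, cfg.box_size_sd))
                clutter.append((fu, fv, fw, fh, cfg.fp_persist_frames))
        for (u, v, w, h, _) in clutter:
            boxes.append(
                Box(x=u - w / 2, y=v - h / 2, w=w, h=h, confidence=rng.uniform(0.5, 1.0))
            )
        det_frames.append(FrameDetections(frame_index=f, boxes=boxes))

    true_count = 0
    for p in plants:
        crossed = False
        for f in range(2, n_frames + 1):
            prev = p.center_v(f - 1, cfg.camera_velocity)
            curr = p.center_v(f, cfg.camera_velocity)
            if check_crossing(prev, curr, baseline_row) is not None:
                crossed = True
                break
        true_count += crossed

    truth = GroundTruth(
        config=replace(cfg, n_frames=n_frames),
        plants=plants,
        frames=truth_frames,
        true_count=true_count,
        baseline_row=baseline_row,
    )
    return det_frames, truth


def evaluate_counts(predicted: list[int], truth: list[int]) -> dict[str, float]:
    """Regression-style agreement between predicted and reference counts.

    Returns the coefficient of determination of the linear fit of predicted
    on reference counts (``r_squared``), the mean absolute error (``mae``),
    and the mean signed bias (``bias``, predicted minus reference).
    Requires at least two clips for ``r_squared``.
    """
    if len(predicted) != len(truth):
        raise ValueError(
            f"predicted and truth must have equal length, got {len(predicted)} "
            f"and {len(truth)}"
        )
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(truth, dtype=float)
    err = p - t
    out = {"mae": float(np.mean(np.abs(err))), "bias": float(np.mean(err))}
    if len(p) >= 2 and np.ptp(t) > 0:
        if np.ptp(p) == 0:
            out["r_squared"] = 0.0
        else:
            fit = stats.linregress(t, p)
            out["r_squared"] = float(fit.rvalue**2)
    else:
        out["r_squared"] = float("nan")
    return out
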