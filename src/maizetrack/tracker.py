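"""Multi-object plant tracker: predict → associate → update, with lifecycle.

Each frame the tracker (1) propagates every active track through the
constant-velocity Kalman prediction, (2) matches predicted boxes to the
frame's detections by maximal total IoU with a gate, (3) Kalman-updates the
matched tracks, (4) spawns a new track for every unmatched detection, and
(5) ages unmatched tracks, removing any whose consecutive-miss counter
``v_lost`` reaches ``t_lost``.  Tracks are predicted even while unmatched,
so a track coasts through short detector dropouts and can be re-associated
— and can still cross the counting line — without changing identity.

Track ids are assigned strictly increasing and never reused: a plant whose
track dies and which is later re-detected receives a fresh id, which is why
counting is done on baseline crossings rather than on the number of ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import kalman
from .association import build_cost_matrix, match
from .counter import CountResult, LineCounter
from .geometry import Box, box_to_measurement
from .kalman import NoiseModel, TrackState


@dataclass
class TrackerConfig:
    """All tunables of the tracking + counting pipeline.

    ``t_thresh`` is the IoU association gate; ``t_lost`` the number of
    consecutive misses a track survives; ``t_life`` the matched-frame count
    required before a track may be counted; ``baseline_fraction`` places the
    counting line as a fraction of image height.
    """

    t_thresh: float = 0.3
    t_lost: int = 5
    t_life: int = 3
    baseline_fraction: float = 0.5
    direction: str = "both"
    gate_before_solve: bool = False
    life_on_age: bool = False
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if not 0.0 < self.t_thresh < 1.0:
            raise ValueError(f"t_thresh must lie in (0, 1), got {self.t_thresh}")
        if self.t_lost < 1:
            raise ValueError(f"t_lost must be >= 1, got {self.t_lost}")
        if self.t_life < 1:
            raise ValueError(f"t_life must be >= 1, got {self.t_life}")
        if not 0.0 < self.baseline_fraction < 1.0:
            raise ValueError(
                f"baseline_fraction must lie in (0, 1), got {self.baseline_fraction}"
            )


@dataclass
class FrameDetections:
    """All detection boxes of one (1-based) frame."""

    frame_index: int
    boxes: list[Box] = field(default_factory=list)


@dataclass
class Track:
    """One tracked plant: identity, filter state, and lifecycle counters."""

    id: int
    state: TrackState
    v_lost: int = 0  # consecutive missed frames; reset on every match
    age: int = 1  # frames since creation, inclusive
    hits: int = 1  # matched frames; creation detection counts as the first
    counted: bool = False

    @property
    def center_v(self) -> float:
        return float(self.state.x[1])

    def to_box(self) -> Box:
        return kalman.state_to_box(self.state)


@dataclass
class FrameLog:
    """What happened in one tracker step."""

    frame_index: int
    matches: list[tuple[int, int, float]]  # (track id, detection index, iou)
    births: list[int]
    deaths: list[int]
    n_active: int


@dataclass(frozen=True)
class TrackSnapshot:
    """One track's box in one frame, as written to the track file."""

    frame_index: int
    track_id: int
    box: Box
    hits: int
    counted: bool


class PlantTracker:
    """Stateful per-clip tracker; feed frames in order via :meth:`step`."""

    def __init__(self, cfg: TrackerConfig | None = None) -> None:
        self.cfg = cfg or TrackerConfig()
        self.tracks: list[Track] = []
        self._next_id = 1
        self._last_frame: int | None = None

    def _new_track(self, box: Box) -> Track:
        state = kalman.init_track_state(box_to_measurement(box), self.cfg.noise)
        track = Track(id=self._next_id, state=state)
        self._next_id += 1
        return track

    def step(self, dets: FrameDetections) -> FrameLog:
        """Advance the tracker by one frame.

        Newly created tracks are initialized, not Kalman-updated, in their
        birth frame; they join association from the next frame on.
        """
        if self._last_frame is not None and dets.frame_index <= self._last_frame:
            raise ValueError(
                f"frame indices must be strictly increasing: got {dets.frame_index} "
                f"after {self._last_frame}"
            )
        self._last_frame = dets.frame_index
        cfg = self.cfg

        for track in self.tracks:
            track.state = kalman.predict(track.state, cfg.noise)

        C = build_cost_matrix([t.to_box() for t in self.tracks], dets.boxes)
        assoc = match(C, cfg.t_thresh, gate_before_solve=cfg.gate_before_solve)

        matched_log = []
        for ti, dj, iou_val in assoc.matches:
            track = self.tracks[ti]
            track.state = kalman.update(
                track.state, box_to_measurement(dets.boxes[dj]), cfg.noise
            )
            track.hits += 1
            track.v_lost = 0
            matched_log.append((track.id, dj, iou_val))
        for ti in assoc.unmatched_tracks:
            self.tracks[ti].v_lost += 1
        for track in self.tracks:
            track.age += 1

        deaths = [t.id for t in self.tracks if t.v_lost >= cfg.t_lost]
        self.tracks = [t for t in self.tracks if t.v_lost < cfg.t_lost]

        births = []
        for dj in assoc.unmatched_detections:
            track = self._new_track(dets.boxes[dj])
            self.tracks.append(track)
            births.append(track.id)

        return FrameLog(
            frame_index=dets.frame_index,
            matches=matched_log,
            births=births,
            deaths=deaths,
            n_active=len(self.tracks),
        )


def run_clip(
    frames: list[FrameDetections],
    cfg: TrackerConfig | None = None,
    image_height: float = 540.0,
) -> tuple[list[TrackSnapshot], CountResult, list[FrameLog]]:
    """Track and count a whole clip.

    Deterministic given identical inputs and configuration.  Returns the
    per-frame track boxes, the final crossing count, and the per-frame logs.
    An empty clip yields an empty history and zero count.
    """
    cfg = cfg or TrackerConfig()
    tracker = PlantTracker(cfg)
    counter = LineCounter(
        baseline_row=cfg.baseline_fraction * image_height,
        t_life=cfg.t_life,
        direction=cfg.direction,
        life_on_age=cfg.life_on_age,
    )
    history: list[TrackSnapshot] = []
    logs: list[FrameLog] = []
    for dets in frames:
        logs.append(tracker.step(dets))
        counter.count_frame(dets.frame_index, tracker.tracks)
        for track in tracker.tracks:
            history.append(
                TrackSnapshot(
                    frame_index=dets.frame_index,
                    track_id=track.id,
                    box=track.to_box(),
                    hits=track.hits,
                    counted=track.counted,
                )
            )
    return history, counter.result, logs
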