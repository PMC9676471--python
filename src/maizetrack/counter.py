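"""Cross-line counting of tracked plants.

A horizontal counting baseline is placed at a configurable fraction of the
image height (default one half).  A track is counted exactly once, at the
first frame where its Kalman-filtered center row crosses the baseline while
the track is count-eligible (at least ``t_life`` matched frames).  Counting
on the filtered center, rather than on raw detections, lets a track that is
coasting through a short run of missed detections still register its
crossing.

Counting once per identity — rather than counting trackers — makes the
final count robust to the identity churn that detectors cause near image
edges: a plant oscillating back and forth over the line, or re-detected
after a gap, never contributes more than one count per track id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Protocol


class _CountableTrack(Protocol):
    id: int
    hits: int
    age: int
    counted: bool

    @property
    def center_v(self) -> float: ...


@dataclass(frozen=True)
class Crossing:
    """One counted baseline crossing."""

    track_id: int
    frame: int
    direction: str  # "down" (row increasing) or "up"


@dataclass
class CountResult:
    """Accumulated count for a clip; ``total == len(crossings)`` always."""

    baseline_row: float
    total: int = 0
    crossings: list[Crossing] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "baseline_row": self.baseline_row,
            "crossings": [
                {"id": c.track_id, "frame": c.frame, "direction": c.direction}
                for c in self.crossings
            ],
        }


def check_crossing(prev_v: float, curr_v: float, baseline_row: float) -> str | None:
    """Crossing test between two consecutive center rows of one track.

    Returns "down", "up", or None.  A crossing requires the two ordinates
    to lie strictly on opposite sides of the line: ``(prev - b)(curr - b) <
    0``.  A point landing exactly on the line does not cross by itself; the
    stateful counter resolves it at the next off-line observation.
    """
    if (prev_v - baseline_row) * (curr_v - baseline_row) < 0.0:
        return "down" if curr_v > prev_v else "up"
    return None


class LineCounter:
    """Per-clip crossing counter with counted-once semantics.

    Parameters
    ----------
    baseline_row
        Row coordinate of the counting line, in pixels.
    t_life
        Minimum matched-frame count before a track may be counted; filters
        short-lived false-positive tracks.
    direction
        "both" (default), "down", or "up"; restricting the direction guards
        against double counts if the platform reverses heading.
    life_on_age
        Use total track age instead of matched-frame count for eligibility.
    """

    def __init__(
        self,
        baseline_row: float,
        t_life: int = 3,
        direction: str = "both",
        life_on_age: bool = False,
    ) -> None:
        if direction not in ("both", "down", "up"):
            raise ValueError(f"direction must be 'both', 'down' or 'up', got {direction!r}")
        self.result = CountResult(baseline_row=float(baseline_row))
        self.t_life = int(t_life)
        self.direction = direction
        self.life_on_age = life_on_age
        # last strictly-off-line center row per track id, so that a track
        # that lands exactly on the line is judged against its approach side
        self._ref_v: dict[int, float] = {}

    def _eligible(self, track: _CountableTrack) -> bool:
        life = track.age if self.life_on_age else track.hits
        return (not track.counted) and life >= self.t_life

    def count_frame(self, frame_index: int, tracks: Iterable[_CountableTrack]) -> CountResult:
        """Process one frame's active tracks; returns the running result."""
        b = self.result.baseline_row
        for track in tracks:
            v = track.center_v
            ref = self._ref_v.get(track.id)
            if ref is not None and self._eligible(track):
                direction = check_crossing(ref, v, b)
                if direction is not None and self.direction in ("both", direction):
                    track.counted = True
                    self.result.crossings.append(
                        Crossing(track_id=track.id, frame=frame_index, direction=direction)
                    )
                    self.result.total += 1
            if v != b or ref is None:
                self._ref_v[track.id] = v
        return self.result
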