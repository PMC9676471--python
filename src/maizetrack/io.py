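"""Readers and writers for the detection/track text dialect and JSON outputs.

Detections travel in a comma-separated MOTChallenge-style ``det.txt``
subset, one row per detection::

    frame,id,x_left,y_top,width,height,confidence

with 1-based frame numbers.  The id column is ignored on input (detectors
write ``-1``); track files use the same dialect with real track ids.
Floats are written with a fixed two-decimal format (four for confidence),
so writing what was read is byte-stable.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable

import yaml

from .counter import CountResult
from .geometry import Box, InvalidBoxError
from .simulate import GroundTruth, Plant, SimConfig
from .tracker import FrameDetections, TrackSnapshot


class DetectionParseError(ValueError):
    """Raised for malformed detection rows; names the offending line."""


def read_detections(path: str | Path) -> list[FrameDetections]:
    """Parse a detection file into per-frame groups.

    Frames are returned sorted and densified: every frame index from 1 to
    the file's maximum is present, frames without rows as empty lists.  An
    empty file yields an empty sequence.
    """
    by_frame: dict[int, list[Box]] = {}
    max_frame = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if len(parts) < 6:
                raise DetectionParseError(
                    f"{path}:{lineno}: expected at least 6 comma-separated "
                    f"fields, got {len(parts)}"
                )
            try:
                frame = int(parts[0])
                x, y, w, h = (float(p) for p in parts[2:6])
                conf = float(parts[6]) if len(parts) > 6 and parts[6] != "" else None
            except ValueError as exc:
                raise DetectionParseError(f"{path}:{lineno}: {exc}") from exc
            if frame < 1:
                raise DetectionParseError(
                    f"{path}:{lineno}: frame index must be >= 1, got {frame}"
                )
            try:
                box = Box(x=x, y=y, w=w, h=h, confidence=conf)
            except InvalidBoxError as exc:
                raise DetectionParseError(f"{path}:{lineno}: {exc}") from exc
            by_frame.setdefault(frame, []).append(box)
            max_frame = max(max_frame, frame)
    return [
        FrameDetections(frame_index=f, boxes=by_frame.get(f, []))
        for f in range(1, max_frame + 1)
    ]


def _fmt_row(frame: int, obj_id: int, box: Box) -> str:
    conf = box.confidence if box.confidence is not None else 1.0
    return (
        f"{frame},{obj_id},{box.x:.2f},{box.y:.2f},{box.w:.2f},{box.h:.2f},{conf:.4f}"
    )


def write_detections(frames: Iterable[FrameDetections], path: str | Path) -> None:
    """Write a detection stream in the input dialect (id column = -1)."""
    with open(path, "w") as fh:
        for fd in frames:
            for box in fd.boxes:
                fh.write(_fmt_row(fd.frame_index, -1, box) + "\n")


def write_tracks(history: Iterable[TrackSnapshot], path: str | Path) -> None:
    """Write per-frame track boxes with their real track ids."""
    with open(path, "w") as fh:
        for snap in history:
            fh.write(_fmt_row(snap.frame_index, snap.track_id, snap.box) + "\n")


def write_counts(result: CountResult, path: str | Path, clip: str = "") -> None:
    payload = {"clip": clip, **result.as_dict()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_counts(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialize ground truth (config, plants, per-frame boxes, count) to JSON."""
    payload = {
        "config": asdict(truth.config),
        "true_count": truth.true_count,
        "baseline_row": truth.baseline_row,
        "plants": [asdict(p) for p in truth.plants],
        "frames": [
            [
                {"id": pid, "x": b.x, "y": b.y, "w": b.w, "h": b.h}
                for pid, b in frame
            ]
            for frame in truth.frames
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    cfg = SimConfig(**payload["config"])
    return GroundTruth(
        config=cfg,
        plants=[Plant(**p) for p in payload["plants"]],
        frames=[
            [(d["id"], Box(x=d["x"], y=d["y"], w=d["w"], h=d["h"])) for d in frame]
            for frame in payload["frames"]
        ],
        true_count=payload["true_count"],
        baseline_row=payload["baseline_row"],
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON, a YAML subset) config mapping of CLI options."""
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(data).__name__}")
    return data
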