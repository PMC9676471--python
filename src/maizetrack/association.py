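"""IoU-cost assignment between predicted track boxes and detections.

Each frame, predicted track boxes are matched one-to-one to detections so
that the total IoU of the matched pairs is maximal (solved with the
Hungarian / linear-sum-assignment algorithm), and any assigned pair whose
IoU falls below a gate threshold (default 0.3) is demoted to unmatched on
both sides.  By default gating is applied *after* solving; the reverse
order — zeroing sub-threshold entries before solving — is available via
``gate_before_solve`` for comparison, since the two can differ in rare
configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import Box


@dataclass
class AssociationResult:
    """One-to-one matching outcome for a single frame.

    ``matches`` holds (track_index, detection_index, iou) triples; the
    unmatched lists complete exact partitions of both index sets.
    """

    matches: list[tuple[int, int, float]] = field(default_factory=list)
    unmatched_tracks: list[int] = field(default_factory=list)
    unmatched_detections: list[int] = field(default_factory=list)

    @property
    def total_iou(self) -> float:
        return sum(m[2] for m in self.matches)


def build_cost_matrix(track_boxes: list[Box], det_boxes: list[Box]) -> np.ndarray:
    """Pairwise IoU matrix, shape (n_tracks, n_detections).

    Vectorized over both lists; either may be empty.
    """
    m, n = len(track_boxes), len(det_boxes)
    if m == 0 or n == 0:
        return np.zeros((m, n))
    t = np.array([[b.x, b.y, b.x_right, b.y_bottom] for b in track_boxes])
    d = np.array([[b.x, b.y, b.x_right, b.y_bottom] for b in det_boxes])
    ix = np.minimum(t[:, None, 2], d[None, :, 2]) - np.maximum(t[:, None, 0], d[None, :, 0])
    iy = np.minimum(t[:, None, 3], d[None, :, 3]) - np.maximum(t[:, None, 1], d[None, :, 1])
    inter = np.clip(ix, 0.0, None) * np.clip(iy, 0.0, None)
    area_t = ((t[:, 2] - t[:, 0]) * (t[:, 3] - t[:, 1]))[:, None]
    area_d = ((d[:, 2] - d[:, 0]) * (d[:, 3] - d[:, 1]))[None, :]
    return inter / (area_t + area_d - inter)


def match(
    C: np.ndarray,
    t_thresh: float = 0.3,
    gate_before_solve: bool = False,
) -> AssociationResult:
    """Optimal one-to-one matching of a rectangular IoU matrix, gated at ``t_thresh``.

    Rows are tracks, columns detections.  Pairs with IoU < ``t_thresh``
    (in particular all zero-IoU pairs) are never reported as matches.
    Degenerate or empty matrices yield all-unmatched results.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.size == 0:
        m, n = C.shape
        return AssociationResult(
            unmatched_tracks=list(range(m)), unmatched_detections=list(range(n))
        )
    if not 0.0 < t_thresh < 1.0:
        raise ValueError(f"t_thresh must lie in (0, 1), got {t_thresh}")
    m, n = C.shape
    solve_on = np.where(C >= t_thresh, C, 0.0) if gate_before_solve else C
    rows, cols = linear_sum_assignment(solve_on, maximize=True)
    matches = []
    matched_rows: set[int] = set()
    matched_cols: set[int] = set()
    for i, j in zip(rows, cols):
        if C[i, j] >= t_thresh:
            matches.append((int(i), int(j), float(C[i, j])))
            matched_rows.add(int(i))
            matched_cols.add(int(j))
    return AssociationResult(
        matches=matches,
        unmatched_tracks=[i for i in range(m) if i not in matched_rows],
        unmatched_detections=[j for j in range(n) if j not in matched_cols],
    )
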