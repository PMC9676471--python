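"""Independent reference computations used to check the implementation.

These deliberately use brute force or reduced closed forms, never the code
paths they verify.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

from maizetrack.geometry import Box


def pixel_iou(a: Box, b: Box) -> float:
    """IoU by counting integer pixel memberships; boxes must have integer coords."""
    pa = {
        (i, j)
        for i in range(int(a.x), int(a.x_right))
        for j in range(int(a.y), int(a.y_bottom))
    }
    pb = {
        (i, j)
        for i in range(int(b.x), int(b.x_right))
        for j in range(int(b.y), int(b.y_bottom))
    }
    union = pa | pb
    return len(pa & pb) / len(union)


def best_assignment_total(C: np.ndarray, t_thresh: float) -> float:
    """Gated total IoU of the assignment maximizing ungated total IoU.

    Enumerates every full one-to-one assignment of the smaller side, picks
    the one with maximal total IoU, then drops sub-threshold pairs — the
    same two-step order the matcher contracts to.
    """
    C = np.asarray(C, dtype=float)
    m, n = C.shape
    if m == 0 or n == 0:
        return 0.0
    transposed = m > n
    A = C.T if transposed else C  # rows are the smaller side
    best_total, best_pairs = -1.0, []
    for cols in permutations(range(A.shape[1]), A.shape[0]):
        pairs = list(enumerate(cols))
        total = sum(A[i, j] for i, j in pairs)
        if total > best_total:
            best_total, best_pairs = total, pairs
    return sum(A[i, j] for i, j in best_pairs if A[i, j] >= t_thresh)


class ScalarCVKalman:
    """Independent 2-state (position, velocity) constant-velocity filter.

    The 7-state plant filter is block-diagonal over (u, u̇), (v, v̇),
    (s, ṡ) and (r), so its u-marginal must match this reduced filter
    exactly.
    """

    def __init__(self, z0: float, q=(1.0, 1e-2), r: float = 1.0, p0=(10.0, 1e4)):
        self.x = np.array([z0, 0.0])
        self.P = np.diag(p0)
        self.F = np.array([[1.0, 1.0], [0.0, 1.0]])
        self.Q = np.diag(q)
        self.H = np.array([[1.0, 0.0]])
        self.R = np.array([[r]])

    def predict(self) -> None:
        self.x = self.F @ self.x
        self.P = self.F @ self.P @ self.F.T + self.Q

    def update(self, z: float) -> float:
        S = self.H @ self.P @ self.H.T + self.R
        K = self.P @ self.H.T / S[0, 0]
        innovation = z - self.x[0]
        self.x = self.x + (K * innovation).ravel()
        self.P = (np.eye(2) - K @ self.H) @ self.P
        return float(innovation)
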