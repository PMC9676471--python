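"""Constant-velocity Kalman filter over the 7-dimensional plant state.

Each tracked plant carries the state vector

    t = (u, v, s, r, u̇, v̇, ṡ)

where (u, v) is the box center, s its area, r its aspect ratio, and the
dotted components are per-frame rates of change; the aspect ratio is assumed
constant.  Because the camera translates at a (near) uniform velocity at a
high frame rate, the apparent plant motion between consecutive frames is
well modelled as constant velocity with one frame as the time step.

The observation is the 4-vector (u, v, s, r) extracted from a matched
detection box.  Prediction propagates the state through the linear dynamics
F and inflates the covariance by the process noise Q; the update uses the
Joseph-form covariance formula, which preserves symmetry and positive
semi-definiteness regardless of rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Box, Measurement, measurement_to_box

STATE_DIM = 7
MEAS_DIM = 4


def _default_F() -> np.ndarray:
    # identity plus unit coupling of position-like components to their rates
    F = np.eye(STATE_DIM)
    F[0, 4] = F[1, 5] = F[2, 6] = 1.0
    return F


def _default_Q() -> np.ndarray:
    return np.diag([1.0, 1.0, 1.0, 1.0, 1e-2, 1e-2, 1e-4])


def _default_H() -> np.ndarray:
    return np.eye(MEAS_DIM, STATE_DIM)


def _default_R() -> np.ndarray:
    return np.diag([1.0, 1.0, 10.0, 10.0])


def _default_P0() -> np.ndarray:
    # velocities start at 0, so their initial uncertainty is kept large
    return np.diag([10.0, 10.0, 10.0, 10.0, 1e4, 1e4, 1e4])


@dataclass
class NoiseModel:
    """The filter's dynamics, observation, and noise matrices.

    Defaults encode a per-frame constant-velocity model: F couples
    (u, v, s) to their rates with dt = 1; Q = diag(1, 1, 1, 1, 1e-2, 1e-2,
    1e-4) trusts the velocity components much more than the positions;
    H observes (u, v, s, r) directly; R = diag(1, 1, 10, 10) reflects that
    detector area/aspect estimates are noisier than center coordinates.
    P0 is the initial covariance given to new tracks.  All five matrices
    are overridable.
    """

    F: np.ndarray = field(default_factory=_default_F)
    Q: np.ndarray = field(default_factory=_default_Q)
    H: np.ndarray = field(default_factory=_default_H)
    R: np.ndarray = field(default_factory=_default_R)
    P0: np.ndarray = field(default_factory=_default_P0)

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.P0 = np.asarray(self.P0, dtype=float)
        expected = {
            "F": (STATE_DIM, STATE_DIM),
            "Q": (STATE_DIM, STATE_DIM),
            "H": (MEAS_DIM, STATE_DIM),
            "R": (MEAS_DIM, MEAS_DIM),
            "P0": (STATE_DIM, STATE_DIM),
        }
        for name, shape in expected.items():
            got = getattr(self, name).shape
            if got != shape:
                raise ValueError(f"{name} must have shape {shape}, got {got}")


@dataclass
class TrackState:
    """State mean ``x`` (7-vector) and covariance ``P`` (7x7, symmetric PSD)."""

    x: np.ndarray
    P: np.ndarray


def _symmetrize(P: np.ndarray) -> np.ndarray:
    return (P + P.T) / 2.0


def init_track_state(m: Measurement, model: NoiseModel | None = None) -> TrackState:
    """Initialize a track from its first detection.

    Positions (u, v, s, r) are copied from the measurement and all three
    velocity components are set to 0; the covariance starts at ``model.P0``.
    """
    model = model or NoiseModel()
    x = np.array([m.u, m.v, m.s, m.r, 0.0, 0.0, 0.0])
    return TrackState(x=x, P=model.P0.copy())


def predict(state: TrackState, model: NoiseModel) -> TrackState:
    """A priori step: x' = F x, P' = F P Fᵀ + Q.

    If the predicted area would become non-positive (s + ṡ ≤ 0), the area
    rate is clamped to 0 for this prediction so the state still converts to
    a valid box; the track stays alive.
    """
    x = state.x.copy()
    if x[2] + x[6] <= 0.0:
        x[6] = 0.0
    x_new = model.F @ x
    P_new = _symmetrize(model.F @ state.P @ model.F.T + model.Q)
    return TrackState(x=x_new, P=P_new)


def update(state: TrackState, m: Measurement, model: NoiseModel) -> TrackState:
    """A posteriori step with Joseph-form covariance.

    y = z − H x is the innovation, S = H P Hᵀ + R its covariance,
    K = P Hᵀ S⁻¹ the gain (computed by solving the S-system rather than
    inverting S), and

        P⁺ = (I − K H) P (I − K H)ᵀ + K R Kᵀ

    which remains symmetric PSD even under rounding.
    """
    H, R = model.H, model.R
    z = np.array([m.u, m.v, m.s, m.r])
    P = state.P
    y = z - H @ state.x
    S = _symmetrize(H @ P @ H.T + R)
    try:
        K = np.linalg.solve(S, H @ P).T
    except np.linalg.LinAlgError as exc:  # S is PD whenever R is PD
        raise np.linalg.LinAlgError(
            f"singular innovation covariance during track update: {exc}"
        ) from exc
    x_new = state.x + K @ y
    A = np.eye(STATE_DIM) - K @ H
    P_new = _symmetrize(A @ P @ A.T + K @ R @ K.T)
    return TrackState(x=x_new, P=P_new)


def state_to_box(state: TrackState, confidence: float | None = None) -> Box:
    """Emit the state's (u, v, s, r) components as a box."""
    u, v, s, r = state.x[:4]
    return measurement_to_box(Measurement(u=u, v=v, s=s, r=r), confidence=confidence)
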