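import numpy as np
import pytest

from maizetrack.geometry import Box, Measurement, box_to_measurement
from maizetrack.kalman import (
    NoiseModel,
    TrackState,
    init_track_state,
    predict,
    state_to_box,
    update,
)
from oracles import ScalarCVKalman


@pytest.fixture
def model():
    return NoiseModel()


def random_psd(rng, n=7, scale=10.0):
    A = rng.normal(size=(n, n)) * scale
    return A @ A.T / n


class TestInitialization:
    def test_positions_copied_velocities_zero(self, model):
        st = init_track_state(Measurement(25, 40, 1200, 0.75), model)
        assert np.allclose(st.x, [25, 40, 1200, 0.75, 0, 0, 0])
        assert np.allclose(st.P, model.P0)

    def test_initial_covariance_independent_of_measurement(self, model):
        a = init_track_state(Measurement(1, 2, 3, 4), model)
        b = init_track_state(Measurement(500, 100, 900, 0.3), model)
        assert np.array_equal(a.P, b.P)


class TestPredict:
    def test_velocities_added_to_positions(self, model):
        st = TrackState(x=np.array([100, 200, 400, 1, 2, 3, 0.0]), P=model.P0.copy())
        out = predict(st, model)
        assert np.allclose(out.x, [102, 203, 400, 1, 2, 3, 0])

    def test_zero_velocity_leaves_positions(self, model):
        st = init_track_state(Measurement(10, 20, 100, 1), model)
        out = predict(st, model)
        assert np.allclose(out.x[:4], st.x[:4])

    def test_covariance_grows_by_at_least_Q(self, model, rng):
        for _ in range(20):
            P = random_psd(rng)
            out = predict(TrackState(x=np.ones(7), P=P), model)
            assert np.all(np.diag(out.P) >= np.diag(model.Q) - 1e-9)

    def test_degenerate_area_rate_clamped(self, model):
        st = TrackState(
            x=np.array([10, 10, 5.0, 1, 0, 0, -7.0]), P=model.P0.copy()
        )
        out = predict(st, model)
        assert out.x[2] == pytest.approx(5.0)  # area held, not driven negative
        box = state_to_box(out)
        assert box.w > 0 and box.h > 0


class TestUpdate:
    def test_zero_residual_leaves_state(self, model):
        st = predict(init_track_state(Measurement(10, 20, 100, 1), model), model)
        out = update(st, Measurement(10, 20, 100, 1), model)
        assert np.allclose(out.x, st.x)

    def test_joseph_form_matches_simple_form_for_optimal_gain(self, model, rng):
        # (I-KH)P(I-KH)^T + KRK^T == (I-KH)P when K is the optimal gain
        for _ in range(20):
            P = random_psd(rng)
            st = TrackState(x=rng.normal(size=7), P=P)
            out = update(st, Measurement(*rng.uniform(1, 100, size=4)), model)
            H, R = model.H, model.R
            S = H @ P @ H.T + R
            K = P @ H.T @ np.linalg.inv(S)
            simple = (np.eye(7) - K @ H) @ P
            assert np.allclose(out.P, (simple + simple.T) / 2, atol=1e-8)

    def test_matches_independent_scalar_filter(self, model):
        # u-marginal of the 7-state filter equals a 2-state CV filter exactly
        zs = [50.0, 52.5, 54.0, 57.2, 60.1, 61.0, 64.3, 66.6]
        st = init_track_state(Measurement(zs[0], 10, 100, 1), model)
        scalar = ScalarCVKalman(zs[0])
        for z in zs[1:]:
            st = update(predict(st, model), Measurement(z, 10, 100, 1), model)
            scalar.predict()
            scalar.update(z)
        assert st.x[0] == pytest.approx(scalar.x[0], abs=1e-10)
        assert st.x[4] == pytest.approx(scalar.x[1], abs=1e-10)

    def test_stationary_measurement_converges(self, model):
        # the u-innovation sequence must match the independent scalar filter
        # exactly, and decay to steady state after 50 iterations
        target = Measurement(300, 150, 900, 1.1)
        st = init_track_state(Measurement(290, 140, 800, 1.0), model)
        scalar = ScalarCVKalman(290.0)
        innovation = np.inf
        for _ in range(50):
            st = predict(st, model)
            innovation = abs(target.u - st.x[0])
            st = update(st, target, model)
            scalar.predict()
            scalar_innovation = abs(scalar.update(target.u))
        assert innovation == pytest.approx(scalar_innovation, abs=1e-12)
        assert innovation < 1e-2
        assert st.x[0] == pytest.approx(target.u, abs=1e-2)
        assert st.x[1] == pytest.approx(target.v, abs=1e-2)


class TestFilterProperties:
    def test_noiseless_constant_velocity_prediction(self, model):
        # exact linear trajectory: one-step-ahead prediction locks on
        vel = (3.0, -2.0)
        meas = [
            Measurement(100 + vel[0] * k, 300 + vel[1] * k, 1600, 0.9)
            for k in range(60)
        ]
        st = init_track_state(meas[0], model)
        worst = 0.0
        for k, m in enumerate(meas[1:], start=1):
            st = predict(st, model)
            if k > 10:
                worst = max(worst, abs(st.x[0] - m.u), abs(st.x[1] - m.v))
            st = update(st, m, model)
        assert worst <= 1e-3

    def test_covariance_symmetric_psd_over_random_cycles(self, model, rng):
        st = init_track_state(Measurement(100, 100, 400, 1), model)
        for _ in range(1000):
            st = predict(st, model)
            m = Measurement(*rng.uniform(10, 500, size=2), rng.uniform(50, 2000),
                            rng.uniform(0.3, 3.0))
            st = update(st, m, model)
            assert np.allclose(st.P, st.P.T, atol=1e-9)
            assert np.linalg.eigvalsh(st.P).min() >= -1e-8

    def test_zero_Q_small_R_limit_reproduces_measurements(self):
        # with no process trust and near-exact measurements the filter
        # output must follow the data
        model = NoiseModel(Q=np.zeros((7, 7)), R=np.eye(4) * 1e-12)
        st = init_track_state(Measurement(10, 10, 100, 1), model)
        m = Measurement(14, 7, 120, 1.2)
        for _ in range(3):
            st = update(predict(st, model), m, model)
        assert np.allclose(st.x[:4], [m.u, m.v, m.s, m.r], atol=1e-5)


def test_noise_model_shape_validation():
    with pytest.raises(ValueError, match="F"):
        NoiseModel(F=np.eye(6))
    with pytest.raises(ValueError, match="R"):
        NoiseModel(R=np.eye(3))


def test_state_round_trips_through_box(model):
    b = Box(100, 50, 30, 45)
    st = init_track_state(box_to_measurement(b), model)
    b2 = state_to_box(st)
    assert (b2.x, b2.y, b2.w, b2.h) == pytest.approx((b.x, b.y, b.w, b.h))
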