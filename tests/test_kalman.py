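import numpy as np
import pytest

from conftest import make_ar1_kinematics, make_linear_counts
from fingerbmi.kalman import (
    DecoderModel,
    DecoderState,
    ObservationModel,
    StateModel,
    decode_offline,
    decode_online,
    fit_observation_model,
    fit_state_model,
    initial_state,
    kf_step,
    run_filter,
    select_lag,
)
from fingerbmi.signal_prep import (
    DegenerateFitError,
    KinematicSeries,
    SpikeCountMatrix,
)


def simple_model(a=0.8, s2=0.01, dt=0.05, C=None, Q=None, refit=False):
    state = StateModel(a_vv=np.array([a]), sigma_v_sq=np.array([s2]),
                       dt=dt, n_dof=1)
    if C is None:
        C = np.array([[1.0, 2.0, 3.0], [0.5, -1.0, 2.0], [-1.0, 0.5, 4.0]])
    if Q is None:
        Q = np.eye(C.shape[0])
    obs = ObservationModel(C=C, Q=Q, lag=0, form="position_and_velocity",
                           n_dof=1)
    return DecoderModel(state=state, obs=obs, refit=refit)


class TestStateModel:
    def test_structure_1dof(self):
        m = StateModel(a_vv=np.array([0.86]), sigma_v_sq=np.array([0.01]),
                       dt=0.05, n_dof=1)
        np.testing.assert_array_equal(
            m.A, [[1, 0.05, 0], [0, 0.86, 0], [0, 0, 1]])
        np.testing.assert_array_equal(m.W, np.diag([0, 0.01, 0]))

    def test_structure_2dof_decoupled(self):
        m = StateModel(a_vv=np.array([0.8, 0.9]),
                       sigma_v_sq=np.array([0.01, 0.02]), dt=0.05, n_dof=2)
        A, W = m.A, m.W
        # cross-DOF transition and process-noise terms are structural zeros
        assert A[2, 3] == A[3, 2] == 0
        assert W[2, 3] == W[3, 2] == 0
        np.testing.assert_array_equal(np.diag(A), [1, 1, 0.8, 0.9, 1])
        np.testing.assert_array_equal(np.diag(W), [0, 0, 0.01, 0.02, 0])

    def test_noiseless_ar_recovered_exactly(self):
        vel = 0.5 ** np.arange(200)
        pos = 0.5 + np.cumsum(vel) * 0.05
        kin = KinematicSeries(dt=0.05, positions=pos, velocities=vel)
        m = fit_state_model(kin)
        assert m.a_vv[0] == pytest.approx(0.5, abs=1e-12)
        assert m.sigma_v_sq[0] == pytest.approx(0.0, abs=1e-12)

    def test_ar1_recovery_matches_ols_oracle(self, rng):
        kin = make_ar1_kinematics(10_000, a=0.86, sigma=0.1, rng=rng)
        m = fit_state_model(kin)
        v = kin.velocities[:, 0]
        # independent closed-form OLS slope through the origin
        oracle = np.dot(v[:-1], v[1:]) / np.dot(v[:-1], v[:-1])
        assert m.a_vv[0] == pytest.approx(oracle, abs=1e-12)
        assert 0.84 <= m.a_vv[0] <= 0.88

    def test_all_zero_velocities_degenerate(self):
        kin = KinematicSeries(dt=0.05, positions=np.full(200, 0.5),
                              velocities=np.zeros(200))
        with pytest.raises(DegenerateFitError):
            fit_state_model(kin)


class TestObservationModel:
    def test_known_coefficients_recovered(self, rng):
        kin = make_ar1_kinematics(10_000, rng=rng)
        C_true = np.array([[2.0, 1.0, 3.0]])
        counts_raw = np.hstack([kin.positions, kin.velocities,
                                np.ones((kin.n_bins, 1))]) @ C_true.T
        counts_raw = counts_raw + rng.normal(0, 0.5, counts_raw.shape)
        counts = SpikeCountMatrix(dt=0.05,
                                  counts=np.maximum(np.round(counts_raw), 0).astype(int))
        obs = fit_observation_model(counts, kin)
        np.testing.assert_allclose(obs.C[0], C_true[0], rtol=0.05)

    def test_constant_rate_channel(self, rng):
        kin = make_ar1_kinematics(2_000, rng=rng)
        counts = SpikeCountMatrix(dt=0.05,
                                  counts=np.full((kin.n_bins, 2), 4, dtype=int))
        obs = fit_observation_model(counts, kin)
        np.testing.assert_allclose(obs.C[:, :2], 0.0, atol=1e-8)
        np.testing.assert_allclose(obs.C[:, 2], 4.0, atol=1e-8)

    def test_velocity_only_form_has_no_position_column(self, rng):
        kin = make_ar1_kinematics(2_000, rng=rng)
        counts = make_linear_counts(kin, np.array([[0.0, 2.0, 3.0]]), rng)
        obs = fit_observation_model(counts, kin, form="velocity_only")
        assert obs.C.shape == (1, 2)  # velocity + offset only
        assert obs.C_full[0, 0] == 0.0  # position entry structurally zero

    def test_collinear_regressors_named(self):
        # constant positions make position collinear with the offset
        kin = KinematicSeries(dt=0.05, positions=np.full(500, 0.5),
                              velocities=np.linspace(-1, 1, 500))
        counts = SpikeCountMatrix(dt=0.05,
                                  counts=np.ones((500, 2), dtype=int))
        with pytest.raises(DegenerateFitError, match="collinear"):
            fit_observation_model(counts, kin)

    def test_q_symmetric_psd(self, rng):
        kin = make_ar1_kinematics(3_000, rng=rng)
        C = np.column_stack([rng.normal(0, 1, 8), rng.normal(0, 1, 8),
                             rng.uniform(1, 3, 8)])
        counts = make_linear_counts(kin, C, rng)
        obs = fit_observation_model(counts, kin)
        np.testing.assert_array_equal(obs.Q, obs.Q.T)
        assert np.min(np.linalg.eigvalsh(obs.Q)) >= -1e-10


class TestLagSelection:
    @pytest.mark.parametrize("true_lag", [0, 2])
    def test_recovers_simulated_lag(self, true_lag, rng):
        # neural activity leads kinematics by true_lag bins
        kin = make_ar1_kinematics(4_000, rng=rng)
        C = np.column_stack([rng.normal(0, 1, 12), rng.normal(0, 2, 12),
                             rng.uniform(2, 4, 12)])
        X = np.hstack([kin.positions, kin.velocities,
                       np.ones((kin.n_bins, 1))])
        rates = X @ C.T
        shifted = np.zeros_like(rates)
        if true_lag:
            shifted[:-true_lag] = rates[true_lag:]
        else:
            shifted = rates
        y = shifted + rng.normal(0, 1.0, shifted.shape)
        counts = SpikeCountMatrix(dt=0.05,
                                  counts=np.maximum(np.round(y), 0).astype(int))
        assert select_lag(counts, kin) == true_lag

    def test_exact_ties_break_to_smaller_lag(self, rng, monkeypatch):
        import fingerbmi.kalman as kalman
        monkeypatch.setattr(kalman, "decode_offline",
                            lambda *a, **k: {"velocity_rho": np.array([0.5])})
        kin = make_ar1_kinematics(500, rng=rng)
        counts = SpikeCountMatrix(dt=0.05, counts=np.ones((500, 3), dtype=int))
        assert select_lag(counts, kin) == 0


class TestKfStep:
    def test_no_information_limit(self):
        # huge observation noise: posterior stays at the prior prediction
        model = simple_model(Q=np.eye(3) * 1e12)
        st = DecoderState(x=np.array([0.5, 0.3, 1.0]), P=np.eye(3) * 0.01)
        out = kf_step(st, np.array([50.0, -20.0, 30.0]), model)
        np.testing.assert_allclose(out.x, model.state.A @ st.x, atol=1e-6)

    def test_offset_component_stays_one(self, rng):
        model = simple_model()
        st = initial_state(model)
        for _ in range(10):
            st = kf_step(st, rng.normal(0, 5, 3), model)
            assert st.x[-1] == 1.0

    def test_posterior_covariance_symmetric(self, rng):
        model = simple_model()
        st = initial_state(model)
        for _ in range(5):
            st = kf_step(st, rng.normal(0, 5, 3), model)
        np.testing.assert_array_equal(st.P, st.P.T)


class TestControlLaw:
    def test_integrated_velocity_arithmetic(self):
        model = simple_model()
        st = DecoderState(x=np.array([0.0, 0.2, 1.0]), P=np.eye(3) * 0.01)
        st, cursor = decode_online(st, np.array([0.5]), model)
        assert cursor[0] == pytest.approx(0.51)
        assert st.x[0] == pytest.approx(0.51)  # state position overwritten

    def test_cursor_equals_cumulative_velocity_sum(self, rng):
        model = simple_model()
        counts = SpikeCountMatrix(
            dt=0.05, counts=rng.poisson(3.0, size=(200, 3)))
        dec = run_filter(counts, model, start_pos=0.5,
                         control_mode="integrated_velocity")
        expected = 0.5 + np.cumsum(dec.velocities[:, 0]) * 0.05
        np.testing.assert_allclose(dec.positions[:, 0], expected, atol=1e-12)

    def test_zero_velocity_keeps_cursor_constant(self):
        model = simple_model()
        st = DecoderState(x=np.array([0.5, 0.0, 1.0]), P=np.eye(3) * 0.01)
        for _ in range(5):
            st, cursor = decode_online(st, np.array([0.5]), model)
            assert cursor[0] == 0.5


class TestOfflineDecode:
    def test_noiseless_observations_reproduce_kinematics(self, rng):
        # states generated by the model's own recursion, observed exactly with
        # near-zero observation noise: the filter pins the generating states
        model = simple_model(a=0.9, s2=0.01,
                             C=np.array([[1.0, 0.0, 0.5], [0.0, 1.0, 0.2],
                                         [1.0, 1.0, 1.0], [0.5, -1.0, 0.3]]),
                             Q=np.eye(4) * 1e-10)
        A = model.state.A
        x = np.array([0.5, 0.0, 1.0])
        X = np.empty((400, 3))
        for t in range(400):
            x = A @ x
            x[1] += rng.normal(0, 0.1)  # velocity process noise
            X[t] = x
        counts = SpikeCountMatrix(dt=0.05, counts=np.zeros((400, 4), dtype=int))
        counts.counts = X @ model.obs.C.T  # exact continuous observations
        dec = run_filter(counts, model, start_pos=0.5, control_mode="filter")
        np.testing.assert_allclose(dec.positions[5:, 0], X[5:, 0], atol=1e-5)
        np.testing.assert_allclose(dec.velocities[5:, 0], X[5:, 1], atol=1e-5)

    def test_high_snr_self_consistency(self, rng):
        kin = make_ar1_kinematics(3_000, rng=rng)
        C = np.column_stack([rng.normal(0, 2, 20), rng.normal(0, 3, 20),
                             rng.uniform(2, 4, 20)])
        counts = make_linear_counts(kin, C, rng, noise_sd=0.5)
        res = decode_offline(counts, kin, n_folds=5)
        assert res["position_rho"][0] > 0.9

    def test_shuffled_counts_decode_nothing(self, rng):
        kin = make_ar1_kinematics(10_000, rng=rng)
        C = np.column_stack([rng.normal(0, 2, 10), rng.normal(0, 3, 10),
                             rng.uniform(2, 4, 10)])
        counts = make_linear_counts(kin, C, rng, noise_sd=0.5)
        shuffled = SpikeCountMatrix(
            dt=0.05, counts=counts.counts[rng.permutation(kin.n_bins)])
        res = decode_offline(shuffled, kin, n_folds=5)
        # velocity carries the information flow; its decode collapses to
        # chance (decoded position is an integrated series, whose correlation
        # against another smooth series is not tightly bounded)
        assert abs(res["velocity_rho"][0]) < 0.1


class TestSerialization:
    def test_json_round_trip(self, rng, tmp_path):
        from fingerbmi.io import load_decoder, save_decoder
        model = simple_model(refit=True)
        p = tmp_path / "model.json"
        save_decoder(model, p)
        back = load_decoder(p)
        assert back.refit
        assert back.obs.form == model.obs.form
        np.testing.assert_array_equal(back.obs.C, model.obs.C)
        np.testing.assert_array_equal(back.state.A, model.state.A)
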