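"""Linear Kalman decoding of finger kinematics from binned spike counts.

The state is ``[pos, vel, 1]`` for one finger-group DOF (or
``[pos_a, pos_b, vel_a, vel_b, 1]`` for two), with a state-transition model in
which position is explained exactly by velocity integration and only the
velocity carries process noise.  The observation model is linear in position
and/or velocity plus a per-channel baseline, with a full residual covariance
across channels and an optional neural-to-kinematic time lag of 0-3 bins.

Fitting is exact maximum likelihood for this linear-Gaussian model: ordinary
least squares for the coefficients, residual (co)variance for the noise.
Online control uses integrated velocity -- the cursor moves by the decoded
velocity each bin and the filter's position state is overwritten with the
cursor so the next update is conditioned on what the subject saw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_prep import DegenerateFitError, KinematicSeries, SpikeCountMatrix

#: Candidate neural-to-kinematic lags, in bins.
LAG_CANDIDATES = (0, 1, 2, 3)

FORMS = ("position_only", "velocity_only", "position_and_velocity")


class NumericalFailureError(RuntimeError):
    """The filter covariance lost positive semidefiniteness."""


@dataclass(frozen=True)
class StateModel:
    """State-transition model: damped-velocity random walk with exact position integration.

    ``A`` and ``W`` carry structural zeros everywhere except the velocity
    damping/noise entries; for two DOFs the finger groups are fully decoupled
    (no cross-DOF transition or process-noise terms).
    """

    a_vv: np.ndarray        # (n_dof,) velocity damping
    sigma_v_sq: np.ndarray  # (n_dof,) velocity noise variance, (arc/s)^2
    dt: float
    n_dof: int

    @property
    def dim(self) -> int:
        return 2 * self.n_dof + 1

    @property
    def A(self) -> np.ndarray:
        d = self.n_dof
        A = np.zeros((self.dim, self.dim))
        for i in range(d):
            A[i, i] = 1.0
            A[i, d + i] = self.dt
            A[d + i, d + i] = self.a_vv[i]
        A[-1, -1] = 1.0
        return A

    @property
    def W(self) -> np.ndarray:
        d = self.n_dof
        W = np.zeros((self.dim, self.dim))
        for i in range(d):
            W[d + i, d + i] = self.sigma_v_sq[i]
        return W


@dataclass(frozen=True)
class ObservationModel:
    """Linear tuning model: counts = C @ [regressors, 1] + Gaussian noise.

    ``C`` has one column per regressor of the chosen ``form`` plus a trailing
    baseline column; ``Q`` is the full channels x channels residual covariance.
    ``lag`` aligns counts at bin ``t - lag`` with kinematics at bin ``t``
    (neural activity leads the movement it encodes).
    """

    C: np.ndarray
    Q: np.ndarray
    lag: int
    form: str
    n_dof: int

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown measurement-model form {self.form!r}")
        expected = len(form_columns(self.form, self.n_dof)) + 1
        if self.C.shape[1] != expected:
            raise ValueError(
                f"C has {self.C.shape[1]} columns, form {self.form!r} needs {expected}"
            )

    @property
    def n_channels(self) -> int:
        return self.C.shape[0]

    @property
    def C_full(self) -> np.ndarray:
        """C embedded into the full state dimension (zeros for absent regressors)."""
        dim = 2 * self.n_dof + 1
        full = np.zeros((self.C.shape[0], dim))
        cols = form_columns(self.form, self.n_dof) + [dim - 1]
        full[:, cols] = self.C
        return full


def form_columns(form: str, n_dof: int) -> list[int]:
    """State-vector column indices of the regressors used by ``form``."""
    pos = list(range(n_dof))
    vel = list(range(n_dof, 2 * n_dof))
    if form == "position_only":
        return pos
    if form == "velocity_only":
        return vel
    if form == "position_and_velocity":
        return pos + vel
    raise ValueError(f"unknown measurement-model form {form!r}")


@dataclass(frozen=True)
class DecoderModel:
    """A fully fitted decoder: state + observation models and the ReFIT flag."""

    state: StateModel
    obs: ObservationModel
    refit: bool = False

    @property
    def dt(self) -> float:
        return self.state.dt

    @property
    def n_dof(self) -> int:
        return self.state.n_dof

    def to_dict(self) -> dict:
        return {
            "a_vv": self.state.a_vv.tolist(),
            "sigma_v_sq": self.state.sigma_v_sq.tolist(),
            "dt": self.state.dt,
            "n_dof": self.state.n_dof,
            "C": self.obs.C.tolist(),
            "Q": self.obs.Q.tolist(),
            "lag": self.obs.lag,
            "form": self.obs.form,
            "refit": self.refit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecoderModel":
        state = StateModel(
            a_vv=np.asarray(d["a_vv"], dtype=float),
            sigma_v_sq=np.asarray(d["sigma_v_sq"], dtype=float),
            dt=float(d["dt"]),
            n_dof=int(d["n_dof"]),
        )
        obs = ObservationModel(
            C=np.asarray(d["C"], dtype=float),
            Q=np.asarray(d["Q"], dtype=float),
            lag=int(d["lag"]),
            form=str(d["form"]),
            n_dof=int(d["n_dof"]),
        )
        return cls(state=state, obs=obs, refit=bool(d["refit"]))


@dataclass
class DecoderState:
    """Posterior state estimate and covariance; the offset component is pinned to 1."""

    x: np.ndarray
    P: np.ndarray
    refit_mode: bool = False


def initial_state(model: DecoderModel, cursor: float | np.ndarray = 0.5) -> DecoderState:
    """Session/block-start state: cursor position, zero velocity, P = W."""
    d = model.n_dof
    x = np.zeros(2 * d + 1)
    x[:d] = cursor
    x[-1] = 1.0
    return DecoderState(x=x, P=model.state.W.copy(), refit_mode=model.refit)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_state_model(kinematics: KinematicSeries) -> StateModel:
    """Fit the velocity damping and noise variance per DOF by least squares.

    For each DOF, ``a_vv`` minimises sum (v_t - a v_{t-1})^2 (no intercept) and
    ``sigma_v_sq`` is the residual variance.  The position row of A is fixed
    analytically (pure integration), never estimated.  Training velocities
    should already be noise-thresholded.
    """
    vel = kinematics.velocities
    if vel.shape[0] < 2:
        raise DegenerateFitError("need at least 2 bins to fit the state model")
    a = np.empty(vel.shape[1])
    s2 = np.empty(vel.shape[1])
    for d in range(vel.shape[1]):
        v_prev, v_next = vel[:-1, d], vel[1:, d]
        denom = float(v_prev @ v_prev)
        if denom == 0.0:
            raise DegenerateFitError(f"all-zero training velocities for DOF {d}")
        a[d] = float(v_prev @ v_next) / denom
        resid = v_next - a[d] * v_prev
        s2[d] = float(resid @ resid) / resid.size
    return StateModel(a_vv=a, sigma_v_sq=s2, dt=kinematics.dt,
                      n_dof=vel.shape[1])


def _regressors(kinematics: KinematicSeries, form: str) -> np.ndarray:
    cols = form_columns(form, kinematics.n_dof)
    full = np.hstack([kinematics.positions, kinematics.velocities,
                      np.ones((kinematics.n_bins, 1))])
    return full[:, cols + [2 * kinematics.n_dof]]


def fit_observation_model(counts: SpikeCountMatrix, kinematics: KinematicSeries,
                          form: str = "position_and_velocity", lag: int = 0,
                          ridge: float = 1e-6) -> ObservationModel:
    """ML fit of the tuning coefficients C and residual covariance Q.

    Counts at bin ``t - lag`` are regressed on kinematic state at bin ``t``
    (per-channel OLS with a constant); Q is the covariance of the stacked
    residuals.  A tiny ridge (relative to the mean diagonal) is added to Q if
    it is singular, which happens in few-channel sessions.
    """
    if counts.n_bins != kinematics.n_bins:
        raise ValueError("counts and kinematics must share the bin grid")
    X = _regressors(kinematics, form)
    T = X.shape[0]
    if lag < 0 or lag >= T:
        raise ValueError("lag must be a small nonnegative number of bins")
    Y = counts.counts[: T - lag].astype(float)
    Xl = X[lag:]

    rank = np.linalg.matrix_rank(Xl)
    if rank < Xl.shape[1]:
        # name the collinear columns to make the error actionable
        names = _column_names(form, kinematics.n_dof)
        _, R = np.linalg.qr(Xl)
        bad = [names[j] for j in range(Xl.shape[1])
               if abs(R[j, j]) < 1e-10 * max(1.0, abs(R[0, 0]))]
        raise DegenerateFitError(
            f"rank-deficient regressors (rank {rank} < {Xl.shape[1]}); "
            f"collinear columns: {bad or 'unidentified'}"
        )

    B, *_ = np.linalg.lstsq(Xl, Y, rcond=None)
    resid = Y - Xl @ B
    Q = resid.T @ resid / resid.shape[0]
    Q = 0.5 * (Q + Q.T)
    if np.linalg.matrix_rank(Q) < Q.shape[0] or np.min(np.linalg.eigvalsh(Q)) <= 0:
        Q = Q + ridge * np.mean(np.diag(Q)) * np.eye(Q.shape[0])
    return ObservationModel(C=B.T, Q=Q, lag=lag, form=form,
                            n_dof=kinematics.n_dof)


def _column_names(form: str, n_dof: int) -> list[str]:
    pos = [f"pos{d}" for d in range(n_dof)]
    vel = [f"vel{d}" for d in range(n_dof)]
    base = {"position_only": pos, "velocity_only": vel,
            "position_and_velocity": pos + vel}[form]
    return base + ["offset"]


def fit_decoder(counts: SpikeCountMatrix, kinematics: KinematicSeries,
                form: str = "position_and_velocity",
                lag: int | None = None) -> DecoderModel:
    """Fit a complete decoder; selects the lag by cross-validation if not given."""
    state = fit_state_model(kinematics)
    if lag is None:
        lag = select_lag(counts, kinematics, form=form)
    obs = fit_observation_model(counts, kinematics, form=form, lag=lag)
    return DecoderModel(state=state, obs=obs, refit=False)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def kf_step(state: DecoderState, y: np.ndarray, model: DecoderModel) -> DecoderState:
    """One predict/update cycle of the Kalman filter.

    In ReFIT mode the a-priori covariance is masked to zero position (and
    offset) uncertainty before the gain is formed, so innovations move the
    state only through the velocity components.
    """
    A, W = model.state.A, model.state.W
    C, Q = model.obs.C_full, model.obs.Q

    x_pred = A @ state.x
    P_pred = A @ state.P @ A.T + W
    if state.refit_mode:
        from .refit import refit_apriori_mask
        P_pred = refit_apriori_mask(P_pred, model.n_dof)

    S = C @ P_pred @ C.T + Q
    K = P_pred @ C.T @ np.linalg.inv(S)
    x_new = x_pred + K @ (y - C @ x_pred)
    x_new[-1] = 1.0
    # Joseph-form update: PSD-preserving under ill-conditioned Q
    IKC = np.eye(P_pred.shape[0]) - K @ C
    P_new = IKC @ P_pred @ IKC.T + K @ Q @ K.T
    P_new = 0.5 * (P_new + P_new.T)
    if np.any(np.diag(P_new) < -1e-9):
        raise NumericalFailureError("posterior covariance lost PSD")
    return DecoderState(x=x_new, P=P_new, refit_mode=state.refit_mode)


def decode_online(state: DecoderState, cursor: np.ndarray, model: DecoderModel,
                  control_mode: str = "integrated_velocity") -> tuple[DecoderState, np.ndarray]:
    """Apply the control law after a filter update and return the new cursor.

    Integrated-velocity control: the cursor moves by the posterior velocity
    times the bin width, and the filter's position state is overwritten with
    the cursor so the next decode is conditioned on the displayed position.
    """
    d = model.n_dof
    if control_mode == "integrated_velocity":
        new_cursor = np.asarray(cursor, dtype=float) + state.x[d:2 * d] * model.dt
        state.x[:d] = new_cursor
    elif control_mode == "filter":
        new_cursor = state.x[:d].copy()
    else:
        raise ValueError(f"unknown control mode {control_mode!r}")
    return state, new_cursor


def run_filter(counts: SpikeCountMatrix, model: DecoderModel,
               start_pos: float | np.ndarray = 0.5,
               control_mode: str = "filter") -> KinematicSeries:
    """Run the fitted filter over a count matrix and return decoded kinematics.

    With ``lag`` L, the decoded state at bin ``t`` is updated with the counts
    recorded at bin ``t - L``; the first L bins carry the prediction only.
    """
    d = model.n_dof
    lag = model.obs.lag
    T = counts.n_bins
    st = initial_state(model, cursor=start_pos)
    cursor = np.atleast_1d(np.asarray(start_pos, dtype=float)) * np.ones(d)
    pos = np.zeros((T, d))
    vel = np.zeros((T, d))
    for t in range(T):
        if t - lag >= 0:
            st = kf_step(st, counts.counts[t - lag].astype(float), model)
        else:
            st = DecoderState(x=model.state.A @ st.x,
                              P=model.state.A @ st.P @ model.state.A.T + model.state.W,
                              refit_mode=st.refit_mode)
            st.x[-1] = 1.0
        st, cursor = decode_online(st, cursor, model, control_mode=control_mode)
        pos[t] = cursor
        vel[t] = st.x[d:2 * d]
    return KinematicSeries(dt=model.dt, positions=pos, velocities=vel)


# ---------------------------------------------------------------------------
# offline evaluation
# ---------------------------------------------------------------------------

def _fold_slices(n: int, k: int) -> list[slice]:
    edges = np.linspace(0, n, k + 1).astype(int)
    return [slice(edges[i], edges[i + 1]) for i in range(k)]


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def decode_offline(counts: SpikeCountMatrix, kinematics: KinematicSeries,
                   form: str = "position_and_velocity", lag: int = 0,
                   n_folds: int = 5, control_mode: str = "filter",
                   velocity_cutoff: float | None = None) -> dict:
    """Cross-validated offline reconstruction of held-out kinematics.

    The series is split into ``n_folds`` contiguous folds; for each fold the
    decoder is fitted on the remaining bins and run over the held-out bins
    (starting from the true position at the fold boundary).  Pearson
    correlations between predicted and actual position and velocity are
    reported per DOF (fold-mean), with zero-variance folds skipped as missing.
    """
    from .signal_prep import threshold_training_velocity

    T = kinematics.n_bins
    d = kinematics.n_dof
    pred_pos = np.full((T, d), np.nan)
    pred_vel = np.full((T, d), np.nan)
    corrs_pos = []
    corrs_vel = []
    for sl in _fold_slices(T, n_folds):
        train = np.ones(T, dtype=bool)
        train[sl] = False
        kin_tr = KinematicSeries(dt=kinematics.dt,
                                 positions=kinematics.positions[train],
                                 velocities=kinematics.velocities[train])
        if velocity_cutoff is not None:
            kin_tr.velocities = threshold_training_velocity(
                kin_tr.velocities, velocity_cutoff)
        cnt_tr = SpikeCountMatrix(dt=counts.dt, counts=counts.counts[train],
                                  channel_ids=counts.channel_ids)
        state = fit_state_model(kin_tr)
        obs = fit_observation_model(cnt_tr, kin_tr, form=form, lag=lag)
        model = DecoderModel(state=state, obs=obs)
        cnt_te = SpikeCountMatrix(dt=counts.dt, counts=counts.counts[sl],
                                  channel_ids=counts.channel_ids)
        dec = run_filter(cnt_te, model,
                         start_pos=kinematics.positions[sl.start if sl.start < T else -1],
                         control_mode=control_mode)
        pred_pos[sl] = dec.positions
        pred_vel[sl] = dec.velocities
        corrs_pos.append([_safe_corr(dec.positions[:, j], kinematics.positions[sl, j])
                          for j in range(d)])
        corrs_vel.append([_safe_corr(dec.velocities[:, j], kinematics.velocities[sl, j])
                          for j in range(d)])
    return {
        "position_rho": np.nanmean(np.asarray(corrs_pos, dtype=float), axis=0),
        "velocity_rho": np.nanmean(np.asarray(corrs_vel, dtype=float), axis=0),
        "predicted": KinematicSeries(dt=kinematics.dt, positions=pred_pos,
                                     velocities=pred_vel),
    }


def select_lag(counts: SpikeCountMatrix, kinematics: KinematicSeries,
               candidates=LAG_CANDIDATES, form: str = "position_and_velocity",
               n_folds: int = 5) -> int:
    """Pick the lag maximising cross-validated velocity reconstruction.

    Velocity drives the control law, so the cross-validated offline velocity
    correlation is the selection criterion; exact ties break to the smaller lag.
    """
    candidates = sorted(candidates)
    best_lag, best_score = candidates[0], -np.inf
    for lag in candidates:
        res = decode_offline(counts, kinematics, form=form, lag=lag,
                             n_folds=n_folds)
        with np.errstate(all="ignore"):
            score = float(np.nanmean(res["velocity_rho"]))
        if np.isfinite(score) and score > best_score + 1e-12:
            best_lag, best_score = lag, score
    return int(best_lag)
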