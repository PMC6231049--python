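"""Closed-loop synthetic-session engine: tuned encoder, simulated user, task logic.

This module stands in for the primate rig.  It emulates:

* a population of ~50 channels whose per-bin threshold-crossing counts are
  Poisson around a rectified linear function of finger position and velocity
  (plus a baseline), optionally cross-tuned between two finger-group DOFs;
* a feedback-controlled user who issues corrective velocity commands toward
  the current target from the *displayed* cursor, with a reaction delay, a
  speed cap and signal-dependent motor noise.  The encoder is driven by the
  user's clean intended command (the premise that makes intention estimation
  meaningful), while the hand -- when there is one -- executes the command
  plus motor noise;
* the target-acquisition trial engine (center-out / random / flex-extend
  target sequences, hold timer that resets on target exit, timeout, immediate
  next-target presentation).

All randomness flows from explicit ``numpy.random.Generator`` objects, so a
(scenario, seed) pair reproduces a session bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kalman import DecoderModel, fit_decoder, initial_state, kf_step, decode_online
from .refit import estimate_intent, retrain_measurement_model
from .signal_prep import (
    DEFAULT_DT,
    VELOCITY_CUTOFF,
    KinematicSeries,
    SpikeCountMatrix,
    select_channels,
    threshold_training_velocity,
)

#: Non-center target positions for the center-out style (includes the
#: printed 5%/95% extremes, symmetric about the 50% center).
CENTER_OUT_POSITIONS = (0.05, 0.20, 0.35, 0.65, 0.80, 0.95)

TARGET_STYLES = ("center_out", "random", "flex_extend")


@dataclass(frozen=True)
class TaskConfig:
    """Target-acquisition task parameters (arc-fraction units, seconds)."""

    target_style: str = "center_out"
    target_width: float = 0.165
    hold_time: float = 0.5
    timeout: float = 10.0
    dt: float = DEFAULT_DT
    display_clamp: tuple[float, float] = (-0.5, 1.5)

    def __post_init__(self) -> None:
        if self.target_style not in TARGET_STYLES:
            raise ValueError(f"unknown target style {self.target_style!r}")
        if not 0 < self.target_width < 1:
            raise ValueError("target width must lie in (0, 1)")
        if not self.hold_time < self.timeout:
            raise ValueError("hold time must be shorter than the timeout")


@dataclass(frozen=True)
class EncoderModel:
    """Poisson tuned-channel population: counts ~ Poisson(max(0, C @ [pos, vel, 1])).

    ``coeffs`` is (n_channels, 2*n_dof + 1) in counts/bin, columns ordered
    position(s), velocity(s), baseline; baselines are nonnegative.
    """

    coeffs: np.ndarray
    n_dof: int = 1
    cross_tuning_corr: float | None = None  # bookkeeping for 2-DOF scenarios

    def __post_init__(self) -> None:
        if np.any(self.coeffs[:, -1] < 0):
            raise ValueError("baseline coefficients must be nonnegative")

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[0]

    def rates(self, pos: np.ndarray, vel: np.ndarray) -> np.ndarray:
        """Rectified per-bin expected counts for (bins, n_dof) kinematics."""
        pos = np.atleast_2d(pos)
        vel = np.atleast_2d(vel)
        X = np.hstack([pos, vel, np.ones((pos.shape[0], 1))])
        return np.maximum(X @ self.coeffs.T, 0.0)


def make_tuned_population(n_channels: int, rng: np.random.Generator,
                          n_dof: int = 1,
                          pos_scale: tuple[float, float] = (0.12, 0.5),
                          vel_scale: tuple[float, float] = (0.05, 0.4),
                          base_range: tuple[float, float] = (1.0, 3.0),
                          cross_tuning_corr: float | None = None,
                          exclusive: bool = False) -> EncoderModel:
    """Draw a random tuned population.

    Position/velocity coefficients get random signs and magnitudes uniform on
    the given ranges (counts/bin per arc, counts/bin per arc/s); baselines are
    uniform on ``base_range`` counts/bin.  For two DOFs, ``cross_tuning_corr``
    rho builds the second DOF's tuning as ``rho * first + sqrt(1-rho^2) *
    independent`` (co-contraction-like sharing); ``exclusive`` instead splits
    the population into two halves each tuned to a single DOF.
    """
    def draw(scale):
        signs = rng.choice([-1.0, 1.0], size=n_channels)
        return signs * rng.uniform(*scale, size=n_channels)

    base = rng.uniform(*base_range, size=n_channels)
    if n_dof == 1:
        coeffs = np.column_stack([draw(pos_scale), draw(vel_scale), base])
        return EncoderModel(coeffs=coeffs, n_dof=1)
    if n_dof != 2:
        raise ValueError("only 1 or 2 DOFs supported")

    p0, v0 = draw(pos_scale), draw(vel_scale)
    if exclusive:
        p1, v1 = draw(pos_scale), draw(vel_scale)
        half = n_channels // 2
        p0[half:] = 0.0
        v0[half:] = 0.0
        p1[:half] = 0.0
        v1[:half] = 0.0
        corr = 0.0
    else:
        rho = 0.0 if cross_tuning_corr is None else float(cross_tuning_corr)
        mix = np.sqrt(max(0.0, 1.0 - rho ** 2))
        p1 = rho * p0 + mix * draw(pos_scale)
        v1 = rho * v0 + mix * draw(vel_scale)
        corr = rho
    coeffs = np.column_stack([p0, p1, v0, v1, base])
    return EncoderModel(coeffs=coeffs, n_dof=2, cross_tuning_corr=corr)


def generate_spikes(encoder: EncoderModel, kinematics: KinematicSeries,
                    rng: np.random.Generator) -> SpikeCountMatrix:
    """Sample Poisson counts from the encoder driven by the given kinematics."""
    rates = encoder.rates(kinematics.positions, kinematics.velocities)
    counts = rng.poisson(rates)
    return SpikeCountMatrix(dt=kinematics.dt, counts=counts)


@dataclass(frozen=True)
class UserModel:
    """Feedback-control policy of the simulated subject.

    The intended velocity command is ``clamp(gain * (target - perceived
    position), +-speed_cap)``; perception lags the display by ``delay_bins``.
    Motor noise on the executed (hand) velocity is signal-dependent
    (``std = motor_noise * |command| + noise_floor``) and temporally smooth:
    an AR(1) process with per-bin correlation ``noise_smoothness`` rather than
    white jitter, as muscle noise is low-pass.  ``hold_still`` freezes the
    hand while commands continue to drive the neural population.
    """

    gain: float = 3.0             # /s
    delay_bins: int = 4           # 200 ms at 50 ms bins
    speed_cap: float = 2.0        # arc/s
    motor_noise: float = 0.25     # fraction of |command|
    noise_floor: float = 0.02     # arc/s
    noise_smoothness: float = 0.8  # AR(1) coefficient per bin
    hold_still: bool = False

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.delay_bins < 0:
            raise ValueError("delay must be nonnegative")


@dataclass
class TrialRecord:
    """One target-acquisition attempt."""

    trial_index: int
    block_id: int
    decoder_id: str
    target_center: np.ndarray      # (n_dof,)
    target_width: float
    start_pos: np.ndarray          # cursor at trial start, (n_dof,)
    bin_start: int                 # session bin index of first trial bin
    bin_end: int                   # exclusive
    success: bool
    first_contact: float | None    # s from trial start, None if never touched
    acquire_time: float | None     # s from trial start to hold onset (success)
    elapsed: float                 # s, total trial duration
    hold_time: float
    timeout: float


@dataclass
class SessionResult:
    """Per-bin traces and trial log of one simulated block or session."""

    kinematics: KinematicSeries          # hand (or cursor) positions + velocities
    intended: KinematicSeries            # encoder-driving kinematics
    counts: SpikeCountMatrix | None
    trials: list[TrialRecord]
    target_centers: np.ndarray           # (n_bins, n_dof), NaN outside trials
    decoder_id: str = "hand"
    block_id: int = 0


def make_target_sequence(style: str, n: int, rng: np.random.Generator,
                         center: float = 0.5) -> np.ndarray:
    """Generate ``n`` target centers for the given style.

    center_out: every even-indexed target at the 50% center, odd-indexed drawn
    uniformly from the six peripheral positions; random: uniform on
    [0.05, 0.95]; flex_extend: strict 95% / 5% alternation.
    """
    if n < 1:
        raise ValueError("need at least one target")
    if style == "center_out":
        out = np.full(n, center)
        n_odd = n // 2
        out[1::2] = rng.choice(CENTER_OUT_POSITIONS, size=n_odd)
        # the first target moves away from center
        out[0::2] = center
        return out
    if style == "random":
        return rng.uniform(0.05, 0.95, size=n)
    if style == "flex_extend":
        out = np.empty(n)
        out[0::2] = 0.95
        out[1::2] = 0.05
        return out
    raise ValueError(f"unknown target style {style!r}")


class _TrialEngine:
    """Bin-by-bin trial bookkeeping: contact, hold (reset on exit), timeout."""

    def __init__(self, task: TaskConfig, targets: np.ndarray, n_dof: int,
                 active_dof: int, rest_pos: float, decoder_id: str,
                 block_id: int):
        self.task = task
        self.targets = targets
        self.n_dof = n_dof
        self.active_dof = active_dof
        self.rest_pos = rest_pos
        self.decoder_id = decoder_id
        self.block_id = block_id
        self.hold_bins = max(int(round(task.hold_time / task.dt)), 1)
        self.timeout_bins = int(round(task.timeout / task.dt))
        self.records: list[TrialRecord] = []
        self._begin(0, None)

    def _begin(self, session_bin: int, start_pos) -> None:
        self.idx = len(self.records)
        self.t0 = session_bin
        self.start_pos = None if start_pos is None else np.array(start_pos)
        self.bins_in_target = 0
        self.first_contact_bin: int | None = None

    @property
    def done(self) -> bool:
        return len(self.records) >= len(self.targets)

    def current_target(self) -> np.ndarray:
        c = np.full(self.n_dof, self.rest_pos)
        c[self.active_dof] = self.targets[self.idx]
        return c

    def step(self, session_bin: int, pos: np.ndarray) -> None:
        """Advance one bin given the cursor position at the end of that bin."""
        if self.done:
            return
        if self.start_pos is None:
            self.start_pos = np.array(pos)  # not knowable before the first bin
        target = self.targets[self.idx]
        p = pos[self.active_dof]
        in_target = abs(p - target) <= self.task.target_width / 2.0
        bins_elapsed = session_bin - self.t0 + 1
        if in_target:
            if self.first_contact_bin is None:
                # entry happens during this bin; time it at the bin start
                self.first_contact_bin = bins_elapsed - 1
            self.bins_in_target += 1
        else:
            self.bins_in_target = 0
        dt = self.task.dt
        if self.bins_in_target >= self.hold_bins:
            hold_onset = bins_elapsed - self.hold_bins  # start of the hold run
            self._finish(session_bin, pos, success=True,
                         first_contact=self.first_contact_bin * dt,
                         acquire_time=hold_onset * dt,
                         elapsed=bins_elapsed * dt)
        elif bins_elapsed >= self.timeout_bins:
            fc = None if self.first_contact_bin is None else self.first_contact_bin * dt
            self._finish(session_bin, pos, success=False, first_contact=fc,
                         acquire_time=None, elapsed=bins_elapsed * dt)

    def _finish(self, session_bin, pos, success, first_contact, acquire_time,
                elapsed) -> None:
        self.records.append(TrialRecord(
            trial_index=self.idx, block_id=self.block_id,
            decoder_id=self.decoder_id,
            target_center=self.current_target(),
            target_width=self.task.target_width,
            start_pos=np.array(self.start_pos),
            bin_start=self.t0, bin_end=session_bin + 1,
            success=success, first_contact=first_contact,
            acquire_time=acquire_time, elapsed=elapsed,
            hold_time=self.task.hold_time, timeout=self.task.timeout,
        ))
        if not self.done:
            self._begin(session_bin + 1, pos)  # next target appears immediately


def _delayed(history: list, t: int, delay: int):
    return history[max(t - delay, 0)]


def simulate_hand_session(user: UserModel, task: TaskConfig, n_trials: int,
                          rng: np.random.Generator,
                          encoder: EncoderModel | None = None,
                          n_dof: int = 1, active_dof: int = 0,
                          rest_pos: float = 0.0,
                          start_pos: float = 0.5) -> SessionResult:
    """Simulate a hand-control run (physical plant), e.g. a training session.

    Returns measured kinematics (command + motor noise, integrated), the clean
    intended kinematics that drive the neural population, Poisson counts when
    an encoder is supplied, and the trial log.
    """
    targets = make_target_sequence(task.target_style, n_trials, rng)
    engine = _TrialEngine(task, targets, n_dof, active_dof, rest_pos,
                          decoder_id="hand", block_id=0)
    max_bins = n_trials * engine.timeout_bins + 1

    pos = np.full(n_dof, rest_pos)
    pos[active_dof] = start_pos
    pos_hist: list[np.ndarray] = [pos.copy()]
    tgt_hist: list[np.ndarray] = [engine.current_target()]

    P, Vexec, Vint, Pint, Centers = [], [], [], [], []
    t = 0
    phi = user.noise_smoothness
    noise_state = np.zeros(n_dof)
    while not engine.done and t < max_bins:
        perceived_pos = _delayed(pos_hist, t, user.delay_bins)
        perceived_tgt = _delayed(tgt_hist, t, user.delay_bins)
        cmd = np.clip(user.gain * (perceived_tgt - perceived_pos),
                      -user.speed_cap, user.speed_cap)
        noise_std = user.motor_noise * np.abs(cmd) + user.noise_floor
        noise_state = (phi * noise_state
                       + np.sqrt(1.0 - phi ** 2) * rng.normal(0, noise_std))
        exec_vel = np.zeros(n_dof) if user.hold_still else cmd + noise_state
        pos = pos + exec_vel * task.dt

        Centers.append(engine.current_target())
        engine.step(t, pos)
        P.append(pos.copy())
        Vexec.append(exec_vel if not user.hold_still else np.zeros(n_dof))
        Vint.append(cmd.copy())
        Pint.append(pos.copy())
        pos_hist.append(pos.copy())
        tgt_hist.append(engine.current_target() if not engine.done else tgt_hist[-1])
        t += 1

    measured = KinematicSeries(dt=task.dt, positions=np.array(P),
                               velocities=np.array(Vexec))
    intended = KinematicSeries(dt=task.dt, positions=np.array(Pint),
                               velocities=np.array(Vint))
    counts = None
    if encoder is not None:
        counts = generate_spikes(encoder, intended, rng)
    return SessionResult(kinematics=measured, intended=intended, counts=counts,
                         trials=engine.records,
                         target_centers=np.array(Centers), decoder_id="hand")


def run_closed_loop(decoder: DecoderModel, encoder: EncoderModel,
                    user: UserModel, task: TaskConfig, n_trials: int,
                    rng: np.random.Generator,
                    active_dof: int = 0, rest_pos: float = 0.0,
                    start_pos: float = 0.5, decoder_id: str = "kf",
                    block_id: int = 0) -> SessionResult:
    """Run one closed-loop BMI block: user -> encoder -> decoder -> cursor.

    Each bin: the user forms a corrective command from the *displayed*
    (clamped) cursor after a reaction delay; the encoder emits Poisson counts
    from the intended kinematics (internalized cursor position + clean
    command); the decoder consumes the counts and moves the cursor by
    integrated velocity.  Decoder state is never clamped.
    """
    n_dof = decoder.n_dof
    targets = make_target_sequence(task.target_style, n_trials, rng)
    engine = _TrialEngine(task, targets, n_dof, active_dof, rest_pos,
                          decoder_id=decoder_id, block_id=block_id)
    max_bins = n_trials * engine.timeout_bins + 1

    cursor = np.full(n_dof, rest_pos, dtype=float)
    cursor[active_dof] = start_pos
    state = initial_state(decoder, cursor=cursor)
    lo, hi = task.display_clamp
    disp_hist: list[np.ndarray] = [np.clip(cursor, lo, hi)]
    tgt_hist: list[np.ndarray] = [engine.current_target()]

    P, V, Vint, Pint, Centers, Counts = [], [], [], [], [], []
    t = 0
    while not engine.done and t < max_bins:
        displayed = np.clip(cursor, lo, hi)
        perceived_pos = _delayed(disp_hist, t, user.delay_bins)
        perceived_tgt = _delayed(tgt_hist, t, user.delay_bins)
        cmd = np.clip(user.gain * (perceived_tgt - perceived_pos),
                      -user.speed_cap, user.speed_cap)

        rates = encoder.rates(displayed[None, :], cmd[None, :])[0]
        y = rng.poisson(rates).astype(float)
        state = kf_step(state, y, decoder)
        state, cursor = decode_online(state, cursor, decoder)

        Centers.append(engine.current_target())
        engine.step(t, cursor)
        P.append(cursor.copy())
        V.append(state.x[n_dof:2 * n_dof].copy())
        Vint.append(cmd.copy())
        Pint.append(displayed.copy())
        Counts.append(y)
        disp_hist.append(np.clip(cursor, lo, hi))
        tgt_hist.append(engine.current_target() if not engine.done else tgt_hist[-1])
        t += 1

    decoded = KinematicSeries(dt=task.dt, positions=np.array(P),
                              velocities=np.array(V))
    intended = KinematicSeries(dt=task.dt, positions=np.array(Pint),
                               velocities=np.array(Vint))
    counts = SpikeCountMatrix(dt=task.dt, counts=np.array(Counts, dtype=int))
    return SessionResult(kinematics=decoded, intended=intended, counts=counts,
                         trials=engine.records,
                         target_centers=np.array(Centers),
                         decoder_id=decoder_id, block_id=block_id)


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """A fully seeded synthetic-session description."""

    name: str
    seed: int
    n_channels: int = 48
    n_dof: int = 1
    pos_scale: tuple[float, float] = (0.12, 0.5)
    vel_scale: tuple[float, float] = (0.05, 0.4)
    task_train: TaskConfig = field(default_factory=lambda: TaskConfig(
        target_style="center_out", target_width=0.15, hold_time=0.75))
    task_eval: TaskConfig = field(default_factory=lambda: TaskConfig(
        target_style="center_out", target_width=0.165, hold_time=0.5))
    user: UserModel = field(default_factory=UserModel)
    n_hand_trials: int = 120
    n_online_trials: int = 80
    n_block_trials: int = 40
    n_sets: int = 2
    cross_tuning_corr: float | None = None
    exclusive_tuning: bool = False
    n_block_trials_2dof: int = 60
    context_perturbation: float = 0.0  # relative tuning jitter mid-session

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


def build_session_scenario(name: str, seed: int = 0) -> Scenario:
    """Preset scenarios mirroring the study's session designs at reduced size.

    ``refit_day``: hand training, online initial-KF trials, then alternating
    initial-KF / ReFIT evaluation blocks.  ``two_dof_ABAB``: four alternating
    hand blocks with one active DOF each, cross-tuned population.
    ``two_dof_exclusive``: the same design with DOF-exclusive tuning.
    ``context_switch``: a refit day whose encoder tuning is perturbed for the
    second half of the evaluation blocks.
    """
    if name == "refit_day":
        return Scenario(name=name, seed=seed)
    # The 2-DOF analysis days use the full 96-channel array and a strongly
    # tuned population; co-contraction-like sharing is near-total, matching
    # the observation that modulated units carried both finger groups.
    two_dof_task = TaskConfig(target_style="center_out", target_width=0.165,
                              hold_time=1.0)
    if name == "two_dof_ABAB":
        return Scenario(name=name, seed=seed, n_dof=2, n_channels=96,
                        cross_tuning_corr=0.98,
                        pos_scale=(0.3, 1.2), vel_scale=(1.0, 3.0),
                        task_train=two_dof_task)
    if name == "two_dof_exclusive":
        return Scenario(name=name, seed=seed, n_dof=2, n_channels=96,
                        exclusive_tuning=True,
                        pos_scale=(0.3, 1.2), vel_scale=(1.0, 3.0),
                        task_train=two_dof_task)
    if name == "context_switch":
        return Scenario(name=name, seed=seed, context_perturbation=0.3)
    raise ValueError(f"unknown scenario preset {name!r}")


def run_refit_day(scenario: Scenario, seed: int | None = None,
                  lag: int | None = None) -> dict:
    """Execute the full two-stage session: train, online KF, ReFIT, A-B blocks.

    Returns a dict with the fitted models, the hand/online sessions, and the
    list of evaluation blocks (decoder_id 'kf' or 'refit', alternating).
    """
    seed = scenario.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    r_enc, r_hand, r_online, *r_blocks = [np.random.default_rng(s)
                                          for s in ss.spawn(3 + 2 * scenario.n_sets)]

    encoder = make_tuned_population(scenario.n_channels, r_enc,
                                    n_dof=scenario.n_dof,
                                    pos_scale=scenario.pos_scale,
                                    vel_scale=scenario.vel_scale)
    hand = simulate_hand_session(scenario.user, scenario.task_train,
                                 scenario.n_hand_trials, r_hand,
                                 encoder=encoder)

    sel = select_channels(hand.counts)
    counts = hand.counts.subset(sel.active_ids)
    kin_train = KinematicSeries(
        dt=hand.kinematics.dt, positions=hand.kinematics.positions,
        velocities=threshold_training_velocity(hand.kinematics.velocities,
                                               VELOCITY_CUTOFF))
    kf_model = fit_decoder(counts, kin_train, lag=lag)

    enc_active = EncoderModel(coeffs=encoder.coeffs[sel.active_ids],
                              n_dof=scenario.n_dof)
    online = run_closed_loop(kf_model, enc_active, scenario.user,
                             scenario.task_eval, scenario.n_online_trials,
                             r_online, decoder_id="kf_online", block_id=-1)

    intent = estimate_intent(online.kinematics, online.target_centers,
                             scenario.task_eval.target_width)
    refit_model = retrain_measurement_model(online.counts, intent, kf_model)

    blocks: list[SessionResult] = []
    block_id = 0
    for s in range(scenario.n_sets):
        for model, did in ((kf_model, "kf"), (refit_model, "refit")):
            enc = enc_active
            if scenario.context_perturbation and s >= scenario.n_sets // 2:
                r_pert = np.random.default_rng(ss.spawn(1)[0])
                jitter = 1.0 + scenario.context_perturbation * r_pert.standard_normal(
                    enc_active.coeffs.shape)
                enc = EncoderModel(coeffs=np.abs(enc_active.coeffs * jitter)
                                   * np.sign(enc_active.coeffs),
                                   n_dof=scenario.n_dof)
            blocks.append(run_closed_loop(
                model, enc, scenario.user, scenario.task_eval,
                scenario.n_block_trials, r_blocks[block_id % len(r_blocks)],
                decoder_id=did, block_id=block_id))
            block_id += 1

    return {
        "scenario": scenario,
        "encoder": encoder,
        "channel_selection": sel,
        "hand": hand,
        "train_counts": counts,
        "train_kinematics": kin_train,
        "kf_model": kf_model,
        "refit_model": refit_model,
        "online": online,
        "intent": intent,
        "blocks": blocks,
    }


def run_two_dof_session(scenario: Scenario, seed: int | None = None) -> dict:
    """A-B-A-B alternating single-active-DOF hand blocks for 2-DOF analysis.

    The restrained DOF is held at full extension while the active DOF runs the
    center-out task; blocks alternate index-like (DOF 0) and MRP-like (DOF 1).
    Returns concatenated kinematics and counts plus per-bin active-DOF labels.
    """
    seed = scenario.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    r_enc, *r_blk = [np.random.default_rng(s) for s in ss.spawn(5)]
    encoder = make_tuned_population(
        scenario.n_channels, r_enc, n_dof=2,
        pos_scale=scenario.pos_scale, vel_scale=scenario.vel_scale,
        cross_tuning_corr=scenario.cross_tuning_corr,
        exclusive=scenario.exclusive_tuning)

    kins, counts_list, labels, all_trials = [], [], [], []
    for b, active in enumerate((0, 1, 0, 1)):
        sess = simulate_hand_session(
            scenario.user, scenario.task_train, scenario.n_block_trials_2dof,
            r_blk[b], encoder=encoder, n_dof=2, active_dof=active,
            rest_pos=0.0, start_pos=0.5)
        kins.append(sess.kinematics)
        counts_list.append(sess.counts.counts)
        labels.append(np.full(sess.kinematics.n_bins, active))
        all_trials.extend(sess.trials)

    kin = KinematicSeries(dt=scenario.task_train.dt,
                          positions=np.vstack([k.positions for k in kins]),
                          velocities=np.vstack([k.velocities for k in kins]))
    counts = SpikeCountMatrix(dt=scenario.task_train.dt,
                              counts=np.vstack(counts_list))
    return {
        "scenario": scenario,
        "encoder": encoder,
        "kinematics": kin,
        "counts": counts,
        "active_dof": np.concatenate(labels),
        "trials": all_trials,
    }
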