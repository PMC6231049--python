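# Methods

This note documents the models, the synthetic-session generator, the numerical
choices, and what the package's tests do and do not establish about real
recordings.

## Decoding model

The decoder is a discrete-time linear-Gaussian state-space model over the
kinematics of one finger-group degree of freedom (two for the 2-DOF variant),
binned at `dt = 50 ms`:

* **State** `x_t = [pos, vel, 1]ᵀ` (2-DOF: `[pos_a, pos_b, vel_a, vel_b, 1]ᵀ`).
  Positions are fractions of the flex-extend arc (0 = full extension,
  1 = full flexion) and are never clamped inside the computation; the
  −50 %…150 % clamp applies only to the *displayed* cursor.
* **Transition** `x_t = A x_{t−1} + w`, with the position row fixed to exact
  velocity integration (`pos_t = pos_{t−1} + dt·vel_{t−1}`), a single free
  velocity-damping coefficient `a_vv` per DOF, and process noise only on the
  velocity diagonal. For two DOFs, `A` and `W` carry no cross-finger terms:
  the physical model is decoupled by construction, so any decoded co-movement
  must come from the observation model. The structural zeros are asserted, not
  estimated.
* **Observation** `y_{t−lag} = C x_t + q`, per-channel linear tuning to
  position and/or velocity plus a baseline column, with full (channel ×
  channel) residual covariance `Q`. Three model forms are available
  (position-only, velocity-only, position+velocity); position+velocity is the
  default, the form used for all online work. The lag (0–3 bins) aligns
  neural activity with the movement it leads.

"Maximum likelihood" fitting of this model is ordinary least squares per
channel plus the residual (co)variance — the exact ML solution for a
linear-Gaussian model — so the package uses plain `lstsq` rather than an
iterative estimator. `a_vv` is the no-intercept autoregression of the
training velocities after the 0.2 %flex/s noise threshold is applied. The lag
is chosen to maximize 5-fold cross-validated offline *velocity* reconstruction
(velocity drives the control law); exact ties break to the smaller lag.

Filtering uses the time-varying gain (full covariance recursion, Joseph-form
update for numerical robustness) rather than a pre-converged steady-state
gain. `Q` receives a relative ridge of 1e−6 × mean diagonal only if singular,
which matters for few-channel sessions and duplicated channels. Block starts
initialize position at the current cursor (0.5 at session start), velocity 0,
and `P = W`.

**Control law.** Online, the cursor moves by the posterior velocity
(`pos_t = pos_{t−1} + vel_{t|t}·dt`) and the filter's position state is then
overwritten with the cursor, so the next update is conditioned on what the
subject actually saw. Offline reconstructions default to the raw filter
output instead.

## ReFIT

Stage two retrains only `(C, Q)` from an online block run with the initial
filter: decoded velocities are flipped to point at the target center
(magnitude preserved) and zeroed when the cursor is inside the visible target
extent (`|p − c| ≤ w/2`); decoded positions and the first-stage `A`, `W`, and
lag are untouched. The recalibrated filter assumes the subject has perfectly
internalized the cursor position: the predicted covariance is masked to its
velocity diagonal block before the gain (position, offset, and — for two
DOFs — cross-velocity entries zeroed). Algebraically this makes the gain's
position row identically zero, so decoded position is *exactly* the integral
of decoded velocity; the tests assert this to machine precision. Whether a
bin straddling target entry is zeroed or flipped is decided by the cursor
position at the end of that bin.

## Synthetic sessions

The simulator emulates the study conditions end to end:

* **Encoder.** 48 channels (default 1-DOF scenario) with per-bin counts
  Poisson-distributed around `max(0, c_ip·pos + c_iv·vel + c_io)`. Baselines
  are uniform on 1–3 counts/bin (20–60 spikes/s); tuning magnitudes are
  uniform with random sign, position 0.12–0.5 and velocity 0.05–0.4
  counts/bin. These scales were calibrated once so that the offline 5-fold
  reconstruction of a training day matches the decode quality reported for
  primate finger control (position ρ ≈ 0.81, velocity ρ ≈ 0.64); all
  downstream results inherit this operating point.
* **User.** A feedback controller: intended velocity
  `clamp(gain·(target − perceived position), ±2 arc/s)` with gain 3 /s and a
  200 ms (4-bin) reaction delay, perception taken from the clamped displayed
  cursor. Motor noise is signal-dependent (std = 0.25·|command| + 0.02 arc/s)
  and temporally smooth (AR(1), per-bin correlation 0.8) — muscle noise is
  low-pass, and white per-bin noise would inflate the fitted velocity process
  noise unrealistically.
* **Neural drive.** The encoder is driven by the user's *intended* kinematics
  — the clean command for velocity, the internalized (displayed) cursor for
  position — while the hand, when present, executes the command plus motor
  noise. This is the premise that makes intention estimation meaningful: hand
  training labels are noisy versions of the neural drive, and correcting
  online velocities toward the target recovers labels closer to it. It also
  reproduces decoding without physical movement (hold-still sessions).
* **Task.** Targets per the study styles: center-out (7 positions, every
  other target at 50 % flexion, peripherals at {5, 20, 35, 65, 80, 95} % —
  the printed extremes plus a symmetric interior), random (uniform on
  5–95 %), flex-extend (95 %/5 % alternation). Hold 500–750 ms (1 s for the
  2-DOF day), widths 15–16.5 % of the arc, hold timer reset on target exit,
  next target presented immediately at the current cursor. The timeout is
  never printed in the source protocol; 10 s is used — comfortably beyond the
  >3 s slow trials — and configurable.
* **Session sizes.** The default `refit_day` preset runs 120 hand-training
  trials, 80 online initial-KF trials, and 2 alternating evaluation block
  pairs of 40 trials — the same design as the original sessions
  (≈300/≈200/3×50) at reduced counts chosen to keep a 20-seed batch within
  minutes on one CPU. Counts are preset fields and can be raised.
* **2-DOF presets.** The alternating A-B-A-B single-active-DOF design uses
  the full 96-channel array with a strongly tuned population (velocity
  1.0–3.0 counts/bin). `two_dof_ABAB` draws the second DOF's tuning with
  correlation 0.98 to the first (near-total sharing, consistent with the
  observation that nearly all modulated units carried both finger groups);
  `two_dof_exclusive` splits the population into two halves tuned to a single
  DOF each. The co-movement ratio (restrained-DOF ÷ moving-DOF predicted
  velocity RMS) is ≈0.55 under shared tuning and ≈0.18 under exclusive
  tuning; the residual 0.18 is the Poisson-noise floor of the decode, not
  leakage through the fitted coefficients.
* **Onset-classification scenarios.** Trials at 20 ms resolution with a
  Gaussian response bump (sd 20 ms) time-locked to onset. `separable` splits
  channels between finger groups; `identical` gives both groups the same
  response (accuracy pins to chance); `broad` gives equal gains but a
  ±20 ms group-specific latency, placing the class information in response
  *timing* — the sliding 160 ms/20 ms window preserves it while a single
  100 ms bin integrates it away, reproducing the direction of the
  temporal-resolution comparison. These are clean constructions: absolute
  accuracies (≈100 % when separable) are synthetic ceilings, not predictions
  for real recordings.

## What the tests establish — and what they do not

The simulator reproduces the *directional* findings: ReFIT beats the initial
Kalman filter in median bit rate across seeded sessions (one-sided sign
test), orbiting fraction drops, intention estimation raises velocity
modulation of tuned channels significantly against a label-randomization
null, and shared tuning produces the 2-DOF co-movement artifact while
exclusive tuning does not. Magnitudes depend on the simulated user and
encoder: real primate behavior includes motivation, learning within session,
non-stationary tuning, electrode noise, and failures to acquire (the
simulated user succeeds within the timeout at this SNR, so success-rate gains
are near zero where the animals showed a few percent). The fitted velocity
damping on simulated hand data (≈0.91) sits slightly above the values fitted
to real finger movement (≈0.86), a consequence of the first-order user model.

## Numerical and edge-case conventions

* Bins are half-open `[t, t + dt)`; an event exactly on a boundary counts in
  the later bin. Binning conserves event counts over the covered span.
* The first bin's velocity is 0 (no pre-session position exists).
* The moving-average smoother shrinks its window at trace edges rather than
  padding.
* Channel selection uses a strict `> 1 spike/s` comparison; a hand-curated
  exclusion list removes channels regardless of rate (impedance-based vetting
  is not reproducible from counts alone).
* The velocity threshold zeroes magnitudes strictly below 0.002 arc/s and is
  applied to training data only.
* Fitts throughput uses the Shannon formulation `ID = log₂(1 + D/w)`; the
  formula variant is recorded in every output manifest. Failed trials
  contribute zero bits but their full elapsed time.
* Trials excluded from analysis: the first 5 per block, and random-style
  trials whose target lies within 10 % flexion of the start position.
* Modulation ignores zero-velocity bins and is undefined (NaN) when either
  movement direction has no bins; its randomization null reassigns each bin's
  corrected/raw label with probability ½.
* Rank-deficient regressors raise an error naming the collinear columns;
  all-zero training velocities raise a degenerate-fit error rather than
  returning a silent zero model.
* Negative predicted rates are allowed in the linear observation model (the
  Gaussian update does not require nonnegativity); only the *simulator*
  rectifies rates before Poisson sampling.

## Known limitations

Only 1 or 2 DOFs; no spiking biophysics, LFPs, or electrode-drift model; no
adaptive/recursive re-estimation; the SVM's regularization is the standard
soft-margin penalty (the kernel-machine reading of an L1-penalized SVM) with
`C` and `γ` exposed as tunables rather than fixed hyperparameters; onset
detection (threshold 0.05 arc/s sustained for 2 steps) is a package
convention, since "began to flex" admits many operationalizations.
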