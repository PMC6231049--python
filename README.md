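# fingerbmi

Continuous decoding of finger-group position from motor-cortical spike counts,
with the two-stage **ReFIT** (recalibrated feedback intention-trained) Kalman
filter and a closed-loop synthetic-session simulator.

Brain-machine interfaces for dexterous hand control must decode *precise*
finger movements, not just arm reaches. This package implements the full
decoding pipeline for a 1-D (or 2-D) finger-group task, in which a virtual
fingertip moves along the flex-extend arc (0 = full extension, 1 = full
flexion) to acquire and hold spherical targets:

* **Signal preparation** — flex-sensor calibration, 50 ms binning with a 50 ms
  moving-average smoother, finite-difference velocities, threshold-crossing
  spike counting, and >1 spike/s channel selection.
* **Kalman decoding** — a linear filter over the state `x_t = [pos, vel, 1]ᵀ`
  with state transition

  ```
      A = [1  dt  0;  0  a_vv  0;  0  0  1],   W = diag(0, σ_v², 0)
  ```

  (position is explained exactly by velocity integration; only velocity
  carries process noise) and a linear observation model
  `y_i = c_ip·pos + c_iv·vel + c_io` with full noise covariance `Q` and a
  0–3-bin neural-to-kinematic lag. All parameters are maximum-likelihood
  (ordinary least squares) fits from a hand-control training run. Online, the
  cursor is driven by **integrated velocity**:
  `pos_t = pos_{t−1} + vel_{t|t}·dt`, and the filter's position state is
  overwritten with the displayed cursor.
* **ReFIT recalibration** — after ~an online block with the initial filter,
  the decoded velocities are *intention-estimated* (flipped to point at the
  target; zeroed inside it), the measurement model `(C, Q)` is refit against
  these corrected kinematics, and the recalibrated filter runs with **zero
  a-priori position uncertainty**: the predicted covariance is masked to its
  velocity diagonal before the gain, so the Kalman gain's position row is
  identically zero.
* **Metrics** — Fitts-law throughput (`ID = log₂(1 + D/w)` bits per acquired
  target; bit rate = bits over task time with hold periods excluded),
  acquisition/orbiting-time decomposition, velocity modulation
  (|flexion − extension| firing-rate difference) with a randomization null,
  per-channel encoding correlation and drop-one-channel decoder value.
* **Movement-onset classification** — index vs middle-ring-pinkie (MRP)
  flexion onsets classified from 160 ms sliding-window spike counts stepped
  every 20 ms, with a Gaussian-kernel SVM under stratified 10-fold CV.
* **Closed-loop simulator** — a Poisson tuned-channel encoder plus a
  feedback-controlled user (reaction delay, speed cap, signal-dependent motor
  noise) and the target/hold/timeout trial engine, so the whole pipeline runs
  and is tested without animal recordings.

## Worked example

Run a complete simulated experiment day — hand-control training, initial
Kalman filter, online recalibration block, ReFIT, then alternating evaluation
blocks — and compare the two decoders:

```python
import numpy as np
from fingerbmi import metrics
from fingerbmi.tasks import build_session_scenario, run_refit_day

sc = build_session_scenario("refit_day", seed=1)
res = run_refit_day(sc)
for decoder in ("kf", "refit"):
    trials = [t for b in res["blocks"] if b.decoder_id == decoder
              for t in b.trials]
    ex = metrics.trial_exclusions(trials, sc.task_eval)
    print(decoder, "bit rate %.2f bps, orbiting fraction %.2f" %
          (metrics.bit_rate(trials, ex), metrics.orbiting_fraction(trials, ex)))
print("fitted a_vv %.3f, lag %d bins" %
      (res["kf_model"].state.a_vv[0], res["kf_model"].obs.lag))
```

prints

```
kf bit rate 1.00 bps, orbiting fraction 0.35
refit bit rate 1.39 bps, orbiting fraction 0.13
fitted a_vv 0.912, lag 0 bins
```

The initial Kalman filter acquires targets at ~1 bit/s but spends about a
third of each trial *orbiting* — oscillating around the target after first
contact without completing the hold. ReFIT's sharper velocity tuning and
position-certain gain cut the orbiting fraction by more than half and raise
throughput accordingly, the same signature reported for primate finger
control.

The same pipeline is scriptable from a shell:

```bash
fingerbmi simulate --preset refit_day --seed 1 --out session/
fingerbmi evaluate --trials session/trials.csv --out session/metrics/
fingerbmi classify --scenario broad --n-per-class 200 --seed 1 --out cls/
```

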