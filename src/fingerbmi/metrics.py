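"""Performance and neural-analysis metrics: throughput, timing, tuning.

Throughput follows the Fitts-law convention used for BMI target acquisition:
each successful trial earns ``ID = log2(1 + D / w)`` bits (D = start-to-target
distance, w = target width; Shannon formulation), failed trials earn zero, and
a block's bit rate is total bits over total task time with hold periods
excluded.  Timing decomposes into acquisition time (trial start to the onset
of the successful hold) and orbiting time (first target contact to hold
onset; for failures, first contact to the end of the timeout).

Neural analyses: velocity modulation (|flexion rate - extension rate|), its
change under intention estimation with a randomization null, per-channel
encoding correlation, and drop-one-channel decoder value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kalman import decode_offline
from .signal_prep import KinematicSeries, SpikeCountMatrix
from .tasks import TaskConfig, TrialRecord

logger = logging.getLogger(__name__)

#: Fitts index-of-difficulty variant recorded in every output manifest.
BIT_RATE_FORMULA = "shannon: ID = log2(1 + D/w)"


def index_of_difficulty(distance: float, width: float) -> float:
    """Shannon-formulation Fitts index of difficulty, in bits."""
    return float(np.log2(1.0 + distance / width))


def trial_exclusions(trials: list[TrialRecord], task: TaskConfig,
                     n_warmup: int = 5,
                     proximity: float = 0.10) -> list[bool]:
    """Flag trials excluded from performance analysis.

    The first ``n_warmup`` trials of each block are excluded (initial decoder
    adjustment); for the random target style, trials whose target center lies
    within ``proximity`` of the start position are excluded as requiring
    minimal movement.  Returns one ``excluded`` flag per trial.
    """
    seen: dict[int, int] = {}
    flags = []
    for tr in trials:
        k = seen.get(tr.block_id, 0)
        seen[tr.block_id] = k + 1
        excluded = k < n_warmup
        if task.target_style == "random" and not excluded:
            d = float(np.max(np.abs(tr.target_center - tr.start_pos)))
            excluded = d < proximity
        flags.append(excluded)
    return flags


def trial_bits(trial: TrialRecord) -> float:
    """Bits earned by one trial: ID for a success, 0 for a failure."""
    if not trial.success:
        return 0.0
    d = float(np.max(np.abs(trial.target_center - trial.start_pos)))
    return index_of_difficulty(d, trial.target_width)


def trial_task_time(trial: TrialRecord) -> float:
    """Time charged to the trial, hold excluded.

    Successful trials are charged their acquisition time; failures the full
    elapsed time to timeout.
    """
    return trial.acquire_time if trial.success else trial.elapsed


def bit_rate(trials: list[TrialRecord],
             excluded: list[bool] | None = None) -> float:
    """Fitts bit rate over a set of trials: total bits / total task time."""
    if excluded is None:
        excluded = [False] * len(trials)
    kept = [t for t, ex in zip(trials, excluded) if not ex]
    total_time = sum(trial_task_time(t) for t in kept)
    if total_time <= 0:
        logger.warning("bit_rate: zero total task time")
        return float("nan")
    return sum(trial_bits(t) for t in kept) / total_time


def timing_decomposition(trial: TrialRecord) -> tuple[float, float | None]:
    """(acquisition_time, orbiting_time) for one trial, hold excluded.

    Orbiting is first-contact-to-hold-onset for successes and
    first-contact-to-timeout for failures; ``None`` if the target was never
    touched (or, for a failure, orbiting spans contact to timeout end).
    """
    if trial.success:
        acq = trial.acquire_time
        orbit = None if trial.first_contact is None else acq - trial.first_contact
    else:
        acq = trial.elapsed
        orbit = (None if trial.first_contact is None
                 else trial.elapsed - trial.first_contact)
    return acq, orbit


def orbiting_fraction(trials: list[TrialRecord],
                      excluded: list[bool] | None = None) -> float:
    """Mean fraction of each trial's task time spent orbiting."""
    if excluded is None:
        excluded = [False] * len(trials)
    fracs = []
    for tr, ex in zip(trials, excluded):
        if ex:
            continue
        acq, orbit = timing_decomposition(tr)
        if orbit is not None and acq > 0:
            fracs.append(orbit / acq)
        elif orbit is None:
            fracs.append(np.nan)  # never touched: undefined, skipped below
    return float(np.nanmean(fracs)) if fracs else float("nan")


def block_summary(trials: list[TrialRecord], task: TaskConfig) -> pd.DataFrame:
    """Per-block performance table (bit rate, success, timing; mean +- s.e.m.)."""
    excluded = trial_exclusions(trials, task)
    rows = []
    blocks = sorted({t.block_id for t in trials})
    for b in blocks:
        sub = [(t, ex) for t, ex in zip(trials, excluded) if t.block_id == b]
        kept = [t for t, ex in sub if not ex]
        if not kept:
            continue
        acq = np.array([timing_decomposition(t)[0] for t in kept])
        orb = np.array([timing_decomposition(t)[1] for t in kept
                        if timing_decomposition(t)[1] is not None])
        rows.append({
            "block_id": b,
            "decoder_id": kept[0].decoder_id,
            "n_trials": len(sub),
            "n_analyzed": len(kept),
            "success_rate": float(np.mean([t.success for t in kept])),
            "bit_rate_bps": bit_rate([t for t, _ in sub],
                                     [ex for _, ex in sub]),
            "mean_acquire_s": float(acq.mean()),
            "sem_acquire_s": float(acq.std(ddof=1) / np.sqrt(len(acq)))
            if len(acq) > 1 else np.nan,
            "mean_orbiting_s": float(orb.mean()) if orb.size else np.nan,
            "orbiting_fraction": orbiting_fraction(
                [t for t, _ in sub], [ex for _, ex in sub]),
        })
    return pd.DataFrame(rows)


def trial_table(trials: list[TrialRecord], task: TaskConfig) -> pd.DataFrame:
    """Tidy one-row-per-trial metrics table."""
    excluded = trial_exclusions(trials, task)
    rows = []
    for tr, ex in zip(trials, excluded):
        acq, orbit = timing_decomposition(tr)
        rows.append({
            "trial_index": tr.trial_index,
            "block_id": tr.block_id,
            "decoder_id": tr.decoder_id,
            "target_center": float(np.max(tr.target_center))
            if tr.target_center.size > 1 else float(tr.target_center[0]),
            "target_width": tr.target_width,
            "success": tr.success,
            "excluded": ex,
            "bits": trial_bits(tr),
            "acquisition_s": acq,
            "orbiting_s": orbit if orbit is not None else np.nan,
            "task_time_s": trial_task_time(tr),
        })
    return pd.DataFrame(rows)


def comovement_ratio(predicted: KinematicSeries, active_dof: np.ndarray) -> float:
    """Inactive-to-active predicted-velocity RMS ratio in a 2-DOF decode.

    For each block the restrained DOF's predicted velocity RMS is divided by
    the moving DOF's; the mean over both DOFs' blocks quantifies the
    co-movement artifact (≈0 for independent tuning, approaching 1 when the
    two finger groups share their tuning).
    """
    active_dof = np.asarray(active_dof)
    ratios = []
    for dof in range(predicted.n_dof):
        mask = active_dof == dof
        if not mask.any():
            continue
        act = np.sqrt(np.nanmean(predicted.velocities[mask, dof] ** 2))
        for other in range(predicted.n_dof):
            if other == dof and predicted.n_dof > 1:
                continue
            inact = np.sqrt(np.nanmean(predicted.velocities[mask, other] ** 2))
            ratios.append(inact / act)
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# neural analyses
# ---------------------------------------------------------------------------

def modulation(counts: SpikeCountMatrix, velocities: np.ndarray,
               dof: int = 0) -> np.ndarray:
    """Velocity modulation per channel, in spikes/s.

    In one dimension velocity tuning reduces to the absolute difference in
    mean firing rate between flexion (v > 0) and extension (v < 0) bins; bins
    with exactly zero velocity are ignored.  Undefined (NaN) if either side
    has no bins.
    """
    from .signal_prep import _as_bins_by_dof

    v = _as_bins_by_dof(velocities)[:, dof]
    flex, ext = v > 0, v < 0
    if not flex.any() or not ext.any():
        return np.full(counts.n_channels, np.nan)
    r_flex = counts.counts[flex].mean(axis=0) / counts.dt
    r_ext = counts.counts[ext].mean(axis=0) / counts.dt
    return np.abs(r_flex - r_ext)


def modulation_bootstrap_null(counts: SpikeCountMatrix,
                              raw_velocities: np.ndarray,
                              corrected_velocities: np.ndarray,
                              n_boot: int, rng: np.random.Generator,
                              channels: np.ndarray | None = None) -> dict:
    """Randomization null for the modulation change under intention estimation.

    The observed statistic is the mean (over channels) change in modulation
    from raw to corrected velocity labels.  Under the null that intention
    correction has no systematic effect, which bins receive a corrected label
    is arbitrary: each replicate assigns every bin its corrected label with
    probability 1/2 (raw otherwise) and recomputes the modulation change.
    p is the one-sided fraction of null changes at least as large as observed.
    """
    if n_boot < 100:
        logger.warning("modulation_bootstrap_null: n_boot=%d is small", n_boot)
    raw = np.asarray(raw_velocities, dtype=float).reshape(-1)
    corrected = np.asarray(corrected_velocities, dtype=float).reshape(-1)
    mod_raw = modulation(counts, raw)
    if channels is not None:
        mod_raw = mod_raw[channels]
    observed = modulation(counts, corrected)
    observed = (observed[channels] if channels is not None else observed)
    obs_change = float(np.nanmean(observed - mod_raw))

    null = np.empty(n_boot)
    for b in range(n_boot):
        take = rng.random(corrected.size) < 0.5
        hybrid = np.where(take, corrected, raw)
        m = modulation(counts, hybrid)
        if channels is not None:
            m = m[channels]
        null[b] = np.nanmean(m - mod_raw)
    p = float((np.sum(null >= obs_change) + 1) / (n_boot + 1))
    return {"observed_change": obs_change, "null": null, "p_value": p}


def encoding_rho(counts: SpikeCountMatrix, kinematics: KinematicSeries,
                 form: str = "position_and_velocity", lag: int = 0,
                 n_folds: int = 5) -> np.ndarray:
    """Cross-validated Pearson correlation between predicted and observed counts.

    Per channel: the tuning model is fitted on the training folds and its
    predicted rate is correlated with the held-out observed counts.
    """
    from .kalman import _fold_slices, _regressors, fit_observation_model

    T = kinematics.n_bins
    X = _regressors(kinematics, form)
    pred = np.full((T - lag, counts.n_channels), np.nan)
    obs = counts.counts[: T - lag].astype(float)
    Xl = X[lag:]
    for sl in _fold_slices(T - lag, n_folds):
        train = np.ones(T - lag, dtype=bool)
        train[sl] = False
        kin_tr = KinematicSeries(dt=kinematics.dt,
                                 positions=kinematics.positions[lag:][train],
                                 velocities=kinematics.velocities[lag:][train])
        cnt_tr = SpikeCountMatrix(dt=counts.dt, counts=counts.counts[:T - lag][train],
                                  channel_ids=counts.channel_ids)
        model = fit_observation_model(cnt_tr, kin_tr, form=form, lag=0)
        pred[sl] = Xl[sl] @ model.C.T
    rho = np.empty(counts.n_channels)
    for j in range(counts.n_channels):
        a, b = pred[:, j], obs[:, j]
        rho[j] = (np.nan if np.std(a) == 0 or np.std(b) == 0
                  else float(np.corrcoef(a, b)[0, 1]))
    return rho


def channel_value(counts: SpikeCountMatrix, kinematics: KinematicSeries,
                  channel: int, form: str = "position_and_velocity",
                  lag: int = 0, n_folds: int = 5) -> float:
    """Drop-one-channel change in offline velocity-decode correlation.

    value = rho(without channel) - rho(with channel); a negative value means
    the decoder predicts velocity worse without the channel, i.e. the channel
    is valuable.
    """
    if counts.n_channels < 2:
        raise ValueError("need at least 2 channels")
    full = decode_offline(counts, kinematics, form=form, lag=lag,
                          n_folds=n_folds)
    keep = [c for c in counts.channel_ids if c != channel]
    reduced = decode_offline(counts.subset(keep), kinematics, form=form,
                             lag=lag, n_folds=n_folds)
    return float(np.nanmean(reduced["velocity_rho"])
                 - np.nanmean(full["velocity_rho"]))


@dataclass
class ChannelAnalysis:
    """Per-channel quality summary used to pick 'high quality' examples."""

    modulation: np.ndarray
    encoding_rho: np.ndarray
    value: np.ndarray
    high_quality: np.ndarray

    @classmethod
    def compute(cls, counts: SpikeCountMatrix, kinematics: KinematicSeries,
                form: str = "position_and_velocity", lag: int = 0,
                min_modulation: float = 1.0,
                rho_threshold: float = 0.05) -> "ChannelAnalysis":
        mod = modulation(counts, kinematics.velocities)
        rho = encoding_rho(counts, kinematics, form=form, lag=lag)
        val = np.array([channel_value(counts, kinematics, ch, form=form, lag=lag)
                        for ch in counts.channel_ids])
        hq = (mod > min_modulation) & (rho > rho_threshold) & (val < 0)
        return cls(modulation=mod, encoding_rho=rho, value=val, high_quality=hq)
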