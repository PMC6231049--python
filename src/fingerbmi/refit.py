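"""Intention estimation and the second-stage ReFIT recalibration.

ReFIT retrains the observation model from online decoder output after
"correcting" the decoded velocities under the assumption that the subject
always intends to move toward the current target: off-target velocities are
flipped to point at the target center (magnitude preserved), on-target
velocities are set to zero.  Decoded positions are left untouched.  During
subsequent online control the Kalman gain is computed with zero a-priori
position uncertainty, which makes the decoded position depend on the neural
innovations only through velocity integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .kalman import DecoderModel, fit_observation_model
from .signal_prep import KinematicSeries, SpikeCountMatrix

logger = logging.getLogger(__name__)


@dataclass
class IntentionEstimatedSeries:
    """Online-decoded positions with intention-corrected velocities."""

    kinematics: KinematicSeries   # positions unchanged; velocities corrected
    on_target_mask: np.ndarray    # (n_bins, n_dof) bool
    valid_mask: np.ndarray        # bins assigned to a trial


def estimate_intent(decoded: KinematicSeries, target_centers: np.ndarray,
                    target_width: float | np.ndarray) -> IntentionEstimatedSeries:
    """Correct decoded velocities to always point at the per-bin target.

    ``target_centers`` is (n_bins, n_dof) (NaN marks bins with no trial
    assignment; those are excluded from retraining with a logged count).  A
    bin whose cursor lies within the visible target extent, ``|p - c| <=
    width/2``, gets zero velocity; otherwise the velocity keeps its magnitude
    and takes the sign of ``c - p``.
    """
    from .signal_prep import _as_bins_by_dof

    pos = decoded.positions
    vel = decoded.velocities
    centers = _as_bins_by_dof(target_centers)
    if centers.shape != pos.shape:
        raise ValueError("target_centers must be one center per bin per DOF")
    half_w = np.asarray(target_width, dtype=float) / 2.0

    valid = ~np.isnan(centers).any(axis=1)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("estimate_intent: %d bins without a trial assignment", n_dropped)

    err = centers - pos
    on_target = np.abs(err) <= half_w
    corrected = np.sign(err) * np.abs(vel)
    corrected[on_target] = 0.0
    corrected[~valid] = 0.0
    return IntentionEstimatedSeries(
        kinematics=KinematicSeries(dt=decoded.dt, positions=pos.copy(),
                                   velocities=corrected),
        on_target_mask=on_target,
        valid_mask=valid,
    )


def retrain_measurement_model(counts: SpikeCountMatrix,
                              intent: IntentionEstimatedSeries,
                              model: DecoderModel) -> DecoderModel:
    """Refit C and Q against intention-estimated kinematics; keep A, W, lag.

    Only the measurement-model coefficients change in the second stage; the
    state-transition model and the lag are carried over from the initial fit.
    Returns a new decoder with the ReFIT flag set.
    """
    valid = intent.valid_mask
    kin = KinematicSeries(dt=intent.kinematics.dt,
                          positions=intent.kinematics.positions[valid],
                          velocities=intent.kinematics.velocities[valid])
    cnt = SpikeCountMatrix(dt=counts.dt, counts=counts.counts[valid],
                           channel_ids=counts.channel_ids)
    obs = fit_observation_model(cnt, kin, form=model.obs.form, lag=model.obs.lag)
    return DecoderModel(state=model.state, obs=obs, refit=True)


def refit_apriori_mask(P_pred: np.ndarray, n_dof: int = 1) -> np.ndarray:
    """Zero the a-priori position (and offset) uncertainty before the gain.

    Keeps only the velocity diagonal block of the predicted covariance: all
    position and offset rows/columns are zeroed and, for two DOFs, so is the
    cross-finger velocity covariance.  The resulting Kalman gain has an
    identically zero position row, so position evolves purely by velocity
    integration.
    """
    dim = 2 * n_dof + 1
    if P_pred.shape != (dim, dim):
        raise ValueError(f"P_pred must be {dim}x{dim} for {n_dof} DOF")
    masked = np.zeros_like(P_pred)
    for i in range(n_dof, 2 * n_dof):
        masked[i, i] = P_pred[i, i]
    return masked
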