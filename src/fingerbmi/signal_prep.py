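"""Sensor calibration, binning, smoothing, velocity, and channel selection.

Raw inputs are a 1 kHz resistive flex-sensor trace (10-bit ADC readings) and
per-channel spike (threshold-crossing) event times.  Everything downstream
works on a common fixed-width bin grid (50 ms by default): binned positions on
the flex-extend arc (0 = full extension, 1 = full flexion), finite-difference
velocities, and a bins x channels count matrix.

Positions are kept as unclamped arc fractions throughout; the [-50%, 150%]
clamp is a display-side concern and lives in the task engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Default bin width in seconds.
DEFAULT_DT = 0.05

#: Training-velocity magnitude cutoff in arc fraction per second (0.2 %flex/s).
VELOCITY_CUTOFF = 0.002

#: Minimum mean firing rate (spikes/s) for a channel to be retained.
MIN_CHANNEL_RATE = 1.0


class InvalidCalibrationError(ValueError):
    """Flex-sensor calibration endpoints coincide."""


class DegenerateFitError(ValueError):
    """Model fitting is impossible on the supplied training data."""


@dataclass(frozen=True)
class RawSensorTrace:
    """A 1 kHz flex-sensor recording with its calibration endpoints.

    ``adc_extension`` / ``adc_flexion`` are the ADC readings noted at full
    extension and full flexion of the active finger group.
    """

    sample_times: np.ndarray  # seconds, strictly increasing
    adc_values: np.ndarray
    adc_extension: float
    adc_flexion: float

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times, dtype=float)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("sample_times must be strictly increasing")
        if self.adc_extension == self.adc_flexion:
            raise InvalidCalibrationError(
                "calibration endpoints coincide "
                f"(adc_extension == adc_flexion == {self.adc_extension})"
            )


def _as_bins_by_dof(a) -> np.ndarray:
    """Coerce a kinematic array to (n_bins, n_dof); 1-D input is one DOF."""
    a = np.asarray(a, dtype=float)
    return a.reshape(-1, 1) if a.ndim == 1 else a


@dataclass
class KinematicSeries:
    """Binned position and velocity of one or two finger-group DOFs.

    ``positions`` and ``velocities`` are (n_bins, n_dof) arrays in arc
    fraction and arc fraction per second.
    """

    dt: float
    positions: np.ndarray
    velocities: np.ndarray

    def __post_init__(self) -> None:
        self.positions = _as_bins_by_dof(self.positions)
        self.velocities = _as_bins_by_dof(self.velocities)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities must have the same shape")

    @property
    def n_bins(self) -> int:
        return self.positions.shape[0]

    @property
    def n_dof(self) -> int:
        return self.positions.shape[1]

    @classmethod
    def from_positions(cls, positions: np.ndarray, dt: float) -> "KinematicSeries":
        """Build a series from binned positions, deriving velocities."""
        positions = _as_bins_by_dof(positions)
        return cls(dt=dt, positions=positions,
                   velocities=compute_velocity(positions, dt))


@dataclass
class SpikeCountMatrix:
    """Threshold-crossing counts per fixed-width bin per channel."""

    dt: float
    counts: np.ndarray  # (n_bins, n_channels) nonnegative ints
    channel_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (bins x channels)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not self.channel_ids:
            self.channel_ids = list(range(self.counts.shape[1]))
        if len(self.channel_ids) != self.counts.shape[1]:
            raise ValueError("channel_ids length must match count columns")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_channels(self) -> int:
        return self.counts.shape[1]

    def mean_rates(self) -> np.ndarray:
        """Mean firing rate per channel in spikes/s."""
        return self.counts.mean(axis=0) / self.dt

    def subset(self, channel_ids) -> "SpikeCountMatrix":
        """Restrict to the given channel ids, preserving their order here."""
        idx = [self.channel_ids.index(c) for c in channel_ids]
        return SpikeCountMatrix(dt=self.dt, counts=self.counts[:, idx],
                                channel_ids=list(channel_ids))


@dataclass(frozen=True)
class ChannelSelection:
    """Active channels: mean rate strictly above ``min_rate``, minus manual exclusions."""

    active_ids: list[int]
    min_rate: float
    manual_exclusions: list[int]


def calibrate_position(trace: RawSensorTrace) -> np.ndarray:
    """Map raw ADC readings onto the flex-extend arc.

    A reading equal to ``adc_extension`` maps to 0 and ``adc_flexion`` to 1
    (linear in between).  The output is *not* clamped to [0, 1]: hyperextension
    and over-flexion remain representable.
    """
    v = np.asarray(trace.adc_values, dtype=float)
    return (v - trace.adc_extension) / (trace.adc_flexion - trace.adc_extension)


def smooth_and_bin(positions: np.ndarray, dt: float = DEFAULT_DT,
                   sample_rate: float = 1000.0) -> np.ndarray:
    """Smooth a 1 kHz position trace and average it into ``dt`` bins.

    A centered moving average whose span equals the bin width is applied
    samplewise (the window shrinks at the trace edges, so no samples are
    fabricated), then samples are averaged within each half-open bin
    ``[k*dt, (k+1)*dt)``.  A trailing partial bin is dropped.
    """
    x = np.asarray(positions, dtype=float)
    if x.size == 0:
        return np.empty(0)
    span = max(int(round(dt * sample_rate)), 1)
    # centered moving average with shrinking edge windows via cumulative sums
    half = span // 2
    cs = np.concatenate([[0.0], np.cumsum(x)])
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + (span - half), n)  # exclusive
    smoothed = (cs[hi] - cs[lo]) / (hi - lo)

    per_bin = int(round(dt * sample_rate))
    n_bins = n // per_bin
    if n_bins == 0:
        return np.empty(0)
    return smoothed[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)


def compute_velocity(positions: np.ndarray, dt: float) -> np.ndarray:
    """First differences of binned positions scaled by the bin width.

    ``vel[t] = (pos[t] - pos[t-1]) / dt``; the first bin's velocity is defined
    as 0 (there is no pre-session position to difference against).
    """
    pos = np.asarray(positions, dtype=float)
    vel = np.zeros_like(pos)
    if pos.shape[0] >= 2:
        vel[1:] = np.diff(pos, axis=0) / dt
    return vel


def threshold_training_velocity(velocities: np.ndarray,
                                cutoff: float = VELOCITY_CUTOFF) -> np.ndarray:
    """Zero out sub-threshold velocities (sensor-noise suppression).

    Velocities with magnitude strictly below ``cutoff`` (default 0.2 %flex/s,
    i.e. 0.002 arc/s) are set to 0.  Applied to training data only.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    v = np.asarray(velocities, dtype=float).copy()
    v[np.abs(v) < cutoff] = 0.0
    return v


def bin_spikes(event_times: dict[int, np.ndarray], dt: float,
               t_start: float, n_bins: int) -> SpikeCountMatrix:
    """Histogram spike event times onto the half-open bin grid.

    Bin ``k`` covers ``[t_start + k*dt, t_start + (k+1)*dt)``; an event landing
    exactly on a boundary is counted in the later bin.  Events outside the grid
    are dropped (with a logged count).
    """
    channel_ids = sorted(event_times)
    counts = np.zeros((n_bins, len(channel_ids)), dtype=np.int64)
    edges = t_start + dt * np.arange(n_bins + 1)
    n_dropped = 0
    for j, ch in enumerate(channel_ids):
        t = np.asarray(event_times[ch], dtype=float)
        inside = (t >= edges[0]) & (t < edges[-1])
        n_dropped += int(t.size - inside.sum())
        # np.histogram closes the last bin; half-open filtering above restores
        # the [start, end) convention for the final edge.
        counts[:, j], _ = np.histogram(t[inside], bins=edges)
    if n_dropped:
        logger.info("bin_spikes: dropped %d events outside the bin grid", n_dropped)
    return SpikeCountMatrix(dt=dt, counts=counts, channel_ids=channel_ids)


def select_channels(counts: SpikeCountMatrix,
                    min_rate: float = MIN_CHANNEL_RATE,
                    manual_exclusions: list[int] | None = None) -> ChannelSelection:
    """Retain channels whose mean rate is strictly above ``min_rate`` spikes/s.

    Channels on the hand-curated ``manual_exclusions`` list (artifact-prone
    high-impedance sites) are removed regardless of rate.
    """
    if counts.n_bins == 0:
        raise ValueError("empty count matrix")
    manual_exclusions = list(manual_exclusions or [])
    rates = counts.mean_rates()
    active = [ch for ch, r in zip(counts.channel_ids, rates)
              if r > min_rate and ch not in manual_exclusions]
    if not active:
        logger.warning("select_channels: no channel exceeds %.3g spikes/s", min_rate)
    return ChannelSelection(active_ids=active, min_rate=min_rate,
                            manual_exclusions=manual_exclusions)
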