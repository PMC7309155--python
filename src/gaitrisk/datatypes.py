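"""Core containers for lumbar-IMU gait recordings and cohort records.

A recording is six synchronized channels sampled at a fixed rate during a
six-minute walking test: trunk acceleration (m/s^2) and angular velocity
(deg/s) along the mediolateral (ml), vertical (v) and anteroposterior (ap)
body axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical channel order, matching the on-disk column order.
CHANNELS = ("a_ml", "a_v", "a_ap", "w_ml", "w_v", "w_ap")

#: Acceleration channels (m/s^2) and angular-velocity channels (deg/s).
ACCEL_CHANNELS = ("a_ml", "a_v", "a_ap")
GYRO_CHANNELS = ("w_ml", "w_v", "w_ap")

#: Standard gravity, used to convert accelerations recorded in [g].
G_TO_MS2 = 9.80665


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


class SamplingError(ValueError):
    """Raised when timestamps are inconsistent with the declared rate."""


@dataclass
class ImuTimeSeries:
    """Six-channel inertial recording on a uniform time grid.

    Parameters
    ----------
    t : ndarray
        Timestamps in seconds, 0-based, strictly increasing with spacing
        ``1/sampling_rate``.
    a_ml, a_v, a_ap : ndarray
        Accelerations in m/s^2.
    w_ml, w_v, w_ap : ndarray
        Angular velocities in deg/s.
    sampling_rate : float
        Sampling frequency in Hz (default 100).
    """

    t: np.ndarray
    a_ml: np.ndarray
    a_v: np.ndarray
    a_ap: np.ndarray
    w_ml: np.ndarray
    w_v: np.ndarray
    w_ap: np.ndarray
    sampling_rate: float = 100.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in CHANNELS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t.size
        if n < 2:
            raise ValueError("a recording needs at least 2 samples")
        for name in CHANNELS:
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name!r} length differs from t")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise SamplingError("timestamps must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.sampling_rate)) > 1e-9:
            raise SamplingError(
                f"timestamp spacing deviates from 1/{self.sampling_rate} Hz "
                "by more than 1e-9 s"
            )
        for name in CHANNELS:
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"channel {name!r} contains non-finite values")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Recording duration in seconds (n / sampling_rate)."""
        return self.t.size / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}")
        return getattr(self, name)

    def as_array(self) -> np.ndarray:
        """Stack channels into a (6, n) array in canonical order."""
        return np.stack([getattr(self, c) for c in CHANNELS])


@dataclass
class ParticipantRecord:
    """One participant: id, Timed Up and Go time, recording, faller label.

    ``faller`` is 1 if the participant fell at least once during the
    six-month follow-up, else 0.
    """

    participant_id: str
    tug_time: float
    series: ImuTimeSeries
    faller: int

    def __post_init__(self) -> None:
        if not self.tug_time > 0:
            raise ValueError("tug_time must be positive")
        if self.faller not in (0, 1):
            raise ValueError("faller label must be 0 or 1")


@dataclass
class Frame:
    """Fixed-duration window of a recording, labelled by its participant."""

    participant_id: str
    start_time: float
    duration: float
    data: np.ndarray  # (6, duration * sampling_rate)
    label: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(CHANNELS):
            raise ValueError("frame data must have shape (6, n_samples)")


@dataclass
class VariabilityProfile:
    """The 12 variability indices of one recording.

    ``sd[c]`` is the sample standard deviation of channel ``c`` in channel
    units; ``d[c]`` is the box-counting fractal dimension of its graph
    (dimensionless, between 1 for a smooth trace and 2 for a maximally
    irregular one).
    """

    sd: dict = field(default_factory=dict)
    d: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        """Flatten to a mapping ``{'SDa_ml': ..., 'Da_ml': ..., ...}``."""
        row = {}
        for c in CHANNELS:
            row[f"SD{c}"] = self.sd[c]
        for c in CHANNELS:
            row[f"D{c}"] = self.d[c]
        return row
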