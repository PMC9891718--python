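"""Core containers shared by the kymograph-analysis modules.

Conventions used throughout the package:

* A kymograph is a 2-D array with **rows = position along the flagellum**
  (row 0 is the flagellar base) and **columns = frames** (time).
* User-facing units are micrometres and seconds; pixel/frame indices are
  0-based and time windows are half-open ``[t0, t1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Kymograph",
    "SpikeEvent",
    "IFTTrajectory",
    "FlagellumSummary",
]


@dataclass(eq=False)
class Kymograph:
    """Calibrated single-channel kymograph.

    Parameters
    ----------
    intensity
        2-D float array, shape ``(n_rows, n_frames)``; rows are positions
        from the base (row 0), columns are frames.  Values must be finite.
    pixel_size
        Spatial calibration in µm per pixel (row spacing).
    frame_interval
        Temporal calibration in seconds per frame (column spacing).
    channel
        Free-form channel label (e.g. ``"gcamp"``, ``"kap-gfp"``).
    """

    intensity: np.ndarray
    pixel_size: float = 0.16
    frame_interval: float = 0.05
    channel: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("kymograph intensity must be a 2-D array")
        if self.intensity.shape[0] < 2 or self.intensity.shape[1] < 2:
            raise ValueError("kymograph needs at least 2 rows and 2 columns")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("kymograph intensity contains non-finite values")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def n_rows(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[1]

    @property
    def length_um(self) -> float:
        """Flagellar length spanned by the rows, (n_rows − 1)·pixel_size."""
        return (self.n_rows - 1) * self.pixel_size

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval

    @property
    def times(self) -> np.ndarray:
        """Start time of each frame in seconds."""
        return np.arange(self.n_frames) * self.frame_interval

    def with_intensity(self, intensity: np.ndarray) -> "Kymograph":
        """Copy of this kymograph with the image replaced, calibration kept."""
        return replace(self, intensity=np.asarray(intensity, dtype=float))


@dataclass
class SpikeEvent:
    """One detected Ca²⁺ influx event.

    ``area`` is the integrated above-baseline intensity of the spatially
    summed trace over the event, in a.u.·s.
    """

    onset_s: float
    end_s: float
    peak_time_s: float
    peak_amplitude: float
    area: float
    extent: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not (self.onset_s <= self.peak_time_s <= self.end_s):
            raise ValueError("event requires onset ≤ peak time ≤ end")
        if self.area <= 0:
            raise ValueError("event area must be positive")


# Direction labels for IFT trajectories.
ANTEROGRADE = "anterograde"
RETROGRADE = "retrograde"
PAUSED_MIXED = "paused-mixed"


@dataclass(eq=False)
class IFTTrajectory:
    """A single IFT train's path through a kymograph.

    ``points`` has columns (frame, position_px); ``intensities`` holds the
    per-point intensity in a.u.  Positions are in pixels from the base and
    may be sub-pixel.  Anterograde trains move away from the base (row 0),
    i.e. their net displacement in pixels is positive.
    """

    track_id: int
    points: np.ndarray
    intensities: np.ndarray
    direction: str = ""
    velocity_um_s: float = float("nan")
    truncated: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (frame, position)")
        if len(self.intensities) != len(self.points):
            raise ValueError("one intensity per point required")
        frames = self.points[:, 0]
        if np.any(np.diff(frames) <= 0):
            raise ValueError("trajectory frames must be strictly increasing")

    @property
    def frames(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def positions(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def start_frame(self) -> int:
        return int(self.points[0, 0])

    @property
    def end_frame(self) -> int:
        return int(self.points[-1, 0])

    @property
    def net_displacement_px(self) -> float:
        return float(self.points[-1, 1] - self.points[0, 1])

    @property
    def mean_intensity(self) -> float:
        return float(np.mean(self.intensities))

    def touches_base(self, tol_px: float = 2.0) -> bool:
        return bool(np.min(self.positions) <= tol_px)

    def touches_tip(self, n_rows: int, tol_px: float = 2.0) -> bool:
        return bool(np.max(self.positions) >= n_rows - 1 - tol_px)


@dataclass
class FlagellumSummary:
    """Per-flagellum scalar metrics extracted from one or two kymographs."""

    length_um: float = 0.0
    injection_intensity: float = 0.0  # a.u. µm⁻¹ s⁻¹
    anterograde_frequency: float = 0.0  # s⁻¹
    retrograde_frequency: float = 0.0  # s⁻¹
    anterograde_velocity: float = 0.0  # µm/s
    retrograde_velocity: float = 0.0  # µm/s
    returning_intensity: float = 0.0  # a.u.
    background_intensity: float = 0.0  # a.u.
    influx_intensity: float = 0.0  # a.u./s
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "length_um": self.length_um,
            "injection_intensity": self.injection_intensity,
            "anterograde_frequency": self.anterograde_frequency,
            "retrograde_frequency": self.retrograde_frequency,
            "anterograde_velocity": self.anterograde_velocity,
            "retrograde_velocity": self.retrograde_velocity,
            "returning_intensity": self.returning_intensity,
            "background_intensity": self.background_intensity,
            "influx_intensity": self.influx_intensity,
        }
        d.update(self.extras)
        return d
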