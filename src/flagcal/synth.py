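"""Synthetic kymograph and table generators with exact ground truth.

The generators emulate the statistical structure of TIRF kymographs of
*Chlamydomonas* flagella: a GCaMP channel carrying stochastic Ca²⁺ influx
events on a photobleaching baseline, and an IFT channel carrying linear
anterograde/retrograde train traces with optional retrograde pausing that
can be released by Ca²⁺ spikes.  Every generator is a pure function of
``(config, seed)`` and returns the exact ground truth alongside the image,
so detection and quantification can be scored without real movies.

Default geometry follows the imaging description the analysis is built
for: 12 µm flagellum, 0.16 µm pixels, 20 frames per second.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    ANTEROGRADE,
    PAUSED_MIXED,
    RETROGRADE,
    FlagellumSummary,
    IFTTrajectory,
    Kymograph,
    SpikeEvent,
)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "make_ca_kymograph",
    "make_ift_kymograph",
    "make_dual_kymograph",
    "make_length_series",
]

BASE_REFERENCE_PX = 2  # rows from the base used for entry/return accounting


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic kymograph generators.

    Spatial/temporal geometry defaults to 12 µm at 0.16 µm px⁻¹ and 20 fps.
    Train speeds default to 2 µm/s anterograde and 3 µm/s retrograde.
    Spike events form a renewal process whose inter-event intervals are
    exponential (Poisson) or gamma with ``spike_shape > 1`` (regularised,
    under-dispersed — the non-Poisson regime).  Intensities are arbitrary
    units on a 16-bit-like scale.
    """

    flagellum_length: float = 12.0  # µm
    pixel_size: float = 0.16  # µm/px
    frame_interval: float = 0.05  # s/frame
    duration: float = 60.0  # s

    # IFT channel
    anterograde_rate: float = 1.2  # trains/s
    retrograde_rate: float = 1.2  # trains/s
    anterograde_speed: float = 2.0  # µm/s
    retrograde_speed: float = 3.0  # µm/s
    train_intensity_mean: float = 100.0  # a.u. per trajectory pixel
    train_intensity_sd: float = 15.0
    pause_prob: float = 0.0  # probability a retrograde train pauses once
    pause_duration: float = 5.0  # s, when not released by a spike
    reactivate_on_spike: bool = False

    # Ca²⁺ channel
    spike_process: str = "exponential"  # or "gamma"
    spike_shape: float = 1.0  # gamma shape; 1 = exponential
    spike_rate: float = 0.15  # events/s
    spike_amplitude: float = 300.0  # a.u. peak, per pixel
    spike_duration: float = 1.0  # s
    spike_extent: float = 3.0  # µm (FWHM-like spatial scale)

    # shared nuisances
    bleach_rate: float = 0.0  # s⁻¹
    noise_sd: float = 8.0  # a.u.
    background: float = 50.0  # a.u.
    bleedthrough_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.bleedthrough_fraction < 1.0:
            raise ValueError("bleedthrough_fraction must lie in [0, 1)")
        for name in ("flagellum_length", "pixel_size", "frame_interval", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "anterograde_rate",
            "retrograde_rate",
            "spike_rate",
            "bleach_rate",
            "noise_sd",
            "background",
            "pause_prob",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.spike_process not in ("exponential", "gamma"):
            raise ValueError("spike_process must be 'exponential' or 'gamma'")

    @property
    def n_rows(self) -> int:
        return int(round(self.flagellum_length / self.pixel_size)) + 1

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))


@dataclass
class GroundTruth:
    """Exact truth accompanying a synthetic kymograph."""

    spikes: list = field(default_factory=list)  # list[SpikeEvent]
    trajectories: list = field(default_factory=list)  # list[IFTTrajectory]
    summary: FlagellumSummary = field(default_factory=FlagellumSummary)
    bleach_rate: float = 0.0
    bleedthrough_fraction: float = 0.0
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    clean_ca: np.ndarray | None = None
    clean_ift: np.ndarray | None = None

    def as_dict(self) -> dict:
        """JSON-serialisable view (images excluded)."""
        return {
            "bleach_rate": self.bleach_rate,
            "bleedthrough_fraction": self.bleedthrough_fraction,
            "spike_times": list(map(float, self.spike_times)),
            "spikes": [
                {
                    "onset_s": s.onset_s,
                    "end_s": s.end_s,
                    "peak_time_s": s.peak_time_s,
                    "peak_amplitude": s.peak_amplitude,
                    "area": s.area,
                    "extent": list(s.extent),
                }
                for s in self.spikes
            ],
            "trajectories": [
                {
                    "track_id": t.track_id,
                    "direction": t.direction,
                    "velocity_um_s": t.velocity_um_s,
                    "truncated": t.truncated,
                    "points": t.points.tolist(),
                    "intensities": t.intensities.tolist(),
                }
                for t in self.trajectories
            ],
            "summary": self.summary.as_dict(),
        }


# ---------------------------------------------------------------------------
# event-time machinery


def _renewal_times(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Event times of the spike renewal process on [0, duration)."""
    if cfg.spike_rate == 0:
        return np.empty(0)
    mean_gap = 1.0 / cfg.spike_rate
    times = []
    t = 0.0
    # generous upper bound on the event count, then trim
    while True:
        if cfg.spike_process == "exponential" or cfg.spike_shape == 1.0:
            gap = rng.exponential(mean_gap)
        else:
            gap = rng.gamma(cfg.spike_shape, mean_gap / cfg.spike_shape)
        t += gap
        if t >= cfg.duration:
            break
        times.append(t)
    return np.asarray(times)


# ---------------------------------------------------------------------------
# Ca²⁺ channel


def _render_spikes(cfg: SynthConfig, rng: np.random.Generator, spike_times: np.ndarray):
    """Clean (noise-free, bleach-free, zero-background) spike image + truth."""
    n_rows, n_frames = cfg.n_rows, cfg.n_frames
    img = np.zeros((n_rows, n_frames))
    rows = np.arange(n_rows)
    events: list[SpikeEvent] = []
    for t0 in spike_times:
        center_um = rng.uniform(0.15, 0.85) * cfg.flagellum_length
        sigma_px = 0.5 * cfg.spike_extent / cfg.pixel_size
        spatial = np.exp(-0.5 * ((rows - center_um / cfg.pixel_size) / sigma_px) ** 2)
        j0 = int(np.ceil(t0 / cfg.frame_interval))
        j1 = int(np.floor((t0 + cfg.spike_duration) / cfg.frame_interval))
        j1 = min(j1, n_frames - 1)
        if j1 < j0:
            continue
        frames = np.arange(j0, j1 + 1)
        phase = (frames * cfg.frame_interval - t0) / cfg.spike_duration
        temporal = np.sin(np.pi * np.clip(phase, 0.0, 1.0))  # half-sine pulse
        pulse = cfg.spike_amplitude * spatial[:, None] * temporal[None, :]
        img[:, frames] += pulse
        area = float(pulse.sum() * cfg.frame_interval)
        if area <= 0:
            continue
        peak_j = frames[int(np.argmax(temporal))]
        sig_rows = np.where(spatial > 0.05)[0]
        events.append(
            SpikeEvent(
                onset_s=float(j0 * cfg.frame_interval),
                end_s=float(j1 * cfg.frame_interval),
                peak_time_s=float(peak_j * cfg.frame_interval),
                peak_amplitude=float(pulse.max()),
                area=area,
                extent=(int(sig_rows[0]), int(sig_rows[-1])),
            )
        )
    return img, events


def make_ca_kymograph(cfg: SynthConfig, seed: int) -> tuple[Kymograph, GroundTruth]:
    """Synthetic GCaMP kymograph: background + spikes, bleaching, noise.

    The observed image is
    ``(background + spikes) · exp(−bleach_rate·t) + N(0, noise_sd²)``.
    Truth records every spike's onset, end, peak and pre-noise, pre-bleach
    area (spatial sum × frame interval), plus influx intensity and spike
    frequency over the movie.
    """
    rng = np.random.default_rng(seed)
    spike_times = _renewal_times(cfg, rng)
    clean, events = _render_spikes(cfg, rng, spike_times)
    t = np.arange(cfg.n_frames) * cfg.frame_interval
    decay = np.exp(-cfg.bleach_rate * t)[None, :]
    img = (cfg.background + clean) * decay
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)

    total_area = sum(e.area for e in events)
    summary = FlagellumSummary(
        length_um=(cfg.n_rows - 1) * cfg.pixel_size,
        influx_intensity=total_area / cfg.duration,
        extras={"spike_frequency": len(events) / cfg.duration},
    )
    truth = GroundTruth(
        spikes=events,
        summary=summary,
        bleach_rate=cfg.bleach_rate,
        spike_times=spike_times,
        clean_ca=clean,
    )
    kymo = Kymograph(
        img, pixel_size=cfg.pixel_size, frame_interval=cfg.frame_interval, channel="gcamp"
    )
    return kymo, truth


# ---------------------------------------------------------------------------
# IFT channel


def _train_vertices(
    cfg: SynthConfig,
    rng: np.random.Generator,
    t_entry: float,
    direction: str,
    spike_times: np.ndarray,
):
    """Piecewise-linear (time s, position µm) vertices for one train."""
    L = cfg.flagellum_length
    if direction == ANTEROGRADE:
        v = cfg.anterograde_speed
        return [(t_entry, 0.0), (t_entry + L / v, L)], False
    v = cfg.retrograde_speed
    paused = cfg.pause_prob > 0 and rng.random() < cfg.pause_prob
    if not paused:
        return [(t_entry, L), (t_entry + L / v, 0.0)], False
    pause_pos = rng.uniform(0.2, 0.8) * L
    t_pause = t_entry + (L - pause_pos) / v
    if cfg.reactivate_on_spike:
        later = spike_times[spike_times > t_pause]
        t_resume = float(later[0]) if later.size else float("inf")
    else:
        t_resume = t_pause + cfg.pause_duration
    if not np.isfinite(t_resume):
        # never released: stays paused to the end of the movie
        return [(t_entry, L), (t_pause, pause_pos), (cfg.duration, pause_pos)], True
    return [
        (t_entry, L),
        (t_pause, pause_pos),
        (t_resume, pause_pos),
        (t_resume + pause_pos / v, 0.0),
    ], True


def _rasterize(cfg: SynthConfig, vertices, intensity: float):
    """Per-frame (frame, row_px) points of a vertex path inside the movie."""
    ts = np.array([v[0] for v in vertices])
    xs = np.array([v[1] for v in vertices])
    j0 = max(0, int(np.ceil(ts[0] / cfg.frame_interval)))
    j1 = min(cfg.n_frames - 1, int(np.floor(ts[-1] / cfg.frame_interval)))
    if j1 < j0:
        return None
    frames = np.arange(j0, j1 + 1)
    pos_um = np.interp(frames * cfg.frame_interval, ts, xs)
    rows = pos_um / cfg.pixel_size
    return frames, rows, np.full(frames.size, intensity)


def make_ift_kymograph(cfg: SynthConfig, seed: int) -> tuple[Kymograph, GroundTruth]:
    """Synthetic IFT kymograph with Poisson train entries.

    Anterograde trains run base→tip at ``anterograde_speed``; retrograde
    trains run tip→base at ``retrograde_speed`` and may pause once
    mid-course.  With ``reactivate_on_spike`` the pause ends at the first
    Ca²⁺ spike after its start (the spike process is drawn from the same
    config), otherwise after ``pause_duration``.  Truth stores every
    per-frame sample of every train and the summary metrics recomputed
    from those samples.
    """
    rng = np.random.default_rng(seed)
    spike_times = _renewal_times(cfg, rng) if cfg.reactivate_on_spike else np.empty(0)

    n_rows, n_frames = cfg.n_rows, cfg.n_frames
    clean = np.zeros((n_rows, n_frames))
    trajs: list[IFTTrajectory] = []
    track_id = 0
    for direction, rate in (
        (ANTEROGRADE, cfg.anterograde_rate),
        (RETROGRADE, cfg.retrograde_rate),
    ):
        t = 0.0
        while rate > 0:
            t += rng.exponential(1.0 / rate)
            if t >= cfg.duration:
                break
            vertices, paused = _train_vertices(cfg, rng, t, direction, spike_times)
            amp = max(rng.normal(cfg.train_intensity_mean, cfg.train_intensity_sd), 1.0)
            ras = _rasterize(cfg, vertices, amp)
            if ras is None:
                continue
            frames, rows, intens = ras
            ridx = np.clip(np.round(rows).astype(int), 0, n_rows - 1)
            np.add.at(clean, (ridx, frames), intens)
            truncated = vertices[-1][0] > cfg.duration
            speed = cfg.anterograde_speed if direction == ANTEROGRADE else cfg.retrograde_speed
            trajs.append(
                IFTTrajectory(
                    track_id=track_id,
                    points=np.column_stack([frames, rows]),
                    intensities=intens,
                    direction=direction,
                    velocity_um_s=speed if direction == ANTEROGRADE else -speed,
                    truncated=truncated,
                )
            )
            track_id += 1

    t_axis = np.arange(n_frames) * cfg.frame_interval
    decay = np.exp(-cfg.bleach_rate * t_axis)[None, :]
    img = (cfg.background + clean) * decay
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)

    truth = GroundTruth(
        trajectories=trajs,
        bleach_rate=cfg.bleach_rate,
        spike_times=spike_times,
        clean_ift=clean,
        summary=_truth_summary(cfg, trajs),
    )
    kymo = Kymograph(
        img, pixel_size=cfg.pixel_size, frame_interval=cfg.frame_interval, channel="ift"
    )
    return kymo, truth


def _truth_summary(cfg: SynthConfig, trajs: list) -> FlagellumSummary:
    """Summary metrics recomputed exactly from the truth trajectory list."""
    length_um = (cfg.n_rows - 1) * cfg.pixel_size
    antero = [t for t in trajs if t.direction == ANTEROGRADE]
    retro = [t for t in trajs if t.direction == RETROGRADE]
    injection = sum(float(t.intensities.sum()) for t in antero) / (
        length_um * cfg.duration
    )
    n_antero = sum(1 for t in antero if np.min(t.positions) <= BASE_REFERENCE_PX)
    n_retro = sum(1 for t in retro if np.min(t.positions) <= BASE_REFERENCE_PX)
    return FlagellumSummary(
        length_um=length_um,
        injection_intensity=injection,
        anterograde_frequency=n_antero / cfg.duration,
        retrograde_frequency=n_retro / cfg.duration,
        anterograde_velocity=cfg.anterograde_speed,
        retrograde_velocity=cfg.retrograde_speed,
        background_intensity=cfg.background,
    )


# ---------------------------------------------------------------------------
# dual channel


def make_dual_kymograph(
    cfg: SynthConfig, seed: int
) -> tuple[Kymograph, Kymograph, GroundTruth]:
    """Simultaneous GCaMP and mScarlet-IFT kymographs with bleed-through.

    One spike process drives both channels: the Ca²⁺ image renders the
    spikes, and (with ``reactivate_on_spike``) the same spike times release
    paused retrograde trains in the IFT image.  The observed GCaMP channel
    is contaminated by a known fraction of the IFT channel:
    ``observed = clean_gcamp + fraction·clean_ift + noise``.
    """
    rng = np.random.default_rng(seed)
    spike_times = _renewal_times(cfg, rng)
    clean_ca, events = _render_spikes(cfg, rng, spike_times)

    n_rows, n_frames = cfg.n_rows, cfg.n_frames
    clean_ift = np.zeros((n_rows, n_frames))
    trajs: list[IFTTrajectory] = []
    track_id = 0
    for direction, rate in (
        (ANTEROGRADE, cfg.anterograde_rate),
        (RETROGRADE, cfg.retrograde_rate),
    ):
        t = 0.0
        while rate > 0:
            t += rng.exponential(1.0 / rate)
            if t >= cfg.duration:
                break
            vertices, paused = _train_vertices(cfg, rng, t, direction, spike_times)
            amp = max(rng.normal(cfg.train_intensity_mean, cfg.train_intensity_sd), 1.0)
            ras = _rasterize(cfg, vertices, amp)
            if ras is None:
                continue
            frames, rows, intens = ras
            ridx = np.clip(np.round(rows).astype(int), 0, n_rows - 1)
            np.add.at(clean_ift, (ridx, frames), intens)
            speed = cfg.anterograde_speed if direction == ANTEROGRADE else cfg.retrograde_speed
            trajs.append(
                IFTTrajectory(
                    track_id=track_id,
                    points=np.column_stack([frames, rows]),
                    intensities=intens,
                    direction=direction,
                    velocity_um_s=speed if direction == ANTEROGRADE else -speed,
                    truncated=vertices[-1][0] > cfg.duration,
                )
            )
            track_id += 1

    t_axis = np.arange(n_frames) * cfg.frame_interval
    decay = np.exp(-cfg.bleach_rate * t_axis)[None, :]
    ca_signal = (cfg.background + clean_ca) * decay
    ift_signal = (cfg.background + clean_ift) * decay
    gcamp = ca_signal + cfg.bleedthrough_fraction * ift_signal
    mscarlet = ift_signal.copy()
    if cfg.noise_sd > 0:
        gcamp = gcamp + rng.normal(0.0, cfg.noise_sd, size=gcamp.shape)
        mscarlet = mscarlet + rng.normal(0.0, cfg.noise_sd, size=mscarlet.shape)

    summary = _truth_summary(cfg, trajs)
    summary.influx_intensity = sum(e.area for e in events) / cfg.duration
    truth = GroundTruth(
        spikes=events,
        trajectories=trajs,
        summary=summary,
        bleach_rate=cfg.bleach_rate,
        bleedthrough_fraction=cfg.bleedthrough_fraction,
        spike_times=spike_times,
        clean_ca=ca_signal,
        clean_ift=clean_ift,
    )
    g = Kymograph(
        gcamp, pixel_size=cfg.pixel_size, frame_interval=cfg.frame_interval, channel="gcamp"
    )
    m = Kymograph(
        mscarlet,
        pixel_size=cfg.pixel_size,
        frame_interval=cfg.frame_interval,
        channel="mscarlet",
    )
    return g, m, truth


# ---------------------------------------------------------------------------
# scatter tables


def make_length_series(
    n: int,
    relation: tuple[str, float, float],
    noise: float,
    seed: int,
    length_range: tuple[float, float] = (2.0, 14.0),
):
    """Table of (length, metric) pairs with a known mean relation.

    ``relation`` is ``("linear", a, b)`` for metric = a + b·L or
    ``("decay", a, b)`` for metric = a + b/L, plus Gaussian scatter of
    standard deviation ``noise``.  Emulates per-flagellum scatter data
    (influx intensity or IFT intensity against length).
    """
    import pandas as pd

    form, a, b = relation
    rng = np.random.default_rng(seed)
    L = rng.uniform(length_range[0], length_range[1], size=n)
    if form == "linear":
        mean = a + b * L
    elif form == "decay":
        mean = a + b / L
    else:
        raise ValueError("relation form must be 'linear' or 'decay'")
    y = mean + rng.normal(0.0, noise, size=n) if noise > 0 else mean
    return pd.DataFrame({"length_um": L, "metric": y})
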