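"""Joint analysis of simultaneous Ca²⁺ (GCaMP) and IFT kymographs.

Covers spectral bleed-through correction, selection of isolated Ca²⁺
bursts, and event-triggered analysis of IFT behaviour in five successive
5-second windows around each burst onset (labelled a–e, spanning
[−10, −5), [−5, 0), [0, 5), [5, 10) and [10, 15) s relative to onset;
window c starts at the burst).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .core import ANTEROGRADE, RETROGRADE, Kymograph, SpikeEvent
from . import kymo_ca, kymo_ift

__all__ = [
    "WINDOW_LABELS",
    "WINDOW_OFFSETS_S",
    "WindowedMetrics",
    "bleedthrough_correct",
    "merge_bursts",
    "select_bursts",
    "windowed_metrics",
    "collect_window_matrix",
    "paired_window_test",
]

WINDOW_LABELS = ("a", "b", "c", "d", "e")
WINDOW_OFFSETS_S = (-10.0, -5.0, 0.0, 5.0, 10.0)
WINDOW_S = 5.0

DEFAULT_BLEEDTHROUGH = 0.2


def bleedthrough_correct(
    gcamp: Kymograph, mscarlet: Kymograph, fraction: float = DEFAULT_BLEEDTHROUGH
) -> Kymograph:
    """Remove spectral bleed-through of the IFT channel from the GCaMP one.

    ``corrected = gcamp − fraction · mscarlet``, element-wise; values may
    go negative (no clipping), which keeps the correction exactly
    invertible.  Shapes and calibrations must match.
    """
    if gcamp.intensity.shape != mscarlet.intensity.shape:
        raise ValueError("channel shapes differ")
    if (gcamp.pixel_size, gcamp.frame_interval) != (
        mscarlet.pixel_size,
        mscarlet.frame_interval,
    ):
        raise ValueError("channel calibrations differ")
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    return gcamp.with_intensity(gcamp.intensity - fraction * mscarlet.intensity)


def merge_bursts(events: list[SpikeEvent], merge_gap_s: float = 1.0):
    """Group spike events into bursts: maximal runs separated by < gap.

    Returns a list of (onset_s, end_s, total_area) triples sorted by onset.
    """
    if not events:
        return []
    ev = sorted(events, key=lambda e: e.onset_s)
    bursts = [[ev[0].onset_s, ev[0].end_s, ev[0].area]]
    for e in ev[1:]:
        if e.onset_s - bursts[-1][1] < merge_gap_s:
            bursts[-1][1] = max(bursts[-1][1], e.end_s)
            bursts[-1][2] += e.area
        else:
            bursts.append([e.onset_s, e.end_s, e.area])
    return [tuple(b) for b in bursts]


def select_bursts(
    events: list[SpikeEvent],
    movie_duration_s: float,
    quiet_s: float = 10.0,
    min_area: float = 2000.0,
    merge_gap_s: float = 1.0,
) -> list[float]:
    """Onsets of isolated, large Ca²⁺ bursts suitable for windowing.

    A burst qualifies when (i) no influx event ends within ``quiet_s``
    before its onset, (ii) its merged area exceeds ``min_area`` a.u.·s,
    and (iii) the full five-window frame [onset−10 s, onset+15 s) fits
    inside the movie.  The onset is the first constituent event's onset.
    """
    bursts = merge_bursts(events, merge_gap_s)
    onsets = []
    for i, (onset, end, area) in enumerate(bursts):
        if area <= min_area:
            continue
        if i > 0 and onset - bursts[i - 1][1] < quiet_s:
            continue
        if onset < quiet_s:
            continue
        if onset + WINDOW_OFFSETS_S[0] < 0:
            continue
        if onset + WINDOW_OFFSETS_S[-1] + WINDOW_S > movie_duration_s:
            continue
        onsets.append(float(onset))
    return onsets


@dataclass
class WindowedMetrics:
    """Per-window IFT and Ca²⁺ metrics around one burst onset.

    Each field holds five values ordered a→e.  Frequencies are per
    second; speeds are µm/s averaged over the trains present in the
    window (paused trains enter with speed ≈ 0 unless excluded upstream).
    """

    burst_onset_s: float
    injection_intensity: np.ndarray
    returning_intensity: np.ndarray
    anterograde_frequency: np.ndarray
    retrograde_frequency: np.ndarray
    anterograde_speed: np.ndarray
    retrograde_speed: np.ndarray
    ca_influx_sum: np.ndarray
    background_intensity: np.ndarray

    def as_dict(self) -> dict:
        return {
            "burst_onset_s": self.burst_onset_s,
            **{
                name: dict(zip(WINDOW_LABELS, getattr(self, name).tolist()))
                for name in (
                    "injection_intensity",
                    "returning_intensity",
                    "anterograde_frequency",
                    "retrograde_frequency",
                    "anterograde_speed",
                    "retrograde_speed",
                    "ca_influx_sum",
                    "background_intensity",
                )
            },
        }


def _window_speed(trajs, w0, w1, frame_interval, pixel_size, direction):
    """Mean |slope| of in-window trajectory segments for one direction."""
    speeds = []
    for t in trajs:
        if t.direction != direction:
            continue
        times = t.frames * frame_interval
        sel = (times >= w0) & (times < w1)
        if sel.sum() < 3:
            continue
        f = t.frames[sel]
        p = t.positions[sel]
        slope = np.polyfit(f, p, 1)[0]
        speeds.append(abs(slope) * pixel_size / frame_interval)
    return float(np.mean(speeds)) if speeds else float("nan")


def windowed_metrics(
    gcamp: Kymograph,
    ift_kymo: Kymograph,
    trajs,
    onset_s: float,
    events: list[SpikeEvent] | None = None,
) -> WindowedMetrics:
    """Event-triggered five-window metrics around one burst onset.

    Injection and returning intensity assign each trajectory to the
    window containing its base crossing (first point for anterograde,
    final point for retrograde); frequencies count base crossings inside
    the window; speeds fit each train's in-window segment.  ``events``
    (for the Ca²⁺ influx sums) default to running spike detection on the
    supplied GCaMP kymograph, which should already be bleed-through
    corrected.
    """
    dur = ift_kymo.duration_s
    if onset_s + WINDOW_OFFSETS_S[0] < 0 or onset_s + WINDOW_OFFSETS_S[-1] + WINDOW_S > dur:
        raise ValueError("window out of range: burst too close to the movie edge")
    if events is None:
        events = kymo_ca.detect_spikes(kymo_ca.smooth(gcamp))

    fi = ift_kymo.frame_interval
    px = ift_kymo.pixel_size
    inj = np.empty(5)
    ret = np.empty(5)
    fa = np.empty(5)
    fr = np.empty(5)
    va = np.empty(5)
    vr = np.empty(5)
    ca_sum = np.empty(5)
    bg = np.empty(5)
    for i, off in enumerate(WINDOW_OFFSETS_S):
        w0 = onset_s + off
        w1 = w0 + WINDOW_S
        inj[i] = kymo_ift.returning_intensity(trajs, (w0, w1), fi, kind="injecting")
        ret[i] = kymo_ift.returning_intensity(trajs, (w0, w1), fi, kind="returning")
        fa[i] = _window_frequency(trajs, w0, w1, fi, ANTEROGRADE)
        fr[i] = _window_frequency(trajs, w0, w1, fi, RETROGRADE)
        va[i] = _window_speed(trajs, w0, w1, fi, px, ANTEROGRADE)
        vr[i] = _window_speed(trajs, w0, w1, fi, px, RETROGRADE)
        ca_sum[i] = sum(e.area for e in events if w0 <= e.onset_s < w1)
        f0 = int(round(w0 / fi))
        f1 = int(round(w1 / fi))
        bg[i] = kymo_ift.background_intensity(
            ift_kymo, trajs, frame_range=(f0, f1), moving_only=True
        )
    return WindowedMetrics(
        burst_onset_s=onset_s,
        injection_intensity=inj,
        returning_intensity=ret,
        anterograde_frequency=fa,
        retrograde_frequency=fr,
        anterograde_speed=va,
        retrograde_speed=vr,
        ca_influx_sum=ca_sum,
        background_intensity=bg,
    )


def _window_frequency(trajs, w0, w1, frame_interval, direction, base_tol_px=2.0):
    n = 0
    for t in trajs:
        if t.direction != direction:
            continue
        times = t.frames * frame_interval
        near = t.positions <= base_tol_px
        if np.any(near & (times >= w0) & (times < w1)):
            n += 1
    return n / (w1 - w0)


def collect_window_matrix(metrics_list: list[WindowedMetrics], name: str) -> np.ndarray:
    """Stack one metric across bursts into an (n_bursts, 5) matrix."""
    return np.vstack([getattr(m, name) for m in metrics_list])


def paired_window_test(metric_matrix: np.ndarray):
    """Paired two-tailed t tests between neighbouring windows.

    ``metric_matrix`` has one row per burst and five columns (windows
    a–e).  Returns ``(t, p, degenerate)`` arrays of length 4 for the pairs
    (a,b), (b,c), (c,d), (d,e).  Identical columns give t=0, p=1; a
    constant non-zero shift with zero variance is flagged degenerate
    (p undefined rather than zero).
    """
    m = np.asarray(metric_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] != 5:
        raise ValueError("metric matrix must be (n_bursts, 5)")
    t_out = np.empty(4)
    p_out = np.empty(4)
    degenerate = np.zeros(4, dtype=bool)
    for k in range(4):
        a = m[:, k]
        b = m[:, k + 1]
        ok = np.isfinite(a) & np.isfinite(b)
        d = (b - a)[ok]
        if d.size < 2:
            t_out[k], p_out[k] = np.nan, np.nan
            degenerate[k] = True
            continue
        if np.allclose(d, 0.0):
            t_out[k], p_out[k] = 0.0, 1.0
            continue
        if np.std(d, ddof=1) == 0:
            t_out[k], p_out[k] = np.inf, np.nan
            degenerate[k] = True
            continue
        res = sstats.ttest_rel(b[ok], a[ok])
        t_out[k], p_out[k] = float(res.statistic), float(res.pvalue)
    return t_out, p_out, degenerate
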