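"""File formats and kymograph construction.

Kymographs travel as 16-bit grayscale TIFF (rows = position, base at
row 0; columns = frames) with a JSON metadata sidecar carrying the
spatial and temporal calibration, or as a plain CSV mirror.  Events and
trajectories are CSV tables; ground truth and summaries are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .core import IFTTrajectory, Kymograph, SpikeEvent

__all__ = [
    "read_kymograph",
    "write_kymograph",
    "read_events",
    "write_events",
    "read_trajectories_csv",
    "write_trajectories_csv",
    "write_truth",
    "read_truth",
    "write_summary",
    "build_kymograph",
]

META_KEYS = ("pixel_size", "frame_interval")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_kymograph(path, kymo: Kymograph) -> None:
    """Write a kymograph as 16-bit TIFF (or CSV) plus a metadata sidecar.

    Intensities must fit in [0, 65535] for TIFF; out-of-range values
    raise rather than clip silently.  Negative values are only
    representable in the CSV mirror.
    """
    path = Path(path)
    meta = {
        "pixel_size": kymo.pixel_size,
        "frame_interval": kymo.frame_interval,
        "channel": kymo.channel,
    }
    if path.suffix.lower() in (".tif", ".tiff"):
        img = np.round(kymo.intensity)
        if img.min() < 0 or img.max() > 65535:
            raise ValueError(
                "intensity outside the 16-bit range [0, 65535]; "
                "rescale before writing TIFF or use CSV"
            )
        tifffile.imwrite(path, img.astype(np.uint16))
    elif path.suffix.lower() == ".csv":
        np.savetxt(path, kymo.intensity, delimiter=",")
    else:
        raise ValueError(f"unsupported kymograph format: {path.suffix}")
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_kymograph(path) -> Kymograph:
    """Read a TIFF or CSV kymograph; the metadata sidecar is required."""
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(
            f"metadata sidecar {side.name} not found; required keys: {META_KEYS}"
        )
    meta = json.loads(side.read_text())
    missing = [k for k in META_KEYS if k not in meta]
    if missing:
        raise KeyError(f"metadata sidecar is missing keys: {missing}")
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path).astype(float)
    elif path.suffix.lower() == ".csv":
        img = np.loadtxt(path, delimiter=",")
    else:
        raise ValueError(f"unsupported kymograph format: {path.suffix}")
    return Kymograph(
        img,
        pixel_size=float(meta["pixel_size"]),
        frame_interval=float(meta["frame_interval"]),
        channel=str(meta.get("channel", "")),
    )


def write_events(path, events: list[SpikeEvent]) -> None:
    pd.DataFrame(
        [
            {
                "onset_s": e.onset_s,
                "end_s": e.end_s,
                "peak_s": e.peak_time_s,
                "amplitude": e.peak_amplitude,
                "area": e.area,
                "row_min": e.extent[0],
                "row_max": e.extent[1],
            }
            for e in events
        ],
        columns=["onset_s", "end_s", "peak_s", "amplitude", "area", "row_min", "row_max"],
    ).to_csv(path, index=False)


def read_events(path) -> list[SpikeEvent]:
    df = pd.read_csv(path)
    return [
        SpikeEvent(
            onset_s=r.onset_s,
            end_s=r.end_s,
            peak_time_s=r.peak_s,
            peak_amplitude=r.amplitude,
            area=r.area,
            extent=(int(r.row_min), int(r.row_max)),
        )
        for r in df.itertuples()
    ]


def write_trajectories_csv(path, trajs: list[IFTTrajectory]) -> None:
    rows = []
    for t in trajs:
        for (f, p), inten in zip(t.points, t.intensities):
            rows.append(
                {
                    "track_id": t.track_id,
                    "frame": f,
                    "position_px": p,
                    "intensity": inten,
                    "direction": t.direction,
                }
            )
    pd.DataFrame(
        rows, columns=["track_id", "frame", "position_px", "intensity", "direction"]
    ).to_csv(path, index=False)


def read_trajectories_csv(path, kymo: Kymograph | None = None) -> list[IFTTrajectory]:
    from .kymo_ift import import_trajectories

    return import_trajectories(path, kymo=kymo)


def write_truth(path, truth) -> None:
    Path(path).write_text(json.dumps(truth.as_dict(), indent=1))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_summary(path, summary) -> None:
    d = summary.as_dict() if hasattr(summary, "as_dict") else dict(summary)
    Path(path).write_text(json.dumps(d, indent=1))


def build_kymograph(
    movie: np.ndarray,
    path_points,
    width_px: int = 7,
    pixel_size: float = 0.16,
    frame_interval: float = 0.05,
    channel: str = "",
) -> Kymograph:
    """Extract a kymograph from a movie along a hand-traced polyline.

    ``movie`` is (frames, y, x); ``path_points`` is a polyline of (x, y)
    vertices starting at the flagellar base.  For every frame the
    intensity profile is sampled at one-pixel arc-length steps along the
    polyline and averaged over ``width_px`` samples perpendicular to the
    local direction — the line-profile construct used for hand-traced
    axonemes.  Row 0 of the result corresponds to the first path point.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be a 3-D (frames, y, x) stack")
    pts = np.asarray(path_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("path must be an (n ≥ 2, 2) polyline of (x, y)")
    n_f, n_y, n_x = movie.shape
    if (
        pts[:, 0].min() < 0
        or pts[:, 0].max() > n_x - 1
        or pts[:, 1].min() < 0
        or pts[:, 1].max() > n_y - 1
    ):
        raise ValueError("path lies outside the image")

    # resample the polyline at unit arc-length spacing
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    s = np.arange(0.0, arclen[-1] + 1e-9, 1.0)
    x = np.interp(s, arclen, pts[:, 0])
    y = np.interp(s, arclen, pts[:, 1])
    # unit tangents and normals (central differences)
    tx = np.gradient(x)
    ty = np.gradient(y)
    norm = np.hypot(tx, ty)
    nx, ny = -ty / norm, tx / norm
    offsets = np.arange(width_px) - (width_px - 1) / 2.0

    n_rows = len(s)
    out = np.empty((n_rows, n_f))
    sample_x = x[:, None] + offsets[None, :] * nx[:, None]
    sample_y = y[:, None] + offsets[None, :] * ny[:, None]
    coords = np.stack([sample_y.ravel(), sample_x.ravel()])
    for f in range(n_f):
        prof = ndimage.map_coordinates(movie[f], coords, order=1, mode="nearest")
        out[:, f] = prof.reshape(n_rows, width_px).mean(axis=1)
    return Kymograph(
        out, pixel_size=pixel_size, frame_interval=frame_interval, channel=channel
    )
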