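"""Tracking-table I/O and derived kinematic channels.

Recordings arrive as per-frame delimited tables exported by commercial
video-tracking software: timestamp, nose-point and center-point positions
(arena cm), body elongation (%), activity (%), and boolean zone-membership
channels. This module reads and writes those tables, computes the derived
channels the bout detector consumes (distance moved, velocity, zone
membership), and provides the two smoothing operators used throughout:
a centered moving average and a fixed-window locally weighted (lowess)
track smoother.

Conventions
-----------
* Coordinates are arena-frame centimetres, origin at an arena corner.
* Time zero is the first frame; frame ``i`` has timestamp ``i / frame_rate``.
* Missing samples (animal not detected) are NaN and stay NaN through
  smoothing; detector predicates evaluate False on missing frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely

__all__ = [
    "CORE_CHANNELS",
    "Dialect",
    "TrackingSeries",
    "Zone",
    "read_tracking",
    "write_tracking",
    "load_zone",
    "save_zone",
    "moving_average",
    "lowess_track",
    "distance_moved",
    "velocity",
    "in_zone",
]

#: Required columns, in file order. Additional boolean zone channels are
#: named ``in_<zone>``.
CORE_CHANNELS = (
    "t_s",
    "nose_x",
    "nose_y",
    "center_x",
    "center_y",
    "elongation",
    "activity",
)


@dataclass(frozen=True)
class Dialect:
    """Delimiter / decimal convention of a tracking export.

    Comma decimals require a non-comma delimiter (the usual semicolon
    convention of European exports).
    """

    delimiter: str = ","
    decimal: str = "."

    def __post_init__(self) -> None:
        if self.decimal == self.delimiter:
            raise ValueError("decimal mark and delimiter must differ")
        if self.decimal not in (".", ","):
            raise ValueError(f"unsupported decimal mark {self.decimal!r}")


@dataclass
class Zone:
    """A named arena zone given as a closed polygon in arena cm."""

    name: str
    vertices: Sequence[tuple[float, float]]

    def polygon(self) -> shapely.Polygon:
        poly = shapely.Polygon(self.vertices)
        if not poly.is_valid:
            raise ValueError(f"zone {self.name!r}: polygon invalid (self-intersecting?)")
        return poly


@dataclass
class TrackingSeries:
    """One recording session: per-frame multichannel table.

    ``frames`` holds the columns in :data:`CORE_CHANNELS` plus any number
    of ``in_<zone>`` boolean channels. Elongation and activity are
    percentages in [0, 100]; NaN marks a missing sample.
    """

    frame_rate_hz: float
    frames: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be > 0")
        missing = [c for c in CORE_CHANNELS if c not in self.frames.columns]
        if missing:
            raise ValueError(f"tracking table lacks required channels: {missing}")
        for ch in ("elongation", "activity"):
            v = self.frames[ch].to_numpy(float)
            ok = np.isnan(v) | ((v >= 0.0) & (v <= 100.0))
            if not ok.all():
                bad = int(np.flatnonzero(~ok)[0])
                raise ValueError(f"{ch} out of [0, 100] at frame {bad}: {v[bad]}")

    # -- convenience accessors -------------------------------------------

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def channel(self, name: str) -> np.ndarray:
        return self.frames[name].to_numpy(float)

    def xy(self, point: str) -> np.ndarray:
        """(n, 2) positions for ``point`` in {'nose', 'center'}."""
        return self.frames[[f"{point}_x", f"{point}_y"]].to_numpy(float)

    @property
    def zone_channels(self) -> list[str]:
        return [c for c in self.frames.columns if c.startswith("in_")]

    def slice_frames(self, start: int, stop: int | None = None) -> "TrackingSeries":
        sub = self.frames.iloc[start:stop].reset_index(drop=True).copy()
        sub["t_s"] = np.arange(len(sub)) / self.frame_rate_hz
        return TrackingSeries(self.frame_rate_hz, sub)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_RATE_PREFIX = "# frame_rate_hz="


def _fmt(v: float, decimal: str) -> str:
    if np.isnan(v):
        return ""
    s = repr(float(v))
    return s.replace(".", decimal) if decimal != "." else s


def write_tracking(series: TrackingSeries, path: str | Path, dialect: Dialect = Dialect()) -> None:
    """Write a series as delimited text, round-trippable by :func:`read_tracking`.

    The frame rate travels in a leading ``# frame_rate_hz=`` comment line.
    Zone channels are written as 0/1.
    """
    cols = list(CORE_CHANNELS) + series.zone_channels
    zone_set = set(series.zone_channels)
    arrays = {c: series.frames[c].to_numpy() for c in cols}
    d = dialect.delimiter
    with open(path, "w") as fh:
        fh.write(f"{_RATE_PREFIX}{series.frame_rate_hz!r}\n")
        fh.write(d.join(cols) + "\n")
        n = series.n_frames
        cells = []
        for c in cols:
            if c in zone_set:
                cells.append(np.asarray(arrays[c], bool).astype(int).astype(str))
            else:
                vals = np.asarray(arrays[c], float)
                cells.append(np.array([_fmt(v, dialect.decimal) for v in vals]))
        for i in range(n):
            fh.write(d.join(col[i] for col in cells) + "\n")


def read_tracking(path: str | Path, dialect: Dialect = Dialect()) -> TrackingSeries:
    """Read a delimited tracking table into a validated :class:`TrackingSeries`.

    Raises
    ------
    ValueError
        on unknown channel names (listing them) or ragged rows (naming the
        1-based file line).
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    frame_rate = None
    start = 0
    if lines[0].startswith(_RATE_PREFIX):
        frame_rate = float(lines[0][len(_RATE_PREFIX):].replace(dialect.decimal, "."))
        start = 1
    if frame_rate is None:
        raise ValueError(f"{path}: missing '{_RATE_PREFIX}' header line")
    header = lines[start].split(dialect.delimiter)
    unknown = [c for c in header if c not in CORE_CHANNELS and not c.startswith("in_")]
    if unknown:
        raise ValueError(f"{path}: unknown channel names: {unknown}")
    lacking = [c for c in CORE_CHANNELS if c not in header]
    if lacking:
        raise ValueError(f"{path}: missing required channels: {lacking}")
    ncol = len(header)
    rows = lines[start + 1:]
    data: dict[str, list[float]] = {c: [] for c in header}
    for i, line in enumerate(rows):
        parts = line.split(dialect.delimiter)
        if len(parts) != ncol:
            raise ValueError(
                f"{path}: line {start + i + 2}: expected {ncol} fields, got {len(parts)}"
            )
        for c, cell in zip(header, parts):
            if cell == "":
                data[c].append(np.nan)
            else:
                data[c].append(float(cell.replace(dialect.decimal, ".")))
    frames = pd.DataFrame({c: np.asarray(v, float) for c, v in data.items()})
    for c in header:
        if c.startswith("in_"):
            frames[c] = frames[c].fillna(0).astype(bool)
    return TrackingSeries(frame_rate, frames)


def save_zone(zone: Zone, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"name": zone.name, "vertices": [list(v) for v in zone.vertices]}, fh)


def load_zone(path: str | Path) -> Zone:
    with open(path) as fh:
        doc = json.load(fh)
    return Zone(doc["name"], [tuple(v) for v in doc["vertices"]])


# ---------------------------------------------------------------------------
# Smoothers
# ---------------------------------------------------------------------------


def moving_average(channel: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered moving mean over ``window_samples``, truncated at the edges.

    The window for frame ``i`` spans ``[i - (w-1)//2, i + w//2]`` clipped to
    the series (for even ``w`` the extra sample falls on the trailing side).
    NaN samples are excluded from the mean of their neighbours but remain
    NaN themselves — smoothing never invents data at missing frames.
    """
    if window_samples < 1:
        raise ValueError("window_samples must be >= 1")
    x = np.asarray(channel, float)
    if window_samples == 1:
        return x.copy()
    n = x.size
    finite = np.isfinite(x)
    # Anchor at the first finite sample so constant channels come back
    # bit-exact (cumsum round-off must not push a channel sitting exactly
    # on a detection threshold across it).
    ref = x[finite][0] if finite.any() else 0.0
    vals = np.where(finite, x - ref, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    ccnt = np.concatenate(([0], np.cumsum(finite.astype(np.int64))))
    idx = np.arange(n)
    lo = np.clip(idx - (window_samples - 1) // 2, 0, n)
    hi = np.clip(idx + window_samples // 2 + 1, 0, n)
    m = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore"):
        out = np.where(m > 0, ref + (csum[hi] - csum[lo]) / np.maximum(m, 1), np.nan)
    out[~finite] = np.nan
    return out


def _tricube(u: np.ndarray) -> np.ndarray:
    return np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3


def _wls_line_at(xw: np.ndarray, yw: np.ndarray, w: np.ndarray, x0: float) -> float:
    """Weighted degree-1 least squares of y on x, evaluated at x0."""
    sw = w.sum()
    if sw <= 0:
        return np.nan
    xm = (w * xw).sum() / sw
    ym = (w * yw).sum() / sw
    sxx = (w * (xw - xm) ** 2).sum()
    if sxx <= 0:
        return ym
    slope = (w * (xw - xm) * (yw - ym)).sum() / sxx
    return ym + slope * (x0 - xm)


def _lowess_1d(y: np.ndarray, window: int) -> np.ndarray:
    n = y.size
    h = (window - 1) // 2
    if n <= 1 or h == 0:
        return y.copy()
    # Interior frames: the window is symmetric around the frame, so the
    # slope term of the local linear fit cancels and the fit collapses to a
    # fixed tricube-weighted average — one convolution for the whole series.
    offs = np.arange(-h, h + 1)
    w = _tricube(offs / h)
    w = w / w.sum()
    out = np.convolve(y, w[::-1], mode="same")
    # Edge frames: truncated, asymmetric windows need the real local fit.
    edge = min(h, n)
    for i in list(range(edge)) + list(range(max(n - edge, edge), n)):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        xs = np.arange(lo, hi, dtype=float)
        dmax = np.abs(xs - i).max()
        wt = _tricube((xs - i) / dmax) if dmax > 0 else np.ones_like(xs)
        if (wt > 0).sum() < 2:
            out[i] = y[i]
        else:
            out[i] = _wls_line_at(xs, y[lo:hi], wt, float(i))
    return out


def lowess_track(xy_series: np.ndarray, window_samples: int = 9) -> np.ndarray:
    """Locally weighted linear (lowess) smoothing of an (n, 2) track.

    Each coordinate is fit by weighted degree-1 regression against the
    sample index over a fixed ``window_samples``-sample window centered on
    the frame, with tricube weights; endpoints use truncated windows.
    ``window_samples`` must be odd and >= 3. Collinear tracks are fixed
    points of the operator.
    """
    if window_samples < 3:
        raise ValueError("window_samples must be >= 3")
    if window_samples % 2 == 0:
        raise ValueError("window_samples must be odd")
    xy = np.asarray(xy_series, float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("xy_series must have shape (n, 2)")
    return np.column_stack([_lowess_1d(xy[:, 0], window_samples),
                            _lowess_1d(xy[:, 1], window_samples)])


# ---------------------------------------------------------------------------
# Derived channels
# ---------------------------------------------------------------------------


def distance_moved(xy_series: np.ndarray, smoothed: bool = False,
                   lowess_window: int = 9) -> np.ndarray:
    """Per-frame Euclidean displacement (cm/frame); first frame gets 0.

    With ``smoothed=True`` positions are lowess-smoothed first, the
    convention of tracking exports that pair "distance moved" with a track
    smoothing window.
    """
    xy = np.asarray(xy_series, float)
    if xy.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if smoothed:
        xy = lowess_track(xy, lowess_window)
    d = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1]))
    return np.concatenate(([0.0], d))


def velocity(xy_series: np.ndarray, frame_rate_hz: float, smoothed: bool = False,
             lowess_window: int = 9) -> np.ndarray:
    """Speed (cm/s): per-frame displacement times the frame rate."""
    return distance_moved(xy_series, smoothed=smoothed, lowess_window=lowess_window) * frame_rate_hz


def in_zone(xy_series: np.ndarray, zone: Zone) -> np.ndarray:
    """Boolean membership of each position in the zone polygon.

    The polygon boundary counts as inside; frames with missing coordinates
    are False.
    """
    poly = zone.polygon()
    xy = np.asarray(xy_series, float)
    ok = np.isfinite(xy).all(axis=1)
    out = np.zeros(xy.shape[0], dtype=bool)
    if ok.any():
        pts = shapely.points(xy[ok, 0], xy[ok, 1])
        out[ok] = shapely.covers(poly, pts)
    return out
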