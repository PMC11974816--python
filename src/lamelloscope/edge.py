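"""Kymograph construction, cell-edge tracing, spreading and protrusion
speeds, and protrusion-phase classification.

Sign convention: the kymograph's spatial axis runs from cell interior to
exterior (the first line endpoint is the interior one), and outward edge
displacement is positive.  Velocities are centred finite differences in
µm/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .core_io import ChannelStack

__all__ = [
    "Kymograph",
    "EdgeTrace",
    "build_kymograph",
    "trace_edge",
    "spreading_speed",
    "protrusion_speed",
    "classify_phases",
]

PROTRUSION, STALL, RETRACTION = "protrusion", "stall", "retraction"


@dataclass
class Kymograph:
    """Space x time intensity matrix sampled along a line.

    ``values`` has shape (S, T): rows are positions along the sampling line
    ordered interior -> exterior, columns are frames.
    """

    values: np.ndarray
    space_step_um: float
    time_step_s: float
    line: tuple[tuple[float, float], tuple[float, float]] = ((0, 0), (0, 0))
    width_px: int = 3

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("kymograph values must be 2-D (space, time)")
        if self.width_px < 1:
            raise ValueError("averaging width must be >= 1")


@dataclass
class EdgeTrace:
    """Edge position per frame extracted from a kymograph."""

    position_um: np.ndarray            # outward position along the line
    time_s: np.ndarray
    velocity_um_min: np.ndarray        # centred finite difference
    interpolated: np.ndarray = None    # frames without a threshold crossing
    phases: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.position_um), dtype=bool)

    @property
    def n_frames(self) -> int:
        return len(self.position_um)


def build_kymograph(stack: ChannelStack, channel: str | int,
                    line: tuple[tuple[float, float], tuple[float, float]],
                    width_px: int = 3) -> Kymograph:
    """Sample intensity along a line per frame, averaged over ``width_px``
    parallel lines offset along the normal.

    The line is given as ((r0, c0), (r1, c1)) pixel coordinates with the
    first endpoint on the cell-interior side; samples are taken at 1 px
    spacing by bilinear interpolation.
    """
    if width_px < 1 or width_px % 2 == 0:
        raise ValueError("width_px must be a positive odd number")
    (r0, c0), (r1, c1) = line
    length = float(np.hypot(r1 - r0, c1 - c0))
    if length == 0:
        raise ValueError("degenerate line")
    n_samples = int(np.floor(length)) + 1
    t = np.linspace(0.0, length, n_samples)
    direction = np.array([r1 - r0, c1 - c0]) / length
    normal = np.array([-direction[1], direction[0]])
    base = np.array([r0, c0])[:, None] + direction[:, None] * t[None, :]

    h, w = stack.frame_shape
    offsets = np.arange(width_px) - width_px // 2
    chan = (stack.channel_index(channel) if isinstance(channel, str) else channel)
    if (base[0].min() < -1 or base[0].max() > h or
            base[1].min() < -1 or base[1].max() > w):
        raise ValueError("sampling line falls outside the image")

    values = np.zeros((n_samples, stack.n_frames))
    for frame in range(stack.n_frames):
        img = stack.pixels[frame, chan]
        acc = np.zeros(n_samples)
        for off in offsets:
            coords = base + normal[:, None] * off
            acc += ndi.map_coordinates(img, coords, order=1, mode="nearest")
        values[:, frame] = acc / width_px
    return Kymograph(values, space_step_um=stack.pixel_size_um,
                     time_step_s=stack.frame_interval_s,
                     line=line, width_px=width_px)


def trace_edge(kym: Kymograph, max_missing_fraction: float = 0.5) -> EdgeTrace:
    """Track the cell edge as the outermost Otsu-threshold crossing per frame.

    The threshold is computed once on the whole kymograph.  Within each
    column the edge is the last sample at or above threshold, refined to
    sub-pixel position by linear interpolation across the crossing.  Frames
    without a crossing are linearly interpolated from neighbours and flagged.
    """
    vals = kym.values
    if np.ptp(vals) == 0:
        raise ValueError("blank kymograph")
    thr = threshold_otsu(vals)
    n_space, n_frames = vals.shape
    pos = np.full(n_frames, np.nan)
    for t in range(n_frames):
        col = vals[:, t]
        above = np.nonzero(col >= thr)[0]
        # isolated above-threshold samples are noise spikes, not the edge:
        # the outermost crossing must be supported by its interior neighbour
        above = above[(above == 0) | (col[np.maximum(above - 1, 0)] >= thr)]
        if above.size == 0:
            continue
        i = above[-1]                      # outermost sample above threshold
        if i == n_space - 1:
            pos[t] = float(i)
        else:
            # linear interpolation to where the profile crosses the threshold
            lo, hi = col[i], col[i + 1]
            frac = (lo - thr) / (lo - hi) if lo != hi else 0.0
            pos[t] = i + float(np.clip(frac, 0.0, 1.0))
    missing = np.isnan(pos)
    if missing.mean() > max_missing_fraction:
        raise ValueError(
            f"{missing.sum()}/{n_frames} frames without an edge crossing")
    if missing.any():
        idx = np.arange(n_frames)
        pos[missing] = np.interp(idx[missing], idx[~missing], pos[~missing])

    position_um = pos * kym.space_step_um
    time_s = np.arange(n_frames) * kym.time_step_s
    velocity = np.gradient(position_um, time_s) * 60.0   # µm/min
    return EdgeTrace(position_um, time_s, velocity, interpolated=missing)


def _window_slope(pos: np.ndarray, time_s: np.ndarray) -> float:
    """Least-squares slope of position (µm) over time, in µm/min."""
    coeffs = np.polyfit(time_s / 60.0, pos, 1)
    return float(coeffs[0])


def spreading_speed(trace: EdgeTrace, min_window_fraction: float = 0.2
                    ) -> float:
    """Average spreading speed: regression slope over the fast phase.

    The fast phase is the contiguous window (length >= ``min_window_fraction``
    of the trace) with the highest mean outward velocity; the returned speed
    is the least-squares slope of position over that window.  Purely
    retracting traces yield a negative value.
    """
    n = trace.n_frames
    if n < 10:
        raise ValueError("trace too short (need >= 10 frames)")
    min_len = max(2, int(np.ceil(min_window_fraction * n)))
    pos, time_s = trace.position_um, trace.time_s
    best = (-np.inf, 0, min_len)
    for i in range(n - min_len):
        for j in range(i + min_len, n):
            mean_v = (pos[j] - pos[i]) / (time_s[j] - time_s[i])
            if mean_v > best[0]:
                best = (mean_v, i, j)
    _, i, j = best
    return _window_slope(pos[i:j + 1], time_s[i:j + 1])


def classify_phases(trace: EdgeTrace, v_stall_um_min: float = 0.5,
                    min_run_frames: int = 3) -> np.ndarray:
    """Label each frame protrusion / stall / retraction by velocity.

    Velocity above +``v_stall_um_min`` is protrusion, below the negative is
    retraction, in between is stall.  Runs shorter than ``min_run_frames``
    are merged into the preceding run (or the following one at the start).
    The labels are also stored on the trace.
    """
    v = trace.velocity_um_min
    labels = np.where(v > v_stall_um_min, PROTRUSION,
                      np.where(v < -v_stall_um_min, RETRACTION, STALL))
    labels = labels.astype(object)
    if min_run_frames > 1:
        changed = True
        while changed:
            changed = False
            runs = _runs(labels)
            if len(runs) <= 1:
                break
            for k, (start, stop, lab) in enumerate(runs):
                if stop - start < min_run_frames:
                    neighbour = runs[k - 1][2] if k > 0 else runs[k + 1][2]
                    labels[start:stop] = neighbour
                    changed = True
                    break
    trace.phases = labels
    return labels


def _runs(labels: np.ndarray) -> list[tuple[int, int, object]]:
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((start, i, labels[start]))
            start = i
    return runs


def protrusion_speed(trace: EdgeTrace, n_events: int = 5,
                     v_stall_um_min: float = 0.5, min_run_frames: int = 3,
                     min_event_um: float = 0.2) -> float:
    """Mean protrusion speed over the largest protrusion events.

    Protrusion events are maximal runs of protrusion-phase frames whose net
    outward displacement is at least ``min_event_um``; the ``n_events``
    events with the largest displacement each contribute their regression
    slope, and the mean slope is returned.
    """
    if trace.phases is None:
        classify_phases(trace, v_stall_um_min, min_run_frames)
    events = []
    for start, stop, lab in _runs(trace.phases):
        if lab != PROTRUSION or stop - start < 2:
            continue
        disp = trace.position_um[stop - 1] - trace.position_um[start]
        if disp >= min_event_um:
            events.append((disp, start, stop))
    if len(events) < n_events:
        raise ValueError(
            f"only {len(events)} protrusion events >= {min_event_um} µm; "
            f"need {n_events}")
    events.sort(reverse=True)
    slopes = [_window_slope(trace.position_um[s:e], trace.time_s[s:e])
              for _, s, e in events[:n_events]]
    return float(np.mean(slopes))
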