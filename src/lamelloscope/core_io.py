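"""Shared data types, TIFF/CSV readers and writers, configuration and logging.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)`` with pixel centers at integer
  coordinates;
* physical quantities are converted through ``pixel_size_um`` (µm per pixel)
  and ``frame_interval_s`` (seconds per frame);
* image intensities are promoted to ``float64`` on load and never clipped to
  a bit depth.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("lamelloscope")

__all__ = [
    "ChannelStack",
    "BinaryMask",
    "PipelineConfig",
    "read_stack",
    "write_stack",
    "write_table",
    "read_table",
    "file_sha256",
    "log_stage",
]


@dataclass
class ChannelStack:
    """A registered multi-channel time-lapse image.

    Parameters
    ----------
    pixels : ndarray, shape (T, C, H, W)
        Non-negative intensities indexed ``(time, channel, row, col)``.
    channel_names : sequence of str
        Ordered channel labels, one per channel axis entry.
    pixel_size_um : float
        Lateral calibration, µm per pixel (> 0).
    frame_interval_s : float
        Time between consecutive frames, seconds (> 0).
    """

    pixels: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 4:
            raise ValueError(
                f"pixels must be 4-D (time, channel, row, col), got {self.pixels.ndim}-D"
            )
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.pixels.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.pixels.shape[1]} channels"
            )
        for name, value in (("pixel_size_um", self.pixel_size_um),
                            ("frame_interval_s", self.frame_interval_s)):
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and positive, got {value}")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; available: {self.channel_names}"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """Return the (T, H, W) sub-stack for a named channel."""
        return self.pixels[:, self.channel_index(name)]

    def with_pixels(self, pixels: np.ndarray) -> "ChannelStack":
        """Copy of this stack with new pixel data and identical calibration."""
        return ChannelStack(pixels, self.channel_names,
                            self.pixel_size_um, self.frame_interval_s)


@dataclass
class BinaryMask:
    """2-D boolean mask with the spatial calibration of the image it masks."""

    pixels: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size_um ** 2


#: Defaults for every tunable stage parameter.  Values stated by the source
#: protocol (bleed-through coefficients are *calibrated*, never defaulted)
#: keep the published numbers; the rest are documented package choices.
DEFAULT_CONFIG: dict = {
    "io": {"interleave": "channel-fastest"},
    "ratio": {"denoise_sigma": 0.5, "edge_depth_um": 1.5,
              "background_channel": "reference", "min_object_px": 64},
    "fret": {"percentile_clip": (1.0, 99.0)},
    "kymo": {"width_px": 3, "v_stall_um_min": 0.5, "min_run_frames": 3,
             "n_events": 5, "min_event_um": 0.2},
    "xcorr": {"presmooth_sigma": 1.0, "n_near_edge_px": 4,
              "series": "displacement", "smoothing_factor": 0.5},
    "porosity": {"blur_sigma": 0.5, "tophat_radius": 15, "min_pore_px": 10,
                 "connectivity": 8, "invert": False},
    "measure": {"k_sd": 1.5, "band_px": 5},
    "adhesions": {"bins_um2": (0.05, 0.20, 1.75)},
    "track": {"diameter_um": 25.0, "quality_threshold": 0.08,
              "max_link_um": 50.0, "gap_close_um": 50.0, "max_frame_gap": 3,
              "min_duration_min": 60.0, "min_span_um": 18.0,
              "span_metric": "path"},
    "seed": 0,
}


def _merge(base: dict, override: Mapping) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


@dataclass
class PipelineConfig:
    """Per-stage parameter blocks plus free-text run provenance.

    Every parameter has a default; user files only need to state overrides.
    """

    params: dict = field(default_factory=lambda: _merge(DEFAULT_CONFIG, {}))
    provenance: str = ""

    def __getitem__(self, stage: str) -> dict:
        return self.params[stage]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        provenance = raw.pop("provenance", "")
        return cls(params=_merge(DEFAULT_CONFIG, raw), provenance=provenance)

    def to_yaml(self, path: str | Path) -> None:
        payload = dict(self.params)
        if self.provenance:
            payload["provenance"] = self.provenance
        with open(path, "w") as fh:
            yaml.safe_dump(_plainify(payload), fh, sort_keys=False)


def _plainify(obj):
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def read_stack(path: str | Path, channel_names: Sequence[str],
               pixel_size_um: float, frame_interval_s: float,
               interleave: str = "channel-fastest") -> ChannelStack:
    """Read a multi-page TIFF and de-interleave pages into (time, channel).

    Parameters
    ----------
    interleave : {"channel-fastest", "frame-fastest"}
        "channel-fastest" (default): pages cycle through the channels within
        each timepoint, i.e. page order is t0c0, t0c1, ..., t1c0, ...
        "frame-fastest": whole-channel blocks, c0t0, c0t1, ..., c1t0, ...
    """
    pages = tifffile.imread(str(path))
    pages = np.asarray(pages, dtype=float)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"expected a stack of 2-D pages, got shape {pages.shape}")
    n_chan = len(channel_names)
    if n_chan < 1 or pages.shape[0] % n_chan:
        raise ValueError(
            f"page count {pages.shape[0]} is not divisible by channel count {n_chan}"
        )
    n_frames = pages.shape[0] // n_chan
    if interleave == "channel-fastest":
        pixels = pages.reshape(n_frames, n_chan, *pages.shape[1:])
    elif interleave == "frame-fastest":
        pixels = pages.reshape(n_chan, n_frames, *pages.shape[1:]).transpose(1, 0, 2, 3)
    else:
        raise ValueError(f"unknown interleave convention {interleave!r}")
    return ChannelStack(pixels, tuple(channel_names), pixel_size_um, frame_interval_s)


def write_stack(stack: ChannelStack, path: str | Path,
                interleave: str = "channel-fastest") -> None:
    """Write a ChannelStack as an interleaved multi-page float32 TIFF."""
    if interleave == "channel-fastest":
        pages = stack.pixels.reshape(-1, *stack.frame_shape)
    elif interleave == "frame-fastest":
        pages = stack.pixels.transpose(1, 0, 2, 3).reshape(-1, *stack.frame_shape)
    else:
        raise ValueError(f"unknown interleave convention {interleave!r}")
    tifffile.imwrite(str(path), pages.astype(np.float32),
                     photometric="minisblack")


def write_table(rows: pd.DataFrame | Sequence[Mapping], path: str | Path,
                float_format: str = "%.10g") -> None:
    """Write tabular records as UTF-8 CSV with a header and '.' decimals."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, index=False, float_format=float_format, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def log_stage(stage: str, **params) -> None:
    """Emit one structured log line: stage name plus its parameters."""
    rendered = " ".join(f"{k}={v!r}" for k, v in params.items())
    logger.info("stage=%s %s", stage, rendered)
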