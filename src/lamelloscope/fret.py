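"""Bleed-through-corrected FRET efficiency maps.

The FRET detection channel of an intensity-based biosensor is contaminated
by direct donor emission (fraction ``alpha`` of the donor signal under donor
excitation) and directly excited acceptor emission (fraction ``beta`` of the
acceptor signal).  With background-subtracted channels the corrected
efficiency is

    E = (FRET_raw - alpha * donor - beta * acceptor) / donor

computed per pixel inside the cell mask.  ``alpha`` and ``beta`` are
calibrated from cells expressing a single fluorophore, as the slope of a
zero-intercept linear fit of FRET-channel intensity against the fluorophore
intensity; calibration is a persisted artifact, never a hard-coded constant.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .core_io import BinaryMask, ChannelStack
from .ratiometric import RatioMap, make_cell_mask, subtract_background

__all__ = [
    "FretCalibration",
    "estimate_bleedthrough",
    "corrected_fret_map",
    "FretEfficiencyMap",
    "lp_to_cb_fret",
    "edge_line_profile",
]


@dataclass
class FretCalibration:
    """Donor (alpha) and acceptor (beta) bleed-through fractions."""

    alpha: float = 0.0
    beta: float = 0.0
    fit_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in (("alpha", self.alpha), ("beta", self.beta)):
            if not 0 <= value < 1:
                raise ValueError(f"{name} must lie in [0, 1), got {value}")

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"alpha": self.alpha, "beta": self.beta,
                       "fit_diagnostics": self.fit_diagnostics}, fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "FretCalibration":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(raw["alpha"], raw["beta"], raw.get("fit_diagnostics", {}))


@dataclass
class FretEfficiencyMap:
    """Per-pixel corrected FRET efficiency, NaN outside the mask."""

    pixels: np.ndarray
    mask: BinaryMask

    def export_pixels(self) -> np.ndarray:
        return np.where(np.isfinite(self.pixels), self.pixels, 0.0)


def _zero_intercept_slope(x: np.ndarray, y: np.ndarray,
                          percentile_clip: tuple[float, float] = (1.0, 99.0)
                          ) -> tuple[float, dict]:
    """Least-squares slope of y = s*x after clipping x-outliers.

    Pixels with x outside the [p_lo, p_hi] intensity percentiles are
    discarded as hot/dead pixels before the fit.
    """
    lo, hi = np.percentile(x, percentile_clip)
    keep = (x >= lo) & (x <= hi)
    xs, ys = x[keep], y[keep]
    denom = float(np.dot(xs, xs))
    if denom == 0:
        raise ValueError("all fluorophore intensities are zero after clipping")
    slope = float(np.dot(xs, ys) / denom)
    resid = ys - slope * xs
    diagnostics = {
        "n_pixels": int(xs.size),
        "rms_residual": float(np.sqrt(np.mean(resid ** 2))),
        "x_range": (float(xs.min()), float(xs.max())),
    }
    return slope, diagnostics


def estimate_bleedthrough(stack: ChannelStack, which: str,
                          fluorophore_channel: str | None = None,
                          fret_channel: str = "FRET",
                          percentile_clip: tuple[float, float] = (1.0, 99.0),
                          min_pixels: int = 100) -> FretCalibration:
    """Calibrate one bleed-through fraction from a single-fluorophore stack.

    ``which`` is "donor" (alpha, from donor-only cells) or "acceptor" (beta,
    from acceptor-only cells).  Each frame is background-subtracted, masked
    by Otsu on the fluorophore channel, and in-mask pixels are pooled across
    frames; the coefficient is the zero-intercept regression slope of FRET
    intensity on fluorophore intensity.  Negative fitted slopes are clamped
    to 0 with a warning.
    """
    if which not in ("donor", "acceptor"):
        raise ValueError("which must be 'donor' or 'acceptor'")
    if fluorophore_channel is None:
        fluorophore_channel = "mTFP1" if which == "donor" else "mVenus"
    fluo_idx = stack.channel_index(fluorophore_channel)
    fret_idx = stack.channel_index(fret_channel)

    xs, ys = [], []
    for t in range(stack.n_frames):
        guide = stack.pixels[t, fluo_idx]
        # background set located on the high-contrast fluorophore channel;
        # unclipped values keep the zero-intercept fit unbiased in the dim
        # FRET channel, where noise straddles zero after subtraction
        fluo, _ = subtract_background(guide, clip=False)
        fret, _ = subtract_background(stack.pixels[t, fret_idx],
                                      background_from=guide, clip=False)
        mask = make_cell_mask(guide, min_object_px=1,
                              pixel_size_um=stack.pixel_size_um)
        xs.append(fluo[mask.pixels])
        ys.append(fret[mask.pixels])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size < min_pixels:
        raise ValueError(f"only {x.size} in-mask pixels; need >= {min_pixels}")
    slope, diagnostics = _zero_intercept_slope(x, y, percentile_clip)
    if slope < 0:
        warnings.warn(f"fitted {which} bleed-through slope {slope:.4g} < 0; "
                      "clamping to 0", stacklevel=2)
        slope = 0.0
    diagnostics["which"] = which
    if which == "donor":
        return FretCalibration(alpha=slope, fit_diagnostics=diagnostics)
    return FretCalibration(beta=slope, fit_diagnostics=diagnostics)


def corrected_fret_map(fret_raw: np.ndarray, donor: np.ndarray,
                       acceptor: np.ndarray, cal: FretCalibration,
                       mask: BinaryMask,
                       eps_factor: float = 1e-6) -> FretEfficiencyMap:
    """Apply E = (FRET_raw - alpha*donor - beta*acceptor) / donor per pixel.

    Channels must be background-subtracted and registered.  Pixels where the
    donor falls below ``eps_factor`` times its in-mask median (or outside the
    mask) are flagged NaN.
    """
    fret_raw = np.asarray(fret_raw, dtype=float)
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if not fret_raw.shape == donor.shape == acceptor.shape == mask.pixels.shape:
        raise ValueError("channel and mask shapes differ")
    in_mask_donor = donor[mask.pixels]
    eps = eps_factor * float(np.median(in_mask_donor)) if in_mask_donor.size else eps_factor
    valid = mask.pixels & (donor > max(eps, 0.0))
    numerator = fret_raw - cal.alpha * donor - cal.beta * acceptor
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = np.where(valid, numerator / np.where(valid, donor, 1.0), np.nan)
    return FretEfficiencyMap(eff, mask)


def lp_to_cb_fret(eff_map: FretEfficiencyMap, lp_mask: BinaryMask,
                  cb_mask: BinaryMask) -> float:
    """Lamellipodia-to-cell-body efficiency ratio: mean(LP) / mean(CB)."""
    lp, cb = lp_mask.pixels, cb_mask.pixels
    if not lp.any() or not cb.any():
        raise ValueError("LP and CB masks must both be non-empty")
    if (lp & cb).any():
        raise ValueError("LP and CB masks overlap")
    lp_mean = np.nanmean(eff_map.pixels[lp])
    cb_mean = np.nanmean(eff_map.pixels[cb])
    if not np.isfinite(lp_mean) or not np.isfinite(cb_mean) or cb_mean == 0:
        raise ValueError("no defined efficiency values in LP or CB mask")
    return float(lp_mean / cb_mean)


def edge_line_profile(value_map: FretEfficiencyMap | RatioMap,
                      edge_curve: np.ndarray, depth_um: float, bin_um: float,
                      pixel_size_um: float) -> "pd.DataFrame":
    """Mean value versus distance from the cell edge, in bins of ``bin_um``.

    ``edge_curve`` is an (N, 2) polyline of (row, col) points on the mask
    boundary.  In-mask pixels are binned by Euclidean distance to the
    (densely resampled) curve up to ``depth_um``; per-bin mean, SE and count
    are returned, with empty bins flagged NaN.
    """
    import pandas as pd

    if depth_um <= 0 or bin_um <= 0:
        raise ValueError("depth_um and bin_um must be > 0")
    curve = np.asarray(edge_curve, dtype=float)
    if curve.ndim != 2 or curve.shape[0] < 2:
        raise ValueError("edge_curve must be an (N>=2, 2) polyline")
    # resample each segment at quarter-pixel steps for accurate distances
    pts = []
    for p, q in zip(curve[:-1], curve[1:]):
        seg_len = np.linalg.norm(q - p)
        n = max(2, int(np.ceil(seg_len * 4)))
        pts.append(p + np.linspace(0, 1, n)[:, None] * (q - p))
    dense = np.vstack(pts)
    tree = cKDTree(dense)

    mask = value_map.mask.pixels
    rr, cc = np.nonzero(mask)
    dists_px, _ = tree.query(np.column_stack([rr, cc]))
    dists_um = dists_px * pixel_size_um
    vals = value_map.pixels[rr, cc]

    edges = np.arange(0.0, depth_um + bin_um, bin_um)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (dists_um >= lo) & (dists_um < hi) & np.isfinite(vals)
        v = vals[sel]
        rows.append({
            "distance_um": (lo + hi) / 2,
            "mean": float(np.mean(v)) if v.size else np.nan,
            "se": float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan,
            "n_pixels": int(v.size),
        })
    return pd.DataFrame(rows)
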