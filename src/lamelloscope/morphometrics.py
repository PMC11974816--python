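"""Lamellipodial intensity quantification, marker-enriched perimeter
fraction, and focal-adhesion class statistics.

Focal adhesions are classified by area using the published bins:
nascent [0.05, 0.20) µm², mature [0.20, 1.75] µm², fibrillar (1.75, ∞) µm²;
objects below 0.05 µm² are dropped (and counted).  The boundary values use
an explicit half-open convention (0.20 -> mature, 1.75 -> mature).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import polygon2mask
from skimage.measure import find_contours
from skimage.morphology import disk

from .core_io import BinaryMask
from .ratiometric import subtract_background

__all__ = [
    "project_and_clean",
    "roi_mean",
    "normalize_to_control",
    "enriched_perimeter_fraction",
    "classify_adhesions",
    "ADHESION_CLASSES",
]

ADHESION_CLASSES = ("nascent", "mature", "fibrillar")
_MIN_AREA_UM2, _NASCENT_HI, _MATURE_HI = 0.05, 0.20, 1.75


def project_and_clean(zstack: np.ndarray) -> np.ndarray:
    """Maximum-intensity z-projection followed by background subtraction."""
    zstack = np.asarray(zstack, dtype=float)
    if zstack.ndim == 2:
        zstack = zstack[None]
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise ValueError("zstack must be (Z, H, W) with Z >= 1")
    mip = zstack.max(axis=0)
    cleaned, _ = subtract_background(mip)
    return cleaned


def roi_mean(image: np.ndarray, roi_polygon: np.ndarray,
             roi_id: str = "roi", channel: str = "") -> dict:
    """Mean intensity over pixels whose centers fall inside a polygon.

    ``roi_polygon`` is an (N >= 3, 2) array of (row, col) vertices; the
    polygon is implicitly closed.  Returns a measurement record with the
    mean grayscale value inside the ROI.
    """
    image = np.asarray(image, dtype=float)
    poly = np.asarray(roi_polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise ValueError("roi_polygon must be an (N>=3, 2) vertex list")
    mask = polygon2mask(image.shape, poly)
    if not mask.any():
        raise ValueError("polygon encloses no pixel centers")
    return {"roi_id": roi_id, "channel": channel,
            "mean_intensity": float(image[mask].mean()),
            "n_pixels": int(mask.sum())}


def normalize_to_control(measurements: pd.DataFrame,
                         control_ids: list | set,
                         id_column: str = "roi_id",
                         value_column: str = "mean_intensity") -> pd.DataFrame:
    """Divide every measurement by the mean of the control group.

    Adds a ``normalized_intensity`` column; the control group's normalised
    mean is exactly 1 by construction.
    """
    df = measurements.copy()
    control = df[df[id_column].isin(set(control_ids))]
    if control.empty:
        raise ValueError("control subset is empty")
    control_mean = control[value_column].mean()
    if not control_mean > 0:
        raise ValueError("control mean must be > 0")
    df["normalized_intensity"] = df[value_column] / control_mean
    return df


def enriched_perimeter_fraction(marker_image: np.ndarray,
                                cell_mask: BinaryMask, k_sd: float = 1.5,
                                band_px: int = 5) -> float:
    """Fraction of the cell perimeter where the marker is enriched.

    A boundary location is enriched when the mean marker intensity of the
    in-mask pixels within ``band_px`` of it exceeds the whole-cell mean plus
    ``k_sd`` standard deviations.  The boundary is the longest subpixel
    contour of the mask, and the fraction is arclength-weighted.
    """
    marker = np.asarray(marker_image, dtype=float)
    mask = cell_mask.pixels
    if marker.shape != mask.shape:
        raise ValueError("marker and mask shapes differ")
    if not mask.any():
        raise ValueError("empty cell mask")
    in_cell = marker[mask]
    threshold = in_cell.mean() + k_sd * in_cell.std()

    # local in-mask mean within a disc of radius band_px at every pixel
    foot = disk(band_px).astype(float)
    weighted = ndi.convolve(np.where(mask, marker, 0.0), foot, mode="constant")
    counts = ndi.convolve(mask.astype(float), foot, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        local_mean = np.where(counts > 0, weighted / counts, -np.inf)

    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no boundary contour")
    contour = max(contours, key=len)
    seg_vec = np.diff(contour, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    mid = (contour[:-1] + contour[1:]) / 2.0
    rr = np.clip(np.round(mid[:, 0]).astype(int), 0, mask.shape[0] - 1)
    cc = np.clip(np.round(mid[:, 1]).astype(int), 0, mask.shape[1] - 1)
    enriched = local_mean[rr, cc] > threshold
    total = seg_len.sum()
    if total == 0:
        raise ValueError("degenerate boundary")
    return float(seg_len[enriched].sum() / total)


def classify_adhesions(areas_um2) -> tuple[pd.DataFrame, dict]:
    """Classify focal-adhesion areas into nascent / mature / fibrillar.

    Returns the classified table (with sub-minimum objects dropped) and a
    summary dict with per-class fractions over classified objects plus the
    dropped count.
    """
    areas = np.asarray(areas_um2, dtype=float)
    if np.any(areas < 0):
        raise ValueError("areas must be >= 0")
    dropped = int((areas < _MIN_AREA_UM2).sum())
    kept = areas[areas >= _MIN_AREA_UM2]
    labels = np.where(kept < _NASCENT_HI, "nascent",
                      np.where(kept <= _MATURE_HI, "mature", "fibrillar"))
    table = pd.DataFrame({"area_um2": kept, "adhesion_class": labels})
    n = len(kept)
    fractions = {cls: (float((labels == cls).sum() / n) if n else float("nan"))
                 for cls in ADHESION_CLASSES}
    summary = {"fractions": fractions, "n_classified": n, "n_dropped": dropped}
    return table, summary
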