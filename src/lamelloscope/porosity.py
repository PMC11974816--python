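"""Actin-meshwork porosity and pore sizes from EM micrographs.

Chain: Gaussian blur -> white top-hat (extracts linear features thinner than
the structuring disc) -> two-cluster k-means binarisation on pixel
intensities (deterministic percentile initialisation) -> porosity = fraction
of in-ROI background pixels -> pore sizes = connected components of the
inverted foreground mask.

The pipeline operates on filament-bright images; micrographs presented in
inverted contrast are flipped with ``invert=True`` before processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk, white_tophat
from sklearn.cluster import KMeans

from .core_io import BinaryMask

__all__ = [
    "MeshworkResult",
    "preprocess_em",
    "binarize_kmeans",
    "porosity",
    "pore_sizes",
    "analyze_meshwork",
]


@dataclass
class MeshworkResult:
    """Porosity and pore-size statistics for one EM image."""

    foreground_mask: BinaryMask
    porosity: float
    pore_areas_px: np.ndarray
    mean_pore_area_px: float
    pore_areas_nm2: np.ndarray | None = None
    mean_pore_area_nm2: float | None = None
    params: dict = field(default_factory=dict)


def preprocess_em(image: np.ndarray, blur_sigma: float = 0.5,
                  tophat_radius: int = 15, invert: bool = False) -> np.ndarray:
    """Gaussian blur then white top-hat with a disc structuring element.

    The top-hat (image minus its morphological opening) retains features
    narrower than ``tophat_radius`` — the filaments — and maps smooth
    background to ≈ 0; output is non-negative.
    """
    image = np.asarray(image, dtype=float)
    if np.ptp(image) == 0:
        raise ValueError("constant image")
    if tophat_radius < 1:
        raise ValueError("tophat_radius must be >= 1")
    if invert:
        image = image.max() - image
    blurred = ndi.gaussian_filter(image, blur_sigma) if blur_sigma > 0 else image
    return white_tophat(blurred, footprint=disk(tophat_radius))


def binarize_kmeans(image: np.ndarray) -> BinaryMask:
    """Two-cluster k-means on pixel intensities; foreground = brighter cluster.

    Cluster centres are initialised at the 25th and 75th intensity
    percentiles and Lloyd iterations run to convergence, so the mask is
    bit-reproducible.
    """
    image = np.asarray(image, dtype=float)
    values = image.reshape(-1, 1)
    init = np.percentile(values, [25.0, 75.0]).reshape(-1, 1)
    if init[0, 0] == init[1, 0]:
        raise ValueError("degenerate intensity distribution: single cluster")
    km = KMeans(n_clusters=2, init=init, n_init=1, max_iter=300)
    labels = km.fit_predict(values).reshape(image.shape)
    bright = int(np.argmax(km.cluster_centers_.ravel()))
    return BinaryMask(labels == bright)


def porosity(mask: BinaryMask, roi: BinaryMask | None = None) -> float:
    """Fraction of ROI pixels that are background (devoid of filaments)."""
    roi_px = roi.pixels if roi is not None else np.ones_like(mask.pixels)
    if not roi_px.any():
        raise ValueError("empty ROI")
    return float((~mask.pixels & roi_px).sum() / roi_px.sum())


def pore_sizes(mask: BinaryMask, roi: BinaryMask | None = None,
               min_area_px: int = 10, connectivity: int = 8,
               nm_per_px: float | None = None
               ) -> tuple[np.ndarray, float]:
    """Areas of void components in the inverted foreground mask.

    Components touching the ROI (or image) border are excluded — their true
    extent is unbounded — and components below ``min_area_px`` discarded.
    Returns areas in px² (and the mean; NaN when no pore survives).  With
    ``nm_per_px`` set, areas are additionally converted in analyze_meshwork.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    roi_px = roi.pixels if roi is not None else np.ones_like(mask.pixels)
    if not roi_px.any():
        raise ValueError("empty ROI")
    voids = ~mask.pixels & roi_px
    structure = (np.ones((3, 3), dtype=int) if connectivity == 8
                 else ndi.generate_binary_structure(2, 1))
    labels, n = ndi.label(voids, structure=structure)
    if n == 0:
        return np.empty(0), float("nan")
    # border of the ROI: ROI pixels adjacent to outside-ROI or image border
    interior = ndi.binary_erosion(roi_px, structure=np.ones((3, 3)),
                                  border_value=0)
    border_labels = np.unique(labels[~interior & (labels > 0)])
    areas = np.bincount(labels.ravel())[1:]
    keep = np.ones(n, dtype=bool)
    keep[border_labels - 1] = False
    areas = areas[keep]
    areas = areas[areas >= min_area_px]
    mean = float(areas.mean()) if areas.size else float("nan")
    return areas.astype(float), mean


def analyze_meshwork(image: np.ndarray, blur_sigma: float = 0.5,
                     tophat_radius: int = 15, invert: bool = False,
                     roi: BinaryMask | None = None, min_area_px: int = 10,
                     connectivity: int = 8,
                     nm_per_px: float | None = None) -> MeshworkResult:
    """Full chain: preprocess -> k-means binarise -> porosity + pore sizes."""
    prepped = preprocess_em(image, blur_sigma, tophat_radius, invert)
    mask = binarize_kmeans(prepped)
    poro = porosity(mask, roi)
    areas, mean_area = pore_sizes(mask, roi, min_area_px, connectivity)
    areas_nm2 = mean_nm2 = None
    if nm_per_px is not None:
        areas_nm2 = areas * nm_per_px ** 2
        mean_nm2 = mean_area * nm_per_px ** 2
    return MeshworkResult(
        foreground_mask=mask, porosity=poro,
        pore_areas_px=areas, mean_pore_area_px=mean_area,
        pore_areas_nm2=areas_nm2, mean_pore_area_nm2=mean_nm2,
        params=dict(blur_sigma=blur_sigma, tophat_radius=tophat_radius,
                    invert=invert, min_area_px=min_area_px,
                    connectivity=connectivity, nm_per_px=nm_per_px),
    )
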