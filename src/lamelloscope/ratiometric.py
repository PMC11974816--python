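"""Ratiometric map construction: shading correction, registration,
background subtraction, denoising, channel division and cell masking.

The processing chain (in order) is: flat-field (shading) correction with a
cell-free blank, rigid registration onto the first frame, per-frame
background subtraction (median of the below-Otsu pixels), Gaussian denoising
(σ = 0.5 px), reporter/reference division, and a logical AND with a binary
cell mask derived from a structural channel.  Out-of-mask or near-zero-
denominator pixels are flagged NaN in memory (zero is a legal ratio) and
written as 0 on export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.registration import optical_flow_tvl1, phase_cross_correlation
from skimage.transform import warp

from .core_io import BinaryMask, ChannelStack, log_stage

__all__ = [
    "RatioMap",
    "shading_correct",
    "register_frames",
    "subtract_background",
    "make_cell_mask",
    "ratio_map",
    "edge_body_ratio",
    "ratiometric_movie",
]


@dataclass
class RatioMap:
    """Per-pixel reporter/reference ratio, NaN outside the cell mask."""

    pixels: np.ndarray
    mask: BinaryMask
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != self.mask.pixels.shape:
            raise ValueError("ratio map and mask shapes differ")
        inside = self.pixels[self.mask.pixels]
        finite = inside[np.isfinite(inside)]
        if finite.size and finite.min() < 0:
            raise ValueError("defined ratio values must be >= 0")

    def export_pixels(self) -> np.ndarray:
        """Ratio image with flagged pixels encoded as 0 for TIFF export."""
        return np.where(np.isfinite(self.pixels), self.pixels, 0.0)


def shading_correct(stack: ChannelStack, blank: np.ndarray,
                    smooth_sigma: float = 0.0) -> ChannelStack:
    """Flat-field each channel with a cell-free reference image.

    ``blank`` is either one 2-D image shared by all channels or a per-channel
    array of shape (C, H, W).  After optional Gaussian smoothing each blank is
    normalised to unit mean, so overall intensity scale is preserved.
    """
    blank = np.asarray(blank, dtype=float)
    if blank.ndim == 2:
        blank = np.broadcast_to(blank, (stack.n_channels, *blank.shape))
    if blank.shape != (stack.n_channels, *stack.frame_shape):
        raise ValueError("blank shape does not match the stack")
    fields = np.empty_like(blank)
    for c in range(stack.n_channels):
        b = ndi.gaussian_filter(blank[c], smooth_sigma) if smooth_sigma > 0 else blank[c]
        if b.min() <= 0:
            raise ValueError("blank image must be strictly positive after smoothing")
        fields[c] = b / b.mean()
    corrected = stack.pixels / fields[None, :, :, :]
    log_stage("shading_correct", smooth_sigma=smooth_sigma)
    return stack.with_pixels(corrected)


def register_frames(stack: ChannelStack, method: str = "translation",
                    reference_channel: int | str = 0,
                    upsample_factor: int = 10
                    ) -> tuple[ChannelStack, np.ndarray]:
    """Align every frame onto the first frame's coordinate system.

    ``method`` is "translation" (phase correlation, rigid shift — the
    default, adequate for stage drift) or "dense-flow" (TV-L1 optical flow,
    per-pixel displacement).  Returns the registered stack plus the
    estimated per-frame displacements for audit: shape (T, 2) mean (row,
    col) shift for translation, (T, 2, H, W) fields for dense flow.
    """
    if stack.n_frames == 0:
        raise ValueError("empty stack")
    ref_idx = (stack.channel_index(reference_channel)
               if isinstance(reference_channel, str) else reference_channel)
    target = stack.pixels[0, ref_idx]
    out = stack.pixels.copy()
    if method == "translation":
        shifts = np.zeros((stack.n_frames, 2))
        for t in range(1, stack.n_frames):
            shift, _, _ = phase_cross_correlation(
                target, stack.pixels[t, ref_idx], upsample_factor=upsample_factor)
            shifts[t] = shift
            for c in range(stack.n_channels):
                out[t, c] = ndi.shift(stack.pixels[t, c], shift,
                                      order=1, mode="nearest")
        displacements = shifts
    elif method == "dense-flow":
        h, w = stack.frame_shape
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        displacements = np.zeros((stack.n_frames, 2, h, w))
        for t in range(1, stack.n_frames):
            v, u = optical_flow_tvl1(target, stack.pixels[t, ref_idx])
            displacements[t] = np.stack([v, u])
            coords = np.array([rr + v, cc + u])
            for c in range(stack.n_channels):
                out[t, c] = warp(stack.pixels[t, c], coords,
                                 order=1, mode="edge", preserve_range=True)
    else:
        raise ValueError(f"unknown registration method {method!r}")
    log_stage("register_frames", method=method)
    return stack.with_pixels(out), displacements


def subtract_background(image: np.ndarray,
                        background_from: np.ndarray | None = None,
                        clip: bool = True) -> tuple[np.ndarray, float]:
    """Subtract the median intensity of the background pixels.

    The background pixel set is everything below the Otsu threshold of
    ``background_from`` (default: the image itself; pass a high-contrast
    companion channel to locate background reliably in low-contrast
    channels).  The median of ``image`` over that set is subtracted from the
    whole image; negatives are clipped to 0 unless ``clip=False`` (fits that
    rely on unbiased residuals should see unclipped values).  Raises on
    constant guide images, where the Otsu threshold is undefined.
    """
    image = np.asarray(image, dtype=float)
    guide = image if background_from is None else np.asarray(background_from, float)
    if guide.shape != image.shape:
        raise ValueError("background_from shape differs from image")
    if np.ptp(guide) == 0:
        raise ValueError("constant image: background is undefined")
    thr = threshold_otsu(guide)
    background = image[guide < thr]
    if background.size == 0:       # all mass above threshold
        background = image[guide <= thr]
    level = float(np.median(background))
    out = image - level
    if clip:
        out = np.clip(out, 0.0, None)
    return out, level


def make_cell_mask(structural_channel: np.ndarray,
                   min_object_px: int = 64,
                   pixel_size_um: float = 1.0) -> BinaryMask:
    """Binary cell mask: Otsu threshold, fill holes, keep the largest blob."""
    img = np.asarray(structural_channel, dtype=float)
    if np.ptp(img) == 0:
        raise ValueError("constant structural channel: no cell to segment")
    fg = img > threshold_otsu(img)
    fg = ndi.binary_fill_holes(fg)
    labels, n = ndi.label(fg)
    if n == 0:
        raise ValueError("no foreground component found")
    sizes = np.bincount(labels.ravel())[1:]
    if sizes.max() < min_object_px:
        raise ValueError(
            f"largest component has {sizes.max()} px < min_object_px={min_object_px}")
    keep = labels == (int(np.argmax(sizes)) + 1)
    return BinaryMask(keep, pixel_size_um)


def ratio_map(reporter: np.ndarray, reference: np.ndarray, mask: BinaryMask,
              denoise_sigma: float = 0.5, frame_index: int = 0,
              eps_factor: float = 1e-6) -> RatioMap:
    """Divide denoised reporter by denoised reference inside the cell mask.

    Both channels must already be background-subtracted.  Pixels outside the
    mask, or whose denominator falls below ``eps_factor`` times the in-mask
    median reference, are flagged NaN rather than producing infinities.
    """
    reporter = np.asarray(reporter, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if reporter.shape != reference.shape or reporter.shape != mask.pixels.shape:
        raise ValueError("reporter, reference and mask shapes differ")
    if denoise_sigma > 0:
        reporter = ndi.gaussian_filter(reporter, denoise_sigma)
        reference = ndi.gaussian_filter(reference, denoise_sigma)
    in_mask_ref = reference[mask.pixels]
    eps = eps_factor * float(np.median(in_mask_ref)) if in_mask_ref.size else eps_factor
    valid = mask.pixels & (reference > max(eps, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, reporter / np.where(valid, reference, 1.0), np.nan)
    ratio = np.where(valid, np.clip(ratio, 0.0, None), np.nan)
    return RatioMap(ratio, mask, frame_index)


def edge_body_ratio(rmap: RatioMap, edge_depth_um: float,
                    pixel_size_um: float) -> float:
    """Mean ratio in the edge band over mean ratio in the remaining body.

    The edge band is the set of in-mask pixels whose Euclidean distance to
    the mask boundary is at most ``edge_depth_um``.
    """
    if edge_depth_um <= 0:
        raise ValueError("edge_depth_um must be > 0")
    mask = rmap.mask.pixels
    if not mask.any():
        raise ValueError("empty mask")
    dist = ndi.distance_transform_edt(mask)
    band = mask & (dist <= edge_depth_um / pixel_size_um)
    body = mask & ~band
    if not body.any():
        raise ValueError("edge band covers the whole cell; reduce edge_depth_um")
    vals = rmap.pixels
    edge_vals = vals[band]
    body_vals = vals[body]
    edge_mean = np.nanmean(edge_vals)
    body_mean = np.nanmean(body_vals)
    if not np.isfinite(edge_mean) or not np.isfinite(body_mean) or body_mean == 0:
        raise ValueError("edge or body band has no defined ratio values")
    return float(edge_mean / body_mean)


def ratiometric_movie(stack: ChannelStack, reporter: str = "reporter",
                      reference: str = "reference",
                      structural: str | None = None,
                      blank: np.ndarray | None = None,
                      register: bool = True,
                      denoise_sigma: float = 0.5,
                      min_object_px: int = 64) -> list[RatioMap]:
    """Full chain: shading -> registration -> background -> denoise -> ratio -> mask.

    ``structural`` names the channel used for the cell mask (defaults to the
    reference channel, the package's documented default; the reporter can be
    selected instead).  The background level is computed per frame and each
    channel subtracts its own level.
    """
    if blank is not None:
        stack = shading_correct(stack, blank)
    if register and stack.n_frames > 1:
        stack, _ = register_frames(stack, reference_channel=reference)
    rep_idx = stack.channel_index(reporter)
    ref_idx = stack.channel_index(reference)
    struct_idx = stack.channel_index(structural) if structural else ref_idx
    maps = []
    for t in range(stack.n_frames):
        guide = stack.pixels[t, ref_idx]   # background set from the reference
        rep, _ = subtract_background(stack.pixels[t, rep_idx], background_from=guide)
        ref, _ = subtract_background(stack.pixels[t, ref_idx], background_from=guide)
        mask = make_cell_mask(stack.pixels[t, struct_idx],
                              min_object_px=min_object_px,
                              pixel_size_um=stack.pixel_size_um)
        maps.append(ratio_map(rep, ref, mask, denoise_sigma=denoise_sigma,
                              frame_index=t))
    return maps
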