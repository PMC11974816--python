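"""Synthetic microscopy data with known ground truth.

Every input class the pipeline consumes can be generated here with its
generating parameters recorded, so each analysis stage is validated by
parameter recovery: the zero-noise limit must be inverted exactly and noisy
data within stated tolerances.

The simulated cell is a disc with a half-elliptical protruding lobe, which
gives a well-defined free cell edge and an unambiguous outward normal for
kymograph lines.  Noise is additive Gaussian (optionally Poisson shot noise);
illumination shading is a smooth multiplicative polynomial bump normalised to
unit mean so that flat-field correction removes it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import line as draw_line
from skimage.morphology import disk

from .core_io import BinaryMask, ChannelStack

__all__ = [
    "GroundTruth",
    "cell_footprint",
    "shading_field",
    "simulate_ratiometric_movie",
    "simulate_fret_triplet",
    "simulate_meshwork",
    "simulate_edge_movie",
    "simulate_tracks",
    "simulate_adhesion_table",
]

ADHESION_BINS_UM2 = (0.05, 0.20, 1.75, 5.0)  # nascent | mature | fibrillar caps


@dataclass
class GroundTruth:
    """Generating parameters and latent variables of one synthetic dataset."""

    seed: int
    params: dict = field(default_factory=dict)
    true_ratio_map: np.ndarray | None = None
    mask: BinaryMask | None = None
    shading: np.ndarray | None = None
    drift_px: np.ndarray | None = None          # (T, 2) cumulative (row, col)
    true_alpha: float | None = None
    true_beta: float | None = None
    true_efficiency_map: np.ndarray | None = None
    true_porosity: float | None = None
    filament_mask: np.ndarray | None = None
    true_pore_areas_px: np.ndarray | None = None
    true_edge_position_um: np.ndarray | None = None
    true_velocity_um_min: np.ndarray | None = None
    true_phases: np.ndarray | None = None
    true_lag_s: float | None = None
    true_tracks: pd.DataFrame | None = None


def cell_footprint(shape: tuple[int, int],
                   lobe_fraction: float = 0.45) -> np.ndarray:
    """Boolean cell footprint: a disc plus a half-elliptical lobe.

    The disc is centred left of the image centre; the lobe protrudes toward
    +col (the "free edge" direction used by kymograph fixtures).
    """
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    r0, c0 = h / 2.0, w * 0.38
    radius = 0.30 * min(h, w)
    body = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2
    # half-ellipse lobe, extending lobe_fraction of the image width to the right
    a = lobe_fraction * w - (c0 + 0)  # semi-axis along col from the disc centre
    a = max(a, radius * 1.2)
    b = 0.55 * radius
    lobe = ((cc >= c0)
            & (((rr - r0) / b) ** 2 + ((cc - c0) / a) ** 2 <= 1.0))
    return body | lobe


def shading_field(shape: tuple[int, int], amplitude: float) -> np.ndarray:
    """Smooth multiplicative illumination profile, normalised to unit mean.

    A low-order polynomial bump: brightest near the optical axis (image
    centre), falling off quadratically, modulated by ``amplitude``.
    """
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    u = (rr - h / 2) / (h / 2)
    v = (cc - w / 2) / (w / 2)
    bump = 1.0 + amplitude * (1.0 - 0.5 * (u ** 2 + v ** 2))
    return bump / bump.mean()


def _edge_band(mask: np.ndarray, depth_px: float) -> np.ndarray:
    dist = ndi.distance_transform_edt(mask)
    return mask & (dist <= depth_px)


def simulate_ratiometric_movie(
    shape: tuple[int, int] = (128, 128),
    n_frames: int = 10,
    gradient_peak: float = 1.5,
    body_ratio: float = 1.0,
    shading_amplitude: float = 0.0,
    drift_px_per_frame: tuple[int, int] = (0, 0),
    noise_sd: float = 0.0,
    seed: int = 0,
    pixel_size_um: float = 0.3,
    frame_interval_s: float = 10.0,
    edge_depth_um: float = 1.5,
    reference_level: float = 1000.0,
    background_level: float = 20.0,
) -> tuple[ChannelStack, GroundTruth]:
    """Two-channel reporter/reference movie over a protruding cell.

    The true ratio map is ``gradient_peak`` inside an edge band of depth
    ``edge_depth_um`` and ``body_ratio`` in the remaining cell body, giving
    an exact known edge-to-body ratio.  The reporter channel is the true
    ratio times the reference channel; shading multiplies both channels;
    rigid drift (integer pixels per frame) rolls every frame; Gaussian noise
    is added last.
    """
    if shape[0] <= 0 or shape[1] <= 0 or n_frames <= 0:
        raise ValueError("shape and n_frames must be positive")
    if not gradient_peak >= body_ratio > 0:
        raise ValueError("require gradient_peak >= body_ratio > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    mask = cell_footprint(shape)
    band = _edge_band(mask, edge_depth_um / pixel_size_um)
    true_ratio = np.where(band, gradient_peak, np.where(mask, body_ratio, 0.0))

    # camera/media pedestal is additive under the cell signal so that the
    # shading-correct -> background-subtract -> divide chain inverts exactly
    reference = background_level + np.where(mask, reference_level, 0.0)
    reporter = background_level + np.where(mask, true_ratio * reference_level, 0.0)
    shade = shading_field(shape, shading_amplitude)

    drift_step = np.asarray(drift_px_per_frame, dtype=int)
    frames = np.empty((n_frames, 2, *shape))
    drift = np.zeros((n_frames, 2), dtype=int)
    for t in range(n_frames):
        drift[t] = t * drift_step
        for c, base in enumerate((reporter, reference)):
            img = np.roll(base * shade, shift=tuple(drift[t]), axis=(0, 1))
            if noise_sd > 0:
                img = img + rng.normal(0.0, noise_sd, size=shape)
            frames[t, c] = np.clip(img, 0.0, None)

    stack = ChannelStack(frames, ("reporter", "reference"),
                         pixel_size_um, frame_interval_s)
    truth = GroundTruth(
        seed=seed,
        params=dict(gradient_peak=gradient_peak, body_ratio=body_ratio,
                    shading_amplitude=shading_amplitude, noise_sd=noise_sd,
                    edge_depth_um=edge_depth_um,
                    reference_level=reference_level,
                    background_level=background_level),
        true_ratio_map=true_ratio,
        mask=BinaryMask(mask, pixel_size_um),
        shading=shade,
        drift_px=drift,
    )
    return stack, truth


def simulate_fret_triplet(
    shape: tuple[int, int] = (128, 128),
    n_frames: int = 1,
    efficiency_map: float | np.ndarray = 0.2,
    alpha: float = 0.3072,
    beta: float = 0.05228,
    noise_sd: float = 0.0,
    seed: int = 0,
    variant: str = "both",
    pixel_size_um: float = 0.3,
    frame_interval_s: float = 180.0,
    donor_level: float = 1000.0,
    acceptor_level: float = 800.0,
    background_level: float = 100.0,
) -> tuple[ChannelStack, GroundTruth]:
    """Three-channel (mTFP1, mVenus, FRET) stack from the forward model

        FRETraw = E * mTFP1 + alpha * mTFP1 + beta * mVenus (+ noise),

    i.e. the exact inverse of the bleed-through correction equation.

    ``variant``: "both" expresses donor and acceptor; "donor-only" and
    "acceptor-only" zero the other fluorophore (and the transfer term), the
    configurations used to calibrate alpha and beta.  In-cell intensities
    ramp radially (~0.4x to 1.6x the channel level) so that the
    zero-intercept regression sees a spread of intensities, as real
    expression gradients provide.  A constant camera background is added to
    every channel; analysis must remove it before fitting.
    """
    if not (0 <= alpha < 1 and 0 <= beta < 1):
        raise ValueError("alpha and beta must lie in [0, 1)")
    eff = np.asarray(efficiency_map, dtype=float)
    if np.any(eff < 0) or np.any(eff >= 1):
        raise ValueError("efficiency_map must lie in [0, 1)")
    if variant not in ("both", "donor-only", "acceptor-only"):
        raise ValueError(f"unknown variant {variant!r}")
    rng = np.random.default_rng(seed)

    mask = cell_footprint(shape)
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    radial = np.hypot(rr - h / 2, cc - w / 2) / (0.5 * np.hypot(h, w))
    ramp = 1.6 - 1.2 * radial          # bright centre, dim rim

    donor = np.where(mask, donor_level * ramp, 0.0)
    acceptor = np.where(mask, acceptor_level * ramp, 0.0)
    eff_map = np.where(mask, np.broadcast_to(eff, shape), 0.0)
    if variant == "donor-only":
        acceptor = np.zeros(shape)
        eff_map = np.zeros(shape)
    elif variant == "acceptor-only":
        donor = np.zeros(shape)
        eff_map = np.zeros(shape)
    fret = eff_map * donor + alpha * donor + beta * acceptor

    frames = np.empty((n_frames, 3, *shape))
    for t in range(n_frames):
        for c, base in enumerate((donor, acceptor, fret)):
            img = base + background_level
            if noise_sd > 0:
                img = img + rng.normal(0.0, noise_sd, size=shape)
            frames[t, c] = np.clip(img, 0.0, None)

    stack = ChannelStack(frames, ("mTFP1", "mVenus", "FRET"),
                         pixel_size_um, frame_interval_s)
    truth = GroundTruth(
        seed=seed,
        params=dict(variant=variant, noise_sd=noise_sd,
                    donor_level=donor_level, acceptor_level=acceptor_level,
                    background_level=background_level),
        true_alpha=alpha, true_beta=beta,
        true_efficiency_map=eff_map,
        mask=BinaryMask(mask, pixel_size_um),
    )
    return stack, truth


def simulate_meshwork(
    shape: tuple[int, int] = (256, 256),
    n_filaments: int = 900,
    filament_width_px: int = 3,
    seed: int = 0,
    filament_level: float = 180.0,
    background_level: float = 30.0,
    background_bump: float = 10.0,
    noise_sd: float = 3.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Grayscale EM-like image: bright filament lattice on a dark background.

    The meshwork is the edge set of a Voronoi tessellation of random seed
    points (roughly ``n_filaments`` straight filament segments, three edges
    per seed point), drawn at ``filament_width_px`` thickness.  Unlike
    independent random chords, a lattice keeps every filament thinner than
    the pores it bounds — the geometry of branched actin networks that
    top-hat filtering relies on — and pore density rises smoothly with
    ``n_filaments``.  ``true_porosity`` is the exact fraction of pixels not
    covered by any filament, and void component areas are recorded.  A
    slowly varying background bump emulates uneven replica contrast.
    """
    if shape[0] <= 0 or shape[1] <= 0:
        raise ValueError("shape must be positive")
    if n_filaments < 0:
        raise ValueError("n_filaments must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = shape

    fil = np.zeros(shape, dtype=bool)
    n_seeds = n_filaments // 3
    if n_seeds >= 1:
        from scipy.spatial import Voronoi

        pts = rng.uniform([0.0, 0.0], [h, w], size=(n_seeds, 2))
        # mirror the points across every border so all interior ridges are
        # finite and cells are closed at the image edge
        mirrored = [pts]
        for axis, lim in ((0, 0.0), (0, float(h)), (1, 0.0), (1, float(w))):
            m = pts.copy()
            m[:, axis] = 2 * lim - m[:, axis]
            mirrored.append(m)
        vor = Voronoi(np.vstack(mirrored))
        for (p, q), (v0, v1) in zip(vor.ridge_points, vor.ridge_vertices):
            if v0 == -1 or v1 == -1 or (p >= n_seeds and q >= n_seeds):
                continue
            a, b = vor.vertices[v0], vor.vertices[v1]
            if not (np.isfinite(a).all() and np.isfinite(b).all()):
                continue
            a = np.clip(a, [0, 0], [h - 1, w - 1]).astype(int)
            b = np.clip(b, [0, 0], [h - 1, w - 1]).astype(int)
            rr, cc = draw_line(a[0], a[1], b[0], b[1])
            fil[rr, cc] = True
        if filament_width_px > 1:
            fil = ndi.binary_dilation(fil, structure=disk(filament_width_px // 2))

    true_porosity = 1.0 - fil.mean()
    labels, _ = ndi.label(~fil, structure=np.ones((3, 3), dtype=int))
    areas = np.bincount(labels.ravel())[1:]

    image = np.where(fil, filament_level, 0.0)
    image += background_level + background_bump * shading_field(shape, 1.0)
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=shape)

    truth = GroundTruth(
        seed=seed,
        params=dict(n_filaments=n_filaments,
                    filament_width_px=filament_width_px, noise_sd=noise_sd),
        true_porosity=true_porosity,
        filament_mask=fil,
        true_pore_areas_px=areas[areas > 0],
    )
    return image, truth


def _phase_velocity_series(phase_plan, n_frames: int, frame_interval_s: float
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Expand a list of (phase, velocity µm/min, duration s) into per-frame arrays."""
    total = sum(d for _, _, d in phase_plan)
    if abs(total - n_frames * frame_interval_s) > 1e-6:
        raise ValueError(
            f"phase durations sum to {total} s but movie spans "
            f"{n_frames * frame_interval_s} s"
        )
    velocity = np.empty(n_frames)
    phases = np.empty(n_frames, dtype=object)
    t = 0.0
    for phase, v, dur in phase_plan:
        i0 = int(round(t / frame_interval_s))
        i1 = int(round((t + dur) / frame_interval_s))
        velocity[i0:i1] = v
        phases[i0:i1] = phase
        t += dur
    return velocity, phases


def simulate_edge_movie(
    n_frames: int = 60,
    phase_plan: Sequence[tuple[str, float, float]] | None = None,
    signal_lag_s: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (64, 120),
    pixel_size_um: float = 0.4,
    frame_interval_s: float = 10.0,
    start_col: float = 30.0,
    cell_level: float = 1000.0,
    background_level: float = 20.0,
    signal_base: float = 1.2,
    signal_gain_min_per_um: float = 0.15,
    band_px: int = 6,
    noise_sd: float = 0.0,
) -> tuple[ChannelStack, GroundTruth]:
    """Movie of a cell edge advancing along +col per a protrusion phase plan.

    Channel 0 ("ratio") carries a near-edge reporter band whose intensity is
    an affine map of the edge velocity delayed by ``signal_lag_s``; channel 1
    ("structural") is a plain binary-contrast cell, so a kymograph line along
    a row reads the edge as a bright front.  A positive lag means the signal
    *leads* the edge (the reporter at time t mirrors the velocity at t+lag).
    """
    if phase_plan is None:
        phase_plan = [("protrusion", 2.0, n_frames * frame_interval_s)]
    velocity, phases = _phase_velocity_series(phase_plan, n_frames, frame_interval_s)
    rng = np.random.default_rng(seed)

    # edge position: cumulative integral of velocity (µm), edge at start_col px
    pos_um = start_col * pixel_size_um + np.concatenate(
        ([0.0], np.cumsum(velocity[:-1] * frame_interval_s / 60.0)))
    pos_px = pos_um / pixel_size_um

    # signal(t) tracks the instantaneous edge velocity at t + lag (signal
    # leads the edge by lag).  velocity[i] is the piecewise-constant rate on
    # [t_i, t_{i+1}); the instantaneous velocity AT t_i is the mean of the
    # adjacent segment rates, matching a centred finite difference.
    v_inst = np.empty(n_frames)
    v_inst[0] = velocity[0]
    v_inst[1:] = 0.5 * (velocity[:-1] + velocity[1:])
    lag_frames = signal_lag_s / frame_interval_s
    idx = np.arange(n_frames) + lag_frames
    v_lead = np.interp(idx, np.arange(n_frames), v_inst)
    signal = signal_base + signal_gain_min_per_um * v_lead

    h, w = shape
    cols = np.arange(w)
    frames = np.empty((n_frames, 2, h, w))
    for t in range(n_frames):
        # partial coverage of the edge pixel (pixel i spans [i-0.5, i+0.5)),
        # so the rendered edge moves smoothly at sub-pixel resolution
        coverage = np.clip(pos_px[t] - cols + 0.5, 0.0, 1.0)[None, :]
        band = (cols[None, :] > pos_px[t] - band_px)
        interior_value = np.where(band, signal[t] * cell_level,
                                  signal_base * cell_level)
        structural = background_level + (cell_level - background_level) * coverage
        ratio = background_level + (interior_value - background_level) * coverage
        for c, img in enumerate((ratio, structural)):
            img = np.broadcast_to(img, (h, w)).astype(float)
            if noise_sd > 0:
                img = img + rng.normal(0.0, noise_sd, size=(h, w))
            frames[t, c] = img

    stack = ChannelStack(frames, ("ratio", "structural"),
                         pixel_size_um, frame_interval_s)
    truth = GroundTruth(
        seed=seed,
        params=dict(phase_plan=list(phase_plan), band_px=band_px,
                    noise_sd=noise_sd, start_col=start_col,
                    signal_base=signal_base,
                    signal_gain_min_per_um=signal_gain_min_per_um),
        true_edge_position_um=pos_um,
        true_velocity_um_min=velocity,
        true_phases=phases,
        true_lag_s=signal_lag_s,
    )
    return stack, truth


def simulate_tracks(
    n_cells: int = 10,
    n_frames: int = 20,
    speed_um_min: float = 0.5,
    persistence: float = 0.7,
    frame_interval_s: float = 720.0,
    seed: int = 0,
    dropout: float = 0.0,
    spacing_um: float = 200.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Correlated-random-walk nucleus tracks with optional missed detections.

    Cells start on a grid ``spacing_um`` apart and take constant-length steps
    (``speed_um_min * dt``); the heading turns by a wrapped Gaussian whose SD
    scales with ``1 - persistence`` (persistence 1 → straight lines).
    ``dropout`` is the per-detection miss probability (first and last frames
    of each track always detected, so gap closing, not track truncation, is
    exercised).  Returns a detection table (frame, x_um, y_um, quality) and a
    ground-truth table that additionally carries the true track identity.
    """
    if n_cells < 1 or n_frames < 1:
        raise ValueError("n_cells and n_frames must be >= 1")
    if not 0 <= persistence <= 1:
        raise ValueError("persistence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    step = speed_um_min * frame_interval_s / 60.0
    turn_sd = (1.0 - persistence) * np.pi

    grid = int(np.ceil(np.sqrt(n_cells)))
    records = []
    for cell in range(n_cells):
        r, c = divmod(cell, grid)
        x, y = c * spacing_um, r * spacing_um
        theta = rng.uniform(0, 2 * np.pi)
        for frame in range(n_frames):
            records.append((cell, frame, x, y))
            theta += rng.normal(0.0, turn_sd) if turn_sd > 0 else 0.0
            x += step * np.cos(theta)
            y += step * np.sin(theta)
    truth_df = pd.DataFrame(records, columns=["true_track_id", "frame", "x_um", "y_um"])

    keep = np.ones(len(truth_df), dtype=bool)
    if dropout > 0:
        keep = rng.random(len(truth_df)) >= dropout
        first_last = (truth_df["frame"] == 0) | (truth_df["frame"] == n_frames - 1)
        keep |= first_last.to_numpy()
    detections = truth_df.loc[keep, ["frame", "x_um", "y_um"]].copy()
    detections["quality"] = 1.0
    detections = detections.sort_values(["frame", "x_um"]).reset_index(drop=True)

    truth = GroundTruth(
        seed=seed,
        params=dict(n_cells=n_cells, n_frames=n_frames,
                    speed_um_min=speed_um_min, persistence=persistence,
                    frame_interval_s=frame_interval_s, dropout=dropout),
        true_tracks=truth_df,
    )
    return detections, truth


def simulate_adhesion_table(counts_per_class: tuple[int, int, int],
                            seed: int = 0) -> pd.DataFrame:
    """Focal-adhesion areas drawn uniformly within each class's area bin.

    Classes follow the published bins: nascent [0.05, 0.20), mature
    [0.20, 1.75], fibrillar (1.75, ∞) µm² (fibrillar draws capped at 5 µm²).
    """
    if any(c < 0 for c in counts_per_class):
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    lo_edges = ADHESION_BINS_UM2[:-1]
    hi_edges = ADHESION_BINS_UM2[1:]
    areas = []
    for count, lo, hi in zip(counts_per_class, lo_edges, hi_edges):
        areas.append(rng.uniform(lo, hi, size=count))
    all_areas = np.concatenate(areas) if areas else np.empty(0)
    return pd.DataFrame({"area_um2": all_areas})
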