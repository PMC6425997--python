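"""Ratiometric FRET biosensor pipeline for localized RAC1 activation.

The single-chain DORA RAC1 sensor reports activation as the Venus (acceptor)
over Cerulean3 (donor) emission ratio.  The processing chain mirrors standard
ratio imaging practice:

1. background correction (per frame and channel, median outside the cell),
2. integer-pixel stack alignment to the first frame (donor cross-correlation),
3. 3×3 mean smoothing of both fluorescence channels,
4. donor bleed-through correction and ratioing,
       F = (V − β·C) / C,
   with the acceptor threshold sending background pixels to NaN,
5. membrane-vs-cytosol activation ratio A(t) in the sector facing the
   particle contact site.

β defaults to 0.62 (donor fraction leaking into the acceptor channel) and can
be recalibrated from donor-only cells with :func:`estimate_bleedthrough`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

from .types import FretStack

logger = logging.getLogger(__name__)

DEFAULT_BLEED_THROUGH = 0.62
#: Membrane ROI thickness in μm (the actin-rich rim at the contact site).
DEFAULT_MEMBRANE_WIDTH = 1.0
#: Half-angle (degrees) of the sector centered on the contact direction.
DEFAULT_SECTOR_HALFANGLE = 45.0


@dataclass
class RatioMap:
    """Bleed-through-corrected Venus/Cerulean3 ratio with NaN background."""

    ratio: np.ndarray  # (T, H, W)
    beta_used: float
    acceptor_threshold: float
    n_division_guard: int = 0


@dataclass
class ActivationTrace:
    """Membrane and cytosol mean ratios near the contact site, over time.

    ``activation_ratio`` A(t) = membrane_mean / cytosol_mean; NaN where either
    ROI mean is undefined (missing particle, empty ROI, all-NaN ratio).
    """

    times: np.ndarray  # minutes
    membrane_mean: np.ndarray
    cytosol_mean: np.ndarray
    activation_ratio: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.times.size),
                "time_min": self.times,
                "membrane_mean": self.membrane_mean,
                "cytosol_mean": self.cytosol_mean,
                "activation_ratio": self.activation_ratio,
            }
        )


def _frame_cell_mask(frame: np.ndarray) -> np.ndarray:
    if np.ptp(frame) == 0:
        return np.zeros(frame.shape, dtype=bool)
    mask = frame > threshold_otsu(frame)
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(frame), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def derive_cell_masks(stack: FretStack) -> np.ndarray:
    """Per-frame boolean cell mask from the donor channel (Otsu, largest CC)."""
    return np.stack([_frame_cell_mask(f) for f in stack.donor])


def background_correct(
    stack: FretStack, cell_mask_series: np.ndarray | None = None
) -> tuple[FretStack, np.ndarray]:
    """Subtract, per frame and channel, the median outside the cell; clip at 0."""
    if cell_mask_series is None:
        cell_mask_series = derive_cell_masks(stack)
    out = {}
    for name in ("donor", "acceptor", "particle"):
        frames = getattr(stack, name).copy()
        for t in range(stack.n_frames):
            outside = ~cell_mask_series[t]
            level = float(np.median(frames[t][outside])) if outside.any() else 0.0
            frames[t] = np.clip(frames[t] - level, 0.0, None)
        out[name] = frames
    return replace(stack, **out), cell_mask_series


def align_stack(stack: FretStack, reference: int = 0) -> tuple[FretStack, np.ndarray]:
    """Integer-pixel registration of every frame to the reference frame.

    Shifts are estimated by cross-correlation of the donor channel and applied
    identically to all three channels.  Returns the aligned stack and the
    applied (dx, dy) shifts per frame.
    """
    ref = stack.donor[reference]
    shifts = np.zeros((stack.n_frames, 2), dtype=int)
    donor = stack.donor.copy()
    acceptor = stack.acceptor.copy()
    particle = stack.particle.copy()
    for t in range(stack.n_frames):
        if t == reference:
            continue
        shift_rc, _, _ = phase_cross_correlation(ref, stack.donor[t], normalization=None)
        dy, dx = (int(round(v)) for v in shift_rc)
        shifts[t] = (dx, dy)
        for arr in (donor, acceptor, particle):
            arr[t] = ndimage.shift(arr[t], (dy, dx), order=0, mode="constant", cval=0.0)
    return replace(stack, donor=donor, acceptor=acceptor, particle=particle), shifts


def smooth_stack(stack: FretStack, size: int = 3) -> FretStack:
    """Uniform mean filter (default 3×3) on both fluorescence channels."""
    if size < 1:
        raise ValueError("kernel size must be >= 1")
    out = {}
    for name in ("donor", "acceptor"):
        frames = getattr(stack, name)
        out[name] = np.stack(
            [ndimage.uniform_filter(f, size=size, mode="nearest") for f in frames]
        )
    return replace(stack, **out)


def estimate_bleedthrough(donor_only_stacks) -> float:
    """Estimate β from donor-only cells.

    Pools background-corrected acceptor vs donor intensities over in-cell
    pixels of all provided stacks and returns the least-squares slope.
    """
    xs, ys = [], []
    for stack in donor_only_stacks:
        corrected, masks = background_correct(stack)
        for t in range(corrected.n_frames):
            mask = masks[t]
            if mask.any():
                xs.append(corrected.donor[t][mask])
                ys.append(corrected.acceptor[t][mask])
    if not xs:
        raise ValueError("degenerate calibration: no cell pixels found")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if np.ptp(x) == 0 or np.var(x) < 1e-12:
        raise ValueError("degenerate calibration: constant donor signal")
    slope, _intercept = np.polyfit(x, y, 1)
    return float(slope)


def default_acceptor_threshold(acceptor: np.ndarray) -> float:
    """Background-removal threshold: median + 3 scaled-MAD of the acceptor."""
    med = float(np.median(acceptor))
    mad = float(np.median(np.abs(acceptor - med)))
    return med + 3.0 * 1.4826 * mad


def ratio_map(
    stack: FretStack,
    beta: float = DEFAULT_BLEED_THROUGH,
    acceptor_threshold: float | None = None,
) -> RatioMap:
    """Bleed-through-corrected ratio F = (V − β·C)/C with NaN background.

    The threshold applies to the acceptor (Venus) channel only; pixels below
    it become NaN in every frame they fail.  Pixels passing the threshold with
    zero donor signal are also NaN (division guard) and counted.
    """
    if not 0.0 <= beta < 1.0:
        raise ValueError("beta must lie in [0, 1)")
    V = stack.acceptor
    C = stack.donor
    if acceptor_threshold is None:
        acceptor_threshold = default_acceptor_threshold(V)
    valid = V >= acceptor_threshold
    div_ok = C > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid & div_ok, (V - beta * C) / np.where(div_ok, C, 1.0), np.nan)
    n_guard = int(np.count_nonzero(valid & ~div_ok))
    if n_guard:
        logger.info("ratio_map: %d above-threshold pixels had zero donor signal", n_guard)
    return RatioMap(
        ratio=ratio,
        beta_used=float(beta),
        acceptor_threshold=float(acceptor_threshold),
        n_division_guard=n_guard,
    )


def particle_centroid_series(stack: FretStack, k: float = 5.0) -> np.ndarray:
    """Per-frame particle centroid in μm, NaN rows where no particle is found."""
    out = np.full((stack.n_frames, 2), np.nan)
    for t, frame in enumerate(stack.particle):
        background = float(np.median(frame))
        noise = 1.4826 * float(np.median(np.abs(frame - background)))
        floor = background + k * noise
        if not np.any(frame > floor):
            continue
        threshold = max(float(threshold_otsu(frame)), floor)
        mask = frame > threshold
        labels, n = ndimage.label(mask)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(frame), labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
        row, col = ndimage.center_of_mass(np.clip(frame - background, 0, None) * mask)
        out[t] = ((col + 0.5) * stack.pixel_size, (row + 0.5) * stack.pixel_size)
    return out


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def activation_trace(
    rmap: RatioMap,
    particle_centroids: np.ndarray,
    cell_mask_series: np.ndarray,
    pixel_size: float,
    frame_interval: float = 1.0,
    *,
    sector_halfangle: float = DEFAULT_SECTOR_HALFANGLE,
    membrane_width: float = DEFAULT_MEMBRANE_WIDTH,
) -> ActivationTrace:
    """Membrane/cytosol activation ratio near the particle contact site.

    Per frame, the membrane ROI is the set of in-mask pixels within
    ``membrane_width`` μm of the mask boundary and inside the angular sector
    (± ``sector_halfangle``) centered on the cell-centroid → particle-centroid
    direction; the cytosol ROI is the deeper in-sector remainder.  Means are
    NaN-aware; frames with no particle or an empty ROI yield NaN.
    """
    T, H, W = rmap.ratio.shape
    if cell_mask_series.shape != (T, H, W):
        raise ValueError("cell_mask_series must match the ratio map shape")
    particle_centroids = np.asarray(particle_centroids, dtype=float)
    if particle_centroids.shape != (T, 2):
        raise ValueError("particle_centroids must be (T, 2)")
    ax_x = (np.arange(W) + 0.5) * pixel_size
    ax_y = (np.arange(H) + 0.5) * pixel_size
    xx, yy = np.meshgrid(ax_x, ax_y)
    membrane = np.full(T, np.nan)
    cytosol = np.full(T, np.nan)
    for t in range(T):
        mask = cell_mask_series[t].astype(bool)
        pc = particle_centroids[t]
        if not mask.any() or not np.all(np.isfinite(pc)):
            continue
        row, col = ndimage.center_of_mass(mask)
        cx, cy = (col + 0.5) * pixel_size, (row + 0.5) * pixel_size
        direction = np.arctan2(pc[1] - cy, pc[0] - cx)
        if np.hypot(pc[0] - cx, pc[1] - cy) < pixel_size:
            continue  # contact direction undefined
        depth = ndimage.distance_transform_edt(mask) * pixel_size
        angles = _wrap_angle(np.arctan2(yy - cy, xx - cx) - direction)
        sector = np.abs(angles) <= np.deg2rad(sector_halfangle)
        roi_m = mask & sector & (depth <= membrane_width)
        roi_c = mask & sector & (depth > membrane_width)
        vals_m = rmap.ratio[t][roi_m]
        vals_c = rmap.ratio[t][roi_c]
        vals_m = vals_m[np.isfinite(vals_m)]
        vals_c = vals_c[np.isfinite(vals_c)]
        if vals_m.size:
            membrane[t] = float(vals_m.mean())
        if vals_c.size:
            cytosol[t] = float(vals_c.mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        activation = np.where(
            np.isfinite(membrane) & np.isfinite(cytosol) & (cytosol > 0),
            membrane / cytosol,
            np.nan,
        )
    return ActivationTrace(
        times=np.arange(T) * frame_interval,
        membrane_mean=membrane,
        cytosol_mean=cytosol,
        activation_ratio=activation,
    )


def run_fret_pipeline(
    stack: FretStack,
    beta: float = DEFAULT_BLEED_THROUGH,
    *,
    acceptor_threshold: float | None = None,
    smooth_size: int = 3,
    sector_halfangle: float = DEFAULT_SECTOR_HALFANGLE,
    membrane_width: float = DEFAULT_MEMBRANE_WIDTH,
) -> tuple[RatioMap, ActivationTrace, np.ndarray, np.ndarray]:
    """Full chain: background → align → smooth → ratio → activation trace.

    Returns the ratio map, the activation trace, the applied alignment shifts
    and the (post-alignment) cell mask series.
    """
    corrected, _ = background_correct(stack)
    aligned, shifts = align_stack(corrected)
    masks = derive_cell_masks(aligned)
    smoothed = smooth_stack(aligned, size=smooth_size)
    rmap = ratio_map(smoothed, beta=beta, acceptor_threshold=acceptor_threshold)
    centroids = particle_centroid_series(aligned)
    trace = activation_trace(
        rmap,
        centroids,
        masks,
        pixel_size=stack.pixel_size,
        frame_interval=stack.frame_interval,
        sector_halfangle=sector_halfangle,
        membrane_width=membrane_width,
    )
    return rmap, trace, shifts, masks


def render_ratio_heatmap(
    rmap: RatioMap,
    lut_range: tuple[float, float] | None = None,
    cmap: str = "coolwarm",
    out_dir=None,
    prefix: str = "ratio",
) -> list[np.ndarray]:
    """Render each ratio frame through a blue→red LUT; NaN maps to black.

    Out-of-range values clip to the LUT endpoints.  When ``out_dir`` is given,
    one PNG per frame is written there.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import Normalize

    finite = rmap.ratio[np.isfinite(rmap.ratio)]
    if lut_range is None:
        if finite.size == 0:
            lut_range = (0.0, 1.0)
        else:
            lut_range = (float(np.percentile(finite, 2)), float(np.percentile(finite, 98)))
    vmin, vmax = lut_range
    if not vmax > vmin:
        vmax = vmin + 1e-6
    colormap = plt.get_cmap(cmap).copy()
    colormap.set_bad((0.0, 0.0, 0.0, 1.0))
    norm = Normalize(vmin=vmin, vmax=vmax, clip=True)
    frames = []
    for t, frame in enumerate(rmap.ratio):
        rgba = colormap(norm(np.ma.masked_invalid(frame)))
        rgba = (rgba * 255).astype(np.uint8)
        frames.append(rgba)
        if out_dir is not None:
            from pathlib import Path

            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            plt.imsave(out / f"{prefix}_{t:03d}.png", rgba)
    return frames
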