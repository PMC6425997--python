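"""Ground-truthed synthetic event images and FRET biosensor stacks.

The generators emulate the statistical structure the downstream analysis
assumes: an imaging-flow-cytometer-like four-channel event image per cell
(brightfield, nuclear stain, surface marker, particle fluorescence) and a
widefield two-camera biosensor time lapse with donor-to-acceptor bleed-through.
Every generated object is paired with the ground truth that produced it, so
each analysis stage can be tested against a known answer without any
downloaded data.

Geometry classes of an event
----------------------------
``no_particle``
    Cell only; the particle channel carries pure background.
``bound``
    Particle centroid placed exactly on the outside of the membrane, at
    distance R + D/2 from the cell centroid (R cell radius, D particle
    diameter).
``internalized``
    Particle fully engulfed.  The centroid is drawn from the inner half of
    the admissible range, d <= (R - D/2)/2, emulating the perinuclear
    position of particle-containing phagosomes after uptake.
``off_plane``
    Particle present but defocused (different focal plane): the particle
    channel is rendered with a large Gaussian blur.  These events must be
    removed by the focus gate, never scored.

All randomness flows through :func:`numpy.random.default_rng` seeded from the
caller; identical parameters and seed give bit-identical arrays.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .types import EventImage, FretStack

logger = logging.getLogger(__name__)

LABELS = ("no_particle", "bound", "internalized", "off_plane")

# ---------------------------------------------------------------------------
# Event-generator defaults (the emulated acquisition conditions)
# ---------------------------------------------------------------------------
DEFAULT_PIXEL_SIZE = 0.33  # μm/px, 63x-objective scale (7 μm cell ~ 21 px)
DEFAULT_IMAGE_SIDE = 64  # px
BACKGROUND_LEVEL = 100.0  # counts, fluorescence channels, 16-bit range
BRIGHTFIELD_BACKGROUND = 1000.0  # counts
BRIGHTFIELD_ATTENUATION = 0.35  # cell disc is 35 % darker than background
SURFACE_BRIGHTNESS = 1000.0  # counts above background
NUCLEUS_BRIGHTNESS = 800.0
PARTICLE_BRIGHTNESS = 4000.0  # bright dsRed-like particle label
IN_FOCUS_BLUR = 0.15  # μm, optical blur of in-focus channels
OFF_PLANE_BLUR = 1.0  # μm, particle-channel blur of off-plane events
BACTERIUM_DIAMETER = 1.0  # μm, rendered as a circle
BEAD_DIAMETER = 3.0  # μm, polystyrene bead
CELL_RADIUS_MEAN = 3.5  # μm (7 μm cell diameter)
CELL_RADIUS_SD = 0.3
DEFAULT_NOISE_SD = 50.0  # counts = 5 % of the surface signal
MAX_COUNTS = 65535.0

# ---------------------------------------------------------------------------
# FRET-generator defaults
# ---------------------------------------------------------------------------
FRET_PIXEL_SIZE = 0.065  # μm/px: 63x objective, 1.6x optovar, 6.45 μm camera px
FRET_IMAGE_SIDE = 208  # px
FRET_CELL_RADIUS = 5.0  # μm, Ramos-like B cell
FRET_BACKGROUND = 100.0  # counts
DEFAULT_BLEED_THROUGH = 0.62  # donor fraction leaking into the acceptor channel
MEMBRANE_BAND_UM = 1.0  # μm, thickness of the membrane-proximal activation band
SECTOR_HALFANGLE_DEG = 45.0  # degrees, contact sector half-angle
DEFAULT_FRET_FRAMES = 12
DEFAULT_FRAME_INTERVAL = 0.5  # minutes
DONOR_PROFILE_FALLOFF = 0.3  # radial thinning of the cytosolic donor signal


@dataclass(frozen=True)
class EventGroundTruth:
    """Generator-side truth for one event; used only by tests and evaluation.

    Positions are physical (x, y) coordinates in μm with x along image
    columns and y along rows; the coordinate of pixel (row r, col c) is
    ((c + 0.5) * pixel_size, (r + 0.5) * pixel_size).
    """

    label: str
    cell_center: tuple[float, float]
    cell_radius: float
    particle_center: tuple[float, float] | None
    particle_diameter: float
    focus_blur_sigma: tuple[float, float, float, float]
    seed: int

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if not self.cell_radius > 0:
            raise ValueError("cell_radius must be positive")
        if not self.particle_diameter > 0:
            raise ValueError("particle_diameter must be positive")
        if self.label == "no_particle":
            if self.particle_center is not None:
                raise ValueError("no_particle events carry no particle_center")
        elif self.particle_center is None:
            raise ValueError(f"{self.label} events require a particle_center")
        d = self.centroid_distance
        if self.label == "bound":
            expected = self.cell_radius + self.particle_diameter / 2
            if abs(d - expected) > 1e-6:
                raise ValueError(
                    f"bound events place the particle centroid at R + D/2 = "
                    f"{expected:.4f} μm from the cell centroid, got {d:.4f}"
                )
        if self.label == "internalized":
            if d > self.cell_radius - self.particle_diameter / 2 + 1e-9:
                raise ValueError("internalized particle must lie fully inside the cell")
        if self.label == "off_plane" and self.focus_blur_sigma[3] < OFF_PLANE_BLUR - 1e-9:
            raise ValueError(
                f"off_plane events need particle-channel blur >= {OFF_PLANE_BLUR} μm"
            )

    @property
    def centroid_distance(self) -> float | None:
        """True cell-to-particle centroid distance in μm, or None."""
        if self.particle_center is None:
            return None
        return math.hypot(
            self.particle_center[0] - self.cell_center[0],
            self.particle_center[1] - self.cell_center[1],
        )


def _pixel_grid(image_side: int, pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    ax = (np.arange(image_side) + 0.5) * pixel_size
    return np.meshgrid(ax, ax)  # xx varies along columns, yy along rows


def _disc(xx, yy, center, radius, pixel_size) -> np.ndarray:
    """Anti-aliased disc coverage in [0, 1] (linear edge over one pixel)."""
    dist = np.hypot(xx - center[0], yy - center[1])
    return np.clip((radius - dist) / pixel_size + 0.5, 0.0, 1.0)


def random_truth(
    rng: np.random.Generator,
    label: str | None = None,
    *,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    image_side: int = DEFAULT_IMAGE_SIDE,
    particle_diameter: float = BACTERIUM_DIAMETER,
    seed: int = 0,
) -> EventGroundTruth:
    """Draw one ground truth of the requested (or random) geometry class."""
    if label is None:
        label = LABELS[rng.integers(len(LABELS))]
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    half = image_side * pixel_size / 2
    radius = float(np.clip(rng.normal(CELL_RADIUS_MEAN, CELL_RADIUS_SD), 2.8, 4.2))
    center = (half + rng.uniform(-1.0, 1.0), half + rng.uniform(-1.0, 1.0))
    blur = [IN_FOCUS_BLUR] * 4
    particle_center = None
    if label != "no_particle":
        theta = rng.uniform(0.0, 2 * np.pi)
        if label == "bound":
            d = radius + particle_diameter / 2
        elif label == "internalized":
            # inner half of the admissible range: engulfed particles sit deep
            d = rng.uniform(0.0, 0.5 * (radius - particle_diameter / 2))
        else:  # off_plane: lateral position unconstrained
            d = rng.uniform(0.0, radius + particle_diameter / 2)
            blur[3] = OFF_PLANE_BLUR
        particle_center = (
            center[0] + d * math.cos(theta),
            center[1] + d * math.sin(theta),
        )
    return EventGroundTruth(
        label=label,
        cell_center=center,
        cell_radius=radius,
        particle_center=particle_center,
        particle_diameter=particle_diameter,
        focus_blur_sigma=tuple(blur),
        seed=seed,
    )


def _check_containment(truth: EventGroundTruth, pixel_size: float, image_side: int) -> None:
    extent = image_side * pixel_size
    margin_cell = 3 * max(truth.focus_blur_sigma[:3]) + pixel_size
    lo = min(truth.cell_center) - truth.cell_radius - margin_cell
    hi = max(truth.cell_center) + truth.cell_radius + margin_cell
    if truth.particle_center is not None:
        margin_p = truth.particle_diameter / 2 + 3 * truth.focus_blur_sigma[3] + pixel_size
        lo = min(lo, min(truth.particle_center) - margin_p)
        hi = max(hi, max(truth.particle_center) + margin_p)
    if lo < 0 or hi > extent:
        raise ValueError(
            f"frame too small: scene spans [{lo:.2f}, {hi:.2f}] μm but the frame is "
            f"{extent:.2f} μm across"
        )


def _render_event(truth: EventGroundTruth, pixel_size: float, image_side: int) -> list[np.ndarray]:
    xx, yy = _pixel_grid(image_side, pixel_size)
    cell = _disc(xx, yy, truth.cell_center, truth.cell_radius, pixel_size)
    nucleus = _disc(xx, yy, truth.cell_center, 0.55 * truth.cell_radius, pixel_size)
    channels = [
        BRIGHTFIELD_BACKGROUND * (1.0 - BRIGHTFIELD_ATTENUATION * cell),
        BACKGROUND_LEVEL + NUCLEUS_BRIGHTNESS * nucleus,
        BACKGROUND_LEVEL + SURFACE_BRIGHTNESS * cell,
        np.full_like(cell, BACKGROUND_LEVEL),
    ]
    if truth.particle_center is not None:
        channels[3] = BACKGROUND_LEVEL + PARTICLE_BRIGHTNESS * _disc(
            xx, yy, truth.particle_center, truth.particle_diameter / 2, pixel_size
        )
    for i, sigma in enumerate(truth.focus_blur_sigma):
        if sigma > 0:
            channels[i] = ndimage.gaussian_filter(channels[i], sigma / pixel_size, mode="nearest")
    return channels


def generate_event(
    truth: EventGroundTruth | str = "random",
    *,
    noise_sd: float = 0.0,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    image_side: int = DEFAULT_IMAGE_SIDE,
    seed: int = 0,
    particle_diameter: float = BACTERIUM_DIAMETER,
    event_id: str = "",
) -> tuple[EventImage, EventGroundTruth]:
    """Render one four-channel event image with additive Gaussian noise.

    ``truth`` may be an :class:`EventGroundTruth`, a label name, or
    ``"random"`` (uniform over the four classes).  Identical parameters and
    seed produce bit-identical output.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    if isinstance(truth, str):
        label = None if truth == "random" else truth
        truth = random_truth(
            rng,
            label,
            pixel_size=pixel_size,
            image_side=image_side,
            particle_diameter=particle_diameter,
            seed=seed,
        )
    else:
        truth = replace(truth, seed=seed)
    _check_containment(truth, pixel_size, image_side)
    channels = _render_event(truth, pixel_size, image_side)
    if noise_sd > 0:
        channels = [
            np.clip(c + rng.normal(0.0, noise_sd, c.shape), 0.0, MAX_COUNTS) for c in channels
        ]
    image = EventImage(
        *channels, pixel_size=pixel_size, event_id=event_id or f"event-{truth.seed}"
    )
    return image, truth


def generate_cohort(
    n: int,
    class_mixture,
    noise_sd: float = DEFAULT_NOISE_SD,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    seed: int = 0,
    *,
    image_side: int = DEFAULT_IMAGE_SIDE,
    particle_diameter: float = BACTERIUM_DIAMETER,
) -> tuple[list[EventImage], list[EventGroundTruth]]:
    """Draw ``n`` events i.i.d. from a mixture over the four geometry classes.

    ``class_mixture`` gives probabilities in the order
    (no_particle, bound, internalized, off_plane); per-event seeds are derived
    deterministically from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mixture = np.asarray(class_mixture, dtype=float)
    if mixture.shape != (4,):
        raise ValueError(
            f"class_mixture must hold one probability per label {LABELS}, got shape {mixture.shape}"
        )
    for i, p in enumerate(mixture):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"class_mixture[{i}] = {p} lies outside [0, 1]")
    if abs(mixture.sum() - 1.0) > 1e-9:
        raise ValueError(f"class_mixture sums to {mixture.sum()!r}, expected 1")
    rng = np.random.default_rng(seed)
    label_idx = rng.choice(len(LABELS), size=n, p=mixture)
    event_seeds = rng.integers(0, 2**31 - 1, size=n)
    images, truths = [], []
    for k, (idx, es) in enumerate(zip(label_idx, event_seeds)):
        img, tr = generate_event(
            LABELS[idx],
            noise_sd=noise_sd,
            pixel_size=pixel_size,
            image_side=image_side,
            seed=int(es),
            particle_diameter=particle_diameter,
            event_id=f"event-{k:04d}",
        )
        images.append(img)
        truths.append(tr)
    return images, truths


# ---------------------------------------------------------------------------
# FRET biosensor forward model
# ---------------------------------------------------------------------------


@dataclass
class FretGroundTruth:
    """Truth for a synthetic biosensor stack, in drift-free reference coordinates.

    ``activation_map_series`` holds the true ratiometric activation a(x, t),
    defined (non-NaN) exactly on the cell footprint.  The forward model per
    pixel is V_signal = (a + β)·C_signal with C_signal the background-free
    donor signal; each rendered frame is translated by ``drift_series`` before
    noise is added.
    """

    activation_map_series: np.ndarray  # (T, H, W), NaN off the cell footprint
    bleed_through: float  # β in [0, 1)
    background_level: float  # counts
    drift_series: np.ndarray  # (T, 2) integer (dx, dy) pixel translations
    seed: int
    pixel_size: float = FRET_PIXEL_SIZE
    cell_mask: np.ndarray | None = None  # (H, W) footprint
    donor_profile: np.ndarray | None = None  # (H, W) relative donor signal
    particle_center_series: np.ndarray | None = None  # (T, 2) μm, NaN if absent
    particle_diameter: float = BACTERIUM_DIAMETER

    def __post_init__(self) -> None:
        if not 0.0 <= self.bleed_through < 1.0:
            raise ValueError("bleed_through must lie in [0, 1)")
        self.activation_map_series = np.asarray(self.activation_map_series, dtype=float)
        self.drift_series = np.asarray(self.drift_series)
        if self.drift_series.shape != (self.activation_map_series.shape[0], 2):
            raise ValueError("drift_series must be (T, 2)")


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def make_fret_truth(
    frames: int = DEFAULT_FRET_FRAMES,
    *,
    image_side: int = FRET_IMAGE_SIDE,
    pixel_size: float = FRET_PIXEL_SIZE,
    cell_radius: float = FRET_CELL_RADIUS,
    cell_center: tuple[float, float] | None = None,
    baseline_activation: float = 1.0,
    contact_gain: float = 2.0,
    engulf_start: int = 4,
    engulf_stop: int = 9,
    sector_halfangle: float = SECTOR_HALFANGLE_DEG,
    band_width: float = MEMBRANE_BAND_UM,
    bleed_through: float = DEFAULT_BLEED_THROUGH,
    background: float = FRET_BACKGROUND,
    particle_diameter: float = BACTERIUM_DIAMETER,
    include_particle: bool = True,
    max_drift: int = 0,
    seed: int = 0,
) -> FretGroundTruth:
    """Construct the ground truth of an engulfment movie.

    The cell is a disc; the particle touches the membrane along +x.  During
    frames ``engulf_start <= t < engulf_stop`` the membrane-proximal band
    (within ``band_width`` μm of the cell edge) inside the contact sector
    (± ``sector_halfangle`` around the contact direction) carries
    ``contact_gain`` times the baseline activation; elsewhere and at other
    times activation is at baseline.  ``max_drift`` > 0 adds random integer
    frame translations in [-max_drift, max_drift] px (frame 0 stays at zero).
    """
    if frames < 1:
        raise ValueError("frames must be >= 1")
    rng = np.random.default_rng(seed)
    half = image_side * pixel_size / 2
    if cell_center is None:
        cell_center = (half, half)
    xx, yy = _pixel_grid(image_side, pixel_size)
    r = np.hypot(xx - cell_center[0], yy - cell_center[1])
    footprint = r <= cell_radius
    needed = cell_radius + (max_drift + 2) * pixel_size
    if include_particle:
        needed += particle_diameter
    if min(cell_center) - needed < 0 or max(cell_center) + needed > image_side * pixel_size:
        raise ValueError("frame too small for the requested cell geometry")
    # membrane-proximal band within the contact sector, on the pixel grid
    depth = ndimage.distance_transform_edt(footprint) * pixel_size
    angle = np.arctan2(yy - cell_center[1], xx - cell_center[0])
    sector = np.abs(_wrap_angle(angle)) <= np.deg2rad(sector_halfangle)  # contact along +x
    band = footprint & (depth <= band_width) & sector
    base = np.where(footprint, baseline_activation, np.nan)
    maps = np.stack([base.copy() for _ in range(frames)])
    for t in range(max(engulf_start, 0), min(engulf_stop, frames)):
        maps[t][band] = baseline_activation * contact_gain
    profile = np.where(
        footprint, 1.0 - DONOR_PROFILE_FALLOFF * (r / cell_radius) ** 2, 0.0
    )
    drift = np.zeros((frames, 2), dtype=int)
    if max_drift > 0 and frames > 1:
        drift[1:] = rng.integers(-max_drift, max_drift + 1, size=(frames - 1, 2))
    particle_series = np.full((frames, 2), np.nan)
    if include_particle:
        contact = (cell_center[0] + cell_radius + particle_diameter / 2, cell_center[1])
        particle_series[:] = contact
    return FretGroundTruth(
        activation_map_series=maps,
        bleed_through=bleed_through,
        background_level=background,
        drift_series=drift,
        seed=seed,
        pixel_size=pixel_size,
        cell_mask=footprint,
        donor_profile=profile,
        particle_center_series=particle_series,
        particle_diameter=particle_diameter,
    )


def _shift_frame(frame: np.ndarray, dx: int, dy: int) -> np.ndarray:
    return ndimage.shift(frame, (dy, dx), order=0, mode="constant", cval=0.0)


def generate_fret_stack(
    truth: FretGroundTruth,
    donor_brightness: float = 1000.0,
    noise_sd: float = 0.0,
    frames: int | None = None,
    seed: int = 0,
    *,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> tuple[FretStack, FretGroundTruth]:
    """Render a donor/acceptor/particle stack from a :class:`FretGroundTruth`.

    Per pixel and frame: donor = C_signal + background + noise and
    acceptor = (a + β)·C_signal + background + noise, where C_signal is the
    background-free donor signal (brightness times the cell's radial profile);
    each frame is translated by the truth's drift before noise is added.
    """
    if not 0.0 <= truth.bleed_through < 1.0:
        raise ValueError("bleed_through must lie in [0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n_truth = truth.activation_map_series.shape[0]
    n = n_truth if frames is None else int(frames)
    if n < 1 or n > n_truth:
        raise ValueError(f"frames must lie in [1, {n_truth}]")
    rng = np.random.default_rng(seed)
    shape = truth.activation_map_series.shape[1:]
    c_signal = donor_brightness * truth.donor_profile
    activation = np.nan_to_num(truth.activation_map_series, nan=0.0)
    xx, yy = _pixel_grid(shape[0], truth.pixel_size)
    donor = np.empty((n, *shape))
    acceptor = np.empty_like(donor)
    particle = np.empty_like(donor)
    for t in range(n):
        v_signal = (activation[t] + truth.bleed_through) * c_signal
        p_signal = np.zeros(shape)
        if truth.particle_center_series is not None and np.all(
            np.isfinite(truth.particle_center_series[t])
        ):
            disc = _disc(
                xx, yy, truth.particle_center_series[t], truth.particle_diameter / 2,
                truth.pixel_size,
            )
            p_signal = PARTICLE_BRIGHTNESS * ndimage.gaussian_filter(
                disc, IN_FOCUS_BLUR / truth.pixel_size, mode="nearest"
            )
        dx, dy = (int(v) for v in truth.drift_series[t])
        for src, dst in ((c_signal, donor), (v_signal, acceptor), (p_signal, particle)):
            frame = _shift_frame(src, dx, dy) + truth.background_level
            if noise_sd > 0:
                frame = frame + rng.normal(0.0, noise_sd, shape)
            dst[t] = np.clip(frame, 0.0, MAX_COUNTS)
    stack = FretStack(
        donor=donor,
        acceptor=acceptor,
        particle=particle,
        pixel_size=truth.pixel_size,
        frame_interval=frame_interval,
    )
    return stack, truth


def generate_donor_only(
    n_cells: int,
    bleed_through: float = DEFAULT_BLEED_THROUGH,
    donor_brightness: float = 1000.0,
    noise_sd: float = 20.0,
    seed: int = 0,
    *,
    image_side: int = 176,
    pixel_size: float = FRET_PIXEL_SIZE,
) -> tuple[list[FretStack], FretGroundTruth]:
    """Donor-only calibration cells: activation forced to zero everywhere.

    The acceptor channel then carries only the leaked donor signal,
    V = β·C_signal + background + noise, which is what a bleed-through
    calibration measures.  Cell size and brightness vary between cells so the
    pooled donor intensities span a usable range.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    stacks: list[FretStack] = []
    first_truth: FretGroundTruth | None = None
    half = image_side * pixel_size / 2
    for _ in range(n_cells):
        radius = rng.uniform(3.5, 5.0)
        gain = rng.uniform(0.7, 1.3)
        jitter = rng.uniform(-0.5, 0.5, size=2)
        cell_seed = int(rng.integers(0, 2**31 - 1))
        truth = make_fret_truth(
            frames=1,
            image_side=image_side,
            pixel_size=pixel_size,
            cell_radius=radius,
            cell_center=(half + jitter[0], half + jitter[1]),
            baseline_activation=0.0,
            contact_gain=1.0,
            engulf_start=0,
            engulf_stop=0,
            bleed_through=bleed_through,
            include_particle=False,
            seed=cell_seed,
        )
        stack, truth = generate_fret_stack(
            truth,
            donor_brightness=donor_brightness * gain,
            noise_sd=noise_sd,
            seed=cell_seed,
        )
        stacks.append(stack)
        if first_truth is None:
            first_truth = truth
    return stacks, first_truth


def truth_table(truths: list[EventGroundTruth]):
    """Ground truths as a tidy table (one row per event), for evaluation."""
    import pandas as pd

    rows = []
    for k, t in enumerate(truths):
        rows.append(
            {
                "event_id": f"event-{k:04d}",
                "label": t.label,
                "cell_x": t.cell_center[0],
                "cell_y": t.cell_center[1],
                "cell_radius": t.cell_radius,
                "particle_x": t.particle_center[0] if t.particle_center else np.nan,
                "particle_y": t.particle_center[1] if t.particle_center else np.nan,
                "particle_diameter": t.particle_diameter,
                "centroid_distance": t.centroid_distance
                if t.centroid_distance is not None
                else np.nan,
                "blur_brightfield": t.focus_blur_sigma[0],
                "blur_nucleus": t.focus_blur_sigma[1],
                "blur_surface": t.focus_blur_sigma[2],
                "blur_particle": t.focus_blur_sigma[3],
                "seed": t.seed,
            }
        )
    return pd.DataFrame(rows)
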