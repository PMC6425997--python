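"""Internalization scoring of single-cell event images.

Given a four-channel event image, the pipeline segments the B cell (surface
marker channel) and the particle (particle channel), gates out events whose
particle is not in the cell's focal plane, and computes the radius-corrected
centroid-distance internalization score

    s = R / max(d, eps),

with R the equivalent-circle cell radius, d the distance between the cell and
particle centroids, and eps one pixel in μm (so s stays finite when the
centroids coincide).  Membrane-bound geometry gives s <= 1; a particle deep in
the cell gives a large s.  Events with s >= τ (default τ = 2) are classified
as internalized, the rest as bound.  Cohorts are summarized by the gating
chain

    all events -> in focus -> particle-positive -> internalized

with %-interacting = particle-positive / focused and %-internalized =
internalized / particle-positive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .types import EventImage

logger = logging.getLogger(__name__)

#: Internalization threshold τ: events with s >= τ count as internalized.
DEFAULT_THRESHOLD = 2.0

#: Floor ε of the centroid distance in the score, in μm: one pixel at the
#: native instrument calibration.  A fixed physical constant keeps the score
#: invariant when the same scene is imaged at a different pixel size.
SCORE_EPSILON_UM = 0.33

#: Particle-detection gate: a particle is present when some pixel exceeds the
#: channel background by k times the estimated noise level.
DEFAULT_DETECTION_K = 5.0

# Focus-gate cutoffs on the normalized gradient-RMS sharpness metric (per μm).
# Calibrated once on the synthetic generator's sharp vs. defocused populations
# (see docs/methods.md) and fixed here.
DEFAULT_FOCUS_CUTOFF_CELL = 0.45
DEFAULT_FOCUS_CUTOFF_PARTICLE = 1.2

#: 8-connectivity for component labelling (diagonal pixels stay connected).
_CONNECTIVITY = np.ones((3, 3), dtype=bool)

LABEL_EXCLUDED = "excluded_unfocused"
LABEL_NO_PARTICLE = "no_particle"
LABEL_BOUND = "bound"
LABEL_INTERNALIZED = "internalized"
CLASS_LABELS = (LABEL_EXCLUDED, LABEL_NO_PARTICLE, LABEL_BOUND, LABEL_INTERNALIZED)


@dataclass(frozen=True)
class CellSegmentation:
    mask: np.ndarray
    centroid: tuple[float, float]  # (x, y) μm
    radius: float  # μm, equivalent-circle radius


@dataclass(frozen=True)
class ParticleSegmentation:
    mask: np.ndarray
    centroid: tuple[float, float]  # (x, y) μm


@dataclass(frozen=True)
class FocusResult:
    passed: bool
    focus_cell: float
    focus_particle: float  # NaN when no particle is present


@dataclass(frozen=True)
class EventFeatures:
    """Per-event geometry and quality features."""

    event_id: str
    cell_centroid: tuple[float, float]
    particle_centroid: tuple[float, float] | None
    cell_radius: float
    centroid_distance: float | None
    focus_cell: float
    focus_particle: float
    score: float | None


@dataclass(frozen=True)
class Classification:
    label: str
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"label must be one of {CLASS_LABELS}")
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")


@dataclass(frozen=True)
class CohortSummary:
    """Gating-chain counts and the two headline percentages.

    ``pct_internalized`` is NaN (undefined, not zero) when no event is
    particle-positive.
    """

    n_total: int
    n_focused: int
    n_particle_positive: int
    n_internalized: int
    pct_interacting: float
    pct_internalized: float

    def __post_init__(self) -> None:
        chain = (self.n_total, self.n_focused, self.n_particle_positive, self.n_internalized)
        if any(b > a for a, b in zip(chain, chain[1:])):
            raise ValueError(f"gating-chain counts must be non-increasing, got {chain}")


def _to_physical(centroid_rc: tuple[float, float], pixel_size: float) -> tuple[float, float]:
    row, col = centroid_rc
    return ((col + 0.5) * pixel_size, (row + 0.5) * pixel_size)


def segment_cell(image: EventImage) -> CellSegmentation:
    """Segment the cell on the surface-marker channel.

    Otsu threshold, hole filling, largest connected component; the centroid is
    intensity-weighted and the radius is the equivalent-circle radius
    sqrt(area / π) in μm.
    """
    surface = image.surface
    if np.ptp(surface) == 0:
        raise ValueError("no cell detected: surface channel is constant")
    mask = surface > threshold_otsu(surface)
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask, structure=_CONNECTIVITY)
    if n == 0:
        raise ValueError("no cell detected: empty segmentation")
    sizes = ndimage.sum_labels(np.ones_like(surface), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    background = float(np.median(surface[~mask])) if (~mask).any() else 0.0
    support = ndimage.binary_dilation(mask, iterations=3)
    weights = np.clip(surface - background, 0.0, None) * support
    centroid_rc = ndimage.center_of_mass(weights)
    radius = math.sqrt(mask.sum() * image.pixel_size**2 / math.pi)
    return CellSegmentation(mask, _to_physical(centroid_rc, image.pixel_size), radius)


def segment_particle(image: EventImage, k: float = DEFAULT_DETECTION_K) -> ParticleSegmentation | None:
    """Segment the particle, or report it absent.

    The particle counts as absent when no pixel exceeds the channel background
    (median) by ``k`` times the noise level (scaled MAD).  With multiple
    components the largest wins and a warning is logged.
    """
    channel = image.particle
    background = float(np.median(channel))
    noise = 1.4826 * float(np.median(np.abs(channel - background)))
    floor = background + k * noise
    if not np.any(channel > floor):
        return None
    threshold = max(float(threshold_otsu(channel)), floor)
    mask = channel > threshold
    labels, n = ndimage.label(mask, structure=_CONNECTIVITY)
    if n == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(channel), labels, index=np.arange(1, n + 1))
    order = np.sort(sizes)
    if n > 1 and order[-2] >= max(4.0, 0.1 * order[-1]):
        logger.warning(
            "event %s: %d particle components detected; keeping the largest",
            image.event_id, n,
        )
    mask = labels == (1 + int(np.argmax(sizes)))
    # weighted centroid over the dilated mask: includes the symmetric blur
    # skirt the hard threshold truncates, removing a ~0.2 px centroid bias
    support = ndimage.binary_dilation(mask, iterations=3)
    weights = np.clip(channel - background, 0.0, None) * support
    centroid_rc = ndimage.center_of_mass(weights)
    return ParticleSegmentation(mask, _to_physical(centroid_rc, image.pixel_size))


def focus_metric(channel: np.ndarray, mask: np.ndarray, pixel_size: float) -> float:
    """Normalized gradient-RMS sharpness of ``channel`` restricted to ``mask``.

    Gradient RMS over the mask divided by the mean background-subtracted
    in-mask intensity, per μm; higher is sharper.
    """
    if not mask.any():
        return 0.0
    background = float(np.median(channel[~mask])) if (~mask).any() else 0.0
    signal = channel - background
    gy, gx = np.gradient(signal)
    grms = float(np.sqrt(np.mean((gx**2 + gy**2)[mask])))
    mean_intensity = float(signal[mask].mean())
    if mean_intensity <= 0:
        return 0.0
    return grms / mean_intensity / pixel_size


def focus_gate(
    image: EventImage,
    cell_mask: np.ndarray,
    particle_mask: np.ndarray | None = None,
    *,
    cell_cutoff: float = DEFAULT_FOCUS_CUTOFF_CELL,
    particle_cutoff: float = DEFAULT_FOCUS_CUTOFF_PARTICLE,
) -> FocusResult:
    """Shared-focal-plane gate.

    Passes when the cell sharpness metric reaches ``cell_cutoff`` and, if a
    particle is present, its sharpness reaches ``particle_cutoff``.  Events
    failing the gate are excluded from all downstream denominators except the
    total event count.
    """
    f_cell = focus_metric(image.surface, cell_mask, image.pixel_size)
    if particle_mask is None:
        return FocusResult(f_cell >= cell_cutoff, f_cell, float("nan"))
    f_particle = focus_metric(image.particle, particle_mask, image.pixel_size)
    return FocusResult(
        f_cell >= cell_cutoff and f_particle >= particle_cutoff, f_cell, f_particle
    )


def internalization_score(
    cell_radius: float,
    centroid_distance: float | None,
    epsilon: float = SCORE_EPSILON_UM,
    formula: str = "ratio",
) -> float:
    """Radius-corrected centroid-distance internalization score.

    ``formula="ratio"`` (default) gives the dimensionless s = R / max(d, ε)
    with ε a fixed one-pixel floor in μm; ``formula="depth"`` gives the
    alternative reading s = R - d in μm.  Both are monotonically
    non-increasing in d.
    """
    if centroid_distance is None:
        raise ValueError("score undefined without particle")
    if centroid_distance < 0:
        raise ValueError("centroid_distance must be non-negative")
    if not epsilon > 0:
        raise ValueError("epsilon must be positive")
    if formula == "ratio":
        return cell_radius / max(centroid_distance, epsilon)
    if formula == "depth":
        return cell_radius - centroid_distance
    raise ValueError(f"unknown score formula {formula!r}")


def classify_event(
    score: float | None,
    particle_present: bool,
    focus_passed: bool,
    threshold: float = DEFAULT_THRESHOLD,
) -> Classification:
    """Assign the event label; the focus gate precedes everything else."""
    if not focus_passed:
        label = LABEL_EXCLUDED
    elif not particle_present:
        label = LABEL_NO_PARTICLE
    elif score is None:
        raise ValueError("particle present but score missing")
    elif score >= threshold:
        label = LABEL_INTERNALIZED
    else:
        label = LABEL_BOUND
    return Classification(label, threshold)


def analyze_event(
    image: EventImage,
    *,
    threshold: float = DEFAULT_THRESHOLD,
    detection_k: float = DEFAULT_DETECTION_K,
    cell_cutoff: float = DEFAULT_FOCUS_CUTOFF_CELL,
    particle_cutoff: float = DEFAULT_FOCUS_CUTOFF_PARTICLE,
    epsilon: float = SCORE_EPSILON_UM,
    formula: str = "ratio",
) -> tuple[EventFeatures, Classification]:
    """Full single-event pipeline: segment, gate, score, classify."""
    cell = segment_cell(image)
    particle = segment_particle(image, k=detection_k)
    focus = focus_gate(
        image,
        cell.mask,
        particle.mask if particle else None,
        cell_cutoff=cell_cutoff,
        particle_cutoff=particle_cutoff,
    )
    distance = score = None
    if particle is not None:
        distance = math.hypot(
            particle.centroid[0] - cell.centroid[0],
            particle.centroid[1] - cell.centroid[1],
        )
        score = internalization_score(cell.radius, distance, epsilon, formula)
    classification = classify_event(score, particle is not None, focus.passed, threshold)
    features = EventFeatures(
        event_id=image.event_id,
        cell_centroid=cell.centroid,
        particle_centroid=particle.centroid if particle else None,
        cell_radius=cell.radius,
        centroid_distance=distance,
        focus_cell=focus.focus_cell,
        focus_particle=focus.focus_particle,
        score=score,
    )
    return features, classification


def analyze_cohort(images, **kwargs) -> pd.DataFrame:
    """Run :func:`analyze_event` on every image; one row per event."""
    rows = []
    for image in images:
        feat, cls = analyze_event(image, **kwargs)
        rows.append(
            {
                "event_id": feat.event_id,
                "cell_x": feat.cell_centroid[0],
                "cell_y": feat.cell_centroid[1],
                "cell_radius": feat.cell_radius,
                "particle_x": feat.particle_centroid[0] if feat.particle_centroid else np.nan,
                "particle_y": feat.particle_centroid[1] if feat.particle_centroid else np.nan,
                "centroid_distance": feat.centroid_distance
                if feat.centroid_distance is not None
                else np.nan,
                "focus_cell": feat.focus_cell,
                "focus_particle": feat.focus_particle,
                "score": feat.score if feat.score is not None else np.nan,
                "label": cls.label,
            }
        )
    return pd.DataFrame(rows)


def summarize_cohort(labels) -> CohortSummary:
    """Gating-chain counts and percentages from per-event labels."""
    labels = [lbl.label if isinstance(lbl, Classification) else str(lbl) for lbl in labels]
    if len(labels) == 0:
        raise ValueError("cannot summarize an empty cohort")
    unknown = set(labels) - set(CLASS_LABELS)
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}")
    n_total = len(labels)
    n_focused = n_total - labels.count(LABEL_EXCLUDED)
    n_internalized = labels.count(LABEL_INTERNALIZED)
    n_particle_positive = labels.count(LABEL_BOUND) + n_internalized
    pct_interacting = (
        100.0 * n_particle_positive / n_focused if n_focused else float("nan")
    )
    pct_internalized = (
        100.0 * n_internalized / n_particle_positive if n_particle_positive else float("nan")
    )
    return CohortSummary(
        n_total=n_total,
        n_focused=n_focused,
        n_particle_positive=n_particle_positive,
        n_internalized=n_internalized,
        pct_interacting=pct_interacting,
        pct_internalized=pct_internalized,
    )


def auc_time_course(times, values) -> float:
    """Trapezoidal area under a % internalized time course (units %·min)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.ndim != 1 or times.shape != values.shape:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if times.size < 2:
        raise ValueError("need at least two time points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(values, times))


def plot_score_histogram(scores, threshold: float = DEFAULT_THRESHOLD, path=None, bins=40):
    """Histogram of internalization scores with the bound/internalized split."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = np.asarray(scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(scores, bins=bins, color="0.4")
    ax.axvline(threshold, color="crimson", ls="--", label=f"τ = {threshold:g}")
    ax.axvspan(threshold, max(scores.max(initial=threshold), threshold) * 1.05,
               color="crimson", alpha=0.12)
    ax.set_xlabel("internalization score s")
    ax.set_ylabel("event count")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
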