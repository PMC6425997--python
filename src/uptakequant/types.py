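"""Shared array containers: single-cell event images and biosensor time-lapse stacks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed channel order of an imaging-flow-cytometry event image.
CHANNEL_NAMES = ("brightfield", "nucleus", "surface", "particle")


@dataclass
class EventImage:
    """One multi-channel single-cell event image with pixel calibration.

    Channels (equal shape, intensities in counts, all >= 0):

    ``brightfield``
        Transmitted-light image; the cell appears darker than the background.
    ``nucleus``
        Nuclear stain (DAPI-like).
    ``surface``
        Surface-marker stain covering the cell footprint (HLA-DR-like);
        used for cell segmentation.
    ``particle``
        Particle fluorescence (labelled bacterium or bead).
    """

    brightfield: np.ndarray
    nucleus: np.ndarray
    surface: np.ndarray
    particle: np.ndarray
    pixel_size: float  # μm per pixel
    event_id: str = ""

    def __post_init__(self) -> None:
        arrays = [np.asarray(getattr(self, name), dtype=float) for name in CHANNEL_NAMES]
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise ValueError(f"all channels must share one shape, got {sorted(shapes)}")
        if arrays[0].ndim != 2:
            raise ValueError("channels must be 2-D arrays")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        for name, arr in zip(CHANNEL_NAMES, arrays):
            if np.any(arr < 0):
                raise ValueError(f"negative intensities in {name!r} channel")
            setattr(self, name, arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.surface.shape

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNEL_NAMES:
            raise KeyError(f"unknown channel {name!r}")
        return getattr(self, name)

    def stack(self) -> np.ndarray:
        """Channels stacked along axis 0 in the fixed channel order."""
        return np.stack([getattr(self, name) for name in CHANNEL_NAMES])


@dataclass
class FretStack:
    """Time-lapse two-camera biosensor acquisition plus a particle channel.

    ``donor`` is the Cerulean3 (CFP) emission, ``acceptor`` the Venus (YFP)
    emission acquired simultaneously, ``particle`` the fluorescent particle
    channel.  All arrays are (T, H, W) in counts.
    """

    donor: np.ndarray
    acceptor: np.ndarray
    particle: np.ndarray
    pixel_size: float  # μm per pixel
    frame_interval: float = 1.0  # minutes between frames

    def __post_init__(self) -> None:
        for name in ("donor", "acceptor", "particle"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        shapes = {self.donor.shape, self.acceptor.shape, self.particle.shape}
        if len(shapes) != 1:
            raise ValueError("donor, acceptor and particle arrays must share one shape")
        if self.donor.ndim != 3 or self.donor.shape[0] < 1:
            raise ValueError("stacks must be (T, H, W) with T >= 1")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.donor.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.donor.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in minutes (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval
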