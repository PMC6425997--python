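"""Reading and writing of event TIFFs, biosensor stacks and result tables.

Events are stored one multi-page TIFF per event (one page per channel, fixed
order: brightfield, nucleus, surface, particle) next to a ground-truth CSV and
a JSON config capturing the generator parameters.  Biosensor stacks are one
multi-page float TIFF per channel plus a JSON metadata file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import EventGroundTruth, truth_table
from .types import CHANNEL_NAMES, EventImage, FretStack

CSV_KWARGS = dict(index=False, float_format="%.10g", lineterminator="\n")


def write_events(out_dir, images, truths=None, config: dict | None = None) -> Path:
    """Write events as multi-page TIFFs plus ground-truth CSV and config JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pixel_sizes = {img.pixel_size for img in images}
    if len(pixel_sizes) != 1:
        raise ValueError("all events in one directory must share a pixel size")
    for i, img in enumerate(images):
        name = img.event_id or f"event-{i:04d}"
        tifffile.imwrite(out / f"{name}.tif", img.stack().astype(np.float32),
                         photometric="minisblack")
    meta = {
        "pixel_size_um": images[0].pixel_size,
        "channel_order": list(CHANNEL_NAMES),
        "n_events": len(images),
    }
    if config:
        meta.update(config)
    (out / "config.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    if truths is not None:
        truth_table(list(truths)).to_csv(out / "ground_truth.csv", **CSV_KWARGS)
    return out


def read_events(in_dir) -> list[EventImage]:
    """Read a directory written by :func:`write_events` (or any conforming set)."""
    src = Path(in_dir)
    config = json.loads((src / "config.json").read_text())
    pixel_size = float(config["pixel_size_um"])
    images = []
    for path in sorted(src.glob("*.tif")):
        pages = tifffile.imread(path)
        if pages.ndim != 3 or pages.shape[0] != 4:
            raise ValueError(f"{path.name}: expected 4 channel pages, got shape {pages.shape}")
        images.append(
            EventImage(*[p.astype(float) for p in pages], pixel_size=pixel_size,
                       event_id=path.stem)
        )
    if not images:
        raise ValueError(f"no event TIFFs found in {src}")
    return images


def write_fret_stack(out_dir, stack: FretStack) -> Path:
    """Write donor/acceptor/particle TIFFs plus acquisition metadata JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("donor", "acceptor", "particle"):
        tifffile.imwrite(out / f"{name}.tif", getattr(stack, name).astype(np.float32),
                         photometric="minisblack")
    meta = {
        "pixel_size_um": stack.pixel_size,
        "frame_interval_min": stack.frame_interval,
        "n_frames": stack.n_frames,
        "channels": ["donor", "acceptor", "particle"],
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return out


def read_fret_stack(in_dir) -> FretStack:
    src = Path(in_dir)
    meta = json.loads((src / "metadata.json").read_text())
    arrays = {}
    for name in ("donor", "acceptor", "particle"):
        arr = tifffile.imread(src / f"{name}.tif").astype(float)
        arrays[name] = arr[None] if arr.ndim == 2 else arr
    return FretStack(
        pixel_size=float(meta["pixel_size_um"]),
        frame_interval=float(meta.get("frame_interval_min", 1.0)),
        **arrays,
    )


def write_ratio_map(path, rmap) -> Path:
    """Ratio map as 32-bit float TIFF with NaN preserved."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, rmap.ratio.astype(np.float32), photometric="minisblack")
    return path


def write_table(path, df: pd.DataFrame) -> Path:
    """Deterministic CSV output (UTF-8, LF endings, '.' decimal separator)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, **CSV_KWARGS)
    return path
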