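"""Standard-format I/O: multi-page TIFF image stacks, label maps, CSV tables.

Image stacks are written as one TIFF page per channel with a JSON
description carrying channel names, roles, probe names and the physical
pixel size, so a written stack reads back without external metadata. A run
configuration can override the stored channel naming and pixel size (a
logged warning notes the override).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import NUCLEUS_STAIN, TRANSCRIPT_PROBE
from .errors import FormatError
from .simulate import GroundTruthField, ImageStack

logger = logging.getLogger(__name__)

CELL_TABLE_SCHEMA = "ishquant.cell_table.v1"


def write_image_stack(stack: ImageStack, path) -> None:
    names = list(stack.channels)
    data = np.stack([stack.channels[n] for n in names]).astype(np.float32)
    description = json.dumps({
        "channels": names,
        "channel_roles": [stack.channel_roles[n] for n in names],
        "probe_names": [stack.probe_names.get(n, n) for n in names],
        "pixel_size_um": stack.pixel_size_um,
    })
    tifffile.imwrite(path, data, photometric="minisblack", description=description,
                     metadata=None)


def read_image_stack(path, channel_names: tuple[str, ...] = (),
                     nucleus_channel: str = "DAPI",
                     pixel_size_um: float | None = None) -> ImageStack:
    """Read a multi-page TIFF as an ImageStack.

    Channel names come from the embedded JSON description when present,
    else from ``channel_names`` (which must then match the page count).
    An explicit ``pixel_size_um`` wins over stored metadata with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"image file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description or ""
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"could not read TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 2D pages, got array of shape {data.shape}")

    meta = None
    if desc:
        try:
            parsed = json.loads(desc)
            if isinstance(parsed, dict) and "channels" in parsed:
                meta = parsed
        except (json.JSONDecodeError, TypeError):
            meta = None

    n_pages = data.shape[0]
    if channel_names:
        if len(channel_names) != n_pages:
            raise FormatError(
                f"{path}: {n_pages} TIFF pages but {len(channel_names)} configured channels"
            )
        names = list(channel_names)
        if meta and list(meta["channels"]) != names:
            logger.warning("%s: configured channel names override stored ones", path)
    elif meta:
        names = list(meta["channels"])
        if len(names) != n_pages:
            raise FormatError(
                f"{path}: metadata names {len(names)} channels but file has {n_pages} pages"
            )
    else:
        raise FormatError(f"{path}: no channel metadata and no configured channel names")

    if meta and not channel_names:
        roles = dict(zip(names, meta["channel_roles"]))
        probes = dict(zip(names, meta.get("probe_names", names)))
    else:
        roles = {n: (NUCLEUS_STAIN if n == nucleus_channel else TRANSCRIPT_PROBE)
                 for n in names}
        probes = {n: n for n in names}

    stored_px = meta.get("pixel_size_um") if meta else None
    if pixel_size_um is not None:
        if stored_px is not None and abs(stored_px - pixel_size_um) > 1e-9:
            logger.warning("%s: config pixel size %.4g um overrides stored %.4g um",
                           path, pixel_size_um, stored_px)
        px = float(pixel_size_um)
    elif stored_px is not None:
        px = float(stored_px)
    else:
        raise FormatError(f"{path}: pixel size neither stored nor configured")

    channels = {n: np.asarray(data[i], dtype=np.float32) for i, n in enumerate(names)}
    return ImageStack(channels=channels, pixel_size_um=px,
                      channel_roles=roles, probe_names=probes)


def write_label_map(labels: np.ndarray, path) -> None:
    if labels.max() > np.iinfo(np.uint16).max:
        raise FormatError(f"too many labels for 16-bit TIFF: {labels.max()}")
    tifffile.imwrite(path, labels.astype(np.uint16), photometric="minisblack")


def read_label_map(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_cell_table(df: pd.DataFrame, path) -> None:
    """CSV with a schema-version header comment line."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# {CELL_TABLE_SCHEMA}\n")
        df.to_csv(fh, index=False)


def read_cell_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cell table not found: {path}")
    return pd.read_csv(path, comment="#")


def write_ground_truth(gt: GroundTruthField, out_dir, prefix: str = "") -> None:
    out_dir = Path(out_dir)
    gt.cells_dataframe().to_csv(out_dir / f"{prefix}ground_truth_cells.csv", index=False)
    gt.dots_dataframe().to_csv(out_dir / f"{prefix}ground_truth_dots.csv", index=False)
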