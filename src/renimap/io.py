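"""Reading and writing the pipeline's on-disk formats.

Multichannel stacks travel as multi-page TIFFs with a JSON channel manifest;
label masks as integer TIFFs; cell and transcript tables as CSV; ground
truth and statistics as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from renimap.errors import ConfigError
from renimap.stack import ChannelStack

__all__ = [
    "read_stack", "write_stack", "read_label_mask", "write_label_mask",
    "read_cells", "write_cells", "read_transcripts", "write_transcripts",
]


def write_stack(stack: ChannelStack, tiff_path: str | Path, manifest_path: str | Path) -> None:
    """Write all channels (markers then blanks) as one multi-page TIFF plus a
    JSON manifest recording names, blank assignments, and pixel size."""
    names = list(stack.channels) + list(stack.blank_channels)
    pages = [stack.channels.get(n, stack.blank_channels.get(n)) for n in names]
    tifffile.imwrite(tiff_path, np.stack([p.astype(np.float32) for p in pages]))
    Path(manifest_path).write_text(json.dumps({
        "channels": list(stack.channels),
        "blank_channels": list(stack.blank_channels),
        "channel_to_blank": stack.channel_to_blank,
        "pixel_size_um": stack.pixel_size,
    }, indent=1))


def read_stack(tiff_path: str | Path, manifest_path: str | Path) -> ChannelStack:
    manifest = json.loads(Path(manifest_path).read_text())
    pages = tifffile.imread(tiff_path)
    names = manifest["channels"] + manifest["blank_channels"]
    if len(pages) != len(names):
        raise ConfigError(
            f"TIFF has {len(pages)} pages but manifest names {len(names)} channels")
    arrays = dict(zip(names, pages))
    return ChannelStack(
        channels={n: arrays[n].astype(float) for n in manifest["channels"]},
        blank_channels={n: arrays[n].astype(float) for n in manifest["blank_channels"]},
        pixel_size=manifest["pixel_size_um"],
        channel_to_blank=manifest["channel_to_blank"],
    )


def write_label_mask(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(mask).astype(np.int32))


def read_label_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int64)


def write_cells(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, index=False)


def read_cells(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_transcripts(transcripts: pd.DataFrame, path: str | Path) -> None:
    transcripts.to_csv(path, index=False)


def read_transcripts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("x", "y", "gene"):
        if col not in df.columns:
            raise ConfigError(f"transcript table missing column {col!r}")
    return df
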