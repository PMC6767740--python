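"""Tile <-> montage conversion and TIFF I/O.

Single-cell tiles are packed row-major into fixed 30 x 30 = 900-slot
montages, one montage per channel, written as single-page grayscale TIFFs
with a sidecar CSV manifest (`slot,event_id`) linking slots to events.
Destitching inverts stitching bit-exactly; padded trailing slots are never
returned.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Montage", "stitch", "destitch", "save_montage", "load_montage"]

DEFAULT_GRID = (30, 30)  # 900 tiles per montage


@dataclass
class Montage:
    """A tiled per-channel image with a row-major slot -> event manifest."""

    channel: str  # "BF" or "DF"
    grid: tuple[int, int]
    tile_shape: tuple[int, int]
    image: np.ndarray
    manifest: list[str]  # event_ids, slot order; len <= rows*cols

    def __post_init__(self) -> None:
        rows, cols = self.grid
        th, tw = self.tile_shape
        if len(self.manifest) > rows * cols:
            raise ValueError("manifest longer than grid capacity")
        if self.image.shape != (rows * th, cols * tw):
            raise ValueError(
                f"montage image shape {self.image.shape} != grid x tile "
                f"{(rows * th, cols * tw)}"
            )

    def slot_of(self, index: int) -> tuple[int, int]:
        """Row-major slot (row, col) of manifest entry ``index``."""
        return divmod(index, self.grid[1])


def _center_pad(tile: np.ndarray, tile_shape: tuple[int, int], pad_value: float) -> np.ndarray:
    th, tw = tile_shape
    h, w = tile.shape
    if h > th or w > tw:
        raise ValueError(f"tile of shape {tile.shape} exceeds tile_shape {tile_shape}")
    if (h, w) == (th, tw):
        return tile
    out = np.full((th, tw), pad_value, dtype=tile.dtype)
    y0, x0 = (th - h) // 2, (tw - w) // 2
    out[y0 : y0 + h, x0 : x0 + w] = tile
    return out


def stitch(
    tiles: list[np.ndarray],
    event_ids: list[str] | None = None,
    *,
    channel: str = "BF",
    tile_shape: tuple[int, int] | None = None,
    grid: tuple[int, int] = DEFAULT_GRID,
    pad_value: float = 0.0,
) -> list[Montage]:
    """Pack single-channel tiles into 900-slot montages, row-major.

    Tiles smaller than ``tile_shape`` are center-padded with ``pad_value``;
    larger tiles are rejected. The last montage's unused trailing slots are
    filled with ``pad_value``. Manifest order equals input order.
    """
    if not tiles:
        raise ValueError("no tiles to stitch")
    if event_ids is None:
        event_ids = [f"E{i:06d}" for i in range(len(tiles))]
    if len(event_ids) != len(tiles):
        raise ValueError("event_ids length must match tiles")
    if tile_shape is None:
        tile_shape = (
            max(t.shape[0] for t in tiles),
            max(t.shape[1] for t in tiles),
        )
    rows, cols = grid
    capacity = rows * cols
    th, tw = tile_shape
    dtype = np.result_type(*[t.dtype for t in tiles])

    montages: list[Montage] = []
    for start in range(0, len(tiles), capacity):
        chunk = tiles[start : start + capacity]
        ids = list(event_ids[start : start + capacity])
        image = np.full((rows * th, cols * tw), pad_value, dtype=dtype)
        for k, tile in enumerate(chunk):
            r, c = divmod(k, cols)
            image[r * th : (r + 1) * th, c * tw : (c + 1) * tw] = _center_pad(
                np.asarray(tile), tile_shape, pad_value
            )
        montages.append(
            Montage(
                channel=channel,
                grid=grid,
                tile_shape=tile_shape,
                image=image,
                manifest=ids,
            )
        )
    return montages


def destitch(montage: Montage) -> list[np.ndarray]:
    """Recover exactly ``len(manifest)`` tiles in manifest order."""
    if not montage.manifest:
        raise ValueError("montage has an empty manifest")
    rows, cols = montage.grid
    th, tw = montage.tile_shape
    tiles = []
    for k in range(len(montage.manifest)):
        r, c = divmod(k, cols)
        tiles.append(montage.image[r * th : (r + 1) * th, c * tw : (c + 1) * tw].copy())
    return tiles


def save_montage(montage: Montage, path: str | Path) -> Path:
    """Write a single-page grayscale TIFF plus a `slot,event_id` sidecar CSV.

    Float images in [0, 1] are stored losslessly as 16-bit; integer images
    keep their dtype.
    """
    path = Path(path)
    image = montage.image
    if np.issubdtype(image.dtype, np.floating):
        if image.min() < 0.0 or image.max() > 1.0:
            raise ValueError("float montage pixels must lie in [0, 1] for 16-bit storage")
        image = np.round(image * 65535.0).astype(np.uint16)
    tifffile.imwrite(
        path,
        image,
        metadata={
            "channel": montage.channel,
            "grid": list(montage.grid),
            "tile_shape": list(montage.tile_shape),
        },
    )
    sidecar = path.with_suffix(".csv")
    with open(sidecar, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slot", "event_id"])
        for slot, event_id in enumerate(montage.manifest):
            writer.writerow([slot, event_id])
    return path


def load_montage(
    path: str | Path,
    *,
    channel: str | None = None,
    tile_shape: tuple[int, int] | None = None,
    grid: tuple[int, int] = DEFAULT_GRID,
) -> Montage:
    """Read a montage TIFF and its sidecar manifest.

    16-bit images are rescaled back to float in [0, 1]. Metadata embedded at
    save time supplies channel/grid/tile geometry unless overridden.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        image = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if channel is None:
        channel = str(meta.get("channel", "BF"))
    if "grid" in meta:
        grid = tuple(meta["grid"])  # type: ignore[assignment]
    if tile_shape is None:
        if "tile_shape" not in meta:
            raise ValueError("tile_shape missing from both metadata and arguments")
        tile_shape = tuple(meta["tile_shape"])  # type: ignore[assignment]
    if image.dtype == np.uint16:
        image = image.astype(float) / 65535.0

    sidecar = path.with_suffix(".csv")
    if not sidecar.exists():
        raise FileNotFoundError(f"manifest sidecar not found: {sidecar}")
    manifest: list[str] = []
    with open(sidecar, newline="") as fh:
        for row in csv.DictReader(fh):
            manifest.append(row["event_id"])
    return Montage(
        channel=channel, grid=grid, tile_shape=tile_shape, image=image, manifest=manifest
    )
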