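"""Tiled TIFF mosaics and the experiment manifest.

The microscope scans the chip as a grid of abutting tiles (10 x 10 by
default), one uncompressed 16-bit grayscale TIFF per tile and channel.
The manifest (``manifest.yaml``) records the chip geometry, phase
metadata, and every tile's (phase, channel, row, col) -> file mapping.
Tiles abut exactly -- there is no stage overlap to stitch -- so assembly
is lossless placement and round trips are pixel-identical.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = ["Mosaic", "TileError", "read_tile_grid", "write_tile_grid",
           "load_manifest", "save_manifest"]


class TileError(ValueError):
    """A tile set is incomplete or inconsistent with its manifest."""


@dataclass
class Mosaic:
    """A single-channel chip-frame image assembled from tiles."""

    data: np.ndarray
    pixel_size_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def load_manifest(manifest_path) -> dict:
    path = Path(manifest_path)
    if not path.exists():
        raise TileError(f"manifest not found: {path}")
    with open(path) as fh:
        manifest = yaml.safe_load(fh) or {}
    manifest.setdefault("tiles", [])
    return manifest


def save_manifest(manifest: dict, manifest_path) -> None:
    """Write the manifest atomically (tmp file + rename)."""
    path = Path(manifest_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".yaml")
    try:
        with os.fdopen(fd, "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def tile_name(phase: str, channel: str, row: int, col: int) -> str:
    return f"{phase}_{channel}_r{row}_c{col}.tif"


def write_tile_grid(mosaic: Mosaic, manifest_path, phase: str, channel: str,
                    tile_grid: tuple[int, int] | None = None) -> list[str]:
    """Split a mosaic into uncompressed 16-bit TIFF tiles next to the
    manifest and record them in it.  Mosaic dimensions must divide the
    tile grid exactly."""
    path = Path(manifest_path)
    manifest = load_manifest(path) if path.exists() else {"tiles": []}
    if tile_grid is None:
        tile_grid = tuple(manifest.get("tile_grid") or (1, 1))
    gr, gc = tile_grid
    ny, nx = mosaic.data.shape
    if ny % gr or nx % gc:
        raise TileError(
            f"mosaic shape {mosaic.data.shape} not divisible by tile grid {tile_grid}")
    th, tw = ny // gr, nx // gc
    data = np.ascontiguousarray(mosaic.data, dtype=np.uint16)

    manifest["tile_grid"] = [gr, gc]
    manifest["tile_shape"] = [th, tw]
    manifest.setdefault("pixel_size_um", mosaic.pixel_size_um)
    tiles = [t for t in manifest["tiles"]
             if not (t["phase"] == phase and t["channel"] == channel)]
    written = []
    for r in range(gr):
        for c in range(gc):
            fname = tile_name(phase, channel, r, c)
            tifffile.imwrite(path.parent / fname,
                             data[r * th:(r + 1) * th, c * tw:(c + 1) * tw],
                             compression=None)
            tiles.append({"phase": phase, "channel": channel,
                          "row": r, "col": c, "file": fname})
            written.append(fname)
    manifest["tiles"] = tiles
    save_manifest(manifest, path)
    return written


def read_tile_grid(manifest_path, phase: str, channel: str) -> Mosaic:
    """Assemble the mosaic for one phase/channel from its tiles.

    Every (row, col) position of the manifest's tile grid must be listed
    exactly once; tiles are placed abutting with no overlap.
    """
    path = Path(manifest_path)
    manifest = load_manifest(path)
    entries = [t for t in manifest["tiles"]
               if t["phase"] == phase and t["channel"] == channel]
    if not entries:
        raise TileError(f"no tiles for phase={phase!r} channel={channel!r}")
    gr, gc = manifest.get("tile_grid", [1, 1])
    seen = {}
    for t in entries:
        key = (t["row"], t["col"])
        if key in seen:
            raise TileError(f"tile listed twice: {t['file']}")
        seen[key] = t
    missing = [(r, c) for r in range(gr) for c in range(gc) if (r, c) not in seen]
    if missing:
        raise TileError(f"missing tiles for phase={phase!r} channel={channel!r}: "
                        f"{missing[:5]}{'...' if len(missing) > 5 else ''}")

    first = tifffile.imread(path.parent / seen[(0, 0)]["file"])
    th, tw = first.shape
    out = np.zeros((gr * th, gc * tw), dtype=np.uint16)
    for (r, c), t in seen.items():
        tile = tifffile.imread(path.parent / t["file"])
        if tile.shape != (th, tw):
            raise TileError(
                f"tile {t['file']} has shape {tile.shape}, expected {(th, tw)}")
        out[r * th:(r + 1) * th, c * tw:(c + 1) * tw] = tile
    return Mosaic(data=out,
                  pixel_size_um=float(manifest.get("pixel_size_um", 1.0)),
                  provenance={"manifest": str(path), "phase": phase,
                              "channel": channel, "n_tiles": len(entries)})
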