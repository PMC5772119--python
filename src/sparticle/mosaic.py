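"""Tile-grid assembly into one calibrated whole-slide mosaic.

Tiles acquired by a motorized stage in meander order are placed at their
nominal grid offsets (no feature registration — stage geometry is trusted)
after a per-tile multiplicative brightness normalization that corrects for
light-source fluctuation using the modal background grey value of each tile.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .synth import DEFAULT_PIXEL_SIZE_UM, grid_footprint, meander_order

__all__ = [
    "Tile", "Mosaic", "estimate_background", "normalize_tiles", "stitch",
    "read_tiles", "save_mosaic", "load_mosaic", "grid_footprint",
]


@dataclass
class Tile:
    """One grayscale tile with its grid position and calibration."""

    image: np.ndarray
    row: int
    col: int
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.image.ndim != 2:
            raise ValueError("tiles must be single-channel 2-D images")


@dataclass
class Mosaic:
    """Assembled whole-slide image with provenance of its construction."""

    image: np.ndarray
    pixel_size_um: float
    provenance: dict = field(default_factory=dict)


def estimate_background(tile) -> int:
    """Modal grey value of the tile histogram (ties break to the lowest mode).

    In a well-sampled slide most pixels are empty background, so the
    histogram mode is a robust estimate of the illumination level.
    """
    arr = tile.image if isinstance(tile, Tile) else np.asarray(tile)
    if arr.size == 0:
        raise ValueError("cannot estimate background of an empty tile")
    vals = np.rint(arr).astype(np.int64).ravel()
    if vals.min() < 0:
        vals = vals - vals.min()  # bincount needs non-negative; mode unaffected order
    counts = np.bincount(vals)
    return int(np.argmax(counts))


def normalize_tiles(tiles: list[Tile], reference="median-of-backgrounds"
                    ) -> tuple[list[Tile], dict]:
    """Scale each tile by reference / background(tile), clipped to bit depth.

    ``reference`` is either a grey value or the string
    ``"median-of-backgrounds"`` (the median modal background over all tiles).
    Returns the normalized tiles and the applied gain per (row, col).
    Normalization is multiplicative: illumination fluctuation acts as a gain,
    and a gain preserves zero.
    """
    if not tiles:
        raise ValueError("need at least one tile")
    backgrounds = [estimate_background(t) for t in tiles]
    if any(b == 0 for b in backgrounds):
        raise ValueError("tile background estimate of 0; cannot normalize")
    if isinstance(reference, str):
        if reference != "median-of-backgrounds":
            raise ValueError(f"unknown reference {reference!r}")
        ref = float(np.median(backgrounds))
    else:
        ref = float(reference)

    out, gains = [], {}
    for t, bg in zip(tiles, backgrounds):
        gain = ref / bg
        dtype = t.image.dtype
        vmax = np.iinfo(dtype).max if np.issubdtype(dtype, np.integer) else None
        scaled = t.image.astype(np.float64) * gain
        if vmax is not None:
            scaled = np.clip(np.rint(scaled), 0, vmax).astype(dtype)
        out.append(Tile(scaled, t.row, t.col, t.pixel_size_um))
        gains[(t.row, t.col)] = gain
    return out, gains


def stitch(tiles: list[Tile], rows: int, cols: int, overlap_fraction: float,
           order: str = "meander") -> Mosaic:
    """Place tiles at nominal offsets; in overlaps the later-placed tile wins.

    The placement step is ``round(tile_size * (1 - overlap_fraction))`` and
    the output dimensions follow the closed-form grid footprint.  Tiles may
    be passed in any order — placement is by (row, col) metadata — so the
    result is permutation-safe.
    """
    if order != "meander":
        raise ValueError("only meander placement order is supported")
    by_pos = {(t.row, t.col): t for t in tiles}
    if len(by_pos) != len(tiles):
        raise ValueError("duplicate tile grid positions")
    for pos in meander_order(rows, cols):
        if pos not in by_pos:
            raise ValueError(f"missing tile for grid position {pos}")
    shapes = {t.image.shape for t in tiles}
    if len(shapes) != 1:
        raise ValueError("all tiles in a grid must share dimensions")
    th, tw = shapes.pop()
    step_r = int(round(th * (1.0 - overlap_fraction)))
    step_c = int(round(tw * (1.0 - overlap_fraction)))
    H = grid_footprint(th, rows, overlap_fraction)
    W = grid_footprint(tw, cols, overlap_fraction)

    canvas = np.zeros((H, W), dtype=tiles[0].image.dtype)
    for r, c in meander_order(rows, cols):
        t = by_pos[(r, c)]
        y, x = r * step_r, c * step_c
        canvas[y:y + th, x:x + tw] = t.image
    return Mosaic(
        canvas,
        tiles[0].pixel_size_um,
        provenance={
            "rows": rows, "cols": cols, "overlap_fraction": overlap_fraction,
            "tile_shape": (th, tw),
        },
    )


_PATTERN = re.compile(r"r(\d+)_c(\d+)\.tiff?$")


def read_tiles(directory, pixel_size_um: float | None = None) -> list[Tile]:
    """Load tiles from a directory: a ``manifest.json`` if present, otherwise
    any files matching the ``r{row}_c{col}.tif`` pattern."""
    d = Path(directory)
    manifest = d / "manifest.json"
    tiles = []
    if manifest.exists():
        with open(manifest) as fh:
            meta = json.load(fh)
        px = pixel_size_um or meta.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM)
        for entry in meta["tiles"]:
            img = tifffile.imread(d / entry["filename"])
            tiles.append(Tile(img, entry["row"], entry["col"], px))
    else:
        px = pixel_size_um or DEFAULT_PIXEL_SIZE_UM
        for f in sorted(d.iterdir()):
            m = _PATTERN.match(f.name)
            if m:
                tiles.append(Tile(tifffile.imread(f), int(m.group(1)),
                                  int(m.group(2)), px))
    if not tiles:
        raise ValueError(f"no tiles found in {d}")
    return tiles


def save_mosaic(mosaic: Mosaic, path) -> None:
    """Write the mosaic as TIFF with the pixel size in the resolution tags
    (pixels per centimeter)."""
    ppcm = 1e4 / mosaic.pixel_size_um
    tifffile.imwrite(path, mosaic.image, resolution=(ppcm, ppcm),
                     resolutionunit="CENTIMETER")


def load_mosaic(path, pixel_size_um: float | None = None) -> Mosaic:
    """Read a mosaic TIFF; pixel size from the resolution tags unless given."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        img = page.asarray()
        px = pixel_size_um
        if px is None:
            try:
                xres = page.tags["XResolution"].value
                unit = page.tags["ResolutionUnit"].value
                per_unit = xres[0] / xres[1]
                unit_um = {2: 25400.0, 3: 1e4}.get(int(unit))
                if unit_um and per_unit > 0:
                    px = unit_um / per_unit
            except (KeyError, ZeroDivisionError):
                px = None
        if px is None:
            px = DEFAULT_PIXEL_SIZE_UM
    return Mosaic(img, float(px))
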