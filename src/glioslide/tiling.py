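"""Slide tiling: overlapping tile grids, per-tile region fractions, and filters.

An annotated slide is converted into a "tile sheet": one row per tile with
its coordinates and the fraction of the tile area covered by each segmented
region class (necrosis, preexisting brain parenchyma, bleeding, scar).
Tumor is never an explicit mask — it is the complement of the annotated
classes.  Tiles containing both tumor and necrosis are flagged perinecrotic;
tiles containing both tumor and preexisting tissue are flagged as
infiltration zone.

Coordinates are 0-based with x = column, y = row; a tile occupies the
half-open pixel box [x0, x0+size) x [y0, y0+size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Region classes carried by every tile record.  ``tumor`` is the complement.
REGION_CLASSES = ("tumor", "necrosis", "preexisting", "bleeding", "scar")

#: Mask classes a SlidePackage may carry (everything except the complement).
MASK_CLASSES = ("necrosis", "preexisting", "bleeding", "scar")

#: Minimum fraction of a class for "contains both" context flags.  A strict
#: > 0 rule would fire on single-pixel mask noise.
CONTEXT_EPS = 0.05

SHEET_COLUMNS = [
    "slide_id", "patient_id", "x0", "y0", "size_px",
    "frac_tumor", "frac_necrosis", "frac_preexisting", "frac_bleeding",
    "frac_scar", "perinecrotic", "infiltration",
]


@dataclass
class SlidePackage:
    """An image plus its region segmentation masks.

    Parameters
    ----------
    image : ndarray, shape (H, W, 3), uint8
        RGB slide image at the working resolution.
    masks : dict str -> ndarray of bool, shape (H, W)
        Region masks keyed by class name (subset of :data:`MASK_CLASSES`).
        Masks must be mutually disjoint; missing classes count as empty.
    microns_per_px : float
        Physical pixel size of the working level.
    """

    image: np.ndarray
    masks: dict
    microns_per_px: float
    slide_id: str = "slide"
    patient_id: str = "patient"

    def __post_init__(self):
        h, w = self.image.shape[:2]
        for name, m in self.masks.items():
            if name not in MASK_CLASSES:
                raise ValueError(f"unknown region class {name!r}")
            if m.shape != (h, w):
                raise ValueError(
                    f"mask {name!r} shape {m.shape} does not match image "
                    f"({h}, {w}) for slide {self.slide_id!r}")
        if self.microns_per_px <= 0:
            raise ValueError("microns_per_px must be positive")

    @property
    def shape(self):
        return self.image.shape[:2]

    def mask(self, name: str) -> np.ndarray:
        """Mask for ``name``, or an all-False array if absent."""
        m = self.masks.get(name)
        if m is None:
            return np.zeros(self.shape, bool)
        return m.astype(bool)

    def tumor_mask(self) -> np.ndarray:
        """Complement of all annotated region masks."""
        out = np.ones(self.shape, bool)
        for name in MASK_CLASSES:
            out &= ~self.mask(name)
        return out


@dataclass
class TileRecord:
    """One tile of a slide with region bookkeeping."""

    slide_id: str
    patient_id: str
    x0: int
    y0: int
    size_px: int
    frac: dict = field(default_factory=dict)
    perinecrotic: bool = False
    infiltration: bool = False

    def __post_init__(self):
        if self.frac:
            total = sum(self.frac.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"tile fractions sum to {total!r}, expected 1")


def grid_positions(dim_px: int, tile_px: int, overlap_px: int = 0) -> np.ndarray:
    """1-D tile start positions covering ``dim_px`` pixels.

    Positions advance with stride ``tile_px - overlap_px``; a final tile is
    anchored at ``dim_px - tile_px`` so the whole extent is covered even when
    the stride does not divide it evenly.

    Returns an int array of sorted, deduplicated start positions.  If the
    dimension is smaller than the tile a warning is issued and the result is
    empty.
    """
    if tile_px < 1:
        raise ValueError("tile_px must be >= 1")
    if not (0 <= overlap_px < tile_px):
        raise ValueError("overlap_px must satisfy 0 <= overlap < tile_px")
    if dim_px < tile_px:
        warnings.warn(
            f"dimension {dim_px} smaller than tile {tile_px}; no tiles",
            stacklevel=2)
        return np.array([], dtype=np.int64)
    stride = tile_px - overlap_px
    pos = np.arange(0, dim_px - tile_px + 1, stride, dtype=np.int64)
    last = dim_px - tile_px
    if pos[-1] != last:
        pos = np.append(pos, last)
    return np.unique(pos)


def _window_sums(mask: np.ndarray, xs, ys, size: int) -> np.ndarray:
    """Pixel counts of ``mask`` in every (y, x) tile window, via integral image."""
    ii = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), np.int64)
    np.cumsum(np.cumsum(mask, axis=0), axis=1, out=ii[1:, 1:])
    ys = np.asarray(ys)[:, None]
    xs = np.asarray(xs)[None, :]
    return (ii[ys + size, xs + size] - ii[ys, xs + size]
            - ii[ys + size, xs] + ii[ys, xs])


def make_tilesheet(slide: SlidePackage, tile_px: int, overlap_px: int = 0,
                   context_eps: float = CONTEXT_EPS) -> list[TileRecord]:
    """Tile a slide and compute per-tile region fractions and context flags.

    For every tile, ``frac[c]`` is the fraction of tile pixels covered by the
    mask of class ``c``; ``frac["tumor"]`` is one minus the sum of the
    others.  A tile is perinecrotic when it contains more than ``context_eps``
    of both tumor and necrosis, and infiltration-zone when it contains both
    tumor and preexisting tissue.
    """
    h, w = slide.shape
    xs = grid_positions(w, tile_px, overlap_px)
    ys = grid_positions(h, tile_px, overlap_px)
    area = float(tile_px * tile_px)
    counts = {c: _window_sums(slide.mask(c), xs, ys, tile_px)
              for c in MASK_CLASSES}
    records = []
    for i, y0 in enumerate(ys):
        for j, x0 in enumerate(xs):
            frac = {c: counts[c][i, j] / area for c in MASK_CLASSES}
            frac["tumor"] = 1.0 - sum(frac.values())
            tum = frac["tumor"] > context_eps
            records.append(TileRecord(
                slide_id=slide.slide_id, patient_id=slide.patient_id,
                x0=int(x0), y0=int(y0), size_px=tile_px, frac=frac,
                perinecrotic=bool(tum and frac["necrosis"] > context_eps),
                infiltration=bool(tum and frac["preexisting"] > context_eps),
            ))
    return records


def filter_and_exclude(sheet: list[TileRecord], min_tumor_frac: float = 0.5,
                       min_tiles_per_patient: int = 50):
    """Keep tiles with tumor fraction strictly above threshold, then drop
    patients whose kept-tile count falls below ``min_tiles_per_patient``.

    Returns ``(kept_records, excluded_patient_ids)``; exclusion removes every
    tile of the affected patient.
    """
    kept = [t for t in sheet if t.frac["tumor"] > min_tumor_frac]
    counts: dict[str, int] = {}
    for t in kept:
        counts[t.patient_id] = counts.get(t.patient_id, 0) + 1
    excluded = sorted(p for p, n in counts.items() if n < min_tiles_per_patient)
    excluded_set = set(excluded)
    kept = [t for t in kept if t.patient_id not in excluded_set]
    return kept, excluded


def sheet_to_frame(sheet: list[TileRecord]) -> pd.DataFrame:
    rows = [{
        "slide_id": t.slide_id, "patient_id": t.patient_id,
        "x0": t.x0, "y0": t.y0, "size_px": t.size_px,
        **{f"frac_{c}": t.frac[c] for c in REGION_CLASSES},
        "perinecrotic": t.perinecrotic, "infiltration": t.infiltration,
    } for t in sheet]
    return pd.DataFrame(rows, columns=SHEET_COLUMNS)


def frame_to_sheet(df: pd.DataFrame) -> list[TileRecord]:
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tile sheet is missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(TileRecord(
            slide_id=str(row.slide_id), patient_id=str(row.patient_id),
            x0=int(row.x0), y0=int(row.y0), size_px=int(row.size_px),
            frac={c: float(getattr(row, f"frac_{c}")) for c in REGION_CLASSES},
            perinecrotic=bool(row.perinecrotic),
            infiltration=bool(row.infiltration),
        ))
    return out


def write_tilesheet(sheet: list[TileRecord], path) -> None:
    """Write a tile sheet CSV.  Fractions round-trip exactly (shortest repr)."""
    sheet_to_frame(sheet).to_csv(path, index=False)


def read_tilesheet(path) -> list[TileRecord]:
    """Read a tile sheet CSV written by :func:`write_tilesheet`."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - passthrough
        raise ValueError(f"malformed tile sheet CSV {path}: {exc}") from exc
    return frame_to_sheet(df)


def rasterize_polygons(polygons, shape) -> np.ndarray:
    """Rasterize a list of polygons (each a sequence of (x, y) vertices in
    pixel coordinates) into a boolean mask — the plain-JSON stand-in for a
    vendor annotation export."""
    from skimage.draw import polygon as _poly

    mask = np.zeros(shape, bool)
    for verts in polygons:
        v = np.asarray(verts, float)
        rr, cc = _poly(v[:, 1], v[:, 0], shape=shape)
        mask[rr, cc] = True
    return mask
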