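"""Microenvironment quantification: nuclei, densities, stained areas.

A deliberately small, reproducible detector: the RGB image is transformed
to the stain-deconvolved hematoxylin channel, smoothed, thresholded, and
connected components within an area window become cell records with
centroid, area, perimeter and circularity (4*pi*area / perimeter^2, clipped
to 1; the perimeter is the Crofton 4-direction estimate of the component
boundary length, which converges to the true contour length and keeps the
circularity of rasterized disks near 1).  On top of that sit per-region summaries: cellularity and median
circularity per mm^2, marker point densities, and stained-area fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import rgb2hed
from skimage.measure import label as cc_label
from skimage.measure import regionprops


@dataclass
class DetectorParams:
    """Nucleus detector settings (physical units, resolution-independent)."""

    smooth_sigma_um: float = 0.7
    hematoxylin_threshold: float = 0.06
    min_area_um2: float = 8.0
    max_area_um2: float = 850.0


@dataclass
class CellRecord:
    x: float
    y: float
    area_px: float
    perimeter_px: float
    circularity: float


def detect_nuclei(image: np.ndarray, microns_per_px: float,
                  params: DetectorParams | None = None) -> pd.DataFrame:
    """Detect nuclei on an H&E-like RGB image.

    Returns a DataFrame with columns ``x``, ``y`` (centroid, pixels),
    ``area_px``, ``perimeter_px``, ``circularity``.  Deterministic for
    fixed parameters.
    """
    if microns_per_px is None or microns_per_px <= 0:
        raise ValueError("microns_per_px must be a positive number")
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image")
    params = params or DetectorParams()
    hed = rgb2hed(image / 255.0 if image.dtype == np.uint8 else image)
    h = ndimage.gaussian_filter(hed[..., 0],
                                params.smooth_sigma_um / microns_per_px)
    binary = h > params.hematoxylin_threshold
    lab = cc_label(binary, connectivity=2)
    min_area_px = params.min_area_um2 / microns_per_px ** 2
    max_area_px = params.max_area_um2 / microns_per_px ** 2
    rows = []
    for rp in regionprops(lab):
        if not (min_area_px <= rp.area <= max_area_px):
            continue
        per = max(rp.perimeter_crofton, 1e-9)
        circ = min(4.0 * np.pi * rp.area / per ** 2, 1.0)
        cy, cx = rp.centroid
        rows.append((cx, cy, float(rp.area), float(per), float(circ)))
    return pd.DataFrame(rows, columns=["x", "y", "area_px", "perimeter_px",
                                       "circularity"])


def _mask_area_mm2(mask: np.ndarray, microns_per_px: float) -> float:
    return float(mask.sum()) * (microns_per_px / 1000.0) ** 2


def _points_in_mask(x, y, mask) -> int:
    xi = np.asarray(x, float).astype(int)
    yi = np.asarray(y, float).astype(int)
    ok = (xi >= 0) & (xi < mask.shape[1]) & (yi >= 0) & (yi < mask.shape[0])
    return int(mask[yi[ok], xi[ok]].sum())


def cellularity(cells: pd.DataFrame, region_mask: np.ndarray,
                microns_per_px: float):
    """Nucleus density (per mm^2) and median circularity within a region."""
    area = _mask_area_mm2(region_mask, microns_per_px)
    if area <= 0:
        raise ValueError("empty region mask")
    inside = np.zeros(len(cells), bool)
    if len(cells):
        xi = cells["x"].to_numpy().astype(int)
        yi = cells["y"].to_numpy().astype(int)
        ok = (xi >= 0) & (xi < region_mask.shape[1]) & \
             (yi >= 0) & (yi < region_mask.shape[0])
        inside[ok] = region_mask[yi[ok], xi[ok]]
    density = float(inside.sum()) / area
    med_circ = float(cells.loc[inside, "circularity"].median()) if inside.any() \
        else float("nan")
    return density, med_circ


def marker_density(points: pd.DataFrame, region_mask: np.ndarray,
                   microns_per_px: float) -> float:
    """Positive-cell density per mm^2: points inside the mask / mask area."""
    area = _mask_area_mm2(region_mask, microns_per_px)
    if area <= 0:
        raise ValueError("empty region mask")
    if len(points) == 0:
        return 0.0
    return _points_in_mask(points["x_px"], points["y_px"], region_mask) / area


def stained_area_fraction(stain_mask: np.ndarray,
                          region_mask: np.ndarray) -> float:
    """Stained-area percentage of a region: 100 * |stain & region| / |region|."""
    if stain_mask.shape != region_mask.shape:
        raise ValueError("stain and region masks must share a shape")
    denom = int(region_mask.sum())
    if denom == 0:
        raise ValueError("empty region mask")
    return 100.0 * int((stain_mask & region_mask).sum()) / denom


def region_table(slide, regions: dict, cells: pd.DataFrame | None = None,
                 markers: dict | None = None,
                 params: DetectorParams | None = None) -> pd.DataFrame:
    """One summary row per region of a slide.

    ``regions`` maps label -> boolean mask.  ``markers`` maps marker name
    to either a point DataFrame (columns ``x_px``, ``y_px``) or a boolean
    stained-area mask.  ``cells`` defaults to running the detector on the
    slide image.  Output columns: region, area_mm2, cellularity_per_mm2,
    median_circularity, then ``density_<marker>`` or ``area_pct_<marker>``.
    """
    if not regions:
        raise ValueError("no regions given")
    if cells is None:
        cells = detect_nuclei(slide.image, slide.microns_per_px, params)
    rows = []
    for name, mask in regions.items():
        if not mask.any():
            continue
        dens, circ = cellularity(cells, mask, slide.microns_per_px)
        row = {"slide_id": slide.slide_id, "region": name,
               "area_mm2": _mask_area_mm2(mask, slide.microns_per_px),
               "cellularity_per_mm2": dens, "median_circularity": circ}
        for mk, payload in (markers or {}).items():
            if isinstance(payload, pd.DataFrame):
                row[f"density_{mk}"] = marker_density(
                    payload, mask, slide.microns_per_px)
            else:
                row[f"area_pct_{mk}"] = stained_area_fraction(
                    np.asarray(payload, bool), mask)
        rows.append(row)
    return pd.DataFrame(rows)
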