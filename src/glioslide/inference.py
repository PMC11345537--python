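"""Tile prediction, cohort z-scoring, patient-level calls, and heatmaps.

Predictions live in tidy DataFrames: one row per tile with the tile key
columns (``slide_id``, ``patient_id``, ``x0``, ``y0``, ``size_px``) plus
``ts_classical``, ``ts_mesenchymal``, ``ts_proneural`` for the subtype head
and ``rs_raw`` / ``rs_z`` for the risk head.  Patient-level risk calls
follow the study's rules exactly: tiles with z-scored risk strictly above 1
are high-risk tiles, and a patient is called high-risk when at least 25% of
their tiles are high-risk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .augment import center_crop
from .synthcohort import SUBTYPES
from .tiling import SlidePackage, grid_positions

TS_COLS = ["ts_classical", "ts_mesenchymal", "ts_proneural"]

#: a high-risk tile has z-scored risk strictly above this
HIGH_RISK_Z = 1.0
#: a patient is high-risk when the high-risk tile fraction reaches this
HIGH_RISK_TILE_CUTOFF = 0.25
#: survival misclassification bounds (years)
MISCLASS_HIGH_SURV = 1.5   # high-risk but survived > 18 months
MISCLASS_LOW_SURV = 1.0    # low-risk but survived < 12 months
NEAR_CORRECT_MARGIN = 0.01


def _tile_windows(sheet, slides, crop_px):
    imgs = []
    for t in sheet:
        slide = slides.get(t.slide_id)
        if slide is None:
            raise KeyError(f"no slide image for tile of slide {t.slide_id!r}")
        win = slide.image[t.y0:t.y0 + t.size_px, t.x0:t.x0 + t.size_px]
        imgs.append(center_crop(win, crop_px) if crop_px else win)
    return np.stack(imgs)


def predict_tiles(model, sheet, slides: dict, crop_px: int | None = None,
                  batch: int = 256) -> pd.DataFrame:
    """Score every tile of a sheet with one model (center crop, no
    augmentation); deterministic given the model.

    ``slides`` maps slide_id -> :class:`SlidePackage`.  Returns a DataFrame
    with tile keys plus the head's score columns.
    """
    crop_px = crop_px or getattr(model.spec, "input_px", None)
    rows = {
        "slide_id": [t.slide_id for t in sheet],
        "patient_id": [t.patient_id for t in sheet],
        "x0": [t.x0 for t in sheet], "y0": [t.y0 for t in sheet],
        "size_px": [t.size_px for t in sheet],
    }
    preds = []
    for i in range(0, len(sheet), batch):
        x = _tile_windows(sheet[i:i + batch], slides, crop_px)
        preds.append(model.predict(x))
    df = pd.DataFrame(rows)
    if not sheet:
        return df
    p = np.concatenate(preds)
    if model.head_kind == "ts":
        for j, c in enumerate(TS_COLS):
            df[c] = p[:, j]
    else:
        df["rs_raw"] = p
    return df


TILE_KEYS = ["slide_id", "patient_id", "x0", "y0", "size_px"]


def merge_predictions(rs_df: pd.DataFrame, ts_df: pd.DataFrame) -> pd.DataFrame:
    """Join risk and subtype predictions on the tile key columns."""
    return rs_df.merge(ts_df, on=TILE_KEYS, validate="one_to_one")


def zscore_scores(records: pd.DataFrame,
                  scope: str = "per_fold_then_concat") -> pd.DataFrame:
    """Standardize raw risk scores to ``rs_z`` (population SD).

    ``scope="per_fold_then_concat"`` standardizes within each value of the
    ``fold`` column before concatenation (validation-fold predictions keep
    no cross-fold offsets); ``scope="global"`` standardizes over all rows.
    """
    if scope not in ("per_fold_then_concat", "global"):
        raise ValueError(f"unknown scope {scope!r}")
    df = records.copy()

    def _z(x):
        x = np.asarray(x, float)
        if len(np.unique(x)) < 2:
            raise ValueError("zero variance in rs_raw within scope")
        return (x - x.mean()) / x.std()

    if scope == "global" or "fold" not in df.columns:
        df["rs_z"] = _z(df["rs_raw"])
    else:
        df["rs_z"] = (df.groupby("fold")["rs_raw"]
                        .transform(lambda s: _z(s.to_numpy())))
    return df


def aggregate_patient(records: pd.DataFrame,
                      clinical: pd.DataFrame | None = None,
                      cutoff: float = HIGH_RISK_TILE_CUTOFF) -> pd.DataFrame:
    """Patient-level risk calls from tile-level z-scored risk.

    ``mean_rs_z`` is the arithmetic mean; ``high_frac`` is the fraction of
    tiles with ``rs_z`` strictly above 1; ``risk_group`` is ``"high"`` when
    ``high_frac >= cutoff`` (boundary inclusive).
    """
    g = records.groupby("patient_id")["rs_z"]
    out = pd.DataFrame({
        "patient_id": list(g.groups),
        "mean_rs_z": g.mean().to_numpy(),
        "high_frac": g.apply(lambda s: float((s > HIGH_RISK_Z).mean())).to_numpy(),
        "n_tiles": g.size().to_numpy(),
    })
    out["risk_group"] = np.where(out["high_frac"] >= cutoff, "high", "low")
    if clinical is not None:
        out = out.merge(clinical, on="patient_id", how="left")
    return out


def subtype_calls(records: pd.DataFrame,
                  true_fractions: pd.DataFrame | None = None):
    """Winner-takes-all subtype calls.

    Returns ``(tile_labels, sample_calls)``: per-tile argmax labels (ties
    broken by the fixed order classical < mesenchymal < proneural) and a
    per-patient DataFrame with the tile-mean score vector, the argmax
    sample label, and — when ``true_fractions`` (clinical table with
    ``frac_*`` columns) is given — the ground-truth predominance label
    (component >= 0.70, else ``"mixed"``).
    """
    scores = records[TS_COLS].to_numpy(float)
    tile_labels = pd.Series(
        [SUBTYPES[i] for i in scores.argmax(axis=1)],
        index=records.index, name="tile_subtype")
    mean = records.groupby("patient_id")[TS_COLS].mean()
    sample = pd.DataFrame({
        "patient_id": mean.index,
        **{c: mean[c].to_numpy() for c in TS_COLS},
    })
    sample["pred_subtype"] = [
        SUBTYPES[i] for i in mean.to_numpy().argmax(axis=1)]
    if true_fractions is not None:
        fr = true_fractions.set_index("patient_id")[
            ["frac_classical", "frac_mesenchymal", "frac_proneural"]]
        fr = fr.reindex(sample["patient_id"]).to_numpy(float)
        dom = fr.argmax(axis=1)
        sample["true_subtype"] = [
            SUBTYPES[i] if fr[k, i] >= 0.70 else "mixed"
            for k, i in enumerate(dom)]
    return tile_labels, sample.reset_index(drop=True)


def misclassification_flags(calls: pd.DataFrame) -> pd.DataFrame:
    """Misclassification rules on merged patient calls.

    Expects columns ``risk_group``, ``surv_time_years`` and, for subtype
    flags, ``pred_subtype``/``true_subtype`` plus the mean score columns.
    ``survival_misclassified`` is true for high-risk patients surviving
    beyond 18 months and low-risk patients surviving under 12 months — the
    12-to-18-month window is deliberately unflagged.  ``near_correct``
    marks subtype mismatches where the top predicted score beats the true
    subtype's score by less than 0.01.
    """
    df = calls.copy()
    high = df["risk_group"] == "high"
    t = df["surv_time_years"].to_numpy(float)
    df["survival_misclassified"] = (high & (t > MISCLASS_HIGH_SURV)) | \
                                   (~high & (t < MISCLASS_LOW_SURV))
    if "pred_subtype" in df.columns and "true_subtype" in df.columns:
        df["subtype_mismatch"] = df["pred_subtype"] != df["true_subtype"]
        near = np.zeros(len(df), bool)
        scores = df[TS_COLS].to_numpy(float)
        for k, (mis, true_lab) in enumerate(
                zip(df["subtype_mismatch"], df["true_subtype"])):
            if mis and true_lab in SUBTYPES:
                top = scores[k].max()
                truth = scores[k][SUBTYPES.index(true_lab)]
                near[k] = (top - truth) < NEAR_CORRECT_MARGIN
        df["near_correct"] = near
    return df


def mean_rs_by_subtype_region(records: pd.DataFrame) -> pd.DataFrame:
    """Per-slide mean z-scored risk within each winner-takes-all subtype
    region; slides without tiles of a subtype simply omit that row.

    ``records`` must carry both heads' columns (see
    :func:`merge_predictions`).
    """
    tile_labels, _ = subtype_calls(records)
    df = records.assign(tile_subtype=tile_labels)
    out = (df.groupby(["slide_id", "tile_subtype"], observed=True)["rs_z"]
             .mean().reset_index()
             .rename(columns={"rs_z": "mean_rs_z"}))
    return out


# --------------------------------------------------------------------------
# Heatmaps
# --------------------------------------------------------------------------

def heatmap_grid(model, slide: SlidePackage, window_px: int,
                 stride_px: int | None = None,
                 crop_px: int | None = None):
    """Model predictions on a window grid covering the whole slide.

    Windows are laid out with the tiling grid logic (anchored final
    position, full coverage).  Returns ``(grids, xs, ys)``: for a subtype
    model a dict of three (ny, nx) grids keyed by subtype, for a risk model
    a single (ny, nx) array under key ``"rs"``; ``xs``/``ys`` are the
    window start coordinates, so cell (i, j) covers pixels
    ``[xs[j], xs[j]+window_px) x [ys[i], ys[i]+window_px)``.
    """
    h, w = slide.shape
    if window_px > min(h, w):
        raise ValueError(f"window {window_px} larger than slide {(h, w)}")
    stride = stride_px if stride_px is not None else window_px
    overlap = window_px - stride
    if not 0 <= overlap < window_px:
        raise ValueError("stride must lie in (0, window_px]")
    xs = grid_positions(w, window_px, overlap)
    ys = grid_positions(h, window_px, overlap)
    crop = crop_px or getattr(model.spec, "input_px", None) or window_px
    imgs = []
    for y0 in ys:
        for x0 in xs:
            win = slide.image[y0:y0 + window_px, x0:x0 + window_px]
            imgs.append(center_crop(win, crop))
    preds = []
    stack = np.stack(imgs)
    for i in range(0, len(stack), 256):
        preds.append(model.predict(stack[i:i + 256]))
    p = np.concatenate(preds)
    ny, nx = len(ys), len(xs)
    if model.head_kind == "ts":
        grids = {SUBTYPES[j]: p[:, j].reshape(ny, nx) for j in range(3)}
    else:
        grids = {"rs": p.reshape(ny, nx)}
    return grids, xs, ys


def grid_cell_for_pixel(xs, ys, x: float, y: float, window_px: int):
    """Inverse of the heatmap layout: grid cell whose window contains the
    pixel, preferring the cell whose window starts closest."""
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    j = int(np.argmin(np.where((xs <= x) & (x < xs + window_px),
                               x - xs, np.inf)))
    i = int(np.argmin(np.where((ys <= y) & (y < ys + window_px),
                               y - ys, np.inf)))
    return i, j


def threshold_heatmap(grid: np.ndarray, smooth_sigma: float = 1.0) -> np.ndarray:
    """Binarize a prediction grid into hot cells.

    The grid is Gaussian-smoothed (sigma in grid cells; per-window
    predictions are noisy and heatmaps are conventionally smoothed before
    display) and thresholded with Otsu's method, which needs no tuned
    cutoff.
    """
    from scipy.ndimage import gaussian_filter
    from skimage.filters import threshold_otsu

    g = gaussian_filter(grid, smooth_sigma) if smooth_sigma > 0 else grid
    return g > threshold_otsu(g)


def grid_to_pixel_mask(cell_mask: np.ndarray, xs, ys, window_px: int,
                       shape) -> np.ndarray:
    """Paint selected grid cells back into pixel space (union of their
    windows) — used to compare thresholded heatmaps with planted regions."""
    out = np.zeros(shape, bool)
    for i, y0 in enumerate(ys):
        for j, x0 in enumerate(xs):
            if cell_mask[i, j]:
                out[y0:y0 + window_px, x0:x0 + window_px] = True
    return out


def render_heatmap(grid: np.ndarray, slide: SlidePackage, path,
                   window_px: int, xs=None, ys=None,
                   alpha: float = 0.45, cmap: str = "coolwarm") -> None:
    """Overlay a risk grid on the slide image and write a PNG.

    High values render red, low values blue (diverging colormap), blended
    over the H&E at the given opacity.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(slide.image)
    h, w = slide.shape
    ax.imshow(grid, cmap=cmap, alpha=alpha, extent=(0, w, h, 0),
              interpolation="bilinear")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
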