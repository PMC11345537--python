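"""End-to-end orchestration: cohort -> tiles -> cross-validated models ->
patient-level calls.

This is the glue the worked example and the reproduction script run: tile
every slide of a (synthetic) cohort, filter tiles and patients, assign
stratified folds, train the risk and subtype heads per fold, score each
fold's validation tiles, z-score risk within folds, and aggregate to
patient-level risk groups and subtype calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import (aggregate_patient, merge_predictions, predict_tiles,
                        subtype_calls, zscore_scores)
from .nn import BackboneSpec
from .synthcohort import CohortBundle
from .tiling import filter_and_exclude, make_tilesheet
from .training import TilePool, TrainConfig, assign_folds, train_two_phase


@dataclass
class PipelineResult:
    sheet: list
    folds: pd.Series
    predictions: pd.DataFrame          # merged rs + ts tile predictions
    patient_calls: pd.DataFrame        # risk calls + subtype calls + clinical
    models: dict = field(default_factory=dict)
    histories: dict = field(default_factory=dict)


def tile_cohort(bundle: CohortBundle, tile_px: int, overlap_px: int,
                min_tumor_frac: float = 0.5, min_tiles_per_patient: int = 50):
    """Tile every slide, keep >50%-tumor tiles, drop thin patients."""
    sheet = []
    for pid, slide in bundle.slides.items():
        sheet.extend(make_tilesheet(slide, tile_px, overlap_px))
    kept, excluded = filter_and_exclude(sheet, min_tumor_frac,
                                        min_tiles_per_patient)
    return kept, excluded


def _pool_for(bundle: CohortBundle, sheet, patient_ids):
    wanted = set(patient_ids)
    tiles: dict[str, list] = {p: [] for p in wanted}
    for t in sheet:
        if t.patient_id in wanted:
            img = bundle.slides[t.patient_id].image
            tiles[t.patient_id].append(
                img[t.y0:t.y0 + t.size_px, t.x0:t.x0 + t.size_px])
    tiles = {p: np.stack(v) for p, v in tiles.items() if v}
    clin = bundle.clinical[bundle.clinical["patient_id"].isin(tiles)]
    return TilePool(tiles=tiles, clinical=clin)


def run_cv_pipeline(bundle: CohortBundle, tile_px: int = 64,
                    overlap_px: int = 8, k: int = 5,
                    train_config: TrainConfig | None = None,
                    heads=("rs", "ts"),
                    min_tiles_per_patient: int = 50) -> PipelineResult:
    """Cross-validated two-head training and patient-level aggregation.

    Validation-fold predictions are concatenated across folds after
    per-fold z-scoring of the raw risk scores, exactly as the statistics
    layer expects.
    """
    cfg = train_config or TrainConfig.desk()
    kept, _ = tile_cohort(bundle, tile_px, overlap_px,
                          min_tiles_per_patient=min_tiles_per_patient)
    pids = sorted({t.patient_id for t in kept})
    clin = bundle.clinical[bundle.clinical["patient_id"].isin(pids)]
    folds = assign_folds(clin.reset_index(drop=True), k=k, seed=cfg.seed)
    fold_of = dict(zip(clin["patient_id"], folds))

    rs_parts, ts_parts = [], []
    models, histories = {}, {}
    backbone = BackboneSpec("tiny_test", input_px=cfg.crop_px)
    for fold in range(k):
        val_ids = [p for p in pids if fold_of[p] == fold]
        train_ids = [p for p in pids if fold_of[p] != fold]
        train_pool = _pool_for(bundle, kept, train_ids)
        val_pool = _pool_for(bundle, kept, val_ids)
        val_sheet = [t for t in kept if t.patient_id in set(val_ids)]
        slides = {bundle.slides[p].slide_id: bundle.slides[p] for p in val_ids}
        for head in heads:
            model, hist = train_two_phase(train_pool, val_pool, backbone,
                                          head, cfg)
            models[(fold, head)] = model
            histories[(fold, head)] = hist
            df = predict_tiles(model, val_sheet, slides, crop_px=cfg.crop_px)
            df["fold"] = fold
            (rs_parts if head == "rs" else ts_parts).append(df)

    result_parts = {}
    if "rs" in heads:
        rs = zscore_scores(pd.concat(rs_parts, ignore_index=True),
                           scope="per_fold_then_concat")
        result_parts["rs"] = rs
    if "ts" in heads:
        result_parts["ts"] = pd.concat(ts_parts, ignore_index=True)
    if len(result_parts) == 2:
        preds = merge_predictions(
            result_parts["rs"],
            result_parts["ts"].drop(columns=["fold"]))
    else:
        preds = next(iter(result_parts.values()))

    calls = None
    if "rs" in heads:
        calls = aggregate_patient(preds, clinical=bundle.clinical)
    if "ts" in heads:
        _, sample = subtype_calls(preds, true_fractions=bundle.clinical)
        calls = (sample if calls is None else
                 calls.merge(sample, on="patient_id", how="left"))
    return PipelineResult(sheet=kept, folds=folds, predictions=preds,
                          patient_calls=calls, models=models,
                          histories=histories)
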