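import numpy as np
import pandas as pd
import pytest

from glioslide.inference import (aggregate_patient, grid_cell_for_pixel,
                                 grid_to_pixel_mask, heatmap_grid,
                                 mean_rs_by_subtype_region,
                                 merge_predictions, misclassification_flags,
                                 predict_tiles, subtype_calls, zscore_scores)
from glioslide.nn import BackboneSpec, TinyModel
from glioslide.tiling import SlidePackage, TileRecord


def _pred_frame(rs_z, patient_id="p1", **extra):
    n = len(rs_z)
    base = {"slide_id": ["s1"] * n, "patient_id": [patient_id] * n,
            "x0": np.arange(n) * 64, "y0": [0] * n, "size_px": [64] * n,
            "rs_z": rs_z}
    base.update(extra)
    return pd.DataFrame(base)


class TestZScore:
    def test_arithmetic(self):
        df = pd.DataFrame({"rs_raw": [1.0, 2.0, 3.0]})
        out = zscore_scores(df, scope="global")
        assert np.allclose(out["rs_z"], [-1.2247448, 0.0, 1.2247448])
        assert out["rs_z"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["rs_z"].std(ddof=0) == pytest.approx(1.0)

    def test_per_fold_removes_offsets_global_does_not(self, rng):
        a = rng.normal(0, 1, 50)
        df = pd.DataFrame({
            "rs_raw": np.concatenate([a, a + 10.0]),
            "fold": np.repeat([0, 1], 50)})
        per = zscore_scores(df, scope="per_fold_then_concat")
        glo = zscore_scores(df, scope="global")
        means_per = per.groupby("fold")["rs_z"].mean()
        means_glo = glo.groupby("fold")["rs_z"].mean()
        assert np.allclose(means_per, 0.0, atol=1e-12)
        assert abs(means_glo[1] - means_glo[0]) > 1.0

    def test_rank_order_preserved(self, rng):
        raw = rng.normal(0, 3, 30)
        out = zscore_scores(pd.DataFrame({"rs_raw": raw}), scope="global")
        assert (np.argsort(out["rs_z"]) == np.argsort(raw)).all()

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            zscore_scores(pd.DataFrame({"rs_raw": [1.0, 1.0]}),
                          scope="global")


class TestAggregate:
    def test_quarter_high_fraction_is_high_risk(self):
        out = aggregate_patient(_pred_frame([2.0, 0.0, 0.0, 0.0]))
        assert out.loc[0, "high_frac"] == 0.25
        assert out.loc[0, "risk_group"] == "high"

    def test_all_below_one_is_low(self):
        out = aggregate_patient(_pred_frame([0.9, 0.5, -1.0, 0.99]))
        assert out.loc[0, "risk_group"] == "low"

    def test_z_exactly_one_is_not_high_risk_tile(self):
        out = aggregate_patient(_pred_frame([1.0, 1.0, 1.0, 1.0]))
        assert out.loc[0, "high_frac"] == 0.0

    def test_order_independent(self, rng):
        z = rng.normal(0, 1, 40)
        a = aggregate_patient(_pred_frame(z))
        b = aggregate_patient(_pred_frame(z[rng.permutation(40)]))
        assert a.loc[0, "mean_rs_z"] == pytest.approx(b.loc[0, "mean_rs_z"])
        assert a.loc[0, "high_frac"] == b.loc[0, "high_frac"]


class TestSubtypeCalls:
    def _records(self, rows):
        n = len(rows)
        df = _pred_frame([0.0] * n)
        df[["ts_classical", "ts_mesenchymal", "ts_proneural"]] = rows
        return df

    def test_predominance_boundary(self):
        clin = pd.DataFrame({
            "patient_id": ["p1"],
            "frac_classical": [0.70], "frac_mesenchymal": [0.20],
            "frac_proneural": [0.10]})
        _, sample = subtype_calls(self._records([[1, 0, 0]]), clin)
        assert sample.loc[0, "true_subtype"] == "classical"
        clin2 = clin.assign(frac_classical=0.69, frac_mesenchymal=0.21)
        _, sample2 = subtype_calls(self._records([[1, 0, 0]]), clin2)
        assert sample2.loc[0, "true_subtype"] == "mixed"

    def test_tie_broken_by_fixed_class_order(self):
        records = self._records([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        tile_labels, sample = subtype_calls(records)
        assert tile_labels.tolist() == ["classical", "mesenchymal"]
        # sample mean (0.5, 0.5, 0) ties -> classical by fixed order
        assert sample.loc[0, "pred_subtype"] == "classical"


class TestMisclassification:
    def _calls(self, group, surv, pred="classical", true="classical",
               scores=(0.4, 0.3, 0.3)):
        return pd.DataFrame({
            "patient_id": ["p1"], "risk_group": [group],
            "surv_time_years": [surv], "pred_subtype": [pred],
            "true_subtype": [true],
            "ts_classical": [scores[0]], "ts_mesenchymal": [scores[1]],
            "ts_proneural": [scores[2]]})

    def test_high_risk_long_survivor_misclassified(self):
        out = misclassification_flags(self._calls("high", 2.0))
        assert bool(out.loc[0, "survival_misclassified"])

    def test_intermediate_window_is_intentionally_unflagged(self):
        out = misclassification_flags(self._calls("low", 1.2))
        assert not bool(out.loc[0, "survival_misclassified"])

    def test_low_risk_short_survivor_misclassified(self):
        out = misclassification_flags(self._calls("low", 0.8))
        assert bool(out.loc[0, "survival_misclassified"])

    def test_near_correct_margin(self):
        out = misclassification_flags(self._calls(
            "low", 2.0, pred="mesenchymal", true="classical",
            scores=(0.330, 0.335, 0.335)))
        assert bool(out.loc[0, "subtype_mismatch"])
        assert bool(out.loc[0, "near_correct"])
        out2 = misclassification_flags(self._calls(
            "low", 2.0, pred="mesenchymal", true="classical",
            scores=(0.30, 0.40, 0.30)))
        assert not bool(out2.loc[0, "near_correct"])


class TestMeanRsBySubtypeRegion:
    def test_hand_computed_group_means(self):
        df = _pred_frame([1.0, 2.0, 3.0, 4.0])
        df[["ts_classical", "ts_mesenchymal", "ts_proneural"]] = [
            [1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]
        out = mean_rs_by_subtype_region(df)
        vals = out.set_index("tile_subtype")["mean_rs_z"]
        assert vals["classical"] == 1.5
        assert vals["mesenchymal"] == 3.0
        assert vals["proneural"] == 4.0

    def test_single_label_equals_slide_mean(self, rng):
        z = rng.normal(0, 1, 12)
        df = _pred_frame(z)
        df[["ts_classical", "ts_mesenchymal", "ts_proneural"]] = \
            np.tile([0.2, 0.5, 0.3], (12, 1))
        out = mean_rs_by_subtype_region(df)
        assert len(out) == 1
        assert out.loc[0, "mean_rs_z"] == pytest.approx(z.mean())

    def test_tile_order_invariant(self, rng):
        z = rng.normal(0, 1, 20)
        scores = rng.dirichlet([1, 1, 1], 20)
        df = _pred_frame(z)
        df[["ts_classical", "ts_mesenchymal", "ts_proneural"]] = scores
        perm = rng.permutation(20)
        df2 = df.iloc[perm].reset_index(drop=True)
        a = mean_rs_by_subtype_region(df).set_index("tile_subtype")
        b = mean_rs_by_subtype_region(df2).set_index("tile_subtype")
        assert np.allclose(a["mean_rs_z"], b.loc[a.index, "mean_rs_z"])


def _toy_slide(rng, h=160, w=160):
    img = rng.integers(0, 255, (h, w, 3), dtype=np.uint8)
    return SlidePackage(image=img, masks={}, microns_per_px=0.92,
                        slide_id="s1", patient_id="p1")


class TestPredictTiles:
    def test_duplicate_tiles_identical_scores(self, rng):
        slide = _toy_slide(rng)
        model = TinyModel("rs", BackboneSpec("tiny_test", input_px=56))
        t = TileRecord("s1", "p1", 0, 0, 64,
                       {"tumor": 1.0, "necrosis": 0, "preexisting": 0,
                        "bleeding": 0, "scar": 0})
        df = predict_tiles(model, [t, t], {"s1": slide}, crop_px=56)
        assert df["rs_raw"].iloc[0] == df["rs_raw"].iloc[1]

    def test_untrained_head_outputs_constant_zero(self, rng):
        slide = _toy_slide(rng)
        model = TinyModel("rs", BackboneSpec("tiny_test", input_px=56))
        tiles = [TileRecord("s1", "p1", x, 0, 64,
                            {"tumor": 1.0, "necrosis": 0, "preexisting": 0,
                             "bleeding": 0, "scar": 0}) for x in (0, 64)]
        df = predict_tiles(model, tiles, {"s1": slide}, crop_px=56)
        assert np.allclose(df["rs_raw"], 0.0)

    def test_missing_slide_errors(self, rng):
        model = TinyModel("rs", BackboneSpec("tiny_test", input_px=56))
        t = TileRecord("ghost", "p1", 0, 0, 64,
                       {"tumor": 1.0, "necrosis": 0, "preexisting": 0,
                        "bleeding": 0, "scar": 0})
        with pytest.raises(KeyError, match="ghost"):
            predict_tiles(model, [t], {}, crop_px=56)


class TestHeatmap:
    def test_constant_model_constant_grid(self, rng):
        slide = _toy_slide(rng)
        model = TinyModel("rs", BackboneSpec("tiny_test", input_px=56))
        grids, xs, ys = heatmap_grid(model, slide, window_px=64, stride_px=32)
        g = grids["rs"]
        assert g.shape == (len(ys), len(xs))
        assert np.allclose(g, 0.0)

    def test_grid_dims_match_grid_positions(self, rng):
        from glioslide.tiling import grid_positions
        slide = _toy_slide(rng, 160, 224)
        model = TinyModel("ts", BackboneSpec("tiny_test", input_px=56))
        grids, xs, ys = heatmap_grid(model, slide, window_px=64, stride_px=48)
        assert np.array_equal(xs, grid_positions(224, 64, 16))
        assert np.array_equal(ys, grid_positions(160, 64, 16))
        assert set(grids) == {"classical", "mesenchymal", "proneural"}

    def test_cell_pixel_roundtrip(self, rng):
        slide = _toy_slide(rng)
        model = TinyModel("rs", BackboneSpec("tiny_test", input_px=56))
        _, xs, ys = heatmap_grid(model, slide, window_px=64, stride_px=32)
        for i, y0 in enumerate(ys):
            for j, x0 in enumerate(xs):
                assert grid_cell_for_pixel(xs, ys, x0, y0, 64) == (i, j)

    def test_pixel_mask_painting(self):
        cells = np.zeros((2, 2), bool)
        cells[0, 1] = True
        mask = grid_to_pixel_mask(cells, [0, 32], [0, 32], 32, (64, 64))
        assert mask[:32, 32:].all()
        assert mask.sum() == 32 * 32

    def test_window_larger_than_slide_rejected(self, rng):
        slide = _toy_slide(rng, 64, 64)
        model = TinyModel("rs", BackboneSpec("tiny_test", input_px=56))
        with pytest.raises(ValueError):
            heatmap_grid(model, slide, window_px=128)


def test_merge_predictions_joins_on_tile_key(rng):
    rs = _pred_frame([0.5, 1.5])
    rs["rs_raw"] = [0.1, 0.2]
    ts = _pred_frame([0.0, 0.0]).drop(columns=["rs_z"])
    ts[["ts_classical", "ts_mesenchymal", "ts_proneural"]] = \
        [[1, 0, 0], [0, 1, 0]]
    merged = merge_predictions(rs, ts)
    assert len(merged) == 2
    assert {"rs_z", "ts_classical"} <= set(merged.columns)
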