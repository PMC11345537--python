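import io
from dataclasses import replace

import numpy as np
import pytest

from conftest import pure_patient
from glioslide.stats import harrell_c
from glioslide.synthcohort import (MARKERS, SubtypeMixture, SynthConfig,
                                   build_scene, clinical_table,
                                   generate_cohort, render_marker_map,
                                   render_slide, sample_patient,
                                   sample_subtype_fractions, sample_survival)


class TestSubtypeMixture:
    def test_simplex_invariants_enforced(self):
        with pytest.raises(ValueError):
            SubtypeMixture(0.5, 0.6, 0.1)
        with pytest.raises(ValueError):
            SubtypeMixture(-0.1, 0.6, 0.5)

    def test_predominance_threshold(self):
        assert SubtypeMixture(0.70, 0.20, 0.10).predominant() == "classical"
        assert SubtypeMixture(0.69, 0.21, 0.10).predominant() == "mixed"

    def test_flat_concentration_limit(self, rng):
        cfg = SynthConfig(p_spiky=0.0,
                          dirichlet_flat=(1e6, 1e6, 1e6))
        mix = sample_subtype_fractions(cfg, rng)
        assert np.allclose(mix.as_array(), 1 / 3, atol=1e-3)

    def test_fixed_seed_reproducible(self):
        cfg = SynthConfig()
        a = sample_subtype_fractions(cfg, np.random.default_rng(4))
        b = sample_subtype_fractions(cfg, np.random.default_rng(4))
        assert a == b

    def test_predominant_share_matches_cohort_composition(self, rng):
        """~55.6% of draws have a >= 0.70 component (1 - mixed share)."""
        cfg = SynthConfig()
        draws = np.array([sample_subtype_fractions(cfg, rng).as_array()
                          for _ in range(10_000)])
        share = float((draws.max(axis=1) >= 0.7).mean())
        assert abs(share - 0.556) < 0.05

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(dirichlet_spiky=(0.0, 1.0, 1.0))


class TestSurvivalModel:
    def test_km_median_matches_closed_form_weibull(self, rng):
        """With no risk effect and neutral covariates the Kaplan-Meier
        median equals the Weibull closed-form median."""
        from lifelines import KaplanMeierFitter

        cfg = SynthConfig(risk_effect_beta=0.0)
        t, e = zip(*(sample_survival(0.0, 60.0, "female", False, cfg, rng)
                     for _ in range(2000)))
        km = KaplanMeierFitter().fit(np.array(t), np.array(e))
        closed = cfg.weibull_scale_years * np.log(2) ** (1 / cfg.weibull_shape)
        assert km.median_survival_time_ == pytest.approx(closed, rel=0.08)

    def test_latent_risk_concordance_grows_with_beta(self, rng):
        cs = []
        for beta in (0.0, 0.5, 1.0):
            cfg = SynthConfig(risk_effect_beta=beta)
            risk = rng.standard_normal(2000)
            t, e = zip(*(sample_survival(r, 60.0, "female", False, cfg, rng)
                         for r in risk))
            cs.append(harrell_c(np.array(t), np.array(e), risk))
        assert cs[0] < cs[1] < cs[2]
        assert cs[2] >= 0.70
        assert abs(cs[0] - 0.5) < 0.03

    def test_zero_horizon_censors_everything(self, rng):
        cfg = SynthConfig(censor_horizon_years=0.0)
        for _ in range(20):
            _, event = sample_survival(0.0, 60.0, "male", True, cfg, rng)
            assert event is False


class TestRenderSlide:
    def test_pure_classical_density_recovers_reference_median(self, small_cfg):
        """Planted and detected tumor cellularity near 6,146 / mm^2."""
        from glioslide.microenv import cellularity, detect_nuclei

        p = pure_patient(0, risk=0.0)
        slide, truth = render_slide(p, small_cfg, np.random.default_rng(5),
                                    return_truth=True)
        tumor = slide.tumor_mask()
        area = tumor.sum() * small_cfg.mm2_per_px
        planted = len(truth["nuclei"]["tumor"]) / area
        assert abs(planted - 6146) / 6146 < 0.15
        cells = detect_nuclei(slide.image, small_cfg.microns_per_px)
        detected, _ = cellularity(cells, tumor, small_cfg.microns_per_px)
        assert abs(detected - 6146) / 6146 < 0.15

    def test_zero_necrosis_fraction_empty_mask(self, small_cfg):
        cfg = replace(small_cfg, necrosis_area_frac=0.0)
        p = pure_patient(1)
        slide = render_slide(p, cfg, np.random.default_rng(1))
        assert not slide.mask("necrosis").any()

    def test_same_seed_identical_pixels(self, small_cfg):
        p = pure_patient(2)
        a = render_slide(p, small_cfg, np.random.default_rng(9))
        b = render_slide(p, small_cfg, np.random.default_rng(9))
        assert np.array_equal(a.image, b.image)
        for k in a.masks:
            assert np.array_equal(a.masks[k], b.masks[k])

    def test_masks_disjoint_and_area_fractions(self, small_cfg, rng):
        p = sample_patient(small_cfg, "PX")
        scene = build_scene(p, small_cfg, rng)
        m = scene.masks
        overlap = (m["necrosis"].astype(int) + m["preexisting"]
                   + m["bleeding"])
        assert overlap.max() <= 1
        assert abs(m["necrosis"].mean() - small_cfg.necrosis_area_frac) \
            <= 0.2 * small_cfg.necrosis_area_frac
        assert abs(m["preexisting"].mean()
                   - small_cfg.infiltration_band_frac) \
            <= 0.2 * small_cfg.infiltration_band_frac

    def test_weight_field_average_matches_mixture(self, small_cfg, rng):
        for pid in ("A", "B", "C"):
            p = sample_patient(small_cfg, pid)
            scene = build_scene(p, small_cfg, rng)
            err = np.abs(scene.weights.mean(axis=(1, 2))
                         - p.mixture.as_array()).max()
            assert err < 0.05

    def test_nucleus_pleomorphism_grows_with_risk(self, small_cfg):
        """Higher latent risk widens the nucleus-area distribution."""
        from glioslide.microenv import detect_nuclei

        spreads = []
        for risk in (-2.0, 2.0):
            p = pure_patient(0, risk=risk)
            slide = render_slide(p, small_cfg, np.random.default_rng(3))
            cells = detect_nuclei(slide.image, small_cfg.microns_per_px)
            la = np.log(cells["area_px"])
            spreads.append(la.quantile(0.9) - la.quantile(0.1))
        assert spreads[1] > spreads[0]

    def test_canvas_too_small_rejected(self):
        cfg = SynthConfig.test_profile(canvas_px=(128, 128))
        with pytest.raises(ValueError):
            render_slide(pure_patient(0), cfg, np.random.default_rng(0))


class TestMarkerMaps:
    @pytest.mark.parametrize("subtype_idx,marker,expected", [
        (1, "CD8", 36.0),     # mesenchymal CD8+ median
        (0, "CD68", 96.0),    # classical CD68+ median
    ])
    def test_point_density_recovers_reference_median(self, subtype_idx,
                                                     marker, expected):
        # pure-subtype region spanning the whole canvas, ~3.5 mm^2
        cfg = SynthConfig.test_profile(canvas_px=(2048, 2048), seed=0,
                                       necrosis_area_frac=0.0,
                                       bleeding_area_frac=0.0,
                                       infiltration_band_frac=0.0)
        p = pure_patient(subtype_idx, risk=0.0)
        mm = render_marker_map(p, marker, cfg, np.random.default_rng(21))
        area_mm2 = 2048 * 2048 * cfg.mm2_per_px
        density = len(mm.points) / area_mm2
        assert abs(density - expected) / expected < 0.2

    def test_zero_intensity_empty(self):
        cfg = SynthConfig.test_profile(
            marker_point_density={"CD3": (0.0, 0.0, 0.0),
                                  "CD8": (10., 36., 9.),
                                  "CD68": (96., 243., 72.),
                                  "CD163": (9., 348., 37.),
                                  "Ki67": (290., 108., 60.)})
        mm = render_marker_map(pure_patient(0), "CD3", cfg,
                               np.random.default_rng(0))
        assert len(mm.points) == 0

    def test_cd8_depleted_at_high_risk(self):
        cfg = SynthConfig.test_profile(canvas_px=(1024, 1024),
                                       necrosis_area_frac=0.0,
                                       bleeding_area_frac=0.0,
                                       infiltration_band_frac=0.0)
        counts = []
        for risk in (-1.5, 1.5):
            p = pure_patient(1, risk=risk)
            mm = render_marker_map(p, "CD8", cfg, np.random.default_rng(2))
            counts.append(len(mm.points))
        assert counts[1] < counts[0]

    def test_area_marker_returns_mask_with_target_fraction(self, small_cfg):
        p = pure_patient(1)  # mesenchymal: HLA-DR 8%
        mm = render_marker_map(p, "HLADR", small_cfg,
                               np.random.default_rng(3))
        assert mm.stained_mask is not None
        scene = build_scene(p, small_cfg, np.random.default_rng(3))
        frac = mm.stained_mask[scene.tumor].mean()
        assert abs(frac - 0.08) < 0.02

    def test_unknown_marker_rejected(self, small_cfg):
        with pytest.raises(ValueError):
            render_marker_map(pure_patient(0), "CD999", small_cfg,
                              np.random.default_rng(0))
        assert "CD8" in MARKERS


class TestGenerateCohort:
    def test_counts_and_clinical_rows(self, small_cohort):
        assert len(small_cohort.patients) == 8
        assert len(small_cohort.slides) == 8
        assert len(small_cohort.clinical) == 8
        assert set(small_cohort.markers) == {
            (p.patient_id, m) for p in small_cohort.patients
            for m in ("CD8", "CD68")}

    def test_same_seed_byte_identical_clinical(self, small_cfg):
        cfg = replace(small_cfg, n_patients=6)
        out = []
        for _ in range(2):
            bundle = generate_cohort(cfg, render=False)
            buf = io.StringIO()
            bundle.clinical.to_csv(buf, index=False)
            out.append(buf.getvalue())
        assert out[0] == out[1]

    def test_event_fraction_near_configured_target(self):
        cfg = SynthConfig.test_profile(n_patients=60, seed=17)
        bundle = generate_cohort(cfg, render=False)
        assert abs(bundle.clinical["event"].mean()
                   - cfg.expected_event_frac) <= 0.1

    def test_clinical_table_invariants(self, small_cohort):
        cl = small_cohort.clinical
        fr = cl[["frac_classical", "frac_mesenchymal", "frac_proneural"]]
        assert np.allclose(fr.sum(axis=1), 1.0, atol=1e-9)
        assert (cl["surv_time_years"] > 0).all()
        assert cl["sex"].isin(["female", "male"]).all()

    def test_too_few_patients_rejected(self, small_cfg):
        with pytest.raises(ValueError):
            generate_cohort(replace(small_cfg, n_patients=1))

    def test_write_roundtrip(self, small_cfg, tmp_path):
        cfg = replace(small_cfg, n_patients=2)
        bundle = generate_cohort(cfg, markers=("CD8",), out_dir=tmp_path)
        assert (tmp_path / "clinical.csv").exists()
        assert len(list((tmp_path / "slides").glob("*.png"))) == 2
        assert len(list((tmp_path / "markers").glob("*.csv"))) == 2
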