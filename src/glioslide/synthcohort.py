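"""Synthetic glioblastoma cohort generator.

Every downstream stage of the pipeline (tiling, training, aggregation,
survival statistics, morphometrics) is exercised on cohorts produced here:
H&E-like RGB slides with region masks (necrosis, preexisting brain,
bleeding), immunomarker point maps, and a clinical table with overall
survival, covariates and transcriptional-subtype fractions.

The generative model, in outline:

* Each patient carries a 3-component subtype mixture (classical,
  mesenchymal, proneural) drawn from a two-component Dirichlet mixture: a
  "spiky" component concentrated on a randomly chosen dominant subtype and
  a "flat" component producing mixed profiles.  The mixing weight is set so
  that roughly 56% of patients have a predominant (>= 0.70) subtype.
* A standardized latent risk score drives survival through a Weibull
  proportional-hazards model together with age, sex and radiochemotherapy,
  and drives the slide phenotype: higher cellularity, more variable nucleus
  shapes, and depleted CD8+ infiltration.
* A slide is a pink eosin background with dark elliptical nuclei whose
  local density and eccentricity follow a spatially smoothed subtype weight
  field; the proneural weight is raised inside the infiltration band and
  the mesenchymal weight near necrosis.  Region masks are mutually disjoint
  and the slide-averaged weight field reproduces the patient mixture.
* Marker maps are Poisson point processes with mixture-weighted per-subtype
  intensities; area markers (HLA-DR, CD34) come as stained-area masks.

All randomness flows from a single seed; per-patient substreams are derived
by stable hashing of the patient id, so cohorts are reproducible patient by
patient and under parallel generation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .tiling import SlidePackage

SUBTYPES = ("classical", "mesenchymal", "proneural")

POINT_MARKERS = ("CD3", "CD8", "CD68", "CD163", "Ki67")
AREA_MARKERS = ("HLADR", "CD34")
MARKERS = POINT_MARKERS + AREA_MARKERS


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SubtypeMixture:
    """Subtype fraction vector; components are non-negative and sum to 1."""

    classical: float
    mesenchymal: float
    proneural: float

    def __post_init__(self):
        v = self.as_array()
        if np.any(v < 0):
            raise ValueError(f"negative subtype fraction in {v}")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"subtype fractions sum to {v.sum()!r}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.classical, self.mesenchymal, self.proneural])

    @classmethod
    def from_array(cls, v) -> "SubtypeMixture":
        v = np.asarray(v, float)
        return cls(float(v[0]), float(v[1]), float(v[2]))

    def predominant(self, threshold: float = 0.70) -> str:
        """Predominant subtype label, or ``"mixed"`` below the threshold."""
        v = self.as_array()
        i = int(v.argmax())
        return SUBTYPES[i] if v[i] >= threshold else "mixed"


@dataclass
class LatentPatient:
    """One simulated patient: mixture, latent risk, covariates, survival."""

    patient_id: str
    mixture: SubtypeMixture
    latent_risk: float
    age_years: float
    sex: str
    tmz: bool
    surv_time_years: float = float("nan")
    event: bool = False

    def __post_init__(self):
        if not np.isfinite(self.latent_risk):
            raise ValueError("latent_risk must be finite")
        if self.age_years <= 0:
            raise ValueError("age_years must be positive")
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex {self.sex!r}")


@dataclass
class SynthConfig:
    """All knobs of the generator.

    Distributional anchors (documented per field) are medians and cohort
    shares from the reference clinical cohort; geometry defaults give a
    ~1.4 mm square slide at 20x-equivalent resolution, and
    :meth:`test_profile` shrinks everything to 512-pixel canvases with
    64-pixel tiles for fast experiments on the same code path.
    """

    n_patients: int = 60
    canvas_px: tuple = (3072, 3072)
    microns_per_px: float = 0.46
    tile_px: int = 512                  # reference tile geometry for context bands
    # region geometry
    necrosis_area_frac: float = 0.08
    infiltration_band_frac: float = 0.15
    bleeding_area_frac: float = 0.015
    # subtype mixture: spiky/flat Dirichlet mixture, dominant drawn with the
    # predominant-class shares of the reference cohort (34:50:21)
    dirichlet_spiky: tuple = (30.0, 2.0, 2.0)
    dirichlet_flat: tuple = (5.0, 5.0, 5.0)
    p_spiky: float = 0.555              # gives ~0.556 predominant share
    dominant_probs: tuple = (34 / 105, 50 / 105, 21 / 105)
    # nucleus phenotype per subtype (classical, mesenchymal, proneural)
    subtype_density_per_mm2: tuple = (6146.0, 5484.0, 5321.0)
    subtype_eccentricity: tuple = (0.60, 0.75, 0.45)
    subtype_nucleus_area_um2: tuple = (36.0, 30.0, 24.0)
    density_risk_gamma: float = 0.2     # log-density shift per risk SD
    risk_field_sigma: float = 0.5       # SD of smooth within-slide risk variation
    shape_sigma_base: float = 0.18      # lognormal sigma of nucleus area ...
    shape_sigma_risk: float = 0.12      # ... plus this * sigmoid(risk)
    # off-tumor nucleus densities (per mm2)
    preexisting_density_per_mm2: float = 2500.0
    necrosis_density_per_mm2: float = 400.0
    # markers: per-subtype medians; points per mm2 / stained-area percent
    marker_point_density: dict = field(default_factory=lambda: {
        "CD3": (34.0, 129.0, 25.0),
        "CD8": (10.0, 36.0, 9.0),
        "CD68": (96.0, 243.0, 72.0),
        "CD163": (9.0, 348.0, 37.0),
        "Ki67": (290.0, 108.0, 60.0),
    })
    marker_area_percent: dict = field(default_factory=lambda: {
        "HLADR": (2.0, 8.0, 1.0),
        "CD34": (4.0, 5.0, 2.0),
    })
    cd8_risk_gamma: float = 0.4         # CD8 intensity ~ exp(-gamma * risk)
    # survival model (Weibull proportional hazards)
    risk_effect_beta: float = 1.0
    weibull_shape: float = 1.5
    weibull_scale_years: float = 1.136  # population median OS ~1.16 y
    hr_age_per_year: float = 1.025
    hr_male: float = 1.14
    hr_tmz: float = 0.43
    censor_horizon_years: float = 5.0
    censor_uniform_max_years: float = 8.0
    expected_event_frac: float = 0.77   # implied by the defaults above
    # covariate distributions
    age_mean: float = 62.5
    age_sd: float = 11.0
    p_male: float = 0.616
    p_tmz: float = 0.743
    seed: int = 0

    def __post_init__(self):
        for name in ("necrosis_area_frac", "infiltration_band_frac",
                     "bleeding_area_frac", "p_spiky", "p_male", "p_tmz"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if np.any(np.asarray(self.subtype_density_per_mm2) <= 0):
            raise ValueError("subtype densities must be positive")
        if np.any(np.asarray(self.dirichlet_spiky) <= 0) or \
                np.any(np.asarray(self.dirichlet_flat) <= 0):
            raise ValueError("Dirichlet concentrations must be positive")
        if not all(0.0 <= e < 1.0 for e in self.subtype_eccentricity):
            raise ValueError("eccentricities must lie in [0, 1)")
        if self.weibull_shape <= 0 or self.weibull_scale_years <= 0:
            raise ValueError("Weibull parameters must be positive")
        if self.microns_per_px <= 0:
            raise ValueError("microns_per_px must be positive")

    @classmethod
    def test_profile(cls, **overrides) -> "SynthConfig":
        """Desk-scale geometry: 512-pixel canvas, 64-pixel reference tiles.

        The pixel size is doubled (0.92 um/px) so that a 64-pixel tile
        spans ~59 um and contains ~20 nuclei; at full-scale resolution a
        64-pixel tile would hold too few nuclei to carry any signal.
        """
        base = dict(canvas_px=(512, 512), tile_px=64, microns_per_px=0.92)
        base.update(overrides)
        return cls(**base)

    @property
    def mm2_per_px(self) -> float:
        return (self.microns_per_px / 1000.0) ** 2


def patient_rng(config: SynthConfig, patient_id: str,
                stream: int = 0) -> np.random.Generator:
    """Per-patient substream, stable under cohort size and parallelism."""
    key = zlib.crc32(patient_id.encode())
    return np.random.default_rng(
        np.random.SeedSequence((config.seed, key, stream)))


# --------------------------------------------------------------------------
# Clinical sampling
# --------------------------------------------------------------------------

def sample_subtype_fractions(config: SynthConfig,
                             rng: np.random.Generator) -> SubtypeMixture:
    """Draw a subtype mixture from the spiky/flat Dirichlet mixture.

    With probability ``p_spiky`` the concentration vector is the spiky one,
    rotated so its large component sits on a dominant subtype drawn with
    ``dominant_probs``; otherwise the flat concentration is used.
    """
    if rng.random() < config.p_spiky:
        dom = int(rng.choice(3, p=np.asarray(config.dominant_probs)
                             / np.sum(config.dominant_probs)))
        conc = np.empty(3)
        rest = iter(config.dirichlet_spiky[1:])
        for i in range(3):
            conc[i] = config.dirichlet_spiky[0] if i == dom else next(rest)
    else:
        conc = np.asarray(config.dirichlet_flat, float)
    v = rng.dirichlet(conc)
    return SubtypeMixture.from_array(v / v.sum())


def sample_survival(latent_risk: float, age_years: float, sex: str,
                    tmz: bool, config: SynthConfig,
                    rng: np.random.Generator):
    """Event time from a Weibull proportional-hazards model, with censoring.

    The log hazard is ``beta * risk + log(1.025) * (age - 60) +
    log(1.14) * male + log(0.43) * tmz``; censoring is the minimum of the
    administrative horizon and an independent uniform draw.  Returns
    ``(observed_time_years, event)``.
    """
    lp = (config.risk_effect_beta * latent_risk
          + np.log(config.hr_age_per_year) * (age_years - 60.0)
          + np.log(config.hr_male) * (sex == "male")
          + np.log(config.hr_tmz) * tmz)
    e = rng.exponential()
    t_event = config.weibull_scale_years * (e / np.exp(lp)) ** (1.0 / config.weibull_shape)
    c = min(config.censor_horizon_years,
            rng.uniform(0.0, config.censor_uniform_max_years))
    return float(min(t_event, c)), bool(t_event <= c)


def sample_patient(config: SynthConfig, patient_id: str) -> LatentPatient:
    """Draw one full patient record from its dedicated substream."""
    rng = patient_rng(config, patient_id, stream=0)
    mixture = sample_subtype_fractions(config, rng)
    latent_risk = float(rng.standard_normal())
    age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 25, 92))
    sex = "male" if rng.random() < config.p_male else "female"
    tmz = bool(rng.random() < config.p_tmz)
    t, ev = sample_survival(latent_risk, age, sex, tmz, config, rng)
    return LatentPatient(patient_id=patient_id, mixture=mixture,
                         latent_risk=latent_risk, age_years=age, sex=sex,
                         tmz=tmz, surv_time_years=max(t, 1e-9), event=ev)


# --------------------------------------------------------------------------
# Slide scene: masks + subtype weight field + risk field
# --------------------------------------------------------------------------

def _smooth_field(shape, rng, lowres=16, order=3):
    low = rng.standard_normal((lowres, lowres))
    zoom = (shape[0] / lowres, shape[1] / lowres)
    f = ndimage.zoom(low, zoom, order=order)
    return f[:shape[0], :shape[1]]


def region_masks(config: SynthConfig, rng: np.random.Generator) -> dict:
    """Disjoint boolean masks for necrosis, preexisting brain and bleeding.

    Preexisting tissue is a wavy band along the left edge (the infiltration
    front); necrosis and bleeding are smoothed-noise blobs thresholded at
    the quantile that yields the configured area fraction outside the band.
    """
    h, w = config.canvas_px
    masks = {}
    # preexisting band on the left, with a wavy boundary
    y = np.arange(h)
    base = config.infiltration_band_frac * w
    wave = 0.15 * base * np.sin(2 * np.pi * y / h * rng.uniform(1.0, 3.0)
                                + rng.uniform(0, 2 * np.pi))
    jitter = ndimage.gaussian_filter1d(rng.standard_normal(h), h / 32.0)
    jitter *= 0.1 * base / max(jitter.std(), 1e-9)
    edge = np.clip(base + wave + jitter, 0, w)
    pre = np.arange(w)[None, :] < edge[:, None]
    if config.infiltration_band_frac == 0:
        pre[:] = False
    masks["preexisting"] = pre

    free = ~pre
    for name, frac, scale in (("necrosis", config.necrosis_area_frac, 8),
                              ("bleeding", config.bleeding_area_frac, 24)):
        if frac <= 0:
            masks[name] = np.zeros((h, w), bool)
            continue
        f = _smooth_field((h, w), rng, lowres=scale)
        f[~free] = np.inf           # never place inside occupied regions
        thr = np.quantile(f[free], frac * free.size / free.sum()
                          if free.sum() else 0.0)
        m = (f <= thr) & free
        masks[name] = m
        free = free & ~m
    return masks


def subtype_weight_field(mixture: SubtypeMixture, masks: dict,
                         config: SynthConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """Per-pixel subtype weights, shape (3, H, W), summing to 1 pixelwise.

    Smoothed random logit fields are biased so the proneural weight rises
    inside the infiltration band (within two tile-widths of preexisting
    tissue) and the mesenchymal weight rises near necrosis; additive
    offsets are then calibrated so the canvas-averaged weights match the
    patient mixture.
    """
    h, w = config.canvas_px
    tau = 1.2
    logits = np.stack([tau * _smooth_field((h, w), rng) for _ in range(3)])
    band = 2.0 * config.tile_px
    for name, idx in (("preexisting", 2), ("necrosis", 1)):
        m = masks.get(name)
        if m is not None and m.any():
            dist = ndimage.distance_transform_edt(~m)
            logits[idx] += 1.5 * np.exp(-dist / band)
    target = np.clip(mixture.as_array(), 1e-12, None)
    offset = np.zeros(3)
    for _ in range(40):
        z = logits + offset[:, None, None]
        z -= z.max(axis=0, keepdims=True)
        ez = np.exp(z)
        wgt = ez / ez.sum(axis=0, keepdims=True)
        mean = wgt.mean(axis=(1, 2))
        offset = np.clip(offset + np.log(target / np.clip(mean, 1e-12, None)),
                         -30, 30)
        if np.max(np.abs(mean - target)) < 1e-3:
            break
    return wgt


@dataclass
class SlideScene:
    """Geometry shared between the H&E rendering and the marker maps."""

    masks: dict
    weights: np.ndarray          # (3, H, W)
    risk_field: np.ndarray       # (H, W), standardized latent-risk scale
    tumor: np.ndarray            # (H, W) bool


def build_scene(patient: LatentPatient, config: SynthConfig,
                rng: np.random.Generator,
                risk_field: np.ndarray | None = None) -> SlideScene:
    h, w = config.canvas_px
    if min(h, w) < 4 * config.tile_px:
        raise ValueError(
            f"canvas {config.canvas_px} smaller than 4 tile widths "
            f"({4 * config.tile_px})")
    masks = region_masks(config, rng)
    weights = subtype_weight_field(patient.mixture, masks, config, rng)
    if risk_field is None:
        # smooth within-slide variation around the patient's latent risk,
        # so risk heatmaps have genuine spatial structure
        local = _smooth_field((h, w), rng)
        local = local / max(local.std(), 1e-9)
        risk_field = patient.latent_risk + config.risk_field_sigma * local
    tumor = ~(masks["preexisting"] | masks["necrosis"] | masks["bleeding"])
    return SlideScene(masks=masks, weights=weights,
                      risk_field=np.asarray(risk_field, float), tumor=tumor)


# --------------------------------------------------------------------------
# Nucleus placement and H&E rendering
# --------------------------------------------------------------------------

def _place_points(density_px: np.ndarray, allowed: np.ndarray,
                  rng: np.random.Generator, min_dist: float = 0.0):
    """Sample an inhomogeneous point process on ``allowed`` pixels.

    Thinning against ``density_px`` (expected points per pixel), with an
    optional hard-core minimum distance enforced by an occupancy grid.
    Returns an (N, 2) float array of (x, y) positions.
    """
    lam = np.where(allowed, density_px, 0.0)
    total = float(lam.sum())
    if total <= 0:
        return np.empty((0, 2))
    n_target = int(rng.poisson(total))
    if n_target == 0:
        return np.empty((0, 2))
    h, w = lam.shape
    lam_max = float(lam.max())
    if min_dist <= 0:
        # direct thinning, vectorized
        n_cand = int(n_target / max(lam.mean() / lam_max, 1e-9) * 1.2) + 50
        n_cand = min(n_cand, 50 * n_target + 1000)
        xs = rng.uniform(0, w, n_cand)
        ys = rng.uniform(0, h, n_cand)
        keep = rng.random(n_cand) * lam_max < lam[ys.astype(int), xs.astype(int)]
        pts = np.column_stack([xs[keep], ys[keep]])
        return pts[:n_target]
    cell = max(min_dist, 1.0)
    gw, gh = int(w / cell) + 1, int(h / cell) + 1
    grid: dict[tuple, list] = {}
    pts = []
    attempts = 0
    max_attempts = 60 * n_target
    while len(pts) < n_target and attempts < max_attempts:
        attempts += 1
        x = rng.uniform(0, w)
        y = rng.uniform(0, h)
        if rng.random() * lam_max >= lam[int(y), int(x)]:
            continue
        gx, gy = int(x / cell), int(y / cell)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for (px, py) in grid.get((gx + dx, gy + dy), ()):
                    if (px - x) ** 2 + (py - y) ** 2 < min_dist ** 2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        grid.setdefault((gx, gy), []).append((x, y))
        pts.append((x, y))
    return np.asarray(pts, float).reshape(-1, 2)


def _draw_nuclei(image, centers, areas_px, eccs, rng, color=(64, 48, 112)):
    from skimage.draw import ellipse as _ellipse

    h, w = image.shape[:2]
    for (x, y), area, ecc in zip(centers, areas_px, eccs):
        b_over_a = np.sqrt(max(1.0 - ecc ** 2, 1e-4))
        a = np.sqrt(area / (np.pi * b_over_a))
        b = a * b_over_a
        rr, cc = _ellipse(y, x, b, a, shape=(h, w),
                          rotation=rng.uniform(0, np.pi))
        shade = rng.normal(0, 10, 3)
        image[rr, cc] = np.clip(np.asarray(color, float) + shade, 0, 255)


def render_slide(patient: LatentPatient, config: SynthConfig,
                 rng: np.random.Generator,
                 scene: SlideScene | None = None,
                 return_truth: bool = False):
    """Render an H&E-like slide for a patient.

    The RGB image has an eosin-pink background with region-specific tints
    (pale necrosis, red bleeding, pale-pink preexisting brain) and dark
    elliptical nuclei.  Local nucleus density is the subtype-weighted
    mixture of the per-subtype medians, modulated by ``exp(gamma * risk)``;
    local eccentricity is the weighted eccentricity mixture; the lognormal
    spread of nucleus areas grows with latent risk (pleomorphism).

    Returns a :class:`~glioslide.tiling.SlidePackage`, or with
    ``return_truth=True`` a ``(slide, truth)`` pair where ``truth`` holds
    the scene and the planted nucleus centers per compartment.
    """
    if scene is None:
        scene = build_scene(patient, config, rng)
    h, w = config.canvas_px
    masks, weights, risk = scene.masks, scene.weights, scene.risk_field

    img = np.empty((h, w, 3), float)
    img[:] = (235, 186, 204)                                  # eosin background
    img += rng.normal(0, 4, (h, w, 3))
    img[masks["preexisting"]] = (240, 205, 215)
    img[masks["necrosis"]] = (242, 214, 218)
    img[masks["bleeding"]] = (170, 40, 50)
    img += ndimage.gaussian_filter(rng.normal(0, 12, (h, w)), 6)[..., None]

    dens = np.asarray(config.subtype_density_per_mm2)
    density_mm2 = np.tensordot(dens, weights, axes=(0, 0))
    density_mm2 = density_mm2 * np.exp(config.density_risk_gamma * risk)
    density_px = density_mm2 * config.mm2_per_px

    # per-pixel mean nucleus area: subtype-weighted (proneural smallest)
    area_field = np.tensordot(np.asarray(config.subtype_nucleus_area_um2),
                              weights, axes=(0, 0)) / config.microns_per_px ** 2
    area_px_mean = float(max(config.subtype_nucleus_area_um2)
                         / config.microns_per_px ** 2)
    r_eq = np.sqrt(area_px_mean / np.pi)
    min_dist = 2.3 * r_eq

    ecc_field = np.tensordot(np.asarray(config.subtype_eccentricity),
                             weights, axes=(0, 0))

    truth_points = {}
    # tumor nuclei
    pts = _place_points(density_px, scene.tumor, rng, min_dist=min_dist)
    truth_points["tumor"] = pts
    if len(pts):
        ix = pts[:, 0].astype(int)
        iy = pts[:, 1].astype(int)
        sigma = (config.shape_sigma_base
                 + config.shape_sigma_risk / (1 + np.exp(-risk[iy, ix])))
        areas = area_field[iy, ix] * np.exp(
            rng.standard_normal(len(pts)) * sigma - sigma ** 2 / 2)
        eccs = np.clip(ecc_field[iy, ix] + rng.normal(0, 0.08, len(pts)),
                       0, 0.95)
        _draw_nuclei(img, pts, areas, eccs, rng)
    # sparse nuclei in preexisting brain and necrotic debris
    for name, d_mm2, ecc, color in (
            ("preexisting", config.preexisting_density_per_mm2, 0.3, (80, 60, 120)),
            ("necrosis", config.necrosis_density_per_mm2, 0.5, (120, 100, 140))):
        m = masks[name]
        if not m.any():
            truth_points[name] = np.empty((0, 2))
            continue
        d_px = np.full((h, w), d_mm2 * config.mm2_per_px)
        pts2 = _place_points(d_px, m, rng, min_dist=min_dist)
        truth_points[name] = pts2
        if len(pts2):
            areas = 0.7 * area_px_mean * np.exp(
                rng.standard_normal(len(pts2)) * 0.15)
            eccs = np.clip(rng.normal(ecc, 0.05, len(pts2)), 0, 0.9)
            _draw_nuclei(img, pts2, areas, eccs, rng, color=color)

    slide = SlidePackage(
        image=np.clip(img, 0, 255).astype(np.uint8),
        masks={k: v for k, v in masks.items()},
        microns_per_px=config.microns_per_px,
        slide_id=f"{patient.patient_id}_he",
        patient_id=patient.patient_id)
    if return_truth:
        return slide, {"scene": scene, "nuclei": truth_points}
    return slide


def render_striped_slide(config: SynthConfig, rng: np.random.Generator,
                         stripe_frac: float = 0.4, risk_amp: float = 1.5,
                         mixture: SubtypeMixture | None = None):
    """A slide with a planted high-risk vertical stripe.

    The latent-risk field is ``+risk_amp`` inside a stripe occupying the
    rightmost ``stripe_frac`` of the canvas and ``-risk_amp`` outside; no
    other region structure is used.  Returns ``(slide, stripe_mask)``.
    """
    h, w = config.canvas_px
    cfg = replace(config, necrosis_area_frac=0.0, bleeding_area_frac=0.0,
                  infiltration_band_frac=0.0)
    mixture = mixture or SubtypeMixture(1 / 3, 1 / 3, 1 / 3)
    patient = LatentPatient(
        patient_id="stripe", mixture=mixture, latent_risk=0.0,
        age_years=60.0, sex="female", tmz=False,
        surv_time_years=1.0, event=True)
    stripe = np.zeros((h, w), bool)
    stripe[:, int((1 - stripe_frac) * w):] = True
    risk_field = np.where(stripe, risk_amp, -risk_amp)
    scene = build_scene(patient, cfg, rng, risk_field=risk_field)
    slide = render_slide(patient, cfg, rng, scene=scene)
    return slide, stripe


# --------------------------------------------------------------------------
# Marker maps
# --------------------------------------------------------------------------

@dataclass
class MarkerMap:
    """Positive-cell centroids and, for area markers, a stained-area mask."""

    marker: str
    points: pd.DataFrame                 # columns x_px, y_px, marker
    stained_mask: np.ndarray | None = None


def render_marker_map(patient: LatentPatient, marker: str,
                      config: SynthConfig, rng: np.random.Generator,
                      scene: SlideScene | None = None) -> MarkerMap:
    """Simulate an immunomarker readout for one slide.

    Point markers (CD3, CD8, CD68, CD163, Ki67) are Poisson point processes
    restricted to tumor tissue with intensity equal to the subtype-weighted
    per-subtype median; the CD8 intensity is additionally scaled by
    ``exp(-gamma * risk)``, depleting T cells in high-risk areas.  Area
    markers (HLA-DR, CD34) return a stained-area mask whose tumor-area
    fraction matches the subtype-weighted percentage.
    """
    if marker not in MARKERS:
        raise ValueError(f"unknown marker {marker!r}; expected one of {MARKERS}")
    if scene is None:
        scene = build_scene(patient, config, rng)
    h, w = config.canvas_px
    if marker in POINT_MARKERS:
        med = np.asarray(config.marker_point_density[marker])
        lam_mm2 = np.tensordot(med, scene.weights, axes=(0, 0))
        if marker == "CD8":
            lam_mm2 = lam_mm2 * np.exp(-config.cd8_risk_gamma * scene.risk_field)
        pts = _place_points(lam_mm2 * config.mm2_per_px, scene.tumor, rng)
        df = pd.DataFrame({"x_px": pts[:, 0], "y_px": pts[:, 1],
                           "marker": marker})
        return MarkerMap(marker=marker, points=df)
    med = np.asarray(config.marker_area_percent[marker]) / 100.0
    frac_field = np.tensordot(med, scene.weights, axes=(0, 0))
    target = float(frac_field[scene.tumor].mean()) if scene.tumor.any() else 0.0
    noise = ndimage.gaussian_filter(rng.standard_normal((h, w)), 4)
    stained = np.zeros((h, w), bool)
    if target > 0 and scene.tumor.any():
        thr = np.quantile(noise[scene.tumor], target)
        stained = (noise <= thr) & scene.tumor
    df = pd.DataFrame({"x_px": [], "y_px": [], "marker": []})
    return MarkerMap(marker=marker, points=df, stained_mask=stained)


# --------------------------------------------------------------------------
# Cohort assembly and I/O
# --------------------------------------------------------------------------

CLINICAL_COLUMNS = ["patient_id", "age_years", "sex", "tmz",
                    "surv_time_years", "event", "frac_classical",
                    "frac_mesenchymal", "frac_proneural"]


@dataclass
class CohortBundle:
    """A generated cohort: patients, slides, marker maps, clinical table."""

    config: SynthConfig
    patients: list
    clinical: pd.DataFrame
    slides: dict = field(default_factory=dict)      # patient_id -> SlidePackage
    truths: dict = field(default_factory=dict)      # patient_id -> truth dict
    markers: dict = field(default_factory=dict)     # (patient_id, marker) -> MarkerMap

    def patient(self, pid: str) -> LatentPatient:
        return next(p for p in self.patients if p.patient_id == pid)

    def write(self, out_dir) -> None:
        """Write clinical CSV, slide/mask PNGs and marker CSVs."""
        import imageio.v3 as iio
        from pathlib import Path

        out = Path(out_dir)
        try:
            (out / "slides").mkdir(parents=True, exist_ok=True)
            (out / "masks").mkdir(exist_ok=True)
            (out / "markers").mkdir(exist_ok=True)
            self.clinical.to_csv(out / "clinical.csv", index=False)
            for pid, slide in self.slides.items():
                iio.imwrite(out / "slides" / f"{pid}.png", slide.image)
                for name, m in slide.masks.items():
                    iio.imwrite(out / "masks" / f"{pid}_{name}.png",
                                (m.astype(np.uint8) * 255))
            for (pid, marker), mm in self.markers.items():
                mm.points.to_csv(out / "markers" / f"{pid}_{marker}.csv",
                                 index=False)
                if mm.stained_mask is not None:
                    iio.imwrite(out / "markers" / f"{pid}_{marker}_area.png",
                                mm.stained_mask.astype(np.uint8) * 255)
        except OSError as exc:
            raise OSError(f"cohort write failed under {out}: {exc}") from exc


def clinical_table(patients) -> pd.DataFrame:
    rows = []
    for p in patients:
        v = p.mixture.as_array()
        rows.append({
            "patient_id": p.patient_id, "age_years": p.age_years,
            "sex": p.sex, "tmz": p.tmz,
            "surv_time_years": p.surv_time_years, "event": p.event,
            "frac_classical": v[0], "frac_mesenchymal": v[1],
            "frac_proneural": v[2]})
    return pd.DataFrame(rows, columns=CLINICAL_COLUMNS)


def generate_cohort(config: SynthConfig, render: bool = True,
                    markers=("CD8", "CD68"), out_dir=None) -> CohortBundle:
    """Generate a full synthetic cohort.

    With ``render=False`` only the clinical table and latent patients are
    produced (fast path for survival-level experiments).  ``markers`` lists
    the immunomarker maps to simulate per patient.
    """
    if config.n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    patients = [sample_patient(config, f"P{i:03d}")
                for i in range(config.n_patients)]
    bundle = CohortBundle(config=config, patients=patients,
                          clinical=clinical_table(patients))
    if render:
        for p in patients:
            rng = patient_rng(config, p.patient_id, stream=1)
            slide, truth = render_slide(p, config, rng, return_truth=True)
            bundle.slides[p.patient_id] = slide
            bundle.truths[p.patient_id] = truth
            mrng = patient_rng(config, p.patient_id, stream=2)
            for m in markers:
                bundle.markers[(p.patient_id, m)] = render_marker_map(
                    p, m, config, mrng, scene=truth["scene"])
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
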