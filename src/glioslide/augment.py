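"""Cropping and H&E-specific stochastic augmentation for training tiles.

Inference uses a deterministic center crop with no augmentation; training
uses a random crop plus a randomized chain of histology-appropriate
transforms: 90-degree rotations and flips, brightness/contrast jitter,
hue–saturation–value jitter, multiplicative/additive jitter in the
stain-deconvolved (hematoxylin–eosin–DAB) space, Gaussian blur and noise,
and JPEG compression artifacts.  Every magnitude is a policy field; the
identity policy (all apply probabilities zero) returns the input bitwise
unchanged.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.color import hed2rgb, hsv2rgb, rgb2hed, rgb2hsv


@dataclass
class AugmentPolicy:
    """Magnitudes and per-transform application probabilities.

    ``apply_prob`` maps transform name (``"geometric"``, ``"brightness"``,
    ``"hsv"``, ``"stain"``, ``"blur"``, ``"noise"``, ``"jpeg"``) to a
    probability in [0, 1]; missing keys default to 0.
    """

    flip: bool = True
    rot90: bool = True
    brightness_delta: float = 0.1   # fraction of dynamic range
    contrast_range: tuple = (0.9, 1.1)
    hue_sigma: float = 0.02
    saturation_sigma: float = 0.05
    value_sigma: float = 0.05
    stain_jitter_alpha: float = 0.05  # multiplicative, per HED channel
    stain_jitter_beta: float = 0.01   # additive, per HED channel
    blur_sigma_max: float = 1.0
    noise_sigma_max: float = 5.0      # uint8 counts
    jpeg_quality_range: tuple = (70, 95)
    apply_prob: dict = field(default_factory=dict)

    def __post_init__(self):
        for k, p in self.apply_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"apply_prob[{k!r}] = {p} outside [0, 1]")
        lo, hi = self.jpeg_quality_range
        if not (1 <= lo <= hi <= 100):
            raise ValueError("jpeg_quality_range must lie within [1, 100]")

    def prob(self, name: str) -> float:
        return self.apply_prob.get(name, 0.0)

    @classmethod
    def identity(cls) -> "AugmentPolicy":
        return cls(apply_prob={})

    @classmethod
    def default(cls) -> "AugmentPolicy":
        """Moderate histology policy: geometry always, photometric sometimes."""
        return cls(apply_prob={
            "geometric": 1.0, "brightness": 0.5, "hsv": 0.5, "stain": 0.5,
            "blur": 0.25, "noise": 0.25, "jpeg": 0.25,
        })

    @classmethod
    def geometric_only(cls) -> "AugmentPolicy":
        """Rotations/flips only; preserves the pixel-value multiset."""
        return cls(apply_prob={"geometric": 1.0})


def _check_rgb(image: np.ndarray) -> None:
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected RGB (H, W, 3) image, got {image.shape}")


def random_crop(tile_image: np.ndarray, out_px: int, rng: np.random.Generator):
    """Axis-aligned square crop at a uniformly drawn offset."""
    _check_rgb(tile_image)
    h, w = tile_image.shape[:2]
    if out_px > min(h, w):
        raise ValueError(f"crop {out_px} exceeds input {(h, w)}")
    y0 = int(rng.integers(0, h - out_px + 1))
    x0 = int(rng.integers(0, w - out_px + 1))
    return tile_image[y0:y0 + out_px, x0:x0 + out_px]


def center_crop(tile_image: np.ndarray, out_px: int):
    """Deterministic centered crop; odd margins floor toward the origin."""
    _check_rgb(tile_image)
    h, w = tile_image.shape[:2]
    if out_px > min(h, w):
        raise ValueError(f"crop {out_px} exceeds input {(h, w)}")
    y0 = (h - out_px) // 2
    x0 = (w - out_px) // 2
    return tile_image[y0:y0 + out_px, x0:x0 + out_px]


def _geometric(img, policy, rng):
    if policy.rot90:
        img = np.rot90(img, int(rng.integers(0, 4)))
    if policy.flip:
        if rng.random() < 0.5:
            img = img[:, ::-1]
        if rng.random() < 0.5:
            img = img[::-1, :]
    return np.ascontiguousarray(img)


def _brightness_contrast(img, policy, rng):
    f = img.astype(np.float32)
    delta = rng.uniform(-policy.brightness_delta, policy.brightness_delta) * 255
    lo, hi = policy.contrast_range
    gain = rng.uniform(lo, hi)
    return (f - 127.5) * gain + 127.5 + delta


def _hsv_jitter(img, policy, rng):
    hsv = rgb2hsv(np.clip(img, 0, 255) / 255.0)
    hsv[..., 0] = (hsv[..., 0] + rng.normal(0, policy.hue_sigma)) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * (1 + rng.normal(0, policy.saturation_sigma)), 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] * (1 + rng.normal(0, policy.value_sigma)), 0, 1)
    return hsv2rgb(hsv) * 255.0


def _stain_jitter(img, policy, rng):
    hed = rgb2hed(np.clip(img, 0, 255) / 255.0)
    alpha = 1 + rng.normal(0, policy.stain_jitter_alpha, size=3)
    beta = rng.normal(0, policy.stain_jitter_beta, size=3)
    return hed2rgb(hed * alpha + beta) * 255.0


def _jpeg(img, policy, rng):
    lo, hi = policy.jpeg_quality_range
    q = int(rng.integers(lo, hi + 1))
    buf = io.BytesIO()
    Image.fromarray(np.clip(img, 0, 255).astype(np.uint8)).save(
        buf, format="JPEG", quality=q)
    buf.seek(0)
    return np.asarray(Image.open(buf)).astype(np.float32)


def he_augment(image: np.ndarray, policy: AugmentPolicy,
               rng: np.random.Generator) -> np.ndarray:
    """Apply the stochastic augmentation chain to a uint8 RGB tile.

    Transforms fire independently with their configured probabilities, in a
    fixed order (geometric, photometric, degradation).  Output has the same
    shape and dtype range as the input.
    """
    _check_rgb(image)
    out = image
    if rng.random() < policy.prob("geometric"):
        out = _geometric(out, policy, rng)
    touched = False
    f = out.astype(np.float32)
    if rng.random() < policy.prob("brightness"):
        f = _brightness_contrast(f, policy, rng)
        touched = True
    if rng.random() < policy.prob("hsv"):
        f = _hsv_jitter(f, policy, rng)
        touched = True
    if rng.random() < policy.prob("stain"):
        f = _stain_jitter(f, policy, rng)
        touched = True
    if rng.random() < policy.prob("blur"):
        sigma = rng.uniform(0, policy.blur_sigma_max)
        if sigma > 0:
            f = np.stack([gaussian_filter(f[..., c], sigma) for c in range(3)],
                         axis=-1)
        touched = True
    if rng.random() < policy.prob("noise"):
        sigma = rng.uniform(0, policy.noise_sigma_max)
        f = f + rng.normal(0, sigma, size=f.shape)
        touched = True
    if rng.random() < policy.prob("jpeg"):
        f = _jpeg(f, policy, rng)
        touched = True
    if not touched:
        return out if out.dtype == image.dtype else out.astype(image.dtype)
    return np.clip(np.rint(f), 0, 255).astype(np.uint8)
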