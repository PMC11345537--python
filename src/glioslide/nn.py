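"""Minimal convolutional network with explicit gradients.

The pipeline trains a frozen feature backbone with a task head on top:
either a 3-neuron softmax head for transcriptional-subtype fractions or a
1-neuron linear head whose output enters a Cox partial-likelihood loss.
For desk-scale experiments the backbone is a small strided CNN
(``tiny_test``) implemented here in NumPy with hand-written backward
passes, so training needs no deep-learning framework.  The full-size
depthwise-separable architecture (``xception_shaped``, 2048-wide pooled
features) is represented by its exact layer table for parameter accounting
and feature-width arithmetic; its weights are not shipped.

Layers follow a simple protocol: ``forward(x)`` caches what backward needs,
``backward(grad)`` returns the input gradient and accumulates parameter
gradients in ``.grads`` parallel to ``.params``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# --------------------------------------------------------------------------
# Layer-table accounting for the full-size backbone
# --------------------------------------------------------------------------

#: feature width of the global-pooled penultimate layer, per backbone
FEATURE_DIM = {"xception_shaped": 2048, "tiny_test": 56}


def _sepconv(cin, cout, k=3):
    """(depthwise kernel, pointwise kernel) parameter counts, no biases."""
    return k * k * cin, cin * cout


def _bn(c):
    """Batch-norm parameter count: gamma, beta, running mean, running var."""
    return 4 * c


def _xception_layer_table():
    """Every parameter-bearing layer of the headless backbone, in order.

    Entries are (name, parameter_count, is_final_two_sepconv_kernels).
    Convolutions carry no biases; batch norm contributes 4 numbers per
    channel (two learned, two running buffers).
    """
    rows = []

    def conv(name, cin, cout, k):
        rows.append((name, k * k * cin * cout, False))
        rows.append((name + "_bn", _bn(cout), False))

    def sep(name, cin, cout, final=False):
        dw, pw = _sepconv(cin, cout)
        rows.append((name + "_dw", dw, final))
        rows.append((name + "_pw", pw, final))
        rows.append((name + "_bn", _bn(cout), False))

    def residual(name, cin, cout):
        rows.append((name, cin * cout, False))  # 1x1 projection
        rows.append((name + "_bn", _bn(cout), False))

    # entry flow
    conv("conv1", 3, 32, 3)
    conv("conv2", 32, 64, 3)
    for i, (cin, cout) in enumerate([(64, 128), (128, 256), (256, 728)], 1):
        sep(f"block{i}_sep1", cin, cout)
        sep(f"block{i}_sep2", cout, cout)
        residual(f"block{i}_res", cin, cout)
    # middle flow: 8 blocks of 3 separable convs at width 728
    for b in range(4, 12):
        for s in range(1, 4):
            sep(f"block{b}_sep{s}", 728, 728)
    # exit flow
    sep("block12_sep1", 728, 728)
    sep("block12_sep2", 728, 1024)
    residual("block12_res", 728, 1024)
    sep("exit_sep1", 1024, 1536, final=True)
    sep("exit_sep2", 1536, 2048, final=True)
    return rows


def _tiny_layer_table():
    """Layer table of the desk-scale backbone (conv kernels + biases);
    the finetune flag marks layers unfrozen by default fine-tuning."""
    return [
        ("conv1_w", 3 * 3 * 3 * 24, True), ("conv1_b", 24, True),
        ("conv2_w", 3 * 3 * 24 * 16, True), ("conv2_b", 16, True),
    ]


@dataclass
class BackboneSpec:
    """Identity and geometry of a feature backbone."""

    name: str = "tiny_test"
    input_px: int = 56
    frozen: bool = True
    finetune_last_n_convs: int = 2

    def __post_init__(self):
        if self.name not in FEATURE_DIM:
            raise ValueError(f"unknown backbone {self.name!r}")

    @property
    def feature_dim(self) -> int:
        return FEATURE_DIM[self.name]


def count_parameters(backbone: BackboneSpec, stage: str) -> int:
    """Exact parameter counts from the backbone layer table.

    ``total_no_top`` counts every parameter of the headless backbone,
    including batch-normalization running-statistics buffers.
    ``finetune_trainable`` counts only the kernels unfrozen during
    fine-tuning: for the full-size backbone, the depthwise and pointwise
    kernels of the final two separable convolutions (their normalization
    parameters stay frozen).
    """
    if backbone.name == "xception_shaped":
        rows = _xception_layer_table()
    elif backbone.name == "tiny_test":
        rows = _tiny_layer_table()
    else:  # pragma: no cover - guarded by BackboneSpec
        raise ValueError(f"unknown backbone {backbone.name!r}")
    if stage == "total_no_top":
        return sum(n for _, n, _ in rows)
    if stage == "finetune_trainable":
        return sum(n for _, n, fin in rows if fin)
    raise ValueError(f"unknown stage {stage!r}")


def concat_feature_width(specs) -> int:
    """Width of the per-tile feature vector formed by concatenating the
    global-pooled penultimate activations of several models."""
    return sum(
        (s if isinstance(s, BackboneSpec) else BackboneSpec(s)).feature_dim
        for s in specs)


# --------------------------------------------------------------------------
# Layers
# --------------------------------------------------------------------------

def _im2col(x, k, stride):
    """(N, H, W, C) -> (N, Ho, Wo, k*k*C) patch matrix (valid padding)."""
    n, h, w, c = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    s = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, shape=(n, ho, wo, k, k, c),
        strides=(s[0], s[1] * stride, s[2] * stride, s[1], s[2], s[3]),
        writeable=False)
    return windows.reshape(n, ho, wo, k * k * c), ho, wo


class Conv2D:
    """Valid-padding strided convolution with bias and optional ReLU."""

    def __init__(self, cin, cout, k=3, stride=2, relu=True, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (k * k * cin))
        self.w = (rng.standard_normal((k * k * cin, cout)) * scale).astype(np.float64)
        self.b = np.zeros(cout)
        self.k, self.stride, self.relu = k, stride, relu
        self.trainable = False
        self.grads = None
        self._cache = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        cols, ho, wo = _im2col(x, self.k, self.stride)
        z = cols @ self.w + self.b
        out = np.maximum(z, 0.0) if self.relu else z
        self._cache = (x.shape, cols, z)
        return out

    def backward(self, grad):
        x_shape, cols, z = self._cache
        if self.relu:
            grad = grad * (z > 0)
        n, ho, wo, cout = grad.shape
        g2 = grad.reshape(-1, cout)
        if self.trainable:
            c2 = cols.reshape(-1, cols.shape[-1])
            self.grads = [c2.T @ g2, g2.sum(axis=0)]
        # input gradient via col2im
        gcols = (g2 @ self.w.T).reshape(n, ho, wo, self.k, self.k, -1)
        dx = np.zeros(x_shape)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dx[:, i:i + ho * s:s, j:j + wo * s:s, :] += gcols[:, :, :, i, j, :]
        return dx


class Dense:
    """Fully connected head layer."""

    def __init__(self, fin, fout, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = rng.standard_normal((fin, fout)) * np.sqrt(1.0 / fin)
        self.b = np.zeros(fout)
        self.trainable = True
        self.grads = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        if self.trainable:
            self.grads = [self._x.T @ grad, grad.sum(axis=0)]
        return grad @ self.w.T


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def oriented_filter_bank() -> np.ndarray:
    """Fixed 3x3x3x24 first-layer filters: two color probes (luminance and
    a hematoxylin-direction contrast) times six spatial kernels (DC, two
    axis edges, two diagonal edges, Laplacian), each in both signs.

    This plays the role generic pretrained early layers play in transfer
    learning: a frozen, task-agnostic edge/blob vocabulary.
    """
    spatial = [
        np.full((3, 3), 1 / 9),
        np.array([[-1, 0, 1]] * 3) / 6.0,
        (np.array([[-1, 0, 1]] * 3) / 6.0).T,
        np.array([[0, 1, 2], [-1, 0, 1], [-2, -1, 0]]) / 8.0,
        np.array([[2, 1, 0], [1, 0, -1], [0, -1, -2]]) / 8.0,
        np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]]) / 4.0,
    ]
    colors = [np.array([1.0, 1.0, 1.0]) / 3.0,
              np.array([-0.6, -0.2, 0.9])]
    filters = []
    for cv in colors:
        for sk in spatial:
            for sign in (1.0, -1.0):
                filters.append(sign * 3.0 * sk[:, :, None] * cv[None, None, :])
    return np.stack(filters, axis=-1)


class TinyModel:
    """Tiny backbone + task head.

    ``head`` is ``"ts"`` (3-way softmax over subtype fractions) or ``"rs"``
    (single linear risk neuron).  The backbone is two strided convolutions:
    a fixed oriented-filter stem (the desk-scale stand-in for generic
    pretrained early layers) and a randomly initialized mixing layer.  The
    pooled feature vector concatenates the mean-pooled stem activations
    with the mean- and energy-pooled (squared-activation) outputs of the
    second convolution, so first- and second-order tile statistics are both
    linearly available to the head.  Feature scales are frozen from the
    first batch the model sees (a batch-norm-style calibration), after
    which the model is a fixed deterministic function.

    Both convolutions start frozen; :meth:`set_finetune` unfreezes the last
    ``n`` of them for phase-2 training.
    """

    N_STEM = 24
    N_MIX = 16

    def __init__(self, head: str, spec: BackboneSpec | None = None, seed: int = 0):
        if head not in ("ts", "rs"):
            raise ValueError(f"unknown head {head!r}")
        spec = spec or BackboneSpec("tiny_test")
        if spec.name != "tiny_test":
            raise ValueError("only the tiny_test backbone has trainable weights")
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.head_kind = head
        conv1 = Conv2D(3, self.N_STEM, rng=rng)
        conv1.w[:] = oriented_filter_bank().reshape(-1, self.N_STEM)
        conv2 = Conv2D(self.N_STEM, self.N_MIX, rng=rng)
        self.conv_layers = [conv1, conv2]
        self.head = Dense(spec.feature_dim, 3 if head == "ts" else 1, rng=rng)
        self.head.w[:] = 0.0  # neutral head at initialization
        self._feat_loc = None
        self._feat_scale = None

    # -- structure ---------------------------------------------------------
    @property
    def layers(self):
        return [*self.conv_layers, self.head]

    def set_finetune(self, last_n_convs: int) -> None:
        for layer in self.conv_layers:
            layer.trainable = False
        if last_n_convs > 0:
            for layer in self.conv_layers[-last_n_convs:]:
                layer.trainable = True

    def trainable_layers(self):
        return [l for l in self.layers if getattr(l, "trainable", False)]

    # -- computation -------------------------------------------------------
    def _prep(self, images):
        x = np.asarray(images, np.float64)
        if x.max() > 1.5:
            x = x / 255.0
        return x

    def _raw_features(self, images):
        x = self._prep(images)
        h1 = self.conv_layers[0].forward(x)
        h2 = self.conv_layers[1].forward(h1)
        feat = np.concatenate([h1.mean(axis=(1, 2)), h2.mean(axis=(1, 2)),
                               (h2 ** 2).mean(axis=(1, 2))], axis=1)
        self._h1, self._h2 = h1, h2
        return feat

    def features(self, images) -> np.ndarray:
        """Global-pooled penultimate activations, shape (N, feature_dim).

        The first call calibrates per-feature location/scale (frozen
        thereafter) so all pooled statistics reach the head on comparable
        scales.
        """
        feat = self._raw_features(images)
        if self._feat_scale is None:
            self._feat_loc = feat.mean(axis=0)
            self._feat_scale = feat.std(axis=0) + 1e-6
        return (feat - self._feat_loc) / self._feat_scale

    def forward(self, images) -> np.ndarray:
        z = self.head.forward(self.features(images))
        if self.head_kind == "ts":
            self._last_probs = softmax(z)
            return self._last_probs
        return z[:, 0]

    def predict(self, images) -> np.ndarray:
        return self.forward(images)

    def backward(self, grad_out) -> None:
        """Backpropagate d(loss)/d(model output) through head and any
        unfrozen convolutions, filling each trainable layer's ``.grads``."""
        if self.head_kind == "ts":
            # grad through softmax: J^T g
            p = self._last_probs
            g = p * (grad_out - (grad_out * p).sum(axis=1, keepdims=True))
        else:
            g = np.asarray(grad_out)[:, None]
        g = self.head.backward(g)
        if not any(l.trainable for l in self.conv_layers):
            return
        g = g / self._feat_scale[None, :]
        conv1, conv2 = self.conv_layers
        h1, h2 = self._h1, self._h2
        n1 = self.N_STEM
        n2 = self.N_MIX
        g1m, g2m, g2e = g[:, :n1], g[:, n1:n1 + n2], g[:, n1 + n2:]
        area2 = h2.shape[1] * h2.shape[2]
        gh2 = (g2m[:, None, None, :] + 2.0 * h2 * g2e[:, None, None, :]) / area2
        gh1 = conv2.backward(gh2)
        area1 = h1.shape[1] * h1.shape[2]
        gh1 = gh1 + g1m[:, None, None, :] / area1
        conv1.backward(gh1)

    def parameter_hash(self, convs_only: bool = True) -> int:
        import hashlib
        h = hashlib.sha256()
        layers = self.conv_layers if convs_only else self.layers
        for layer in layers:
            for p in layer.params:
                h.update(np.ascontiguousarray(p).tobytes())
        return int.from_bytes(h.digest()[:8], "big")


class Adam:
    """Adam optimizer over the trainable layers of a model."""

    def __init__(self, model: TinyModel, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.state = {}
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        for li, layer in enumerate(self.model.layers):
            if not getattr(layer, "trainable", False) or layer.grads is None:
                continue
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                key = (li, pi)
                if key not in self.state:
                    self.state[key] = (np.zeros_like(p), np.zeros_like(p))
                m, v = self.state[key]
                m[:] = self.beta1 * m + (1 - self.beta1) * g
                v[:] = self.beta2 * v + (1 - self.beta2) * g * g
                mh = m / (1 - self.beta1 ** self.t)
                vh = v / (1 - self.beta2 ** self.t)
                p -= lr * mh / (np.sqrt(vh) + self.eps)
            layer.grads = None
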