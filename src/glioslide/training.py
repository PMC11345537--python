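"""Two-head training: Cox partial-likelihood risk head and subtype head.

The survival head is a single linear neuron trained with the negative log
partial likelihood of the Cox proportional-hazards model, computed within
each mini-batch (risk sets are batch-internal) with Breslow handling of
tied event times.  The subtype head is a 3-neuron softmax trained with mean
squared error against the patient's subtype fraction vector.

Training follows a two-phase schedule: phase 1 keeps the backbone frozen
and fits only the head; phase 2 unfreezes the last convolution layers at a
lower learning rate.  Batches are assembled by a cycle sampler that draws
one random tile per patient per pass through the cohort, so slides with
many tiles do not dominate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .augment import AugmentPolicy, center_crop, he_augment, random_crop
from .nn import Adam, BackboneSpec, TinyModel
from .stats import harrell_c


# --------------------------------------------------------------------------
# Losses
# --------------------------------------------------------------------------

@dataclass
class SurvivalBatch:
    """Scores, follow-up times and event indicators for one mini-batch."""

    scores: np.ndarray
    times: np.ndarray
    events: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, float)
        self.times = np.asarray(self.times, float)
        self.events = np.asarray(self.events, bool)
        if not (len(self.scores) == len(self.times) == len(self.events)):
            raise ValueError("scores, times, events must have equal length")
        if np.any(self.times <= 0):
            raise ValueError("follow-up times must be positive")


def cox_ph_loss(batch: SurvivalBatch) -> float:
    """Negative log Cox partial likelihood, averaged over events.

    L = -(1/d) * sum_{i: event} [ r_i - log sum_{j: t_j >= t_i} exp(r_j) ]

    with d the number of events in the batch.  Risk sets are formed within
    the batch; tied event times share a risk set (Breslow).  The inner sum
    uses a max-shifted log-sum-exp.  A batch with no events contributes 0.
    """
    loss, _ = cox_ph_loss_grad(batch)
    return loss


def cox_ph_loss_grad(batch: SurvivalBatch):
    """Loss and its gradient with respect to the scores."""
    if len(batch.scores) == 0:
        raise ValueError("empty batch")
    r, t, e = batch.scores, batch.times, batch.events
    d = int(e.sum())
    if d == 0:
        return 0.0, np.zeros_like(r)
    shift = r.max()
    er = np.exp(r - shift)
    # at_risk[i, j] = 1 if t_j >= t_i  (row i = event i's risk set)
    at_risk = t[None, :] >= t[:, None]
    denom = at_risk @ er                       # sum over risk set, shifted
    ev = np.flatnonzero(e)
    loss = -(r[ev] - (np.log(denom[ev]) + shift)).sum() / d
    # dL/dr_k = -(1/d) [ e_k - sum_{i in events, t_k >= t_i} er_k / denom_i ]
    w = np.zeros_like(r)
    w[ev] = 1.0 / denom[ev]
    grad = -(e.astype(float) - er * (at_risk[ev].T @ (1.0 / denom[ev]))) / d
    return float(loss), grad


def subtype_mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean squared error between predicted and true subtype fractions.

    Accepts single 3-vectors or (N, 3) batches; the batch value is the mean
    over all components, so it equals the mean of per-sample losses.
    """
    pred = np.asarray(pred, float)
    target = np.asarray(target, float)
    if pred.shape != target.shape:
        raise ValueError("shape mismatch")
    return float(np.mean((pred - target) ** 2))


# --------------------------------------------------------------------------
# Folds and sampling
# --------------------------------------------------------------------------

def assign_folds(clinical: pd.DataFrame, k: int = 5, seed: int = 0) -> pd.Series:
    """Stratified cross-validation folds, one label per patient.

    Stratification key: event indicator x survival-time quartile x
    (predominant subtype when fraction columns are present, else a single
    stratum).  Patients are shuffled within strata and dealt cyclically, so
    fold sizes differ by at most one.
    """
    n = len(clinical)
    if k > n:
        raise ValueError(f"k={k} exceeds number of patients {n}")
    rng = np.random.default_rng(seed)
    df = clinical.reset_index(drop=True)
    quart = pd.qcut(df["surv_time_years"], 4, labels=False, duplicates="drop")
    key = df["event"].astype(int).astype(str) + "_" + quart.astype(str)
    frac_cols = ["frac_classical", "frac_mesenchymal", "frac_proneural"]
    if all(c in df.columns for c in frac_cols):
        fr = df[frac_cols].to_numpy(float)
        dom = np.where(fr.max(axis=1) >= 0.70,
                       fr.argmax(axis=1).astype(str), "mixed")
        key = key + "_" + dom
    order = []
    for stratum in sorted(key.unique()):
        idx = np.flatnonzero((key == stratum).to_numpy())
        rng.shuffle(idx)
        order.extend(idx.tolist())
    folds = np.empty(n, int)
    folds[np.array(order)] = np.arange(n) % k
    return pd.Series(folds, index=clinical.index, name="fold")


def cycle_sampler(tiles_per_patient: dict, rng: np.random.Generator):
    """Infinite stream of (patient_id, tile_index) pairs.

    Each cycle shuffles the patients and yields one uniformly drawn tile per
    patient, so over C cycles every patient appears exactly C times.
    """
    patients = sorted(tiles_per_patient)
    for pid in patients:
        if tiles_per_patient[pid] < 1:
            raise ValueError(f"patient {pid!r} has no kept tiles")
    while True:
        order = np.array(patients, dtype=object)
        rng.shuffle(order)
        for pid in order:
            yield pid, int(rng.integers(0, tiles_per_patient[pid]))


# --------------------------------------------------------------------------
# Training data container
# --------------------------------------------------------------------------

@dataclass
class TilePool:
    """In-memory training set: per-patient tile images plus labels.

    ``tiles`` maps patient_id -> uint8 array (n_tiles, H, W, 3).
    ``clinical`` must carry surv_time_years and event; subtype fraction
    columns are required for the ts head.
    """

    tiles: dict
    clinical: pd.DataFrame

    def __post_init__(self):
        self.clinical = self.clinical.set_index(
            self.clinical["patient_id"].astype(str), drop=False)
        missing = [p for p in self.tiles if p not in self.clinical.index]
        if missing:
            raise ValueError(f"patients without clinical rows: {missing}")

    @property
    def patients(self):
        return sorted(self.tiles)

    def counts(self):
        return {p: len(v) for p, v in self.tiles.items()}

    def label_rs(self, pid):
        row = self.clinical.loc[pid]
        return float(row["surv_time_years"]), bool(row["event"])

    def label_ts(self, pid):
        row = self.clinical.loc[pid]
        return row[["frac_classical", "frac_mesenchymal",
                    "frac_proneural"]].to_numpy(float)


@dataclass
class TrainConfig:
    """Schedule and optimizer settings for two-phase training.

    Defaults mirror the full-size protocol: 25 epochs of 150 steps at batch
    64 with Adam (lr 1e-3, staircase decay 0.9 every 400 steps) for phase 1,
    then 10 fine-tuning epochs at lr 1e-4 with decay 0.8, with 20 cached
    validation batches scored once per epoch.  ``desk()`` is the scaled-down
    profile used throughout the test-size experiments.
    """

    phase1_epochs: int = 25
    steps_per_epoch: int = 150
    batch: int = 64
    lr1: float = 0.001
    decay1: float = 0.9
    decay_every: int = 400
    phase2_epochs: int = 10
    lr2: float = 0.0001
    decay2: float = 0.8
    n_val_batches: int = 20
    crop_px: int = 512
    finetune_last_n_convs: int = 2
    policy: AugmentPolicy = field(default_factory=AugmentPolicy.geometric_only)
    seed: int = 0

    def __post_init__(self):
        for name in ("phase1_epochs", "steps_per_epoch", "batch",
                     "phase2_epochs", "n_val_batches", "decay_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.decay1 < 1 and 0 < self.decay2 < 1):
            raise ValueError("decay factors must lie in (0, 1)")

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        base = dict(phase1_epochs=5, steps_per_epoch=60, batch=64,
                    lr1=0.003, phase2_epochs=2, lr2=0.0001,
                    n_val_batches=10, crop_px=56, finetune_last_n_convs=1)
        base.update(overrides)
        return cls(**base)


def learning_rate(config: TrainConfig, phase: int, step: int) -> float:
    """Staircase-decayed learning rate at a (0-based) step within a phase."""
    if phase == 1:
        return config.lr1 * config.decay1 ** (step // config.decay_every)
    return config.lr2 * config.decay2 ** (step // config.decay_every)


def _make_batch(pool: TilePool, draws, head: str, config: TrainConfig,
                rng, train: bool):
    imgs, labels = [], []
    for pid, ti in draws:
        img = pool.tiles[pid][ti]
        if train:
            img = random_crop(img, config.crop_px, rng)
            img = he_augment(img, config.policy, rng)
        else:
            img = center_crop(img, config.crop_px)
        imgs.append(img)
        labels.append(pool.label_ts(pid) if head == "ts" else pool.label_rs(pid))
    x = np.stack(imgs)
    if head == "ts":
        return x, np.stack(labels)
    t = np.array([l[0] for l in labels])
    e = np.array([l[1] for l in labels])
    return x, (t, e)


def _val_metric(model: TinyModel, head: str, val_batches):
    preds, targets = [], []
    for x, y in val_batches:
        preds.append(model.predict(x))
        targets.append(y)
    if head == "ts":
        return subtype_mse_loss(np.concatenate(preds), np.concatenate(targets))
    scores = np.concatenate(preds)
    t = np.concatenate([y[0] for y in targets])
    e = np.concatenate([y[1] for y in targets])
    return harrell_c(t, e, scores)


def train_two_phase(train_pool: TilePool, val_pool: TilePool,
                    backbone: BackboneSpec, head: str,
                    config: TrainConfig):
    """Train a head on a frozen backbone, then fine-tune the last convs.

    Returns ``(model, history)`` where ``history`` is a DataFrame with one
    row per epoch: epoch, phase, lr, train_loss, val_metric (MSE for the
    ts head, concordance for the rs head).  Fully deterministic given
    ``config.seed``.
    """
    if not train_pool.tiles:
        raise ValueError("empty training fold")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7)))
    model = TinyModel(head, backbone, seed=config.seed)
    model.set_finetune(0)
    opt = Adam(model)

    # validation batches cached once, before training
    val_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 11)))
    val_stream = cycle_sampler(val_pool.counts(), val_rng)
    val_batches = []
    for _ in range(config.n_val_batches):
        draws = [next(val_stream) for _ in range(config.batch)]
        val_batches.append(_make_batch(val_pool, draws, head, config,
                                       val_rng, train=False))

    stream = cycle_sampler(train_pool.counts(), rng)
    history = []
    epoch = 0

    def run_phase(phase, n_epochs):
        nonlocal epoch
        step = 0
        for _ in range(n_epochs):
            losses = []
            for _ in range(config.steps_per_epoch):
                draws = [next(stream) for _ in range(config.batch)]
                x, y = _make_batch(train_pool, draws, head, config, rng,
                                   train=True)
                pred = model.forward(x)
                if head == "ts":
                    loss = subtype_mse_loss(pred, y)
                    grad = 2.0 * (pred - y) / pred.size
                else:
                    batch = SurvivalBatch(pred, y[0], y[1])
                    loss, grad = cox_ph_loss_grad(batch)
                model.backward(grad)
                opt.step(learning_rate(config, phase, step))
                losses.append(loss)
                step += 1
            epoch += 1
            history.append({
                "epoch": epoch, "phase": phase,
                "lr": learning_rate(config, phase, step - 1),
                "train_loss": float(np.mean(losses)),
                "val_metric": float(_val_metric(model, head, val_batches)),
            })

    run_phase(1, config.phase1_epochs)
    model.set_finetune(config.finetune_last_n_convs)
    run_phase(2, config.phase2_epochs)
    return model, pd.DataFrame(history)


def extract_features(models, tiles) -> np.ndarray:
    """Concatenate each model's global-pooled penultimate activations.

    ``tiles`` is a (N, H, W, 3) array; the result has one row per tile and
    width equal to the sum of the models' feature dimensions, in model
    order.
    """
    if not models:
        raise ValueError("need at least one model")
    px = {getattr(m.spec, "input_px", None) for m in models}
    if len(px) > 1:
        raise ValueError(f"models disagree on input geometry: {px}")
    return np.concatenate([m.features(tiles) for m in models], axis=1)
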