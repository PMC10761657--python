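"""Training: combined L2 + perceptual loss, K-fold splitting, the train loop.

The loss is ``w_l2 * MSE(pred, target) + w_perc * MSE(F(pred), F(target))``
where ``F`` is a fixed (frozen) convolutional feature extractor.  By default
``F`` is a seed-determined random three-layer network: random fixed features
are a valid structural penalty -- they respond to edges and textures rather
than per-voxel intensity -- and they keep the package hermetic (no external
weight downloads).  A differently parameterised extractor can be supplied
through :class:`LossConfig`.

Optimisation follows the reference protocol: Adam, batch size 5, initial
learning rate 3e-4 annealed to zero with a cosine schedule, one model
trained jointly on slab pairs from *all* short durations against the
reference-duration target.  Cross-validation folds are drawn at patient
level (K = 10 by default) so no patient contributes slabs to both sides of
a fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grad import Adam, Tensor, Conv3d, leaky_relu, mse
from .networks import RestorationNet

__all__ = [
    "LossConfig",
    "TrainConfig",
    "FoldSplit",
    "PerceptualExtractor",
    "combined_loss",
    "make_folds",
    "cosine_lr",
    "train",
]


# ---------------------------------------------------------------------------
# perceptual feature extractor (fixed, frozen)
# ---------------------------------------------------------------------------

class PerceptualExtractor:
    """A frozen random convolutional feature network.

    ``n_layers`` 3x3x3 convolutions with LeakyReLU, He-initialised from
    ``seed`` and never trained.  Gradients flow through it to the prediction
    but its own weights are constant.
    """

    def __init__(self, n_layers: int = 3, channels: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.layers = []
        c_in = 1
        for _ in range(n_layers):
            self.layers.append(Conv3d(c_in, channels, (3, 3, 3), rng=rng,
                                      trainable=False))
            c_in = channels

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for layer in self.layers:
            h = leaky_relu(layer(h), 0.01)
        return h


@dataclass
class LossConfig:
    """Weights and extractor of the combined restoration loss."""
    w_l2: float = 1.0
    w_perc: float = 0.1
    perc_layers: int = 3
    perc_channels: int = 8
    perc_seed: int = 0
    _extractor: PerceptualExtractor | None = field(default=None, repr=False,
                                                   compare=False)

    def __post_init__(self):
        if self.w_l2 < 0 or self.w_perc < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.w_l2 == 0 and self.w_perc == 0:
            raise ValueError("at least one loss weight must be positive")

    @property
    def extractor(self) -> PerceptualExtractor | None:
        if self.w_perc == 0:
            return None
        if self._extractor is None:
            object.__setattr__(self, "_extractor",
                               PerceptualExtractor(self.perc_layers,
                                                   self.perc_channels,
                                                   self.perc_seed))
        return self._extractor


def combined_loss(pred, target, cfg: LossConfig) -> Tensor:
    """``w_l2 * MSE + w_perc * feature-space MSE`` as a scalar graph node."""
    pred_t = pred if isinstance(pred, Tensor) else Tensor(pred)
    target_d = target.data if isinstance(target, Tensor) else np.asarray(target)
    if pred_t.data.shape != target_d.shape:
        raise ValueError("pred and target must have the same shape")
    loss = mse(pred_t, target_d) * cfg.w_l2 if cfg.w_l2 > 0 else None
    if cfg.w_perc > 0:
        F = cfg.extractor
        f_pred = F(pred_t)
        f_target = F(Tensor(target_d))
        perc = mse(f_pred, f_target.data) * cfg.w_perc
        loss = perc if loss is None else loss + perc
    return loss


# ---------------------------------------------------------------------------
# patient-level K folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldSplit:
    """K pairwise-disjoint patient-ID sets covering the training cohort."""
    folds: tuple[frozenset, ...]

    def validation_ids(self, k: int) -> frozenset:
        return self.folds[k]

    def training_ids(self, k: int) -> frozenset:
        return frozenset().union(*(f for i, f in enumerate(self.folds) if i != k))


def make_folds(patient_ids, K: int = 10, seed: int = 0) -> FoldSplit:
    """Shuffle patients and split into K folds with sizes differing by <= 1."""
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("patient ids must be unique")
    if len(ids) < K:
        raise ValueError(f"need at least K={K} patients, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    base, extra = divmod(len(ids), K)
    folds = []
    start = 0
    for k in range(K):
        size = base + (1 if k < extra else 0)
        folds.append(frozenset(shuffled[start:start + size]))
        start += size
    return FoldSplit(folds=tuple(folds))


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    batch_size: int = 5
    epochs: int = 400
    lr_init: float = 3e-4
    schedule: str = "cosine"
    optimizer: str = "adam"
    seed: int = 0
    k_folds: int = 10

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1 or self.lr_init <= 0:
            raise ValueError("invalid training configuration")
        if self.schedule not in {"cosine", "constant"}:
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")


def cosine_lr(epoch: int, cfg: TrainConfig) -> float:
    """Cosine annealing from ``lr_init`` at epoch 0 to 0 at the last epoch."""
    if cfg.schedule == "constant" or cfg.epochs == 1:
        return cfg.lr_init
    return cfg.lr_init * 0.5 * (1.0 + math.cos(math.pi * epoch / (cfg.epochs - 1)))


def _stack(batch_arrays) -> np.ndarray:
    return np.stack(batch_arrays).astype(np.float32)[..., None]


def train(pairs, net: RestorationNet, train_cfg: TrainConfig,
          loss_cfg: LossConfig, val_pairs=None):
    """Train a restoration network on slab pairs.

    ``pairs`` is a sequence of ``(pet_slab, ct_slab_or_None, target_slab)``
    tuples of normalized ``(H, W, S)`` arrays covering all short durations.
    Returns ``(net, history)`` where history has one record per epoch with
    the learning rate, mean training loss and (if ``val_pairs`` is given)
    mean validation loss.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(train_cfg.seed)
    opt = Adam(net.parameters(), lr=train_cfg.lr_init)
    needs_ct = net.config.use_ct_branch
    history = []
    for epoch in range(train_cfg.epochs):
        lr = cosine_lr(epoch, train_cfg)
        opt.lr = lr
        order = rng.permutation(len(pairs))
        losses = []
        for start in range(0, len(pairs), train_cfg.batch_size):
            chunk = [pairs[i] for i in order[start:start + train_cfg.batch_size]]
            pet = _stack([c[0] for c in chunk])
            tgt = _stack([c[2] for c in chunk])
            ct = _stack([c[1] for c in chunk]) if needs_ct else None
            pred = net.forward(pet, ct)
            loss = combined_loss(pred, tgt, loss_cfg)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        rec = {"epoch": epoch, "lr": lr, "train_loss": float(np.mean(losses))}
        if val_pairs:
            rec["val_loss"] = evaluate_loss(val_pairs, net, loss_cfg,
                                            train_cfg.batch_size)
        history.append(rec)
    return net, history


def evaluate_loss(pairs, net: RestorationNet, loss_cfg: LossConfig,
                  batch_size: int = 5) -> float:
    """Mean combined loss over a dataset without updating weights."""
    needs_ct = net.config.use_ct_branch
    losses = []
    pairs = list(pairs)
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start:start + batch_size]
        pet = _stack([c[0] for c in chunk])
        tgt = _stack([c[2] for c in chunk])
        ct = _stack([c[1] for c in chunk]) if needs_ct else None
        pred = net.forward(pet, ct)
        losses.append(float(combined_loss(pred, tgt, loss_cfg).data)
                      * len(chunk))
    return float(np.sum(losses) / len(pairs))
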