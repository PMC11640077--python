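"""Dataset splitting, label-aware augmentation, losses, and the fit loop.

Everything stochastic (split shuffle, weight init, epoch shuffling,
augmentation draws) funnels through a single integer seed, so a fit is fully
determined by ``(data, config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .fdi import fdi_flip_permutation
from .network import SEIBEDNetwork

__all__ = [
    "TrainConfig", "FitResult", "split_dataset", "augment", "hflip_sample",
    "compute_loss", "fit",
]


@dataclass(frozen=True)
class TrainConfig:
    split_fraction: float = 0.8
    batch_size: int = 2
    epochs: int = 200
    learning_rate: float = 3e-3
    optimizer: str = "adam"
    seed: int = 0
    hflip_with_fdi_remap: bool = False
    rotation_deg: float = 0.0
    brightness_jitter: float = 0.0
    loss: str = "bce_per_channel"     # or "ce_with_background"

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.loss not in ("bce_per_channel", "ce_with_background"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class FitResult:
    """Outcome of a fit: the trained network, its loss trace and the split."""

    model: SEIBEDNetwork
    loss_trace: list[float]
    train_ids: list[int] = field(default_factory=list)
    test_ids: list[int] = field(default_factory=list)

    @property
    def final_loss(self) -> float:
        return self.loss_trace[-1]


def split_dataset(sample_ids, fraction: float = 0.8, seed: int = 0):
    """Deterministic shuffled train/test split.

    The train side takes ``ceil(n * fraction)`` samples, so a 313-image set
    at 0.8 splits 251/62.  Returns ``(train_ids, test_ids)``: disjoint and
    exhaustive.
    """
    ids = list(sample_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5917]))
    order = rng.permutation(n)
    n_train = math.ceil(n * fraction)
    train = [ids[i] for i in order[:n_train]]
    test = [ids[i] for i in order[n_train:]]
    return train, test


def hflip_sample(image: np.ndarray, planes: np.ndarray):
    """Mirror a sample left-right and remap mask channels across quadrants.

    The flip swaps the patient's sides, so channel k of the output carries
    the mirrored plane of its contralateral tooth (FDI 11 <-> 21, 48 <-> 38).
    Applying this twice restores the original sample exactly.
    """
    perm = fdi_flip_permutation()
    flipped_img = image[..., ::-1].copy()
    flipped_planes = planes[:, ::-1, :][:, :, perm].copy()
    return flipped_img, flipped_planes


def augment(image: np.ndarray, planes: np.ndarray, cfg: TrainConfig,
            rng: np.random.Generator):
    """Jointly augment an image/mask pair.

    Geometric transforms hit the image and every mask plane identically
    (nearest-neighbor for masks, so they stay binary); a horizontal flip
    additionally applies the FDI channel permutation; photometric jitter
    touches the image only.
    """
    img, msk = image, planes
    if cfg.hflip_with_fdi_remap and rng.random() < 0.5:
        img, msk = hflip_sample(img, msk)
    if cfg.rotation_deg > 0:
        angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
        msk = ndimage.rotate(msk, angle, axes=(0, 1), reshape=False, order=0,
                             mode="constant", cval=0)
    if cfg.brightness_jitter > 0:
        img = np.clip(img * (1 + rng.uniform(-cfg.brightness_jitter,
                                             cfg.brightness_jitter))
                      + rng.uniform(-0.5, 0.5) * cfg.brightness_jitter, 0, 1)
    return img, msk


def _ce_labels(planes: np.ndarray) -> np.ndarray:
    """Single-label truth for the softmax head: lowest-index tooth channel
    at (possibly overlapping) tooth pixels, background class 32 elsewhere."""
    any_tooth = planes.sum(axis=-1) > 0
    lowest = planes.argmax(axis=-1)  # first nonzero channel
    return np.where(any_tooth, lowest, 32)


def compute_loss(logits, truth_planes: np.ndarray, kind: str = "bce_per_channel"):
    """Segmentation loss on a logits batch (Tensor or ndarray).

    ``bce_per_channel`` — mean binary cross-entropy over all pixels and the
    32 independent sigmoid channels.  ``ce_with_background`` — mean per-pixel
    categorical cross-entropy over 33 classes.  Returns a scalar Tensor when
    given a Tensor (differentiable), else a float.
    """
    truth = np.asarray(truth_planes)
    if not np.isin(truth, (0, 1)).all():
        raise ValueError("truth masks must be binary")
    is_tensor = isinstance(logits, nn.Tensor)
    lt = logits if is_tensor else nn.Tensor(np.asarray(logits))
    if kind == "bce_per_channel":
        out = nn.bce_with_logits_mean(lt, truth)
    elif kind == "ce_with_background":
        out = nn.softmax_ce_mean(lt, _ce_labels(truth))
    else:
        raise ValueError(f"unknown loss {kind!r}")
    return out if is_tensor else float(out.data)


def fit(model: SEIBEDNetwork, train_set, cfg: TrainConfig,
        callback=None) -> FitResult:
    """Minibatch gradient training of the network on (image, masks) pairs.

    ``train_set`` is a sequence of ``(image, masks)`` where ``masks`` is a
    :class:`~toothseg.synthetic.ToothMaskStack` or an (H, W, 32) array.
    Records the mean minibatch loss per epoch; aborts with a diagnostic on a
    non-finite loss.
    """
    if len(train_set) == 0:
        raise ValueError("train set is empty")
    images = [np.asarray(img, dtype=np.float32) for img, _ in train_set]
    masks = [np.asarray(getattr(m, "planes", m), dtype=np.float32)
             for _, m in train_set]

    ss = np.random.SeedSequence([int(cfg.seed), 0xF17])
    rng_shuffle, rng_aug = (np.random.default_rng(s) for s in ss.spawn(2))

    if cfg.optimizer == "adam":
        opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    else:
        opt = _SGD(model.params(), lr=cfg.learning_rate)

    n = len(images)
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng_shuffle.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch_imgs, batch_masks = [], []
            for i in idx:
                img, msk = augment(images[i], masks[i], cfg, rng_aug)
                batch_imgs.append(img)
                batch_masks.append(msk)
            x = np.stack(batch_imgs)
            t = np.stack(batch_masks)
            logits = model.forward_tensor(x, training=True)
            loss = compute_loss(logits, t, cfg.loss)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged: non-finite loss {value} at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(value)
        trace.append(float(np.mean(epoch_losses)))
        if callback is not None:
            callback(epoch, trace[-1])
    return FitResult(model=model, loss_trace=trace)


class _SGD:
    def __init__(self, params, lr: float) -> None:
        self.params, self.lr = list(params), lr

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
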