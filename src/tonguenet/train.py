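"""Training and evaluation loops.

Training minimises per-pixel cross-entropy with AdamW and a polynomial
learning-rate decay (power 0.9). Each epoch draws a fresh augmentation of
every training pair and resizes it to the fixed training resolution. One
master seed fans out to separate streams for shuffling, augmentation and
weight initialisation, so runs are exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, cross_entropy
from .data import AugmentConfig, ImagePair, _resize, augment
from .metrics import MetricSummary, SegMetricsRecord, evaluate_pair, summarize
from .model import GATongueNet, normalize_image
from .nn import AdamW

logger = logging.getLogger(__name__)

__all__ = ["TrainSettings", "train_model", "evaluate_model", "EpochLog"]


@dataclass
class TrainSettings:
    epochs: int = 12
    batch_size: int = 8
    lr: float = 1e-3
    weight_decay: float = 0.01
    lr_power: float = 0.9      # polynomial decay exponent
    input_size: tuple[int, int] = (128, 128)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0


@dataclass
class EpochLog:
    epoch: int
    loss: float
    val_dice: float | None = None


def _to_batch(pairs: list[ImagePair], size: tuple[int, int]
              ) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for p in pairs:
        img = p.image if p.image.shape[:2] == size else _resize(p.image, size, False)
        msk = p.mask if p.mask.shape == size else _resize(p.mask, size, True)
        xs.append(normalize_image(img))
        ys.append(msk.astype(np.int64))
    return np.stack(xs), np.stack(ys)


def train_model(model: GATongueNet, train_pairs: list[ImagePair],
                settings: TrainSettings,
                val_pairs: list[ImagePair] | None = None,
                callback=None) -> list[EpochLog]:
    """Train in place; returns the per-epoch log."""
    if not train_pairs:
        raise ValueError("empty training set")
    rng_shuffle = np.random.default_rng(settings.seed + 1)
    rng_aug = np.random.default_rng(settings.seed + 2)
    opt = AdamW(model.parameters(), lr=settings.lr,
                weight_decay=settings.weight_decay)
    n = len(train_pairs)
    steps_per_epoch = (n + settings.batch_size - 1) // settings.batch_size
    total_steps = settings.epochs * steps_per_epoch
    logs: list[EpochLog] = []
    step = 0
    for epoch in range(settings.epochs):
        model.train()
        order = rng_shuffle.permutation(n)
        losses = []
        for b0 in range(0, n, settings.batch_size):
            batch = [augment(train_pairs[i], settings.augment, rng_aug)
                     for i in order[b0:b0 + settings.batch_size]]
            x, y = _to_batch(batch, settings.input_size)
            logits = model(Tensor(x))
            loss = cross_entropy(logits, y)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, step {step}; aborting")
            opt.zero_grad()
            loss.backward()
            opt.lr = settings.lr * (1 - step / total_steps) ** settings.lr_power
            opt.step()
            losses.append(float(loss.data))
            step += 1
        entry = EpochLog(epoch=epoch, loss=float(np.mean(losses)))
        if val_pairs:
            records, _ = evaluate_model(model, val_pairs)
            entry.val_dice = float(np.mean([r.dice for r in records]))
        logs.append(entry)
        logger.info("epoch %d: loss %.4f%s", epoch, entry.loss,
                    f" val_dice {entry.val_dice:.4f}" if entry.val_dice else "")
        if callback is not None:
            callback(entry)
    model.eval()
    return logs


def evaluate_model(model: GATongueNet, pairs: list[ImagePair]
                   ) -> tuple[list[SegMetricsRecord], dict[str, MetricSummary]]:
    """Per-image scores at native resolution plus per-metric mean and CI."""
    model.eval()
    records = [evaluate_pair(model.predict_mask(p.image), p.mask, id=p.id)
               for p in pairs]
    summaries = summarize(records) if len(records) >= 2 else {}
    return records, summaries
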