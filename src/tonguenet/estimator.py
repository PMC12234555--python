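"""Scikit-learn-style estimator facade over the segmentation network.

``TongueSegmenter`` follows the sklearn estimator contract: constructor
arguments are hyperparameters stored verbatim, ``fit`` trains the network
and sets trailing-underscore attributes, ``predict`` returns binary masks,
and ``score`` returns the mean Dice coefficient, so the class composes
with sklearn model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .backbone import BACKBONE_PRESETS
from .data import AugmentConfig, ImagePair
from .head import HeadConfig, MDiConfig
from .model import GATongueNet, ModelConfig, load_checkpoint, save_checkpoint
from .neck import NeckConfig
from .train import TrainSettings, evaluate_model, train_model

__all__ = ["TongueSegmenter"]


def _as_pairs(X, y=None) -> list[ImagePair]:
    if y is None:
        return [p if isinstance(p, ImagePair)
                else ImagePair(np.asarray(p[0]), np.asarray(p[1]))
                for p in X]
    return [ImagePair(np.asarray(img), np.asarray(msk), id=str(i))
            for i, (img, msk) in enumerate(zip(X, y))]


class TongueSegmenter(BaseEstimator):
    """Binary tongue-body segmenter.

    Parameters
    ----------
    preset : {"tiny", "base"}
        Network sizing. ``tiny`` is CPU-scale; ``base`` is the ~14M-parameter
        configuration.
    use_difp, use_mdi : bool
        Ablation switches for the dilated-pyramid neck and the
        multi-dilation head block. Both off gives the plain
        encoder + MLP-decoder baseline.
    m, rates : int, tuple of int
        Number of dilated branches in the head block and their rates.
    neck_dilations : tuple of int
        Per-level dilation rates of the neck output convolutions.
    epochs, batch_size, lr, weight_decay : training hyperparameters.
    input_size : (H, W) training resolution (inference is native-size).
    augment : AugmentConfig or None
        ``None`` uses the default training augmentation suite.
    seed : master seed for initialisation, shuffling and augmentation.

    Attributes
    ----------
    model_ : GATongueNet            fitted network
    config_ : ModelConfig           resolved architecture configuration
    history_ : list of EpochLog     per-epoch loss (and val Dice if given)
    n_parameters_ : int             trainable parameter count
    """

    def __init__(self, preset: str = "tiny", use_difp: bool = True,
                 use_mdi: bool = True, m: int = 3,
                 rates: tuple[int, ...] = (1, 2, 4),
                 neck_dilations: tuple[int, ...] = (1, 2, 4, 6),
                 num_classes: int = 2, epochs: int = 12, batch_size: int = 8,
                 lr: float = 1e-3, weight_decay: float = 0.01,
                 input_size: tuple[int, int] = (128, 128),
                 augment: AugmentConfig | None = None, seed: int = 0,
                 verbose: int = 0):
        self.preset = preset
        self.use_difp = use_difp
        self.use_mdi = use_mdi
        self.m = m
        self.rates = rates
        self.neck_dilations = neck_dilations
        self.num_classes = num_classes
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.input_size = input_size
        self.augment = augment
        self.seed = seed
        self.verbose = verbose

    # -- construction ---------------------------------------------------------
    def build_config(self) -> ModelConfig:
        backbone = BACKBONE_PRESETS[self.preset]
        width = 256 if self.preset == "base" else 32
        return ModelConfig(
            backbone=backbone,
            neck=NeckConfig(out_channels=width,
                            dilation_per_level=tuple(self.neck_dilations)),
            head=HeadConfig(embed_channels=width, num_classes=self.num_classes),
            mdi=MDiConfig(m=self.m, rates=tuple(self.rates)),
            use_difp=self.use_difp, use_mdi=self.use_mdi,
            init_seed=self.seed,
        )

    def build_model(self) -> GATongueNet:
        return GATongueNet(self.build_config())

    # -- sklearn API ----------------------------------------------------------
    def fit(self, X, y=None, X_val=None, y_val=None) -> "TongueSegmenter":
        """Train on images X (HxWx3 uint8) and masks y (HxW {0,1})."""
        pairs = _as_pairs(X, y)
        val_pairs = _as_pairs(X_val, y_val) if X_val is not None else None
        self.config_ = self.build_config()
        self.model_ = GATongueNet(self.config_)
        self.n_parameters_ = self.model_.n_parameters()
        settings = TrainSettings(
            epochs=self.epochs, batch_size=self.batch_size, lr=self.lr,
            weight_decay=self.weight_decay,
            input_size=tuple(self.input_size),
            augment=self.augment or AugmentConfig(seed=self.seed),
            seed=self.seed)
        callback = (lambda e: print(f"epoch {e.epoch}: loss {e.loss:.4f}")) \
            if self.verbose else None
        self.history_ = train_model(self.model_, pairs, settings,
                                    val_pairs=val_pairs, callback=callback)
        return self

    def predict(self, X) -> list[np.ndarray]:
        """Binary masks for a list of HxWx3 uint8 images (native size)."""
        check_is_fitted(self, "model_")
        return [self.model_.predict_mask(np.asarray(img)) for img in X]

    def predict_proba(self, X) -> list[np.ndarray]:
        """Per-pixel softmax probabilities, one HxWxK array per image."""
        check_is_fitted(self, "model_")
        out = []
        for img in X:
            logits = self.model_.predict_logits(np.asarray(img))
            e = np.exp(logits - logits.max(axis=-1, keepdims=True))
            out.append(e / e.sum(axis=-1, keepdims=True))
        return out

    def score(self, X, y) -> float:
        """Mean Dice coefficient over the given image/mask pairs."""
        check_is_fitted(self, "model_")
        records, _ = evaluate_model(self.model_, _as_pairs(X, y))
        return float(np.mean([r.dice for r in records]))

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        check_is_fitted(self, "model_")
        save_checkpoint(self.model_, path)

    @classmethod
    def from_checkpoint(cls, path) -> "TongueSegmenter":
        model = load_checkpoint(path)
        est = cls()
        est.model_ = model
        est.config_ = model.config
        est.n_parameters_ = model.n_parameters()
        est.history_ = []
        return est
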