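"""Balloon segmentation: normalisation, Dice loss, and the trainable model.

The segmenter is an encoder-decoder network with a residual encoder and a
single-channel sigmoid output.  Balloon pixels make up well under 1 % of a
frame, so training minimises the Dice loss, which is insensitive to that
class imbalance.  Model selection keeps the weights of the epoch with the
global minimum of the validation loss.

The public surface is scikit-learn shaped: :class:`CatheterSegmenter`
implements ``fit`` / ``predict`` / ``predict_proba`` with fitted attributes
(``model_``, ``best_epoch_``, loss histories); the module-level functions
(:func:`train`, :func:`predict_mask`, ...) are thin wrappers over it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .nn import ResidualUNet, sigmoid
from .synthetic import AnnotatedFrame

__all__ = [
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "TrainingConfig",
    "CatheterSegmenter",
    "normalize",
    "dice_loss",
    "build_model",
    "select_best_epoch",
    "train",
    "predict_mask",
]

#: published per-channel statistics of the ImageNet training corpus,
#: applied after 0-1 rescaling and replication to three channels
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


@dataclass
class TrainingConfig:
    """Hyper-parameters of the reference training recipe.

    Defaults are the full-scale recipe (200 epochs, learning rate 1e-5,
    batch 64, Adam, 34-layer-style residual encoder); scaled-down runs
    override them.
    """

    learning_rate: float = 1e-5
    batch_size: int = 64
    n_epochs: int = 200
    encoder_preset: str = "resnet34"
    use_pretrained_encoder: bool = False
    pretrained_weights: str | None = None
    prediction_threshold: float = 0.5
    dice_eps: float = 1.0
    rng_seed: int = 0
    imagenet_mean: tuple[float, float, float] = IMAGENET_MEAN
    imagenet_std: tuple[float, float, float] = IMAGENET_STD

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.prediction_threshold != 0.5:
            raise ValueError("prediction_threshold is fixed at 0.5")


def normalize(image: np.ndarray,
              mean: Sequence[float] = IMAGENET_MEAN,
              std: Sequence[float] = IMAGENET_STD) -> np.ndarray:
    """Normalise one grayscale image for the network.

    Steps: rescale to [0, 1] over the image's own range, replicate to three
    channels, then subtract/divide the per-channel reference statistics.
    A constant image rescales to all zeros (with a warning).

    Returns a ``(3, H, W)`` float array.
    """
    image = np.asarray(image, dtype=np.float64)
    lo, hi = image.min(), image.max()
    if hi > lo:
        scaled = (image - lo) / (hi - lo)
    else:
        warnings.warn("constant image: range normalisation yields all zeros")
        scaled = np.zeros_like(image)
    out = np.repeat(scaled[None], 3, axis=0)
    mean = np.asarray(mean, dtype=np.float64)[:, None, None]
    std = np.asarray(std, dtype=np.float64)[:, None, None]
    return (out - mean) / std


def dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = 1.0) -> float:
    """Dice loss ``1 - (2*|P∩T| + eps) / (|P| + |T| + eps)``.

    ``pred`` holds probabilities in [0, 1]; ``target`` is binary.  The
    smoothing term ``eps`` keeps the loss defined (and zero) when both masks
    are empty, which matters because a share of training frames is
    deliberately catheter-free.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if pred.min() < 0 or pred.max() > 1:
        raise ValueError("pred values must lie in [0, 1]")
    num = 2.0 * (pred * target).sum() + eps
    den = pred.sum() + target.sum() + eps
    return float(1.0 - num / den)


def _dice_loss_with_logit_grad(logits: np.ndarray, target: np.ndarray,
                               eps: float) -> tuple[float, np.ndarray]:
    """Mean per-image Dice loss over a batch and its gradient w.r.t. logits."""
    p = sigmoid(logits)
    t = target.astype(np.float64)
    n = logits.shape[0]
    num = 2.0 * (p * t).sum(axis=(1, 2, 3)) + eps
    den = p.sum(axis=(1, 2, 3)) + t.sum(axis=(1, 2, 3)) + eps
    loss = float(np.mean(1.0 - num / den))
    # dL/dp = (N - 2 t D) / D^2 per image, then through the sigmoid
    dldp = (num[:, None, None, None] - 2.0 * t * den[:, None, None, None]) \
        / den[:, None, None, None] ** 2
    dlogits = dldp * p * (1.0 - p) / n
    return loss, dlogits.astype(logits.dtype)


def select_best_epoch(val_loss_history: Sequence[float]) -> int:
    """1-based epoch of the global minimum validation loss (earliest on ties)."""
    if len(val_loss_history) == 0:
        raise ValueError("empty loss history")
    return int(np.argmin(val_loss_history)) + 1


def build_model(config: TrainingConfig) -> ResidualUNet:
    """Instantiate the (untrained) segmentation network for ``config``."""
    model = ResidualUNet(in_channels=3, preset=config.encoder_preset,
                         rng_seed=config.rng_seed)
    if config.use_pretrained_encoder:
        if not config.pretrained_weights:
            raise ValueError(
                "use_pretrained_encoder=True requires pretrained_weights "
                "(a checkpoint file); no weight download is performed"
            )
        model.load(config.pretrained_weights)
    return model


def _pad_to_multiple(x: np.ndarray, k: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflect-pad channels-last (N, H, W, C) so H and W are multiples of ``k``."""
    h, w = x.shape[1], x.shape[2]
    ph = (-h) % k
    pw = (-w) % k
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), mode="reflect")
    return x, (h, w)


class CatheterSegmenter(BaseEstimator):
    """Binary balloon segmenter with a scikit-learn estimator interface.

    Parameters mirror :class:`TrainingConfig`.  ``fit`` expects raw grayscale
    images ``X`` of shape ``(n, H, W)`` and binary masks ``y`` of the same
    shape; normalisation and padding are internal.

    Attributes (after ``fit``)
    --------------------------
    model_ : the trained network (weights of the best epoch)
    best_epoch_ : 1-based epoch with the global minimum validation loss
        (earliest on ties)
    train_loss_history_, val_loss_history_ : per-epoch mean Dice losses
    """

    def __init__(self, learning_rate: float = 1e-5, batch_size: int = 64,
                 n_epochs: int = 200, encoder_preset: str = "resnet34",
                 use_pretrained_encoder: bool = False,
                 pretrained_weights: str | None = None,
                 prediction_threshold: float = 0.5, dice_eps: float = 1.0,
                 random_state: int = 0):
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.encoder_preset = encoder_preset
        self.use_pretrained_encoder = use_pretrained_encoder
        self.pretrained_weights = pretrained_weights
        self.prediction_threshold = prediction_threshold
        self.dice_eps = dice_eps
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            n_epochs=self.n_epochs, encoder_preset=self.encoder_preset,
            use_pretrained_encoder=self.use_pretrained_encoder,
            pretrained_weights=self.pretrained_weights,
            prediction_threshold=self.prediction_threshold,
            dice_eps=self.dice_eps, rng_seed=self.random_state,
        )

    def _prepare(self, X: np.ndarray, factor: int) -> tuple[np.ndarray, tuple[int, int]]:
        X = np.asarray(X)
        if X.ndim == 2:
            X = X[None]
        batch = np.stack([normalize(img).transpose(1, 2, 0) for img in X]).astype(np.float32)
        return _pad_to_multiple(batch, factor)

    # ------------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray,
            X_val: np.ndarray | None = None,
            y_val: np.ndarray | None = None) -> "CatheterSegmenter":
        """Train on frames ``(X, y)``; track the validation loss on
        ``(X_val, y_val)`` (defaults to the training set) and keep the
        weights of its global minimum."""
        config = self._config()
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 3 or X.shape != y.shape or len(X) == 0:
            raise ValueError("X and y must be nonempty (n, H, W) arrays of equal shape")
        if X_val is None:
            X_val, y_val = X, y
        X_val = np.asarray(X_val, dtype=np.float64)
        y_val = np.asarray(y_val)
        if len(X_val) == 0:
            raise ValueError("validation set must be nonempty")

        model = build_model(config)
        factor = model.downsample_factor
        Xn, _ = self._prepare(X, factor)
        yn, _ = _pad_to_multiple(y[..., None].astype(np.float32), factor)
        Xvn, _ = self._prepare(X_val, factor)
        yvn, _ = _pad_to_multiple(y_val[..., None].astype(np.float32), factor)

        opt = model.make_optimizer(config.learning_rate)
        rng = np.random.default_rng(config.rng_seed)
        n = len(Xn)
        train_hist: list[float] = []
        val_hist: list[float] = []
        best_val = np.inf
        best_state: list[np.ndarray] | None = None
        best_epoch = 1
        for epoch in range(1, config.n_epochs + 1):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, config.batch_size):
                idx = order[start:start + config.batch_size]
                logits = model.forward(Xn[idx], training=True)
                loss, dlogits = _dice_loss_with_logit_grad(logits, yn[idx], config.dice_eps)
                model.zero_grad()
                model.backward(dlogits)
                opt.step()
                losses.append(loss)
            train_hist.append(float(np.mean(losses)))
            val_hist.append(self._eval_loss(model, Xvn, yvn, config))
            if val_hist[-1] < best_val:  # strict: earliest epoch wins ties
                best_val = val_hist[-1]
                best_epoch = epoch
                best_state = [a.copy() for a in model.state_arrays()]
        if best_state is not None:
            for dst, src in zip(model.state_arrays(), best_state):
                dst[...] = src

        self.model_ = model
        self.best_epoch_ = best_epoch
        self.train_loss_history_ = train_hist
        self.val_loss_history_ = val_hist
        self.best_val_loss_ = float(best_val)
        return self

    def _eval_loss(self, model, Xn, yn, config) -> float:
        losses = []
        for start in range(0, len(Xn), config.batch_size):
            sl = slice(start, start + config.batch_size)
            p = model.predict_proba(Xn[sl])
            num = 2.0 * (p * yn[sl]).sum(axis=(1, 2, 3)) + config.dice_eps
            den = p.sum(axis=(1, 2, 3)) + yn[sl].sum(axis=(1, 2, 3)) + config.dice_eps
            losses.extend(1.0 - num / den)
        return float(np.mean(losses))

    # ------------------------------------------------------------------
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-pixel balloon probabilities, shape ``(n, H, W)``."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "model_")
        single = np.asarray(X).ndim == 2
        Xn, (h, w) = self._prepare(X, self.model_.downsample_factor)
        out = []
        for start in range(0, len(Xn), max(int(self.batch_size), 1)):
            out.append(self.model_.predict_proba(Xn[start:start + max(int(self.batch_size), 1)]))
        proba = np.concatenate(out)[:, :h, :w, 0]
        return proba[0] if single else proba

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Binary masks: sigmoid output thresholded at 0.5 (inclusive)."""
        proba = self.predict_proba(X)
        return (proba >= self.prediction_threshold).astype(np.uint8)

    # ------------------------------------------------------------------
    def save(self, model_dir: str | Path) -> None:
        """Write the weights plus a JSON sidecar (config, best epoch, losses)."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "model_")
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        self.model_.save(model_dir / "weights.npz")
        sidecar = {
            "params": self.get_params(),
            "best_epoch": self.best_epoch_,
            "train_loss_history": self.train_loss_history_,
            "val_loss_history": self.val_loss_history_,
        }
        (model_dir / "model.json").write_text(json.dumps(sidecar, indent=2))
        with open(model_dir / "loss_history.csv", "w") as fh:
            fh.write("epoch,train_loss,val_loss\n")
            for i, (tl, vl) in enumerate(zip(self.train_loss_history_,
                                             self.val_loss_history_), start=1):
                fh.write(f"{i},{tl:.6f},{vl:.6f}\n")

    @classmethod
    def load(cls, model_dir: str | Path) -> "CatheterSegmenter":
        model_dir = Path(model_dir)
        sidecar = json.loads((model_dir / "model.json").read_text())
        est = cls(**sidecar["params"])
        model = ResidualUNet(in_channels=3, preset=est.encoder_preset,
                             rng_seed=est.random_state)
        model.load(model_dir / "weights.npz")
        est.model_ = model
        est.best_epoch_ = sidecar["best_epoch"]
        est.train_loss_history_ = sidecar["train_loss_history"]
        est.val_loss_history_ = sidecar["val_loss_history"]
        est.best_val_loss_ = min(sidecar["val_loss_history"]) if sidecar["val_loss_history"] else None
        return est


# ---------------------------------------------------------------------------
# frame-level wrappers


def frames_to_arrays(frames: Sequence[AnnotatedFrame]) -> tuple[np.ndarray, np.ndarray]:
    """Stack AnnotatedFrames into (images, masks) arrays."""
    X = np.stack([f.image for f in frames])
    y = np.stack([f.gt_mask for f in frames])
    return X, y


def train(train_frames: Sequence[AnnotatedFrame],
          val_frames: Sequence[AnnotatedFrame],
          config: TrainingConfig | None = None) -> CatheterSegmenter:
    """Train a segmenter on annotated frames; returns the fitted estimator."""
    config = config or TrainingConfig()
    if len(train_frames) == 0 or len(val_frames) == 0:
        raise ValueError("training and validation sets must be nonempty")
    X, y = frames_to_arrays(train_frames)
    Xv, yv = frames_to_arrays(val_frames)
    est = CatheterSegmenter(
        learning_rate=config.learning_rate, batch_size=config.batch_size,
        n_epochs=config.n_epochs, encoder_preset=config.encoder_preset,
        use_pretrained_encoder=config.use_pretrained_encoder,
        pretrained_weights=config.pretrained_weights,
        prediction_threshold=config.prediction_threshold,
        dice_eps=config.dice_eps, random_state=config.rng_seed,
    )
    return est.fit(X, y, Xv, yv)


def predict_mask(model: CatheterSegmenter, image: np.ndarray) -> np.ndarray:
    """Binary balloon mask for one image."""
    return model.predict(image)
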