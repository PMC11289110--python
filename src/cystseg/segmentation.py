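"""Segmentation backends, the compact reference net, and the training recipe.

A segmentation backend is anything that maps a preprocessed RGB image to
a per-pixel cyst probability map of the same height/width — a trained
network, or a trivial baseline such as red-channel darkness.  The whole
evaluation pipeline is agnostic to which backend produced the masks.

The reference net is a miniature of the U-Net family: a 3-level
encoder-decoder with skip connections, instance normalization and ~0.1M
parameters, small enough to train on a single CPU.  It is trained with
the standard recipe for this task: binary cross-entropy, Adam at
learning rate 1e-4, batch size 8, cosine annealing with warm restarts
(T0 = 10, Tmult = 2), early stopping on validation pixel-wise IoU with
patience 10, at most 100 epochs, and probability maps binarized at 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _nn

__all__ = [
    "TrainConfig",
    "binarize",
    "CystSegmenter",
    "RedDarknessBaseline",
    "train_reference_model",
    "predict_image",
]


@dataclass(frozen=True)
class TrainConfig:
    """The fixed training hyperparameters (see module docstring)."""

    batch_size: int = 8
    learning_rate: float = 1e-4
    t0: int = 10
    t_mult: int = 2
    eta_min: float = 0.0
    patience: int = 10
    max_epochs: int = 100
    threshold: float = 0.5
    base_channels: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("batch_size", "learning_rate", "t0", "t_mult", "patience",
                     "max_epochs", "base_channels"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")


def binarize(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Discretize a probability map: pixel is cyst iff p > threshold.

    The inequality is strict, so a map of exactly 0.5 everywhere yields an
    all-background mask at the default threshold.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    p = np.asarray(probabilities)
    if p.size and (p.min() < -1e-6 or p.max() > 1 + 1e-6):
        raise ValueError("probability map has values outside [0, 1]")
    return p > threshold


class _TinyUNet:
    """3-level encoder-decoder with skip connections (numpy, NHWC)."""

    def __init__(self, base: int, rng: np.random.Generator, in_channels: int = 3):
        C = _nn.Conv2d
        N = _nn.InstanceNorm
        b = base
        self.e11, self.n11 = C(in_channels, b, 3, rng), N(b)
        self.e12, self.n12 = C(b, b, 3, rng), N(b)
        self.e21, self.n21 = C(b, 2 * b, 3, rng), N(2 * b)
        self.e22, self.n22 = C(2 * b, 2 * b, 3, rng), N(2 * b)
        self.b1, self.nb1 = C(2 * b, 4 * b, 3, rng), N(4 * b)
        self.b2, self.nb2 = C(4 * b, 4 * b, 3, rng), N(4 * b)
        self.d21, self.nd21 = C(6 * b, 2 * b, 3, rng), N(2 * b)
        self.d22, self.nd22 = C(2 * b, 2 * b, 3, rng), N(2 * b)
        self.d11, self.nd11 = C(3 * b, b, 3, rng), N(b)
        self.d12, self.nd12 = C(b, b, 3, rng), N(b)
        self.out = C(b, 1, 1, rng)
        self.out.b[:] = -2.0  # start near the background prior
        self.base = base
        self.in_channels = in_channels

    def layers(self) -> list:
        return [self.e11, self.n11, self.e12, self.n12,
                self.e21, self.n21, self.e22, self.n22,
                self.b1, self.nb1, self.b2, self.nb2,
                self.d21, self.nd21, self.d22, self.nd22,
                self.d11, self.nd11, self.d12, self.nd12, self.out]

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers())

    def _block(self, x, conv, norm):
        h = norm.forward(conv.forward(x))
        out, mask = _nn.relu(h)
        return out, mask

    def forward(self, x: np.ndarray) -> np.ndarray:
        c = {}
        a, c["m11"] = self._block(x, self.e11, self.n11)
        a, c["m12"] = self._block(a, self.e12, self.n12)
        p1, c["i1"] = _nn.maxpool2(a)
        b, c["m21"] = self._block(p1, self.e21, self.n21)
        b, c["m22"] = self._block(b, self.e22, self.n22)
        p2, c["i2"] = _nn.maxpool2(b)
        z, c["mb1"] = self._block(p2, self.b1, self.nb1)
        z, c["mb2"] = self._block(z, self.b2, self.nb2)
        u2 = _nn.upsample2(z)
        cat2 = np.concatenate([u2, b], axis=-1)
        d2, c["md21"] = self._block(cat2, self.d21, self.nd21)
        d2, c["md22"] = self._block(d2, self.d22, self.nd22)
        u1 = _nn.upsample2(d2)
        cat1 = np.concatenate([u1, a], axis=-1)
        d1, c["md11"] = self._block(cat1, self.d11, self.nd11)
        d1, c["md12"] = self._block(d1, self.d12, self.nd12)
        logits = self.out.forward(d1)
        self._cache = c
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        c = self._cache
        b = self.base
        d = self.out.backward(dlogits)
        d = self.d12.backward(self.nd12.backward(_nn.relu_backward(d, c["md12"])))
        d = self.d11.backward(self.nd11.backward(_nn.relu_backward(d, c["md11"])))
        du1, da = d[..., :2 * b], d[..., 2 * b:]
        d = _nn.upsample2_backward(du1)
        d = self.d22.backward(self.nd22.backward(_nn.relu_backward(d, c["md22"])))
        d = self.d21.backward(self.nd21.backward(_nn.relu_backward(d, c["md21"])))
        du2, db = d[..., :4 * b], d[..., 4 * b:]
        d = _nn.upsample2_backward(du2)
        d = self.b2.backward(self.nb2.backward(_nn.relu_backward(d, c["mb2"])))
        d = self.b1.backward(self.nb1.backward(_nn.relu_backward(d, c["mb1"])))
        d = _nn.maxpool2_backward(d, c["i2"])
        d = d + db
        d = self.e22.backward(self.n22.backward(_nn.relu_backward(d, c["m22"])))
        d = self.e21.backward(self.n21.backward(_nn.relu_backward(d, c["m21"])))
        d = _nn.maxpool2_backward(d, c["i1"])
        d = d + da
        d = self.e12.backward(self.n12.backward(_nn.relu_backward(d, c["m12"])))
        self.e11.backward(self.n11.backward(_nn.relu_backward(d, c["m11"])))
        self._cache = None

    def get_weights(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(l.W.copy(), l.b.copy()) for l in self.layers()]

    def set_weights(self, weights) -> None:
        for layer, (w, bias) in zip(self.layers(), weights):
            layer.W[...] = w
            layer.b[...] = bias


class CystSegmenter(BaseEstimator):
    """Reference cyst segmentation network with the standard recipe.

    A scikit-learn style estimator: ``fit(X, y)`` trains on image stacks
    ``X`` of shape (n, H, W, 3) (already preprocessed: green channel
    muted, channels normalized) with boolean masks ``y`` of shape
    (n, H, W); ``predict_proba`` returns per-pixel cyst probabilities and
    ``predict`` binary masks at the configured threshold.

    Pass ``X_val``/``y_val`` to :meth:`fit` to enable early stopping on
    validation pixel-wise IoU (accumulated over the whole validation
    set); the returned weights are from the best-validation epoch.
    """

    def __init__(self, base_channels: int = 16, batch_size: int = 8,
                 learning_rate: float = 1e-4, t0: int = 10, t_mult: int = 2,
                 eta_min: float = 0.0, patience: int = 10, max_epochs: int = 100,
                 threshold: float = 0.5, seed: int = 0, verbose: int = 0):
        self.base_channels = base_channels
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.t0 = t0
        self.t_mult = t_mult
        self.eta_min = eta_min
        self.patience = patience
        self.max_epochs = max_epochs
        self.threshold = threshold
        self.seed = seed
        self.verbose = verbose

    @classmethod
    def from_config(cls, config: TrainConfig, **overrides) -> "CystSegmenter":
        params = dict(
            base_channels=config.base_channels, batch_size=config.batch_size,
            learning_rate=config.learning_rate, t0=config.t0,
            t_mult=config.t_mult, eta_min=config.eta_min,
            patience=config.patience, max_epochs=config.max_epochs,
            threshold=config.threshold, seed=config.seed,
        )
        params.update(overrides)
        return cls(**params)

    # -- helpers ---------------------------------------------------------

    @staticmethod
    def _to_batch(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[None]
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError(f"expected (n, H, W, 3) images, got shape {X.shape}")
        if X.shape[1] % 4 or X.shape[2] % 4:
            raise ValueError("image height and width must be multiples of 4")
        return np.ascontiguousarray(X)

    def _val_iou(self, Xv: np.ndarray, yv: np.ndarray) -> float:
        tp = fp = fn = 0
        for i in range(0, len(Xv), self.batch_size):
            probs = _nn.sigmoid(self.net_.forward(Xv[i:i + self.batch_size]))[..., 0]
            pred = probs > self.threshold
            gt = yv[i:i + self.batch_size]
            tp += int(np.count_nonzero(pred & gt))
            fp += int(np.count_nonzero(pred & ~gt))
            fn += int(np.count_nonzero(~pred & gt))
        return tp / (tp + fp + fn)

    # -- estimator API ---------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        """Train; with a validation set, early-stop on pixel-wise IoU."""
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        Xt = self._to_batch(X)
        yt = np.asarray(y, dtype=bool)
        if yt.ndim == 2:
            yt = yt[None]
        if len(Xt) == 0:
            raise ValueError("training set is empty")
        if yt.shape != Xt.shape[:3]:
            raise ValueError(f"mask shape {yt.shape} does not match images")
        have_val = X_val is not None and y_val is not None
        if have_val:
            Xv = self._to_batch(X_val)
            yv = np.asarray(y_val, dtype=bool)
            if yv.ndim == 2:
                yv = yv[None]
            if not yv.any():
                raise ValueError(
                    "validation set has no cyst pixels, so validation IoU is "
                    "undefined; use a richer validation split"
                )

        rng = np.random.default_rng(self.seed)
        self.net_ = _TinyUNet(self.base_channels, rng)
        optimizer = _nn.Adam(self.net_.layers(), lr=self.learning_rate)
        target = yt[..., None].astype(np.float32)  # (n, H, W, 1) to match logits

        history: list[dict] = []
        best_iou, best_epoch, best_weights, since_best = -np.inf, 0, None, 0
        for epoch in range(1, self.max_epochs + 1):
            lr = _nn.cosine_warm_restart_lr(epoch - 1, self.learning_rate,
                                            self.t0, self.t_mult, self.eta_min)
            optimizer.lr = lr
            order = rng.permutation(len(Xt))
            losses = []
            for i in range(0, len(order), self.batch_size):
                sel = order[i:i + self.batch_size]
                logits = self.net_.forward(Xt[sel])
                loss, dz = _nn.bce_with_logits(logits, target[sel])
                self.net_.backward(dz)
                optimizer.step()
                losses.append(loss)
            row = {"epoch": epoch, "lr": lr, "train_loss": float(np.mean(losses)),
                   "val_iou": np.nan}
            if have_val:
                iou = self._val_iou(Xv, yv)
                row["val_iou"] = iou
                if iou > best_iou:
                    best_iou, best_epoch, since_best = iou, epoch, 0
                    best_weights = self.net_.get_weights()
                else:
                    since_best += 1
            history.append(row)
            if self.verbose:
                print(f"epoch {epoch:3d}  lr {lr:.2e}  loss {row['train_loss']:.4f}"
                      f"  val_iou {row['val_iou']:.4f}")
            if have_val and since_best >= self.patience:
                break
        if best_weights is not None:
            self.net_.set_weights(best_weights)
        self.history_ = pd.DataFrame(history)
        self.best_epoch_ = best_epoch if have_val else len(history)
        self.best_val_iou_ = best_iou if have_val else np.nan
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel cyst probabilities, shape (n, H, W) (or (H, W))."""
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")
        single = np.asarray(X).ndim == 3
        Xt = self._to_batch(X)
        out = np.concatenate([
            _nn.sigmoid(self.net_.forward(Xt[i:i + self.batch_size]))[..., 0]
            for i in range(0, len(Xt), self.batch_size)
        ])
        return out[0] if single else out

    def predict(self, X) -> np.ndarray:
        """Binary masks at the configured threshold."""
        return binarize(self.predict_proba(X), self.threshold)

    # -- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")
        arrays = {}
        for i, (w, b) in enumerate(self.net_.get_weights()):
            arrays[f"W{i}"] = w
            arrays[f"b{i}"] = b
        np.savez_compressed(path, params=json.dumps(self.get_params()), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CystSegmenter":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"checkpoint not found: {path}")
        with np.load(path, allow_pickle=False) as data:
            params = json.loads(str(data["params"]))
            params.pop("verbose", None)
            est = cls(**params)
            est.net_ = _TinyUNet(est.base_channels, np.random.default_rng(0))
            n = len(est.net_.layers())
            est.net_.set_weights([(data[f"W{i}"], data[f"b{i}"]) for i in range(n)])
        return est


class RedDarknessBaseline:
    """Trivial no-training backend: cyst probability = red-channel darkness.

    Cyst lumens are dark in the tissue (red) channel, so ``1 - R/255``
    already carries signal.  This baseline exists to exercise the full
    evaluation pipeline without training; it satisfies the backend
    contract (probability map with the input's height/width).
    """

    def __init__(self, gain: float = 1.0):
        self.gain = gain

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X)
        single = X.ndim == 3
        if single:
            X = X[None]
        red = X[..., 0].astype(np.float64)
        if red.max() > 1.5:  # uint8-scale input
            red = red / 255.0
        else:  # normalized input: undo the affine map approximately
            red = np.clip(red * 0.229 + 0.485, 0.0, 1.0)
        prob = np.clip((1.0 - red) * self.gain, 0.0, 1.0)
        return prob[0] if single else prob

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return binarize(self.predict_proba(X), threshold)


def train_reference_model(
    train_images: np.ndarray,
    train_masks: np.ndarray,
    val_images: np.ndarray,
    val_masks: np.ndarray,
    config: TrainConfig | None = None,
    verbose: int = 0,
) -> tuple[CystSegmenter, pd.DataFrame]:
    """Train the reference net with the standard recipe; returns (model, history)."""
    config = config or TrainConfig()
    model = CystSegmenter.from_config(config, verbose=verbose)
    model.fit(train_images, train_masks, X_val=val_images, y_val=val_masks)
    return model, model.history_


def predict_image(backend, image: np.ndarray) -> np.ndarray:
    """Run any backend on one image and validate the output contract."""
    if callable(backend) and not hasattr(backend, "predict_proba"):
        prob = backend(image)
    else:
        prob = backend.predict_proba(image)
    prob = np.asarray(prob)
    if prob.shape != np.asarray(image).shape[:2]:
        raise ValueError(
            f"backend returned shape {prob.shape} for image of shape "
            f"{np.asarray(image).shape[:2]}"
        )
    if prob.size and (prob.min() < 0 or prob.max() > 1):
        raise ValueError("backend probabilities must lie in [0, 1]")
    return prob
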