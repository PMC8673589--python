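"""Supervised CNN classifier used as a numerical observer.

A convolutional binary classifier trained with cross-entropy produces a
score monotonically related to the posterior probability of the
signal-present class, and hence (given sufficient capacity and data) to
the likelihood ratio -- the ideal-observer test statistic.  Deep
instances of this observer therefore approximate the ideal observer
("CNN-IO"); shallow instances are deliberately sub-optimal observers.

Architecture: L conv layers (32 filters, 3x3, ReLU), global average
pooling, and a single fully connected logit unit.  Training uses Adam
(lr 1e-4) on mini-batches with equal class composition, and the
checkpoint with the best validation AUC is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from ._roc import empirical_auc
from .phantom_imaging import ImageEnsemble

__all__ = ["CnnObserverSpec", "CnnObserver", "build_cnn_observer",
           "train_cnn_observer", "observer_statistics"]


@dataclass(frozen=True)
class CnnObserverSpec:
    n_layers: int = 10
    n_filters: int = 32
    lr: float = 1e-4
    batch_present: int = 200
    batch_absent: int = 200
    epochs: int = 50
    patience: int = 10
    steps_per_epoch: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("need at least one convolutional layer")
        if self.n_filters < 1 or self.lr <= 0:
            raise ValueError("invalid observer spec")


class CnnObserver:
    """Image -> scalar score network (logit of the class posterior)."""

    def __init__(self, spec: CnnObserverSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        layers: list = []
        c_in = 1
        for _ in range(spec.n_layers):
            layers += [_nn.Conv2d(c_in, spec.n_filters, rng), _nn.ReLU()]
            c_in = spec.n_filters
        layers += [_nn.GlobalAvgPool(), _nn.Dense(spec.n_filters, 1, rng)]
        self.net = _nn.Sequential(layers)
        self.mu = 0.0
        self.sigma = 1.0
        self.trained = False
        self.history: dict[str, list] = {}

    def set_normalization(self, images: np.ndarray) -> None:
        self.mu = float(np.mean(images))
        self.sigma = float(np.std(images)) or 1.0

    def scores(self, images: np.ndarray, batch_size: int = 500) -> np.ndarray:
        """Deterministic test statistics (logits), one per image."""
        images = np.asarray(images)
        out = np.empty(len(images), dtype=np.float64)
        for a in range(0, len(images), batch_size):
            b = min(a + batch_size, len(images))
            x = ((images[a:b] - self.mu) / self.sigma).astype(np.float32)[..., None]
            out[a:b] = self.net.forward(x, training=False)[:, 0]
        return out

    def state_dict(self) -> dict:
        return {f"p{k}": p.value.copy() for k, p in enumerate(self.net.params())}

    def load_state_dict(self, state: dict) -> None:
        for k, p in enumerate(self.net.params()):
            p.value = np.asarray(state[f"p{k}"], dtype=np.float32)

    def save(self, path) -> None:
        import json
        np.savez_compressed(path, _spec=json.dumps(self.spec.__dict__),
                            _norm=np.array([self.mu, self.sigma]),
                            **self.state_dict())

    @classmethod
    def load(cls, path) -> "CnnObserver":
        import json
        with np.load(path, allow_pickle=False) as data:
            spec = CnnObserverSpec(**json.loads(str(data["_spec"])))
            obs = cls(spec)
            obs.load_state_dict({k: data[k] for k in data.files
                                 if not k.startswith("_")})
            obs.mu, obs.sigma = (float(v) for v in data["_norm"])
        obs.trained = True
        return obs


def build_cnn_observer(spec: CnnObserverSpec) -> CnnObserver:
    """Untrained CNN observer per the spec (deterministic given its seed)."""
    return CnnObserver(spec)


def train_cnn_observer(observer: CnnObserver, train: ImageEnsemble,
                       validation: ImageEnsemble,
                       verbose: bool = False) -> dict:
    """Binary cross-entropy training; keeps the best-validation-AUC weights."""
    spec = observer.spec
    idx1 = np.flatnonzero(train.labels == 1)
    idx0 = np.flatnonzero(train.labels == 0)
    if len(idx1) == 0 or len(idx0) == 0:
        raise ValueError("training set must contain both classes")
    observer.set_normalization(train.images)
    x = ((train.images - observer.mu) / observer.sigma).astype(np.float32)[..., None]
    y = train.labels.astype(np.float64)
    v0, v1 = validation.split_classes()

    rng = np.random.default_rng(spec.seed + 1)
    bp = min(spec.batch_present, len(idx1))
    ba = min(spec.batch_absent, len(idx0))
    steps = spec.steps_per_epoch or max(1, (len(idx0) + len(idx1)) // (bp + ba))
    _nn.tune_conv_layers(observer.net.layers, bp + ba,
                         int(np.prod(train.images.shape[1:])))
    opt = _nn.Adam(observer.net.params(), lr=spec.lr)
    history = {"epoch": [], "train_loss": [], "val_auc": []}
    best = (-np.inf, None)
    stale = 0
    for epoch in range(spec.epochs):
        ep_loss = 0.0
        for _ in range(steps):
            sel = np.concatenate([rng.choice(idx1, bp, replace=False),
                                  rng.choice(idx0, ba, replace=False)])
            z = observer.net.forward(x[sel], training=True)[:, 0]
            loss, dz = _nn.bce_with_logits(z, y[sel])
            opt.zero_grad()
            observer.net.backward(dz[:, None])
            opt.step()
            ep_loss += loss
        val_auc = empirical_auc(observer.scores(v0), observer.scores(v1)).auc
        history["epoch"].append(epoch)
        history["train_loss"].append(ep_loss / steps)
        history["val_auc"].append(val_auc)
        if verbose:
            print(f"epoch {epoch}: loss {ep_loss / steps:.4f} val AUC {val_auc:.4f}")
        if val_auc > best[0]:
            best = (val_auc, observer.state_dict())
            stale = 0
        else:
            stale += 1
            if stale > spec.patience:
                break
    if best[1] is not None:
        observer.load_state_dict(best[1])
    observer.trained = True
    observer.history = history
    return history


def observer_statistics(observer: CnnObserver, images: np.ndarray) -> np.ndarray:
    """Scalar test statistic per image (deterministic at inference)."""
    if not observer.trained:
        raise ValueError("observer has not been trained")
    return observer.scores(np.asarray(images))
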