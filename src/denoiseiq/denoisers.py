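"""DNN-based image denoisers: linear, CNN, and ResNet families.

All three families map a noisy image to a denoised image of the same
size through stacks of 3x3 same-padded convolutions:

* ``linear``  -- D convolution layers with no nonlinearities (32 feature
  channels).  End-to-end the network is an affine map, which permits the
  exact propagation of means and covariance matrices through its layers
  (see :mod:`denoiseiq.covariance_propagation`).
* ``cnn``     -- Conv+ReLU, then Conv+BN+ReLU blocks, a Conv+BN block,
  and a final Conv collapsing 64 feature channels to the output image.
* ``resnet``  -- the cnn layout plus identity skip connections around
  every pair of middle blocks and one long skip from the first block's
  output to the last layer's input; conventionally trained with a
  perceptual (feature-space) loss.

Training minimizes the mean over the batch of per-image squared L2
error (or its feature-space analogue) with Adam at learning rate 1e-4 on
mini-batches of equal signal-present/signal-absent composition, keeping
the weights that achieve the best validation loss.

Images are standardized with scalar (mean, std) statistics of the
training inputs before entering the network and de-standardized on the
way out; the affine normalization is part of the model, folds into the
first/last layer operators for the linear family, and leaves reported
RMSE on the raw intensity scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from . import _nn
from .phantom_imaging import ImageEnsemble

__all__ = [
    "DenoiserArchitecture", "TrainingConfig", "DenoiserModel",
    "RandomConvFeatureExtractor", "IdentityFeatureExtractor",
    "build_denoiser", "mse_loss", "perceptual_loss",
    "train_denoiser", "denoise", "extract_layer_operators",
    "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class DenoiserArchitecture:
    family: str                    # linear | cnn | resnet
    depth: int                     # number of convolutional layers D
    features: Optional[int] = None  # default: 32 linear, 64 nonlinear

    def __post_init__(self):
        if self.family not in ("linear", "cnn", "resnet"):
            raise ValueError(f"unknown family {self.family!r}")
        dmin = 2 if self.family == "linear" else 3
        if self.depth < dmin:
            raise ValueError(f"{self.family} family requires depth >= {dmin}")

    @property
    def n_features(self) -> int:
        return self.features or (32 if self.family == "linear" else 64)


@dataclass
class TrainingConfig:
    """Denoiser training protocol.

    Mini-batches contain ``batch_present`` signal-present plus
    ``batch_absent`` signal-absent images drawn at random from the
    training set; optimization is Adam at ``lr``; the checkpoint with the
    best validation loss within ``epochs`` (early stop after
    ``patience`` non-improving epochs) is returned.
    ``low_noise_target_std``, when set, replaces the noise-free targets
    by independently perturbed low-noise targets (config hook).
    """

    loss: str = "mse"              # mse | perceptual
    lr: float = 1e-4
    batch_present: int = 200
    batch_absent: int = 200
    epochs: int = 200
    patience: int = 20
    seed: int = 0
    steps_per_epoch: Optional[int] = None
    low_noise_target_std: Optional[float] = None
    feature_extractor: Optional[object] = None  # for loss == "perceptual"

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_present <= 0 or self.batch_absent <= 0:
            raise ValueError("batch composition counts must be positive")
        if self.loss not in ("mse", "perceptual"):
            raise ValueError(f"unknown loss {self.loss!r}")


class DenoiserModel:
    """A denoising network: blocks of primitive layers plus a forward tape.

    The tape is a list of ops: ("block", i) applies block i,
    ("save", tag) snapshots the running activation, ("add", tag) adds a
    snapshot (skip connection).  The same tape drives the hand-written
    backward pass, so all three families share one training loop.
    """

    def __init__(self, arch: DenoiserArchitecture, blocks: list, tape: list):
        self.arch = arch
        self.blocks = blocks
        self.tape = tape
        self.mu = 0.0
        self.sigma = 1.0
        self.trained = False
        self.history: dict[str, list] = {}

    def params(self) -> list[_nn.Parameter]:
        return [p for blk in self.blocks for layer in blk for p in layer.params()]

    def set_normalization(self, images: np.ndarray) -> None:
        images = np.asarray(images)
        self.mu = float(images.mean())
        self.sigma = float(images.std()) or 1.0
        self.input_shape = tuple(images.shape[-2:])

    # -- forward/backward in normalized space, channels-last (N,H,W,1) --

    def forward_normalized(self, x: np.ndarray, training: bool = False,
                           upto_layer: Optional[int] = None) -> np.ndarray:
        """Run the tape; ``upto_layer`` truncates after that many conv blocks."""
        saved: dict[str, np.ndarray] = {}
        self._saved_order = []
        done = 0
        for op, tag in self.tape:
            if op == "block":
                for layer in self.blocks[tag]:
                    x = layer.forward(x, training=training)
                done += 1
                if upto_layer is not None and done == upto_layer:
                    return x
            elif op == "save":
                saved[tag] = x
            elif op == "add":
                x = x + saved[tag]
        if upto_layer is not None and upto_layer > done:
            raise ValueError(f"layer index {upto_layer} out of range (D={done})")
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        pending: dict[str, np.ndarray] = {}
        for op, tag in reversed(self.tape):
            if op == "block":
                for layer in reversed(self.blocks[tag]):
                    dout = layer.backward(dout)
                    if dout is None:  # first conv: input grad not required
                        return None
            elif op == "add":
                pending[tag] = pending.get(tag, 0.0) + dout
            elif op == "save":
                if tag in pending:
                    dout = dout + pending.pop(tag)
        return dout

    # -- public inference on raw image stacks --

    def denoise(self, images: np.ndarray, batch_size: int = 200) -> np.ndarray:
        """Deterministic inference (BN uses running statistics)."""
        images = np.asarray(images)
        squeeze = images.ndim == 2
        if squeeze:
            images = images[None]
        out = np.empty_like(images, dtype=np.float32)
        for a in range(0, len(images), batch_size):
            b = min(a + batch_size, len(images))
            x = ((images[a:b] - self.mu) / self.sigma).astype(np.float32)[..., None]
            y = self.forward_normalized(x, training=False)
            out[a:b] = y[..., 0] * self.sigma + self.mu
        return out[0] if squeeze else out

    def state_dict(self) -> dict:
        state = {"mu": self.mu, "sigma": self.sigma}
        for i, blk in enumerate(self.blocks):
            for j, layer in enumerate(blk):
                for k, p in enumerate(layer.params()):
                    state[f"p_{i}_{j}_{k}"] = p.value.copy()
                if isinstance(layer, _nn.BatchNorm2d):
                    state[f"bn_{i}_{j}_mean"] = layer.running_mean.copy()
                    state[f"bn_{i}_{j}_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        self.mu = float(state["mu"])
        self.sigma = float(state["sigma"])
        for i, blk in enumerate(self.blocks):
            for j, layer in enumerate(blk):
                for k, p in enumerate(layer.params()):
                    p.value = np.asarray(state[f"p_{i}_{j}_{k}"], dtype=np.float32)
                if isinstance(layer, _nn.BatchNorm2d):
                    layer.running_mean = np.asarray(state[f"bn_{i}_{j}_mean"],
                                                    dtype=np.float32)
                    layer.running_var = np.asarray(state[f"bn_{i}_{j}_var"],
                                                   dtype=np.float32)


def build_denoiser(arch: DenoiserArchitecture,
                   rng: np.random.Generator) -> DenoiserModel:
    """Construct an untrained denoiser of the requested family and depth."""
    d, f = arch.depth, arch.n_features
    if arch.family == "linear":
        blocks = [[_nn.Conv2d(1, f, rng)]]
        blocks += [[_nn.Conv2d(f, f, rng)] for _ in range(d - 2)]
        blocks += [[_nn.Conv2d(f, 1, rng)]]
        tape = [("block", i) for i in range(d)]
        return DenoiserModel(arch, blocks, tape)

    blocks = [[_nn.Conv2d(1, f, rng), _nn.ReLU()]]
    blocks += [[_nn.Conv2d(f, f, rng), _nn.BatchNorm2d(f), _nn.ReLU()]
               for _ in range(d - 3)]
    blocks += [[_nn.Conv2d(f, f, rng), _nn.BatchNorm2d(f)]]
    blocks += [[_nn.Conv2d(f, 1, rng)]]
    if arch.family == "cnn":
        tape = [("block", i) for i in range(d)]
    else:  # resnet: pairwise skips over middle blocks + one long skip
        tape = [("block", 0), ("save", "long")]
        mids = list(range(1, d - 1))
        i = 0
        while i + 1 < len(mids):
            tag = f"skip{mids[i]}"
            tape += [("save", tag), ("block", mids[i]), ("block", mids[i + 1]),
                     ("add", tag)]
            i += 2
        if i < len(mids):
            tape.append(("block", mids[i]))
        tape += [("add", "long"), ("block", d - 1)]
    return DenoiserModel(arch, blocks, tape)


# ---------------------------------------------------------------------------
# losses and feature extractors
# ---------------------------------------------------------------------------

def mse_loss(outputs: np.ndarray, targets: np.ndarray) -> float:
    """Mean over the batch of per-image squared L2 norms."""
    outputs, targets = np.asarray(outputs), np.asarray(targets)
    if outputs.shape != targets.shape:
        raise ValueError("outputs and targets must share a shape")
    n = outputs.shape[0] if outputs.ndim >= 3 else 1
    return float(((outputs.astype(np.float64) - targets) ** 2).sum() / n)


class IdentityFeatureExtractor:
    """phi(x) = x; makes the perceptual loss reduce to the MSE loss."""

    def forward(self, x, training=False):
        return x

    def backward(self, dout):
        return dout


class RandomConvFeatureExtractor:
    """Frozen fixed-seed convolutional feature bank for the perceptual loss.

    Two 3x3 conv layers with ReLU producing ``n_features`` maps at the
    input spatial size.  The filters are random, deterministic for a
    given seed, and never updated; gradients still flow through to the
    denoiser.  An externally pretrained extractor can be substituted by
    any object with the same forward/backward interface.
    """

    def __init__(self, n_features: int = 64, seed: int = 1234):
        rng = np.random.default_rng(seed)
        self.layers = [_nn.Conv2d(1, n_features, rng), _nn.ReLU(),
                       _nn.Conv2d(n_features, n_features, rng), _nn.ReLU()]
        self.n_features = n_features
        self.seed = seed

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        for p in (q for l in self.layers for q in l.params()):
            p.grad[...] = 0.0  # frozen: discard any accumulated gradient
        return dout


def perceptual_loss(outputs: np.ndarray, targets: np.ndarray,
                    extractor) -> float:
    """MSE loss evaluated in the extractor's feature space."""
    fo = extractor.forward(np.asarray(outputs, dtype=np.float32))
    ft = extractor.forward(np.asarray(targets, dtype=np.float32))
    return mse_loss(fo, ft)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _loss_and_grad(out, target, config):
    if config.loss == "mse":
        return _nn.mse_image_loss(out, target)
    phi = config.feature_extractor
    fo = phi.forward(out, training=True)
    ft = phi.forward(target, training=False)
    loss, dfeat = _nn.mse_image_loss(fo, ft)
    return loss, phi.backward(dfeat)


def train_denoiser(model: DenoiserModel, train: ImageEnsemble,
                   validation: ImageEnsemble, config: TrainingConfig,
                   verbose: bool = False, epoch_hook=None) -> dict:
    """Train in place; returns the history dict (also stored on the model).

    ``epoch_hook(epoch, model)``, when given, runs after each epoch's
    validation pass (e.g. to snapshot intermediate-budget metrics).
    """
    if train.targets is None or validation.targets is None:
        raise ValueError("training and validation ensembles need noise-free targets")
    if config.loss == "perceptual" and config.feature_extractor is None:
        config.feature_extractor = RandomConvFeatureExtractor()

    rng = np.random.default_rng(config.seed)
    model.set_normalization(train.images)
    mu, sig = model.mu, model.sigma

    xtr = ((train.images - mu) / sig).astype(np.float32)[..., None]
    targets = train.targets
    if config.low_noise_target_std is not None:
        targets = targets + rng.normal(
            0.0, config.low_noise_target_std, size=targets.shape)
    ttr = ((targets - mu) / sig).astype(np.float32)[..., None]
    xva = ((validation.images - mu) / sig).astype(np.float32)[..., None]
    tva = ((validation.targets - mu) / sig).astype(np.float32)[..., None]

    idx1 = np.flatnonzero(train.labels == 1)
    idx0 = np.flatnonzero(train.labels == 0)
    if len(idx1) == 0 or len(idx0) == 0:
        raise ValueError("training set must contain both classes")
    bp = min(config.batch_present, len(idx1))
    ba = min(config.batch_absent, len(idx0))
    steps = config.steps_per_epoch or max(1, (len(idx0) + len(idx1)) // (bp + ba))

    pixels = int(np.prod(train.images.shape[1:]))
    _nn.tune_conv_layers([l for blk in model.blocks for l in blk],
                         bp + ba, pixels)
    opt = _nn.Adam(model.params(), lr=config.lr)
    history = {"epoch": [], "train_loss": [], "val_loss": []}
    best = (np.inf, None)
    stale = 0
    for epoch in range(config.epochs):
        ep_loss = 0.0
        for _ in range(steps):
            sel = np.concatenate([rng.choice(idx1, bp, replace=False),
                                  rng.choice(idx0, ba, replace=False)])
            out = model.forward_normalized(xtr[sel], training=True)
            loss, dout = _loss_and_grad(out, ttr[sel], config)
            opt.zero_grad()
            model.backward(dout.astype(np.float32))
            opt.step()
            ep_loss += loss
        val = _validation_loss(model, xva, tva, config)
        history["epoch"].append(epoch)
        history["train_loss"].append(ep_loss / steps)
        history["val_loss"].append(val)
        if verbose:
            print(f"epoch {epoch}: train {ep_loss / steps:.5f} val {val:.5f}")
        if epoch_hook is not None:
            epoch_hook(epoch, model)
        if val < best[0]:
            best = (val, model.state_dict())
            stale = 0
        else:
            stale += 1
            if stale > config.patience:
                break
    if best[1] is not None:
        model.load_state_dict(best[1])
    model.trained = True
    model.history = history
    return history


def _validation_loss(model, xva, tva, config, batch: int = 200) -> float:
    total = 0.0
    for a in range(0, len(xva), batch):
        b = min(a + batch, len(xva))
        out = model.forward_normalized(xva[a:b], training=False)
        if config.loss == "mse":
            total += ((out.astype(np.float64) - tva[a:b]) ** 2).sum()
        else:
            phi = config.feature_extractor
            fo = phi.forward(out)
            ft = phi.forward(tva[a:b])
            total += ((fo.astype(np.float64) - ft) ** 2).sum()
    return total / len(xva)


def denoise(model: DenoiserModel, images: np.ndarray,
            batch_size: int = 200) -> np.ndarray:
    """Apply a trained denoiser to a stack of raw-scale images."""
    return model.denoise(images, batch_size=batch_size)


def extract_layer_operators(model: DenoiserModel,
                            image_shape: Optional[tuple[int, int]] = None):
    """Lift each layer of a *linear* denoiser to an explicit sparse operator.

    Returns a list of :class:`~denoiseiq.covariance_propagation.LayerOperator`
    such that applying all matrices and biases in order to a vectorized raw
    input reproduces the ``model.denoise`` output.  The scalar input/output
    standardization folds into the first and last operators, so the
    intermediate feature vectors live on the network's internal
    (standardized) scale while the final layer returns raw intensities.
    """
    if model.arch.family != "linear":
        raise ValueError("layer operators are defined for the linear family only")
    from .covariance_propagation import conv_layer_operator

    shape = image_shape or getattr(model, "input_shape", None)
    if shape is None:
        raise ValueError("image_shape is required for an untrained model")
    ops = []
    d = model.arch.depth
    for i, blk in enumerate(model.blocks):
        conv = blk[0]
        op = conv_layer_operator(conv.weight.value.astype(np.float64),
                                 conv.bias.value.astype(np.float64), shape)
        if i == 0:
            # z1 = W1 (x - mu)/sigma + b1  ->  (W1/sigma) x + (b1 - W1 mu/sigma 1)
            const = op.matrix @ np.full(op.matrix.shape[1], model.mu / model.sigma)
            op.bias = op.bias - const
            op.matrix = (op.matrix / model.sigma).tocsr()
        if i == d - 1:
            # raw output = sigma * (W_D z + b_D) + mu
            op.bias = model.sigma * op.bias + model.mu
            op.matrix = (model.sigma * op.matrix).tocsr()
        ops.append(op)
    return ops


def save_checkpoint(model: DenoiserModel, path) -> None:
    """Single-file archive: architecture descriptor + weights + history."""
    state = model.state_dict()
    np.savez_compressed(
        path,
        _arch=json.dumps(asdict(model.arch)),
        _history=json.dumps(model.history),
        _input_shape=np.asarray(getattr(model, "input_shape", (0, 0))),
        **state)


def load_checkpoint(path) -> DenoiserModel:
    with np.load(path, allow_pickle=False) as data:
        arch = DenoiserArchitecture(**json.loads(str(data["_arch"])))
        model = build_denoiser(arch, np.random.default_rng(0))
        state = {k: data[k] for k in data.files if not k.startswith("_")}
        model.load_state_dict(state)
        model.history = json.loads(str(data["_history"]))
        shape = tuple(int(v) for v in data["_input_shape"])
        if shape != (0, 0):
            model.input_shape = shape
    model.trained = True
    return model
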