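"""Synthetic nuclear-medicine image simulation for SKE/BKS detection studies.

The object model is a lumpy random background (a Poisson number of
isotropic Gaussian lumps with uniformly distributed centers) plus, under
the signal-present hypothesis, a deterministic Gaussian signal
(signal-known-exactly).  The imaging system is an idealized parallel-hole
collimator described by Gaussian point-response functions
``h_m(r) = A_m exp(-|r - r_m|^2 / (2 w_m^2))`` with ``A_m = h / (2 pi w_m^2)``,
one detector per pixel on the integer lattice.  Because every constituent
is Gaussian, the continuous-to-discrete integral has a closed form: a
Gaussian object component of amplitude ``A`` and width ``w`` centered at
``r_0`` contributes

    A * h * w^2 / (w_m^2 + w^2) * exp(-|r_m - r_0|^2 / (2 (w_m^2 + w^2)))

to detector ``m``.  Measurement noise is uncorrelated mixed
Poisson-Gaussian: each pixel is Poisson with mean equal to the noise-free
pixel value (clamped at zero), plus independent zero-mean Gaussian noise.

Two study presets are provided: a 32x32 study (linear denoising networks)
and a 64x64 study (nonlinear networks).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "LumpyBackgroundParams",
    "GaussianSignalParams",
    "CollimatorSystem",
    "NoiseParams",
    "LumpSet",
    "ImageEnsemble",
    "StudyConfig",
    "sample_lumps",
    "render_background",
    "render_background_stack",
    "render_signal",
    "render_noise_free_pair",
    "add_noise",
    "generate_dataset",
    "study_32",
    "study_64",
]


@dataclass(frozen=True)
class LumpyBackgroundParams:
    """Lumpy object model: Nb ~ Poisson(mean_lumps) Gaussian lumps."""

    mean_lumps: float = 15.0      # expected lump count per object
    amplitude: float = 5.0        # lump amplitude a, object units
    width: float = 3.0            # lump width w_b, pixels
    support: tuple[int, int] = (32, 32)

    def __post_init__(self):
        if self.mean_lumps <= 0:
            raise ValueError("mean_lumps must be positive")
        if self.amplitude <= 0 or self.width <= 0:
            raise ValueError("lump amplitude and width must be positive")


@dataclass(frozen=True)
class GaussianSignalParams:
    """Deterministic Gaussian signal (SKE)."""

    amplitude: float = 2.5        # A_s
    width: float = 1.0            # w_s, pixels
    center: tuple[float, float] = (16.0, 16.0)  # (row, col) pixel coords

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("signal amplitude must be nonnegative")
        if self.width <= 0:
            raise ValueError("signal width must be positive")


@dataclass(frozen=True)
class CollimatorSystem:
    """Idealized parallel-hole collimator: Gaussian PRF per pixel."""

    shape: tuple[int, int] = (32, 32)
    height: float = 20.0          # h
    psf_width: float = 2.0        # w_m, pixels

    @property
    def amplitude(self) -> float:
        """PRF amplitude A_m = h / (2 pi w_m^2)."""
        return self.height / (2.0 * np.pi * self.psf_width ** 2)

    def detector_grid(self) -> tuple[np.ndarray, np.ndarray]:
        rows = np.arange(self.shape[0], dtype=np.float64)
        cols = np.arange(self.shape[1], dtype=np.float64)
        return rows, cols


@dataclass(frozen=True)
class NoiseParams:
    """Uncorrelated mixed Poisson-Gaussian measurement noise."""

    gaussian_std: float = 25.0
    poisson: bool = True

    def __post_init__(self):
        if self.gaussian_std < 0:
            raise ValueError("gaussian_std must be nonnegative")


@dataclass
class LumpSet:
    """Sampled lump configuration: count and continuous (row, col) centers."""

    centers: np.ndarray  # (n_lumps, 2)

    @property
    def count(self) -> int:
        return len(self.centers)


@dataclass
class ImageEnsemble:
    """A labeled stack of images with optional noise-free targets.

    labels: 0 = signal-absent, 1 = signal-present.  ``params`` is a plain
    dict snapshot sufficient to regenerate the ensemble together with
    ``seed``.
    """

    images: np.ndarray
    labels: np.ndarray
    targets: Optional[np.ndarray] = None
    params: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self):
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have the same length")
        if self.targets is not None and self.targets.shape != self.images.shape:
            raise ValueError("targets must match images in shape")

    def __len__(self) -> int:
        return len(self.images)

    def split_classes(self) -> tuple[np.ndarray, np.ndarray]:
        """(signal-absent stack, signal-present stack)."""
        return self.images[self.labels == 0], self.images[self.labels == 1]

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("images", data=self.images, compression="gzip")
            f.create_dataset("labels", data=self.labels)
            if self.targets is not None:
                f.create_dataset("targets", data=self.targets, compression="gzip")
            for k, v in _flatten_params(self.params).items():
                f.attrs[k] = v
            if self.seed is not None:
                f.attrs["seed"] = self.seed

    @classmethod
    def load_h5(cls, path) -> "ImageEnsemble":
        import h5py

        with h5py.File(path, "r") as f:
            images = f["images"][...]
            labels = f["labels"][...]
            targets = f["targets"][...] if "targets" in f else None
            params = {k: v for k, v in f.attrs.items() if k != "seed"}
            seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
        return cls(images=images, labels=labels, targets=targets,
                   params=params, seed=seed)

    def save_npz(self, path) -> None:
        np.savez_compressed(path, images=self.images, labels=self.labels,
                            **({"targets": self.targets} if self.targets is not None else {}))


def _flatten_params(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten_params(v, prefix=f"{key}."))
        elif isinstance(v, (tuple, list)):
            out[key] = np.asarray(v)
        elif v is None:
            out[key] = "none"
        else:
            out[key] = v
    return out


# ---------------------------------------------------------------------------
# object sampling and analytic imaging
# ---------------------------------------------------------------------------

def sample_lumps(params: LumpyBackgroundParams, rng: np.random.Generator) -> LumpSet:
    """Draw one lump configuration: Poisson count, uniform continuous centers."""
    n = int(rng.poisson(params.mean_lumps))
    rows, cols = params.support
    centers = np.empty((n, 2))
    centers[:, 0] = rng.uniform(0.0, rows, size=n)
    centers[:, 1] = rng.uniform(0.0, cols, size=n)
    return LumpSet(centers=centers)


def _gaussian_component_image(centers: np.ndarray, amplitudes: np.ndarray,
                              width: float, system: CollimatorSystem) -> np.ndarray:
    """Closed-form image of a sum of Gaussian object components.

    Each component k with amplitude A_k, object width ``width`` and center
    centers[k] contributes
    A_k * h * width^2/(w_m^2+width^2) * exp(-|r_m - r_k|^2 / (2 (w_m^2+width^2))).
    Separable in row/column, evaluated via outer products.
    """
    rows, cols = system.detector_grid()
    var = system.psf_width ** 2 + width ** 2
    gain = system.height * width ** 2 / var
    if len(centers) == 0:
        return np.zeros(system.shape)
    er = np.exp(-((rows[None, :] - centers[:, 0:1]) ** 2) / (2 * var))  # (n, H)
    ec = np.exp(-((cols[None, :] - centers[:, 1:2]) ** 2) / (2 * var))  # (n, W)
    return gain * np.einsum("k,kh,kw->hw", amplitudes, er, ec)


def render_background(lumps: LumpSet, params: LumpyBackgroundParams,
                      system: CollimatorSystem) -> np.ndarray:
    """Noise-free background image of one lump configuration."""
    if system.shape != params.support:
        raise ValueError("system shape and lump support must agree")
    if lumps.count and (lumps.centers.min() < 0
                        or (lumps.centers >= np.asarray(params.support)).any()):
        raise ValueError("lump centers must lie inside the support")
    amps = np.full(lumps.count, params.amplitude)
    return _gaussian_component_image(lumps.centers, amps, params.width, system)


def render_background_stack(n_images: int, params: LumpyBackgroundParams,
                            system: CollimatorSystem,
                            rng: np.random.Generator) -> np.ndarray:
    """Vectorized batch of noise-free backgrounds; (n, H, W) float32."""
    if system.shape != params.support:
        raise ValueError("system shape and lump support must agree")
    counts = rng.poisson(params.mean_lumps, size=n_images)
    total = int(counts.sum())
    centers = np.empty((total, 2))
    centers[:, 0] = rng.uniform(0.0, params.support[0], size=total)
    centers[:, 1] = rng.uniform(0.0, params.support[1], size=total)
    rows, cols = system.detector_grid()
    var = system.psf_width ** 2 + params.width ** 2
    gain = params.amplitude * system.height * params.width ** 2 / var
    h, w = system.shape
    out = np.empty((n_images, h * w), dtype=np.float32)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    # chunk over images so the (lumps, H, W) scratch array stays small
    max_lumps = max(1, int(2.5e7 // (h * w)))
    i0 = 0
    while i0 < n_images:
        i1 = int(np.searchsorted(offsets, offsets[i0] + max_lumps, side="right"))
        i1 = min(max(i1 - 1, i0 + 1), n_images)
        a, b = offsets[i0], offsets[i1]
        cen = centers[a:b]
        er = np.exp(-((rows[None, :] - cen[:, 0:1]) ** 2) / (2 * var)).astype(np.float32)
        ec = np.exp(-((cols[None, :] - cen[:, 1:2]) ** 2) / (2 * var)).astype(np.float32)
        lump_imgs = (er[:, :, None] * ec[:, None, :]).reshape(b - a, h * w)
        # segment-sum lumps per image; reduceat misbehaves on empty segments
        seg = offsets[i0:i1] - a
        nonempty = counts[i0:i1] > 0
        if nonempty.all():
            out[i0:i1] = np.add.reduceat(lump_imgs, seg, axis=0)
        else:
            block = np.zeros((i1 - i0, h * w), dtype=np.float32)
            if nonempty.any():
                block[nonempty] = np.add.reduceat(lump_imgs, seg[nonempty], axis=0)
            out[i0:i1] = block
        i0 = i1
    return (gain * out).reshape(n_images, h, w)


def render_signal(params: GaussianSignalParams, system: CollimatorSystem) -> np.ndarray:
    """Deterministic noise-free signal image (closed form)."""
    r, c = params.center
    if not (0 <= r < system.shape[0] and 0 <= c < system.shape[1]):
        raise ValueError("signal center must lie inside the support")
    return _gaussian_component_image(
        np.array([[r, c]]), np.array([params.amplitude]), params.width, system)


def render_noise_free_pair(bg_params: LumpyBackgroundParams,
                           sig_params: GaussianSignalParams,
                           system: CollimatorSystem,
                           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One (signal-absent, signal-present) pair sharing the same lumps.

    By linearity of the imaging operator, present = absent + signal image.
    """
    bg = render_background(sample_lumps(bg_params, rng), bg_params, system)
    return bg, bg + render_signal(sig_params, system)


def add_noise(image: np.ndarray, noise: NoiseParams,
              rng: np.random.Generator) -> np.ndarray:
    """Apply mixed Poisson-Gaussian noise to a noise-free image (any stack shape).

    g = Poisson(max(image, 0)) + Normal(0, sigma^2), independently per pixel.
    """
    image = np.asarray(image)
    flat = image.reshape(-1)
    out = np.empty(flat.shape, dtype=np.float32)
    chunk = 16_000_000  # bound the int64/float64 scratch arrays
    for a in range(0, flat.size, chunk):
        b = min(a + chunk, flat.size)
        if noise.poisson:
            vals = rng.poisson(np.maximum(flat[a:b], 0.0)).astype(np.float32)
        else:
            vals = flat[a:b].astype(np.float32).copy()
        if noise.gaussian_std > 0:
            vals += rng.normal(0.0, noise.gaussian_std, size=b - a).astype(np.float32)
        out[a:b] = vals
    return out.reshape(image.shape)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyConfig:
    """Full parameterization of one simulation study.

    Default counts follow the standard protocol: 10,000+10,000 training
    pairs with targets, 200+200 validation pairs with targets,
    10,000+10,000 test images, 2,000+2,000 for observer regularization
    selection, and up to 100,000+100,000 for covariance estimation.
    ``scale`` uniformly rescales every per-class count (minimum 2).
    """

    background: LumpyBackgroundParams = field(default_factory=LumpyBackgroundParams)
    signal: GaussianSignalParams = field(default_factory=GaussianSignalParams)
    system: CollimatorSystem = field(default_factory=CollimatorSystem)
    noise: NoiseParams = field(default_factory=NoiseParams)
    n_train: int = 10_000
    n_validation: int = 200
    n_test: int = 10_000
    n_observer_calibration: int = 2_000
    n_covariance: int = 100_000
    scale: float = 1.0

    def __post_init__(self):
        for name in ("n_train", "n_validation", "n_test",
                     "n_observer_calibration", "n_covariance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0 < self.scale <= 1):
            raise ValueError("scale must be in (0, 1]")

    def count(self, name: str) -> int:
        n = getattr(self, f"n_{name}")
        return max(2, int(round(n * self.scale))) if n else 0

    def snapshot(self) -> dict:
        return {
            "background": asdict(self.background),
            "signal": asdict(self.signal),
            "system": asdict(self.system),
            "noise": asdict(self.noise),
            "counts": {k: self.count(k) for k in
                       ("train", "validation", "test",
                        "observer_calibration", "covariance")},
        }


def study_32(scale: float = 1.0, **overrides) -> StudyConfig:
    """32x32 study: linear denoising networks / covariance propagation."""
    kw = dict(
        background=LumpyBackgroundParams(mean_lumps=15, amplitude=5, width=3,
                                         support=(32, 32)),
        signal=GaussianSignalParams(amplitude=2.5, width=1.0, center=(16.0, 16.0)),
        system=CollimatorSystem(shape=(32, 32), height=20.0, psf_width=2.0),
        noise=NoiseParams(gaussian_std=25.0, poisson=True),
        scale=scale,
    )
    kw.update(overrides)
    return StudyConfig(**kw)


def study_64(scale: float = 1.0, **overrides) -> StudyConfig:
    """64x64 study: nonlinear CNN / ResNet denoising networks."""
    kw = dict(
        background=LumpyBackgroundParams(mean_lumps=50, amplitude=5, width=3,
                                         support=(64, 64)),
        signal=GaussianSignalParams(amplitude=3.0, width=2.0, center=(32.0, 32.0)),
        system=CollimatorSystem(shape=(64, 64), height=20.0, psf_width=2.0),
        noise=NoiseParams(gaussian_std=75.0, poisson=True),
        scale=scale,
    )
    kw.update(overrides)
    return StudyConfig(**kw)


def _make_split(config: StudyConfig, n_per_class: int, with_targets: bool,
                noisy: bool, rng: np.random.Generator, seed_note: int) -> ImageEnsemble:
    s = render_signal(config.signal, config.system).astype(np.float32)
    bg0 = render_background_stack(n_per_class, config.background, config.system, rng)
    bg1 = render_background_stack(n_per_class, config.background, config.system, rng)
    clean = np.concatenate([bg0, bg1 + s[None]], axis=0)
    labels = np.repeat([0, 1], n_per_class).astype(np.int8)
    images = add_noise(clean, config.noise, rng) if noisy else clean
    return ImageEnsemble(
        images=images, labels=labels,
        targets=clean if (with_targets and noisy) else None,
        params=config.snapshot(), seed=seed_note)


def generate_dataset(config: StudyConfig, seed: int,
                     splits: tuple[str, ...] = ("train", "validation", "test",
                                                "observer_calibration"),
                     targets_for: tuple[str, ...] = ("train", "validation"),
                     ) -> dict[str, ImageEnsemble]:
    """Generate the requested splits with independent seeded RNG streams.

    Splits: ``train``/``validation`` are noisy with noise-free targets,
    ``test`` and ``observer_calibration`` are noisy without targets by
    default (``targets_for`` widens this — the noise-free stacks are
    computed on the way regardless, so keeping them never changes the
    random stream), and ``covariance`` is the large *noise-free* ensemble
    used by the covariance decomposition method.  Regeneration from the
    same (config, seed) is byte-identical.
    """
    known = ("train", "validation", "test", "observer_calibration", "covariance")
    for s in splits:
        if s not in known:
            raise ValueError(f"unknown split {s!r}")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(known))
    out = {}
    for name, child in zip(known, children):
        if name not in splits:
            continue
        rng = np.random.default_rng(child)
        n = config.count(name)
        out[name] = _make_split(
            config, n,
            with_targets=name in targets_for,
            noisy=name != "covariance",
            rng=rng, seed_note=seed)
    return out
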