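"""ROC/AUC machinery, image-quality metrics, and experiment drivers.

The canonical detection figure of merit is the empirical (Mann-Whitney)
AUC with Hanley-McNeil standard errors; detection efficiency is the
ratio of an observer's AUC on denoised images to its AUC on the original
noisy images.  Traditional image-quality metrics are pooled RMSE (over
all pixels of all images) and mean SSIM against the noise-free targets.

The experiment drivers reproduce the study designs end to end: the
layerwise RHO propagation table for linear denoisers, the denoiser depth
sweep with all five numerical observers plus RMSE/SSIM, the
signal-size/efficiency grid, and the observer-depth sweep.  Every driver
is reproducible from (config, seed) and emits pandas DataFrames that the
CLI writes as CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from ._roc import (ROCResult, empirical_auc, hanley_mcneil_se,
                   bootstrap_auc_se, binormal_auc)
from . import phantom_imaging as phantom
from .phantom_imaging import ImageEnsemble, StudyConfig, study_32, study_64
from . import linear_observers as lo
from . import denoisers as dn
from . import covariance_propagation as cp

__all__ = [
    "ROCResult", "empirical_auc", "hanley_mcneil_se", "bootstrap_auc_se",
    "binormal_auc", "EfficiencyResult", "detection_efficiency",
    "rmse", "ssim_mean", "ExperimentConfig",
    "noisy_image_rho_auc", "final_layer_rho_auc", "evaluate_all_observers",
    "regenerate_test_targets", "plot_results",
    "run_table1", "run_depth_sweep", "run_signal_size_sweep",
    "run_observer_depth_sweep",
]


@dataclass(frozen=True)
class EfficiencyResult:
    """Detection efficiency e = AUC_denoised / AUC_noisy."""

    efficiency: float
    auc_denoised: float
    auc_noisy: float
    observer: str = ""
    denoiser: str = ""


def detection_efficiency(auc_denoised: float, auc_noisy: float,
                         observer: str = "", denoiser: str = "") -> EfficiencyResult:
    """Ratio of denoised to noisy AUC; may exceed 1 for sub-optimal observers."""
    if auc_noisy <= 0:
        raise ValueError("noisy AUC must be positive")
    return EfficiencyResult(efficiency=float(auc_denoised) / float(auc_noisy),
                            auc_denoised=float(auc_denoised),
                            auc_noisy=float(auc_noisy),
                            observer=observer, denoiser=denoiser)


def rmse(images: np.ndarray, targets: np.ndarray) -> float:
    """Root mean squared error pooled over all pixels of all images."""
    images, targets = np.asarray(images), np.asarray(targets)
    if images.shape != targets.shape:
        raise ValueError("images and targets must share a shape")
    return float(np.sqrt(np.mean((images.astype(np.float64) - targets) ** 2)))


def ssim_mean(images: np.ndarray, targets: np.ndarray,
              data_range: Optional[float] = None) -> float:
    """Mean SSIM over an ensemble (11x11 Gaussian window, K1=.01, K2=.03).

    ``data_range`` defaults to the dynamic range (max - min) of the
    target ensemble; the value of SSIM depends on this convention, so it
    is an explicit argument.
    """
    images, targets = np.asarray(images), np.asarray(targets)
    if images.ndim == 2:
        images, targets = images[None], targets[None]
    if images.shape != targets.shape:
        raise ValueError("images and targets must share a shape")
    if data_range is None:
        data_range = float(targets.max() - targets.min())
    if data_range == 0:
        raise ValueError("degenerate (constant) targets: specify data_range")
    vals = [structural_similarity(t.astype(np.float64), i.astype(np.float64),
                                  data_range=data_range, gaussian_weights=True,
                                  sigma=1.5, win_size=11,
                                  use_sample_covariance=False)
            for i, t in zip(images, targets)]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# reusable evaluation pipelines
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Driver configuration: study preset, grids, and budget knobs.

    ``scale`` rescales every ensemble count; training budgets are capped
    by ``epochs``/``steps_per_epoch`` so the drivers stay runnable on a
    single CPU.  Seeds for data and training are derived from ``seed``.
    """

    study: str = "32x32"                    # "32x32" | "64x64"
    depths: tuple = (3, 5, 7, 9, 11, 13)
    signal_widths: tuple = (1.0, 1.5, 2.0, 2.5, 3.0)
    observer_depths: tuple = (1, 2, 4, 6, 8, 10)
    scale: float = 1.0
    seed: int = 0
    epochs: int = 200
    patience: int = 20
    steps_per_epoch: Optional[int] = None
    batch_present: int = 200
    batch_absent: int = 200
    n_covariance: int = 100_000
    lambda_grid: tuple = lo.DEFAULT_LAMBDA_GRID
    outdir: Optional[str] = None

    def __post_init__(self):
        if not (0 < self.scale <= 1):
            raise ValueError("scale must be in (0, 1]")
        if not self.depths or not self.signal_widths or not self.observer_depths:
            raise ValueError("grids must be nonempty")

    def study_config(self, **overrides) -> StudyConfig:
        base = study_32 if self.study == "32x32" else study_64
        return base(scale=self.scale, n_covariance=self.n_covariance,
                    **overrides)

    def training_config(self, loss: str = "mse", seed_offset: int = 0
                        ) -> dn.TrainingConfig:
        return dn.TrainingConfig(
            loss=loss, batch_present=self.batch_present,
            batch_absent=self.batch_absent, epochs=self.epochs,
            patience=self.patience, steps_per_epoch=self.steps_per_epoch,
            seed=self.seed + 1000 + seed_offset)


def noisy_image_rho_auc(study: StudyConfig, seed: int,
                        lambda_grid: Sequence[float] = lo.DEFAULT_LAMBDA_GRID,
                        ) -> tuple[ROCResult, lo.RhoConfig, lo.CovarianceEstimate]:
    """Full RHO pipeline on noisy measurement images.

    Covariance via the decomposition method from the noise-free
    covariance split; lambda selected on the observer-calibration split;
    AUC evaluated on the test split.
    """
    data = phantom.generate_dataset(
        study, seed, splits=("covariance", "observer_calibration", "test"))
    nf0, nf1 = data["covariance"].split_classes()
    cov = lo.estimate_covariance_decomposition(nf0, nf1, study.noise)
    rho_cfg, tpl = lo.select_rho_lambda(cov, data["observer_calibration"],
                                        candidates=lambda_grid)
    g0, g1 = data["test"].split_classes()
    roc = empirical_auc(lo.apply_linear_template(tpl, g0),
                        lo.apply_linear_template(tpl, g1))
    return roc, rho_cfg, cov


def final_layer_rho_auc(model: dn.DenoiserModel, cov: lo.CovarianceEstimate,
                        validation: ImageEnsemble, test: ImageEnsemble,
                        lambda_grid: Sequence[float] = lo.DEFAULT_LAMBDA_GRID,
                        ) -> dict:
    """RHO AUC at the final layer of a trained linear denoiser."""
    depth = model.arch.depth
    res = cp.layerwise_rho_auc(model, cov, validation, test,
                               lambdas=lambda_grid, layers=[depth])
    return res[depth]


def evaluate_all_observers(noisy_cal: ImageEnsemble, noisy_test: ImageEnsemble,
                           cov: lo.CovarianceEstimate,
                           lambda_grid: Sequence[float] = lo.DEFAULT_LAMBDA_GRID,
                           internal_noise: float = 2.5,
                           cho_seed: int = 0,
                           signal_center: tuple | None = None) -> dict[str, ROCResult]:
    """HO (if well conditioned), RHO, CHO, and NPWMF on one test ensemble.

    ``cov`` must describe the same image distribution as the test set
    (noisy or denoised); the CHO estimates its channelized covariance
    from the calibration ensemble directly.
    """
    g0, g1 = noisy_test.split_classes()
    out: dict[str, ROCResult] = {}
    try:
        ho = lo.hotelling_template(cov)
        out["HO"] = empirical_auc(lo.apply_linear_template(ho, g0),
                                  lo.apply_linear_template(ho, g1))
    except np.linalg.LinAlgError:
        pass
    _, rho = lo.select_rho_lambda(cov, noisy_cal, candidates=lambda_grid)
    out["RHO"] = empirical_auc(lo.apply_linear_template(rho, g0),
                               lo.apply_linear_template(rho, g1))
    npw = lo.npwmf_template(cov)
    out["NPWMF"] = empirical_auc(lo.apply_linear_template(npw, g0),
                                 lo.apply_linear_template(npw, g1))
    shape = noisy_test.images.shape[1:]
    channels = lo.dog_channel_matrix(shape, center=signal_center)
    c0, c1 = noisy_cal.split_classes()
    v0, v1 = lo.channelize(channels, c0), lo.channelize(channels, c1)
    rng = np.random.default_rng(cho_seed)
    t0 = lo.cho_statistics(v0, v1, lo.channelize(channels, g0),
                           lo.InternalNoiseParams(internal_noise), rng)
    t1 = lo.cho_statistics(v0, v1, lo.channelize(channels, g1),
                           lo.InternalNoiseParams(internal_noise), rng)
    out["CHO"] = empirical_auc(t0, t1)
    return out


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def _train_linear_denoiser(config: ExperimentConfig, depth: int,
                           data: dict) -> dn.DenoiserModel:
    arch = dn.DenoiserArchitecture("linear", depth)
    model = dn.build_denoiser(arch, np.random.default_rng(config.seed + depth))
    tcfg = config.training_config(seed_offset=depth)
    dn.train_denoiser(model, data["train"], data["validation"], tcfg)
    return model


def run_table1(config: ExperimentConfig) -> pd.DataFrame:
    """Layerwise RHO propagation table for linear denoisers (32x32 study).

    Trains a linear denoiser per depth in ``config.depths``, propagates
    the input covariance and mean difference through its layers, and
    tabulates the RHO AUC at every layer next to the noisy-image AUC.
    """
    if config.study != "32x32":
        raise ValueError("the propagation study is defined on the 32x32 preset")
    study = config.study_config()
    noisy_roc, _, cov = noisy_image_rho_auc(study, config.seed,
                                            config.lambda_grid)
    data = phantom.generate_dataset(
        study, config.seed, splits=("train", "validation",
                                    "observer_calibration", "test"))
    rows = []
    for depth in config.depths:
        model = _train_linear_denoiser(config, depth, data)
        res = cp.layerwise_rho_auc(model, cov, data["observer_calibration"],
                                   data["test"], lambdas=config.lambda_grid)
        for layer, r in res.items():
            rows.append({"depth": depth, "layer": layer, "auc": r["auc"],
                         "lambda": r["lam"], "rank": r["rank"],
                         "noisy_auc": noisy_roc.auc, "se": noisy_roc.se})
    return pd.DataFrame(rows)


def _depth_sweep_denoised_metrics(model, test: ImageEnsemble,
                                  cal: ImageEnsemble,
                                  test_targets: np.ndarray,
                                  config: ExperimentConfig,
                                  signal_center) -> dict:
    den_test = ImageEnsemble(images=model.denoise(test.images),
                             labels=test.labels, params=test.params)
    den_cal = ImageEnsemble(images=model.denoise(cal.images),
                            labels=cal.labels, params=cal.params)
    d0, d1 = den_test.split_classes()
    cov = lo.estimate_covariance_empirical(
        *(den_cal.split_classes()))
    obs = evaluate_all_observers(den_cal, den_test, cov,
                                 config.lambda_grid,
                                 cho_seed=config.seed + 77,
                                 signal_center=signal_center)
    return {
        "observers": obs,
        "rmse": rmse(den_test.images, test_targets),
        "ssim": ssim_mean(den_test.images, test_targets),
    }


def run_depth_sweep(config: ExperimentConfig,
                    families: tuple = ("cnn", "resnet")) -> pd.DataFrame:
    """Denoiser depth sweep on the 64x64 study: observer AUCs + RMSE/SSIM.

    Trains a denoiser per (family, depth), evaluates HO/RHO/CHO/NPWMF on
    noisy and denoised test images, and reports AUC, efficiency, RMSE and
    SSIM per row.  (The CNN-IO column is produced separately by
    :func:`run_observer_depth_sweep` since observer training dominates
    the budget.)
    """
    study = config.study_config()
    data = phantom.generate_dataset(
        study, config.seed, splits=("train", "validation", "test",
                                    "observer_calibration"))
    # noisy test images with matching noise-free targets for RMSE/SSIM
    test_targets = regenerate_test_targets(study, config.seed)
    center = study.signal.center
    cov_noisy = lo.estimate_covariance_empirical(
        *data["observer_calibration"].split_classes())
    noisy_obs = evaluate_all_observers(
        data["observer_calibration"], data["test"], cov_noisy,
        config.lambda_grid, cho_seed=config.seed + 76, signal_center=center)

    rows = [{"family": "none", "depth": 0, "observer": k, "auc": v.auc,
             "se": v.se, "efficiency": 1.0,
             "rmse": rmse(data["test"].images, test_targets),
             "ssim": ssim_mean(data["test"].images, test_targets)}
            for k, v in noisy_obs.items()]
    for family in families:
        loss = "mse" if family in ("linear", "cnn") else "perceptual"
        for depth in config.depths:
            arch = dn.DenoiserArchitecture(family, depth)
            model = dn.build_denoiser(
                arch, np.random.default_rng(config.seed + depth))
            tcfg = config.training_config(loss=loss, seed_offset=depth)
            dn.train_denoiser(model, data["train"], data["validation"], tcfg)
            res = _depth_sweep_denoised_metrics(
                model, data["test"], data["observer_calibration"],
                test_targets, config, center)
            for k, v in res["observers"].items():
                if k not in noisy_obs:
                    continue
                rows.append({
                    "family": family, "depth": depth, "observer": k,
                    "auc": v.auc, "se": v.se,
                    "efficiency": v.auc / noisy_obs[k].auc,
                    "rmse": res["rmse"], "ssim": res["ssim"]})
    return pd.DataFrame(rows)


def regenerate_test_targets(study: StudyConfig, seed: int) -> np.ndarray:
    """Noise-free targets for the test split (regenerated from the seed)."""
    known = ("train", "validation", "test", "observer_calibration", "covariance")
    ss = np.random.SeedSequence(seed)
    children = dict(zip(known, ss.spawn(len(known))))
    rng = np.random.default_rng(children["test"])
    n = study.count("test")
    s = phantom.render_signal(study.signal, study.system).astype(np.float32)
    bg0 = phantom.render_background_stack(n, study.background, study.system, rng)
    bg1 = phantom.render_background_stack(n, study.background, study.system, rng)
    return np.concatenate([bg0, bg1 + s[None]], axis=0)


def run_signal_size_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """RHO detection efficiency over a (signal width, denoiser depth) grid.

    CNN denoisers with MSE loss; each signal width defines its own study
    (and hence its own training data, covariance, and observers).
    """
    rows = []
    for ws in config.signal_widths:
        study = config.study_config(
            signal=phantom.GaussianSignalParams(
                amplitude=3.0, width=float(ws), center=(32.0, 32.0)))
        data = phantom.generate_dataset(
            study, config.seed, splits=("train", "validation", "test",
                                        "observer_calibration"))
        cov_noisy = lo.estimate_covariance_empirical(
            *data["observer_calibration"].split_classes())
        _, rho = lo.select_rho_lambda(cov_noisy, data["observer_calibration"],
                                      candidates=config.lambda_grid)
        g0, g1 = data["test"].split_classes()
        noisy_auc = empirical_auc(lo.apply_linear_template(rho, g0),
                                  lo.apply_linear_template(rho, g1)).auc
        for depth in config.depths:
            arch = dn.DenoiserArchitecture("cnn", depth)
            model = dn.build_denoiser(
                arch, np.random.default_rng(config.seed + depth))
            dn.train_denoiser(model, data["train"], data["validation"],
                              config.training_config(seed_offset=depth))
            den_cal = ImageEnsemble(
                images=model.denoise(data["observer_calibration"].images),
                labels=data["observer_calibration"].labels)
            den_test = ImageEnsemble(images=model.denoise(data["test"].images),
                                     labels=data["test"].labels)
            cov_d = lo.estimate_covariance_empirical(*den_cal.split_classes())
            _, rho_d = lo.select_rho_lambda(cov_d, den_cal,
                                            candidates=config.lambda_grid)
            d0, d1 = den_test.split_classes()
            auc_d = empirical_auc(lo.apply_linear_template(rho_d, d0),
                                  lo.apply_linear_template(rho_d, d1)).auc
            eff = detection_efficiency(auc_d, noisy_auc, observer="RHO",
                                       denoiser=f"cnn-{depth}")
            rows.append({"signal_width": ws, "depth": depth,
                         "auc_noisy": noisy_auc, "auc_denoised": auc_d,
                         "efficiency": eff.efficiency})
    return pd.DataFrame(rows)


def plot_results(kind: str, df: pd.DataFrame, path) -> None:
    """Quick-look figure for a driver result table (PNG/PDF by suffix).

    kind: "table1" | "depth-sweep" | "signal-size-sweep" |
    "observer-depth-sweep".
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    if kind == "table1":
        for depth, grp in df.groupby("depth"):
            ax.plot(grp["layer"], grp["auc"], marker="o", label=f"D={depth}")
        ax.axhline(df["noisy_auc"].iloc[0], ls="--", c="k", label="noisy")
        ax.set_xlabel("layer index")
        ax.set_ylabel("RHO AUC")
    elif kind == "depth-sweep":
        sub = df[df["depth"] > 0]
        for (family, obs), grp in sub.groupby(["family", "observer"]):
            ax.plot(grp["depth"], grp["auc"], marker="o",
                    label=f"{obs} ({family})")
        for _, row in df[df["depth"] == 0].iterrows():
            ax.axhline(row["auc"], ls="--", alpha=0.4)
        ax.set_xlabel("denoising network depth")
        ax.set_ylabel("AUC")
    elif kind == "signal-size-sweep":
        for ws, grp in df.groupby("signal_width"):
            ax.plot(grp["depth"], grp["efficiency"], marker="o",
                    label=f"w_s={ws}")
        ax.set_xlabel("denoising network depth")
        ax.set_ylabel("RHO detection efficiency")
    elif kind == "observer-depth-sweep":
        for (tag, ddepth), grp in df.groupby(["images", "denoiser_depth"]):
            label = "noisy" if tag == "noisy" else f"{tag} D={ddepth}"
            ax.plot(grp["observer_depth"], grp["auc"], marker="o", label=label)
        ax.set_xlabel("observer depth")
        ax.set_ylabel("AUC")
    else:
        raise ValueError(f"unknown result kind {kind!r}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_observer_depth_sweep(config: ExperimentConfig,
                             denoiser_depths: tuple = (3, 9, 11),
                             families: tuple = ("cnn",)) -> pd.DataFrame:
    """CNN-observer AUC versus observer depth on noisy and denoised images."""
    from . import cnn_observer as co

    study = config.study_config()
    data = phantom.generate_dataset(
        study, config.seed, splits=("train", "validation", "test"))
    eval_sets = {("noisy", 0): (data["train"], data["validation"], data["test"])}
    for family in families:
        loss = "mse" if family == "cnn" else "perceptual"
        for depth in denoiser_depths:
            arch = dn.DenoiserArchitecture(family, depth)
            model = dn.build_denoiser(
                arch, np.random.default_rng(config.seed + depth))
            dn.train_denoiser(model, data["train"], data["validation"],
                              config.training_config(loss=loss,
                                                     seed_offset=depth))
            mk = lambda ens: ImageEnsemble(images=model.denoise(ens.images),
                                           labels=ens.labels,
                                           targets=ens.targets)
            eval_sets[(family, depth)] = (mk(data["train"]),
                                          mk(data["validation"]),
                                          mk(data["test"]))
    rows = []
    for (tag, ddepth), (tr, va, te) in eval_sets.items():
        for odepth in config.observer_depths:
            spec = co.CnnObserverSpec(
                n_layers=odepth, lr=1e-4,
                batch_present=config.batch_present,
                batch_absent=config.batch_absent,
                epochs=config.epochs, patience=config.patience,
                steps_per_epoch=config.steps_per_epoch,
                seed=config.seed + 10 * odepth)
            obs = co.build_cnn_observer(spec)
            co.train_cnn_observer(obs, tr, va)
            g0, g1 = te.split_classes()
            roc = empirical_auc(obs.scores(g0), obs.scores(g1))
            rows.append({"images": tag, "denoiser_depth": ddepth,
                         "observer_depth": odepth, "auc": roc.auc,
                         "se": roc.se})
    return pd.DataFrame(rows)
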