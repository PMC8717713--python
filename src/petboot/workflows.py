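"""End-to-end experiment orchestration.

The two headline experiments mirror the simulation harness used to
validate the image-domain bootstrap: a 2-D attenuated-Radon/FBP study
calibrating bootstrap flux SDs against replication truth, and a 1-D
Poisson-deconvolution study comparing projection-domain and image-domain
bootstrap SDs.  Both are deterministic under a master seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .basis import build_nprm_basis, cluster_timecourses
from .bootstrap import BootstrapSet, image_bootstrap, projection_bootstrap, recycle_bootstrap
from .evaluation import calibrate, replication_truth, rmse_table
from .glm import fit_glm, initial_weights, wls_alpha
from .kinetics import (
    DEFAULT_T_B,
    PARAM_NAMES,
    element_summaries,
    kinetic_params,
    map_bootstrap_kinetics,
    nnls_map,
)
from .scanner import (
    Operator1D,
    RadonTransform2D,
    SinogramGeometry2D,
    calibrate_reference_dose_1d,
    calibrate_reference_dose_2d,
    default_schedule,
    fbp_reconstruct_2d,
    ls_reconstruct_1d,
    make_phantom,
    radon_project,
    select_bandwidth,
    simulate_counts,
)
from .study import DynamicImage, VoxelGrid

__all__ = [
    "ExperimentConfig",
    "run_full_experiment",
    "run_2d_calibration_experiment",
    "run_1d_agreement_experiment",
    "run_bootstrap_rmse_comparison",
]


@dataclass
class ExperimentConfig:
    """Validated configuration for an end-to-end experiment run."""

    mode: str = "2d"
    tracer: str = "fdg"
    image_size: int = 32
    n_frames: int = 20
    n_truth: int = 20
    n_boot: int = 10
    n_retained: int = 5
    n_recycled: int = 50
    n_clusters: int = 8
    l_bins: int = 32
    target_noise: float = 0.15
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if self.mode not in ("1d", "2d"):
            raise ValueError(f"mode must be '1d' or '2d', got {self.mode!r}")
        if self.tracer not in ("fdg", "flt"):
            raise ValueError(f"tracer must be 'fdg' or 'flt', got {self.tracer!r}")
        if self.n_frames < 4 or self.image_size < 4:
            raise ValueError("experiment too small to be meaningful")
        if self.n_clusters + 2 >= self.n_frames:
            raise ValueError("n_clusters + 2 must stay below the number of frames")
        if min(self.n_truth, self.n_boot) < 2:
            raise ValueError("need at least 2 replicates")

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        cfg = cls(**json.loads(Path(path).read_text()))
        cfg.validate()
        return cfg


def _flux_index() -> int:
    return PARAM_NAMES.index("ki")


class _Pipeline2D:
    """Shared 2-D machinery: phantom, projector, dose, bandwidth, basis."""

    def __init__(self, image_size, n_frames, tracer, n_clusters, target_noise, seed, min_k=2):
        self.grid = VoxelGrid((image_size, image_size, 1), (2.0, 2.0, 2.0))
        self.schedule = default_schedule(n_frames)
        self.phantom = make_phantom("2d", tracer, self.grid, self.schedule, seed=seed)
        self.geom = SinogramGeometry2D.scaled(image_size)
        self.op = RadonTransform2D(self.geom)
        self.tau = calibrate_reference_dose_2d(self.phantom, self.op, target_noise, seed=seed)
        # expected counts scale with frame duration (exposure = tau * dt_j)
        self.exposure = self.tau * self.schedule.durations
        self.rates = (
            radon_project(self.phantom.truth, self.op, self.phantom.attenuation)
            * self.schedule.durations[None, None, :]
        )
        truth_imgs = self.grid.unflatten(self.phantom.truth)[:, :, 0, :]
        counts0 = simulate_counts(self.rates, self.tau, seed=seed + 1)
        bws = self.geom.pixel_size * np.array([0.5, 0.75, 1.0, 1.5, 2.25, 3.5])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.bandwidth = select_bandwidth(
                lambda b: fbp_reconstruct_2d(
                    counts0, self.op, self.phantom.attenuation, self.exposure, b
                ),
                bws,
                truth_imgs,
            )
        self.counts0 = counts0
        self.study0 = self.reconstruct(counts0)
        frame_means = self.study0.values.mean(axis=0)
        self.w0, self.phi0 = initial_weights(self.schedule, frame_means)
        clusters = cluster_timecourses(self.study0, n_clusters, weights=self.w0, seed=seed)
        self.basis = build_nprm_basis(
            clusters, self.phantom.aif, self.schedule, weights=self.w0, min_k=min_k
        )
        self.summaries = element_summaries(
            self.basis, t_b=DEFAULT_T_B, t_e=self.schedule.end_time
        )

    def reconstruct(self, counts) -> DynamicImage:
        imgs = fbp_reconstruct_2d(
            counts, self.op, self.phantom.attenuation, self.exposure, self.bandwidth
        )
        values = imgs.reshape(self.grid.n_voxels, -1, order="F")
        return DynamicImage(values=values, grid=self.grid, schedule=self.schedule)

    def map_kinetics(self, values) -> np.ndarray:
        alpha = nnls_map(values, self.basis.design, self.w0)
        return kinetic_params(alpha, self.summaries).stacked()


def run_2d_calibration_experiment(
    image_size: int = 64,
    n_frames: int = 20,
    n_truth: int = 60,
    n_boot: int = 25,
    tracer: str = "fdg",
    n_clusters: int = 16,
    l_bins: int = 48,
    target_noise: float = 0.12,
    seed: int = 1,
    min_k: int = 6,
) -> dict:
    """Calibration of image-domain bootstrap voxel SDs against replication truth.

    Simulates ``n_truth`` independent scan/reconstruct/map replicates for
    the target SDs, fits the heteroscedastic model to one dataset, draws
    ``n_boot`` image-domain bootstrap replicates, and regresses true on
    bootstrap SDs through the origin for every kinetic parameter.
    """
    pipe = _Pipeline2D(image_size, n_frames, tracer, n_clusters, target_noise, seed, min_k=min_k)

    def sim_and_map(rep_seed):
        counts = simulate_counts(pipe.rates, pipe.tau, seed=rep_seed)
        study = pipe.reconstruct(counts)
        return pipe.map_kinetics(study.values), study.values

    truth = replication_truth(
        sim_and_map, n_truth, seed=seed + 100, truth=pipe.phantom.truth, frame_weights=pipe.w0
    )

    fit = fit_glm(pipe.study0, pipe.basis, l_bins=l_bins)
    bset = image_bootstrap(fit, n_boot, seed=seed + 200)
    _, _, sd_maps = map_bootstrap_kinetics(bset, pipe.basis.design, pipe.w0, pipe.summaries)

    calibrations = {}
    for p, name in enumerate(PARAM_NAMES):
        try:
            calibrations[name] = calibrate(truth["sd"][p], sd_maps[name])
        except ValueError:
            continue
    flux = calibrations["ki"]
    return {
        "r2_flux": flux.r_squared,
        "slope_flux": flux.slope,
        "calibrations": calibrations,
        "truth": truth,
        "bootstrap_sd": sd_maps,
        "fit": fit,
        "pipeline": pipe,
        "tau": pipe.tau,
        "bandwidth": pipe.bandwidth,
    }


class _Pipeline1D:
    """Shared 1-D machinery: phantom, operator, dose, bandwidth, basis."""

    def __init__(self, n, n_frames, tracer, beta, n_clusters, target_noise, seed, min_k=2,
                 total_duration=60.0):
        self.grid = VoxelGrid((n, 1, 1), (2.0, 2.0, 2.0))
        self.schedule = default_schedule(n_frames, total=total_duration)
        self.phantom = make_phantom("1d", tracer, self.grid, self.schedule, seed=seed)
        self.op = Operator1D(n, beta)
        self.tau = calibrate_reference_dose_1d(self.phantom, self.op, target_noise, seed=seed)
        self.exposure = self.tau * self.schedule.durations
        self.rates = (
            self.phantom.attenuation[:, None]
            * self.op.apply(self.phantom.truth)
            * self.schedule.durations[None, :]
        )
        counts0 = simulate_counts(self.rates, self.tau, seed=seed + 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.bandwidth = select_bandwidth(
                lambda b: ls_reconstruct_1d(counts0, self.op, self.phantom.attenuation, self.exposure, b),
                np.array([0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.5]),
                self.phantom.truth,
            )
        self.counts0 = counts0
        self.study0 = self.reconstruct(counts0)
        frame_means = self.study0.values.mean(axis=0)
        self.w0, self.phi0 = initial_weights(self.schedule, frame_means)
        clusters = cluster_timecourses(self.study0, n_clusters, weights=self.w0, seed=seed)
        self.basis = build_nprm_basis(
            clusters, self.phantom.aif, self.schedule, weights=self.w0, min_k=min_k
        )
        self.summaries = element_summaries(self.basis, t_b=DEFAULT_T_B, t_e=self.schedule.end_time)

    def reconstruct(self, counts) -> DynamicImage:
        values = ls_reconstruct_1d(
            counts, self.op, self.phantom.attenuation, self.exposure, self.bandwidth
        )
        return DynamicImage(values=values, grid=self.grid, schedule=self.schedule)


def run_1d_agreement_experiment(
    n: int = 128,
    n_frames: int = 20,
    n_boot: int = 25,
    tracer: str = "fdg",
    beta: float = 1.35,
    n_clusters: int = 12,
    l_bins: int = 32,
    target_noise: float = 0.12,
    seed: int = 1,
    min_k: int = 2,
    total_duration: float = 60.0,
    n_datasets: int = 1,
) -> dict:
    """Projection-domain vs image-domain bootstrap SD agreement, 1-D scanner.

    Every simulated dataset receives both a multinomial projection-domain
    bootstrap (reconstructing every count replicate) and a model-based
    image-domain bootstrap, ``n_boot`` replicates each, with kinetics
    mapped per replicate.  Voxel SDs averaged over the ``n_datasets``
    replicate datasets are regressed (projection on image) through the
    origin, pooled over the six kinetic parameters.
    """
    pipe = _Pipeline1D(n, n_frames, tracer, beta, n_clusters, target_noise, seed,
                       min_k=min_k, total_duration=total_duration)

    fit = None
    img_acc = {name: [] for name in PARAM_NAMES}
    proj_acc = {name: [] for name in PARAM_NAMES}
    for s in range(n_datasets):
        if s == 0:
            counts, study = pipe.counts0, pipe.study0
        else:
            counts = simulate_counts(pipe.rates, pipe.tau, seed=seed + 10_000 + s)
            study = pipe.reconstruct(counts)
        fit_s = fit_glm(study, pipe.basis, l_bins=l_bins)
        if fit is None:
            fit = fit_s
        b_img = image_bootstrap(fit_s, n_boot, seed=seed + 200 + 1000 * s)
        _, _, sd_i = map_bootstrap_kinetics(b_img, pipe.basis.design, pipe.w0, pipe.summaries)
        count_reps = projection_bootstrap(counts, n_boot, seed=seed + 300 + 1000 * s)
        value_reps = [pipe.reconstruct(c).values for c in count_reps]
        b_proj = BootstrapSet(kind="projection", replicates=value_reps, seed=seed + 300 + 1000 * s)
        _, _, sd_p = map_bootstrap_kinetics(b_proj, pipe.basis.design, pipe.w0, pipe.summaries)
        for name in PARAM_NAMES:
            img_acc[name].append(sd_i[name])
            proj_acc[name].append(sd_p[name])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd_img = {name: np.nanmean(np.stack(v), axis=0) for name, v in img_acc.items()}
        sd_proj = {name: np.nanmean(np.stack(v), axis=0) for name, v in proj_acc.items()}

    pooled_img = np.concatenate([sd_img[name] for name in PARAM_NAMES])
    pooled_proj = np.concatenate([sd_proj[name] for name in PARAM_NAMES])
    pooled = calibrate(pooled_proj, pooled_img)
    per_param = {}
    for name in PARAM_NAMES:
        try:
            per_param[name] = calibrate(sd_proj[name], sd_img[name])
        except ValueError:
            continue
    return {
        "r2_pooled": pooled.r_squared,
        "slope_pooled": pooled.slope,
        "per_param": per_param,
        "sd_image": sd_img,
        "sd_projection": sd_proj,
        "fit": fit,
        "pipeline": pipe,
        "tau": pipe.tau,
        "bandwidth": pipe.bandwidth,
    }


def run_bootstrap_rmse_comparison(
    image_size: int = 24,
    n_frames: int = 16,
    n_truth: int = 40,
    n_outer: int = 6,
    n_boot: int = 15,
    n_retained: int = 8,
    n_recycled: int = 100,
    n_clusters: int = 8,
    l_bins: int = 24,
    seed: int = 0,
) -> dict:
    """RMSE of recycled vs full image-domain bootstrap SDs, matched seeds.

    The data generator IS the fitted model (correct specification):
    replicate studies are simulated from a reference fit, so the
    replication-true SDs and both bootstrap SD estimates target the same
    quantity.  Returns per-parameter RMSEs for the full image-domain
    bootstrap and the recycled approximation.
    """
    pipe = _Pipeline2D(image_size, n_frames, "fdg", n_clusters, 0.15, seed)
    ref_fit = fit_glm(pipe.study0, pipe.basis, l_bins=l_bins)

    gen = image_bootstrap(ref_fit, n_truth, seed=seed + 1000)
    truth_stack = np.stack([pipe.map_kinetics(rep) for rep in gen.replicates])
    true_sd = np.nanstd(truth_stack, axis=0, ddof=1)  # (P, N)

    rmse_img, rmse_rec = {name: [] for name in PARAM_NAMES}, {name: [] for name in PARAM_NAMES}
    outer = image_bootstrap(ref_fit, n_outer, seed=seed + 2000)
    for s, z_s in enumerate(outer.replicates):
        study_s = DynamicImage(values=z_s, grid=pipe.grid, schedule=pipe.schedule)
        fit_s = fit_glm(study_s, pipe.basis, l_bins=l_bins)
        b_s = image_bootstrap(fit_s, n_boot, seed=seed + 3000 + s)
        _, _, sd_full = map_bootstrap_kinetics(b_s, pipe.basis.design, pipe.w0, pipe.summaries)
        alphas = [wls_alpha(rep, pipe.basis, fit_s.w0)[0] for rep in b_s.replicates[:n_retained]]
        recycled = recycle_bootstrap(alphas, fit_s, n_recycled, seed=seed + 4000 + s)
        _, _, sd_rec = map_bootstrap_kinetics(
            recycled, pipe.basis.design, pipe.w0, pipe.summaries
        )
        for p, name in enumerate(PARAM_NAMES):
            rmse_img[name].append(sd_full[name])
            rmse_rec[name].append(sd_rec[name])

    out = {"rmse_image": {}, "rmse_recycled": {}, "true_sd": true_sd}
    for p, name in enumerate(PARAM_NAMES):
        out["rmse_image"][name] = rmse_table(np.stack(rmse_img[name]), true_sd[p])[0]
        out["rmse_recycled"][name] = rmse_table(np.stack(rmse_rec[name]), true_sd[p])[0]
    return out


def run_full_experiment(config: ExperimentConfig) -> dict:
    """Phantom -> scan -> reconstruct -> fit -> bootstraps -> evaluation tables.

    Writes a manifest (JSON) plus result tables under ``output_dir`` when
    given; returns the manifest dict.  Deterministic under the config seed.
    """
    config.validate()
    stage = "setup"
    try:
        if config.mode == "2d":
            stage = "2d-calibration"
            result = run_2d_calibration_experiment(
                image_size=config.image_size,
                n_frames=config.n_frames,
                n_truth=config.n_truth,
                n_boot=config.n_boot,
                tracer=config.tracer,
                n_clusters=config.n_clusters,
                l_bins=config.l_bins,
                target_noise=config.target_noise,
                seed=config.seed,
            )
            summary = {
                name: {"slope": c.slope, "r_squared": c.r_squared}
                for name, c in result["calibrations"].items()
            }
        else:
            stage = "1d-agreement"
            result = run_1d_agreement_experiment(
                n=config.image_size,
                n_frames=config.n_frames,
                n_boot=config.n_boot,
                tracer=config.tracer,
                n_clusters=config.n_clusters,
                l_bins=config.l_bins,
                target_noise=config.target_noise,
                seed=config.seed,
            )
            summary = {
                name: {"slope": c.slope, "r_squared": c.r_squared}
                for name, c in result["per_param"].items()
            }
            summary["pooled"] = {"slope": result["slope_pooled"], "r_squared": result["r2_pooled"]}
    except Exception as exc:
        raise RuntimeError(f"experiment failed at stage '{stage}': {exc}") from exc

    manifest = {
        "config": asdict(config),
        "stage": "complete",
        "tau": result["tau"],
        "bandwidth": result["bandwidth"],
        "summary": summary,
    }
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        import pandas as pd

        pd.DataFrame(summary).T.to_csv(out / "calibration.tsv", sep="\t")
        manifest["outputs"] = ["manifest.json", "calibration.tsv"]
    return manifest
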