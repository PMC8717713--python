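"""Replication truth, calibration regressions, RMSE and ROI summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CalibrationResult",
    "ROISet",
    "calibrate",
    "rmse_table",
    "relative_error_model",
    "replication_truth",
    "make_nested_rois",
    "roi_analysis",
]


@dataclass
class CalibrationResult:
    """Through-origin calibration of bootstrap SDs against replication truth."""

    slope: float
    r_squared: float
    rmse: float = np.nan
    rmse_pct: float = np.nan
    n: int = 0
    extras: dict = field(default_factory=dict)


@dataclass
class ROISet:
    """Rectangular regions of interest from a nested grid construction."""

    masks: list  # boolean arrays over voxels
    sizes: np.ndarray  # voxel count per ROI
    levels: np.ndarray  # nesting level per ROI

    @property
    def n_rois(self) -> int:
        return len(self.masks)


def calibrate(true_sd: np.ndarray, est_sd: np.ndarray) -> CalibrationResult:
    """No-intercept regression of true SDs on estimated SDs.

    Slope ``sum(xy)/sum(x^2)`` of true-on-estimated; the coefficient of
    determination is uncentered (computed about zero), as appropriate for
    a through-origin model.
    """
    y = np.asarray(true_sd, dtype=float).ravel()
    x = np.asarray(est_sd, dtype=float).ravel()
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    sxx = float(np.sum(x * x))
    if sxx <= 0:
        raise ValueError("degenerate (all-zero) predictor in calibration regression")
    slope = float(np.sum(x * y)) / sxx
    syy = float(np.sum(y * y))
    resid = float(np.sum((y - slope * x) ** 2))
    r2 = 1.0 - resid / syy if syy > 0 else 1.0
    return CalibrationResult(slope=slope, r_squared=r2, n=x.size)


def rmse_table(est_sd_per_replicate: np.ndarray, true_sd: np.ndarray, scale: float | None = None):
    """Root mean squared error of estimated SDs over voxels and replicates.

    ``est_sd_per_replicate`` is ``(N_S, N)`` (a single ``(N,)`` vector is
    treated as one replicate).  When ``scale`` is given the RMSE is also
    reported as a percentage of it.
    """
    est = np.atleast_2d(np.asarray(est_sd_per_replicate, dtype=float))
    true = np.asarray(true_sd, dtype=float)
    if est.shape[1] != true.size:
        raise ValueError("estimate/truth shapes do not agree")
    diff = est - true[None, :]
    keep = np.isfinite(diff)
    rmse = float(np.sqrt(np.mean(diff[keep] ** 2)))
    pct = 100.0 * rmse / scale if scale else np.nan
    return rmse, pct


def relative_error_model(sigma: np.ndarray, mu: np.ndarray, sigma_recon: np.ndarray):
    """Log-log regression of relative parameter SD on scaled reconstruction error.

    Fits ``log(sigma/mu) = g0 + g1 log(sigma_recon/mu)`` by ordinary
    least squares over voxels with strictly positive, finite entries.
    Returns ``(g0, g1, r_squared)``.
    """
    s = np.asarray(sigma, dtype=float).ravel()
    m = np.asarray(mu, dtype=float).ravel()
    sr = np.asarray(sigma_recon, dtype=float).ravel()
    keep = np.isfinite(s) & np.isfinite(m) & np.isfinite(sr) & (s > 0) & (m > 0) & (sr > 0)
    if keep.sum() < 10:
        raise ValueError(f"only {keep.sum()} valid voxels; need at least 10")
    y = np.log(s[keep] / m[keep])
    x = np.log(sr[keep] / m[keep])
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return float(coef[0]), float(coef[1]), float(r2)


def replication_truth(
    simulate_and_map,
    n_replicates: int,
    seed: int = 0,
    truth: np.ndarray | None = None,
    frame_weights: np.ndarray | None = None,
):
    """Target voxel SDs of mapped parameters, by direct replication.

    ``simulate_and_map(replicate_seed)`` must return a pair
    ``(param_stack, recon)`` with ``param_stack`` a ``(P, N)`` parameter
    array and ``recon`` the ``(N, T)`` reconstructed data.  Returns a
    dict with per-parameter SDs and means (``(P, N)``), plus the mean
    weighted reconstruction error ``sigma_recon`` per voxel when the
    noise-free truth is supplied.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    stacks, recon_errs = [], []
    for s in seeds:
        params, recon = simulate_and_map(int(s))
        stacks.append(np.asarray(params, dtype=float))
        if truth is not None:
            diff2 = (np.asarray(recon) - truth) ** 2
            if frame_weights is not None:
                w = np.asarray(frame_weights, dtype=float)
                recon_errs.append(np.sqrt((diff2 * w[None, :]).sum(axis=1) / w.size))
            else:
                recon_errs.append(np.sqrt(diff2.mean(axis=1)))
    import warnings

    arr = np.stack(stacks)  # (N_S, P, N)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = {
            "sd": np.nanstd(arr, axis=0, ddof=1),
            "mean": np.nanmean(arr, axis=0),
            "replicates": arr,
        }
    if recon_errs:
        out["sigma_recon"] = np.mean(recon_errs, axis=0)
    return out


def make_nested_rois(grid_shape: tuple, levels: int = 3, base: int = 4) -> ROISet:
    """Nested rectangular ROI grids of halving block sizes.

    Level ``l`` tiles the (2-D) image with blocks of side
    ``max(nx, ny) / (base * 2^l)`` voxels; empty blocks are dropped by
    callers via masking if needed.
    """
    nx, ny = grid_shape[0], grid_shape[1] if len(grid_shape) > 1 else 1
    masks, sizes, lev = [], [], []
    n = nx * ny
    for l in range(levels):
        side = max(1, max(nx, ny) // (base * 2**l))
        for x0 in range(0, nx, side):
            for y0 in range(0, ny, side):
                mask = np.zeros((nx, ny), dtype=bool)
                mask[x0 : x0 + side, y0 : y0 + side] = True
                flat = mask.ravel(order="F")
                masks.append(flat)
                sizes.append(int(flat.sum()))
                lev.append(l)
    return ROISet(masks=masks, sizes=np.asarray(sizes), levels=np.asarray(lev))


def roi_analysis(
    true_replicates: np.ndarray,
    boot_replicates: np.ndarray,
    rois: ROISet,
    min_defined: float = 0.5,
):
    """Calibration of bootstrap SDs of ROI means against replication truth.

    ``true_replicates`` is ``(N_S, N)`` and ``boot_replicates`` is
    ``(N_B, N)`` for one parameter.  ROI means are taken over defined
    voxels; ROIs with fewer than ``min_defined`` of their voxels defined
    are skipped.  Returns a :class:`CalibrationResult` with per-ROI SD
    vectors in ``extras``.
    """
    import warnings

    t_rep = np.asarray(true_replicates, dtype=float)
    b_rep = np.asarray(boot_replicates, dtype=float)
    true_sd, boot_sd, kept_sizes = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for mask, size in zip(rois.masks, rois.sizes):
            t_means = np.nanmean(t_rep[:, mask], axis=1)
            b_means = np.nanmean(b_rep[:, mask], axis=1)
            frac_ok = np.isfinite(t_rep[:, mask]).mean()
            if frac_ok < min_defined or not np.all(np.isfinite(t_means)):
                continue
            true_sd.append(np.nanstd(t_means, ddof=1))
            boot_sd.append(np.nanstd(b_means, ddof=1))
            kept_sizes.append(size)
    true_sd = np.asarray(true_sd)
    boot_sd = np.asarray(boot_sd)
    result = calibrate(true_sd, boot_sd)
    rmse, _ = rmse_table(boot_sd, true_sd)
    result.rmse = rmse
    result.extras = {"true_sd": true_sd, "boot_sd": boot_sd, "sizes": np.asarray(kept_sizes)}
    return result
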