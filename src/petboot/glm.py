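"""Estimation of the heteroscedastic linear model behind the image-domain bootstrap.

The data are modeled as ``z_ij = x_j' alpha_i + sigma_i phi_j Q(eta_ij | kappa_ij)``
with a sub-ordinate Gaussian field ``eta`` that is independent across
frames and spatially stationary.  This module estimates every unknown:
the coefficients (weighted least squares), the spatial and temporal
scales (alternating conditional updates), the per-bin variance function
and quantile transform ``Q``, and the spatial spectral density of ``eta``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .basis import TemporalBasis
from .study import DynamicImage, FrameSchedule, VoxelGrid

__all__ = [
    "QTransform",
    "SpectralModel",
    "GLMFit",
    "ScaleFit",
    "initial_weights",
    "wls_alpha",
    "iterate_scales",
    "estimate_qtransform",
    "estimate_spectrum",
    "fit_glm",
    "coefficient_covariance",
    "residual_diagnostics",
]

DEFAULT_L_BINS = 64
SCALE_TOL = 1e-6
SCALE_MAX_ITER = 200


# ---------------------------------------------------------------------------
# Q-transform


@dataclass
class QTransform:
    """Piecewise (in kappa) monotone quantile transform.

    For each kappa-bin, a table pairs standard-normal scores with the
    sorted scaled residuals of the bin; evaluation interpolates in the
    table and clamps at the extreme order statistics.
    """

    bin_edges: np.ndarray  # interior edges, length L-1 (finite)
    eta_tables: list  # per-bin normal scores, each sorted ascending
    eps_tables: list  # per-bin residual order statistics
    h: np.ndarray  # per-bin scale, sum(h^2) = L

    @property
    def n_bins(self) -> int:
        return len(self.eta_tables)

    def bin_of(self, kappa: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.bin_edges, np.asarray(kappa, dtype=float), side="left")

    def transform(self, eta: np.ndarray, bins: np.ndarray) -> np.ndarray:
        """Map normal scores to residual scale, bin by bin."""
        eta = np.asarray(eta, dtype=float)
        bins = np.asarray(bins)
        out = np.empty_like(eta, dtype=float)
        for l in range(self.n_bins):
            sel = bins == l
            if np.any(sel):
                out[sel] = np.interp(eta[sel], self.eta_tables[l], self.eps_tables[l])
        return out

    def inverse(self, eps: np.ndarray, bins: np.ndarray) -> np.ndarray:
        """Normal scores of scaled residuals (the normal-quantile plot)."""
        eps = np.asarray(eps, dtype=float)
        bins = np.asarray(bins)
        out = np.empty_like(eps, dtype=float)
        for l in range(self.n_bins):
            sel = bins == l
            if np.any(sel):
                out[sel] = np.interp(eps[sel], self.eps_tables[l], self.eta_tables[l])
        return out

    @classmethod
    def identity(cls, n_bins: int = 1, span: float = 8.0) -> "QTransform":
        nodes = np.linspace(-span, span, 41)
        return cls(
            bin_edges=np.array([]) if n_bins == 1 else np.linspace(-1, 1, n_bins - 1),
            eta_tables=[nodes.copy() for _ in range(n_bins)],
            eps_tables=[nodes.copy() for _ in range(n_bins)],
            h=np.ones(n_bins),
        )


# ---------------------------------------------------------------------------
# Spectral model


@dataclass
class SpectralModel:
    """Spatial spectral density of the sub-ordinate field, on the voxel grid.

    ``density`` is normalized to mean one so that filtered white noise
    keeps unit marginal variance; ``autocorrelation`` is its inverse FFT,
    normalized to one at lag zero.
    """

    density: np.ndarray
    grid: VoxelGrid
    autocorrelation: np.ndarray = None

    def __post_init__(self):
        lam = np.asarray(self.density, dtype=float)
        if lam.shape != self.grid.shape:
            raise ValueError("spectral density shape must match the voxel grid")
        if np.any(lam < 0):
            raise ValueError("spectral density must be non-negative")
        self.density = lam
        if self.autocorrelation is None:
            rho = np.real(np.fft.ifftn(lam))
            self.autocorrelation = rho / rho.flat[0]

    def filter_white(self, white: np.ndarray) -> np.ndarray:
        """Color a grid-shaped field to the stored spectrum (unit variance)."""
        coef = np.fft.fftn(np.asarray(white, dtype=float))
        return np.real(np.fft.ifftn(np.sqrt(self.density) * coef))

    @classmethod
    def flat(cls, grid: VoxelGrid) -> "SpectralModel":
        return cls(density=np.ones(grid.shape), grid=grid)


# ---------------------------------------------------------------------------
# Fit containers


@dataclass
class ScaleFit:
    """Converged scale estimates from the alternating iteration."""

    sigma: np.ndarray  # per-voxel scale, bias-inflated
    sigma_raw: np.ndarray  # per-voxel scale before the bias inflation
    phi: np.ndarray  # per-frame scale, sum(phi^2) = T
    kappa: np.ndarray  # N x T surrogate, NaN on degenerate voxels
    h: np.ndarray  # per-bin variance scale, sum(h^2) = L
    bin_edges: np.ndarray  # interior kappa-bin edges
    bins: np.ndarray  # N x T bin index, -1 on degenerate voxels
    sigma_stage1: np.ndarray
    phi_stage1: np.ndarray
    converged: bool


@dataclass
class GLMFit:
    """All estimated unknowns of the image-domain model for one study."""

    basis: TemporalBasis
    alpha: np.ndarray
    sigma: np.ndarray
    phi: np.ndarray
    w0: np.ndarray
    phi0: np.ndarray
    kappa: np.ndarray
    qtransform: QTransform
    spectrum: SpectralModel
    zhat: np.ndarray
    residuals: np.ndarray
    eta: np.ndarray
    bins: np.ndarray
    grid: VoxelGrid
    schedule: FrameSchedule
    converged: bool = True

    @property
    def n_voxels(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_frames(self) -> int:
        return self.phi.size

    def weight_matrix_diag(self) -> np.ndarray:
        """WLS frame weights used for the coefficient fit."""
        return self.w0

    # -- serialization -----------------------------------------------------

    def to_state(self) -> dict:
        q = self.qtransform
        qstate = {
            "bin_edges": q.bin_edges,
            "h": q.h,
            "tables": {
                f"bin_{l:04d}": {"eta": q.eta_tables[l], "eps": q.eps_tables[l]}
                for l in range(q.n_bins)
            },
        }
        basis = self.basis
        bstate = {
            "design": basis.design,
            "names": "\n".join(basis.names),
            "delays": basis.delays,
            "aif_index": basis.aif_index,
            "patlak_index": basis.patlak_index,
            "residues": {
                f"res_{k:04d}": (
                    {"times": r.times, "values": r.values, "delay": r.delay}
                    if r is not None
                    else {"missing": 1}
                )
                for k, r in enumerate(basis.residues)
            },
        }
        return {
            "basis": bstate,
            "alpha": self.alpha,
            "sigma": self.sigma,
            "phi": self.phi,
            "w0": self.w0,
            "phi0": self.phi0,
            "kappa": self.kappa,
            "qtransform": qstate,
            "density": self.spectrum.density,
            "zhat": self.zhat,
            "residuals": self.residuals,
            "eta": self.eta,
            "bins": self.bins,
            "grid_shape": np.array(self.grid.shape),
            "grid_spacing": np.array(self.grid.spacing),
            "mid_times": self.schedule.mid_times,
            "durations": self.schedule.durations,
            "decay_constant": self.schedule.decay_constant,
            "converged": int(self.converged),
        }

    @classmethod
    def from_state(cls, state: dict) -> "GLMFit":
        from .study import FitSerializationError

        required = {"alpha", "sigma", "phi", "kappa", "qtransform", "density", "zhat"}
        missing = required - set(state)
        if missing:
            raise FitSerializationError(f"fit container missing fields: {sorted(missing)}")
        qstate = state["qtransform"]
        keys = sorted(qstate["tables"])
        q = QTransform(
            bin_edges=np.atleast_1d(np.asarray(qstate["bin_edges"], dtype=float)),
            eta_tables=[qstate["tables"][k]["eta"] for k in keys],
            eps_tables=[qstate["tables"][k]["eps"] for k in keys],
            h=qstate["h"],
        )
        from .kinetics import ResidueModel

        bstate = state["basis"]
        res_keys = sorted(bstate["residues"])
        residues = []
        for k in res_keys:
            r = bstate["residues"][k]
            if "missing" in r:
                residues.append(None)
            else:
                residues.append(
                    ResidueModel(times=r["times"], values=r["values"], delay=float(r["delay"]))
                )
        names = bstate["names"]
        if isinstance(names, bytes):
            names = names.decode()
        basis = TemporalBasis(
            design=bstate["design"],
            names=names.split("\n"),
            residues=residues,
            delays=bstate["delays"],
            aif_index=int(bstate["aif_index"]),
            patlak_index=int(bstate["patlak_index"]),
        )
        grid = VoxelGrid(tuple(state["grid_shape"]), tuple(state["grid_spacing"]))
        schedule = FrameSchedule(
            mid_times=state["mid_times"],
            durations=state["durations"],
            decay_constant=float(state["decay_constant"]),
        )
        return cls(
            basis=basis,
            alpha=state["alpha"],
            sigma=state["sigma"],
            phi=state["phi"],
            w0=state["w0"],
            phi0=state["phi0"],
            kappa=state["kappa"],
            qtransform=q,
            spectrum=SpectralModel(density=state["density"], grid=grid),
            zhat=state["zhat"],
            residuals=state["residuals"],
            eta=state["eta"],
            bins=np.asarray(state["bins"], dtype=int),
            grid=grid,
            schedule=schedule,
            converged=bool(state["converged"]),
        )


# ---------------------------------------------------------------------------
# Stage operations


def initial_weights(schedule: FrameSchedule, frame_means: np.ndarray):
    """Simple fixed temporal weights and the matching scale profile.

    ``w_j = exp(-t_j zeta) dt_j / max(mean_j, m)`` with floor ``m`` equal
    to one tenth of the largest frame mean; ``phi_j`` is proportional to
    ``w_j^{-1/2}``, normalized so that ``sum(phi^2) = T``.
    """
    mu = np.asarray(frame_means, dtype=float)
    if mu.size != schedule.n_frames:
        raise ValueError("frame_means length must equal the number of frames")
    if np.all(mu <= 0):
        raise ValueError("all frame means are zero: no signal to weight")
    m = 0.1 * mu.max()
    mu_star = np.maximum(mu, m)
    w0 = schedule.decay_factors() * schedule.durations / mu_star
    phi0 = 1.0 / np.sqrt(w0)
    phi0 *= np.sqrt(mu.size / (phi0**2).sum())
    return w0, phi0


def wls_alpha(values, design, weights: np.ndarray):
    """Weighted least squares coefficients and residuals, all voxels at once.

    One shared ``K x K`` normal-equations factorization serves every
    voxel.  Raises on a singular system, naming the dependent columns.
    """
    if isinstance(values, DynamicImage):
        values = values.values
    if isinstance(design, TemporalBasis):
        design = design.design
    z = np.asarray(values, dtype=float)
    x = np.asarray(design, dtype=float)
    w = np.asarray(weights, dtype=float)
    xtwx = (x * w[:, None]).T @ x
    cond = np.linalg.cond(xtwx)
    if not np.isfinite(cond) or cond > 1e12:
        # identify offending columns by pivoted QR rank analysis
        from scipy.linalg import qr

        _, rdiag, piv = qr(x * np.sqrt(w)[:, None], pivoting=True, mode="economic")[0:3]
        diag = np.abs(np.diag(rdiag))
        bad = sorted(piv[diag < 1e-10 * max(diag.max(), 1.0)].tolist())
        raise np.linalg.LinAlgError(
            f"design is singular under the given weights; dependent columns: {bad}"
        )
    alpha = np.linalg.solve(xtwx, (x * w[:, None]).T @ z.T).T
    residuals = z - alpha @ x.T
    return alpha, residuals


def coefficient_covariance(design, weights: np.ndarray) -> np.ndarray:
    """Unit-scale coefficient covariance ``[X'WX]^{-1}``."""
    if isinstance(design, TemporalBasis):
        design = design.design
    x = np.asarray(design, dtype=float)
    w = np.asarray(weights, dtype=float)
    return np.linalg.inv((x * w[:, None]).T @ x)


def _normalize_phi(phi_sq: np.ndarray) -> np.ndarray:
    t = phi_sq.size
    return phi_sq * (t / phi_sq.sum())


def iterate_scales(
    residuals: np.ndarray,
    zhat: np.ndarray,
    n_basis: int,
    l_bins: int = DEFAULT_L_BINS,
    tol: float = SCALE_TOL,
    max_iter: int = SCALE_MAX_ITER,
    deflation: np.ndarray | None = None,
) -> ScaleFit:
    """Alternating conditional estimation of spatial, temporal and bin scales.

    Stage 1 fits the homoscedastic-error version (``h == 1``) to fix the
    kappa surrogate ``zhat / (sigma phi)``; stage 2 re-iterates the
    scale updates jointly with the per-bin variance ``h``, on equal-count
    kappa bins fixed after stage 1.  The returned ``sigma`` is inflated
    by ``sqrt(T / (T - K))`` to undo the coefficient-fitting bias.

    When per-frame residual-variance ``deflation`` factors are supplied
    (``var(r_j) = c_j sigma_j^2`` under the fitted hat matrix), residuals
    are studentized frame-by-frame by ``sqrt(c_j)`` instead; this
    subsumes the global inflation (the deflations average ``1 - K/T``),
    so the final ``sigma`` is then left un-inflated.
    """
    r = np.asarray(residuals, dtype=float)
    n, t = r.shape
    if deflation is not None:
        c = np.clip(np.asarray(deflation, dtype=float), 1e-6, None)
        r = r / np.sqrt(c)[None, :]
    if n * t <= l_bins:
        raise ValueError("too few residuals for the requested number of kappa bins")
    r_sq = r**2

    valid = r_sq.sum(axis=1) > 0  # degenerate (zero-residual) voxels excluded
    if not np.any(valid):
        zeros = np.zeros(n)
        ones_t = np.ones(t)
        return ScaleFit(
            sigma=zeros,
            sigma_raw=zeros.copy(),
            phi=ones_t,
            kappa=np.full((n, t), np.nan),
            h=np.ones(l_bins),
            bin_edges=np.array([]),
            bins=np.full((n, t), -1, dtype=int),
            sigma_stage1=zeros.copy(),
            phi_stage1=ones_t.copy(),
            converged=True,
        )

    # -- stage 1: h == 1 ----------------------------------------------------
    sigma_sq = np.ones(n)
    phi_sq = np.ones(t)
    converged = False
    for _ in range(max_iter):
        phi_new = _normalize_phi(r_sq[valid].T @ (1.0 / sigma_sq[valid]) / valid.sum())
        sigma_new = r_sq @ (1.0 / phi_new) / t
        delta = max(
            np.abs(phi_new - phi_sq).max() / phi_sq.max(),
            np.abs(sigma_new - sigma_sq).max() / max(sigma_sq.max(), 1e-300),
        )
        phi_sq, sigma_sq = phi_new, sigma_new
        sigma_sq[~valid] = 0.0
        sigma_sq[valid] = np.maximum(sigma_sq[valid], 1e-300)
        if delta < tol:
            converged = True
            break
    sigma1 = np.sqrt(sigma_sq)
    phi1 = np.sqrt(phi_sq)

    # -- kappa surrogate and equal-count bins, fixed hereafter --------------
    kappa = np.full((n, t), np.nan)
    kappa[valid] = zhat[valid] / (sigma1[valid, None] * phi1[None, :])
    kvals = kappa[valid].ravel()
    edges = np.quantile(kvals, np.arange(1, l_bins) / l_bins)
    bins = np.full((n, t), -1, dtype=int)
    bins[valid] = np.searchsorted(edges, kappa[valid], side="left")

    # -- stage 2: joint (sigma, phi, h) -------------------------------------
    h_sq = np.ones(l_bins)
    converged2 = False
    bins_valid = bins[valid]
    r_sq_valid = r_sq[valid]
    for _ in range(max_iter):
        h_ij = h_sq[bins_valid]
        u = r_sq_valid / h_ij
        phi_new = _normalize_phi(u.T @ (1.0 / sigma_sq[valid]) / valid.sum())
        sigma_v = (u @ (1.0 / phi_new)) / t
        sigma_v = np.maximum(sigma_v, 1e-300)
        eps_sq = r_sq_valid / (sigma_v[:, None] * phi_new[None, :])
        h_new = np.bincount(bins_valid.ravel(), weights=eps_sq.ravel(), minlength=l_bins)
        counts = np.bincount(bins_valid.ravel(), minlength=l_bins)
        h_new = np.where(counts > 0, h_new / np.maximum(counts, 1), 1.0)
        h_new *= l_bins / h_new.sum()
        delta = max(
            np.abs(phi_new - phi_sq).max() / phi_sq.max(),
            np.abs(sigma_v - sigma_sq[valid]).max() / max(sigma_sq[valid].max(), 1e-300),
            np.abs(h_new - h_sq).max(),
        )
        phi_sq = phi_new
        sigma_sq[valid] = sigma_v
        h_sq = h_new
        if delta < tol:
            converged2 = True
            break
    if not (converged and converged2):
        warnings.warn("scale iteration did not fully converge; returning last iterate")

    sigma_raw = np.sqrt(sigma_sq)
    sigma = sigma_raw.copy()
    if deflation is None:
        sigma[valid] *= np.sqrt(t / (t - n_basis))  # coefficient-fitting bias adjustment
    return ScaleFit(
        sigma=sigma,
        sigma_raw=sigma_raw,
        phi=np.sqrt(phi_sq),
        kappa=kappa,
        h=np.sqrt(h_sq),
        bin_edges=edges,
        bins=bins,
        sigma_stage1=sigma1,
        phi_stage1=phi1,
        converged=converged and converged2,
    )


def estimate_qtransform(
    residuals: np.ndarray,
    sigma: np.ndarray,
    phi: np.ndarray,
    bins: np.ndarray,
    bin_edges: np.ndarray,
) -> QTransform:
    """Per-bin quantile tables pairing normal scores with scaled residuals.

    Within each kappa-bin the sorted scaled residuals are matched to the
    standard-normal quantiles ``Phi^{-1}((k - 0.5) / n)``; empty bins are
    merged with their left neighbor (with a warning).
    """
    r = np.asarray(residuals, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    phi = np.asarray(phi, dtype=float)
    valid = sigma > 0
    eps = np.full_like(r, np.nan)
    eps[valid] = r[valid] / (sigma[valid, None] * phi[None, :])

    n_bins = len(bin_edges) + 1
    edges = np.asarray(bin_edges, dtype=float)
    eta_tables, eps_tables, h = [], [], []
    flat_bins = np.asarray(bins)
    empty = []
    for l in range(n_bins):
        vals = eps[flat_bins == l]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            empty.append(l)
            eta_tables.append(None)
            eps_tables.append(None)
            h.append(np.nan)
            continue
        vals = np.sort(vals)
        scores = norm.ppf((np.arange(1, vals.size + 1) - 0.5) / vals.size)
        eta_tables.append(scores)
        eps_tables.append(vals)
        h.append(np.sqrt(np.mean(vals**2)))
    if empty:
        warnings.warn(f"empty kappa bins merged with neighbors: {empty}")
        for l in empty:
            src = next(
                (m for m in list(range(l - 1, -1, -1)) + list(range(l + 1, n_bins)) if eta_tables[m] is not None)
            )
            eta_tables[l] = eta_tables[src]
            eps_tables[l] = eps_tables[src]
            h[l] = h[src]
    h = np.asarray(h)
    h = h * np.sqrt(n_bins / (h**2).sum())
    return QTransform(bin_edges=edges, eta_tables=eta_tables, eps_tables=eps_tables, h=h)


def estimate_spectrum(eta: np.ndarray, phi: np.ndarray, grid: VoxelGrid) -> SpectralModel:
    """Phi-weighted time-average of per-frame periodograms, mean-normalized.

    Frame weights are proportional to ``phi_j^{-2}`` and normalized to
    sum to one; the density is scaled to mean one so simulated fields
    keep unit marginal variance.
    """
    e = np.asarray(eta, dtype=float)
    n, t = e.shape
    if n != grid.n_voxels:
        raise ValueError("eta rows must match the voxel grid")
    w = 1.0 / np.asarray(phi, dtype=float) ** 2
    w = w / w.sum()
    fields = grid.unflatten(e)  # (nx, ny, nz, T)
    lam = np.zeros(grid.shape)
    for j in range(t):
        lam += w[j] * np.abs(np.fft.fftn(fields[..., j])) ** 2 / n
    mean = lam.mean()
    if mean <= 0:
        return SpectralModel.flat(grid)
    return SpectralModel(density=lam / mean, grid=grid)


def fit_glm(
    study: DynamicImage,
    basis: TemporalBasis,
    l_bins: int = DEFAULT_L_BINS,
    tol: float = SCALE_TOL,
    max_iter: int = SCALE_MAX_ITER,
) -> GLMFit:
    """Estimate every model unknown for a study under a fixed basis."""
    z = study.values
    frame_means = z.mean(axis=0)
    w0, phi0 = initial_weights(study.schedule, frame_means)
    alpha, residuals = wls_alpha(z, basis, w0)
    zhat = alpha @ basis.design.T

    if np.allclose(residuals, 0.0):
        # degenerate noiseless refit: zero scales, identity transform
        n, t = z.shape
        return GLMFit(
            basis=basis,
            alpha=alpha,
            sigma=np.zeros(n),
            phi=np.ones(t),
            w0=w0,
            phi0=phi0,
            kappa=np.full((n, t), np.nan),
            qtransform=QTransform.identity(),
            spectrum=SpectralModel.flat(study.grid),
            zhat=zhat,
            residuals=residuals,
            eta=np.zeros((n, t)),
            bins=np.full((n, t), -1, dtype=int),
            grid=study.grid,
            schedule=study.schedule,
            converged=True,
        )

    # Residual variances are deflated frame-wise by the WLS hat matrix:
    # var(r_.j) = sigma^2 [(I-H) diag(phi^2) (I-H)']_jj.  A first pass uses
    # the w0-implied leverages; a second pass recomputes the deflation
    # from the fitted phi before the final scale estimation.
    x = basis.design
    hat = x @ coefficient_covariance(x, w0) @ (x * w0[:, None]).T  # T x T
    resid_proj = np.eye(x.shape[0]) - hat
    deflation = np.clip(1.0 - np.diag(hat), 1e-6, None)
    scales = iterate_scales(
        residuals, zhat, basis.n_elements, l_bins, tol, max_iter, deflation=deflation
    )
    phi_sq = scales.phi**2
    deflation = np.clip(
        np.einsum("jk,k,jk->j", resid_proj, phi_sq, resid_proj) / phi_sq, 1e-6, None
    )
    scales = iterate_scales(
        residuals, zhat, basis.n_elements, l_bins, tol, max_iter, deflation=deflation
    )
    r_student = residuals / np.sqrt(deflation)[None, :]
    q = estimate_qtransform(r_student, scales.sigma, scales.phi, scales.bins, scales.bin_edges)
    valid = scales.sigma > 0
    eps = np.zeros_like(residuals)
    eps[valid] = r_student[valid] / (scales.sigma[valid, None] * scales.phi[None, :])
    eta = np.zeros_like(residuals)
    eta[valid] = q.inverse(eps[valid], scales.bins[valid])
    spectrum = estimate_spectrum(eta, scales.phi, study.grid)
    return GLMFit(
        basis=basis,
        alpha=alpha,
        sigma=scales.sigma,
        phi=scales.phi,
        w0=w0,
        phi0=phi0,
        kappa=scales.kappa,
        qtransform=q,
        spectrum=spectrum,
        zhat=zhat,
        residuals=residuals,
        eta=eta,
        bins=scales.bins,
        grid=study.grid,
        schedule=study.schedule,
        converged=scales.converged,
    )


def residual_diagnostics(fit: GLMFit) -> dict:
    """Numeric diagnostic tables for a complete fit.

    Returns per-frame and per-bin quartile tables of standardized
    residuals, the per-bin variance scale, an overall normal-quantile
    table, and directional autocorrelation profiles in millimetres.
    """
    import pandas as pd

    valid = fit.sigma > 0
    h_ij = np.ones_like(fit.residuals)
    h_ij[fit.bins >= 0] = fit.qtransform.h[fit.bins[fit.bins >= 0]]
    std = np.full_like(fit.residuals, np.nan)
    std[valid] = fit.residuals[valid] / (
        fit.sigma[valid, None] * fit.phi[None, :] * h_ij[valid]
    )

    qs = [0.25, 0.5, 0.75]
    per_frame = pd.DataFrame(
        np.nanquantile(std, qs, axis=0).T,
        columns=["q25", "q50", "q75"],
        index=pd.RangeIndex(fit.n_frames, name="frame"),
    )
    per_frame["phi"] = fit.phi
    per_frame["phi0"] = fit.phi0

    eps = np.full_like(fit.residuals, np.nan)
    eps[valid] = fit.residuals[valid] / (fit.sigma[valid, None] * fit.phi[None, :])
    rows = []
    for l in range(fit.qtransform.n_bins):
        vals = eps[fit.bins == l]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            rows.append([np.nan] * 3 + [fit.qtransform.h[l], 0])
        else:
            rows.append(list(np.quantile(vals, qs)) + [fit.qtransform.h[l], vals.size])
    per_bin = pd.DataFrame(
        rows, columns=["q25", "q50", "q75", "h", "count"], index=pd.RangeIndex(fit.qtransform.n_bins, name="bin")
    )

    finite = std[np.isfinite(std)]
    probs = np.linspace(0.01, 0.99, 99)
    qq = pd.DataFrame(
        {"normal": norm.ppf(probs), "residual": np.quantile(finite, probs) if finite.size else np.nan},
        index=pd.Index(probs, name="prob"),
    )

    rho = fit.spectrum.autocorrelation
    ax_tables = {}
    for axis, name in enumerate(("x", "y", "z")):
        n_ax = fit.grid.shape[axis]
        lags = np.arange(min(n_ax, max(n_ax // 2, 1)))
        idx = [0, 0, 0]
        prof = []
        for lag in lags:
            idx[axis] = lag
            prof.append(rho[tuple(idx)])
        ax_tables[name] = pd.DataFrame(
            {"lag_mm": lags * fit.grid.spacing[axis], "rho": prof}
        )
    return {
        "per_frame": per_frame,
        "per_bin": per_bin,
        "qq": qq,
        "autocorrelation": ax_tables,
    }
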