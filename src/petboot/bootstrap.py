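"""Bootstrap engines: image-domain, projection-domain, and recycling.

The image-domain engine simulates replicate studies from a fitted
heteroscedastic model by coloring white Gaussian noise to the fitted
spatial spectrum and pushing it through the fitted quantile transform.
The projection-domain engine resamples raw binned counts from a
multinomial.  The recycling engine regenerates many coefficient-level
replicates from a small retained set of fitted coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .glm import GLMFit

__all__ = ["BootstrapSet", "image_bootstrap", "projection_bootstrap", "recycle_bootstrap"]


@dataclass
class BootstrapSet:
    """A homogeneous collection of bootstrap replicates.

    ``kind`` is ``"image"`` or ``"projection"`` for value replicates
    (``N x T`` arrays) and ``"recycled"`` for coefficient replicates
    (``N x K`` arrays).
    """

    kind: str
    replicates: list
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.replicates) < 1:
            raise ValueError("a bootstrap set needs at least one replicate")
        shape = np.shape(self.replicates[0])
        if any(np.shape(r) != shape for r in self.replicates):
            raise ValueError("all replicates must share one shape")

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def stacked(self) -> np.ndarray:
        return np.stack([np.asarray(r) for r in self.replicates])


def _replicate_rngs(seed: int, n: int):
    """One independently seeded stream per replicate index."""
    return [np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(b,))) for b in range(n)]


def simulate_glm_replicate(fit: GLMFit, rng: np.random.Generator) -> np.ndarray:
    """One simulated study from the fitted model (frames independent)."""
    n, t = fit.zhat.shape
    z = fit.zhat.copy()
    valid = fit.sigma > 0
    if not np.any(valid):
        return z
    for j in range(t):
        xi = rng.standard_normal(fit.grid.shape)
        eta = fit.grid.flatten(fit.spectrum.filter_white(xi))
        eps = fit.qtransform.transform(eta[valid], fit.bins[valid, j])
        z[valid, j] += fit.sigma[valid] * fit.phi[j] * eps
    return z


def image_bootstrap(fit: GLMFit, n_reps: int, seed: int = 0) -> BootstrapSet:
    """Model-based replicate studies from a complete fit.

    Per frame, white Gaussian noise on the voxel grid is colored by the
    square-root of the fitted spectral density, passed through the
    kappa-binned quantile transform, scaled by ``sigma_i phi_j`` and
    added to the fitted means.  Replicates are reproducible per index.
    """
    reps = [simulate_glm_replicate(fit, rng) for rng in _replicate_rngs(seed, n_reps)]
    return BootstrapSet(kind="image", replicates=reps, seed=seed)


def projection_bootstrap(counts: np.ndarray, n_reps: int, seed: int = 0) -> list:
    """Multinomial resampling of binned count data.

    Each replicate redistributes the total number of detected events over
    the bins with probabilities proportional to the observed counts, so
    totals are conserved exactly.
    """
    c = np.asarray(counts)
    if np.any(c < 0) or not np.allclose(c, np.round(c)):
        raise ValueError("counts must be non-negative integers")
    flat = np.round(c).astype(np.int64).ravel()
    n_events = int(flat.sum())
    if n_events == 0:
        raise ValueError("all-zero count array cannot be resampled")
    p = flat / n_events
    reps = []
    for rng in _replicate_rngs(seed, n_reps):
        reps.append(rng.multinomial(n_events, p).reshape(c.shape))
    return reps


def recycle_bootstrap(
    alpha_samples,
    fit: GLMFit,
    n_out: int,
    seed: int = 0,
    mode: str = "rowwise",
) -> BootstrapSet:
    """Regenerate coefficient replicates from a small retained set.

    Deviations ``(alpha^b - alpha_hat) / sigma_hat`` from the retained
    set are resampled voxel-row by voxel-row (``mode="rowwise"``) or from
    the pool over all voxels (``mode="pooled"``), then each coefficient
    column is re-colored with the fitted spatial filter (variance
    preserving, since the spectral density has mean one), and the result
    is mapped back to the coefficient scale.
    """
    if mode not in ("rowwise", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(alpha_samples, BootstrapSet):
        alphas = alpha_samples.stacked()
    else:
        alphas = np.stack([np.asarray(a, dtype=float) for a in alpha_samples])
    n_in, n, k = alphas.shape
    if n_in < 2:
        raise ValueError("need at least 2 retained coefficient replicates")
    sigma = fit.sigma
    safe = np.where(sigma > 0, sigma, 1.0)
    dev = (alphas - fit.alpha[None, :, :]) / safe[None, :, None]
    dev[:, sigma <= 0, :] = 0.0

    reps = []
    for rng in _replicate_rngs(seed, n_out):
        if mode == "rowwise":
            pick = rng.integers(n_in, size=n)
            d = dev[pick, np.arange(n), :]
        else:
            pick_b = rng.integers(n_in, size=n)
            pick_i = rng.integers(n, size=n)
            d = dev[pick_b, pick_i, :]
        filtered = np.empty_like(d)
        for col in range(k):
            fld = fit.grid.unflatten(d[:, col])
            filtered[:, col] = fit.grid.flatten(fit.spectrum.filter_white(fld))
        filtered[sigma <= 0, :] = 0.0
        reps.append(fit.alpha + sigma[:, None] * filtered)
    return BootstrapSet(kind="recycled", replicates=reps, seed=seed, meta={"mode": mode})
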