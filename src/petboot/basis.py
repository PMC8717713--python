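"""Data-dependent temporal basis construction.

The basis is built in two steps: recursive bisection clustering groups
voxel time-courses by shape, and cross-validation-guided backwards
elimination prunes the candidate sub-TACs (cluster means, or their
residue-model fits) down to a compact set.  In the residue-mapping
variant the arterial input column and its running integral (the Patlak
column) are always present and protected from elimination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


from .kinetics import (
    DEFAULT_T_B,
    ResidueModel,
    fit_residue_model,
    nnls_safe,
    residue_tac,
)
from .study import DynamicImage, FrameSchedule, InputFunction

__all__ = ["ClusterSet", "TemporalBasis", "cluster_timecourses", "backward_eliminate", "build_nprm_basis"]

#: Voxels whose frame-weighted mean is below this fraction of the volume
#: maximum are treated as background (label 0, excluded from clustering).
BACKGROUND_FRACTION = 0.01


@dataclass
class ClusterSet:
    """Shape-based partition of voxel time-courses.

    ``labels`` has one entry per voxel, 0 marking background voxels and
    1..L the clusters; ``means`` holds the arithmetic average member
    time-course per cluster, row-wise (L x T).
    """

    labels: np.ndarray
    means: np.ndarray
    sizes: np.ndarray

    @property
    def n_clusters(self) -> int:
        return self.means.shape[0]


@dataclass
class TemporalBasis:
    """A T x K design of sub-TACs, optionally carrying residue models.

    ``aif_index`` / ``patlak_index`` mark the arterial-input and Patlak
    columns in the residue-mapping variant (-1 when absent).
    """

    design: np.ndarray
    names: list
    residues: list = field(default_factory=list)
    delays: np.ndarray | None = None
    aif_index: int = -1
    patlak_index: int = -1

    def __post_init__(self):
        x = np.asarray(self.design, dtype=float)
        if x.ndim != 2 or x.shape[1] < 1:
            raise ValueError("design must be T x K with K >= 1")
        if not np.all(np.isfinite(x)):
            raise ValueError("design has non-finite entries")
        if np.any(np.all(x == 0.0, axis=0)):
            raise ValueError("design has an identically-zero column")
        self.design = x
        if not self.residues:
            self.residues = [None] * x.shape[1]
        if self.delays is None:
            self.delays = np.zeros(x.shape[1])
        if len(self.residues) != x.shape[1] or len(self.names) != x.shape[1]:
            raise ValueError("metadata length does not match number of columns")

    @property
    def n_elements(self) -> int:
        return self.design.shape[1]

    @property
    def n_frames(self) -> int:
        return self.design.shape[0]


# ---------------------------------------------------------------------------
# Clustering


def _unit_rows(z: np.ndarray, sw: np.ndarray) -> np.ndarray:
    v = z * sw[None, :]
    norms = np.linalg.norm(v, axis=1)
    norms[norms == 0] = 1.0
    return v / norms[:, None]


def _spherical_2means(u: np.ndarray, rng: np.random.Generator, n_iter: int = 30):
    """Split unit vectors into 2 groups by cosine similarity.

    Seeded deterministically: first center is the member farthest from
    the mean direction, second the member farthest from the first.
    """
    mean_dir = u.mean(axis=0)
    nrm = np.linalg.norm(mean_dir)
    mean_dir = mean_dir / nrm if nrm > 0 else u[0]
    c0 = u[np.argmin(u @ mean_dir)]
    c1 = u[np.argmin(u @ c0)]
    assign = np.zeros(u.shape[0], dtype=bool)
    for _ in range(n_iter):
        new = (u @ c1) > (u @ c0)
        if new.all() or (~new).all():
            # degenerate: split off the farthest single member
            new = np.zeros_like(new)
            new[np.argmin(u @ c0)] = True
        if np.array_equal(new, assign) and _ > 0:
            break
        assign = new
        for flag, idx in ((False, 0), (True, 1)):
            sub = u[assign == flag]
            c = sub.mean(axis=0)
            n = np.linalg.norm(c)
            c = c / n if n > 0 else sub[0]
            if idx == 0:
                c0 = c
            else:
                c1 = c
    return assign


def cluster_timecourses(
    study: DynamicImage,
    target_clusters: int,
    weights: np.ndarray | None = None,
    seed: int = 0,
) -> ClusterSet:
    """Partition voxel time-courses into shape-similar clusters.

    Recursive bisection: the cluster with the largest weighted-cosine
    within-scatter is repeatedly split by 2-means on unit-normalized
    (frame-weighted) time-courses, until ``target_clusters`` leaves.
    Background voxels (frame-weighted mean below 1% of the volume
    maximum) are excluded and labeled 0.
    """
    z = study.values
    n, t = z.shape
    if weights is None:
        weights = np.ones(t)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("frame weights must be strictly positive")
    if not 1 <= target_clusters <= n:
        raise ValueError("target_clusters must be in [1, N]")
    rng = np.random.default_rng(seed)

    wmean = (z * w[None, :]).sum(axis=1) / w.sum()
    fg = wmean > BACKGROUND_FRACTION * wmean.max()
    fg_idx = np.nonzero(fg)[0]
    if fg_idx.size == 0:
        raise ValueError("no foreground voxels (all-zero study?)")
    u = _unit_rows(z[fg_idx], np.sqrt(w))

    members = [np.arange(fg_idx.size)]

    def scatter(idx):
        sub = u[idx]
        m = sub.mean(axis=0)
        nm = np.linalg.norm(m)
        if nm == 0:
            return 0.0
        return float((1.0 - sub @ (m / nm)).sum())

    scat = [scatter(members[0])]
    while len(members) < target_clusters:
        order = np.argsort(scat)[::-1]
        split_done = False
        for pos in order:
            if members[pos].size < 2 or scat[pos] <= 1e-12:
                continue
            idx = members[pos]
            assign = _spherical_2means(u[idx], rng)
            left, right = idx[~assign], idx[assign]
            members[pos] = left
            members.append(right)
            scat[pos] = scatter(left)
            scat.append(scatter(right))
            split_done = True
            break
        if not split_done:
            warnings.warn(
                f"only {len(members)} distinguishable clusters (requested {target_clusters})",
                stacklevel=2,
            )
            break

    labels = np.zeros(n, dtype=int)
    means = np.empty((len(members), t))
    sizes = np.empty(len(members), dtype=int)
    for l, idx in enumerate(members):
        labels[fg_idx[idx]] = l + 1
        means[l] = z[fg_idx[idx]].mean(axis=0)
        sizes[l] = idx.size
    return ClusterSet(labels=labels, means=means, sizes=sizes)


# ---------------------------------------------------------------------------
# Backwards elimination


def _gcv(candidates: np.ndarray, subset: list, clusters: ClusterSet, sw: np.ndarray, t: int) -> float:
    """Generalized cross-validation score of a candidate subset.

    ``sum_l |C_l| WRSS_l / (1 - |S|/T)^2`` where WRSS_l is the weighted
    non-negative least squares misfit of cluster mean ``l``.
    """
    design = candidates[subset].T * sw[:, None]
    total = 0.0
    for l in range(clusters.n_clusters):
        target = clusters.means[l] * sw
        _, rnorm = nnls_safe(design, target)
        total += clusters.sizes[l] * rnorm**2
    return total / (1.0 - len(subset) / t) ** 2


def backward_eliminate(
    initial_basis: np.ndarray,
    cluster_means: ClusterSet,
    weights: np.ndarray,
    min_k: int = 2,
    protected: tuple = (),
    residues: list | None = None,
    delays: np.ndarray | None = None,
    names: list | None = None,
    aif_index: int = -1,
    patlak_index: int = -1,
):
    """Greedy GCV-guided column pruning of a candidate sub-TAC set.

    ``initial_basis`` holds candidates row-wise (n_candidates x T).  At
    each step the removable column whose removal minimizes the GCV score
    is dropped (ties broken by lowest index); the subset attaining the
    minimal score along the path (never smaller than ``min_k``) is
    returned as a :class:`TemporalBasis` together with the surviving
    candidate indices.
    """
    cand = np.asarray(initial_basis, dtype=float)
    n_cand, t = cand.shape
    if n_cand >= t:
        raise ValueError(f"{n_cand} candidates with only {t} frames: GCV undefined (|S| >= T)")
    sw = np.sqrt(np.asarray(weights, dtype=float))
    protected = set(protected)
    min_k = max(min_k, len(protected), 1)

    subset = list(range(n_cand))
    path = [(list(subset), _gcv(cand, subset, cluster_means, sw, t))]
    while len(subset) > min_k:
        best_score, best_col = np.inf, None
        for col in subset:
            if col in protected:
                continue
            trial = [c for c in subset if c != col]
            score = _gcv(cand, trial, cluster_means, sw, t)
            if score < best_score - 1e-15:  # strict: ties keep lowest index
                best_score, best_col = score, col
        if best_col is None:
            break
        subset = [c for c in subset if c != best_col]
        path.append((list(subset), best_score))

    scores = np.array([s for _, s in path])
    selected = path[int(np.argmin(scores))][0]

    if residues is None:
        residues = [None] * n_cand
    if delays is None:
        delays = np.zeros(n_cand)
    if names is None:
        names = [f"candidate_{i}" for i in range(n_cand)]
    basis = TemporalBasis(
        design=cand[selected].T,
        names=[names[i] for i in selected],
        residues=[residues[i] for i in selected],
        delays=np.asarray(delays, dtype=float)[selected],
        aif_index=selected.index(aif_index) if aif_index in selected else -1,
        patlak_index=selected.index(patlak_index) if patlak_index in selected else -1,
    )
    return basis, selected


# ---------------------------------------------------------------------------
# Residue-mapping basis


def _aif_spike_residue(spike_duration: float, t_end: float) -> ResidueModel:
    """A unit-integral spike residue of the given (short) duration."""
    from .kinetics import FINE_STEP

    t = np.arange(0.0, t_end + FINE_STEP / 2.0, FINE_STEP)
    vals = np.where(t < spike_duration, 1.0 / spike_duration, 0.0)
    return ResidueModel(times=t, values=vals)


def _constant_residue(t_end: float) -> ResidueModel:
    from .kinetics import FINE_STEP

    t = np.arange(0.0, t_end + FINE_STEP / 2.0, FINE_STEP)
    return ResidueModel(times=t, values=np.ones_like(t))


def frame_averaged_aif(aif: InputFunction, schedule: FrameSchedule) -> np.ndarray:
    """Arterial input averaged over each acquisition frame."""
    from .kinetics import FINE_STEP

    a = schedule.mid_times - schedule.durations / 2.0
    b = schedule.mid_times + schedule.durations / 2.0
    t = np.arange(0.0, schedule.end_time + FINE_STEP, FINE_STEP)
    cp = aif(t)
    g = np.concatenate([[0.0], np.cumsum(0.5 * (cp[1:] + cp[:-1]) * FINE_STEP)])
    return (np.interp(b, t, g) - np.interp(np.clip(a, 0, None), t, g)) / schedule.durations


def patlak_column(aif: InputFunction, schedule: FrameSchedule) -> np.ndarray:
    """Cumulative trapezoid integral of the input at frame mid-times."""
    from .kinetics import FINE_STEP

    t = np.arange(0.0, schedule.end_time + FINE_STEP, FINE_STEP)
    cp = aif(t)
    g = np.concatenate([[0.0], np.cumsum(0.5 * (cp[1:] + cp[:-1]) * FINE_STEP)])
    return np.interp(schedule.mid_times, t, g)


def build_nprm_basis(
    cluster_means: ClusterSet,
    aif: InputFunction,
    schedule: FrameSchedule,
    weights: np.ndarray | None = None,
    min_k: int = 2,
    delay_grid: np.ndarray | None = None,
    spike_duration: float = DEFAULT_T_B,
    n_knots: int = 24,
) -> TemporalBasis:
    """Residue-mapping basis: fitted cluster means plus AIF and Patlak columns.

    Each cluster mean is replaced by its monotone residue-model fit
    (falling back to the raw mean, with a warning, if the fit fails);
    the arterial-input column (spike residue, <= 5 s) and the Patlak
    column (constant residue) are prepended and protected during the
    subsequent backwards elimination.
    """
    if not aif.covers(schedule.end_time):
        raise ValueError("input function does not cover the study duration")
    t = schedule.n_frames
    if weights is None:
        weights = np.ones(t)
    if delay_grid is None:
        delay_grid = np.arange(0.0, 0.5 + 1e-9, 1.0 / 24.0)  # 0-30 s, 2.5 s steps
    t_end = schedule.end_time

    from .kinetics import default_knots

    knots = default_knots(t_end, n_knots=n_knots)
    candidates = [frame_averaged_aif(aif, schedule), patlak_column(aif, schedule)]
    residues = [_aif_spike_residue(spike_duration, t_end), _constant_residue(t_end)]
    delays = [0.0, 0.0]
    names = ["aif", "patlak"]

    for l in range(cluster_means.n_clusters):
        tac = cluster_means.means[l]
        try:
            res = fit_residue_model(
                tac, aif, schedule, delay_grid=delay_grid, weights=weights, knots=knots
            )
            fitted = residue_tac(res, aif, schedule)
            if not np.all(np.isfinite(fitted)) or np.all(fitted == 0.0):
                raise RuntimeError("degenerate residue fit")
        except Exception as exc:  # pragma: no cover - defensive fallback
            warnings.warn(f"residue fit failed for cluster {l + 1} ({exc}); using raw mean")
            res, fitted = None, tac
        candidates.append(fitted)
        residues.append(res)
        delays.append(res.delay if res is not None else 0.0)
        names.append(f"cluster_{l + 1}")

    basis, _ = backward_eliminate(
        np.vstack(candidates),
        cluster_means,
        weights,
        min_k=max(min_k, 2),
        protected=(0, 1),
        residues=residues,
        delays=np.asarray(delays),
        names=names,
        aif_index=0,
        patlak_index=1,
    )
    return basis
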