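"""Non-parametric residue mapping of tracer kinetics.

A tissue time-course is modeled as a convolution of a delayed arterial
input with a monotone non-increasing, non-negative residue function
(a life-table of tracer travel times).  Voxel-level time-courses are fit
as non-negative combinations of basis sub-TACs, each of which carries a
residue, and kinetic parameter maps follow by linearity from per-element
residue summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .study import DynamicImage, FrameSchedule, InputFunction, VOIMask


def nnls_safe(a: np.ndarray, b: np.ndarray):
    """Non-negative least squares with a robust fallback.

    Falls back to bounded least squares on the rare active-set
    non-convergence of the Lawson-Hanson solver.
    """
    try:
        return nnls(a, b, maxiter=max(200, 50 * a.shape[1]))
    except RuntimeError:
        from scipy.optimize import lsq_linear

        res = lsq_linear(a, b, bounds=(0.0, np.inf))
        x = np.maximum(res.x, 0.0)
        return x, float(np.linalg.norm(a @ x - b))

__all__ = [
    "ResidueModel",
    "ResidueDecomposition",
    "KineticMaps",
    "TwoCompartmentParams",
    "two_compartment_residue",
    "fit_residue_model",
    "nnls_map",
    "decompose_residue",
    "residue_summaries",
    "element_summaries",
    "kinetic_params",
    "map_bootstrap_kinetics",
    "voi_percentile_distribution",
    "PARAM_NAMES",
    "default_knots",
    "frame_averaged_convolution_basis",
]

#: Kinetic parameter names, in canonical order.
PARAM_NAMES = ("vb", "vd", "kd", "ki", "mtt", "extraction")

#: Default vascular transit bound: 5 seconds, in minutes.
DEFAULT_T_B = 1.0 / 12.0

#: Default fine evaluation step: half a second, in minutes.
FINE_STEP = 1.0 / 120.0


@dataclass
class ResidueModel:
    """A residue function sampled on a fine uniform grid, with a delay.

    ``values`` must be non-negative and non-increasing; ``times`` starts
    at 0 with steps of at most one second.
    """

    times: np.ndarray
    values: np.ndarray
    delay: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.values, dtype=float)
        if t.shape != r.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D of equal length")
        if np.any(r < -1e-12):
            raise ValueError("residue must be non-negative")
        if np.any(np.diff(r) > 1e-10 * max(1.0, float(r.max(initial=0.0)))):
            raise ValueError("residue must be non-increasing")
        self.times = t
        self.values = np.maximum(r, 0.0)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.interp(t, self.times, self.values, left=self.values[0], right=self.values[-1])


@dataclass
class ResidueDecomposition:
    """Vascular / in-distribution / extraction split of a residue."""

    times: np.ndarray
    r_b: np.ndarray
    r_d: np.ndarray
    r_e: np.ndarray
    t_b: float
    t_e: float


@dataclass
class KineticMaps:
    """Per-voxel kinetic parameter maps; NaN marks undefined entries."""

    vb: np.ndarray
    vd: np.ndarray
    kd: np.ndarray
    ki: np.ndarray
    mtt: np.ndarray
    extraction: np.ndarray

    @property
    def k1(self) -> np.ndarray:
        return self.ki + self.kd

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def stacked(self) -> np.ndarray:
        """(P, N) array in :data:`PARAM_NAMES` order."""
        return np.stack([getattr(self, name) for name in PARAM_NAMES])


@dataclass(frozen=True)
class TwoCompartmentParams:
    """Rate constants of the 2-compartment exchange model plus blood fraction."""

    k1: float
    k2: float
    k3: float
    k4: float
    f_b: float = 0.0

    def __post_init__(self):
        if min(self.k1, self.k2, self.k3, self.k4) < 0:
            raise ValueError("rate constants must be non-negative")
        if not 0 <= self.f_b < 1:
            raise ValueError("f_b must lie in [0, 1)")

    @property
    def eigenrates(self):
        """(lam1, lam2, pi) of the bi-exponential impulse response."""
        s = self.k2 + self.k3 + self.k4
        disc = max(s * s - 4.0 * self.k2 * self.k4, 0.0)
        lam1 = 0.5 * (s + np.sqrt(disc))
        lam2 = 0.5 * (s - np.sqrt(disc))
        if lam1 - lam2 < 1e-14:
            pi = 1.0  # degenerate eigenvalues: single-exponential limit
        else:
            pi = (self.k3 + self.k4 - lam2) / (lam1 - lam2)
        return lam1, lam2, pi


def two_compartment_residue(
    params: TwoCompartmentParams,
    t_b: float = DEFAULT_T_B,
    t_end: float = 90.0,
    step: float = FINE_STEP,
) -> ResidueModel:
    """Analytic residue of the 2-compartment model with a vascular correction.

    The tissue impulse response is a mixture of exponentials,
    ``I_C(t) = k1 (1 - pi) exp(-lam1 t) + k1 pi exp(-lam2 t)``, and the
    returned residue is ``R_o(t) + (1 - f_b) I_C(t)`` where ``R_o`` is a
    triangular pulse on ``[0, t_b]`` integrating to ``f_b``.
    """
    t = np.arange(0.0, t_end + step / 2.0, step)
    lam1, lam2, pi = params.eigenrates
    i_c = params.k1 * ((1.0 - pi) * np.exp(-lam1 * t) + pi * np.exp(-lam2 * t))
    r_o = np.where(t <= t_b, 2.0 * params.f_b / t_b * (1.0 - t / t_b), 0.0)
    return ResidueModel(times=t, values=r_o + (1.0 - params.f_b) * i_c)


def decompose_residue(residue: ResidueModel, t_b: float, t_e: float) -> ResidueDecomposition:
    """Split ``R`` into vascular, in-distribution and extraction components.

    ``R_E`` is the constant ``R(t_e)`` (flux), ``R_B(t) = R(t) - R(t_b)``
    on ``[0, t_b]`` and zero beyond, and ``R_D`` is the remainder.
    """
    if not 0.0 < t_b < t_e:
        raise ValueError(f"need 0 < t_b < t_e, got t_b={t_b}, t_e={t_e}")
    if residue.times[-1] < t_e - 1e-9:
        raise ValueError("residue grid does not cover [0, t_e]")
    t = residue.times
    r = residue.values
    r_e = np.full_like(r, residue(t_e))
    r_b = np.where(t <= t_b, r - residue(t_b), 0.0)
    r_b = np.maximum(r_b, 0.0)
    r_d = r - r_b - r_e
    return ResidueDecomposition(times=t, r_b=r_b, r_d=r_d, r_e=r_e, t_b=t_b, t_e=t_e)


def residue_summaries(residue: ResidueModel, t_b: float, t_e: float) -> dict:
    """Scalar kinetic summaries of one residue.

    Returns ``vb`` (integral of the vascular component), ``kd``
    (``R_D(0)``), ``vd`` (integral of ``R_D`` over the study) and ``ki``
    (``R(t_e)``).
    """
    dec = decompose_residue(residue, t_b, t_e)
    in_b = dec.times <= t_b + 1e-12
    in_e = dec.times <= t_e + 1e-12
    return {
        "vb": float(np.trapezoid(dec.r_b[in_b], dec.times[in_b])),
        "kd": float(dec.r_d[0]),
        "vd": float(np.trapezoid(dec.r_d[in_e], dec.times[in_e])),
        "ki": float(dec.r_e[0]),
    }


# ---------------------------------------------------------------------------
# Residue model fitting


def default_knots(t_e: float, n_knots: int = 24, t_min: float = DEFAULT_T_B) -> np.ndarray:
    """Geometric knot grid on ``(0, t_e]``: dense early, sparse late."""
    return np.geomspace(t_min, t_e, n_knots)


def _double_cumulative(aif: InputFunction, delay: float, t_max: float, step: float):
    """Fine grid, G(t) = int_0^t Cp(s - delay) ds, and H(t) = int_0^t G."""
    t = np.arange(0.0, t_max + step, step)
    cp = aif(t - delay)
    cp[t < delay] = 0.0
    g = np.concatenate([[0.0], np.cumsum(0.5 * (cp[1:] + cp[:-1]) * step)])
    h = np.concatenate([[0.0], np.cumsum(0.5 * (g[1:] + g[:-1]) * step)])
    return t, g, h


def frame_averaged_convolution_basis(
    knots: np.ndarray,
    aif: InputFunction,
    schedule: FrameSchedule,
    delay: float = 0.0,
    step: float = FINE_STEP,
) -> np.ndarray:
    """Frame-averaged convolution of unit step-residues with the input.

    Column ``m`` holds the frame averages of
    ``t -> int_0^t 1{t - s < tau_m} Cp(s - delay) ds``; a non-negative
    combination of these columns is the frame-averaged convolution of a
    non-increasing step residue with the delayed input.
    """
    a = schedule.mid_times - schedule.durations / 2.0
    b = schedule.mid_times + schedule.durations / 2.0
    t_max = float(b[-1]) + step
    t, g, h = _double_cumulative(aif, delay, t_max, step)

    def h_at(x):
        return np.interp(np.clip(x, 0.0, t[-1]), t, h)

    cols = []
    for tau in np.atleast_1d(knots):
        # frame average of G(t) - G(t - tau) is a difference of H values
        num = (h_at(b) - h_at(a)) - (h_at(b - tau) - h_at(a - tau))
        cols.append(num / schedule.durations)
    return np.column_stack(cols)


def _step_residue_values(t: np.ndarray, knots: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """R(t) = sum_m theta_m 1{t <= tau_m}; non-increasing by construction.

    The closed right end keeps R(t_e) positive when the last knot sits at
    the study end (the constant, pure-flux component).
    """
    return (theta[None, :] * (t[:, None] <= knots[None, :])).sum(axis=1)


def fit_residue_model(
    tac: np.ndarray,
    aif: InputFunction,
    schedule: FrameSchedule,
    delay_grid: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    knots: np.ndarray | None = None,
    t_end: float | None = None,
    step: float = FINE_STEP,
) -> ResidueModel:
    """Fit a monotone step residue to a frame-sampled time-course.

    For every candidate delay, a non-negative least squares problem over
    step-residue increments (monotone by construction) is solved against
    the frame-averaged convolution basis; the delay minimizing the
    weighted residual is kept.
    """
    tac = np.asarray(tac, dtype=float)
    if not aif.covers(schedule.end_time):
        raise ValueError("input function does not cover the study duration")
    if t_end is None:
        t_end = schedule.end_time
    if knots is None:
        knots = default_knots(t_end)
    if delay_grid is None:
        delay_grid = np.array([0.0])
    if weights is None:
        weights = np.ones_like(tac)
    sw = np.sqrt(np.asarray(weights, dtype=float))

    best = (np.inf, None, None)
    for delay in np.atleast_1d(delay_grid):
        basis = frame_averaged_convolution_basis(knots, aif, schedule, delay, step)
        theta, rnorm = nnls_safe(basis * sw[:, None], tac * sw)
        if rnorm < best[0]:
            best = (rnorm, float(delay), theta)
    _, delay, theta = best
    t_fine = np.arange(0.0, t_end + step / 2.0, step)
    return ResidueModel(times=t_fine, values=_step_residue_values(t_fine, knots, theta), delay=delay)


def residue_tac(
    residue: ResidueModel,
    aif: InputFunction,
    schedule: FrameSchedule,
    step: float = FINE_STEP,
) -> np.ndarray:
    """Frame-averaged convolution of a residue with the delayed input.

    Evaluates ``t -> int_0^t R(t - s) Cp(s - delay) ds`` on a fine grid by
    FFT convolution and averages it over each acquisition frame.
    """
    from scipy.signal import fftconvolve

    t_max = schedule.end_time + step
    t = np.arange(0.0, t_max, step)
    cp = aif(t - residue.delay)
    cp[t < residue.delay] = 0.0
    r = residue(t)
    # trapezoid-corrected discrete convolution (endpoint half-weights)
    conv = (fftconvolve(r, cp)[: t.size] - 0.5 * (r[0] * cp + r * cp[0])) * step
    # cumulative integral of the convolution, for exact frame averages
    c_int = np.concatenate([[0.0], np.cumsum(0.5 * (conv[1:] + conv[:-1]) * step)])
    a = schedule.mid_times - schedule.durations / 2.0
    b = schedule.mid_times + schedule.durations / 2.0
    ia = np.interp(np.clip(a, 0.0, t[-1]), t, c_int)
    ib = np.interp(np.clip(b, 0.0, t[-1]), t, c_int)
    return (ib - ia) / schedule.durations


# ---------------------------------------------------------------------------
# Voxel-level non-negative mapping


def nnls_map(values: np.ndarray, design: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-voxel non-negative weighted least squares coefficients.

    Parameters
    ----------
    values : ``(N, T)`` data array (or a :class:`DynamicImage`).
    design : ``(T, K)`` temporal design matrix.
    weights : length ``T`` frame weights.

    Returns ``(N, K)`` non-negative coefficients.
    """
    if isinstance(values, DynamicImage):
        values = values.values
    z = np.asarray(values, dtype=float)
    x = np.asarray(design, dtype=float)
    if x.ndim != 2 or x.shape[0] != z.shape[1]:
        raise ValueError("design must be (T, K) matching the data frames")
    sw = np.sqrt(np.asarray(weights, dtype=float))
    xw = x * sw[:, None]
    alpha = np.empty((z.shape[0], x.shape[1]))
    zw = z * sw[None, :]
    for i in range(z.shape[0]):
        alpha[i], _ = nnls_safe(xw, zw[i])
    return alpha


def element_summaries(basis, t_b: float = DEFAULT_T_B, t_e: float | None = None) -> dict:
    """Kinetic summaries for each basis element of a residue-carrying basis.

    Elements without a residue model contribute zero to all summaries.
    Returns arrays of length K: ``vb, kd, vd, ki, delay``.
    """
    k = basis.n_elements
    out = {key: np.zeros(k) for key in ("vb", "kd", "vd", "ki", "delay")}
    for idx in range(k):
        res = basis.residues[idx]
        if res is None:
            continue
        te = t_e if t_e is not None else float(res.times[-1])
        summ = residue_summaries(res, t_b, te)
        for key in ("vb", "kd", "vd", "ki"):
            out[key][idx] = summ[key]
        out["delay"][idx] = basis.delays[idx]
    return out


def kinetic_params(alpha: np.ndarray, summaries: dict) -> KineticMaps:
    """Voxel kinetic maps from non-negative coefficients and element summaries.

    Linear parameters follow by linearity; the mean transit time is the
    flow-weighted average of per-element delays plus volume-to-flow
    ratios, with weights proportional to ``alpha_ik * kd_k`` (elements
    with zero flow are excluded from the weighting).
    """
    a = np.asarray(alpha, dtype=float)
    vb = a @ summaries["vb"]
    kd = a @ summaries["kd"]
    vd = a @ summaries["vd"]
    ki = a @ summaries["ki"]
    k1 = ki + kd

    flow_w = a * summaries["kd"][None, :]  # (N, K), >= 0
    total_flow = flow_w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        kd_el = summaries["kd"]
        per_el_mtt = np.where(kd_el > 0, summaries["delay"] + summaries["vd"] / np.where(kd_el > 0, kd_el, 1.0), 0.0)
        mtt = np.where(total_flow > 0, (flow_w @ per_el_mtt) / np.where(total_flow > 0, total_flow, 1.0), np.nan)
        extraction = np.where(k1 > 0, ki / np.where(k1 > 0, k1, 1.0), np.nan)
    return KineticMaps(vb=vb, vd=vd, kd=kd, ki=ki, mtt=mtt, extraction=extraction)


def map_bootstrap_kinetics(samples, design: np.ndarray, weights: np.ndarray, summaries: dict):
    """Kinetic maps, their mean and SD, for every replicate of a bootstrap set.

    Value replicates are refit by non-negative least squares; coefficient
    replicates (recycled bootstrap) skip refitting and are clamped at zero
    before mapping.  Undefined (NaN) entries are excluded from the
    mean/SD statistics.

    Returns ``(per_replicate_maps, mean_maps, sd_maps)`` where the latter
    two are dicts keyed by parameter name.
    """
    maps = []
    for rep in samples.replicates:
        if samples.kind == "recycled":
            alpha = np.maximum(np.asarray(rep, dtype=float), 0.0)
        else:
            alpha = nnls_map(rep, design, weights)
        maps.append(kinetic_params(alpha, summaries))
    stacks = {name: np.stack([m.as_dict()[name] for m in maps]) for name in PARAM_NAMES}
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN voxels
        mean_maps = {name: np.nanmean(s, axis=0) for name, s in stacks.items()}
        sd_maps = {name: np.nanstd(s, axis=0, ddof=1) for name, s in stacks.items()}
    return maps, mean_maps, sd_maps


def voi_percentile_distribution(per_replicate_values, mask: VOIMask, q: float) -> np.ndarray:
    """Replicate sample of the q-th percentile of a parameter within a VOI."""
    ind = mask.indicator
    out = []
    for values in per_replicate_values:
        v = np.asarray(values, dtype=float).ravel(order="F")
        if v.size != ind.size:
            raise ValueError("parameter map size does not match VOI mask")
        v = v[ind]
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValueError("VOI contains no defined voxels")
        out.append(np.percentile(v, q))
    return np.asarray(out)
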