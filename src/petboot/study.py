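"""Core containers for dynamic PET studies and fit serialization.

Conventions used throughout the package:

* time is in **minutes** everywhere;
* voxels are linearized voxel-major with ``x`` fastest, then ``y``, then
  ``z`` (Fortran order over an ``(nx, ny, nz)`` grid), frames ``0..T-1``;
* activity values are arbitrary concentration-like units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "FrameSchedule",
    "VoxelGrid",
    "DynamicImage",
    "InputFunction",
    "VOIMask",
    "load_dynamic_study",
    "save_dynamic_study",
    "load_schedule",
    "load_input_function",
]


class StudyValidationError(ValueError):
    """Raised when a study component violates its invariants."""


@dataclass(frozen=True)
class FrameSchedule:
    """Frame mid-times and durations, plus the isotope decay constant.

    Parameters
    ----------
    mid_times : array of length T, minutes, strictly increasing.
    durations : array of length T, minutes, strictly positive.
    decay_constant : isotope decay constant (1/min).
    """

    mid_times: np.ndarray
    durations: np.ndarray
    decay_constant: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.mid_times, dtype=float)
        dt = np.asarray(self.durations, dtype=float)
        if t.ndim != 1 or dt.ndim != 1 or t.shape != dt.shape:
            raise StudyValidationError("mid_times and durations must be 1-D, same length")
        if t.size < 2:
            raise StudyValidationError("a schedule needs at least 2 frames")
        if np.any(np.diff(t) <= 0):
            raise StudyValidationError("frame mid-times must be strictly increasing")
        if np.any(dt <= 0):
            raise StudyValidationError("frame durations must be positive")
        object.__setattr__(self, "mid_times", t)
        object.__setattr__(self, "durations", dt)

    @property
    def n_frames(self) -> int:
        return self.mid_times.size

    def decay_factors(self) -> np.ndarray:
        """exp(-t_j * zeta) per frame."""
        return np.exp(-self.mid_times * self.decay_constant)

    @property
    def end_time(self) -> float:
        return float(self.mid_times[-1] + self.durations[-1] / 2.0)


@dataclass(frozen=True)
class VoxelGrid:
    """Voxel lattice: shape ``(nx, ny, nz)`` and spacing in mm per axis."""

    shape: tuple
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        shp = tuple(int(s) for s in self.shape)
        if len(shp) != 3 or any(s < 1 for s in shp):
            raise StudyValidationError("grid shape must be 3 positive integers")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise StudyValidationError("voxel spacing must be 3 positive floats")
        object.__setattr__(self, "shape", shp)
        object.__setattr__(self, "spacing", sp)

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def unflatten(self, values: np.ndarray) -> np.ndarray:
        """Reshape an ``(N, ...)`` voxel-major array to ``(nx, ny, nz, ...)``."""
        v = np.asarray(values)
        return v.reshape(self.shape + v.shape[1:], order="F")

    def flatten(self, volume: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`unflatten`."""
        v = np.asarray(volume)
        return v.reshape((self.n_voxels,) + v.shape[3:], order="F")


@dataclass
class DynamicImage:
    """An ``N x T`` dynamic study: values plus grid and frame schedule."""

    values: np.ndarray
    grid: VoxelGrid
    schedule: FrameSchedule

    def __post_init__(self):
        z = np.asarray(self.values, dtype=float)
        if z.ndim != 2:
            raise StudyValidationError("values must be an N x T array")
        if z.shape[0] != self.grid.n_voxels:
            raise StudyValidationError(
                f"values rows ({z.shape[0]}) do not match grid voxels ({self.grid.n_voxels})"
            )
        if z.shape[1] != self.schedule.n_frames:
            raise StudyValidationError(
                f"values columns ({z.shape[1]}) do not match schedule frames "
                f"({self.schedule.n_frames})"
            )
        if not np.all(np.isfinite(z)):
            raise StudyValidationError("values must be finite")
        self.values = z

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def frame_volume(self, j: int) -> np.ndarray:
        """Frame ``j`` as an ``(nx, ny, nz)`` volume."""
        return self.grid.unflatten(self.values[:, j])


@dataclass(frozen=True)
class InputFunction:
    """Arterial blood concentration time-course, finely sampled in minutes."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise StudyValidationError("input function times/values must be 1-D, same length")
        if np.any(np.diff(t) <= 0):
            raise StudyValidationError("input function times must be strictly increasing")
        if np.any(v < 0):
            raise StudyValidationError("input function must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def covers(self, t_max: float) -> bool:
        return self.times[0] <= 0.0 + 1e-12 and self.times[-1] >= t_max - 1e-9

    def __call__(self, t) -> np.ndarray:
        """Linear interpolation; zero before the first sample and flat after the last."""
        t = np.asarray(t, dtype=float)
        out = np.interp(t, self.times, self.values, left=0.0, right=float(self.values[-1]))
        return out


@dataclass(frozen=True)
class VOIMask:
    """Boolean voxel selector with a label."""

    indicator: np.ndarray
    label: str = ""

    def __post_init__(self):
        ind = np.asarray(self.indicator, dtype=bool).ravel(order="F")
        if ind.sum() < 1:
            raise StudyValidationError(f"VOI '{self.label}' selects no voxels")
        object.__setattr__(self, "indicator", ind)

    @property
    def n_voxels(self) -> int:
        return int(self.indicator.sum())


# ---------------------------------------------------------------------------
# I/O


def load_schedule(path) -> FrameSchedule:
    """Read a frame schedule CSV with header ``mid_time_min,duration_min``.

    A third column, if present, is taken as the decay constant (1/min,
    constant; the first row's value is used).
    """
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise StudyValidationError("schedule file needs at least 2 columns")
    zeta = float(df.iloc[0, 2]) if df.shape[1] >= 3 else 0.0
    return FrameSchedule(
        mid_times=df.iloc[:, 0].to_numpy(float),
        durations=df.iloc[:, 1].to_numpy(float),
        decay_constant=zeta,
    )


def load_input_function(path) -> InputFunction:
    """Read an input-function CSV with header ``time_min,cp``."""
    import pandas as pd

    df = pd.read_csv(path)
    return InputFunction(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


def load_dynamic_study(image_path, schedule_path) -> DynamicImage:
    """Load a 4-D NIfTI-1 volume series together with its frame schedule."""
    import nibabel as nib

    schedule = load_schedule(schedule_path)
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise StudyValidationError(f"expected 4-D image, got {data.ndim}-D")
    if data.shape[3] != schedule.n_frames:
        raise StudyValidationError(
            f"image has {data.shape[3]} frames but schedule has {schedule.n_frames} rows"
        )
    zooms = img.header.get_zooms()[:3]
    grid = VoxelGrid(shape=data.shape[:3], spacing=tuple(float(z) for z in zooms))
    values = data.reshape(grid.n_voxels, schedule.n_frames, order="F")
    return DynamicImage(values=values, grid=grid, schedule=schedule)


def save_dynamic_study(study: DynamicImage, image_path, schedule_path=None) -> None:
    """Write a study back to NIfTI-1 (and optionally its schedule CSV)."""
    import nibabel as nib
    import pandas as pd

    vol = study.grid.unflatten(study.values)
    affine = np.diag(list(study.grid.spacing) + [1.0])
    nib.save(nib.Nifti1Image(vol, affine), str(image_path))
    if schedule_path is not None:
        pd.DataFrame(
            {
                "mid_time_min": study.schedule.mid_times,
                "duration_min": study.schedule.durations,
                "decay_constant": study.schedule.decay_constant,
            }
        ).to_csv(schedule_path, index=False)


# --- fit container -----------------------------------------------------------

_FIT_FORMAT_VERSION = 1


class FitSerializationError(IOError):
    pass


def _write_group(grp: h5py.Group, obj: dict) -> None:
    for key, val in obj.items():
        if isinstance(val, dict):
            _write_group(grp.create_group(key), val)
        elif val is None:
            grp.attrs[key] = "__none__"
        elif isinstance(val, str):
            grp.attrs[key] = val
        elif np.isscalar(val):
            grp.attrs[key] = val
        else:
            grp.create_dataset(key, data=np.asarray(val))


def _read_group(grp: h5py.Group) -> dict:
    out = {}
    for key, val in grp.attrs.items():
        out[key] = None if (isinstance(val, str) and val == "__none__") else val
    for key, val in grp.items():
        if isinstance(val, h5py.Group):
            out[key] = _read_group(val)
        else:
            out[key] = val[()]
    return out


def save_fit(fit, path) -> None:
    """Serialize a :class:`~petboot.glm.GLMFit` to a single HDF5 container."""
    state = fit.to_state()
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FIT_FORMAT_VERSION
        _write_group(f.create_group("fit"), state)


def load_fit(path):
    """Load a fit written by :func:`save_fit`."""
    from .glm import GLMFit

    try:
        with h5py.File(path, "r") as f:
            if "fit" not in f:
                raise FitSerializationError(f"{path}: not a fit container")
            state = _read_group(f["fit"])
    except OSError as exc:
        raise FitSerializationError(f"{path}: corrupt or unreadable fit file: {exc}") from exc
    return GLMFit.from_state(state)
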