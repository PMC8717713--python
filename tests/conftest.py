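import numpy as np
import pytest

from petboot.basis import TemporalBasis
from petboot.glm import fit_glm
from petboot.scanner import default_schedule, synthetic_aif
from petboot.study import DynamicImage, FrameSchedule, VoxelGrid


@pytest.fixture(scope="session")
def schedule20() -> FrameSchedule:
    return default_schedule(20)


@pytest.fixture(scope="session")
def aif():
    return synthetic_aif()


@pytest.fixture(scope="session")
def uniform_schedule() -> FrameSchedule:
    dur = np.full(20, 1.0)
    return FrameSchedule(np.cumsum(dur) - 0.5, dur)


def make_glm_study(
    nx=16, n_frames=12, n_basis=3, sigma_scale=0.3, seed=0, phi=None, grid_z=1
):
    """A study generated exactly from the heteroscedastic product model."""
    rng = np.random.default_rng(seed)
    grid = VoxelGrid((nx, nx, grid_z))
    n = grid.n_voxels
    dur = np.full(n_frames, 1.0)
    sch = FrameSchedule(np.cumsum(dur) - 0.5, dur)
    t = sch.mid_times
    cols = [np.exp(-t / 4.0), t / t.max(), np.ones(n_frames)][:n_basis]
    design = np.column_stack(cols)
    alpha = np.abs(rng.standard_normal((n, n_basis))) * np.linspace(5, 2, n_basis)
    sigma = sigma_scale * (0.5 + rng.random(n))
    if phi is None:
        raw = np.linspace(0.6, 1.4, n_frames)
        phi = np.sqrt(n_frames * raw / raw.sum())
    zhat = alpha @ design.T
    z = zhat + sigma[:, None] * phi[None, :] * rng.standard_normal((n, n_frames))
    study = DynamicImage(z, grid, sch)
    basis = TemporalBasis(design=design, names=[f"b{k}" for k in range(n_basis)])
    truth = {"alpha": alpha, "sigma": sigma, "phi": phi, "zhat": zhat}
    return study, basis, truth


@pytest.fixture(scope="session")
def glm_study():
    return make_glm_study(nx=16, n_frames=12, seed=0)


@pytest.fixture(scope="session")
def glm_fit(glm_study):
    study, basis, _ = glm_study
    return fit_glm(study, basis, l_bins=8)
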