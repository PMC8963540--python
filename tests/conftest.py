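import numpy as np
import pytest

from sedlab import synth
from sedlab.calibration import CalibrationObservations
from sedlab.physics import CONSTANTS, fit_seawater_density_model


@pytest.fixture(scope="session")
def seawater_table():
    df, truth = synth.gen_seawater_table(seed=11, noise_sd=1e-3)
    return df, truth


@pytest.fixture(scope="session")
def seawater_model(seawater_table):
    df, _ = seawater_table
    return fit_seawater_density_model(np.column_stack([df["temp_C"], df["salinity"], df["density"]]))


def make_joint_observations(s_star, pp_star, n_ref=30, n_assay=30, seed=0, noise_cv=0.0):
    """Noise-controlled joint reference+assay observation set from known truth."""
    rng = np.random.default_rng(seed)
    r_ref = np.exp(rng.uniform(np.log(5e-6), np.log(2e-4), n_ref))
    r_assay = np.exp(rng.uniform(np.log(1e-5), np.log(1e-4), n_assay))
    radius = np.concatenate([r_ref, r_assay])
    v_phys = CONSTANTS.stokes_prefactor * pp_star * radius**2
    v0 = v_phys.copy()
    v0[n_ref:] /= np.exp(s_star)  # assay rows are recorded in AU
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        v0 = v0 * rng.lognormal(-0.5 * sigma**2, sigma, size=v0.size)
    h = np.concatenate([np.zeros(n_ref), np.ones(n_assay)])
    return CalibrationObservations(v0, radius, h)


@pytest.fixture
def joint_observations():
    return make_joint_observations
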