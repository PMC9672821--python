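import numpy as np
import pytest

from strokefate import phantom, preproc


@pytest.fixture(scope="session")
def noise_free_cfg() -> phantom.PhantomConfig:
    return phantom.PhantomConfig(noise_sigma=0.0)


@pytest.fixture(scope="session")
def noise_free_patient(noise_free_cfg):
    """One deterministic noise-free phantom patient (series, truth, follow-up)."""
    series, truth, followup = phantom.gen_patient(noise_free_cfg, patient_seed=11)
    return series, truth, followup


@pytest.fixture(scope="session")
def noise_free_series(noise_free_cfg, noise_free_patient):
    series, _, _ = noise_free_patient
    return preproc.PerfusionSeries(
        values=series,
        voxel_spacing=noise_free_cfg.voxel_spacing,
        dt=noise_free_cfg.dt,
        domain="raw",
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
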