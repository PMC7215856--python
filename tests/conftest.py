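"""Shared fixtures: synthetic ground-truth datasets and pipeline runs.

Session-scoped so the heavier pipeline runs happen once per test session.
"""

import numpy as np
import pytest

from fiddec import denoise, preset, separate_t2, standard_ft


@pytest.fixture(scope="session")
def sucrose_truth():
    return preset("sucrose_like", 0)


@pytest.fixture(scope="session")
def sucrose_result(sucrose_truth):
    return denoise(
        sucrose_truth.noisy_fid,
        window_size=1024,
        variant="psmf",
        reassign_initial_segments=1,
        seed=0,
    )


@pytest.fixture(scope="session")
def sucrose_clean_spectrum(sucrose_truth):
    return standard_ft(sucrose_truth.clean_fid)


@pytest.fixture(scope="session")
def diffusion_truth():
    return preset("diffusion_edited_like", 0)


@pytest.fixture(scope="session")
def diffusion_result(diffusion_truth):
    return separate_t2(
        diffusion_truth.noisy_fid,
        window_size=512,
        variant="psmf",
        reassign_initial_segments=1,
        seed=0,
    )


def spectral_correlation(a, b):
    """Pearson correlation of the real parts of two spectra."""
    return float(np.corrcoef(np.real(a.intensities), np.real(b.intensities))[0, 1])
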