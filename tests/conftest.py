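"""Shared fixtures: one model stack built once per session."""

import numpy as np
import pytest

import irlfod as F


@pytest.fixture(scope="session")
def gtab():
    """b=0 volume + the packaged 81-direction b=3000 shell."""
    return F.default_gradient_table(3000.0)


@pytest.fixture(scope="session")
def samp():
    """321-direction hemisphere sampling/atom tessellation."""
    return F.icosphere(3, hemisphere=True)


@pytest.fixture(scope="session")
def basis(samp):
    return F.build_dictionary(samp)


@pytest.fixture(scope="session")
def resp(gtab, samp):
    return F.build_response(gtab, samp)


@pytest.fixture(scope="session")
def operator(resp, basis):
    return F.assemble_operator(resp, basis)


@pytest.fixture(scope="session")
def render():
    """2562-vertex full-sphere render tessellation (fast test default)."""
    return F.icosphere(4)


@pytest.fixture(scope="session")
def render_fine():
    """10242-vertex production render tessellation."""
    return F.icosphere(5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260918)


def stick_spec(direction, iso=0.0, weights=None):
    """Phantom voxel whose fiber tensor matches the model's FA=1 response."""
    direction = np.atleast_2d(direction)
    if weights is None:
        weights = [(1.0 - iso) / len(direction)] * len(direction)
    return F.PhantomSpec(direction, weights, iso,
                         anisotropic_eigenvalues=(2.1e-3, 0.0, 0.0))
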