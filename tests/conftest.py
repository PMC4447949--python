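"""Shared fixtures: every structure is generated at test time."""

import numpy as np
import pytest

from etsface.synthetic_structures import (
    build_bdna,
    build_ets_like_complex,
    build_water_network_complex,
)


@pytest.fixture(scope="session")
def consensus_duplex():
    """Straight fiber duplex of the crystallization 10-mer."""
    return build_bdna("ACCGGAAGTG")


@pytest.fixture(scope="session")
def ets_complex():
    """Planted Ets-footprint complex and its ground truth."""
    return build_ets_like_complex()


@pytest.fixture(scope="session")
def water_complex():
    """Planted four-water recognition network and its ground truth."""
    return build_water_network_complex()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
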