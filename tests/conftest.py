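import numpy as np
import pytest

from ecmri import ComplexImage, PhantomConfig, make_cartesian_mask, make_phantom


def centered_dft_matrix(n: int) -> np.ndarray:
    """Independent closed-form 1-D centered unitary DFT matrix:
    M[k, m] = exp(-2i*pi*(k-c)(m-c)/n) / sqrt(n) with c = n//2."""
    c = n // 2
    k = np.arange(n)[:, None] - c
    m = np.arange(n)[None, :] - c
    return np.exp(-2j * np.pi * k * m / n) / np.sqrt(n)


def centered_dft_2d(H: int, W: int) -> np.ndarray:
    """(H*W, H*W) matrix of the centered unitary 2-D DFT on raveled images."""
    return np.kron(centered_dft_matrix(H), centered_dft_matrix(W))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom(PhantomConfig(size=(64, 64), seed=42))


@pytest.fixture(scope="session")
def mask64_cart30():
    return make_cartesian_mask(64, 64, ratio=0.30, seed=7)


def random_complex(rng, shape) -> np.ndarray:
    return rng.normal(size=shape) + 1j * rng.normal(size=shape)


@pytest.fixture()
def random_image16(rng):
    return ComplexImage(random_complex(rng, (16, 16)))
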