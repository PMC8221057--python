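import numpy as np
import pytest

import vibexciton as vx


@pytest.fixture
def aa_mode():
    """Single C–H stretch surrogate (2918 cm^-1, 0.25 D in-plane)."""
    return vx.aa_ch_mode()


@pytest.fixture
def pfoa_mode():
    """Single C–F stretch surrogate (1213 cm^-1, 0.5 D in-plane)."""
    return vx.pfoa_single_mode()


@pytest.fixture
def band_modes():
    """Three-band C–F surrogate spanning 1100–1280 cm^-1."""
    return vx.pfoa_cf_band_modes()


@pytest.fixture
def z_mode():
    """Single mode polarized along the surface normal (pure H-aggregate)."""
    return vx.MonomerModeSet(("CH",), np.array([2918.0]),
                             np.array([[0.0, 0.0, 0.25]]))


@pytest.fixture
def rng():
    return np.random.default_rng(20210518)


def random_dimer(rng, freq=2918.0, detune=0.0, dipole=0.25):
    """Random two-molecule configuration with one mode each."""
    mode = vx.MonomerModeSet(("m",), np.array([freq]),
                             np.array([[dipole, 0.0, 0.0]]))
    pos = np.zeros((2, 3))
    pos[1] = rng.uniform(-1, 1, 3)
    pos[1] *= rng.uniform(4.0, 12.0) / np.linalg.norm(pos[1])
    orients = vx.random_rotations(2, rng)
    offsets = np.array([[0.0], [detune]])
    return vx.MolecularConfiguration(pos, orients, mode,
                                     freq_offsets=offsets)
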