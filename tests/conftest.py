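import numpy as np
import pytest

from eegms.microstates import normalize_maps
from eegms.montage import synthetic_montage


@pytest.fixture
def small_montage():
    return synthetic_montage(16)


@pytest.fixture
def sphere_montage():
    """Homogeneous full-sphere lattice: no cap-boundary edge effects."""
    return synthetic_montage(64, cap_fraction=1.0)


@pytest.fixture
def ortho_maps():
    """4 exactly orthogonal average-referenced unit maps on 16 channels."""
    rng = np.random.default_rng(42)
    raw = rng.standard_normal((16, 4))
    raw -= raw.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(raw)
    q -= q.mean(axis=0, keepdims=True)
    return normalize_maps(q.T)


def dipolar_maps(montage, n_classes, seed):
    """Orthonormal mixtures of the three dipole patterns on a montage."""
    rng = np.random.default_rng(seed)
    basis = normalize_maps(montage.positions.T)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    return normalize_maps((q @ basis)[:n_classes])
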