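"""Shared fixtures: acquisition schemes, phantom masks, signal helpers."""

import numpy as np
import pytest

from cortexdiff.io_core import AcquisitionScheme, ImageVolume
from cortexdiff.cortical_grid import LABEL_INTERIOR, LABEL_PIAL, LABEL_WM
from cortexdiff.synthetic_data import default_scheme


@pytest.fixture(scope="session")
def scheme() -> AcquisitionScheme:
    """The emulated protocol: 90 directions x 3 shells + 15 b0."""
    return default_scheme()


def multi_tensor_signal(scheme, comps, s0=1.0):
    """Noiseless mixture signal for [(axis, l_par, l_perp, fraction), ...]."""
    S = np.zeros(scheme.n_volumes)
    for axis, lp, lq, f in comps:
        u = np.asarray(axis, float)
        u = u / np.linalg.norm(u)
        c = scheme.bvecs @ u
        S += f * np.exp(-scheme.bvals * (lq + (lp - lq) * c**2))
    return s0 * S


@pytest.fixture(scope="session")
def signal_factory(scheme):
    return lambda comps, s0=1.0: multi_tensor_signal(scheme, comps, s0)


def slab_mask(n_depth=10, n_len=50, pixel=0.175):
    """Labeled slab ribbon: pial top row, gray/white bottom row."""
    lab = np.zeros((n_depth + 2, n_len), int)
    lab[0] = LABEL_PIAL
    lab[-1] = LABEL_WM
    lab[1:-1] = LABEL_INTERIOR
    return ImageVolume(lab, (pixel, pixel, 1.0))


def annulus_mask(r_in=10.0, r_out=20.0, pixel=0.175):
    """Quarter-annulus ribbon with boundary shells on the nominal radii."""
    N = int(np.ceil(r_out)) + 3
    yy, xx = np.meshgrid(np.arange(N), np.arange(N), indexing="ij")
    r = np.hypot(xx, yy)
    lab = np.zeros((N, N), int)
    ribbon = (r >= r_in - 0.5) & (r <= r_out + 0.5)
    lab[ribbon] = LABEL_INTERIOR
    lab[ribbon & (r < r_in + 0.5)] = LABEL_PIAL
    lab[ribbon & (r > r_out - 0.5)] = LABEL_WM
    return ImageVolume(lab, (pixel, pixel, 1.0)), r
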