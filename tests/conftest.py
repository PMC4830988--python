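import numpy as np
import pytest

from neokurt.io import DWIVolume
from neokurt.phantom import (CompartmentParams, make_scheme,
                             signal_from_cumulants)


@pytest.fixture(scope="session")
def scheme18():
    """The study's acquisition layout: 1 b=0 + 18 directions x 3 shells."""
    return make_scheme(18, (500.0, 1000.0, 2000.0))


@pytest.fixture(scope="session")
def worked_params():
    """The recurring reference voxel: f=0.5 single fiber along x."""
    return CompartmentParams(f=0.5, Da_axial=1.2e-3, De_par=1.9e-3,
                             De_perp=1.0e-3, axis=np.array([1.0, 0.0, 0.0]))


@pytest.fixture()
def rng():
    return np.random.default_rng(20160414)


def random_compartment_params(rng, n=1, f_range=(0.1, 0.7)):
    """Random valid two-compartment parameter sets (branch assumption held)."""
    out = []
    while len(out) < n:
        f = rng.uniform(*f_range)
        De_par = rng.uniform(1.2e-3, 2.8e-3)
        Da = rng.uniform(0.5e-3, De_par)
        De_perp = rng.uniform(0.4e-3, De_par)
        axis = rng.standard_normal(3)
        try:
            out.append(CompartmentParams(f=f, Da_axial=Da, De_par=De_par,
                                         De_perp=De_perp, axis=axis))
        except ValueError:
            continue
    return out if n > 1 else out[0]


def cumulant_voxel_volume(params, scheme, reps=(1, 1, 1)):
    """A tiny DWIVolume tiled with one voxel's exact cumulant-form signal."""
    sig = signal_from_cumulants(params, scheme)
    return DWIVolume(np.tile(sig, (*reps, 1)), scheme)
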