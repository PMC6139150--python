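import math

import numpy as np
import pandas as pd
import pytest

from ddflex import coarse_grain, make_hinge_fixture, simulate_em_map
from ddflex.grid_io import AtomicModel, DensityMap

SIGMA_STAR = 3.0  # kernel width used to build self-consistency fixtures


@pytest.fixture(scope="session")
def hinge_small():
    """Small two-domain hinge fixture shared across engine/pipeline tests."""
    return make_hinge_fixture(n_res_per_domain=10, theta_deg=30.0, seed=0)


@pytest.fixture(scope="session")
def selfconsistent_map():
    """Model + map generated from it at a known kernel width (sigma* = 3 A)."""
    fx = make_hinge_fixture(n_res_per_domain=12, theta_deg=30.0, seed=1)
    cm = coarse_grain(fx.start)
    em = simulate_em_map(fx.start, resolution=2.0 * math.sqrt(3.0) * SIGMA_STAR)
    return cm, em


@pytest.fixture()
def toy_map():
    """2x2x2 grid holding the values 0..7."""
    return DensityMap(np.arange(8, dtype=float).reshape(2, 2, 2),
                      origin=[0, 0, 0], voxel_size=[1, 1, 1])


def make_residue_model(residues):
    """AtomicModel from a list of (chain, resid, resname, [(name, element,
    mass, xyz), ...]) tuples."""
    rows = []
    for chain, resid, resname, atoms in residues:
        for name, element, mass, (x, y, z) in atoms:
            rows.append(dict(chain=chain, resid=resid, resname=resname,
                             name=name, element=element, mass=mass,
                             x=x, y=y, z=z, occ=1.0, bfac=0.0))
    return AtomicModel(pd.DataFrame(rows))


ALA_ATOMS = [
    ("N", "N", 14.007, (0.0, 0.0, 0.0)),
    ("CA", "C", 12.011, (1.46, 0.0, 0.0)),
    ("C", "C", 12.011, (2.0, 1.4, 0.0)),
    ("O", "O", 15.999, (1.5, 2.5, 0.0)),
    ("CB", "C", 12.011, (2.0, -0.8, 1.2)),
]

GLY_ATOMS = ALA_ATOMS[:4]
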