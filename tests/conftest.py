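import numpy as np
import pytest

from mdmech.fixtures import _bare_topology
from mdmech.trajio import Box, FFParams, Frame


def open_box(extent: float = 100.0) -> Box:
    return Box(lo=[-extent] * 3, hi=[extent] * 3,
               periodic_flags=(False, False, False))


def make_frame(positions, velocities=None, types=None, timestep=0,
               box=None) -> Frame:
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return Frame(timestep=timestep, box=box or open_box(),
                 atom_ids=np.arange(1, n + 1), positions=positions,
                 type_ids=np.ones(n, dtype=np.int64) if types is None
                 else np.asarray(types, dtype=np.int64),
                 velocities=velocities)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def allterm_system():
    """12-atom system exercising every force-field term type.

    Two chains of four bonded atoms (bonds, angles with Urey-Bradley, a
    multi-term dihedral, an improper) plus free atoms, with LJ + Coulomb
    including a 1-4 pair with dedicated 1-4 parameters, at moderate
    separations so no term is near a singularity.
    """
    rng = np.random.default_rng(7)
    base = np.array([
        [0.0, 0.0, 0.0], [1.5, 0.3, 0.1], [2.6, 1.4, 0.0], [3.9, 1.3, 1.0],
        [6.0, 4.0, 1.0], [7.4, 4.4, 1.2], [8.3, 5.6, 1.9], [9.6, 5.2, 2.8],
        [1.0, 6.0, 3.0], [4.0, 7.0, 0.5], [7.0, 1.0, 3.5], [2.0, 3.5, 4.2]])
    pos = base + rng.normal(0.0, 0.05, size=base.shape)
    types = ["TA", "TB", "TC", "TD"] * 3
    topo = _bare_topology(
        12, types, 12.0, charges=rng.normal(0.0, 0.3, 12),
        bonds=[(0, 1), (1, 2), (2, 3), (4, 5), (5, 6), (6, 7)],
        angles=[(0, 1, 2), (1, 2, 3), (4, 5, 6)],
        dihedrals=[(0, 1, 2, 3), (4, 5, 6, 7), (1, 2, 3, 9)],
        impropers=[(4, 5, 6, 7)])
    params = FFParams()
    for t in ("TA", "TB", "TC", "TD"):
        params.nonbonded[t] = (0.15, 1.9, 0.08, 1.7)
    params.bonds[FFParams._canon2("TA", "TB")] = (250.0, 1.5)
    params.bonds[FFParams._canon2("TB", "TC")] = (200.0, 1.45)
    params.bonds[FFParams._canon2("TC", "TD")] = (180.0, 1.6)
    params.angles[FFParams._canon3("TA", "TB", "TC")] = (50.0, 110.0, 10.0, 2.5)
    params.angles[FFParams._canon3("TB", "TC", "TD")] = (40.0, 120.0, 0.0, 0.0)
    # exact quadruple with two multiplicities, plus a wildcard fallback used
    # by the TB-TC chain of the second molecule
    params.dihedrals[FFParams._canon4("TA", "TB", "TC", "TD")] = {
        1: (2.0, 0.0), 3: (0.5, 180.0)}
    # the (TB, TC, TD, TB) torsion resolves only through the wildcard
    params.dihedrals[FFParams._canon4("X", "TC", "TD", "X")] = {2: (1.2, 90.0)}
    params.impropers[FFParams._canon4("TA", "TB", "TC", "TD")] = (30.0, 10.0)
    params.cutoff, params.switch_start = 9.0, 7.5
    frame = make_frame(pos)
    return frame, topo, params
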