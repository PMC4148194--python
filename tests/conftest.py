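import logging

import numpy as np
import pytest

from isovol import Lattice, SolidRegion
from isovol.electrostatics import AtomRecord, ChargedStructure


@pytest.fixture(autouse=True)
def _quiet_boundary_warnings(caplog):
    # boundary-clipping warnings are expected in many geometric tests
    logging.getLogger("isovol.marching").setLevel(logging.ERROR)
    yield


def make_lattice(half: float, spacing: float = 0.5, center=(0.0, 0.0, 0.0)):
    center = np.asarray(center, dtype=float)
    return Lattice.from_bounds(center - half, center + half, spacing)


def sphere_solid(
    radius: float,
    lattice: Lattice,
    center=(0.0, 0.0, 0.0),
) -> SolidRegion:
    """Analytic sphere as a signed-distance solid."""
    pts = lattice.points()
    d = np.linalg.norm(pts - np.asarray(center, dtype=float), axis=-1)
    return SolidRegion(lattice, radius - d)


def single_atom(
    charge: float,
    radius: float = 1.5,
    position=(0.0, 0.0, 0.0),
    chain: str = "A",
    resnum: int = 1,
    name: str = "X",
    resname: str = "UNK",
) -> AtomRecord:
    return AtomRecord(
        serial=1, name=name, residue_name=resname, chain=chain,
        residue_number=resnum, insertion_code="", position=tuple(position),
        radius=radius, charge=charge,
    )


def structure_of(*atoms: AtomRecord) -> ChargedStructure:
    renumbered = []
    for i, a in enumerate(atoms, start=1):
        from dataclasses import replace

        renumbered.append(replace(a, serial=i))
    return ChargedStructure(renumbered)


@pytest.fixture
def lat8():
    """A 16 Å box at the default 0.5 Å resolution."""
    return make_lattice(8.0)
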