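"""Shared fixtures: tiny structures, short annealing schedules, count series."""

import numpy as np
import pytest

from parchscale.structure_io import Atom, ProteinStructure, Residue
from parchscale.system_builder import AnnealingSchedule


def make_structure(residue_specs, box=None):
    """Build a structure from [(resname, kind, [xyz, ...]), ...] in nm."""
    atoms, residues = [], []
    serial = 0
    for resname, kind, positions in residue_specs:
        start = len(atoms)
        for pos in positions:
            serial += 1
            atoms.append(
                Atom(serial, "OW" if kind == "water" else "CA",
                     "O" if kind == "water" else "C",
                     len(residues), np.asarray(pos, dtype=float))
            )
        residues.append(
            Residue(len(residues), resname, "A", len(residues) + 1,
                    range(start, len(atoms)), kind=kind)
        )
    return ProteinStructure(atoms, residues,
                            box=None if box is None else np.asarray(box, dtype=float))


@pytest.fixture
def structure_factory():
    return make_structure


@pytest.fixture
def short_schedule():
    """A coarse ramp (300 -> 800 K, 51 samples) to keep series small."""
    return AnnealingSchedule(sample_interval_ps=100.0)


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.400   2.000   3.000  1.00  0.00           C
ATOM      3  C   ALA A   1       3.800   2.500   3.000  1.00  0.00           C
ATOM      4  O   ALA A   1       4.500   3.200   3.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.400   0.600   3.000  1.00  0.00           C
END
"""

MIXED_PDB = """\
ATOM      1  CA  GLY A   1       1.000   1.000   1.000  1.00  0.00           C
ATOM      2  OW  SOL A   2       5.000   5.000   5.000  1.00  0.00           O
ATOM      3  OW  SOL A   3       6.000   5.000   5.000  1.00  0.00           O
ATOM      4  OW  SOL A   4       7.000   5.000   5.000  1.00  0.00           O
ATOM      5  NA  NA  A   5       9.000   9.000   9.000  1.00  0.00          Na
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


@pytest.fixture
def mixed_pdb(tmp_path):
    path = tmp_path / "mixed.pdb"
    path.write_text(MIXED_PDB)
    return path
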