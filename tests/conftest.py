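"""Shared fixtures: hand-written PDB snippets and synthetic chain surfaces."""

import numpy as np
import pytest

from zernsurf.structures import AtomRecord, AtomSet, Representation, select_representation
from zernsurf.synthetic import FixtureSpec, make_chain

# 3 residues, full heavy-atom backbone (N, CA, C, O), two side-chain heavy
# atoms (CB on res 1, OG on res 3) and four hydrogens that must be dropped:
# 14 heavy atoms, of which 12 are backbone.
THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.776   7.068  -4.915  1.00  0.00           C
ATOM      4  O   ALA A   1      12.896   8.083  -5.607  1.00  0.00           O
ATOM      5  CB  ALA A   1      10.521   6.311  -4.130  1.00  0.00           C
ATOM      6  H   ALA A   1      10.604   5.422  -7.010  1.00  0.00           H
ATOM      7  HA  ALA A   1      12.009   5.065  -4.965  1.00  0.00           H
ATOM      8  N   GLY A   2      13.599   6.793  -3.905  1.00  0.00           N
ATOM      9  CA  GLY A   2      14.729   7.656  -3.575  1.00  0.00           C
ATOM     10  C   GLY A   2      15.930   7.407  -4.479  1.00  0.00           C
ATOM     11  O   GLY A   2      16.122   6.290  -4.962  1.00  0.00           O
ATOM     12  H   GLY A   2      13.441   5.987  -3.330  1.00  0.00           H
ATOM     13  N   SER A   3      16.749   8.437  -4.699  1.00  0.00           N
ATOM     14  CA  SER A   3      17.935   8.332  -5.545  1.00  0.00           C
ATOM     15  C   SER A   3      17.570   8.539  -7.012  1.00  0.00           C
ATOM     16  O   SER A   3      16.460   8.979  -7.325  1.00  0.00           O
ATOM     17  OG  SER A   3      18.890   9.318  -5.142  1.00  0.00           O
ATOM     18  HG  SER A   3      19.690   9.220  -5.662  1.00  0.00           H
TER
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  N   GLY A   2       2.100   1.300   0.100  1.00  0.00           N
ATOM      4  CA  GLY A   2       3.550   1.420   0.150  1.00  0.00           C
TER
ATOM      5  N   ALA B   1      10.000  10.000  10.000  1.00  0.00           N
ATOM      6  CA  ALA B   1      11.458  10.000  10.000  1.00  0.00           C
ATOM      7  O   HOH B 101      20.000  20.000  20.000  1.00  0.00           O
TER
END
"""


@pytest.fixture
def three_residue_pdb():
    return THREE_RESIDUE_PDB


@pytest.fixture
def two_chain_pdb():
    return TWO_CHAIN_PDB


@pytest.fixture(scope="session")
def chain100():
    """100-residue compact backbone chain, deterministic."""
    return make_chain(FixtureSpec(kind="random_chain", seed=1, n_residues=100))


@pytest.fixture(scope="session")
def chain100_cacno(chain100):
    return select_representation(chain100.atoms, Representation.CACNO)


@pytest.fixture(scope="session")
def small_chain():
    """60-residue chain for the quicker EM / feature tests."""
    return make_chain(FixtureSpec(kind="random_chain", seed=3, n_residues=60))


def single_atom_set(element="C", position=(0.0, 0.0, 0.0)):
    rec = AtomRecord(
        element=element,
        atom_name="CA" if element == "C" else element,
        residue_index=1,
        chain_id="A",
        position=np.asarray(position, dtype=float),
    )
    return AtomSet(atoms=[rec], representation=Representation.AASURF, n_residues=1)


@pytest.fixture
def one_atom():
    return single_atom_set()


def unit_ball_grid(radius=0.7, dim=64, filled=True):
    """Analytic voxel ball directly in unit-sphere coordinates."""
    from zernsurf.surface import UnitSphereGrid

    ax = (np.arange(dim) + 0.5 - dim / 2) * (2.0 / dim)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    mask = x**2 + y**2 + z**2 <= radius**2
    if not filled:
        from scipy import ndimage

        mask = mask & ~ndimage.binary_erosion(mask)
    return UnitSphereGrid(
        values=mask.astype(np.uint8),
        spacing=2.0 / dim,
        origin=np.full(3, -1.0 + 1.0 / dim),
        scale_factor=1.0,
        center=np.zeros(3),
    )
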