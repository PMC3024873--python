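"""PDB structure parsing and surface-representation atom selection.

A protein can be turned into four surface representations, each built from a
different atom subset:

* ``AASURF`` -- all heavy atoms (the classic all-atom molecular surface),
* ``CACNO`` -- the full heavy-atom backbone (C-alpha, C, N, O),
* ``CACN``  -- backbone without the carbonyl oxygen,
* ``CA``    -- C-alpha trace only.

Backbone-based representations expose the main-chain trace and are more
rugged than the all-atom surface, which is why they separate folds better in
shape-based retrieval.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import gemmi
import numpy as np

__all__ = [
    "Representation",
    "AtomRecord",
    "AtomSet",
    "parse_structure",
    "select_representation",
    "write_pdb",
]


class Representation(str, Enum):
    """Atom subset used to build a molecular surface."""

    AASURF = "aasurf"
    CACNO = "cacno"
    CACN = "cacn"
    CA = "ca"


# OXT is the C-terminal carboxyl oxygen: a main-chain heavy atom, counted as O.
_BACKBONE_NAMES = {
    Representation.CA: {"CA"},
    Representation.CACN: {"CA", "C", "N"},
    Representation.CACNO: {"CA", "C", "N", "O", "OXT"},
}


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom read from a coordinate file."""

    element: str
    atom_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray  # (3,) float, Angstrom

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"bad position for atom {self.atom_name}: {self.position}")
        object.__setattr__(self, "position", pos)
        if not self.element:
            raise ValueError("empty element symbol")


@dataclass
class AtomSet:
    """Ordered atom collection tagged with the representation it realises."""

    atoms: list[AtomRecord]
    representation: Representation
    n_residues: int = 0

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("empty atom set")
        if self.n_residues == 0:
            self.n_residues = len(
                {(a.chain_id, a.residue_index) for a in self.atoms}
            )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """Atom positions as an (N, 3) array in Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def ca_positions(self) -> np.ndarray:
        """Per-residue C-alpha positions in chain order, shape (n_res, 3)."""
        pos = [a.position for a in self.atoms if a.atom_name == "CA"]
        if not pos:
            raise ValueError("no C-alpha atoms in set")
        return np.array(pos, dtype=float)


def parse_structure(
    pdb_text: str,
    chain_id: str | None = None,
    mse_as_met: bool = False,
) -> list[AtomRecord]:
    """Extract heavy atoms from PDB-format text.

    Only the first model is used; alternate locations are restricted to the
    blank/'A' conformer. Hydrogens, waters and HETATM residues are dropped
    (selenomethionine can be kept with ``mse_as_met=True``). Residues are
    renumbered sequentially within each chain starting at 1, so downstream
    geometry never depends on author numbering or insertion codes.

    Parameters
    ----------
    pdb_text : str
        Contents of a PDB file.
    chain_id : str, optional
        Restrict extraction to one chain. Raises ``KeyError`` listing the
        available chains when absent.
    mse_as_met : bool
        Treat MSE (selenomethionine) HETATM residues as standard methionine.
    """
    try:
        structure = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed PDB input: {exc}") from exc
    if len(structure) == 0:
        raise ValueError("no atoms: input contains no ATOM records")
    model = structure[0]

    available = [ch.name for ch in model]
    if chain_id is not None and chain_id not in available:
        raise KeyError(
            f"chain {chain_id!r} not found; available chains: {sorted(set(available))}"
        )

    records: list[AtomRecord] = []
    for chain in model:
        if chain_id is not None and chain.name != chain_id:
            continue
        res_counter = 0
        for residue in chain:
            if residue.name == "HOH":
                continue
            if residue.het_flag == "H" and not (mse_as_met and residue.name == "MSE"):
                continue
            res_counter += 1
            for atom in residue:
                if atom.is_hydrogen():
                    continue
                if atom.altloc not in ("\0", "", "A"):
                    continue
                element = atom.element.name
                name = atom.name
                if mse_as_met and residue.name == "MSE" and name == "SE":
                    # stand in for the methionine SD sulfur
                    element, name = "S", "SD"
                records.append(
                    AtomRecord(
                        element=element,
                        atom_name=name,
                        residue_index=res_counter,
                        chain_id=chain.name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    )
                )
    if not records:
        raise ValueError("no atoms: no heavy ATOM records after filtering")
    return records


def select_representation(
    atoms: list[AtomRecord], kind: Representation | str
) -> AtomSet:
    """Filter parsed atoms down to one of the four surface representations.

    ``n_residues`` of the result reflects the residues of the *input* atoms,
    so the sequence-length pre-filter sees the true chain length no matter
    which representation is used for the surface.
    """
    kind = Representation(kind)
    if not atoms:
        raise ValueError("empty atom list")
    n_res = len({(a.chain_id, a.residue_index) for a in atoms})
    if kind is Representation.AASURF:
        selected = [a for a in atoms if a.element not in ("H", "D")]
    else:
        names = _BACKBONE_NAMES[kind]
        selected = [a for a in atoms if a.atom_name in names]
    if not selected:
        raise ValueError(f"no atoms match representation {kind.value!r}")
    return AtomSet(atoms=selected, representation=kind, n_residues=n_res)


_PDB_ATOM = (
    "ATOM  {serial:5d} {name:<4s}{resname:>3s} {chain:1s}{resnum:4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}\n"
)


def write_pdb(atoms: AtomSet | list[AtomRecord], resname: str = "ALA") -> str:
    """Render atoms as minimal PDB-format text (fixed wwPDB v3.3 columns)."""
    if isinstance(atoms, AtomSet):
        atoms = atoms.atoms
    lines = []
    for i, a in enumerate(atoms, start=1):
        name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
        lines.append(
            _PDB_ATOM.format(
                serial=i,
                name=name,
                resname=resname,
                chain=a.chain_id or "A",
                resnum=a.residue_index,
                x=a.position[0],
                y=a.position[1],
                z=a.position[2],
                element=a.element,
            )
        )
    lines.append("END\n")
    return "".join(lines)
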