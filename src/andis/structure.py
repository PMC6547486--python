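"""Protein chains as ordered standard residues with typed heavy atoms.

A :class:`ProteinChain` is the unit of both potential derivation and
scoring.  Parsing keeps only what the potential sees: first model, one
chain, standard amino acids, heavy atoms, highest-priority alternate
location.  Residues are renumbered consecutively from 1 so that residue
separation always means separation in the retained sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser

from .topology import RESIDUE_ATOMS, AtomTypeTable, TypingError, default_table

__all__ = [
    "AtomRecord",
    "Residue",
    "ProteinChain",
    "ParseError",
    "read_pdb",
    "write_pdb",
    "validate_training_chain",
]


class ParseError(ValueError):
    """Structured failure while reading a PDB file."""


@dataclass
class AtomRecord:
    """One typed heavy atom.

    ``residue_index`` is the 1-based position in the retained sequence,
    ``type_index`` the 0..166 heavy-atom type.
    """

    residue_name: str
    atom_name: str
    residue_index: int
    coords: np.ndarray
    type_index: int


@dataclass
class Residue:
    name: str
    index: int
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None

    @property
    def is_complete(self) -> bool:
        present = {a.atom_name for a in self.atoms}
        return present == set(RESIDUE_ATOMS[self.name])


@dataclass
class ProteinChain:
    """Ordered standard residues with heavy-atom coordinates."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def atoms(self):
        for res in self.residues:
            yield from res.atoms

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms()], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "ProteinChain":
        """Copy of the chain with all atom coordinates replaced (same order)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        out = ProteinChain(chain_id=self.chain_id)
        k = 0
        for res in self.residues:
            new_res = Residue(name=res.name, index=res.index)
            for a in res.atoms:
                new_res.atoms.append(AtomRecord(
                    residue_name=a.residue_name, atom_name=a.atom_name,
                    residue_index=a.residue_index,
                    coords=coords[k].copy(), type_index=a.type_index))
                k += 1
            out.residues.append(new_res)
        return out

    @property
    def sequence(self) -> list[str]:
        return [r.name for r in self.residues]


def read_pdb(path, chain_id: str | None = None,
             table: AtomTypeTable | None = None) -> ProteinChain:
    """Read one chain of a PDB file into a :class:`ProteinChain`.

    First model only.  Hydrogens, waters, hetero-residues, OXT and other
    atoms outside the 167-type table, and non-'A'/blank altlocs are
    dropped; retained residues are renumbered consecutively from 1.

    Parameters
    ----------
    chain_id : chain to extract; default = first chain containing standard
        residues.
    """
    table = table or default_table()
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure("s", str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ParseError(f"{path}: no models in file")

    bp_chain = None
    if chain_id is not None:
        for c in model:
            if c.id == chain_id:
                bp_chain = c
                break
        if bp_chain is None:
            raise ParseError(f"{path}: chain {chain_id!r} not found")
    else:
        for c in model:
            if any(r.id[0] == " " and r.get_resname() in RESIDUE_ATOMS
                   for r in c):
                bp_chain = c
                break
        if bp_chain is None:
            raise ParseError(f"{path}: no chain with standard residues")

    chain = ProteinChain(chain_id=str(bp_chain.id).strip() or "A")
    index = 0
    for bp_res in bp_chain:
        hetflag, _, _ = bp_res.id
        name = bp_res.get_resname()
        if hetflag != " " or name not in RESIDUE_ATOMS:
            continue  # waters, ligands, modified residues
        index += 1
        residue = Residue(name=name, index=index)
        for atom in bp_res:
            if atom.element == "H" or atom.element == "D":
                continue
            if atom.get_altloc() not in (" ", "A"):
                continue
            atom_name = atom.get_name()
            if (name, atom_name) not in table.type_of:
                continue  # OXT, terminal variants, nonstandard names
            if residue.atom(atom_name) is not None:
                continue  # duplicate (altloc already covered)
            residue.atoms.append(AtomRecord(
                residue_name=name, atom_name=atom_name, residue_index=index,
                coords=np.asarray(atom.get_coord(), dtype=float),
                type_index=table.index(name, atom_name)))
        if residue.atoms:
            chain.residues.append(residue)
        else:
            index -= 1
    if chain.length == 0:
        raise ParseError(f"{path}: zero standard residues in chain "
                         f"{bp_chain.id!r}")
    for i, res in enumerate(chain.residues, start=1):
        res.index = i
        for a in res.atoms:
            a.residue_index = i
    return chain


_PDB_LINE = ("ATOM  {serial:>5d} {name:<4s}{altloc:1s}{res:<3s} {chain:1s}"
             "{resseq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
             "{occ:6.2f}{b:6.2f}          {elem:>2s}\n")


def _pdb_atom_name(name: str) -> str:
    # single-letter elements are right-padded starting at column 14
    return f" {name:<3s}" if len(name) < 4 else name


def write_pdb(chain: ProteinChain, path) -> None:
    """Write a chain as minimal wwPDB v3.3 ATOM records."""
    with open(path, "w") as fh:
        serial = 0
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                elem = atom.atom_name[0]  # N/C/O/S for standard heavy atoms
                fh.write(_PDB_LINE.format(
                    serial=serial, name=_pdb_atom_name(atom.atom_name),
                    altloc=" ", res=res.name, chain=chain.chain_id[:1],
                    resseq=res.index, icode=" ",
                    x=atom.coords[0], y=atom.coords[1], z=atom.coords[2],
                    occ=1.0, b=0.0, elem=elem))
        fh.write("TER\nEND\n")


def validate_training_chain(chain: ProteinChain) -> tuple[bool, str]:
    """Training-set admission rule: length 30..1000 and complete residues.

    Returns ``(ok, reason)``; ``reason`` is empty when ``ok``.
    """
    if chain.length < 30:
        return False, "length < 30"
    if chain.length > 1000:
        return False, "length > 1000"
    for res in chain.residues:
        if not res.is_complete:
            missing = set(RESIDUE_ATOMS[res.name]) - {a.atom_name
                                                      for a in res.atoms}
            return False, (f"incomplete residue {res.name}{res.index} "
                           f"(missing {','.join(sorted(missing))})")
    return True, ""
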