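"""Residue-specific heavy-atom types and bonded connectivity.

The potential distinguishes 167 heavy-atom types: every (residue, atom-name)
combination over the 20 standard amino acids, from glycine's 4 backbone atoms
to tryptophan's 14 heavy atoms.  Each atom also carries an ordered list of
frame-neighbor candidates derived from covalent connectivity; the first two
candidates present in a structure define the atom's local coordinate system.

Inter-residue bonds are encoded with a prefix: ``-C`` is the carbonyl carbon
of the preceding residue, ``+N`` the amide nitrogen of the following one.
For atoms with a single bonded heavy neighbor the candidate list is extended
with that neighbor's own bonded atoms (the next-neighbor rule), which also
provides the terminal-residue fallbacks.

The canonical table ships as ``data/atom_types.tsv`` so that it is inspectable
and stable; :func:`build_default_table` regenerates it from the bond graphs
below and the two are asserted identical in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

__all__ = [
    "STANDARD_RESIDUES",
    "RESIDUE_ATOMS",
    "AtomTypeTable",
    "build_default_table",
    "default_table",
]

#: Heavy atoms per residue in canonical wwPDB order.
RESIDUE_ATOMS: dict[str, list[str]] = {
    "ALA": ["N", "CA", "C", "O", "CB"],
    "ARG": ["N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASN": ["N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"],
    "ASP": ["N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"],
    "CYS": ["N", "CA", "C", "O", "CB", "SG"],
    "GLN": ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"],
    "GLU": ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"],
    "GLY": ["N", "CA", "C", "O"],
    "HIS": ["N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "ILE": ["N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"],
    "LEU": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"],
    "LYS": ["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"],
    "MET": ["N", "CA", "C", "O", "CB", "CG", "SD", "CE"],
    "PHE": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PRO": ["N", "CA", "C", "O", "CB", "CG", "CD"],
    "SER": ["N", "CA", "C", "O", "CB", "OG"],
    "THR": ["N", "CA", "C", "O", "CB", "OG1", "CG2"],
    "TRP": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1",
            "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1",
            "CE2", "CZ", "OH"],
    "VAL": ["N", "CA", "C", "O", "CB", "CG1", "CG2"],
}

STANDARD_RESIDUES: tuple[str, ...] = tuple(sorted(RESIDUE_ATOMS))

#: Side-chain covalent bonds (heavy atoms, within a residue).
_SIDECHAIN_BONDS: dict[str, list[tuple[str, str]]] = {
    "ALA": [],
    "ARG": [("CB", "CG"), ("CG", "CD"), ("CD", "NE"), ("NE", "CZ"),
            ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CB", "SG")],
    "GLN": [("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")],
    "GLU": [("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")],
    "GLY": [],
    "HIS": [("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"), ("ND1", "CE1"),
            ("CD2", "NE2"), ("CE1", "NE2")],
    "ILE": [("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")],
    "MET": [("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PHE": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "PRO": [("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "SER": [("CB", "OG")],
    "THR": [("CB", "OG1"), ("CB", "CG2")],
    "TRP": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "NE1"),
            ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"), ("CE2", "CZ2"),
            ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")],
    "TYR": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"), ("CZ", "OH")],
    "VAL": [("CB", "CG1"), ("CB", "CG2")],
}


def residue_bonds(residue: str) -> list[tuple[str, str]]:
    """All heavy-atom bonds within ``residue`` plus the peptide links.

    The backbone bonds N-CA, CA-C, C-O, CA-CB are shared by all residues;
    ``-C``/``+N`` denote the peptide bond partners in adjacent residues.
    """
    bonds = [("-C", "N"), ("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "+N")]
    if residue != "GLY":
        bonds.append(("CA", "CB"))
    bonds.extend(_SIDECHAIN_BONDS[residue])
    return bonds


def bonded_map(residue: str) -> dict[str, list[str]]:
    """Ordered bonded-partner lists.  ``-C`` sorts first for N, ``+N`` last
    for C; within a residue partners follow canonical atom order."""
    atoms = RESIDUE_ATOMS[residue]
    order = {name: i for i, name in enumerate(atoms)}
    order["-C"] = -1          # previous residue's C precedes everything
    order["+N"] = len(atoms)  # next residue's N follows everything
    partners: dict[str, list[str]] = {a: [] for a in atoms}
    for x, y in residue_bonds(residue):
        if x in partners:
            partners[x].append(y)
        if y in partners:
            partners[y].append(x)
    return {a: sorted(p, key=order.__getitem__) for a, p in partners.items()}


def _frame_candidates(residue: str) -> dict[str, list[str]]:
    """Ordered frame-neighbor candidates per atom.

    The list starts with the atom's bonded partners; next-neighbor atoms
    (partners of partners, same residue only) are appended so that atoms
    with a single bonded heavy neighbor — and atoms at chain termini whose
    inter-residue partner is absent — still find two frame anchors.
    """
    bonded = bonded_map(residue)
    out: dict[str, list[str]] = {}
    for atom, partners in bonded.items():
        cand = list(partners)
        for p in partners:
            if p in ("-C", "+N"):
                continue
            for q in bonded[p]:
                if q != atom and q not in cand and q not in ("-C", "+N"):
                    cand.append(q)
        out[atom] = cand
    return out


class TypingError(KeyError):
    """Raised for a (residue, atom) pair outside the 167-type table."""


@dataclass(frozen=True)
class AtomTypeTable:
    """Bijection (residue, atom) <-> type index 0..166 plus frame neighbors.

    Attributes
    ----------
    type_of : mapping (residue, atom) -> int
    neighbors_of : mapping (residue, atom) -> ordered candidate neighbor
        names; ``-C``/``+N`` refer to the adjacent residues.
    version : table format tag recorded in serialized potentials.
    """

    type_of: dict[tuple[str, str], int]
    neighbors_of: dict[tuple[str, str], list[str]]
    version: str = "andis-atom-types/1"

    @property
    def n_types(self) -> int:
        return len(set(self.type_of.values()))

    def index(self, residue_name: str, atom_name: str) -> int:
        try:
            return self.type_of[(residue_name, atom_name)]
        except KeyError:
            raise TypingError(
                f"({residue_name}, {atom_name}) is not one of the 167 "
                "standard heavy-atom types"
            ) from None

    def name_of(self, index: int) -> tuple[str, str]:
        for key, idx in self.type_of.items():
            if idx == index:
                return key
        raise TypingError(f"no atom type with index {index}")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {self.version}\n")
            fh.write("# residue\tatom\tindex\tframe_neighbor_candidates\n")
            for (res, atom), idx in sorted(self.type_of.items(),
                                           key=lambda kv: kv[1]):
                nbrs = ",".join(self.neighbors_of[(res, atom)])
                fh.write(f"{res}\t{atom}\t{idx}\t{nbrs}\n")

    @classmethod
    def from_file(cls, path_or_text) -> "AtomTypeTable":
        if hasattr(path_or_text, "read"):
            text = path_or_text.read()
        else:
            text = open(path_or_text).read()
        version = None
        type_of: dict[tuple[str, str], int] = {}
        neighbors: dict[tuple[str, str], list[str]] = {}
        for line in text.splitlines():
            if line.startswith("#"):
                if version is None:
                    version = line.lstrip("# ").strip()
                continue
            if not line.strip():
                continue
            res, atom, idx, nbrs = line.split("\t")
            type_of[(res, atom)] = int(idx)
            neighbors[(res, atom)] = nbrs.split(",")
        return cls(type_of=type_of, neighbors_of=neighbors,
                   version=version or "andis-atom-types/1")


def build_default_table() -> AtomTypeTable:
    """Regenerate the canonical 167-type table from the bond graphs.

    Indices run over residues alphabetically, atoms in canonical order
    within each residue.
    """
    type_of: dict[tuple[str, str], int] = {}
    neighbors: dict[tuple[str, str], list[str]] = {}
    idx = 0
    for res in STANDARD_RESIDUES:
        cand = _frame_candidates(res)
        for atom in RESIDUE_ATOMS[res]:
            type_of[(res, atom)] = idx
            neighbors[(res, atom)] = cand[atom]
            idx += 1
    return AtomTypeTable(type_of=type_of, neighbors_of=neighbors)


_DEFAULT: AtomTypeTable | None = None


def default_table() -> AtomTypeTable:
    """The packaged canonical table (loaded once from data/atom_types.tsv)."""
    global _DEFAULT
    if _DEFAULT is None:
        ref = resources.files("andis").joinpath("data/atom_types.tsv")
        with ref.open() as fh:
            _DEFAULT = AtomTypeTable.from_file(fh)
    return _DEFAULT
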