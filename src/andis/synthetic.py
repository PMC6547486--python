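"""Deterministic toy structures, decoy ensembles and training corpora.

Everything the test suite and the examples consume is generated here, so
no structure downloads are ever needed.  Chains are built with ideal
backbone geometry (helix phi/psi = -57/-47 deg, strand -139/+135 deg) and
side chains grown along the covalent bond tree with idealized bond lengths
and angles.  The chains are chemically plausible but not physically
refined: rings are not closed exactly and rotamers are generic.  That is
sufficient for every statistical property the potential machinery relies
on — complete heavy-atom sets, non-degenerate local frames, and a
reproducible diversity of pair geometries.

Decoys are native structures perturbed by i.i.d. Gaussian coordinate
noise; their pseudo-quality score exp(-RMSD/3) stands in for TM-score (the
evaluation metrics only need a monotone quality signal).

``make_training_corpus`` can plant a known angular preference: for a given
type pair, distance bin and angle kind, matching atom pairs are rigidly
re-posed (the partner residue is moved as a unit onto an exactly
constructed target frame) so the chosen angle falls in a designated hot
bin with probability ``prob``.  Deriving the potential from such a corpus
must recover the hot bin as the energy minimum — the package's main
parameter-recovery check.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import (DIST_EDGES, FrameError, build_local_frame,
                       frame_from_angles)
from .structure import AtomRecord, ProteinChain, Residue, write_pdb
from .topology import RESIDUE_ATOMS, bonded_map, default_table

__all__ = [
    "AA1TO3",
    "FixtureSpec",
    "PlantedBias",
    "build_chain",
    "realize_fixture",
    "make_decoys",
    "make_training_corpus",
    "make_benchmark",
    "rmsd",
]

AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: Default residue alphabet for synthetic corpora and benchmarks.  A
#: desk-scale corpus (tens of chains) cannot populate statistics resolved
#: over all 167 atom types the way thousands of experimental chains do;
#: restricting the sequence alphabet concentrates the counts so that the
#: occurrence threshold is reached at the same rate as in a full-size
#: derivation.  Pass the full residue list to override.
DEFAULT_ALPHABET = ("ALA", "GLY", "LEU", "SER")

_BACKBONE_TORSIONS = {"helix": (-57.0, -47.0), "extended": (-139.0, 135.0)}
_TURN_TORSIONS = (60.0, 120.0)   # packs the two hairpin helices together
_TURN_LENGTH = 4


def _torsion_plan(backbone: str, length: int) -> list[tuple[float, float]]:
    """Per-residue (phi, psi) targets for a named conformation.

    ``hairpin`` is two ideal helices joined by a 4-residue turn chosen so
    the helices pack against each other — the source of the short-range
    (< 7 A) tertiary contacts that a lone ideal helix lacks.
    """
    if backbone in _BACKBONE_TORSIONS:
        phi, psi = _BACKBONE_TORSIONS[backbone]
        return [(phi, psi, 1.0)] * length
    if backbone == "hairpin":
        helix = _BACKBONE_TORSIONS["helix"] + (1.0,)
        # turn torsions are kept rigid (jitter scale 0): they set the
        # helix-helix crossing, and a degree of noise there swings the
        # packed core by several angstroms
        turn = _TURN_TORSIONS + (0.0,)
        first = max(1, (length - _TURN_LENGTH) // 2)
        plan = [helix] * first
        plan += [turn] * min(_TURN_LENGTH, max(0, length - first))
        plan += [helix] * (length - len(plan))
        return plan
    raise ValueError(f"unknown backbone conformation {backbone!r}")

# idealized geometry (A, deg)
_B_CN, _B_NCA, _B_CAC, _B_CO, _B_CACB = 1.329, 1.458, 1.525, 1.231, 1.53
_A_CACN, _A_CNCA, _A_NCAC, _A_CACO = 116.2, 121.7, 111.2, 120.5
_SIDE_ANGLE = 111.0
_SIDE_BONDS = {frozenset(p): b for p, b in [
    (("C", "C"), 1.52), (("C", "N"), 1.47), (("C", "O"), 1.42),
    (("C", "S"), 1.81)]}
_BRANCH_DIHEDRALS = (180.0, 60.0, -60.0, 120.0)


def place_atom(a, b, c, bond: float, angle_deg: float,
               dihedral_deg: float) -> np.ndarray:
    """Position of atom d bonded to c, with angle b-c-d and dihedral
    a-b-c-d (natural extension of reference frame / NeRF placement)."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang, dih = np.radians(angle_deg), np.radians(dihedral_deg)
    d_local = bond * np.array([-np.cos(ang),
                               np.sin(ang) * np.cos(dih),
                               np.sin(ang) * np.sin(dih)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _side_bond(x: str, y: str) -> float:
    return _SIDE_BONDS.get(frozenset((x[0], y[0])), 1.52)


def _normalize_sequence(sequence) -> list[str]:
    if isinstance(sequence, str):
        try:
            return [AA1TO3[ch] for ch in sequence]
        except KeyError as exc:
            raise ValueError(f"unknown residue letter {exc.args[0]!r}")
    seq = list(sequence)
    for name in seq:
        if name not in RESIDUE_ATOMS:
            raise ValueError(f"unknown residue name {name!r}")
    return seq


def build_chain(sequence, backbone: str = "helix", rng=None,
                dihedral_jitter: float = 0.0,
                chain_id: str = "A") -> ProteinChain:
    """Build an all-heavy-atom chain with ideal internal geometry.

    ``dihedral_jitter`` (degrees) adds uniform noise to every backbone and
    side-chain dihedral, drawn from ``rng``; with ``rng=None`` the chain is
    a fixed function of the sequence and conformation.
    """
    seq = _normalize_sequence(sequence)
    plan = _torsion_plan(backbone, len(seq))
    if dihedral_jitter and rng is None:
        raise ValueError("dihedral_jitter needs an rng")

    def jit():
        return float(rng.uniform(-dihedral_jitter, dihedral_jitter)) \
            if (rng is not None and dihedral_jitter) else 0.0

    table = default_table()
    coords: list[dict[str, np.ndarray]] = []
    psi_list = []
    for i, name in enumerate(seq):
        phi = plan[i][0] + plan[i][2] * jit()
        psi = plan[i][1] + plan[i][2] * jit()
        psi_list.append(psi)
        res: dict[str, np.ndarray] = {}
        if i == 0:
            res["N"] = np.zeros(3)
            res["CA"] = np.array([_B_NCA, 0.0, 0.0])
            ang = np.radians(180.0 - _A_NCAC)
            res["C"] = res["CA"] + _B_CAC * np.array(
                [np.cos(ang), np.sin(ang), 0.0])
        else:
            prev = coords[i - 1]
            res["N"] = place_atom(prev["N"], prev["CA"], prev["C"],
                                  _B_CN, _A_CACN, psi_list[i - 1])
            res["CA"] = place_atom(prev["CA"], prev["C"], res["N"],
                                   _B_NCA, _A_CNCA, 180.0)
            res["C"] = place_atom(prev["C"], res["N"], res["CA"],
                                  _B_CAC, _A_NCAC, phi)
        res["O"] = place_atom(res["N"], res["CA"], res["C"],
                              _B_CO, _A_CACO, psi + 180.0)
        if name != "GLY":
            res["CB"] = place_atom(res["N"], res["C"], res["CA"],
                                   _B_CACB, 110.1, -122.6)
            _grow_side_chain(name, res, rng, dihedral_jitter)
        coords.append(res)

    chain = ProteinChain(chain_id=chain_id)
    for i, name in enumerate(seq, start=1):
        residue = Residue(name=name, index=i)
        for atom_name in RESIDUE_ATOMS[name]:
            residue.atoms.append(AtomRecord(
                residue_name=name, atom_name=atom_name, residue_index=i,
                coords=coords[i - 1][atom_name],
                type_index=table.index(name, atom_name)))
        chain.residues.append(residue)
    return chain


def _grow_side_chain(name: str, res: dict[str, np.ndarray], rng,
                     jitter: float) -> None:
    """Walk the side-chain bond tree from CB, placing each atom from its
    parent/grandparent/great-grandparent with generic geometry."""
    bonds = bonded_map(name)
    parent = {"CB": "CA", "CA": "N", "N": "C"}  # N's entry: any anchor
    queue = ["CB"]
    while queue:
        p = queue.pop(0)
        children = [q for q in bonds.get(p, [])
                    if q not in res and q not in ("-C", "+N")]
        g = parent[p]
        gg = parent[g]
        base = None
        for idx, child in enumerate(children):
            if base is None:
                base = (float(rng.choice([180.0, 60.0, -60.0]))
                        if rng is not None else 180.0)
            dih = base + _BRANCH_DIHEDRALS[idx % 4] - 180.0
            if rng is not None and jitter:
                dih += float(rng.uniform(-jitter, jitter))
            res[child] = place_atom(res[gg], res[g], res[p],
                                    _side_bond(p, child), _SIDE_ANGLE, dih)
            parent[child] = p
            queue.append(child)


def rmsd(chain_a: ProteinChain, chain_b: ProteinChain) -> float:
    """Coordinate RMSD over aligned atoms (no superposition; decoys are
    generated in the native's frame)."""
    xa, xb = chain_a.coords_array(), chain_b.coords_array()
    if xa.shape != xb.shape:
        raise ValueError("chains differ in atom count")
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one native + decoy-ensemble fixture."""

    sequence: str
    backbone: str = "helix"
    noise_sd: float = 1.0
    n_decoys: int = 10
    seed: int = 0


def make_decoys(native: ProteinChain, noise_sds, n_per_level: int,
                rng=None, seed: int | None = None, out_dir=None):
    """Gaussian-noise decoys of a native chain plus pseudo-quality scores.

    Returns a list of ``(decoy_id, chain, rmsd, quality)`` with quality =
    exp(-RMSD/3).  With ``out_dir`` set, writes ``native.pdb``, one PDB per
    decoy and a two-column ``scores.tsv`` keyed by decoy id.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    coords = native.coords_array()
    out = []
    k = 0
    for sd in noise_sds:
        for _ in range(n_per_level):
            k += 1
            noise = rng.normal(0.0, sd, size=coords.shape) if sd > 0 else 0.0
            decoy = native.with_coords(coords + noise)
            d_rmsd = rmsd(native, decoy)
            out.append((f"decoy_{k:03d}", decoy, d_rmsd,
                        float(np.exp(-d_rmsd / 3.0))))
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        write_pdb(native, out_path / "native.pdb")
        with open(out_path / "scores.tsv", "w") as fh:
            fh.write("model\tquality\n")
            for decoy_id, decoy, _, quality in out:
                write_pdb(decoy, out_path / f"{decoy_id}.pdb")
                fh.write(f"{decoy_id}\t{quality:.6f}\n")
    return out


def realize_fixture(spec: FixtureSpec, out_dir=None):
    """Build the native chain and decoy ensemble a FixtureSpec describes.

    Returns ``(native, decoys)`` with decoys as from :func:`make_decoys`;
    with ``out_dir`` the usual native/decoys/scores.tsv layout is written.
    """
    rng = np.random.default_rng(spec.seed)
    native = build_chain(spec.sequence, backbone=spec.backbone, rng=rng,
                         dihedral_jitter=4.0)
    decoys = make_decoys(native, [spec.noise_sd], spec.n_decoys, rng=rng,
                         out_dir=out_dir)
    return native, decoys


@dataclass(frozen=True)
class PlantedBias:
    """A known angular preference to embed in a training corpus.

    ``angle_kind``: 0 theta_a, 1 theta_b, 2 phi_a, 3 phi_b, 4 chi (the
    angle measured for the ordered pair type_a -> type_b).
    """

    type_a: tuple[str, str]
    type_b: tuple[str, str]
    dist_bin: int
    angle_kind: int
    hot_bin: int
    prob: float = 0.9


def _sample_angle(kind: str, rng) -> float:
    return float(rng.uniform(0.0, 180.0 if kind == "polar" else 360.0))


def _plant_pairs(chain: ProteinChain, bias: PlantedBias,
                 rng) -> list[tuple[int, int]]:
    """Re-pose matching pairs so the biased angle lands in the hot bin.

    The residue holding the second atom is moved rigidly onto an exactly
    constructed target position + orientation.  Each residue is moved at
    most once.  Returns the (residue_i, residue_j) pairs planted.
    """
    res_a, atom_a = bias.type_a
    res_b, atom_b = bias.type_b
    lo, hi = DIST_EDGES[bias.dist_bin], DIST_EDGES[bias.dist_bin + 1]
    widths = {0: 15.0, 1: 15.0, 2: 30.0, 3: 30.0, 4: 30.0}
    w = widths[bias.angle_kind]
    used: set[int] = set()
    planted: list[tuple[int, int]] = []
    sites_a = [r for r in chain.residues if r.name == res_a]
    sites_b = [r for r in chain.residues if r.name == res_b]
    for ra in sites_a:
        if ra.index in used:
            continue
        for rb in sites_b:
            if rb.index in used or ra.index in used:
                continue
            if abs(ra.index - rb.index) < 7:
                continue
            rec_a, rec_b = ra.atom(atom_a), rb.atom(atom_b)
            if rec_a is None or rec_b is None:
                continue
            try:
                frame_a = build_local_frame(chain, rec_a)
                frame_b = build_local_frame(chain, rec_b)
            except FrameError:
                continue
            r_target = float(rng.uniform(lo + 0.02 * (hi - lo),
                                         hi - 0.02 * (hi - lo)))
            angles = [_sample_angle("polar", rng), _sample_angle("polar", rng),
                      _sample_angle("azimuth", rng),
                      _sample_angle("azimuth", rng),
                      _sample_angle("azimuth", rng)]
            if rng.uniform() < bias.prob:
                angles[bias.angle_kind] = float(rng.uniform(
                    bias.hot_bin * w + 0.05 * w,
                    (bias.hot_bin + 1) * w - 0.05 * w))
            target = frame_from_angles(frame_a, r_target, angles[0],
                                       angles[2], angles[1], angles[3],
                                       angles[4])
            # rigid map of rb's residue: current frame of atom_b -> target
            M = target.rotation.T @ frame_b.rotation
            pivot = rec_b.coords.copy()
            for rec in rb.atoms:
                rec.coords = target.origin + M @ (rec.coords - pivot)
            used.update((ra.index, rb.index))
            planted.append((ra.index, rb.index))
            break
    return planted


def make_training_corpus(n_chains: int, seed: int = 0,
                         planted_bias: PlantedBias | None = None,
                         length_range: tuple[int, int] = (45, 70),
                         dihedral_jitter: float = 4.0,
                         alphabet=DEFAULT_ALPHABET) -> list[ProteinChain]:
    """Seeded corpus of varied-sequence hairpin/helical/extended chains.

    With a :class:`PlantedBias`, sequences are enriched in the two target
    residues and matching pairs are re-posed so the biased angle falls in
    the hot bin with probability ``bias.prob``.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    rng = np.random.default_rng(seed)
    residues = list(alphabet)
    chains = []
    for k in range(n_chains):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if planted_bias is not None:
            others = [r for r in residues
                      if r not in (planted_bias.type_a[0],
                                   planted_bias.type_b[0])]
            pool = ([planted_bias.type_a[0]] * 8 + [planted_bias.type_b[0]] * 8
                    + list(rng.choice(others, size=4)))
            seq = [pool[int(i)] for i in rng.integers(0, len(pool),
                                                      size=length)]
        else:
            seq = [residues[int(i)]
                   for i in rng.integers(0, len(residues), size=length)]
        if planted_bias is not None:
            backbone = "helix"
        elif k == 0:
            backbone = "hairpin"  # a corpus always has >= 1 contact-rich fold
        else:
            u = rng.uniform()
            backbone = "hairpin" if u < 0.8 else (
                "helix" if u < 0.9 else "extended")
        chain = build_chain(seq, backbone=backbone, rng=rng,
                            dihedral_jitter=dihedral_jitter,
                            chain_id="A")
        if planted_bias is not None:
            _plant_pairs(chain, planted_bias, rng)
        chains.append(chain)
    return chains


def make_benchmark(out_dir, n_sets: int = 5, seed: int = 0,
                   noise_sds=(0.5, 0.8, 1.2, 1.8, 2.5),
                   n_per_level: int = 4,
                   length_range: tuple[int, int] = (45, 60),
                   alphabet=DEFAULT_ALPHABET) -> list[Path]:
    """Write a small decoy benchmark in the layout ``benchmark`` expects.

    One folder per set with ``native.pdb``, Gaussian-noise decoys at the
    given noise levels and the pseudo-quality ``scores.tsv``.
    """
    rng = np.random.default_rng(seed)
    residues = list(alphabet)
    out_path = Path(out_dir)
    set_dirs = []
    for k in range(n_sets):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = [residues[int(i)]
               for i in rng.integers(0, len(residues), size=length)]
        native = build_chain(seq, backbone="hairpin", rng=rng,
                             dihedral_jitter=4.0)
        set_dir = out_path / f"set_{k + 1:02d}"
        make_decoys(native, noise_sds, n_per_level, rng=rng,
                    out_dir=set_dir)
        set_dirs.append(set_dir)
    return set_dirs
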