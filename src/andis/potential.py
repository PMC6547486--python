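"""Derivation of the angle potential and the random-walk pair potential.

Observation counts are accumulated over a training corpus of validated
chains and converted into two score matrices by inverse Boltzmann
statistics (k_B*T == 1 throughout, so energies are dimensionless):

* the **angle potential** E_AG[kind, a, b, d, s]: for each of the five
  orientation angles (assumed conditionally independent given distance),
  each ordered type pair (a, b) and each distance bin d,
  E = -ln(p_obs(s) / p_ref) with p_ref = 1/12, the mean observed
  probability over the 12 angle bins.  Every angle-bin count starts from a
  pseudocount of 0.1; slices observed fewer than 20 times (unweighted) are
  left at zero energy.

* the **random-walk pair potential** E_RW[a, b, d]: a distance-only
  potential whose reference state is an ideal freely-jointed chain with
  Kuhn segment length ``l``.  The expected count in bin d for a protein of
  length L is proportional to r^2 * sum_{n=1..L} exp(-3 r^2 / (2 n l^2)) /
  n^{3/2}, evaluated at the bin midpoint, times the bin width, normalized
  per protein so the expected counts inside the reference cutoff sum to the
  observed per-protein pair totals.

Both directions of every unordered pair are accumulated, so the angle
tensor is exactly mirror-symmetric: counts[theta_a, a, b] equals
counts[theta_b, b, a], and likewise for the azimuths.
"""

from __future__ import annotations

import hashlib
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np

from .geometry import DIST_EDGES, N_ANGLE_BINS, N_DIST_BINS, R_MAX
from .interaction import chain_pair_table
from .structure import ProteinChain, validate_training_chain
from .topology import default_table

__all__ = [
    "N_TYPES",
    "PSEUDOCOUNT",
    "MIN_OCCURRENCE",
    "RW_ENERGY_CAP",
    "AngleCountTensor",
    "AnglePotential",
    "RWStatistics",
    "RWPotential",
    "Potential",
    "accumulate",
    "accumulate_pair_table",
    "derive_angle_potential",
    "derive_rw_potential",
    "derive_from_chains",
    "save_potential",
    "load_potential",
    "read_header",
    "MatrixError",
]

N_TYPES = 167
PSEUDOCOUNT = 0.1
MIN_OCCURRENCE = 20
RW_ENERGY_CAP = 10.0
FORMAT_VERSION = "andis-matrix/1"

ANGLE_SHAPE = (5, N_TYPES, N_TYPES, N_DIST_BINS, N_ANGLE_BINS)
OCC_SHAPE = (5, N_TYPES, N_TYPES, N_DIST_BINS)
RW_SHAPE = (N_TYPES, N_TYPES, N_DIST_BINS)

#: permutation of the five angle rows under pair-direction reversal
#: (theta_a<->theta_b, phi_a<->phi_b, chi invariant)
_MIRROR_KINDS = np.array([1, 0, 3, 2, 4])


class MatrixError(ValueError):
    """Unreadable, corrupt or incompatible potential matrix file."""


@dataclass
class AngleCountTensor:
    """Smoothed angle-bin counts plus unweighted occurrence totals."""

    counts: np.ndarray
    raw_occurrence: np.ndarray

    @classmethod
    def empty(cls) -> "AngleCountTensor":
        return cls(counts=np.full(ANGLE_SHAPE, PSEUDOCOUNT),
                   raw_occurrence=np.zeros(OCC_SHAPE, dtype=np.int64))


@dataclass
class AnglePotential:
    """E_AG tensor (5, 167, 167, 29, 12); zero where data were insufficient."""

    E: np.ndarray


@dataclass
class RWStatistics:
    """Pair-count statistics feeding the random-walk reference state."""

    n_obs: np.ndarray = field(
        default_factory=lambda: np.zeros(RW_SHAPE))
    per_protein: list = field(default_factory=list)   # (167,167) per chain
    lengths: list = field(default_factory=list)       # residues per chain
    r_cut_ref: float = R_MAX

    @property
    def n_proteins(self) -> int:
        return len(self.lengths)


@dataclass
class RWPotential:
    """E_RW tensor (167, 167, 29), capped at +RW_ENERGY_CAP."""

    E: np.ndarray
    kuhn_length: float = 3.8
    r_cut_ref: float = R_MAX


@dataclass
class Potential:
    """Derived matrices plus provenance header, as consumed by scoring."""

    angle: AnglePotential
    rw: RWPotential | None = None
    header: dict = field(default_factory=dict)


def accumulate(chain: ProteinChain, tensors: AngleCountTensor,
               rw: RWStatistics | None = None, mode: str = "weighted",
               table=None) -> None:
    """Add one validated training chain's observations to the tensors.

    ``mode='weighted'`` applies the effective-interaction shielding weight
    to the angle counts (the occurrence totals and the RW statistics stay
    unweighted — the sufficiency threshold and the distance distribution
    are about raw observations).
    """
    ok, reason = validate_training_chain(chain)
    if not ok:
        raise ValueError(f"chain rejected for training: {reason}")
    if mode not in ("weighted", "unweighted"):
        raise ValueError(f"unknown accumulation mode {mode!r}")
    t = chain_pair_table(chain, r_max=R_MAX, table=table,
                         with_weights=(mode == "weighted"))
    accumulate_pair_table(t, tensors, rw, chain_length=chain.length,
                          weighted=(mode == "weighted"))


def accumulate_pair_table(t, tensors: AngleCountTensor,
                          rw: RWStatistics | None,
                          chain_length: int, weighted: bool) -> None:
    """Add one chain's enumerated pair table to the count tensors."""
    if len(t) == 0:
        if rw is not None:
            rw.per_protein.append(np.zeros((N_TYPES, N_TYPES)))
            rw.lengths.append(chain_length)
        return
    w = t.weight if weighted else np.ones(len(t))

    P = len(t)
    kinds = np.repeat(np.arange(5), P)
    fwd_s = t.bins.reshape(-1)                       # (5P,) forward bins
    bwd_s = t.bins[_MIRROR_KINDS].reshape(-1)        # mirrored direction
    a5, b5 = np.tile(t.type_a, 5), np.tile(t.type_b, 5)
    d5, w5 = np.tile(t.dist_bin, 5), np.tile(w, 5)
    np.add.at(tensors.counts, (kinds, a5, b5, d5, fwd_s), w5)
    np.add.at(tensors.counts, (kinds, b5, a5, d5, bwd_s), w5)
    np.add.at(tensors.raw_occurrence, (kinds, a5, b5, d5), 1)
    np.add.at(tensors.raw_occurrence, (kinds, b5, a5, d5), 1)

    if rw is not None:
        np.add.at(rw.n_obs, (t.type_a, t.type_b, t.dist_bin), 1.0)
        np.add.at(rw.n_obs, (t.type_b, t.type_a, t.dist_bin), 1.0)
        totals = np.zeros((N_TYPES, N_TYPES))
        np.add.at(totals, (t.type_a, t.type_b), 1.0)
        np.add.at(totals, (t.type_b, t.type_a), 1.0)
        rw.per_protein.append(totals)
        rw.lengths.append(chain_length)


def derive_angle_potential(tensors: AngleCountTensor) -> AnglePotential:
    """Boltzmann inversion of the angle counts against the uniform mean.

    E(s) = -ln(12 * p_obs(s)) on slices with >= 20 raw observations; other
    slices are identically zero.
    """
    E = np.zeros(ANGLE_SHAPE)
    mask = tensors.raw_occurrence >= MIN_OCCURRENCE
    if mask.any():
        c = tensors.counts[mask]                      # (P, 12)
        p = c / c.sum(axis=1, keepdims=True)
        E[mask] = -np.log(N_ANGLE_BINS * p)
    return AnglePotential(E=E)


def _rw_chain_factor(r: np.ndarray, length: int, kuhn_length: float):
    """sum_{n=1..L} exp(-3 r^2 / (2 n l^2)) / n^{3/2}, vectorized in r."""
    n = np.arange(1, length + 1, dtype=float)
    expo = -3.0 * np.square(np.atleast_1d(r))[:, None] / (
        2.0 * n[None, :] * kuhn_length ** 2)
    return (np.exp(expo) / n[None, :] ** 1.5).sum(axis=1)


def rw_reference_bin_probabilities(length: int, kuhn_length: float,
                                   r_cut_ref: float = R_MAX) -> np.ndarray:
    """Reference probability of each distance bin for one protein length.

    Density (r/r_cut)^2 * f_L(r)/f_L(r_cut) at the bin midpoint, times the
    bin width, normalized over the 29 bins so a protein's expected counts
    within r_cut sum to its observed pair total.
    """
    mids = 0.5 * (DIST_EDGES[:-1] + DIST_EDGES[1:])
    widths = np.diff(DIST_EDGES)
    dens = (mids / r_cut_ref) ** 2 * (
        _rw_chain_factor(mids, length, kuhn_length)
        / _rw_chain_factor(np.array([r_cut_ref]), length, kuhn_length)[0])
    q = dens * widths
    return q / q.sum()


def derive_rw_potential(rw: RWStatistics, kuhn_length: float = 3.8,
                        r_cut_ref: float = R_MAX) -> RWPotential:
    """Distance-only potential with the random-walk chain reference state."""
    if rw.n_proteins == 0:
        raise ValueError("no accumulated proteins in RW statistics")
    if abs(r_cut_ref - rw.r_cut_ref) > 1e-9:
        raise ValueError(
            f"requested r_cut_ref {r_cut_ref} does not match the "
            f"accumulated per-protein totals (r_cut_ref={rw.r_cut_ref})")
    # q[p, d]: reference bin distribution per protein (lengths dedup'd)
    q = np.empty((rw.n_proteins, N_DIST_BINS))
    cache: dict[int, np.ndarray] = {}
    for p, L in enumerate(rw.lengths):
        if L not in cache:
            cache[L] = rw_reference_bin_probabilities(L, kuhn_length,
                                                      r_cut_ref)
        q[p] = cache[L]
    totals = np.stack(rw.per_protein)                 # (P, 167, 167)
    expected = np.einsum("pd,pab->abd", q, totals)
    E = np.zeros(RW_SHAPE)
    pos = expected > 0
    with np.errstate(divide="ignore"):
        E[pos] = -np.log(rw.n_obs[pos] / expected[pos])
    E = np.minimum(E, RW_ENERGY_CAP)
    # zero observed & zero expected stays 0 (never touched above)
    return RWPotential(E=E, kuhn_length=kuhn_length, r_cut_ref=r_cut_ref)


def derive_from_chains(chains, mode: str = "weighted",
                       kuhn_length: float = 3.8, table=None) -> Potential:
    """Full derivation pipeline over an iterable of training chains."""
    table = table or default_table()
    tensors = AngleCountTensor.empty()
    rw = RWStatistics()
    n_used = 0
    for chain in chains:
        accumulate(chain, tensors, rw, mode=mode, table=table)
        n_used += 1
    if n_used == 0:
        raise ValueError("empty training corpus")
    angle = derive_angle_potential(tensors)
    rw_pot = derive_rw_potential(rw, kuhn_length=kuhn_length)
    header = {
        "version": FORMAT_VERSION,
        "mode": mode,
        "kuhn_length": kuhn_length,
        "r_cut_ref": R_MAX,
        "rw_energy_cap": RW_ENERGY_CAP,
        "n_proteins": n_used,
        "atom_types": table.version,
    }
    return Potential(angle=angle, rw=rw_pot, header=header)


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def save_potential(potential: Potential, path) -> None:
    """Serialize both tensors plus a JSON header to a single ``.npz``."""
    header = dict(potential.header)
    header.setdefault("version", FORMAT_VERSION)
    header["checksum_angle"] = _digest(potential.angle.E)
    if potential.rw is not None:
        header["checksum_rw"] = _digest(potential.rw.E)
        header["kuhn_length"] = potential.rw.kuhn_length
        header["r_cut_ref"] = potential.rw.r_cut_ref
    arrays = {"E_angle": potential.angle.E,
              "header": np.frombuffer(
                  json.dumps(header).encode(), dtype=np.uint8)}
    if potential.rw is not None:
        arrays["E_rw"] = potential.rw.E
    np.savez(path, **arrays)


def read_header(path) -> dict:
    """Read only the JSON header of a matrix file (tensors stay on disk)."""
    try:
        with np.load(path) as npz:
            raw = bytes(npz["header"].tobytes())
    except (OSError, KeyError, zipfile.BadZipFile) as exc:
        raise MatrixError(f"cannot read matrix header from {path}: {exc}")
    header = json.loads(raw.decode())
    if header.get("version") != FORMAT_VERSION:
        raise MatrixError(
            f"matrix format version mismatch: {header.get('version')!r} "
            f"(expected {FORMAT_VERSION})")
    return header


def load_potential(path) -> Potential:
    """Load a matrix file, verifying version and tensor checksums."""
    header = read_header(path)
    try:
        with np.load(path) as npz:
            E_angle = npz["E_angle"]
            E_rw = npz["E_rw"] if "E_rw" in npz.files else None
    except (OSError, KeyError, zipfile.BadZipFile) as exc:
        raise MatrixError(f"cannot load matrix file {path}: {exc}")
    if _digest(E_angle) != header.get("checksum_angle"):
        raise MatrixError(f"{path}: angle tensor checksum failure")
    rw = None
    if E_rw is not None:
        if _digest(E_rw) != header.get("checksum_rw"):
            raise MatrixError(f"{path}: RW tensor checksum failure")
        rw = RWPotential(E=E_rw,
                         kuhn_length=header.get("kuhn_length", 3.8),
                         r_cut_ref=header.get("r_cut_ref", R_MAX))
    return Potential(angle=AnglePotential(E=E_angle), rw=rw, header=header)
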