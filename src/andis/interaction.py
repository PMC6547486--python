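"""Pair enumeration and effective-interaction shielding weights.

Only atom pairs separated by at least 7 residues in sequence and closer
than 15 A in space enter the potential.  A pair's interaction can further
be down-weighted when a third heavy atom x geometrically shields it: for
every x within 7 A of both endpoints, the shielding angle alpha = angle
a-x-b is computed, and each x with alpha > 60 deg contributes a factor
(180 - alpha)/180 to the pair weight, provided x is at least 2 residues
from both endpoints and at least 7 residues from one of them.  A pair with
no qualifying shielder is fully effective (weight 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (R_MAX, angle_bin, distance_bin, frame_arrays,
                       pair_angles_batch)

__all__ = [
    "MIN_SEPARATION",
    "SHIELD_RADIUS",
    "SHIELD_ANGLE_DEG",
    "AtomPair",
    "PairTable",
    "chain_pair_table",
    "enumerate_pairs",
    "shielding_weight",
]

MIN_SEPARATION = 7      # residues
SHIELD_RADIUS = 7.0     # A, shielder must be this close to both endpoints
SHIELD_ANGLE_DEG = 60.0  # alpha <= 60 deg leaves the pair fully effective


@dataclass
class AtomPair:
    """One enumerated unordered pair (m < n) with its geometry."""

    m: int
    n: int
    type_a: int
    type_b: int
    sep: int
    geometry: "PairGeometry"
    weight: float = 1.0


@dataclass
class PairTable:
    """Vectorized pair list for one chain.

    All arrays are aligned; ``bins`` stacks the five angle-bin rows in the
    order (theta_a, theta_b, phi_a, phi_b, chi).  ``n_skipped_atoms`` counts
    atoms whose local frame was unavailable (their pairs are dropped).
    """

    m: np.ndarray
    n: np.ndarray
    type_a: np.ndarray
    type_b: np.ndarray
    sep: np.ndarray
    r: np.ndarray
    dist_bin: np.ndarray
    bins: np.ndarray           # (5, P) int
    weight: np.ndarray         # (P,) float, 1.0 unless weights computed
    n_skipped_atoms: int = 0

    def __len__(self) -> int:
        return len(self.m)


def _candidate_pairs(coords, res_idx, r_max):
    """Index pairs (m < n) with separation >= 7 and distance < r_max."""
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r_max, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty(0, int), np.empty(0, int)
    m, n = pairs[:, 0], pairs[:, 1]
    d = np.linalg.norm(coords[m] - coords[n], axis=1)
    keep = (np.abs(res_idx[m] - res_idx[n]) >= MIN_SEPARATION) & (d < r_max)
    return m[keep], n[keep]


def chain_pair_table(chain, r_max: float = R_MAX, table=None,
                     with_weights: bool = False) -> PairTable:
    """Enumerate and geometrize all scoring-relevant pairs of a chain."""
    atoms = list(chain.atoms())
    if not atoms:
        return _empty_table()
    coords = np.array([a.coords for a in atoms])
    res_idx = np.array([a.residue_index for a in atoms])
    types = np.array([a.type_index for a in atoms])
    origins, rotations, valid = frame_arrays(chain, table)

    m, n = _candidate_pairs(coords, res_idx, r_max)
    keep = valid[m] & valid[n]
    m, n = m[keep], n[keep]
    if len(m) == 0:
        return _empty_table(n_skipped=int((~valid).sum()))

    r, ta, tb, pa, pb, chi = pair_angles_batch(origins, rotations, m, n)
    bins = np.stack([
        angle_bin(ta, "polar"),
        angle_bin(tb, "polar"),
        angle_bin(pa, "azimuth"),
        angle_bin(pb, "azimuth"),
        angle_bin(chi, "azimuth"),
    ])
    weight = np.ones(len(m))
    if with_weights:
        weight = _shielding_weights(coords, res_idx, m, n)
    return PairTable(
        m=m, n=n, type_a=types[m], type_b=types[n],
        sep=np.abs(res_idx[m] - res_idx[n]), r=r,
        dist_bin=distance_bin(r), bins=bins, weight=weight,
        n_skipped_atoms=int((~valid).sum()))


def _empty_table(n_skipped: int = 0) -> PairTable:
    z = np.empty(0, int)
    return PairTable(m=z, n=z, type_a=z, type_b=z, sep=z,
                     r=np.empty(0), dist_bin=z,
                     bins=np.empty((5, 0), int), weight=np.empty(0),
                     n_skipped_atoms=n_skipped)


def _shielding_weights(coords, res_idx, m, n) -> np.ndarray:
    """Weights for pairs (m, n): product over qualifying shielders of
    (180 - alpha)/180."""
    tree = cKDTree(coords)
    neigh = tree.query_ball_point(coords, SHIELD_RADIUS)
    neigh_sets = [set(ix) for ix in neigh]

    pair_ids: list[int] = []
    shielders: list[int] = []
    for p in range(len(m)):
        mi, ni = int(m[p]), int(n[p])
        cand = sorted(neigh_sets[mi] & neigh_sets[ni])
        for x in cand:
            if x == mi or x == ni:
                continue
            sep_a = abs(res_idx[x] - res_idx[mi])
            sep_b = abs(res_idx[x] - res_idx[ni])
            if sep_a < 2 or sep_b < 2 or max(sep_a, sep_b) < MIN_SEPARATION:
                continue
            pair_ids.append(p)
            shielders.append(x)
    weights = np.ones(len(m))
    if not pair_ids:
        return weights
    pid = np.array(pair_ids)
    x = np.array(shielders)
    va = coords[m[pid]] - coords[x]
    vb = coords[n[pid]] - coords[x]
    da = np.linalg.norm(va, axis=1)
    db = np.linalg.norm(vb, axis=1)
    # query_ball_point is inclusive at the radius; the rule is strict <
    strict = (da < SHIELD_RADIUS) & (db < SHIELD_RADIUS)
    cosa = np.einsum("pi,pi->p", va, vb) / (da * db)
    alpha = np.degrees(np.arccos(np.clip(cosa, -1.0, 1.0)))
    qual = strict & (alpha > SHIELD_ANGLE_DEG)
    factors = (180.0 - alpha[qual]) / 180.0
    np.multiply.at(weights, pid[qual], factors)
    return weights


def enumerate_pairs(chain, r_max: float = R_MAX, table=None,
                    with_weights: bool = False):
    """Yield every qualifying unordered pair of a chain as an AtomPair.

    Thin object view over :func:`chain_pair_table`; the geometry of each
    pair is materialized lazily from the vectorized table.
    """
    from .geometry import PairGeometry
    t = chain_pair_table(chain, r_max=r_max, table=table,
                         with_weights=with_weights)
    # re-derive full float angles for the object API
    atoms = list(chain.atoms())
    coords = np.array([a.coords for a in atoms]) if atoms else np.empty((0, 3))
    origins, rotations, _ = frame_arrays(chain, table) if atoms else (
        None, None, None)
    if len(t) == 0:
        return
    r, ta, tb, pa, pb, chi = pair_angles_batch(origins, rotations, t.m, t.n)
    for p in range(len(t)):
        geom = PairGeometry(
            r=float(r[p]), theta_a=float(ta[p]), theta_b=float(tb[p]),
            phi_a=float(pa[p]), phi_b=float(pb[p]), chi=float(chi[p]),
            dist_bin=int(t.dist_bin[p]),
            angle_bins=tuple(int(b) for b in t.bins[:, p]))
        yield AtomPair(m=int(t.m[p]), n=int(t.n[p]),
                       type_a=int(t.type_a[p]), type_b=int(t.type_b[p]),
                       sep=int(t.sep[p]), geometry=geom,
                       weight=float(t.weight[p]))


def shielding_weight(chain, pair: AtomPair) -> float:
    """Effective-interaction weight of one enumerated pair."""
    atoms = list(chain.atoms())
    coords = np.array([a.coords for a in atoms])
    res_idx = np.array([a.residue_index for a in atoms])
    w = _shielding_weights(coords, res_idx,
                           np.array([pair.m]), np.array([pair.n]))
    return float(w[0])
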