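"""Local atomic coordinate frames and the five orientation angles.

Every heavy atom gets a right-handed orthonormal frame built from its first
two available bonded-neighbor candidates: with u = neighbor1 - atom and
v = neighbor2 - atom, Vx = u/|u|, Vz = (u x v)/|u x v|, Vy = Vz x Vx.  The
relative orientation of an ordered atom pair (a, b) is then described by

* theta_a, phi_a — polar/azimuthal angles of r_ab in frame a,
* theta_b, phi_b — polar/azimuthal angles of r_ba in frame b,
* chi — dihedral between the plane (r_ab, Vz(a)) and the plane
  (Vz(b), r_ba) about the r_ab axis,

all in degrees.  The pair distance is discretized into 29 bins (one wide
bin up to 2.2 A, 0.4-A bins to 7.0 A, 0.5-A bins to 15.0 A); polar angles
into 12 bins of 15 deg, azimuths and the dihedral into 12 bins of 30 deg.
Any fixed orthonormal convention is self-consistent as long as derivation
and scoring share it; matrices produced here are therefore not
interchangeable with other implementations of orientation potentials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "R_MAX",
    "N_DIST_BINS",
    "N_ANGLE_BINS",
    "DIST_EDGES",
    "LocalFrame",
    "PairGeometry",
    "FrameError",
    "build_local_frame",
    "frame_arrays",
    "pair_geometry",
    "pair_angles_batch",
    "distance_bin",
    "angle_bin",
    "frame_from_angles",
]

R_MAX = 15.0
N_DIST_BINS = 29
N_ANGLE_BINS = 12

#: 30 edges of the 29 half-open distance bins [lo, hi).
DIST_EDGES = np.concatenate([
    [0.0],
    np.arange(2.2, 7.0 + 1e-9, 0.4),   # 2.2, 2.6, ..., 7.0
    np.arange(7.5, 15.0 + 1e-9, 0.5),  # 7.5, ..., 15.0
])
assert DIST_EDGES.shape == (30,)

_COLLINEAR_TOL = 1e-8


class FrameError(ValueError):
    """Local frame unavailable (missing neighbor or collinear geometry)."""


@dataclass(frozen=True)
class LocalFrame:
    """Right-handed orthonormal frame anchored at an atom."""

    origin: np.ndarray
    Vx: np.ndarray
    Vy: np.ndarray
    Vz: np.ndarray

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix with rows Vx, Vy, Vz (world -> local)."""
        return np.stack([self.Vx, self.Vy, self.Vz])


@dataclass(frozen=True)
class PairGeometry:
    """Distance, five angles (degrees) and bin indices for an ordered pair."""

    r: float
    theta_a: float
    theta_b: float
    phi_a: float
    phi_b: float
    chi: float
    dist_bin: int
    angle_bins: tuple[int, int, int, int, int]

    @property
    def angles(self) -> tuple[float, float, float, float, float]:
        return (self.theta_a, self.theta_b, self.phi_a, self.phi_b, self.chi)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _COLLINEAR_TOL:
        raise FrameError("zero-length frame vector")
    return v / n


def frame_from_points(origin, p1, p2) -> LocalFrame:
    """Frame from an atom position and its two neighbor positions."""
    origin = np.asarray(origin, float)
    u = np.asarray(p1, float) - origin
    v = np.asarray(p2, float) - origin
    w = np.cross(u, v)
    if np.linalg.norm(w) < _COLLINEAR_TOL * max(np.linalg.norm(u), 1.0):
        raise FrameError("collinear frame neighbors")
    Vx = _unit(u)
    Vz = _unit(w)
    Vy = np.cross(Vz, Vx)
    return LocalFrame(origin=origin, Vx=Vx, Vy=Vy, Vz=Vz)


def _neighbor_coords(chain, residue, atom, table):
    """Positions of the first two available frame-neighbor candidates."""
    found = []
    for cand in table.neighbors_of[(atom.residue_name, atom.atom_name)]:
        if cand == "-C":
            if residue.index >= 2:
                prev = chain.residues[residue.index - 2]
                rec = prev.atom("C")
                if rec is not None:
                    found.append(rec.coords)
        elif cand == "+N":
            if residue.index < chain.length:
                nxt = chain.residues[residue.index]
                rec = nxt.atom("N")
                if rec is not None:
                    found.append(rec.coords)
        else:
            rec = residue.atom(cand)
            if rec is not None:
                found.append(rec.coords)
        if len(found) == 2:
            return found
    raise FrameError(
        f"{atom.residue_name}{residue.index}:{atom.atom_name} has fewer "
        "than two frame neighbors present")


def build_local_frame(chain, atom, table=None) -> LocalFrame:
    """Local frame of one atom in a chain (per the connectivity table)."""
    from .topology import default_table
    table = table or default_table()
    residue = chain.residues[atom.residue_index - 1]
    p1, p2 = _neighbor_coords(chain, residue, atom, table)
    return frame_from_points(atom.coords, p1, p2)


def frame_arrays(chain, table=None):
    """Frames for every atom of a chain, as arrays.

    Returns
    -------
    origins : (N, 3) float array of atom coordinates.
    rotations : (N, 3, 3) array; row k of ``rotations[i]`` is the k-th
        basis vector (Vx, Vy, Vz) of atom i's frame.
    valid : (N,) bool mask; False where the frame is unavailable
        (missing neighbors or collinear geometry).
    """
    from .topology import default_table
    table = table or default_table()
    atoms = list(chain.atoms())
    n = len(atoms)
    origins = np.empty((n, 3))
    rotations = np.zeros((n, 3, 3))
    valid = np.zeros(n, dtype=bool)
    for i, atom in enumerate(atoms):
        origins[i] = atom.coords
        try:
            fr = build_local_frame(chain, atom, table)
        except FrameError:
            continue
        rotations[i] = fr.rotation
        valid[i] = True
    return origins, rotations, valid


def distance_bin(r) -> int | np.ndarray:
    """Index of the distance bin containing ``r`` (scalar or array)."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0) or np.any(r_arr >= R_MAX):
        raise ValueError(f"distance out of range [0, {R_MAX}): {r}")
    bins = np.searchsorted(DIST_EDGES, r_arr, side="right") - 1
    return int(bins) if np.isscalar(r) else bins


def angle_bin(angle, kind: str = "polar") -> int | np.ndarray:
    """Angle bin 0..11; polar bins are 15 deg, azimuth/dihedral 30 deg.

    The closed upper boundary (polar 180 deg) maps to bin 11.
    """
    a = np.asarray(angle, dtype=float)
    if kind == "polar":
        if np.any(a < 0) or np.any(a > 180.0):
            raise ValueError(f"polar angle out of [0, 180]: {angle}")
        width, top = 15.0, 180.0
    else:
        if np.any(a < 0) or np.any(a >= 360.0):
            raise ValueError(f"azimuth/dihedral out of [0, 360): {angle}")
        width, top = 30.0, 360.0
    bins = np.minimum((a / width).astype(int), N_ANGLE_BINS - 1)
    bins = np.where(a >= top, N_ANGLE_BINS - 1, bins)
    return int(bins) if np.isscalar(angle) else bins


def pair_angles_batch(origins, rotations, m, n):
    """Five angles (degrees) for ordered atom pairs, vectorized.

    Parameters
    ----------
    origins, rotations : per-atom frame arrays from :func:`frame_arrays`.
    m, n : integer index arrays of equal length; the pair is ordered m -> n.

    Returns
    -------
    r : distances; theta_a, theta_b in [0, 180]; phi_a, phi_b, chi in
        [0, 360) — each an array aligned with ``m``.
    """
    d = origins[n] - origins[m]
    r = np.linalg.norm(d, axis=1)
    if np.any(r <= 0):
        raise ValueError("degenerate pair: zero distance")
    rhat = d / r[:, None]

    # coordinates of r_ab in frame a and of r_ba in frame b
    la = np.einsum("pij,pj->pi", rotations[m], rhat)
    lb = np.einsum("pij,pj->pi", rotations[n], -rhat)
    theta_a = np.degrees(np.arccos(np.clip(la[:, 2], -1.0, 1.0)))
    theta_b = np.degrees(np.arccos(np.clip(lb[:, 2], -1.0, 1.0)))
    phi_a = np.degrees(np.arctan2(la[:, 1], la[:, 0])) % 360.0
    phi_b = np.degrees(np.arctan2(lb[:, 1], lb[:, 0])) % 360.0

    # dihedral between plane(r_ab, Vz(a)) and plane(Vz(b), r_ba) about r_ab
    vza = rotations[m][:, 2, :]
    vzb = rotations[n][:, 2, :]
    n1 = np.cross(rhat, vza)
    n2 = np.cross(vzb, -rhat)
    x = np.einsum("pi,pi->p", n1, n2)
    y = np.einsum("pi,pi->p", np.cross(n1, n2), rhat)
    chi = np.degrees(np.arctan2(y, x)) % 360.0
    return r, theta_a, theta_b, phi_a, phi_b, chi


def pair_geometry(frame_a: LocalFrame, frame_b: LocalFrame) -> PairGeometry:
    """Distance, angles and bins for one ordered pair of frames."""
    origins = np.stack([frame_a.origin, frame_b.origin])
    rotations = np.stack([frame_a.rotation, frame_b.rotation])
    d = np.linalg.norm(frame_b.origin - frame_a.origin)
    if d <= 0:
        raise ValueError("degenerate pair: zero distance")
    if d >= R_MAX:
        raise ValueError(f"pair distance {d:.2f} A >= {R_MAX} A")
    r, ta, tb, pa, pb, chi = pair_angles_batch(
        origins, rotations, np.array([0]), np.array([1]))
    bins = (int(angle_bin(float(ta[0]), "polar")),
            int(angle_bin(float(tb[0]), "polar")),
            int(angle_bin(float(pa[0]), "azimuth")),
            int(angle_bin(float(pb[0]), "azimuth")),
            int(angle_bin(float(chi[0]), "azimuth")))
    return PairGeometry(
        r=float(r[0]), theta_a=float(ta[0]), theta_b=float(tb[0]),
        phi_a=float(pa[0]), phi_b=float(pb[0]), chi=float(chi[0]),
        dist_bin=int(distance_bin(float(r[0]))), angle_bins=bins)


def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    k = axis / np.linalg.norm(axis)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return (np.eye(3) + np.sin(angle_rad) * K
            + (1 - np.cos(angle_rad)) * (K @ K))


def frame_from_angles(frame_a: LocalFrame, r: float, theta_a: float,
                      phi_a: float, theta_b: float, phi_b: float,
                      chi: float) -> LocalFrame:
    """Construct a partner frame realizing prescribed pair angles.

    Given frame a, a distance and target values (degrees) for all five
    angles, returns a frame b such that ``pair_geometry(frame_a, frame_b)``
    reproduces them.  Used to build synthetic observations with exact
    geometry and as an inverse-consistency oracle.
    """
    ta, pa = np.radians(theta_a), np.radians(phi_a)
    # direction of r_ab in world coordinates from its local coords in a
    local_dir = np.array([np.sin(ta) * np.cos(pa),
                          np.sin(ta) * np.sin(pa),
                          np.cos(ta)])
    Ra = frame_a.rotation
    rhat = Ra.T @ local_dir
    origin_b = frame_a.origin + r * rhat

    # Build any rotation R0 with R0 @ (-rhat) = s, where s is the local
    # direction of r_ba prescribed by (theta_b, phi_b).
    tb, pb = np.radians(theta_b), np.radians(phi_b)
    s = np.array([np.sin(tb) * np.cos(pb),
                  np.sin(tb) * np.sin(pb),
                  np.cos(tb)])
    t = -rhat
    v = np.cross(t, s)
    c = float(np.dot(t, s))
    if np.linalg.norm(v) < 1e-12:
        R0 = np.eye(3) if c > 0 else _rotation_about(
            _any_perpendicular(t), np.pi)
    else:
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R0 = np.eye(3) + K + K @ K * (1.0 / (1.0 + c))
    # R0 maps world t to world s; frame rows are R0 applied to identity
    # basis expressed so that R0 @ t = s holds in *local* terms: we need
    # rotation matrix Rb (world->local) with Rb @ (-rhat) = s; R0 above is
    # world->world mapping t to s composed with identity local axes.
    Rb = R0

    # remaining freedom: pre-rotation about rhat; solve for chi
    def chi_of(Rb_try):
        fb = LocalFrame(origin=origin_b, Vx=Rb_try[0], Vy=Rb_try[1],
                        Vz=Rb_try[2])
        return pair_geometry(frame_a, fb).chi

    chi0 = chi_of(Rb)
    best, best_err = Rb, None
    for delta in ((chi - chi0) % 360.0, (chi0 - chi) % 360.0):
        Q = _rotation_about(rhat, np.radians(delta))
        Rb_try = Q @ Rb.T  # rotate the basis vectors about the pair axis
        Rb_try = Rb_try.T
        err = (chi_of(Rb_try) - chi) % 360.0
        err = min(err, 360.0 - err)
        if best_err is None or err < best_err:
            best, best_err = Rb_try, err
    Rb = best
    return LocalFrame(origin=origin_b, Vx=Rb[0], Vy=Rb[1], Vz=Rb[2])


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    w = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(w, v)) > 0.9:
        w = np.array([0.0, 1.0, 0.0])
    p = np.cross(v, w)
    return p / np.linalg.norm(p)
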