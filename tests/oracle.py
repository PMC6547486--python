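"""Independent reference implementations used only to cross-check the
package: change-of-basis angle computation, brute-force shielding weights,
and textbook metric formulas.  Nothing here imports the code paths it
verifies."""

import numpy as np


def five_angles(origin_a, basis_a, origin_b, basis_b):
    """(theta_a, theta_b, phi_a, phi_b, chi) in degrees via explicit
    change of basis and the four-point dihedral formula.

    ``basis_*`` are 3x3 matrices with rows (Vx, Vy, Vz).
    """
    d = np.asarray(origin_b, float) - np.asarray(origin_a, float)
    r = np.linalg.norm(d)
    rhat = d / r

    def polar_azimuth(basis, direction):
        x = float(np.dot(direction, basis[0]))
        y = float(np.dot(direction, basis[1]))
        z = float(np.dot(direction, basis[2]))
        theta = np.degrees(np.arccos(np.clip(z, -1.0, 1.0)))
        phi = np.degrees(np.arctan2(y, x)) % 360.0
        return theta, phi

    theta_a, phi_a = polar_azimuth(basis_a, rhat)
    theta_b, phi_b = polar_azimuth(basis_b, -rhat)

    # dihedral Vz(a) -- r_ab -- Vz(b), four-point formula
    b0, b1, b2 = np.asarray(basis_a[2]), rhat, np.asarray(basis_b[2])
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    chi = np.degrees(np.arctan2(np.dot(np.cross(b1, v), w),
                                np.dot(v, w))) % 360.0
    return theta_a, theta_b, phi_a, phi_b, chi


def brute_force_weights(coords, res_idx, m_arr, n_arr,
                        radius=7.0, angle_deg=60.0, min_sep=7):
    """O(pairs * atoms) shielding weights by direct triple loop."""
    weights = []
    n_atoms = len(coords)
    for m, n in zip(m_arr, n_arr):
        w = 1.0
        for x in range(n_atoms):
            if x == m or x == n:
                continue
            da = np.linalg.norm(coords[m] - coords[x])
            db = np.linalg.norm(coords[n] - coords[x])
            if not (da < radius and db < radius):
                continue
            sep_a = abs(res_idx[x] - res_idx[m])
            sep_b = abs(res_idx[x] - res_idx[n])
            if sep_a < 2 or sep_b < 2 or max(sep_a, sep_b) < min_sep:
                continue
            va = coords[m] - coords[x]
            vb = coords[n] - coords[x]
            cosa = np.dot(va, vb) / (da * db)
            alpha = np.degrees(np.arccos(np.clip(cosa, -1.0, 1.0)))
            if alpha > angle_deg:
                w *= (180.0 - alpha) / 180.0
        weights.append(w)
    return np.array(weights)


def pearson_textbook(x, y):
    """PCC from the raw definition: covariance over product of sds."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum()
                 / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))


def distance_bin_by_hand(r):
    """Distance bin via explicit piecewise arithmetic."""
    if r < 2.2:
        return 0
    if r < 7.0:
        return 1 + int((r - 2.2) / 0.4)
    return 13 + int((r - 7.0) / 0.5)


def angle_bin_by_hand(value, width):
    return min(int(value / width), 11)
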