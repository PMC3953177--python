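"""Numba kernels for the hot paths: forward kinematics and energy terms.

Each evaluation of the fitness function rebuilds coordinates from
dihedrals and sums pairwise terms; searches spend millions of such
evaluations, so these inner loops are compiled.  The public numpy APIs
in :mod:`chain_model` and :mod:`energy` are thin wrappers around these
kernels — there is exactly one implementation of each formula.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_DEG = np.pi / 180.0


@njit(cache=True, fastmath=False)
def _place(ax, ay, az, bx, by, bz, cx, cy, cz, bond, theta, chi):
    """NeRF atom placement from three reference atoms (angles in radians).

    The placed atom d satisfies |c-d| = bond, angle(b,c,d) = theta and
    dihedral(a,b,c,d) = chi in the IUPAC sign convention.
    """
    bcx, bcy, bcz = cx - bx, cy - by, cz - bz
    inv = 1.0 / np.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx * inv, bcy * inv, bcz * inv
    abx, aby, abz = bx - ax, by - ay, bz - az
    # n = ab x bc (unnormalized), then normalized
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    inv = 1.0 / np.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx * inv, ny * inv, nz * inv
    # m = n x bc
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    d1 = -bond * np.cos(theta)
    d2 = bond * np.sin(theta) * np.cos(chi)
    d3 = bond * np.sin(theta) * np.sin(chi)
    return (cx + d1 * bcx + d2 * mx + d3 * nx,
            cy + d1 * bcy + d2 * my + d3 * ny,
            cz + d1 * bcz + d2 * mz + d3 * nz)


@njit(cache=True)
def fk_batch(angles, geo, is_gly):
    """Forward kinematics for a batch of dihedral states.

    angles : (m, n, 3) degrees; geo : packed geometry (lengths in
    Angstrom, angles already in radians); is_gly : (n,) bool.
    Returns backbone (m, n, 4, 3) ordered N, CA, C, O and cb (m, n, 3)
    with NaN for glycine.
    """
    (b_nca, b_cac, b_cn, b_co, b_cacb,
     a_ncac, a_cacn, a_cnca, a_caco, a_ccacb, imp_cb) = (
        geo[0], geo[1], geo[2], geo[3], geo[4],
        geo[5], geo[6], geo[7], geo[8], geo[9], geo[10])
    m, n, _ = angles.shape
    bb = np.empty((m, n, 4, 3))
    cb = np.full((m, n, 3), np.nan)
    for k in range(m):
        # canonical frame for residue 1
        bb[k, 0, 0, 0] = 0.0
        bb[k, 0, 0, 1] = 0.0
        bb[k, 0, 0, 2] = 0.0
        bb[k, 0, 1, 0] = b_nca
        bb[k, 0, 1, 1] = 0.0
        bb[k, 0, 1, 2] = 0.0
        bb[k, 0, 2, 0] = b_nca - b_cac * np.cos(a_ncac)
        bb[k, 0, 2, 1] = b_cac * np.sin(a_ncac)
        bb[k, 0, 2, 2] = 0.0
        for i in range(1, n):
            pn = bb[k, i - 1, 0]
            pca = bb[k, i - 1, 1]
            pc = bb[k, i - 1, 2]
            # N(i) from psi(i-1)
            x, y, z = _place(pn[0], pn[1], pn[2], pca[0], pca[1], pca[2],
                             pc[0], pc[1], pc[2], b_cn, a_cacn,
                             angles[k, i - 1, 1] * _DEG)
            bb[k, i, 0, 0], bb[k, i, 0, 1], bb[k, i, 0, 2] = x, y, z
            # CA(i) from omega(i)
            x, y, z = _place(pca[0], pca[1], pca[2], pc[0], pc[1], pc[2],
                             bb[k, i, 0, 0], bb[k, i, 0, 1], bb[k, i, 0, 2],
                             b_nca, a_cnca, angles[k, i, 2] * _DEG)
            bb[k, i, 1, 0], bb[k, i, 1, 1], bb[k, i, 1, 2] = x, y, z
            # C(i) from phi(i)
            x, y, z = _place(pc[0], pc[1], pc[2],
                             bb[k, i, 0, 0], bb[k, i, 0, 1], bb[k, i, 0, 2],
                             bb[k, i, 1, 0], bb[k, i, 1, 1], bb[k, i, 1, 2],
                             b_cac, a_ncac, angles[k, i, 0] * _DEG)
            bb[k, i, 2, 0], bb[k, i, 2, 1], bb[k, i, 2, 2] = x, y, z
        # carbonyl O: anti to the next N (chi = psi + 180); the terminal
        # O uses the canonical chi = 0, independent of the inert psi(n)
        for i in range(n):
            chi = (angles[k, i, 1] + 180.0) * _DEG if i < n - 1 else 0.0
            x, y, z = _place(bb[k, i, 0, 0], bb[k, i, 0, 1], bb[k, i, 0, 2],
                             bb[k, i, 1, 0], bb[k, i, 1, 1], bb[k, i, 1, 2],
                             bb[k, i, 2, 0], bb[k, i, 2, 1], bb[k, i, 2, 2],
                             b_co, a_caco, chi)
            bb[k, i, 3, 0], bb[k, i, 3, 1], bb[k, i, 3, 2] = x, y, z
        # CB from the fixed improper dihedral N-C-CA-CB (L-chirality)
        for i in range(n):
            if not is_gly[i]:
                x, y, z = _place(
                    bb[k, i, 0, 0], bb[k, i, 0, 1], bb[k, i, 0, 2],
                    bb[k, i, 2, 0], bb[k, i, 2, 1], bb[k, i, 2, 2],
                    bb[k, i, 1, 0], bb[k, i, 1, 1], bb[k, i, 1, 2],
                    b_cacb, a_ccacb, imp_cb)
                cb[k, i, 0], cb[k, i, 1], cb[k, i, 2] = x, y, z
    return bb, cb


@njit(cache=True)
def lj_kernel(pos, resi, rmin_half, eps, min_sep, cap_fraction):
    """Soft-core 12-6 Lennard-Jones over atom pairs with residue
    separation >= min_sep (see energy module for the form)."""
    na = pos.shape[0]
    total = 0.0
    for i in range(na):
        for j in range(i + 1, na):
            if abs(resi[i] - resi[j]) < min_sep:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            rmin = rmin_half[i] + rmin_half[j]
            e = np.sqrt(eps[i] * eps[j])
            rc = cap_fraction * rmin
            r_eff = r if r > rc else rc
            x2 = (rmin / r_eff) ** 2
            x6 = x2 * x2 * x2
            val = e * (x6 * x6 - 2.0 * x6)
            if r < rc:
                xc2 = (rmin / rc) ** 2
                xc6 = xc2 * xc2 * xc2
                slope = e * (-12.0 * xc6 * xc6 + 12.0 * xc6) / rc
                val += slope * (r - rc)
            total += val
    return total


@njit(cache=True)
def hbond_kernel(n_xyz, o_xyz, c_xyz, min_sep, d0, tol, sigma, weight):
    """Backbone N...O=C hydrogen-bond reward (<= 0): unit-peak Gaussian
    in the N...O distance times cos^2 of the C=O...N angle, gated to
    angles beyond 90 degrees."""
    n = n_xyz.shape[0]
    total = 0.0
    for i in range(n):          # donor N(i)
        for j in range(n):      # acceptor O(j)
            if abs(i - j) < min_sep:
                continue
            dx = n_xyz[i, 0] - o_xyz[j, 0]
            dy = n_xyz[i, 1] - o_xyz[j, 1]
            dz = n_xyz[i, 2] - o_xyz[j, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if abs(d - d0) > tol:
                continue
            g = np.exp(-((d - d0) ** 2) / (2.0 * sigma * sigma))
            v1x = c_xyz[j, 0] - o_xyz[j, 0]
            v1y = c_xyz[j, 1] - o_xyz[j, 1]
            v1z = c_xyz[j, 2] - o_xyz[j, 2]
            dot = v1x * dx + v1y * dy + v1z * dz
            n1 = np.sqrt(v1x * v1x + v1y * v1y + v1z * v1z)
            cosang = dot / (n1 * d)
            if cosang < 0.0:
                total -= weight * g * cosang * cosang
    return total


@njit(cache=True)
def contact_count_kernel(centers, min_sep, radius):
    """Per-residue count of side-chain centers within the shell radius at
    sequence separation >= min_sep."""
    n = centers.shape[0]
    counts = np.zeros(n, dtype=np.int64)
    r2 = radius * radius
    for i in range(n):
        for j in range(n):
            if abs(i - j) < min_sep:
                continue
            dx = centers[i, 0] - centers[j, 0]
            dy = centers[i, 1] - centers[j, 1]
            dz = centers[i, 2] - centers[j, 2]
            if dx * dx + dy * dy + dz * dz <= r2:
                counts[i] += 1
    return counts


@njit(cache=True)
def water_kernel(centers, hydro, min_sep, inner, outer, taper,
                 w_hh, w_hp, w_pp):
    """Class-weighted water-mediated pair term with a cosine-tapered
    switching function equal to 1 on [inner, outer]."""
    n = centers.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if j - i < min_sep:
                continue
            dx = centers[i, 0] - centers[j, 0]
            dy = centers[i, 1] - centers[j, 1]
            dz = centers[i, 2] - centers[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r <= inner - taper or r >= outer + taper:
                continue
            if inner <= r <= outer:
                s = 1.0
            elif r < inner:
                s = 0.5 * (1.0 + np.cos(np.pi * (inner - r) / taper))
            else:
                s = 0.5 * (1.0 + np.cos(np.pi * (r - outer) / taper))
            nh = hydro[i] + hydro[j]
            w = w_hh if nh == 2 else (w_hp if nh == 1 else w_pp)
            total += w * s
    return total
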