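"""Compiled inner loops for the elastic element force assembly.

A numba-jitted scalar kernel evaluates, per element, the CEHS step-parameter
energy and its central-difference gradients in the six relative-pose
coordinates.  If numba is unavailable the caller falls back to the
vectorized numpy path in :mod:`dnadyn.mechanics`; results agree to
finite-difference roundoff.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


_DEG = 180.0 / np.pi


@njit(cache=True, fastmath=False)
def _step_energy_one(r, d, q0, kmat):
    """Energy of one element from relative rotation r (3x3) and displacement d.

    Returns (energy, status); status 1 flags the antiparallel degeneracy.
    """
    cosg = r[2, 2]
    if cosg > 1.0:
        cosg = 1.0
    elif cosg < -1.0:
        cosg = -1.0
    if cosg < -0.999999:
        return 0.0, 1

    hx = -r[1, 2]
    hy = r[0, 2]
    hn = np.sqrt(hx * hx + hy * hy)
    gamma = np.arctan2(hn, cosg)  # stable for small bends
    if hn < 1e-12:
        hx, hy = 1.0, 0.0
    else:
        hx /= hn
        hy /= hn

    ch = np.cos(0.5 * gamma)
    sh = np.sin(0.5 * gamma)
    omc = 1.0 - ch

    xa0 = ch + hx * hx * omc
    xa1 = hy * hx * omc
    xa2 = -hy * sh
    zm0 = hy * sh
    zm1 = -hx * sh
    zm2 = ch

    # x_b = R(hinge, -gamma/2) applied to r[:,0]
    v0, v1, v2 = r[0, 0], r[1, 0], r[2, 0]
    cx0 = hy * v2
    cx1 = -hx * v2
    cx2 = hx * v1 - hy * v0
    hv = hx * v0 + hy * v1
    xb0 = v0 * ch - cx0 * sh + hx * hv * omc
    xb1 = v1 * ch - cx1 * sh + hy * hv * omc
    xb2 = v2 * ch - cx2 * sh

    # twist about z_m
    cr0 = xa1 * xb2 - xa2 * xb1
    cr1 = xa2 * xb0 - xa0 * xb2
    cr2 = xa0 * xb1 - xa1 * xb0
    sin_tw = cr0 * zm0 + cr1 * zm1 + cr2 * zm2
    cos_tw = xa0 * xb0 + xa1 * xb1 + xa2 * xb2
    twist = np.arctan2(sin_tw, cos_tw)

    xm0 = xa0 + xb0
    xm1 = xa1 + xb1
    xm2 = xa2 + xb2
    xn = np.sqrt(xm0 * xm0 + xm1 * xm1 + xm2 * xm2)
    if xn < 1e-6:  # twist at 180 degrees: bisector degenerate
        return 0.0, 1
    xm0 /= xn
    xm1 /= xn
    xm2 /= xn
    ym0 = zm1 * xm2 - zm2 * xm1
    ym1 = zm2 * xm0 - zm0 * xm2
    ym2 = zm0 * xm1 - zm1 * xm0

    q = np.empty(6)
    q[0] = d[0] * xm0 + d[1] * xm1 + d[2] * xm2
    q[1] = d[0] * ym0 + d[1] * ym1 + d[2] * ym2
    q[2] = d[0] * zm0 + d[1] * zm1 + d[2] * zm2
    q[3] = gamma * (hx * xm0 + hy * xm1) * _DEG
    q[4] = gamma * (hx * ym0 + hy * ym1) * _DEG
    q[5] = twist * _DEG

    e = 0.0
    dq = np.empty(6)
    for i in range(6):
        v = q[i] - q0[i]
        if i >= 3:
            v -= 360.0 * np.floor((v + 180.0) / 360.0)
            v *= np.pi / 180.0
        dq[i] = v
    for i in range(6):
        acc = 0.0
        for j in range(6):
            acc += kmat[i, j] * dq[j]
        e += 0.5 * dq[i] * acc
    return e, 0


@njit(cache=True, fastmath=False)
def element_energy_gradients(r_rel, d_loc, q0, kmat, rot_p, rot_m, h):
    """Energies plus central-difference gradients for all elements.

    ``rot_p``/``rot_m`` are the three precomputed +-h axis rotations (3,3,3).
    Returns (e0, g_d, g_psi, status).
    """
    m = r_rel.shape[0]
    e0 = np.empty(m)
    g_d = np.empty((m, 3))
    g_psi = np.empty((m, 3))
    status = 0
    dp = np.empty(3)
    rp = np.empty((3, 3))
    for e in range(m):
        r = r_rel[e]
        d = d_loc[e]
        q = q0[e]
        k = kmat[e]
        val, st = _step_energy_one(r, d, q, k)
        if st != 0:
            status = 1
        e0[e] = val
        for axis in range(3):
            for i in range(3):
                dp[i] = d[i]
            dp[axis] = d[axis] + h
            ep, st = _step_energy_one(r, dp, q, k)
            status |= st
            dp[axis] = d[axis] - h
            em, st = _step_energy_one(r, dp, q, k)
            status |= st
            g_d[e, axis] = (ep - em) / (2.0 * h)
        for axis in range(3):
            for i in range(3):
                for j in range(3):
                    acc = 0.0
                    for l in range(3):
                        acc += rot_p[axis, i, l] * r[l, j]
                    rp[i, j] = acc
            ep, st = _step_energy_one(rp, d, q, k)
            status |= st
            for i in range(3):
                for j in range(3):
                    acc = 0.0
                    for l in range(3):
                        acc += rot_m[axis, i, l] * r[l, j]
                    rp[i, j] = acc
            em, st = _step_energy_one(rp, d, q, k)
            status |= st
            g_psi[e, axis] = (ep - em) / (2.0 * h)
    return e0, g_d, g_psi, status


@njit(cache=True, fastmath=False)
def screened_coulomb(positions, pairs, charges, scale, kappa, cutoff):
    """Debye-Hueckel pair forces; returns (force (n,3), energy, status).

    ``charges`` is the per-node effective charge (units of e) and ``scale``
    the Bjerrum-length energy factor l_B * kBT.  status 1 flags an
    overlapping pair (r < 0.1 nm).
    """
    n = positions.shape[0]
    force = np.zeros((n, 3))
    energy = 0.0
    status = 0
    for k in range(pairs.shape[0]):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dx = positions[j, 0] - positions[i, 0]
        dy = positions[j, 1] - positions[i, 1]
        dz = positions[j, 2] - positions[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        if r < 0.1:
            status = 1
            continue
        if r >= cutoff:
            continue
        e = scale * charges[i] * charges[j] * np.exp(-kappa * r) / r
        energy += e
        fmag = e * (kappa + 1.0 / r) / r
        force[j, 0] += fmag * dx
        force[j, 1] += fmag * dy
        force[j, 2] += fmag * dz
        force[i, 0] -= fmag * dx
        force[i, 1] -= fmag * dy
        force[i, 2] -= fmag * dz
    return force, energy, status


@njit(cache=True, fastmath=False)
def element_energies(r_rel, d_loc, q0, kmat):
    """Energies only (no gradients) for all elements."""
    m = r_rel.shape[0]
    e0 = np.empty(m)
    status = 0
    for e in range(m):
        val, st = _step_energy_one(r_rel[e], d_loc[e], q0[e], kmat[e])
        status |= st
        e0[e] = val
    return e0, status
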