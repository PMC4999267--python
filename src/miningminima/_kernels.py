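"""Compiled inner loops for the toy force field.

The systems are tiny (tens of atoms), so for the millions of energy and
gradient calls made by the conformational search the per-call overhead of
vectorized numpy dominates; these scalar loops compiled with numba evaluate
the same terms at a fraction of the cost.  Results are identical to the
reference numpy path (same formulas, same summation order per term class).
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def energy_and_gradient(x, b_idx, b_k, b_r0, a_idx, a_k, a_t0,
                        t_idx, t_v, t_n, t_g, nb_idx, nb_eps, nb_rmin,
                        nb_qq, kq):
    """Returns (e_bond, e_angle, e_torsion, e_vdw, e_coul, grad)."""
    n = x.shape[0]
    grad = np.zeros((n, 3))
    e_bond = 0.0
    for m in range(b_idx.shape[0]):
        i = b_idx[m, 0]
        j = b_idx[m, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - b_r0[m]
        e_bond += 0.5 * b_k[m] * dr * dr
        c = b_k[m] * dr / r
        grad[i, 0] += c * dx
        grad[i, 1] += c * dy
        grad[i, 2] += c * dz
        grad[j, 0] -= c * dx
        grad[j, 1] -= c * dy
        grad[j, 2] -= c * dz
    e_angle = 0.0
    for m in range(a_idx.shape[0]):
        i = a_idx[m, 0]
        j = a_idx[m, 1]
        k = a_idx[m, 2]
        u = x[i] - x[j]
        v = x[k] - x[j]
        nu = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
        nv = np.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
        cth = (u[0] * v[0] + u[1] * v[1] + u[2] * v[2]) / (nu * nv)
        if cth > 1.0:
            cth = 1.0
        elif cth < -1.0:
            cth = -1.0
        th = np.arccos(cth)
        s2 = 1.0 - cth * cth
        if s2 < 1e-16:
            s2 = 1e-16
        s = np.sqrt(s2)
        dU = a_k[m] * (th - a_t0[m])
        e_angle += 0.5 * a_k[m] * (th - a_t0[m]) ** 2
        for d in range(3):
            gi = -(v[d] / (nu * nv) - cth * u[d] / (nu * nu)) / s
            gk = -(u[d] / (nu * nv) - cth * v[d] / (nv * nv)) / s
            grad[i, d] += dU * gi
            grad[k, d] += dU * gk
            grad[j, d] += dU * (-gi - gk)
    e_torsion = 0.0
    for m in range(t_idx.shape[0]):
        i = t_idx[m, 0]
        j = t_idx[m, 1]
        k = t_idx[m, 2]
        l = t_idx[m, 3]
        b1 = x[j] - x[i]
        b2 = x[k] - x[j]
        b3 = x[l] - x[k]
        n1 = np.empty(3)
        n2 = np.empty(3)
        n1[0] = b1[1] * b2[2] - b1[2] * b2[1]
        n1[1] = b1[2] * b2[0] - b1[0] * b2[2]
        n1[2] = b1[0] * b2[1] - b1[1] * b2[0]
        n2[0] = b2[1] * b3[2] - b2[2] * b3[1]
        n2[1] = b2[2] * b3[0] - b2[0] * b3[2]
        n2[2] = b2[0] * b3[1] - b2[1] * b3[0]
        nb2 = np.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
        mx = (n1[1] * b2[2] - n1[2] * b2[1]) / nb2
        my = (n1[2] * b2[0] - n1[0] * b2[2]) / nb2
        mz = (n1[0] * b2[1] - n1[1] * b2[0]) / nb2
        yv = mx * n2[0] + my * n2[1] + mz * n2[2]
        xv = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
        phi = np.arctan2(yv, xv)
        e_torsion += t_v[m] * (1.0 + np.cos(t_n[m] * phi - t_g[m]))
        dU = -t_v[m] * t_n[m] * np.sin(t_n[m] * phi - t_g[m])
        nn1 = n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2
        nn2 = n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2
        p = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / (nb2 * nb2)
        q = (b3[0] * b2[0] + b3[1] * b2[1] + b3[2] * b2[2]) / (nb2 * nb2)
        for d in range(3):
            di = nb2 / nn1 * n1[d]
            dl = -nb2 / nn2 * n2[d]
            dj = -(1.0 + p) * di + q * dl
            dk = p * di - (1.0 + q) * dl
            grad[i, d] += dU * di
            grad[j, d] += dU * dj
            grad[k, d] += dU * dk
            grad[l, d] += dU * dl
    e_vdw = 0.0
    e_coul = 0.0
    for m in range(nb_idx.shape[0]):
        i = nb_idx[m, 0]
        j = nb_idx[m, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        sr6 = (nb_rmin[m] * nb_rmin[m] / r2) ** 3
        e_vdw += nb_eps[m] * (sr6 * sr6 - 2.0 * sr6)
        e_coul += kq * nb_qq[m] / r
        dUdr = -12.0 * nb_eps[m] / r * (sr6 * sr6 - sr6) - kq * nb_qq[m] / r2
        c = dUdr / r
        grad[i, 0] += c * dx
        grad[i, 1] += c * dy
        grad[i, 2] += c * dz
        grad[j, 0] -= c * dx
        grad[j, 1] -= c * dy
        grad[j, 2] -= c * dz
    return e_bond, e_angle, e_torsion, e_vdw, e_coul, grad
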