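"""Hot inner kernels of the flow solver.

The skew-symmetric convection assembly is the only per-step operation that
touches every cell; it is JIT-compiled with numba when available and falls
back to a vectorized numpy implementation otherwise (identical results).
"""

from __future__ import annotations

import numpy as np

try:
    import numba as _nb

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False


def _convection_numpy(u, cells, grads, area, nn):
    ue = u[cells]  # (nc, 3, 2)
    G = np.einsum("njc,njd->ncd", ue, grads)
    adv = np.einsum("njd,ncd->njc", ue, G)
    asum = adv.sum(axis=1, keepdims=True)
    t1 = (area[:, None, None] / 12.0) * (adv + asum)
    S = np.einsum("njd,nid->nij", ue, grads)
    q = (area[:, None, None] / 12.0) * (ue + ue.sum(axis=1, keepdims=True))
    t2 = np.einsum("nij,njc->nic", S, q)
    contrib = 0.5 * (t1 - t2)
    flat = cells.ravel()
    out = np.empty((nn, 2))
    out[:, 0] = np.bincount(flat, weights=contrib[:, :, 0].ravel(), minlength=nn)
    out[:, 1] = np.bincount(flat, weights=contrib[:, :, 1].ravel(), minlength=nn)
    return out


if _HAVE_NUMBA:

    @_nb.njit(fastmath=True)
    def _convection_jit(u, cells, grads, area, nn):  # pragma: no cover
        out = np.zeros((nn, 2))
        nc = cells.shape[0]
        for n in range(nc):
            i0, i1, i2 = cells[n, 0], cells[n, 1], cells[n, 2]
            u0x, u0y = u[i0, 0], u[i0, 1]
            u1x, u1y = u[i1, 0], u[i1, 1]
            u2x, u2y = u[i2, 0], u[i2, 1]
            gxx = u0x * grads[n, 0, 0] + u1x * grads[n, 1, 0] + u2x * grads[n, 2, 0]
            gxy = u0x * grads[n, 0, 1] + u1x * grads[n, 1, 1] + u2x * grads[n, 2, 1]
            gyx = u0y * grads[n, 0, 0] + u1y * grads[n, 1, 0] + u2y * grads[n, 2, 0]
            gyy = u0y * grads[n, 0, 1] + u1y * grads[n, 1, 1] + u2y * grads[n, 2, 1]
            A12 = area[n] / 12.0
            ax0 = u0x * gxx + u0y * gxy
            ax1 = u1x * gxx + u1y * gxy
            ax2 = u2x * gxx + u2y * gxy
            ay0 = u0x * gyx + u0y * gyy
            ay1 = u1x * gyx + u1y * gyy
            ay2 = u2x * gyx + u2y * gyy
            sax = ax0 + ax1 + ax2
            say = ay0 + ay1 + ay2
            sux = u0x + u1x + u2x
            suy = u0y + u1y + u2y
            axv = (ax0, ax1, ax2)
            ayv = (ay0, ay1, ay2)
            for idx in range(3):
                ii = cells[n, idx]
                bix, biy = grads[n, idx, 0], grads[n, idx, 1]
                t1x = A12 * (axv[idx] + sax)
                t1y = A12 * (ayv[idx] + say)
                t2x = 0.0
                t2y = 0.0
                for j in range(3):
                    ujx = u[cells[n, j], 0]
                    ujy = u[cells[n, j], 1]
                    Sij = ujx * bix + ujy * biy
                    t2x += Sij * A12 * (ujx + sux)
                    t2y += Sij * A12 * (ujy + suy)
                out[ii, 0] += 0.5 * (t1x - t2x)
                out[ii, 1] += 0.5 * (t1y - t2y)
        return out

    def convection(u, cells, grads, area, nn):
        return _convection_jit(u, cells, grads, area, nn)

else:
    convection = _convection_numpy
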