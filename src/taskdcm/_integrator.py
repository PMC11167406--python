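"""Compiled batched integrator for the neural + hemodynamic forward model.

The Gauss-Newton inversion evaluates the forward model once per free
parameter per iteration (finite-difference Jacobian), so the integrator is
the pipeline's hot loop.  The numba kernel keeps the batch dimension
innermost and contiguous so the per-batch arithmetic vectorizes; the pure
numpy implementation in `cohort` has identical dynamics and is used when
numba is unavailable.  Integration is fixed-step (Heun's method by
default, explicit Euler optionally) at the microtime resolution.  The
kernel steps the balloon states (s, f, v, q) in natural coordinates with a
positivity floor; the numpy path integrates the same equations in log
coordinates — the two agree to integrator accuracy and any divergent
excursion is caught by the finiteness check downstream.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba present in supported envs
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=False, fastmath=True)
def _kernel(Aeff, B, C, um, ud, dt, stride, n_vol,
            kappa, gamma, alpha, e0, v0, k1, k2, k3,
            tau, eps, heun):  # pragma: no cover - exercised via wrapper
    # layouts: Aeff (n, n, nb); B (k, n, n, nb); C (n, m, nb);
    # states (n, nb); output (n_vol, n, nb)
    n = Aeff.shape[0]
    nb = Aeff.shape[2]
    nk = B.shape[0]
    nm = C.shape[1]
    n_bins = um.shape[0]
    inv_alpha = 1.0 / alpha
    ln1mE0 = np.log(1.0 - e0)
    floor = 1e-8

    z = np.zeros((n, nb))
    s = np.zeros((n, nb))
    f = np.ones((n, nb))
    v = np.ones((n, nb))
    q = np.ones((n, nb))
    d1 = np.empty((5, n, nb))
    d2 = np.empty((5, n, nb))
    zp = np.empty((n, nb))
    sp = np.empty((n, nb))
    fp = np.empty((n, nb))
    vp = np.empty((n, nb))
    qp = np.empty((n, nb))
    out = np.zeros((n_vol, n, nb))
    vol = 1

    for t in range(n_bins - 1):
        for rep in range(2 if heun else 1):
            if rep == 0:
                zz, ss, ff, vv, qq, tt, dd = z, s, f, v, q, t, d1
            else:
                zz, ss, ff, vv, qq, tt, dd = zp, sp, fp, vp, qp, t, d2
            for i in range(n):
                dzi = dd[0, i]
                for b in range(nb):
                    dzi[b] = 0.0
                for j in range(n):
                    a = Aeff[i, j]
                    zj = zz[j]
                    if nk == 1:
                        u0 = um[tt, 0]
                        b0 = B[0, i, j]
                        for b in range(nb):
                            dzi[b] += (a[b] + u0 * b0[b]) * zj[b]
                    else:
                        for b in range(nb):
                            m = a[b]
                            for k in range(nk):
                                m += um[tt, k] * B[k, i, j, b]
                            dzi[b] += m * zj[b]
                for m_ in range(nm):
                    ci = C[i, m_]
                    u = ud[tt, m_]
                    for b in range(nb):
                        dzi[b] += ci[b] * u
                for b in range(nb):
                    fi = ff[i, b]
                    vi = vv[i, b]
                    qi = qq[i, b]
                    dd[1, i, b] = zz[i, b] - kappa * ss[i, b] - gamma * (fi - 1.0)
                    dd[2, i, b] = ss[i, b]
                    fv = vi ** inv_alpha
                    tb = tau[i, b]
                    dd[3, i, b] = (fi - fv) / tb
                    E = 1.0 - np.exp(ln1mE0 / fi)
                    dd[4, i, b] = (fi * E / e0 - fv * qi / vi) / tb
            if rep == 0 and heun:
                for i in range(n):
                    for b in range(nb):
                        zp[i, b] = z[i, b] + dt * d1[0, i, b]
                        sp[i, b] = s[i, b] + dt * d1[1, i, b]
                        fi = f[i, b] + dt * d1[2, i, b]
                        vi = v[i, b] + dt * d1[3, i, b]
                        qi = q[i, b] + dt * d1[4, i, b]
                        fp[i, b] = fi if fi > floor else floor
                        vp[i, b] = vi if vi > floor else floor
                        qp[i, b] = qi if qi > floor else floor
        if heun:
            for i in range(n):
                for b in range(nb):
                    z[i, b] += 0.5 * dt * (d1[0, i, b] + d2[0, i, b])
                    s[i, b] += 0.5 * dt * (d1[1, i, b] + d2[1, i, b])
                    fi = f[i, b] + 0.5 * dt * (d1[2, i, b] + d2[2, i, b])
                    vi = v[i, b] + 0.5 * dt * (d1[3, i, b] + d2[3, i, b])
                    qi = q[i, b] + 0.5 * dt * (d1[4, i, b] + d2[4, i, b])
                    f[i, b] = fi if fi > floor else floor
                    v[i, b] = vi if vi > floor else floor
                    q[i, b] = qi if qi > floor else floor
        else:
            for i in range(n):
                for b in range(nb):
                    z[i, b] += dt * d1[0, i, b]
                    s[i, b] += dt * d1[1, i, b]
                    fi = f[i, b] + dt * d1[2, i, b]
                    vi = v[i, b] + dt * d1[3, i, b]
                    qi = q[i, b] + dt * d1[4, i, b]
                    f[i, b] = fi if fi > floor else floor
                    v[i, b] = vi if vi > floor else floor
                    q[i, b] = qi if qi > floor else floor
        if (t + 1) % stride == 0 and vol < n_vol:
            for i in range(n):
                for b in range(nb):
                    out[vol, i, b] = 100.0 * eps[i, b] * v0 * (
                        k1 * (1.0 - q[i, b])
                        + k2 * (1.0 - q[i, b] / v[i, b])
                        + k3 * (1.0 - v[i, b])
                    )
            vol += 1
    while vol < n_vol:
        for i in range(n):
            for b in range(nb):
                out[vol, i, b] = 100.0 * eps[i, b] * v0 * (
                    k1 * (1.0 - q[i, b])
                    + k2 * (1.0 - q[i, b] / v[i, b])
                    + k3 * (1.0 - v[i, b])
                )
        vol += 1
    return out


def integrate_batched(Aeff, B, C, um, ud, dt, stride, n_vol, hp, tau, eps,
                      method="heun"):
    """Transpose to batch-innermost layout, run the kernel, transpose back.

    Inputs are batch-major: Aeff (nb, n, n), B (nb, k, n, n), C (nb, n, m),
    tau/eps (nb, n).  Returns (nb, n_vol, n).
    """
    out = _kernel(
        np.ascontiguousarray(np.transpose(Aeff, (1, 2, 0)), np.float64),
        np.ascontiguousarray(np.transpose(B, (1, 2, 3, 0)), np.float64),
        np.ascontiguousarray(np.transpose(C, (1, 2, 0)), np.float64),
        np.ascontiguousarray(um, np.float64),
        np.ascontiguousarray(ud, np.float64),
        float(dt), int(stride), int(n_vol),
        float(hp.kappa), float(hp.gamma), float(hp.alpha), float(hp.e0),
        float(hp.v0), float(hp.k1), float(hp.k2), float(hp.k3),
        np.ascontiguousarray(np.transpose(tau), np.float64),
        np.ascontiguousarray(np.transpose(eps), np.float64),
        method == "heun",
    )
    return np.ascontiguousarray(np.transpose(out, (2, 0, 1)))
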