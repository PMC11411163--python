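"""Compiled forward-Euler kernels for the lysis-circuit ODE system.

One kernel covers the core model and its three extensions, selected by
``variant``:

* 0 core          — x, y, p
* 1 substrate     — adds s, Monod factor s/(K_s+s) on growth, substrate uptake
* 2 mutation      — adds adaptive mutation flux mu*x from x to y
* 3 dilution      — chemostat washout d on x and y, inducer a as a state with
                    da/dt = supply - d*a (the ``ahl`` array is the supply rate)

``pp_mode`` selects the positive-part reading of the toxin dilution term:
0 -> max(gamma - alpha, 0) * p (default), 1 -> max(gamma, 0) * p.

States are hard-clamped at zero after each step; the number of clamp events is
returned.  A non-finite state aborts integration and returns the offending
step index.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def euler_run(x0, y0, p0, s0, a0,
              ahl, dt,
              gamma0, rho_s, alpha0, K, n, beta0, k, m, delta,
              mu, r_s, K_s, d,
              variant, pp_mode):
    ns = ahl.shape[0]
    x = np.empty(ns + 1)
    y = np.empty(ns + 1)
    p = np.empty(ns + 1)
    s = np.empty(ns + 1)
    a = np.empty(ns + 1)
    x[0], y[0], p[0], s[0], a[0] = x0, y0, p0, s0, a0
    n_clamped = 0
    bad = -1
    for i in range(ns):
        xv, yv, pv, sv, av = x[i], y[i], p[i], s[i], a[i]
        if variant == 3:
            level = av
        else:
            level = ahl[i]
        if level > 0.0:
            lm = level ** m
            beta = beta0 * lm / (k ** m + lm)
        else:
            beta = 0.0
        gam = gamma0 * (1.0 - (xv + yv) / rho_s)
        if variant == 1:
            gam = gam * sv / (K_s + sv)
        if pv > 0.0:
            pn_ = pv ** n
            alp = alpha0 * pn_ / (K ** n + pn_)
        else:
            alp = 0.0
        if pp_mode == 0:
            dil = gam - alp
        else:
            dil = gam
        if dil < 0.0:
            dil = 0.0

        dx = (gam - alp) * xv
        dy = gam * yv
        dp = beta - dil * pv - delta * pv
        ds = 0.0
        da = 0.0
        if variant == 1:
            ds = -r_s * (xv + yv) * sv / (K_s + sv)
        elif variant == 2:
            dx -= mu * xv
            dy += mu * xv
        elif variant == 3:
            dx -= d * xv
            dy -= d * yv
            da = ahl[i] - d * av

        xn = xv + dt * dx
        yn = yv + dt * dy
        pn = pv + dt * dp
        sn = sv + dt * ds
        an = av + dt * da
        if xn < 0.0:
            xn = 0.0
            n_clamped += 1
        if yn < 0.0:
            yn = 0.0
            n_clamped += 1
        if pn < 0.0:
            pn = 0.0
            n_clamped += 1
        if sn < 0.0:
            sn = 0.0
            n_clamped += 1
        if an < 0.0:
            an = 0.0
            n_clamped += 1
        if not (np.isfinite(xn) and np.isfinite(yn) and np.isfinite(pn)
                and np.isfinite(sn) and np.isfinite(an)):
            bad = i + 1
            x[i + 1], y[i + 1], p[i + 1], s[i + 1], a[i + 1] = xn, yn, pn, sn, an
            break
        x[i + 1], y[i + 1], p[i + 1], s[i + 1], a[i + 1] = xn, yn, pn, sn, an
    return x, y, p, s, a, n_clamped, bad
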