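"""Compiled time-marching kernels for the column solver.

The production integrator advances the semidiscrete system with the two-stage
second-order TVD Runge-Kutta structure applied to the convective and axial
dispersive fluxes, while the stiff part — intraparticle diffusion and film
exchange — is advanced by L-stable backward-Euler stages embedded in the same
two stages.  Per step, with base state ``y^n`` and step ``dt``::

    w1      = y^n + dt * C(y^n)            + dt   * S(w1)
    y^{n+1} = (y^n + w1)/2 + dt/2 * C(w1)  + dt/2 * S(y^{n+1})

``C`` is the explicit transport operator (bulk only), ``S`` the implicit
exchange/diffusion operator.  For ``S = 0`` this is exactly the Heun/TVD-RK2
update; the implicit treatment removes the severe radial-diffusion step
restriction of a fully explicit scheme on fine shell grids.

Each implicit stage solves, independently for every axial cell, a
block-tridiagonal system over the radial cells plus the local bulk unknown
(blocks ``n_comp x n_comp``, dense only on the diagonal through the
accumulation matrix ``eps_p I + dq*/dc``).  The stage equations are the
conservative Newton form in ``eps_p c + q*``; the Jacobian is factored once
per stage and reused by later (modified-)Newton iterations.  All loops put
the axial index innermost so the block algebra vectorizes across the column.

The kernels are strictly sequential and branch-deterministic: repeated runs
are bit-identical.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["march_imex"]


@njit(cache=True, fastmath=True)
def _conv_rhs(cb, pe, dx, order, gamma, inlet, out):
    """Explicit transport operator: -d/dx of (limited advective + dispersive)
    face fluxes.  Inlet face carries the prescribed total (Danckwerts) flux;
    outlet face is zero-gradient (advective, first order)."""
    nc, nx = cb.shape
    for i in range(nc):
        fprev = inlet[i]
        for j in range(1, nx + 1):
            if j == nx:
                f = cb[i, nx - 1]
            else:
                if order == 2 and 2 <= j <= nx - 1:
                    up = cb[i, j - 1] - cb[i, j - 2]
                    loc = cb[i, j] - cb[i, j - 1]
                    r = (up + gamma) / (loc + gamma)
                    phi = 2.0 * r
                    k2 = (1.0 + 2.0 * r) / 3.0
                    if k2 < phi:
                        phi = k2
                    if phi > 2.0:
                        phi = 2.0
                    if phi < 0.0:
                        phi = 0.0
                    f = cb[i, j - 1] + 0.5 * phi * loc
                else:
                    f = cb[i, j - 1]
                f -= (cb[i, j] - cb[i, j - 1]) / (pe[i] * dx)
            out[i, j - 1] = -(f - fprev) / dx
            fprev = f
    return


@njit(cache=True, fastmath=True)
def _isotherm_q_batch(c, a1, a2, b1, b2, s1, s2, q):
    """q*(max(c,0)) for a whole axial row: c, q are (nc, nx)."""
    nc, nx = c.shape
    for u in range(nx):
        s1[u] = 1.0
        s2[u] = 1.0
    for j in range(nc):
        for u in range(nx):
            cj = c[j, u]
            if cj < 0.0:
                cj = 0.0
            s1[u] += b1[j] * cj
            s2[u] += b2[j] * cj
    for i in range(nc):
        for u in range(nx):
            ci = c[i, u]
            if ci < 0.0:
                ci = 0.0
            q[i, u] = a1[i] * ci / s1[u] + a2[i] * ci / s2[u]
    return


@njit(cache=True, fastmath=True)
def _stage_solve(rb, rp, tau, dom, eps_p, a1, a2, b1, b2,
                 d_face, fp, fb, n_newton, zb, zp, counter):
    """One backward-Euler stage of the stiff operator for all axial cells.

    ``rb (nc, nx)`` and ``rp (nr, nc, nx)`` are the stage base values; the
    solution ``z = (c_p, c_b)`` of::

        eps_p (z_v - rp_v) + q*(z_v) - q*(rp_v) = tau (G_{v+1}(z) - G_v(z)) / dOmega
        z_b - rb = -tau * fb * (z_b - z_{nr-1})

    is written to ``zp (nr, nc, nx)`` and ``zb (nc, nx)``.  ``G`` holds the
    radial diffusive fluxes (zero at the core face, film flux at the
    surface).  The block elimination uses no pivoting: the diagonal blocks
    are strictly diagonally dominant (positive accumulation plus positive
    flux coefficients).
    """
    nc, nx = rb.shape
    nr = rp.shape[0]
    r1 = tau / (dom * dom)
    r2 = tau / dom
    na = 2 * nc
    Cp = np.empty((nr, nc, nc, nx))
    Dinv = np.empty((nr + 1, nc, nc, nx))
    dp = np.empty((nr + 1, nc, nx))
    F = np.empty((nr + 1, nc, nx))
    qr = np.empty((nr, nc, nx))
    qz = np.empty((nc, nx))
    s1 = np.empty(nx)
    s2 = np.empty(nx)
    M = np.empty((nc, nc, nx))
    Baug = np.empty((nc, na, nx))
    ffac = np.empty(nx)
    # initial iterate z = r, and q*(r) per radial row
    for v in range(nr):
        _isotherm_q_batch(rp[v], a1, a2, b1, b2, s1, s2, qr[v])
        for i in range(nc):
            for u in range(nx):
                zp[v, i, u] = rp[v, i, u]
    for i in range(nc):
        for u in range(nx):
            zb[i, u] = rb[i, u]
    # negative-concentration accounting (isotherm sees clipped values)
    neg = 0
    for v in range(nr):
        for i in range(nc):
            for u in range(nx):
                if rp[v, i, u] < -1e-10:
                    neg += 1
    counter[0] += neg

    for it in range(n_newton):
        # residual F(z)
        for v in range(nr):
            _isotherm_q_batch(zp[v], a1, a2, b1, b2, s1, s2, qz)
            for i in range(nc):
                dlo = d_face[i, v] / dom
                if v < nr - 1:
                    dhi = d_face[i, v + 1] / dom
                    for u in range(nx):
                        glow = dlo * (zp[v, i, u] - zp[v - 1, i, u]) if v > 0 else 0.0
                        gup = dhi * (zp[v + 1, i, u] - zp[v, i, u])
                        F[v, i, u] = (eps_p * (zp[v, i, u] - rp[v, i, u])
                                      + qz[i, u] - qr[v, i, u] - r2 * (gup - glow))
                else:
                    for u in range(nx):
                        glow = dlo * (zp[v, i, u] - zp[v - 1, i, u]) if v > 0 else 0.0
                        gup = fp[i] * (zb[i, u] - zp[v, i, u])
                        F[v, i, u] = (eps_p * (zp[v, i, u] - rp[v, i, u])
                                      + qz[i, u] - qr[v, i, u] - r2 * (gup - glow))
        for i in range(nc):
            for u in range(nx):
                F[nr, i, u] = (zb[i, u] - rb[i, u]
                               + tau * fb[i] * (zb[i, u] - zp[nr - 1, i, u]))

        if it == 0:
            # assemble and factor the block-tridiagonal Jacobian (at z = r)
            for v in range(nr):
                # diagonal block M = accumulation + flux diagonal - L Cp_{v-1}
                _isotherm_q_batch(zp[v], a1, a2, b1, b2, s1, s2, qz)  # refresh s1, s2
                for i in range(nc):
                    for k in range(nc):
                        for u in range(nx):
                            ci = zp[v, i, u]
                            if ci < 0.0:
                                ci = 0.0
                            val = -ci * (a1[i] * b1[k] / (s1[u] * s1[u])
                                         + a2[i] * b2[k] / (s2[u] * s2[u]))
                            if i == k:
                                val += a1[i] / s1[u] + a2[i] / s2[u] + eps_p
                            M[i, k, u] = val
                for i in range(nc):
                    if v < nr - 1:
                        dd = r1 * (d_face[i, v] + d_face[i, v + 1])
                    else:
                        dd = r1 * d_face[i, v] + r2 * fp[i]
                    for u in range(nx):
                        M[i, i, u] += dd
                if v > 0:
                    for i in range(nc):
                        low = -r1 * d_face[i, v]
                        for k in range(nc):
                            for u in range(nx):
                                M[i, k, u] -= low * Cp[v - 1, i, k, u]
                # augmented right blocks [U_v | I]
                for i in range(nc):
                    uval = -r1 * d_face[i, v + 1] if v < nr - 1 else -r2 * fp[i]
                    for k in range(na):
                        for u in range(nx):
                            Baug[i, k, u] = 0.0
                    for u in range(nx):
                        Baug[i, i, u] = uval
                        Baug[i, nc + i, u] = 1.0
                # no-pivot Gaussian elimination, vectorized over u
                for col in range(nc):
                    for u in range(nx):
                        ffac[u] = 1.0 / M[col, col, u]
                    for row in range(col + 1, nc):
                        for u in range(nx):
                            s1[u] = M[row, col, u] * ffac[u]
                        for k in range(col, nc):
                            for u in range(nx):
                                M[row, k, u] -= s1[u] * M[col, k, u]
                        for k in range(na):
                            for u in range(nx):
                                Baug[row, k, u] -= s1[u] * Baug[col, k, u]
                for col in range(nc - 1, -1, -1):
                    for u in range(nx):
                        ffac[u] = 1.0 / M[col, col, u]
                    for k in range(na):
                        for u in range(nx):
                            s = Baug[col, k, u]
                            for row in range(col + 1, nc):
                                s -= M[col, row, u] * Baug[row, k, u]
                            Baug[col, k, u] = s * ffac[u]
                for i in range(nc):
                    for k in range(nc):
                        for u in range(nx):
                            Cp[v, i, k, u] = Baug[i, k, u]
                            Dinv[v, i, k, u] = Baug[i, nc + k, u]
            # bulk row: diagonal L and D, dense fill-in through Cp[nr-1]
            for i in range(nc):
                low = -tau * fb[i]
                for k in range(nc):
                    for u in range(nx):
                        val = -low * Cp[nr - 1, i, k, u]
                        if i == k:
                            val += 1.0 + tau * fb[i]
                        M[i, k, u] = val
                for k in range(nc):
                    for u in range(nx):
                        Baug[i, k, u] = 1.0 if i == k else 0.0
            for col in range(nc):
                for u in range(nx):
                    ffac[u] = 1.0 / M[col, col, u]
                for row in range(col + 1, nc):
                    for u in range(nx):
                        s1[u] = M[row, col, u] * ffac[u]
                    for k in range(col, nc):
                        for u in range(nx):
                            M[row, k, u] -= s1[u] * M[col, k, u]
                    for k in range(nc):
                        for u in range(nx):
                            Baug[row, k, u] -= s1[u] * Baug[col, k, u]
            for col in range(nc - 1, -1, -1):
                for u in range(nx):
                    ffac[u] = 1.0 / M[col, col, u]
                for k in range(nc):
                    for u in range(nx):
                        s = Baug[col, k, u]
                        for row in range(col + 1, nc):
                            s -= M[col, row, u] * Baug[row, k, u]
                        Baug[col, k, u] = s * ffac[u]
            for i in range(nc):
                for k in range(nc):
                    for u in range(nx):
                        Dinv[nr, i, k, u] = Baug[i, k, u]

        # forward sweep with stored factors: dp_v = Dinv_v (-F_v - L_v dp_{v-1})
        for v in range(nr):
            for i in range(nc):
                if v > 0:
                    low = -r1 * d_face[i, v]
                    for u in range(nx):
                        qz[i, u] = -F[v, i, u] - low * dp[v - 1, i, u]
                else:
                    for u in range(nx):
                        qz[i, u] = -F[v, i, u]
            for i in range(nc):
                for u in range(nx):
                    s = 0.0
                    for k in range(nc):
                        s += Dinv[v, i, k, u] * qz[k, u]
                    dp[v, i, u] = s
        for i in range(nc):
            low = -tau * fb[i]
            for u in range(nx):
                qz[i, u] = -F[nr, i, u] - low * dp[nr - 1, i, u]
        for i in range(nc):
            for u in range(nx):
                s = 0.0
                for k in range(nc):
                    s += Dinv[nr, i, k, u] * qz[k, u]
                dp[nr, i, u] = s
        # back substitution, applying the update immediately
        for i in range(nc):
            for u in range(nx):
                zb[i, u] += dp[nr, i, u]
        for v in range(nr - 1, -1, -1):
            for i in range(nc):
                for u in range(nx):
                    s = dp[v, i, u]
                    for k in range(nc):
                        nxt = dp[nr, k, u] if v == nr - 1 else dp[v + 1, k, u]
                        s -= Cp[v, i, k, u] * nxt
                    dp[v, i, u] = s
            for i in range(nc):
                for u in range(nx):
                    zp[v, i, u] += dp[v, i, u]
    return


@njit(cache=True, fastmath=True)
def march_imex(cb, cp, nsteps, dt, dx, dom, order, gamma, pe, eps_p,
               a1, a2, b1, b2, d_face, fp, fb, inlet_avg, sample_every,
               n_newton, outlet, counter, minval):
    """March ``nsteps`` fixed steps, sampling the outlet every
    ``sample_every`` steps into ``outlet[1:]`` (``outlet[0]`` is the caller's
    initial sample).  ``cb (nc, nx)`` and ``cp (nc, nx, nr)`` are updated in
    place.  Returns -1 on success or the 1-based step index at which
    nonfinite values were detected."""
    nc, nx = cb.shape
    nr = cp.shape[2]
    conv = np.empty((nc, nx))
    rb = np.empty((nc, nx))
    w1b = np.empty((nc, nx))
    cpT = np.empty((nr, nc, nx))
    w1pT = np.empty((nr, nc, nx))
    rp2 = np.empty((nr, nc, nx))
    for i in range(nc):
        for u in range(nx):
            for v in range(nr):
                cpT[v, i, u] = cp[i, u, v]
    isamp = 0
    for n in range(nsteps):
        inlet = inlet_avg[n]
        # stage 1: w1 = y + dt*C(y) + dt*S(w1)
        _conv_rhs(cb, pe, dx, order, gamma, inlet, conv)
        for i in range(nc):
            for u in range(nx):
                rb[i, u] = cb[i, u] + dt * conv[i, u]
        _stage_solve(rb, cpT, dt, dom, eps_p, a1, a2, b1, b2,
                     d_face, fp, fb, n_newton, w1b, w1pT, counter)
        # stage 2: y+ = (y + w1)/2 + dt/2*C(w1) + dt/2*S(y+)
        _conv_rhs(w1b, pe, dx, order, gamma, inlet, conv)
        for i in range(nc):
            for u in range(nx):
                rb[i, u] = 0.5 * (cb[i, u] + w1b[i, u]) + 0.5 * dt * conv[i, u]
        for v in range(nr):
            for i in range(nc):
                for u in range(nx):
                    rp2[v, i, u] = 0.5 * (cpT[v, i, u] + w1pT[v, i, u])
        _stage_solve(rb, rp2, 0.5 * dt, dom, eps_p, a1, a2, b1, b2,
                     d_face, fp, fb, n_newton, cb, cpT, counter)
        if (n + 1) % sample_every == 0:
            isamp += 1
            ok = True
            mn = 0.0
            for i in range(nc):
                val = cb[i, nx - 1]
                outlet[isamp, i] = val
                if not np.isfinite(val):
                    ok = False
                for u in range(nx):
                    if cb[i, u] < mn:
                        mn = cb[i, u]
                    if not np.isfinite(cb[i, u]):
                        ok = False
            for v in range(nr):
                for i in range(nc):
                    for u in range(nx):
                        if cpT[v, i, u] < mn:
                            mn = cpT[v, i, u]
            if mn < minval[0]:
                minval[0] = mn
            if not ok:
                for i in range(nc):
                    for u in range(nx):
                        for v in range(nr):
                            cp[i, u, v] = cpT[v, i, u]
                return n + 1
    for i in range(nc):
        for u in range(nx):
            for v in range(nr):
                cp[i, u, v] = cpT[v, i, u]
    return -1
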