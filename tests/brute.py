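"""Independent brute-force oracles for the finite-volume operators.

Everything here is written as literal loop-by-loop transcriptions of the
discrete formulas (or as generic dense/ODE machinery), deliberately sharing
no code with the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np


def koren(r):
    return max(0.0, min(2.0 * r, (1.0 + 2.0 * r) / 3.0, 2.0))


def brute_isotherm(c, a1, a2, b1, b2):
    """Scalar-loop bi-Langmuir for one concentration vector."""
    n = len(c)
    s1 = 1.0 + sum(b1[j] * c[j] for j in range(n))
    s2 = 1.0 + sum(b2[j] * c[j] for j in range(n))
    return np.array([a1[i] * c[i] / s1 + a2[i] * c[i] / s2 for i in range(n)])


def brute_isotherm_jac(c, a1, a2, b1, b2, h=1e-7):
    """Jacobian by central finite differences of brute_isotherm."""
    n = len(c)
    J = np.zeros((n, n))
    for k in range(n):
        cp = np.array(c, dtype=float)
        cm = np.array(c, dtype=float)
        cp[k] += h
        cm[k] = max(cm[k] - h, 0.0)
        J[:, k] = (brute_isotherm(cp, a1, a2, b1, b2)
                   - brute_isotherm(cm, a1, a2, b1, b2)) / (cp[k] - cm[k])
    return J


def brute_bulk_rhs(c_b, c_p, config, n_x, order, gamma, inlet, closed=False):
    """Loop transcription of the bulk finite-volume residual."""
    nc = c_b.shape[0]
    dx = 1.0 / n_x
    n_r = c_p.shape[2]
    d_om = 1.0 / n_r
    beta = 3.0 / (1.0 - config.core_fraction**3)
    out = np.zeros_like(c_b)
    for i in range(nc):
        comp = config.components[i]
        kappa = comp.bi * d_om / (2.0 * beta)
        flux = np.zeros(n_x + 1)
        for j in range(n_x + 1):
            if j == 0:
                flux[j] = 0.0 if closed else inlet[i]
                continue
            if j == n_x:
                flux[j] = 0.0 if closed else c_b[i, n_x - 1]
                continue
            if order == 2 and 2 <= j <= n_x - 1:
                r = ((c_b[i, j - 1] - c_b[i, j - 2] + gamma)
                     / (c_b[i, j] - c_b[i, j - 1] + gamma))
                adv = c_b[i, j - 1] + 0.5 * koren(r) * (c_b[i, j] - c_b[i, j - 1])
            else:
                adv = c_b[i, j - 1]
            flux[j] = adv - (c_b[i, j] - c_b[i, j - 1]) / (comp.pe * dx)
        for u in range(n_x):
            sink = (3.0 * comp.bi * comp.eta * config.phase_ratio / (1.0 + kappa)
                    * (c_b[i, u] - c_p[i, u, n_r - 1]))
            out[i, u] = -(flux[u + 1] - flux[u]) / dx - sink
    return out


def brute_particle_rhs(c_b, c_p, config, n_r):
    """Loop transcription of the radial residual with dense per-cell solves."""
    nc, n_x = c_b.shape
    d_om = 1.0 / n_r
    tc3 = config.core_fraction**3
    beta = 3.0 / (1.0 - tc3)
    a1 = [c.a1 for c in config.components]
    a2 = [c.a2 for c in config.components]
    b1 = [c.b1 for c in config.components]
    b2 = [c.b2 for c in config.components]
    out = np.zeros_like(c_p)
    for u in range(n_x):
        for v in range(n_r):
            div = np.zeros(nc)
            for i in range(nc):
                comp = config.components[i]
                kappa = comp.bi * d_om / (2.0 * beta)

                def dcoef(face):
                    theta = (tc3 + (1.0 - tc3) * face * d_om) ** (1.0 / 3.0)
                    return comp.eta * beta**2 * theta**4

                if v == 0:
                    g_lo = 0.0
                else:
                    g_lo = dcoef(v) * (c_p[i, u, v] - c_p[i, u, v - 1]) / d_om
                if v == n_r - 1:
                    g_hi = (comp.eta * beta * comp.bi / (1.0 + kappa)
                            * (c_b[i, u] - c_p[i, u, v]))
                else:
                    g_hi = dcoef(v + 1) * (c_p[i, u, v + 1] - c_p[i, u, v]) / d_om
                div[i] = (g_hi - g_lo) / d_om
            cc = np.maximum(c_p[:, u, v], 0.0)
            A = config.eps_p * np.eye(nc) + brute_isotherm_jac(cc, a1, a2, b1, b2)
            out[:, u, v] = np.linalg.solve(A, div)
    return out


def fully_porous_reference(config, n_x, n_r, t_end, dxi_out, rtol=1e-8):
    """Independent fully porous GRM: spherical theta-coordinate FV + stiff ODE
    integration (scipy BDF).  Valid for core_fraction = 0 only.

    Uses a uniform theta grid with the standard theta^2-weighted conservative
    spherical discretization — a genuinely different spatial parameterization
    from the package's Omega transform.
    """
    from scipy.integrate import solve_ivp

    assert config.core_fraction == 0.0
    nc = config.n_components
    dx = 1.0 / n_x
    dth = 1.0 / n_r
    th_f = np.linspace(0.0, 1.0, n_r + 1)
    th_c = (np.arange(n_r) + 0.5) * dth
    vol = (th_f[1:] ** 3 - th_f[:-1] ** 3) / 3.0  # cell volumes / (4 pi)
    a1 = np.array([c.a1 for c in config.components])
    a2 = np.array([c.a2 for c in config.components])
    b1 = np.array([c.b1 for c in config.components])
    b2 = np.array([c.b2 for c in config.components])
    pe = np.array([c.pe for c in config.components])
    bi = np.array([c.bi for c in config.components])
    eta = np.array([c.eta for c in config.components])
    c_inj = np.array([c.c_inj for c in config.components])
    fb = config.phase_ratio

    nb = nc * n_x

    def rhs(t, y):
        cb = y[:nb].reshape(nc, n_x)
        cp = y[nb:].reshape(nc, n_x, n_r)
        inlet = c_inj if t < config.xi_inj else np.zeros(nc)
        # surface value from the Robin condition, one-sided second order
        kap = bi * (dth / 2.0)
        csurf = (cp[:, :, -1] + kap[:, None] * cb) / (1.0 + kap[:, None])
        dcb = np.zeros_like(cb)
        for i in range(nc):
            flux = np.empty(n_x + 1)
            flux[0] = inlet[i]
            flux[1:-1] = cb[i, :-1] - np.diff(cb[i]) / (pe[i] * dx)
            flux[-1] = cb[i, -1]
            dcb[i] = -np.diff(flux) / dx - 3.0 * bi[i] * eta[i] * fb * (cb[i] - csurf[i])
        # spherical diffusion, conservative in theta
        dcp = np.zeros_like(cp)
        for i in range(nc):
            g = np.zeros((n_x, n_r + 1))
            g[:, 1:-1] = th_f[1:-1] ** 2 * np.diff(cp[i], axis=1) / dth
            g[:, -1] = bi[i] * (cb[i] - csurf[i])
            div = eta[i] * np.diff(g, axis=1) / vol[None, :]
            dcp[i] = div
        # accumulation solve per cell (grids here are tiny; plain loops)
        cpc = np.maximum(cp, 0.0)
        eye = np.eye(nc)
        dcp_out = np.empty_like(dcp)
        for u in range(n_x):
            for v in range(n_r):
                c_loc = cpc[:, u, v]
                ss1 = 1.0 + b1 @ c_loc
                ss2 = 1.0 + b2 @ c_loc
                J = (a1[:, None] * eye / ss1 - np.outer(a1 * c_loc, b1) / ss1**2
                     + a2[:, None] * eye / ss2 - np.outer(a2 * c_loc, b2) / ss2**2)
                A = config.eps_p * eye + J
                dcp_out[:, u, v] = np.linalg.solve(A, dcp[:, u, v])
        return np.concatenate([dcb.ravel(), dcp_out.ravel()])

    # sparsity: bulk tridiagonal in x + film to surface cell; particle
    # tridiagonal in theta + film to bulk; components couple within a cell
    from scipy.sparse import lil_matrix

    ntot = nb + nc * n_x * n_r
    spars = lil_matrix((ntot, ntot), dtype=np.int8)

    def ib(i, u):
        return i * n_x + u

    def ip(i, u, v):
        return nb + (i * n_x + u) * n_r + v

    for i in range(nc):
        for u in range(n_x):
            for uu in (u - 1, u, u + 1):
                if 0 <= uu < n_x:
                    spars[ib(i, u), ib(i, uu)] = 1
            spars[ib(i, u), ip(i, u, n_r - 1)] = 1
            for v in range(n_r):
                for vv in (v - 1, v, v + 1):
                    if 0 <= vv < n_r:
                        for k in range(nc):
                            spars[ip(i, u, v), ip(k, u, vv)] = 1
                for k in range(nc):
                    spars[ip(i, u, v), ib(k, u)] = 1

    t_eval = np.arange(0.0, t_end + 1e-9, dxi_out)
    sol = solve_ivp(rhs, (0.0, t_end), np.zeros(ntot),
                    method="BDF", rtol=rtol, atol=1e-10, t_eval=t_eval,
                    jac_sparsity=spars.tocsr())
    assert sol.success, sol.message
    outlet = sol.y[:nb].reshape(nc, n_x, -1)[:, -1, :]
    return sol.t, np.maximum(outlet, 0.0)
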