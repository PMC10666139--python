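"""Cell-centered finite-volume semidiscretization of the column model.

Bulk phase (per component, dimensionless)::

    dc_b/dxi = -d/dx [ c_face - (1/Pe) dc_b/dx ] - 3 Bi eta F_b (c_b - c_surf)

with the advective face value ``c_face`` reconstructed from cell averages
(first-order upwind or flux-limited second order) and the Danckwerts inlet
imposed as a prescribed *total* flux at ``x = 0``.

Particle phase, on the volume-fraction radial coordinate ``Omega``::

    (eps_p I + dq*/dc) dc_p/dxi = d/dOmega [ eta beta^2 theta(Omega)^4 dc_p/dOmega ]

with ``beta = 3 / (1 - theta_core^3)``, zero flux at ``Omega = 0`` (the
impenetrable core) and the film Robin flux ``eta beta Bi (c_b - c_surf)`` at
``Omega = 1``.  The accumulation matrix couples components through the
analytic bi-Langmuir Jacobian and is inverted cell-by-cell.

These routines are the plain-numpy reference implementation; the production
time loop in :mod:`coregrm.kernels` reproduces them exactly (tested to
round-off) in compiled form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ColumnConfig, bi_langmuir, bi_langmuir_jacobian, theta_of_omega

__all__ = [
    "Grid",
    "StateField",
    "SchemeConfig",
    "ShellGeometry",
    "shell_geometry",
    "limiter_sigma",
    "limiter_pi",
    "reconstruct_interfaces",
    "bulk_rhs",
    "particle_rhs",
    "apply_inlet",
    "inlet_flux_average",
    "apply_outlet",
    "surface_concentration",
    "column_inventory",
]


# ---------------------------------------------------------------------------
# mesh and state containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Grid:
    """Uniform cell-centered mesh on [0,1] (axial) x [0,1] (Omega)."""

    n_x: int
    n_r: int

    def __post_init__(self):
        if self.n_x < 2 or self.n_r < 1:
            raise ValueError(f"degenerate grid {self.n_x} x {self.n_r}")

    @property
    def delta_x(self) -> float:
        return 1.0 / self.n_x

    @property
    def delta_omega(self) -> float:
        return 1.0 / self.n_r

    @property
    def x_faces(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_x + 1)

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.n_x) + 0.5) * self.delta_x

    @property
    def omega_faces(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_r + 1)

    @property
    def omega_centers(self) -> np.ndarray:
        return (np.arange(self.n_r) + 0.5) * self.delta_omega


@dataclass
class StateField:
    """Cell-averaged bulk (``c_b``) and pore (``c_p``) concentrations.

    Shapes: ``c_b (n_comp, n_x)``, ``c_p (n_comp, n_x, n_r)`` with the radial
    index running from the core interface (Omega = 0) outward.
    """

    c_b: np.ndarray
    c_p: np.ndarray

    @classmethod
    def zeros(cls, n_comp: int, grid: Grid) -> "StateField":
        return cls(
            c_b=np.zeros((n_comp, grid.n_x)),
            c_p=np.zeros((n_comp, grid.n_x, grid.n_r)),
        )

    def copy(self) -> "StateField":
        return StateField(self.c_b.copy(), self.c_p.copy())

    def validate(self, tol_neg: float = 1e-10) -> None:
        for name, arr in (("c_b", self.c_b), ("c_p", self.c_p)):
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(f"StateField.{name} contains nonfinite values")
            if arr.min(initial=0.0) < -tol_neg:
                raise FloatingPointError(
                    f"StateField.{name} fell below -{tol_neg:g} "
                    f"(min {arr.min():.3e})"
                )


@dataclass(frozen=True)
class SchemeConfig:
    """Spatial-scheme settings: reconstruction order and limiter regularization."""

    order: int = 2
    gamma_reg: float = 1e-10

    def __post_init__(self):
        if self.order not in (1, 2):
            raise ValueError(f"order must be 1 or 2, got {self.order!r}")
        if self.gamma_reg <= 0.0:
            raise ValueError("gamma_reg must be positive")


@dataclass(frozen=True)
class ShellGeometry:
    """Precomputed radial-operator coefficients for one (config, grid) pair.

    ``d_face[i, v]`` is the transformed diffusivity ``eta_i beta^2 theta^4``
    at radial face ``v``; ``kappa`` closes the surface value to second order,
    ``film_bulk`` multiplies ``(c_b - c_p[..,-1])`` in the bulk sink and
    ``film_particle`` the same difference in the surface flux.
    """

    beta: float
    theta_faces: np.ndarray
    d_face: np.ndarray        # (n_comp, n_r + 1)
    kappa: np.ndarray         # (n_comp,)
    film_particle: np.ndarray  # (n_comp,) = eta*beta*Bi/(1+kappa)
    film_bulk: np.ndarray      # (n_comp,) = 3*Bi*eta*F_b/(1+kappa)


def shell_geometry(config: ColumnConfig, grid: Grid) -> ShellGeometry:
    tc3 = config.core_fraction**3
    beta = 3.0 / (1.0 - tc3)
    theta_f = theta_of_omega(grid.omega_faces, config.core_fraction)
    eta = config.comp_array("eta")
    bi = config.comp_array("bi")
    d_face = eta[:, None] * beta**2 * theta_f[None, :] ** 4
    kappa = bi * grid.delta_omega / (2.0 * beta)
    film_particle = eta * beta * bi / (1.0 + kappa)
    film_bulk = 3.0 * bi * eta * config.phase_ratio / (1.0 + kappa)
    return ShellGeometry(
        beta=beta,
        theta_faces=theta_f,
        d_face=d_face,
        kappa=kappa,
        film_particle=film_particle,
        film_bulk=film_bulk,
    )


def surface_concentration(state: StateField, geom: ShellGeometry) -> np.ndarray:
    """Pore concentration at the particle surface (Omega = 1), second-order
    closure of the film Robin condition from the outermost radial cell."""
    k = geom.kappa[:, None]
    return (state.c_p[:, :, -1] + k * state.c_b) / (1.0 + k)


# ---------------------------------------------------------------------------
# flux limiters and interface reconstruction
# ---------------------------------------------------------------------------


def limiter_sigma(r):
    """Koren-type limiter: max(0, min(2r, (1+2r)/3, 2)).

    Zero at local extrema (r <= 0), unity on uniform slopes (r = 1), bounded
    by 2; yields a third-order-biased second-order TVD reconstruction.
    """
    r = np.asarray(r, dtype=float)
    out = np.maximum(0.0, np.minimum(2.0 * r, np.minimum((1.0 + 2.0 * r) / 3.0, 2.0)))
    return out if out.ndim else float(out)


def limiter_pi(r):
    """van Leer limiter: (r + |r|) / (1 + |r|); same TVD box as ``limiter_sigma``."""
    r = np.asarray(r, dtype=float)
    out = (r + np.abs(r)) / (1.0 + np.abs(r))
    return out if out.ndim else float(out)


def reconstruct_interfaces(values: np.ndarray, order: int = 2,
                           gamma_reg: float = 1e-10) -> np.ndarray:
    """Upwind-biased face values for unit-speed transport in +x.

    ``values`` may be 1-D ``(n,)`` or batched ``(n_comp, n)``; returns faces
    with one more entry along the last axis.  Face ``j`` lies between cells
    ``j-1`` and ``j``; the first and last faces always use the first-order
    (backward) value, matching the boundary treatment of the scheme.
    """
    v = np.asarray(values, dtype=float)
    squeeze = v.ndim == 1
    if squeeze:
        v = v[None, :]
    n = v.shape[-1]
    if n < 2:
        raise ValueError("need at least two cells to reconstruct interfaces")
    faces = np.empty(v.shape[:-1] + (n + 1,), dtype=float)
    faces[..., 0] = v[..., 0]
    faces[..., 1:] = v  # first-order upwind everywhere
    if order == 2 and n >= 3:
        # interior faces j = 2 .. n-1 (upwind cell j-1 has two-sided support)
        up = v[..., 1:-1] - v[..., :-2]     # c_{j-1} - c_{j-2}
        loc = v[..., 2:] - v[..., 1:-1]     # c_j   - c_{j-1}
        r = (up + gamma_reg) / (loc + gamma_reg)
        faces[..., 2:-1] = v[..., 1:-1] + 0.5 * limiter_sigma(r) * loc
    return faces[0] if squeeze else faces


# ---------------------------------------------------------------------------
# boundary conditions
# ---------------------------------------------------------------------------


def apply_inlet(config: ColumnConfig, xi: float) -> np.ndarray:
    """Danckwerts inlet: prescribed total flux per component at ``x = 0``.

    The Robin balance ``c - (1/Pe) dc/dx = c_inj`` states that the combined
    advective-dispersive flux entering the column equals ``c_inj`` during the
    rectangular pulse ``0 <= xi < xi_inj`` and vanishes afterwards; in the
    finite-volume scheme this is imposed exactly on the inlet face flux.
    """
    c_inj = config.comp_array("c_inj")
    return c_inj if 0.0 <= xi < config.xi_inj else np.zeros_like(c_inj)


def inlet_flux_average(config: ColumnConfig, xi: float, dxi: float) -> np.ndarray:
    """Inlet flux averaged over the step ``[xi, xi + dxi]``.

    Using the interval average instead of point samples makes the injected
    mass exactly ``c_inj * xi_inj`` independent of how steps align with the
    pulse edges.
    """
    c_inj = config.comp_array("c_inj")
    lo, hi = max(xi, 0.0), min(xi + dxi, config.xi_inj)
    frac = max(hi - lo, 0.0) / dxi if dxi > 0 else 0.0
    return c_inj * frac


def apply_outlet(state: StateField) -> np.ndarray:
    """Outlet sample under the zero-gradient closure: the last-cell value.

    Read-only: the state is not modified.
    """
    return state.c_b[:, -1].copy()


# ---------------------------------------------------------------------------
# semidiscrete right-hand sides
# ---------------------------------------------------------------------------


def bulk_rhs(state: StateField, config: ColumnConfig, grid: Grid,
             scheme: SchemeConfig, xi: float = 0.0,
             inlet_value: np.ndarray | None = None,
             closed: bool = False) -> np.ndarray:
    """Time derivative of the bulk concentrations, shape ``(n_comp, n_x)``.

    ``inlet_value`` overrides the pointwise Danckwerts flux (used by the
    integrator to pass pulse-averaged values); ``closed=True`` zeroes both
    boundary fluxes, which makes the convective+dispersive operator exactly
    conservative (telescoping) for property tests.
    """
    cb = state.c_b
    nc, nx = cb.shape
    dx = grid.delta_x
    pe = config.comp_array("pe")[:, None]
    geom = shell_geometry(config, grid)

    flux = reconstruct_interfaces(cb, order=scheme.order, gamma_reg=scheme.gamma_reg)
    # dispersive part on interior faces
    flux[:, 1:-1] -= (cb[:, 1:] - cb[:, :-1]) / (pe * dx)
    if closed:
        flux[:, 0] = 0.0
        flux[:, -1] = 0.0
    else:
        flux[:, 0] = apply_inlet(config, xi) if inlet_value is None else inlet_value
        flux[:, -1] = cb[:, -1]  # zero-gradient outlet: advective only

    dcb = -(flux[:, 1:] - flux[:, :-1]) / dx
    # film sink 3 Bi eta F_b (c_b - c_surf); with the second-order surface
    # closure c_b - c_surf = (c_b - c_p[..,-1]) / (1 + kappa), absorbed into
    # the film_bulk coefficient.
    dcb -= geom.film_bulk[:, None] * (cb - state.c_p[:, :, -1])
    return dcb


def particle_rhs(state: StateField, config: ColumnConfig, grid: Grid,
                 scheme: SchemeConfig, counters: dict | None = None) -> np.ndarray:
    """Time derivative of the pore concentrations, shape ``(n_comp, n_x, n_r)``.

    Assembles the conservative radial fluxes (zero at the core interface,
    film Robin flux at the surface) and solves the small per-cell linear
    system with the accumulation matrix ``eps_p I + dq*/dc``.  Negative pore
    concentrations are clipped to zero for the isotherm evaluation only and
    counted in ``counters['negative_clips']``.
    """
    cp = state.c_p
    nc, nx, nr = cp.shape
    dom = grid.delta_omega
    geom = shell_geometry(config, grid)

    flux = np.zeros((nc, nx, nr + 1))
    if nr > 1:
        flux[:, :, 1:-1] = geom.d_face[:, None, 1:-1] * (cp[:, :, 1:] - cp[:, :, :-1]) / dom
    flux[:, :, -1] = geom.film_particle[:, None] * (state.c_b - cp[:, :, -1])
    div = (flux[:, :, 1:] - flux[:, :, :-1]) / dom

    neg = cp < 0.0
    if neg.any():
        if counters is not None:
            counters["negative_clips"] = counters.get("negative_clips", 0) + int(neg.sum())
        cp_iso = np.where(neg, 0.0, cp)
    else:
        cp_iso = cp
    jac = bi_langmuir_jacobian(cp_iso, config)          # (nx, nr, nc, nc)
    acc = config.eps_p * np.eye(nc) + jac
    rhs = np.moveaxis(div, 0, -1)[..., None]            # (nx, nr, nc, 1)
    dcp = np.linalg.solve(acc, rhs)[..., 0]
    return np.moveaxis(dcp, -1, 0)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def column_inventory(state: StateField, config: ColumnConfig, grid: Grid) -> np.ndarray:
    """Total dimensionless amount per component per unit bed volume.

    ``eps_b * sum(c_b) dx + (1 - eps_b)(1 - theta_core^3) *
    sum(eps_p c_p + q*(c_p)) dx dOmega`` — the discrete conserved quantity of
    the scheme up to boundary fluxes.
    """
    q = bi_langmuir(np.maximum(state.c_p, 0.0), config)
    shell = (1.0 - config.eps_b) * (1.0 - config.core_fraction**3)
    bulk = config.eps_b * state.c_b.sum(axis=1) * grid.delta_x
    part = shell * (config.eps_p * state.c_p + q).sum(axis=(1, 2)) * grid.delta_x * grid.delta_omega
    return bulk + part
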