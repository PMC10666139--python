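"""Physical parameters, nondimensionalization, isotherm and radial transform.

The column model is formulated entirely in dimensionless variables:

* ``x`` — axial position over the column length, ``x in [0, 1]``;
* ``xi`` — time in units of the column space time ``L / u_int`` (interstitial
  velocity ``u_int = u / eps_b``);
* ``theta`` — radial position inside an adsorbent bead over the bead radius,
  restricted to the porous shell ``theta in [theta_core, 1]`` for core-shell
  (cored) particles;
* concentrations scaled by a reference feed concentration.

Three dimensionless groups govern transport of each solute:

* ``Pe = L * u_int / D_ax`` — column-length Peclet number,
* ``Bi = k_ext * R_p / (eps_p * D_p)`` — Biot number (film vs pore transfer),
* ``eta = eps_p * D_p * L / (R_p**2 * u_int)`` — space time over intraparticle
  diffusion time.

Adsorption follows the competitive bi-Langmuir isotherm with two independent
site classes (I and II)::

    q_i*(c) = a_i^I c_i / (1 + sum_j b_j^I c_j)
            + a_i^II c_i / (1 + sum_j b_j^II c_j)

Only :class:`DimensionalColumnSpec` carries units; everything downstream of
:func:`nondimensionalize` operates on dimensionless quantities.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "ComponentParams",
    "ColumnConfig",
    "DimensionalComponent",
    "DimensionalColumnSpec",
    "nondimensionalize",
    "bi_langmuir",
    "bi_langmuir_jacobian",
    "omega_of_theta",
    "theta_of_omega",
    "read_scenario",
    "write_scenario",
]


# ---------------------------------------------------------------------------
# dimensionless domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComponentParams:
    """Per-solute dimensionless transport and bi-Langmuir coefficients.

    ``a1``/``a2`` are the Henry constants of sites I and II; ``b1``/``b2`` the
    corresponding nonlinearity coefficients (per unit dimensionless
    concentration). ``c_inj`` is the dimensionless injected concentration.
    """

    pe: float
    bi: float
    eta: float
    a1: float
    a2: float
    b1: float
    b2: float
    c_inj: float

    def __post_init__(self):
        for name in ("pe", "bi", "eta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0.0:
                raise ValueError(f"ComponentParams.{name} must be positive, got {v!r}")
        for name in ("a1", "a2", "b1", "b2", "c_inj"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0.0:
                raise ValueError(f"ComponentParams.{name} must be >= 0, got {v!r}")


@dataclass(frozen=True)
class ColumnConfig:
    """Dimensionless column description: components plus bed/particle geometry."""

    components: tuple[ComponentParams, ...]
    eps_b: float
    eps_p: float
    core_fraction: float = 0.0
    xi_inj: float = 1.0

    def __post_init__(self):
        if len(self.components) == 0:
            raise ValueError("ColumnConfig.components must be nonempty")
        object.__setattr__(self, "components", tuple(self.components))
        for name in ("eps_b", "eps_p"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"ColumnConfig.{name} must lie in (0, 1), got {v!r}")
        if not (0.0 <= self.core_fraction < 1.0):
            raise ValueError(
                f"ColumnConfig.core_fraction must lie in [0, 1), got {self.core_fraction!r}"
            )
        if self.xi_inj <= 0.0:
            raise ValueError(f"ColumnConfig.xi_inj must be positive, got {self.xi_inj!r}")

    @property
    def phase_ratio(self) -> float:
        """Bed phase ratio F_b = (1 - eps_b) / eps_b."""
        return (1.0 - self.eps_b) / self.eps_b

    @property
    def n_components(self) -> int:
        return len(self.components)

    # vectorized views used by the solver -----------------------------------
    def comp_array(self, name: str) -> np.ndarray:
        return np.array([getattr(c, name) for c in self.components], dtype=float)

    def isotherm_coeffs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return (
            self.comp_array("a1"),
            self.comp_array("a2"),
            self.comp_array("b1"),
            self.comp_array("b2"),
        )

    def with_overrides(self, **overrides) -> "ColumnConfig":
        """Return a copy with column-level and/or per-component overrides.

        Recognized keys: ``eps_b``, ``eps_p``, ``core_fraction``, ``xi_inj``
        (column level) and ``pe``, ``bi``, ``eta``, ``a1``, ``a2``, ``b1``,
        ``b2``, ``c_inj`` (applied to every component; pass a sequence to set
        per-component values).
        """
        column_keys = {"eps_b", "eps_p", "core_fraction", "xi_inj"}
        comp_keys = {"pe", "bi", "eta", "a1", "a2", "b1", "b2", "c_inj"}
        col_kw = {}
        comps = list(self.components)
        for key, value in overrides.items():
            if key in column_keys:
                col_kw[key] = value
            elif key in comp_keys:
                values = (
                    list(value)
                    if np.ndim(value) > 0
                    else [value] * len(comps)
                )
                if len(values) != len(comps):
                    raise ValueError(
                        f"override {key!r} has {len(values)} values for "
                        f"{len(comps)} components"
                    )
                comps = [replace(c, **{key: v}) for c, v in zip(comps, values)]
            else:
                raise KeyError(f"unknown override key {key!r}")
        return ColumnConfig(components=tuple(comps), **{
            "eps_b": col_kw.get("eps_b", self.eps_b),
            "eps_p": col_kw.get("eps_p", self.eps_p),
            "core_fraction": col_kw.get("core_fraction", self.core_fraction),
            "xi_inj": col_kw.get("xi_inj", self.xi_inj),
        })


# ---------------------------------------------------------------------------
# dimensional front door
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DimensionalComponent:
    """Per-solute dimensional transport properties.

    ``axial_dispersion`` [L^2/T], ``film_coefficient`` [L/T], ``pore_diffusivity``
    [L^2/T], ``injected_concentration`` [amount/volume]; the Henry constants
    ``a1``/``a2`` are dimensionless and ``b1``/``b2`` carry [volume/amount].
    """

    axial_dispersion: float
    film_coefficient: float
    pore_diffusivity: float
    injected_concentration: float
    a1: float = 0.0
    a2: float = 0.0
    b1: float = 0.0
    b2: float = 0.0


@dataclass(frozen=True)
class DimensionalColumnSpec:
    """Dimensional column description; convenience front door only."""

    bed_void_fraction: float
    particle_porosity: float
    superficial_velocity: float
    column_length: float
    particle_radius: float
    core_radius: float
    components: tuple[DimensionalComponent, ...]
    injection_duration: float
    reference_concentration: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(self.components))
        positive = {
            "superficial_velocity": self.superficial_velocity,
            "column_length": self.column_length,
            "particle_radius": self.particle_radius,
            "injection_duration": self.injection_duration,
            "reference_concentration": self.reference_concentration,
        }
        for name, v in positive.items():
            if not np.isfinite(v) or v <= 0.0:
                raise ValueError(f"DimensionalColumnSpec.{name} must be positive, got {v!r}")
        for name in ("bed_void_fraction", "particle_porosity"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(
                    f"DimensionalColumnSpec.{name} must lie in (0, 1), got {v!r}"
                )
        if not (0.0 <= self.core_radius < self.particle_radius):
            raise ValueError(
                "DimensionalColumnSpec.core_radius must satisfy "
                f"0 <= core_radius < particle_radius, got {self.core_radius!r} "
                f"(particle_radius {self.particle_radius!r}): core leaves no shell"
            )
        for k, comp in enumerate(self.components):
            for name in ("axial_dispersion", "film_coefficient", "pore_diffusivity"):
                v = getattr(comp, name)
                if not np.isfinite(v) or v <= 0.0:
                    raise ValueError(
                        f"components[{k}].{name} must be positive, got {v!r}"
                    )
            if comp.injected_concentration < 0.0:
                raise ValueError(
                    f"components[{k}].injected_concentration must be >= 0"
                )


def nondimensionalize(spec: DimensionalColumnSpec) -> ColumnConfig:
    """Reduce a dimensional column description to its dimensionless groups.

    Uses the interstitial velocity ``u_int = u / eps_b``::

        Pe  = L * u_int / D_ax
        Bi  = k_ext * R_p / (eps_p * D_p)
        eta = eps_p * D_p * L / (R_p**2 * u_int)

    with ``core_fraction = R_core / R_p``, ``xi_inj = t_inj * u_int / L`` and
    concentrations scaled by ``reference_concentration`` (the nonlinearity
    coefficients pick up the inverse scaling).
    """
    u_int = spec.superficial_velocity / spec.bed_void_fraction
    L = spec.column_length
    rp = spec.particle_radius
    cref = spec.reference_concentration
    comps = []
    for comp in spec.components:
        pe = L * u_int / comp.axial_dispersion
        bi = comp.film_coefficient * rp / (spec.particle_porosity * comp.pore_diffusivity)
        eta = spec.particle_porosity * comp.pore_diffusivity * L / (rp**2 * u_int)
        comps.append(
            ComponentParams(
                pe=pe,
                bi=bi,
                eta=eta,
                a1=comp.a1,
                a2=comp.a2,
                b1=comp.b1 * cref,
                b2=comp.b2 * cref,
                c_inj=comp.injected_concentration / cref,
            )
        )
    return ColumnConfig(
        components=tuple(comps),
        eps_b=spec.bed_void_fraction,
        eps_p=spec.particle_porosity,
        core_fraction=spec.core_radius / rp,
        xi_inj=spec.injection_duration * u_int / L,
    )


# ---------------------------------------------------------------------------
# bi-Langmuir isotherm
# ---------------------------------------------------------------------------


def _coeff_arrays(components) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(components, ColumnConfig):
        return components.isotherm_coeffs()
    comps = tuple(components)
    get = lambda name: np.array([getattr(c, name) for c in comps], dtype=float)
    return get("a1"), get("a2"), get("b1"), get("b2")


def bi_langmuir(c_p: np.ndarray, components) -> np.ndarray:
    """Equilibrium solid loading ``q*`` for pore concentrations ``c_p``.

    ``c_p`` has the component axis first and may carry arbitrary trailing grid
    axes; the two site-class denominators are shared across components, which
    is what makes the isotherm competitive.
    """
    a1, a2, b1, b2 = _coeff_arrays(components)
    c = np.asarray(c_p, dtype=float)
    if c.shape[0] != a1.shape[0]:
        raise ValueError(
            f"c_p has {c.shape[0]} components, coefficients have {a1.shape[0]}"
        )
    if np.any(c < 0.0):
        raise ValueError("bi_langmuir: negative pore concentration(s)")
    shape = (-1,) + (1,) * (c.ndim - 1)
    s1 = 1.0 + np.tensordot(b1, c, axes=(0, 0))
    s2 = 1.0 + np.tensordot(b2, c, axes=(0, 0))
    return a1.reshape(shape) * c / s1 + a2.reshape(shape) * c / s2


def bi_langmuir_jacobian(c_p: np.ndarray, components) -> np.ndarray:
    """Analytic Jacobian ``dq_i*/dc_k`` of :func:`bi_langmuir`.

    Returns shape ``grid_shape + (n_comp, n_comp)`` for ``c_p`` of shape
    ``(n_comp,) + grid_shape``, ready for stacked linear solves.
    """
    a1, a2, b1, b2 = _coeff_arrays(components)
    c = np.asarray(c_p, dtype=float)
    n = a1.shape[0]
    s1 = 1.0 + np.tensordot(b1, c, axes=(0, 0))
    s2 = 1.0 + np.tensordot(b2, c, axes=(0, 0))
    grid = np.moveaxis(c, 0, -1)  # grid_shape + (n,)
    jac = np.zeros(grid.shape + (n,), dtype=float)
    eye = np.eye(n)
    for site_a, site_b, s in ((a1, b1, s1), (a2, b2, s2)):
        s_ = s[..., None, None]
        # a_i * (delta_ik / s - c_i b_k / s^2)
        jac += site_a[:, None] * eye / s_
        jac -= (site_a * grid)[..., :, None] * site_b[None, :] / s_**2
    return jac


# ---------------------------------------------------------------------------
# core-shell radial transform
# ---------------------------------------------------------------------------


def omega_of_theta(theta, core_fraction: float):
    """Volume-fraction radial coordinate Omega(theta) of the porous shell.

    ``Omega = (theta^3 - theta_core^3) / (1 - theta_core^3)`` maps the shell
    ``[theta_core, 1]`` onto ``[0, 1]`` so that equal Omega intervals hold
    equal shell volume; at ``theta_core = 0`` it degenerates to the fully
    porous parameterization ``Omega = theta^3`` of the whole bead.
    """
    if not (0.0 <= core_fraction < 1.0):
        raise ValueError(f"core_fraction must lie in [0, 1), got {core_fraction!r}")
    th = np.asarray(theta, dtype=float)
    if np.any(th < core_fraction - 1e-12) or np.any(th > 1.0 + 1e-12):
        raise ValueError("theta outside the porous shell [core_fraction, 1]")
    tc3 = core_fraction**3
    out = (th**3 - tc3) / (1.0 - tc3)
    return np.clip(out, 0.0, 1.0) if out.ndim else float(min(max(out, 0.0), 1.0))


def theta_of_omega(omega, core_fraction: float):
    """Inverse of :func:`omega_of_theta`."""
    if not (0.0 <= core_fraction < 1.0):
        raise ValueError(f"core_fraction must lie in [0, 1), got {core_fraction!r}")
    om = np.asarray(omega, dtype=float)
    if np.any(om < -1e-12) or np.any(om > 1.0 + 1e-12):
        raise ValueError("omega outside [0, 1]")
    tc3 = core_fraction**3
    th = np.cbrt(tc3 + (1.0 - tc3) * np.clip(om, 0.0, 1.0))
    return th if th.ndim else float(th)


# ---------------------------------------------------------------------------
# scenario files (flat INI: [column], [numerics], [components.N])
# ---------------------------------------------------------------------------

_COLUMN_KEYS = ("eps_b", "eps_p", "core_fraction", "xi_inj")
_COMPONENT_KEYS = ("pe", "bi", "eta", "a1", "a2", "b1", "b2", "c_inj")


def read_scenario(path) -> tuple[ColumnConfig, dict]:
    """Read a scenario file; returns ``(ColumnConfig, numerics dict)``.

    ``numerics`` holds whatever keys the ``[numerics]`` section defines
    (``n_x``, ``n_r``, ``order``, ``gamma_reg``, ``cfl_safety``, ``t_end``,
    ``dxi_out``), converted to int where integral.
    """
    parser = configparser.ConfigParser()
    read = parser.read(str(path))
    if not read:
        raise FileNotFoundError(f"scenario file not found: {path}")
    if "column" not in parser:
        raise ValueError(f"scenario file {path} lacks a [column] section")
    col = {k: parser["column"].getfloat(k) for k in _COLUMN_KEYS if k in parser["column"]}
    comp_sections = sorted(
        (s for s in parser.sections() if s.startswith("components.")),
        key=lambda s: int(s.split(".", 1)[1]),
    )
    if not comp_sections:
        raise ValueError(f"scenario file {path} defines no [components.N] sections")
    comps = []
    for sec in comp_sections:
        kw = {}
        for key in _COMPONENT_KEYS:
            if key not in parser[sec]:
                raise ValueError(f"scenario file {path}: [{sec}] missing key {key!r}")
            kw[key] = parser[sec].getfloat(key)
        comps.append(ComponentParams(**kw))
    config = ColumnConfig(components=tuple(comps), **col)
    numerics: dict = {}
    if "numerics" in parser:
        for key, raw in parser["numerics"].items():
            val = float(raw)
            numerics[key] = int(val) if key in ("n_x", "n_r", "order") else val
    return config, numerics


def write_scenario(path, config: ColumnConfig, numerics: dict | None = None) -> None:
    """Write a scenario file readable by :func:`read_scenario` (lossless)."""
    parser = configparser.ConfigParser()
    parser["column"] = {
        "eps_b": repr(config.eps_b),
        "eps_p": repr(config.eps_p),
        "core_fraction": repr(config.core_fraction),
        "xi_inj": repr(config.xi_inj),
    }
    if numerics:
        parser["numerics"] = {k: repr(v) for k, v in numerics.items()}
    for n, comp in enumerate(config.components, start=1):
        parser[f"components.{n}"] = {k: repr(getattr(comp, k)) for k in _COMPONENT_KEYS}
    with open(Path(path), "w") as fh:
        parser.write(fh)
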