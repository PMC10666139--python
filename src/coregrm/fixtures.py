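"""Canned study scenarios and a seeded random-scenario generator.

The scenario library carries the reference parameter set used throughout the
simulation studies: ``Pe = 1500``, ``Bi = 50``, ``eta = 2.0``,
``eps_b = 0.4``, ``eps_p = 0.5``, ``c_inj = 1.0``, ``xi_inj = 1.0`` for every
solute, with bi-Langmuir site constants ``(a1, a2, b1, b2)`` of
``(10, 15, 0.5, 1.0)``, ``(30, 35, 1.5, 2.0)`` and ``(70, 75, 3.0, 3.5)`` for
components one to three.  Named entries:

* ``single_solute``   — one component;
* ``two_component``   — components one and two (the fractionation studies);
* ``three_component`` — all three (longer elution window).

The same scenarios ship as plain INI files under ``coregrm/scenarios`` and
round-trip losslessly through the scenario reader/writer.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .integrate import TimeControls
from .params import ColumnConfig, ComponentParams, read_scenario

__all__ = [
    "SCENARIO_NAMES",
    "reference_scenario",
    "scenario_controls",
    "scenario_path",
    "random_scenario",
]

_BASE = dict(pe=1500.0, bi=50.0, eta=2.0, c_inj=1.0)
_SITES = (
    dict(a1=10.0, a2=15.0, b1=0.5, b2=1.0),
    dict(a1=30.0, a2=35.0, b1=1.5, b2=2.0),
    dict(a1=70.0, a2=75.0, b1=3.0, b2=3.5),
)
_N_COMP = {"single_solute": 1, "two_component": 2, "three_component": 3}
# elution windows for the default (fully porous) parameters
_T_END = {"single_solute": 120.0, "two_component": 120.0, "three_component": 220.0}

SCENARIO_NAMES = tuple(_N_COMP)


def reference_scenario(name: str, **overrides) -> ColumnConfig:
    """Reference scenario by name, with optional overrides applied last.

    Override keys are those of :meth:`ColumnConfig.with_overrides`; scalars
    apply to every component, sequences per component.  Invariant-violating
    overrides are rejected.
    """
    if name not in _N_COMP:
        raise KeyError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    comps = tuple(
        ComponentParams(**_BASE, **_SITES[k]) for k in range(_N_COMP[name])
    )
    config = ColumnConfig(components=comps, eps_b=0.4, eps_p=0.5,
                          core_fraction=0.0, xi_inj=1.0)
    return config.with_overrides(**overrides) if overrides else config


def scenario_controls(name: str, **kwargs) -> TimeControls:
    """Default time controls for a named scenario (fully porous window)."""
    if name not in _T_END:
        raise KeyError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    kwargs.setdefault("t_end", _T_END[name])
    return TimeControls(**kwargs)


def scenario_path(name: str):
    """Path to the shipped scenario INI file (usable with read_scenario)."""
    if name not in _N_COMP:
        raise KeyError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    return resources.files("coregrm") / "scenarios" / f"{name}.ini"


def load_scenario_file(name_or_path) -> tuple[ColumnConfig, dict]:
    """Resolve a library name or a filesystem path to (config, numerics)."""
    if isinstance(name_or_path, str) and name_or_path in _N_COMP:
        with resources.as_file(scenario_path(name_or_path)) as p:
            return read_scenario(p)
    return read_scenario(name_or_path)


def random_scenario(seed: int, n_components: int = 2) -> ColumnConfig:
    """Seeded, reproducible scenario within physically sensible ranges.

    ``Pe in [100, 3000]``, ``Bi in [1, 200]``, ``eta in [0.1, 5]``,
    ``a in [1, 80]``, ``b in [0, 10]``, ``core_fraction in [0, 0.9]``.
    """
    if not (1 <= n_components <= 4):
        raise ValueError("n_components must lie in 1..4")
    rng = np.random.default_rng(seed)
    comps = tuple(
        ComponentParams(
            pe=float(rng.uniform(100.0, 3000.0)),
            bi=float(rng.uniform(1.0, 200.0)),
            eta=float(rng.uniform(0.1, 5.0)),
            a1=float(rng.uniform(1.0, 80.0)),
            a2=float(rng.uniform(1.0, 80.0)),
            b1=float(rng.uniform(0.0, 10.0)),
            b2=float(rng.uniform(0.0, 10.0)),
            c_inj=float(rng.uniform(0.1, 5.0)),
        )
        for _ in range(n_components)
    )
    return ColumnConfig(
        components=comps,
        eps_b=float(rng.uniform(0.3, 0.5)),
        eps_p=float(rng.uniform(0.3, 0.7)),
        core_fraction=float(rng.uniform(0.0, 0.9)),
        xi_inj=float(rng.uniform(0.5, 2.0)),
    )
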