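"""Fractionation analysis: cycle time, cut time, productivity and yield.

The target solute (by default the first-eluting component) is collected from
the moment its outlet concentration first exceeds a detection threshold
(``xi^1``) until the cut time ``xi^cut`` at which the collected fraction's
peak-area purity equals the requested level (99% by default).  The cycle time
``xi^cyc = xi^2 - xi^1`` is the re-injection interval: the next injection is
timed so that its target front arrives exactly as the previous run's last
component falls below the threshold (at ``xi^2``).

With ``m1 = integral of the target outlet over [xi^1, xi^cut]``:

* recovery yield      ``Y    = m1 / (c_inj * xi_inj)``
* reduced productivity ``Y^Pr = c_inj * m1 / xi^cyc``

Both integrals use trapezoidal quadrature on the chromatogram's sample grid;
the cut time is located by a bracketed root search on the cumulative-area
purity, which is monotone decreasing once the later component breaks through.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from .integrate import Chromatogram, TimeControls, simulate
from .params import ColumnConfig
from .scheme import Grid, SchemeConfig

__all__ = [
    "FractionationSpec",
    "PerformanceMetrics",
    "cycle_time",
    "cut_time",
    "productivity",
    "recovery_yield",
    "analyze",
    "scan",
]


@dataclass(frozen=True)
class FractionationSpec:
    """Fraction-collection settings.

    ``target_component`` is 1-based (the earlier-eluting solute by default);
    ``detection_threshold`` is the fraction of each component's own ``c_inj``
    that defines the window endpoints ``xi^1`` and ``xi^2``.
    """

    target_component: int = 1
    purity_level: float = 0.99
    detection_threshold: float = 0.01

    def __post_init__(self):
        if self.target_component < 1:
            raise ValueError("target_component is 1-based and must be >= 1")
        if not (0.0 < self.purity_level < 1.0):
            raise ValueError("purity_level must lie in (0, 1)")
        if not (0.0 < self.detection_threshold < 1.0):
            raise ValueError("detection_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class PerformanceMetrics:
    """Eqs-of-merit of one fractionated run (all dimensionless)."""

    cycle_time: float
    cut_time: float
    productivity: float
    recovery_yield: float
    achieved_purity: float
    collected_amount: float
    xi1: float
    xi2: float
    peak_outlet: tuple  # per-component outlet maxima (tabulated outlet plateau maxima)


# ---------------------------------------------------------------------------
# window endpoints
# ---------------------------------------------------------------------------


def _first_crossing(t: np.ndarray, c: np.ndarray, thr: float) -> float:
    """First up-crossing of ``thr``, linearly interpolated."""
    above = c >= thr
    if not above.any():
        raise ValueError("incomplete elution window: threshold never crossed")
    j = int(np.argmax(above))
    if j == 0:
        return float(t[0])
    t0, t1, c0, c1 = t[j - 1], t[j], c[j - 1], c[j]
    return float(t0 + (thr - c0) / (c1 - c0) * (t1 - t0))


def _last_crossing(t: np.ndarray, c: np.ndarray, thr: float) -> float:
    """Last down-crossing of ``thr``, linearly interpolated."""
    above = c >= thr
    if not above.any():
        raise ValueError("incomplete elution window: threshold never crossed")
    j = int(len(c) - 1 - np.argmax(above[::-1]))  # last index above
    if j == len(c) - 1:
        raise ValueError(
            "incomplete elution window: concentration still above threshold "
            "at the end of the chromatogram; increase t_end"
        )
    t0, t1, c0, c1 = t[j], t[j + 1], c[j], c[j + 1]
    return float(t0 + (c0 - thr) / (c0 - c1) * (t1 - t0))


def _thresholds(chrom: Chromatogram, spec: FractionationSpec) -> np.ndarray:
    c_inj = chrom.config.comp_array("c_inj")
    return spec.detection_threshold * c_inj


def elution_window(chrom: Chromatogram,
                   spec: FractionationSpec | None = None) -> tuple[float, float]:
    """``(xi^1, xi^2)``: target first exceeds its threshold; last component
    falls below its own for good."""
    spec = spec or FractionationSpec()
    thr = _thresholds(chrom, spec)
    tgt = spec.target_component - 1
    xi1 = _first_crossing(chrom.times, chrom.outlet[tgt], thr[tgt])
    xi2 = _last_crossing(chrom.times, chrom.outlet[-1], thr[-1])
    return xi1, xi2


def cycle_time(chrom: Chromatogram, spec: FractionationSpec | None = None) -> float:
    """Re-injection interval ``xi^cyc = xi^2 - xi^1``."""
    xi1, xi2 = elution_window(chrom, spec)
    return xi2 - xi1


# ---------------------------------------------------------------------------
# cut time via cumulative-area purity
# ---------------------------------------------------------------------------


def _cumulative(chrom: Chromatogram, xi1: float):
    """Cumulative collected amounts from ``xi1``: callables m_tgt(t), m_tot(t)."""
    t = chrom.times
    cum = cumulative_trapezoid(chrom.outlet, t, axis=1, initial=0.0)
    base = np.array([np.interp(xi1, t, cum[i]) for i in range(cum.shape[0])])

    def at(time: float) -> np.ndarray:
        return np.array(
            [np.interp(time, t, cum[i]) for i in range(cum.shape[0])]
        ) - base

    return at


def cut_time(chrom: Chromatogram, spec: FractionationSpec | None = None) -> float:
    """Collection stop time of the target at the requested peak-area purity.

    If the fraction stays pure over the target's whole elution (disjoint
    peaks), the cut is the end of the target peak; otherwise the unique time
    at which the cumulative purity drops to ``purity_level``, found by a
    bracketed root search (bisection-type, deterministic).
    """
    spec = spec or FractionationSpec()
    tgt = spec.target_component - 1
    thr = _thresholds(chrom, spec)
    xi1, xi2 = elution_window(chrom, spec)
    t_tgt_end = _last_crossing(chrom.times, chrom.outlet[tgt], thr[tgt])
    t_max = min(t_tgt_end, xi2)
    cum = _cumulative(chrom, xi1)

    def purity(time: float) -> float:
        m = cum(time)
        tot = m.sum()
        return m[tgt] / tot if tot > 0.0 else 1.0

    if purity(t_max) >= spec.purity_level:
        return t_max
    # walk the sample grid for a bracket [t_lo with purity >= level, t_hi below]
    grid_t = chrom.times[(chrom.times > xi1) & (chrom.times <= t_max)]
    t_lo = xi1
    t_hi = None
    for tk in grid_t:
        if purity(float(tk)) >= spec.purity_level:
            t_lo = float(tk)
        else:
            t_hi = float(tk)
            break
    if t_hi is None:
        t_hi = t_max
    if t_lo == xi1 and purity(t_lo + 1e-9 * (t_hi - t_lo)) < spec.purity_level:
        best = max(purity(float(tk)) for tk in grid_t[:10]) if len(grid_t) else 0.0
        raise ValueError(
            "requested purity unattainable at any cut (co-eluting peaks); "
            f"max early purity ~ {best:.4f}"
        )
    return float(brentq(lambda s: purity(s) - spec.purity_level, t_lo, t_hi,
                        xtol=1e-10, rtol=1e-14))


def productivity(chrom: Chromatogram, spec: FractionationSpec,
                 xi_cyc: float, xi_cut: float) -> float:
    """Reduced productivity ``Y^Pr = c_inj * collected / xi^cyc``."""
    spec = spec or FractionationSpec()
    tgt = spec.target_component - 1
    xi1, _ = elution_window(chrom, spec)
    m1 = float(_cumulative(chrom, xi1)(xi_cut)[tgt])
    c_inj = chrom.config.components[tgt].c_inj
    return c_inj * m1 / xi_cyc


def recovery_yield(chrom: Chromatogram, spec: FractionationSpec,
                   xi_cut: float) -> float:
    """Recovery yield ``Y = collected / (c_inj * xi_inj)``."""
    spec = spec or FractionationSpec()
    tgt = spec.target_component - 1
    xi1, _ = elution_window(chrom, spec)
    m1 = float(_cumulative(chrom, xi1)(xi_cut)[tgt])
    comp = chrom.config.components[tgt]
    return m1 / (comp.c_inj * chrom.config.xi_inj)


def analyze(chrom: Chromatogram,
            spec: FractionationSpec | None = None) -> PerformanceMetrics:
    """All fractionation metrics of one chromatogram."""
    spec = spec or FractionationSpec()
    tgt = spec.target_component - 1
    xi1, xi2 = elution_window(chrom, spec)
    xi_cyc = xi2 - xi1
    xi_cut = cut_time(chrom, spec)
    cum = _cumulative(chrom, xi1)
    m = cum(xi_cut)
    m1 = float(m[tgt])
    tot = float(m.sum())
    comp = chrom.config.components[tgt]
    return PerformanceMetrics(
        cycle_time=xi_cyc,
        cut_time=xi_cut,
        productivity=comp.c_inj * m1 / xi_cyc,
        recovery_yield=m1 / (comp.c_inj * chrom.config.xi_inj),
        achieved_purity=m1 / tot if tot > 0.0 else 1.0,
        collected_amount=comp.c_inj * m1,
        xi1=xi1,
        xi2=xi2,
        peak_outlet=tuple(float(v) for v in chrom.outlet.max(axis=1)),
    )


# ---------------------------------------------------------------------------
# parameter sweeps
# ---------------------------------------------------------------------------

_SCAN_PARAMS = ("core_fraction", "c_inj", "bi", "eta")


def scan(param: str, values, base_config: ColumnConfig,
         grid: Grid | None = None, scheme: SchemeConfig | None = None,
         controls: TimeControls | None = None,
         spec: FractionationSpec | None = None,
         n_jobs: int = 1) -> pd.DataFrame:
    """Run simulate + metrics for each value of ``param``.

    Returns a tidy long-format table (one row per value, input order).  A
    failing run is recorded in its row's ``error`` column and the scan
    continues.  ``n_jobs != 1`` fans runs out over processes via joblib with
    order-stable results.
    """
    if param not in _SCAN_PARAMS:
        raise ValueError(f"scan parameter must be one of {_SCAN_PARAMS}, got {param!r}")
    values = [float(v) for v in values]
    if not values:
        raise ValueError("empty scan value list")
    spec = spec or FractionationSpec()

    def one(value: float) -> dict:
        row: dict = {"scan_param": param, "value": value}
        try:
            cfg = base_config.with_overrides(**{param: value})
            # controls with t_end=None lets simulate size the window per value
            chrom, _ = simulate(cfg, grid=grid, scheme=scheme, controls=controls)
            met = analyze(chrom, spec)
            row.update(
                xi_cyc=met.cycle_time,
                xi_cut=met.cut_time,
                productivity=met.productivity,
                yield_=met.recovery_yield,
                achieved_purity=met.achieved_purity,
                error="",
            )
        except Exception as exc:  # noqa: BLE001 — per-row failure is recorded
            row.update(
                xi_cyc=np.nan, xi_cut=np.nan, productivity=np.nan,
                yield_=np.nan, achieved_purity=np.nan, error=str(exc),
            )
        return row

    if n_jobs == 1:
        rows = [one(v) for v in values]
    else:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(delayed(one)(v) for v in values)
    return pd.DataFrame(rows)
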