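"""Heat-flux saturation curve and areal/global carbon-budget arithmetic.

Chemoorganotrophic (heterotrophic) production in a non-buoyant plume
saturates with the vent heat flux Q (MW):

    HP(Q) = a Q / (K + Q)        [ugC L-1 d-1]

The global mean rate is the integral average of this curve between the
surrounding-seawater heat flux and the global vent heat flux, using the
analytic primitive a Q - a K ln(Q + K).  The areal and global budgets are
plain volume x rate arithmetic over plume geometries and active-vent
counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


class BudgetError(ValueError):
    pass


@dataclass
class HeatFluxCurve:
    """Saturation curve HP = a Q / (K + Q)."""

    a: float = 0.0123    # asymptotic rate, ugC L-1 d-1
    K: float = 5.987     # half-saturation heat flux, MW

    def __post_init__(self):
        if self.a <= 0 or self.K <= 0:
            raise BudgetError("curve parameters must be positive")


@dataclass
class FitResult:
    curve: HeatFluxCurve
    residual_se: float
    correlation: float
    n: int
    identifiable: bool = True


#: published estimate of the distribution of active vents at mid-ocean ridges
VENT_COUNTS = {"avg": 1305, "min": 713, "max": 1853}


@dataclass
class BudgetScenario:
    """Plume geometry and vent census for the global extrapolation."""

    rate: float = 0.01235            # ugC L-1 d-1
    vent_count: float = VENT_COUNTS["avg"]
    plume_height: float = 200.0      # m
    area_small: float = 1000.0       # km2
    area_large: float = 400e3        # km2
    large_fraction: float = 0.0      # fraction of plumes at the large area

    def __post_init__(self):
        if min(self.rate, self.vent_count, self.plume_height,
               self.area_small, self.area_large) <= 0:
            raise BudgetError("scenario fields must be positive")
        if not 0.0 <= self.large_fraction <= 1.0:
            raise BudgetError("large_fraction must be within [0, 1]")


def hp_of_heatflux(Q: float, curve: HeatFluxCurve | None = None) -> float:
    """Heterotrophic production rate (ugC L-1 d-1) at heat flux Q (MW)."""
    curve = curve or HeatFluxCurve()
    if Q < 0:
        raise BudgetError("heat flux must be >= 0")
    return curve.a * Q / (curve.K + Q)


def _hp_model(q, a, k):
    return a * q / (k + q)


def fit_hp_curve(rates, heat_fluxes, p0=(0.01, 5.0)) -> FitResult:
    """Nonlinear least squares of the saturation curve to (rate, flux) pairs.

    Reports the fitted parameters, residual standard error and the Pearson
    correlation between fitted and observed rates.  A design with no flux
    dependence leaves K unidentifiable and is flagged.
    """
    rates = np.asarray(rates, dtype=float)
    q = np.asarray(heat_fluxes, dtype=float)
    if rates.size != q.size or rates.size < 3:
        raise BudgetError("need >= 3 paired observations")
    if np.ptp(rates) < 1e-15 or np.ptp(q) < 1e-15:
        return FitResult(
            curve=HeatFluxCurve(max(rates.mean(), 1e-12), 1.0),
            residual_se=float(rates.std(ddof=1)) if rates.size > 1 else 0.0,
            correlation=float("nan"), n=int(rates.size), identifiable=False,
        )
    try:
        popt, pcov = curve_fit(
            _hp_model, q, rates, p0=p0, maxfev=20000,
            bounds=([1e-12, 1e-9], [np.inf, np.inf]),
        )
    except RuntimeError as exc:
        raise BudgetError(
            f"saturation-curve fit did not converge (p0={p0}): {exc}"
        ) from exc
    fitted = _hp_model(q, *popt)
    resid = rates - fitted
    dof = max(rates.size - 2, 1)
    rse = float(np.sqrt(np.sum(resid**2) / dof))
    corr = float(np.corrcoef(fitted, rates)[0, 1])
    identifiable = bool(np.isfinite(pcov).all())
    return FitResult(
        curve=HeatFluxCurve(float(popt[0]), float(popt[1])),
        residual_se=rse, correlation=corr, n=int(rates.size),
        identifiable=identifiable,
    )


def _primitive(Q: float, curve: HeatFluxCurve) -> float:
    return curve.a * Q - curve.a * curve.K * math.log(Q + curve.K)


def average_hp(
    curve: HeatFluxCurve | None = None,
    Q_sw: float = 0.001,
    Q_vents: float = 1e6,
) -> float:
    """Integral average of the saturation curve between two heat fluxes (MW).

    Defaults: surrounding-seawater flux 0.001 MW and the global vent heat
    flux ~1e12 W = 1e6 MW.
    """
    curve = curve or HeatFluxCurve()
    if not Q_vents > Q_sw >= 0:
        raise BudgetError("need Q_vents > Q_sw >= 0")
    return (_primitive(Q_vents, curve) - _primitive(Q_sw, curve)) / (
        Q_vents - Q_sw
    )


def areal_production(rate: float, height: float = 200.0) -> float:
    """Depth-integrated production (gC m-2 y-1) from a plume-layer rate.

    ``rate`` in ugC L-1 d-1 (= mgC m-3 d-1), integrated over the plume
    height (m) and a year.
    """
    if rate < 0 or height <= 0:
        raise BudgetError("rate must be >= 0 and height > 0")
    return rate * 1e-3 * height * 365.0


def global_production(scenario: BudgetScenario) -> float:
    """Global plume production (GtC y-1) for one vent-count scenario."""
    area_km2 = (
        scenario.large_fraction * scenario.area_large
        + (1.0 - scenario.large_fraction) * scenario.area_small
    )
    volume_m3 = scenario.vent_count * area_km2 * 1e6 * scenario.plume_height
    # rate ugC/L/d = 1e-3 gC/m3/d
    gc_per_year = volume_m3 * scenario.rate * 1e-3 * 365.0
    return gc_per_year / 1e15


def global_production_table(
    rate: float = 0.01235,
    plume_height: float = 200.0,
    large_fraction_mixed: float = 0.10,
) -> dict:
    """Avg/min/max global budgets for the small and mixed plume scenarios."""
    out = {}
    for label, frac in (("small", 0.0), ("mixed", large_fraction_mixed)):
        out[label] = {
            k: global_production(BudgetScenario(
                rate=rate, vent_count=n, plume_height=plume_height,
                large_fraction=frac,
            ))
            for k, n in VENT_COUNTS.items()
        }
    return out
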