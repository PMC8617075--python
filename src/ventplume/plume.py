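"""1-D Morton-Turner buoyant plume solver.

A turbulent plume released steadily from a vent orifice into a quiescent,
stably stratified water column is integrated in the classic top-hat flux
variables

* volume flux        Q = u r^2
* momentum flux      M = u^2 r^2
* buoyancy flux      B = g (rho_a(z) - rho) / rho_ref * u r^2

with entrainment u_e = alpha_e u and a Froude-dependent entrainment
coefficient alpha_e = alpha_j - (alpha_j - alpha_p) (Fr_p / Fr)^2 blending
the jet and pure-plume regimes.  The governing system is

    dQ/dz = 2 alpha_e sqrt(M)
    dM/dz = B Q / M
    dB/dz = -N^2(z) Q

which conserves the density-deficit flux exactly in an unstratified ambient.
Temperature and salinity are carried as conservative tracers mixed by
entrainment; the dilution is the volume-flux ratio Q(z)/Q(0).

The plume terminates where it has become denser than the ambient (B < 0) and
its vertical momentum is exhausted; that level is reported as the
non-buoyant-plume (NBP) height together with the dilution factor and the
rise time integral dz/u.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

G = 9.81  # gravitational acceleration, m/s2


class PlumeError(ValueError):
    """Domain or solver error in the plume model."""


@dataclass
class VentSource:
    """Physical source terms of one vent orifice."""

    T0: float          # fluid exit temperature, degC
    S0: float          # fluid salinity, psu
    u0: float          # exit velocity, m/s
    r0: float          # vent radius, m
    depth: float       # m below surface

    def __post_init__(self):
        if self.u0 <= 0:
            raise PlumeError("exit velocity must be positive")
        if self.r0 <= 0:
            raise PlumeError("vent radius must be positive")
        if self.depth <= 0:
            raise PlumeError("depth must be positive")


@dataclass
class AmbientColumn:
    """Ambient water column around the plume.

    ``rho_site`` is the ambient density at vent depth, ``rho_ref`` a
    reference density a height ``dz_ref`` above the NBP; together they set
    the stratification frequency.  ``T_sw``/``S_sw`` are the ambient
    temperature (degC) and salinity used for conservative mixing.
    """

    rho_site: float
    rho_ref: float
    dz_ref: float
    T_sw: float = 2.5
    S_sw: float = 35.0

    def __post_init__(self):
        if self.dz_ref <= 0:
            raise PlumeError("dz_ref must be positive")
        if self.rho_site < self.rho_ref:
            raise PlumeError("unstable stratification: rho_site < rho_ref")


@dataclass
class PlumeProfile:
    """Solved plume on a uniform height grid, plus NBP summary."""

    z: np.ndarray
    r: np.ndarray
    u: np.ndarray
    rho: np.ndarray
    T: np.ndarray
    S: np.ndarray
    dilution: np.ndarray
    Fr: np.ndarray
    alpha_e: np.ndarray
    nbp_height: float
    nbp_dilution: float
    rise_time: float
    nbp_T: float = float("nan")
    nbp_S: float = float("nan")


# ---------------------------------------------------------------------------
# Seawater equation of state

# UNESCO EOS-80 one-atmosphere polynomial (Millero & Poisson 1981).
_RW = (999.842594, 6.793952e-2, -9.095290e-3, 1.001685e-4,
       -1.120083e-6, 6.536332e-9)
_A = (0.824493, -4.0899e-3, 7.6438e-5, -8.2467e-7, 5.3875e-9)
_B = (-5.72466e-3, 1.0227e-4, -1.6546e-6)
_C = 4.8314e-4

#: Approximate isothermal compressibility used for the optional pressure
#: correction (1/bar); the solver itself works with densities at one depth.
COMPRESSIBILITY = 4.4e-6

_T_LINEAR = 40.0  # degC; above this the EOS is extrapolated linearly


def _rho_eos80(T: float, S: float) -> float:
    rw = sum(c * T ** i for i, c in enumerate(_RW))
    a = sum(c * T ** i for i, c in enumerate(_A))
    b = sum(c * T ** i for i, c in enumerate(_B))
    return rw + a * S + b * S ** 1.5 + _C * S * S


def seawater_density(T: float, S: float, p: float = 0.0) -> float:
    """Seawater density (kg/m3) from EOS-80; linearised above 40 degC.

    ``p`` is gauge pressure in bar; a constant-compressibility correction is
    applied (default calls use p = 0, i.e. potential density at the vent
    horizon, which is what the Boussinesq solver needs).
    """
    if not (-2.0 <= T <= 400.0):
        raise PlumeError(f"temperature {T} degC outside model range")
    if not (0.0 <= S <= 45.0):
        raise PlumeError(f"salinity {S} outside model range")
    if T <= _T_LINEAR:
        rho0 = _rho_eos80(T, S)
    else:
        # hot hydrothermal end-members: linear extrapolation of the EOS
        # slope at 40 degC (documented approximation; errors here only
        # shift the first few metres of rise)
        eps = 0.5
        slope = (_rho_eos80(_T_LINEAR, S) - _rho_eos80(_T_LINEAR - eps, S)) / eps
        rho0 = _rho_eos80(_T_LINEAR, S) + slope * (T - _T_LINEAR)
    return rho0 * (1.0 + COMPRESSIBILITY * p)


def buoyancy_frequency(col: AmbientColumn) -> float:
    """Stratification (Brunt-Vaisala) frequency squared, s^-2."""
    return (G / col.rho_ref) * (col.rho_site - col.rho_ref) / col.dz_ref


def entrainment_coefficient(
    Fr: float, alpha_j: float = 0.08, alpha_p: float = 0.16, Fr_p: float = 1.6
) -> float:
    """Froude-dependent entrainment alpha_e = a_j - (a_j - a_p)(Fr_p/Fr)^2.

    Fr -> infinity gives the jet value, Fr = Fr_p the pure-plume value.
    ``Fr = 0`` is signalled; the caller substitutes the pure-plume value.
    """
    if Fr == 0:
        raise PlumeError("Froude number is zero (pure-plume regime)")
    return alpha_j - (alpha_j - alpha_p) * (Fr_p / Fr) ** 2


@dataclass
class EntrainmentParams:
    alpha_j: float = 0.08
    alpha_p: float = 0.16
    Fr_p: float = 1.6


def _alpha_of_state(Q, M, B, ent: EntrainmentParams) -> tuple[float, float]:
    """(Froude number, entrainment coefficient) for a plume state."""
    if Q <= 0 or M <= 0:
        return 0.0, ent.alpha_p
    u = M / Q
    r = Q / math.sqrt(M)
    gprime = B / Q  # g (rho_a - rho)/rho_ref * u r^2 / (u r^2)
    if gprime <= 0:
        # neutrally or negatively buoyant: momentum-driven, but the pure
        # plume value is the safe limit near the top
        return 0.0, ent.alpha_p
    fr = u / math.sqrt(gprime * r)
    alpha = entrainment_coefficient(fr, ent.alpha_j, ent.alpha_p, ent.Fr_p)
    # clamp to the physical bracket of the two regimes
    lo, hi = sorted((ent.alpha_j, ent.alpha_p))
    return fr, min(max(alpha, lo), hi)


def integrate_plume(
    src: VentSource,
    col: AmbientColumn,
    n_cells: int = 300,
    ent: EntrainmentParams | None = None,
    rtol: float = 1e-8,
    z_cap: float | None = None,
) -> PlumeProfile:
    """Integrate the plume from the orifice to its neutral-buoyant level.

    The ambient density is linearly stratified, interpolated from
    (rho_site, rho_ref, dz_ref); the uniform case is recovered when the two
    densities coincide.  The profile is reported on ``n_cells`` uniform
    height cells by interpolation of the adaptive solution.
    """
    ent = ent or EntrainmentParams()
    n2 = buoyancy_frequency(col)

    rho_fluid = seawater_density(src.T0, src.S0)
    q0 = src.u0 * src.r0 ** 2
    m0 = src.u0 ** 2 * src.r0 ** 2
    b0 = G * (col.rho_site - rho_fluid) / col.rho_ref * q0

    if b0 <= 0 and src.u0 <= 0:
        raise PlumeError("non-buoyant source with no momentum: no plume")
    if b0 <= 0:
        # dense jet: rises only on momentum; still integrable but flagged
        pass

    def rhs(z, y):
        q, m, b, t_flux, s_flux, tau = y
        q = max(q, 1e-30)
        m = max(m, 1e-30)
        _, alpha = _alpha_of_state(q, m, b, ent)
        dq = 2.0 * alpha * math.sqrt(m)
        dm = b * q / m
        db = -n2 * q
        u = m / q
        return [dq, dm, db, dq * col.T_sw, dq * col.S_sw, 1.0 / max(u, 1e-12)]

    # terminate once the vertical velocity has collapsed: u_max >= u0, so
    # u <= 1e-3 u0 is guaranteed to lie above the 1%-of-maximum NBP level
    def momentum_exhausted(z, y):
        return y[1] / max(y[0], 1e-30) - 1e-3 * src.u0

    momentum_exhausted.terminal = True
    momentum_exhausted.direction = -1

    if z_cap is None:
        z_cap = max(5.0 * src.depth, 5000.0)
    y0 = [q0, m0, b0, q0 * src.T0, q0 * src.S0, 0.0]
    sol = solve_ivp(
        rhs, (0.0, z_cap), y0, method="RK45", rtol=rtol, atol=1e-12,
        events=momentum_exhausted, dense_output=True, max_step=z_cap / 50.0,
    )
    if not sol.success:
        raise PlumeError(f"plume solver failed: {sol.message}")
    z_top = sol.t[-1]
    if sol.t_events[0].size:
        z_top = float(sol.t_events[0][0])

    z = np.linspace(0.0, z_top, n_cells)
    q, m, b, t_flux, s_flux, tau = sol.sol(z)
    q = np.maximum(q, 1e-30)
    m = np.maximum(m, 1e-30)
    u = m / q
    r = q / np.sqrt(m)
    temp = t_flux / q
    sal = s_flux / q
    dilution = q / q0
    rho_a = col.rho_site - (col.rho_site - col.rho_ref) / col.dz_ref * z
    rho = rho_a - b * col.rho_ref / (G * q)

    fr = np.zeros_like(z)
    alpha = np.zeros_like(z)
    for i in range(n_cells):
        fr[i], alpha[i] = _alpha_of_state(q[i], m[i], b[i], ent)

    # NBP: first grid level where the plume is at least as dense as the
    # ambient and the vertical velocity has collapsed below 1% of its
    # maximum; tie-break toward the lower level.  With the terminal event on
    # momentum this is the top of rise.
    u_max = float(u.max())
    heavy = (b <= 0.0) & (u <= 0.01 * u_max)
    heavy[0] = False
    if heavy.any():
        i_nbp = int(np.argmax(heavy))
    else:
        i_nbp = n_cells - 1
    nbp_height = float(z[i_nbp])
    nbp_dilution = float(dilution[i_nbp])
    rise_time = float(tau[i_nbp])

    return PlumeProfile(
        z=z, r=r, u=u, rho=rho, T=temp, S=sal, dilution=dilution,
        Fr=fr, alpha_e=alpha,
        nbp_height=nbp_height, nbp_dilution=nbp_dilution,
        rise_time=rise_time,
        nbp_T=float(temp[i_nbp]), nbp_S=float(sal[i_nbp]),
    )


FALLBACK_DILUTION = 1e5


def dilute_endmember(
    endmember: dict, seawater: dict, D: float = FALLBACK_DILUTION
) -> dict:
    """Conservative mixing of end-member fluid with seawater at dilution D.

    C_nbp = (C_f + (D - 1) C_sw) / D per species.  Species present in only
    one of the two maps are treated as zero in the other.  When hydrodynamic
    inputs are absent, D defaults to the fallback factor 1e5.
    """
    if D < 1:
        raise PlumeError(f"dilution factor must be >= 1, got {D}")
    out = {}
    for name in set(endmember) | set(seawater):
        cf = endmember.get(name, 0.0)
        csw = seawater.get(name, 0.0)
        out[name] = (cf + (D - 1.0) * csw) / D
    return out
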