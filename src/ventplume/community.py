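"""18-guild Microbial Transition State (MTS) community ODE system.

State vector: 23 chemical species concentrations (mol/m3) followed by 18
guild biomasses (molC/m3).  Dynamics:

    dC/dt = A_met * R_met + A_death * R_death
    A_met = A_ana + A_cat * diag(lambda)
    R_met = diag(mu) X,   R_death = alpha X

with the lambda coupling factors and activity-corrected reaction energies
recomputed at every solver step.  The growth law is the MTS multi-substrate
exponential

    mu = mu_max * prod_i exp( A_met,i / (V_harv [S_i]) )

over consumed species (negative coefficient), excluding the chemostatted
H2O and H+ whose bulk concentrations are not limiting.  mu_max = k_B T / h.

Water and H+ are held fixed during integration (seawater is pH-buffered and
water is the solvent); their activities enter every reaction energy.  The
system conserves carbon exactly by construction (every reaction column is
element-balanced) and numerically to solver tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ventplume.guilds import (
    BIOMASS,
    GuildDefinition,
    HETEROTROPH_NAMES,
    build_matrices,
    default_guilds,
)
from ventplume.species import (
    CHEMOSTAT_SPECIES,
    STATE_SPECIES,
    SpeciesRegistry,
    default_registry,
)
from ventplume.thermodynamics import (
    R_KJ,
    ThermoConditions,
    gibbs_formation,
    lambda_factor,
    log10_gamma,
    water_activity,
)

K_B = 1.380649e-23      # Boltzmann constant, J/K
H_P = 6.62607015e-34    # Planck constant, J s
GC_PER_MOLC = 12.011    # g carbon per mol C

#: molC m-3 s-1  ->  ugC L-1 d-1
RATE_TO_UGC_L_D = GC_PER_MOLC * 86400.0 * 1e3
#: mol m-3 s-1  ->  nmol m-3 d-1
RATE_TO_NMOL_M3_D = 1e9 * 86400.0

SECONDS_PER_DAY = 86400.0

_ACT_FLOOR = 1e-25  # molal floor when evaluating ln Q for absent species


class CommunityError(RuntimeError):
    """Numerical failure in the community simulation."""


def mu_max(T: float) -> float:
    """MTS maximal rate k_B T / h (s^-1)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return K_B * T / H_P


@dataclass
class ModelParams:
    """Tunable parameters of the community model (paper defaults)."""

    V_harv: float = 1000.0           # harvest volume, m3 per mol biomass
    alpha: float = 1.16e-8           # first-order mortality, s^-1
    recycling: tuple = (0.40, 0.10, 0.50)  # DOC_l / DOC_r / POC carbon split
    T: float = 275.65                # K (deep-sea NBP)
    P: float = 300.0                 # bar
    salinity: float = 35.0           # psu, sets ionic strength and a_w
    duration: float = 30 * SECONDS_PER_DAY
    initial_cells: float = 1e5       # cells per ml
    cell_carbon: float = 2e-14       # gC per cell
    guild_fractions: tuple = tuple([1.0 / 18] * 18)
    activity_model: str = "davies"
    mn_dg0_override: float | None = None  # kJ/mol donor, guild 9 catabolism
    rtol: float = 1e-8
    atol: float = 1e-15

    def __post_init__(self):
        if abs(sum(self.recycling) - 1.0) > 1e-9:
            raise ValueError("recycling fractions must sum to 1")
        if abs(sum(self.guild_fractions) - 1.0) > 1e-9:
            raise ValueError("guild fractions must sum to 1")
        for name in ("V_harv", "alpha", "T", "P", "duration",
                     "initial_cells", "cell_carbon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def ionic_strength(self) -> float:
        # seawater-proportional: I = 0.7 mol/kg at S = 35
        return 0.7 * self.salinity / 35.0

    def initial_biomass(self) -> np.ndarray:
        """Guild biomasses (molC/m3) from cell density and carbon quota."""
        total = self.initial_cells * 1e6 * self.cell_carbon / GC_PER_MOLC
        return total * np.asarray(self.guild_fractions, dtype=float)


@dataclass
class CommunityState:
    """Concentrations (mol/m3) + guild biomasses (molC/m3) at time t (s)."""

    C: np.ndarray
    X: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.C.shape != (len(STATE_SPECIES),):
            raise ValueError("concentration vector has wrong length")
        if (self.C < 0).any() or (self.X < 0).any():
            raise ValueError("negative concentrations in community state")

    @property
    def y(self) -> np.ndarray:
        return np.concatenate([self.C, self.X])


def state_from_concentrations(
    concentrations: dict, params: ModelParams
) -> CommunityState:
    """Build the initial state from an NBP composition map."""
    c = np.array(
        [concentrations.get(name, 0.0) for name in STATE_SPECIES], dtype=float
    )
    return CommunityState(C=c, X=params.initial_biomass(), t=0.0)


class _Engine:
    """Precomputed matrices and thermodynamic vectors for one scenario."""

    def __init__(
        self,
        guilds: list[GuildDefinition],
        params: ModelParams,
        registry: SpeciesRegistry | None = None,
    ):
        self.guilds = guilds
        self.params = params
        self.registry = registry or default_registry()
        self.n_sp = len(STATE_SPECIES)
        self.n_g = len(guilds)
        self.A_ana, self.A_cat, self.A_death = build_matrices(
            guilds, self.registry
        )
        cond = ThermoConditions(
            T=params.T, P=params.P, ionic_strength=params.ionic_strength,
            activity_model=params.activity_model,
        )
        # formation energies at in-situ T over [state species..., biomass]
        dgf = [
            gibbs_formation(self.registry[name], cond)
            for name in STATE_SPECIES
        ]
        dgf_bio = gibbs_formation(self.registry[BIOMASS], cond)
        self.dgf_full = np.concatenate(
            [np.asarray(dgf), np.full(self.n_g, dgf_bio)]
        )
        # standard-state reaction energies per guild column
        self.dg0_cat = self.A_cat.T @ self.dgf_full
        self.dg0_ana = self.A_ana.T @ self.dgf_full
        mn = [i for i, g in enumerate(guilds)
              if g.name == "manganese_oxidation"]
        if params.mn_dg0_override is not None and mn:
            self.dg0_cat[mn[0]] = params.mn_dg0_override
        # activity machinery
        self.gamma_log10 = np.array([
            log10_gamma(self.registry[n].charge, params.ionic_strength,
                        params.activity_model)
            for n in STATE_SPECIES
        ])
        self.is_solid = np.array([
            self.registry[n].phase == "solid" for n in STATE_SPECIES
        ])
        self.chemostat = np.array(
            [n in CHEMOSTAT_SPECIES for n in STATE_SPECIES]
        )
        self.ln_aw = math.log(water_activity(params.salinity))
        # pH from the (chemostatted) H+ concentration is set per state
        self.i_h2o = STATE_SPECIES.index("H2O")
        self.i_h = STATE_SPECIES.index("H+")
        self.mu_max = mu_max(params.T)
        self.RT = R_KJ * params.T
        self.dG_diss = np.array([g.dG_diss for g in guilds])
        self.heterotroph = np.array(
            [g.name in HETEROTROPH_NAMES for g in guilds]
        )
        # growth-law exclusion mask over the full state vector: chemostatted
        # species are never counted as limiting substrates
        self.excluded = np.concatenate(
            [self.chemostat, np.zeros(self.n_g, dtype=bool)]
        )

    # -- thermodynamic state -------------------------------------------------

    def ln_activities(self, c: np.ndarray) -> np.ndarray:
        """ln activity over the full state vector (biomass rows -> 0)."""
        molal = np.maximum(c / 1000.0, _ACT_FLOOR)
        ln_a = np.log(molal) + math.log(10.0) * self.gamma_log10
        ln_a[self.is_solid] = 0.0
        ln_a[self.i_h2o] = self.ln_aw
        return np.concatenate([ln_a, np.zeros(self.n_g)])

    def lambdas(self, c: np.ndarray):
        """(lambda vector, active mask, dG_cat, dG_ana) at concentrations c."""
        ln_a = self.ln_activities(c)
        dg_cat = self.dg0_cat + self.RT * (self.A_cat.T @ ln_a)
        dg_ana = self.dg0_ana + self.RT * (self.A_ana.T @ ln_a)
        lam = np.zeros(self.n_g)
        active = np.zeros(self.n_g, dtype=bool)
        for j in range(self.n_g):
            lam[j], active[j] = lambda_factor(
                dg_ana[j], dg_cat[j], self.dG_diss[j]
            )
        return lam, active, dg_cat, dg_ana

    def metabolism(self, c: np.ndarray):
        """(A_met, lambda, active) at concentrations c."""
        lam, active, _, _ = self.lambdas(c)
        a_met = self.A_ana + self.A_cat * lam[np.newaxis, :]
        return a_met, lam, active

    # -- kinetics ------------------------------------------------------------

    def growth_rates(self, c: np.ndarray, a_met: np.ndarray,
                     active: np.ndarray) -> np.ndarray:
        """MTS growth rate per guild (s^-1)."""
        v = self.params.V_harv
        full_c = np.concatenate([c, np.full(self.n_g, np.inf)])
        mu = np.zeros(self.n_g)
        for j in range(self.n_g):
            if not active[j]:
                continue
            cons = (a_met[:, j] < 0) & ~self.excluded
            s = full_c[cons]
            if (s <= 0).any():
                continue
            with np.errstate(over="ignore", divide="ignore"):
                expo = float(np.sum(a_met[cons, j] / (v * s)))
            if expo < -745.0:  # exp underflows to exactly 0
                continue
            mu[j] = self.mu_max * math.exp(expo)
        return mu

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        c = np.maximum(y[: self.n_sp], 0.0)
        x = np.maximum(y[self.n_sp:], 0.0)
        a_met, lam, active = self.metabolism(c)
        mu = self.growth_rates(c, a_met, active)
        r_met = mu * x
        r_death = self.params.alpha * x
        dy = a_met @ r_met + self.A_death @ r_death
        if not np.isfinite(dy).all():
            bad = np.where(~np.isfinite(a_met @ r_met))[0]
            raise CommunityError(
                f"non-finite rate at t={t:.3e}s (rows {bad[:5]})"
            )
        dy[: self.n_sp][self.chemostat] = 0.0
        return dy


def assemble_metabolism(
    guilds: list[GuildDefinition],
    params: ModelParams,
    concentrations: np.ndarray | dict,
    registry: SpeciesRegistry | None = None,
):
    """A_met = A_ana + A_cat diag(lambda) at the given concentrations.

    Returns ``(A_met, lambda, active)`` with rows over the full state
    vector.  Guilds whose catabolism is non-exergonic are flagged inactive
    (their growth rate is forced to 0 downstream).
    """
    eng = _Engine(guilds, params, registry)
    c = _as_vector(concentrations)
    return eng.metabolism(c)


def _as_vector(concentrations) -> np.ndarray:
    if isinstance(concentrations, dict):
        return np.array(
            [concentrations.get(n, 0.0) for n in STATE_SPECIES], dtype=float
        )
    return np.asarray(concentrations, dtype=float)


def growth_rate(
    guild: GuildDefinition,
    a_met_col: dict,
    concentrations: dict,
    params: ModelParams,
    active: bool = True,
) -> float:
    """MTS growth rate (s^-1) for one guild from its metabolism column.

    mu = mu_max(T) * prod over consumed species of exp(A_i / (V_harv [S_i]));
    any consumed substrate at zero concentration gives mu = 0, as does a
    guild flagged inactive by the lambda computation.
    """
    if not active:
        return 0.0
    expo = 0.0
    for name, coef in a_met_col.items():
        if coef >= 0 or name in CHEMOSTAT_SPECIES or name == BIOMASS:
            continue
        s = concentrations.get(name, 0.0)
        if s <= 0:
            return 0.0
        expo += coef / (params.V_harv * s)
    return mu_max(params.T) * math.exp(expo)


def derivative(
    state: CommunityState,
    params: ModelParams,
    guilds: list[GuildDefinition] | None = None,
    registry: SpeciesRegistry | None = None,
) -> np.ndarray:
    """Full right-hand side dC/dt at the given state (mol m-3 s-1)."""
    guilds = guilds or default_guilds()
    eng = _Engine(guilds, params, registry)
    return eng.rhs(state.t, state.y)


@dataclass
class Trajectory:
    """Sampled solution of a community simulation."""

    t: np.ndarray                 # s
    C: np.ndarray                 # (n_t, 23)
    X: np.ndarray                 # (n_t, 18)
    params: ModelParams
    guilds: list
    engine: object = field(repr=False, default=None)

    @property
    def species(self):
        return STATE_SPECIES

    def to_frame(self) -> pd.DataFrame:
        cols = list(STATE_SPECIES) + [f"X_{g.name}" for g in self.guilds]
        df = pd.DataFrame(
            np.hstack([self.C, self.X]), columns=cols
        )
        df.insert(0, "t_s", self.t)
        return df

    def total_carbon(self) -> np.ndarray:
        c_per_species = np.array(
            [self.engine.registry[n].element_count("C")
             for n in STATE_SPECIES]
        )
        return self.C @ c_per_species + self.X.sum(axis=1)


def simulate(
    initial: CommunityState,
    params: ModelParams,
    guilds: list[GuildDefinition] | None = None,
    registry: SpeciesRegistry | None = None,
    n_samples: int = 400,
) -> Trajectory:
    """Stiff adaptive integration of the community over params.duration.

    Sampling is log-spaced early (the thermodynamic relaxation of fresh
    substrate can be fast) and linear late.  Non-negativity is enforced by
    evaluating rates on clipped concentrations; the MTS exponential itself
    drives consumption rates to zero before a substrate is exhausted.
    """
    guilds = guilds or default_guilds()
    eng = _Engine(guilds, params, registry)
    t_end = params.duration
    t_log = np.geomspace(max(t_end * 1e-6, 1e-3), t_end, n_samples // 2)
    t_lin = np.linspace(0.0, t_end, n_samples - n_samples // 2)
    t_eval = np.unique(np.concatenate([[0.0], t_log, t_lin]))
    sol = solve_ivp(
        eng.rhs, (0.0, t_end), initial.y, method="BDF",
        rtol=params.rtol, atol=params.atol, t_eval=t_eval,
    )
    if not sol.success:
        raise CommunityError(
            f"community solver failed: {sol.message}; "
            f"last state at t={sol.t[-1]:.3e}s"
        )
    y = np.maximum(sol.y.T, 0.0)
    return Trajectory(
        t=sol.t, C=y[:, : eng.n_sp], X=y[:, eng.n_sp:],
        params=params, guilds=guilds, engine=eng,
    )


def production_rates(
    traj: Trajectory,
    guilds: list[GuildDefinition] | None = None,
    params: ModelParams | None = None,
) -> dict:
    """Derived production reporters from a trajectory.

    * ``php_ugC_L_d``: prokaryotic heterotrophic production, the
      time-averaged gross anabolic carbon flux into the chemoorganotroph
      guilds.  Computed through the exact budget identity
      integral(mu X) dt = dX + alpha * integral(X) dt, robust to fast
      transients between samples.
    * ``autotrophic_ugC_L_d``: net time-averaged change of summed
      chemolithoautotroph biomass.
    * ``guild_activity_nmol_m3_d``: per-guild catabolic donor consumption
      (lambda mu X averaged over the trajectory).
    """
    guilds = guilds or traj.guilds
    params = params or traj.params
    eng = traj.engine
    t = traj.t
    span = t[-1] - t[0]
    if span <= 0 or len(t) < 2:
        raise ValueError("trajectory must cover a positive time span")
    het = eng.heterotroph
    # gross anabolic flux via the budget identity (per guild)
    int_x = np.trapezoid(traj.X, t, axis=0)
    gross = traj.X[-1] - traj.X[0] + params.alpha * int_x
    gross_rate = gross / span                        # molC m-3 s-1 per guild
    php = float(gross_rate[het].sum() * RATE_TO_UGC_L_D)
    auto_net = float(
        (traj.X[-1][~het].sum() - traj.X[0][~het].sum()) / span
        * RATE_TO_UGC_L_D
    )
    # per-guild catabolic donor consumption, sampled
    lam_mu_x = np.zeros((len(t), eng.n_g))
    for k in range(len(t)):
        c = traj.C[k]
        a_met, lam, active = eng.metabolism(c)
        mu = eng.growth_rates(c, a_met, active)
        lam_mu_x[k] = lam * mu * traj.X[k]
    donor_rate = np.trapezoid(lam_mu_x, t, axis=0) / span
    activity = {
        g.name: float(donor_rate[j] * RATE_TO_NMOL_M3_D)
        for j, g in enumerate(guilds)
    }
    gross_by_guild = {
        g.name: float(gross_rate[j] * RATE_TO_UGC_L_D)
        for j, g in enumerate(guilds)
    }
    return {
        "php_ugC_L_d": php,
        "autotrophic_ugC_L_d": auto_net,
        "guild_activity_nmol_m3_d": activity,
        "guild_gross_ugC_L_d": gross_by_guild,
    }


def run_community(
    concentrations: dict,
    params: ModelParams,
    guilds: list[GuildDefinition] | None = None,
    registry: SpeciesRegistry | None = None,
) -> tuple[Trajectory, dict]:
    """Convenience wrapper: initial state -> trajectory -> rates."""
    guilds = guilds or default_guilds()
    state = state_from_concentrations(concentrations, params)
    traj = simulate(state, params, guilds, registry)
    return traj, production_rates(traj)


SWEEP_BOUNDS = {
    "T": (275.15, 323.15),        # 2-50 degC
    "salinity": (15.0, 45.0),
    "P": (100.0, 500.0),
    "V_harv": (1000.0, 10000.0),
    "alpha": (0.1e-8, 1e-6),
}


def sensitivity_sweep(
    base: ModelParams,
    concentrations: dict,
    ranges: dict,
    guilds: list[GuildDefinition] | None = None,
) -> pd.DataFrame:
    """Grid sweep re-running the simulation; % change in production vs base.

    ``ranges`` maps a ModelParams field name to an iterable of values, each
    within the documented sweep bounds.
    """
    guilds = guilds or default_guilds()
    _, base_rates = run_community(concentrations, base, guilds)
    base_php = base_rates["php_ugC_L_d"]
    base_guild = base_rates["guild_gross_ugC_L_d"]
    rows = []
    for name, values in ranges.items():
        if name in SWEEP_BOUNDS:
            lo, hi = SWEEP_BOUNDS[name]
            for v in values:
                if not (lo <= v <= hi):
                    raise ValueError(
                        f"{name}={v} outside sweep range [{lo}, {hi}]"
                    )
        for v in values:
            params = replace(base, **{name: v})
            _, rates = run_community(concentrations, params, guilds)
            pct = {
                f"pct_{g}": 100.0 * (rates["guild_gross_ugC_L_d"][g] - r0)
                / r0 if r0 != 0 else 0.0
                for g, r0 in base_guild.items()
            }
            rows.append({
                "param": name,
                "value": v,
                "php_ugC_L_d": rates["php_ugC_L_d"],
                "pct_php": (
                    100.0 * (rates["php_ugC_L_d"] - base_php) / base_php
                    if base_php != 0 else 0.0
                ),
                **pct,
            })
    return pd.DataFrame(rows)
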