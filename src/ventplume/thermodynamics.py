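"""Gibbs-energy machinery for the microbial growth model.

Covers formation energies at in-situ temperature (Gibbs-Helmholtz with
constant-enthalpy approximation), activity-corrected reaction energies
(mass-action ratio), ion activity coefficients (Davies or B-dot extended
Debye-Hueckel), the Heijnen dissipation-energy correlation and the
Kleerebezem lambda factor coupling catabolism to anabolism.

Conventions
-----------
* Energies in kJ/mol; anabolic and dissipation energies per mol of C-biomass,
  catabolic energies per mol of electron donor (matching the normalisation of
  the stoichiometry vectors).
* Solids and biomass have unit activity.  Water activity follows a linear
  salinity rule a_w = 1 - 0.000537 S (configurable).
* Pressure correction of formation energies is a no-op by default: the model
  operates at a single depth and the deep-sea pressure shift is a documented
  approximation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ventplume.species import SpeciesRecord, SpeciesRegistry, RegistryError

R_KJ = 8.314462618e-3   # gas constant, kJ/(mol K)
T_REF = 298.15          # reference temperature, K
DAVIES_A = 0.509        # Debye-Hueckel A parameter (25 C value, kept fixed)
BDOT_B = 0.3283         # extended Debye-Hueckel B (1/(angstrom sqrt(molal)))
BDOT_A_RING = 4.0       # generic ion-size parameter, angstrom
BDOT_COEF = 0.041       # B-dot coefficient
WATER_ACTIVITY_SLOPE = 0.000537  # a_w = 1 - slope * S


class ThermoError(ValueError):
    """Domain error in a thermodynamic computation."""


@dataclass
class ThermoConditions:
    """In-situ temperature/pressure/ionic-strength and species activities.

    ``activities`` maps species name to dimensionless activity; species
    missing from the map default to unit activity.
    """

    T: float = T_REF
    P: float = 1.0
    ionic_strength: float = 0.0
    activities: dict = field(default_factory=dict)
    activity_model: str = "davies"

    def __post_init__(self):
        if self.T <= 0:
            raise ThermoError(f"temperature must be positive, got {self.T}")
        if self.P <= 0:
            raise ThermoError(f"pressure must be positive, got {self.P}")
        if self.ionic_strength < 0:
            raise ThermoError("ionic strength must be >= 0")
        for name, a in self.activities.items():
            if a <= 0:
                raise ThermoError(f"non-positive activity for {name}")

    def activity(self, name: str) -> float:
        return self.activities.get(name, 1.0)


def gibbs_formation(species: SpeciesRecord, cond: ThermoConditions) -> float:
    """Formation energy (kJ/mol) at in-situ T via Gibbs-Helmholtz.

    dGf(T) = dGf(T0) * T/T0 + dHf(T0) * (1 - T/T0)  (dCp = 0 approximation).
    Species without an enthalpy keep their reference value.  Pressure is a
    no-op by default.
    """
    if cond.T <= 0:
        raise ThermoError("temperature must be positive")
    tau = cond.T / T_REF
    if species.dHf0 is None:
        return species.dGf0
    return species.dGf0 * tau + species.dHf0 * (1.0 - tau)


def reaction_delta_g(
    stoich: dict,
    cond: ThermoConditions,
    registry: SpeciesRegistry,
) -> float:
    """Activity-corrected reaction energy dG = dG0(T) + RT ln Q in kJ.

    ``stoich`` maps species name to signed coefficient (products positive).
    The energy is per mole of whichever species is normalised to +-1 in the
    input; the caller owns that convention.
    """
    if not stoich or all(v == 0 for v in stoich.values()):
        warnings.warn("empty stoichiometry: reaction energy is 0", stacklevel=2)
        return 0.0
    dg0 = 0.0
    ln_q = 0.0
    for name, nu in stoich.items():
        rec = registry[name]
        dg0 += nu * gibbs_formation(rec, cond)
        a = cond.activity(name)
        if a <= 0:
            raise ThermoError(f"non-positive activity for {name}")
        ln_q += nu * math.log(a)
    return dg0 + R_KJ * cond.T * ln_q


def log10_gamma(charge: float, ionic_strength: float, model: str = "davies") -> float:
    """log10 activity coefficient of an ion at the given ionic strength."""
    if ionic_strength < 0:
        raise ThermoError("ionic strength must be >= 0")
    if charge == 0 or ionic_strength == 0:
        return 0.0
    sqrt_i = math.sqrt(ionic_strength)
    z2 = charge * charge
    if model == "davies":
        return -DAVIES_A * z2 * (sqrt_i / (1.0 + sqrt_i) - 0.3 * ionic_strength)
    if model == "bdot":
        return (
            -DAVIES_A * z2 * sqrt_i / (1.0 + BDOT_B * BDOT_A_RING * sqrt_i)
            + BDOT_COEF * ionic_strength
        )
    if model == "unit":
        return 0.0
    raise ThermoError(f"unknown activity model {model!r}")


def water_activity(salinity: float, slope: float = WATER_ACTIVITY_SLOPE) -> float:
    """Salinity-linear water activity a_w = 1 - slope * S."""
    return 1.0 - slope * salinity


def activity_set(
    concentrations: dict,
    cond: ThermoConditions,
    registry: SpeciesRegistry,
    salinity: float = 0.0,
) -> dict:
    """Map concentrations (mol/m3) to activities.

    1 m3 of solution is taken as ~1e3 kg of solvent, so molality is
    concentration/1000.  Charged aqueous species get the selected ion
    activity model; neutral aqueous species have unit activity coefficient;
    solids and biomass have activity 1; water activity follows salinity.
    """
    out = {}
    for name, c in concentrations.items():
        if c < 0:
            raise ThermoError(f"negative concentration for {name}")
        rec = registry[name]
        if rec.phase in ("solid",):
            out[name] = 1.0
            continue
        if name == "H2O":
            out[name] = water_activity(salinity)
            continue
        if name == "biomass":
            out[name] = 1.0
            continue
        molality = c / 1000.0
        if molality == 0.0:
            # zero concentration has no defined activity; report 0 so the
            # caller can treat the species as absent (growth law handles it)
            out[name] = 0.0
            continue
        gamma = 10.0 ** log10_gamma(
            rec.charge, cond.ionic_strength, cond.activity_model
        )
        out[name] = gamma * molality
    return out


def heijnen_dissipation(chain_length: float, degree_reduction: float) -> float:
    """Heijnen dissipation energy correlation (kJ per molC biomass).

    dG_diss = 200 + 18 (6 - C)^1.8 + exp{ [(3.8 - gamma)^2]^0.16
                                          * (3.6 + 0.4 C) }
    with C the carbon chain length and gamma the degree of reduction of the
    carbon source.  Total function for chain_length >= 1.
    """
    if chain_length < 1:
        raise ThermoError("chain length must be >= 1")
    c = float(chain_length)
    g = float(degree_reduction)
    power_term = 18.0 * abs(6.0 - c) ** 1.8 if c <= 6 else 0.0
    # printed form: for C > 6 the (6-C)^1.8 term is taken as 0 (the
    # correlation was fitted for chain lengths up to 6)
    exp_term = math.exp(((3.8 - g) ** 2) ** 0.16 * (3.6 + 0.4 * c))
    return 200.0 + power_term + exp_term


def lambda_factor(
    dG_ana: float, dG_cat: float, dG_diss: float
) -> tuple[float, bool]:
    """Kleerebezem coupling: catabolic turnovers per molC biomass.

    Returns ``(lambda, active)``.  A non-exergonic catabolism (dG_cat >= 0)
    cannot fund growth: the guild is flagged inactive and lambda is 0.
    Lambda is clamped at >= 0 (a strongly exergonic anabolism cannot make it
    negative).
    """
    if dG_diss <= 0:
        raise ThermoError("dissipation energy must be positive")
    if dG_cat >= 0:
        return 0.0, False
    lam = -(dG_ana + dG_diss) / dG_cat
    return max(lam, 0.0), True
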