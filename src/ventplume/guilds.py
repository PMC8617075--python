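"""The 18 microbial guilds: catabolic/anabolic stoichiometries and matrices.

Each guild is one metabolism: an energy-yielding catabolic reaction
normalised to consume exactly one mole of electron donor, paired with a
biomass-synthesising anabolic reaction normalised to produce exactly one
mole of C-normalised biomass (C1 H1.8 O0.5 N0.2).  Guilds 1-16 are
chemolithoautotrophs (bicarbonate carbon source), guilds 17-18 are
acetate-based chemoorganotrophs (aerobic respiration and denitrification).

Two printed anabolisms required balance corrections, kept here with the
as-printed variants available for inspection:

* the Mn-oxidiser anabolism consumes 2.1 Mn2+ (printed with 1 Mn2+ against
  2.1 MnO2, short 1.1 Mn and 2.2 charge);
* the nitritation anabolism gains +0.7 NO2- on the product side (the
  printed version loses 0.7 N and 0.7 negative charge).

Mortality converts biomass carbon 40% to labile DOC (acetate-C
equivalents), 10% to refractory DOC and 50% to POC; biomass nitrogen is
released as ammonium.  The detrital pool composition C1 H2/3 O1/6 is chosen
so this reaction closes element and charge balance exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ventplume.species import ELEMENTS, STATE_SPECIES, SpeciesRegistry

BIOMASS = "biomass"

#: default dissipation energies, kJ per molC biomass
DG_DISS_AUTOTROPH = 3500.0     # pathways with reversed electron transport
DG_DISS_AEROBIC_HET = 539.0    # acetate aerobic respiration
DG_DISS_DENITRIF_HET = 557.0   # acetate denitrification

#: shared autotroph anabolism on bicarbonate, per reducing power source
_ANA_HS = {"HS-": -2.1, "HCO3-": -1, "NH4+": -0.2, "H+": -2.9,
           "S0": 2.1, "H2O": 2.5, BIOMASS: 1}
_ANA_H2 = {"H2": -2.1, "HCO3-": -1, "NH4+": -0.2, "H+": -0.8,
           "H2O": 2.5, BIOMASS: 1}
_ANA_CH4 = {"CH4": -0.525, "HCO3-": -1, "NH4+": -0.2, "H+": -0.8,
            "CO2": 0.525, "H2O": 1.45, BIOMASS: 1}
_ANA_ACETATE = {"acetate": -0.525, "NH4+": -0.2, "H+": -0.275,
                "HCO3-": 0.05, "H2O": 0.4, BIOMASS: 1}


class BalanceError(ValueError):
    """A reaction fails element or charge balance."""


@dataclass(frozen=True)
class GuildDefinition:
    """One metabolism: paired catabolic and anabolic stoichiometries."""

    name: str
    donor: str
    catabolic_stoich: dict
    anabolic_stoich: dict
    dG_diss: float
    trophic_class: str  # chemolithoautotroph | chemoorganotroph

    def __post_init__(self):
        if abs(self.catabolic_stoich.get(self.donor, 0.0) + 1.0) > 1e-12:
            raise ValueError(
                f"{self.name}: catabolic donor coefficient must be -1"
            )
        if abs(self.anabolic_stoich.get(BIOMASS, 0.0) - 1.0) > 1e-12:
            raise ValueError(
                f"{self.name}: anabolic biomass coefficient must be +1"
            )


def default_guilds(
    dg_diss_autotroph: float = DG_DISS_AUTOTROPH,
    dg_diss_aerobic: float = DG_DISS_AEROBIC_HET,
    dg_diss_denitrif: float = DG_DISS_DENITRIF_HET,
) -> list[GuildDefinition]:
    """The 18 metabolisms in canonical order."""
    auto = "chemolithoautotroph"
    org = "chemoorganotroph"
    g = []

    g.append(GuildDefinition(
        "sulfide_oxidation", "HS-",
        {"HS-": -1, "O2": -0.5, "H+": -1, "S0": 1, "H2O": 1},
        dict(_ANA_HS), dg_diss_autotroph, auto))
    g.append(GuildDefinition(
        "sulfur_oxidation", "S0",
        {"S0": -1, "O2": -1.5, "H2O": -1, "SO4-2": 1, "H+": 2},
        {"S0": -0.7, "HCO3-": -1, "NH4+": -0.2, "H2O": -0.3,
         "SO4-2": 0.7, "H+": 0.6, BIOMASS: 1},
        dg_diss_autotroph, auto))
    g.append(GuildDefinition(
        "thiosulfate_oxidation", "S2O3-2",
        {"S2O3-2": -1, "O2": -2, "H2O": -1, "SO4-2": 2, "H+": 2},
        {"S2O3-2": -0.525, "HCO3-": -1, "NH4+": -0.2, "H2O": -0.125,
         "SO4-2": 1.05, "H+": 0.25, BIOMASS: 1},
        dg_diss_autotroph, auto))
    g.append(GuildDefinition(
        "methane_oxidation", "CH4",
        {"CH4": -1, "O2": -2, "HCO3-": 1, "H+": 1, "H2O": 1},
        dict(_ANA_CH4), dg_diss_autotroph, auto))
    g.append(GuildDefinition(
        "hydrogen_oxidation_knallgas", "H2",
        {"H2": -1, "O2": -0.5, "H2O": 1},
        dict(_ANA_H2), dg_diss_autotroph, auto))
    # nitritation anabolism corrected: +0.7 NO2- restores N and charge
    g.append(GuildDefinition(
        "nitritation", "NH4+",
        {"NH4+": -1, "O2": -1.5, "NO2-": 1, "H+": 2, "H2O": 1},
        {"NH4+": -0.9, "HCO3-": -1, "NO2-": 0.7, "H+": 0.6, "H2O": 1.1,
         BIOMASS: 1},
        dg_diss_autotroph, auto))
    g.append(GuildDefinition(
        "nitratation", "NO2-",
        {"NO2-": -1, "O2": -0.5, "NO3-": 1},
        {"NO2-": -2.1, "HCO3-": -1, "NH4+": -0.2, "H+": -0.8,
         "NO3-": 2.1, "H2O": 0.4, BIOMASS: 1},
        dg_diss_autotroph, auto))
    g.append(GuildDefinition(
        "iron_oxidation", "Fe+2",
        {"Fe+2": -1, "O2": -0.25, "H2O": -1.5, "FeOOH": 1, "H+": 2},
        {"Fe+2": -4.2, "HCO3-": -1, "NH4+": -0.2, "H+": -5,
         "Fe+3": 4.2, "H2O": 2.5, BIOMASS: 1},
        dg_diss_autotroph, auto))
    # Mn-oxidiser anabolism corrected: 2.1 Mn2+ balances the 2.1 MnO2
    g.append(GuildDefinition(
        "manganese_oxidation", "Mn+2",
        {"Mn+2": -1, "O2": -0.5, "H2O": -1, "MnO2": 1, "H+": 2},
        {"Mn+2": -2.1, "HCO3-": -1, "NH4+": -0.2, "H2O": -1.7,
         "MnO2": 2.1, "H+": 3.4, BIOMASS: 1},
        dg_diss_autotroph, auto))
    g.append(GuildDefinition(
        "sulfide_oxidation_denitrification", "HS-",
        {"HS-": -1, "H+": -1.4, "NO3-": -0.4, "S0": 1, "H2O": 1.2,
         "N2": 0.2},
        dict(_ANA_HS), dg_diss_autotroph, auto))
    g.append(GuildDefinition(
        "sulfide_oxidation_dnra", "HS-",
        {"HS-": -1, "H+": -1.5, "NO3-": -0.25, "S0": 1, "H2O": 0.75,
         "NH4+": 0.25},
        dict(_ANA_HS), dg_diss_autotroph, auto))
    g.append(GuildDefinition(
        "hydrogen_oxidation_denitrification", "H2",
        {"H2": -1, "H+": -0.4, "NO3-": -0.4, "H2O": 1.2, "N2": 0.2},
        dict(_ANA_H2), dg_diss_autotroph, auto))
    g.append(GuildDefinition(
        "hydrogen_oxidation_dnra", "H2",
        {"H2": -1, "H+": -0.5, "NO3-": -0.25, "H2O": 0.75, "NH4+": 0.25},
        dict(_ANA_H2), dg_diss_autotroph, auto))
    g.append(GuildDefinition(
        "hydrogenotrophic_methanogenesis", "H2",
        {"H2": -1, "HCO3-": -0.25, "H+": -0.25, "CH4": 0.25, "H2O": 0.75},
        dict(_ANA_H2), dg_diss_autotroph, auto))
    g.append(GuildDefinition(
        "hydrogenotrophic_sulfate_reduction", "H2",
        {"H2": -1, "SO4-2": -0.25, "H+": -0.25, "HS-": 0.25, "H2O": 1},
        dict(_ANA_H2), dg_diss_autotroph, auto))
    g.append(GuildDefinition(
        "anaerobic_methane_oxidation", "CH4",
        {"CH4": -1, "SO4-2": -1, "HCO3-": 1, "HS-": 1, "H2O": 1},
        dict(_ANA_CH4), dg_diss_autotroph, auto))
    g.append(GuildDefinition(
        "aerobic_acetate_respiration", "acetate",
        {"acetate": -1, "O2": -2, "H+": 1, "HCO3-": 2},
        dict(_ANA_ACETATE), dg_diss_aerobic, org))
    g.append(GuildDefinition(
        "acetate_denitrification", "acetate",
        {"acetate": -1, "NO3-": -1.6, "H+": -0.6, "N2": 0.8, "HCO3-": 2,
         "H2O": 0.8},
        dict(_ANA_ACETATE), dg_diss_denitrif, org))
    return g


HETEROTROPH_NAMES = ("aerobic_acetate_respiration", "acetate_denitrification")


def death_stoichiometry() -> dict:
    """Mortality recycling per mol biomass-C: 40/10/50 C split.

    -1 biomass -> 0.2 acetate (0.4 C as labile DOC) + 0.1 DOC_r + 0.5 POC
    + 0.2 NH4+; closes exactly with the detrital pool composition
    C1 H2/3 O1/6 (no residual water, protons or reductant).
    """
    return {BIOMASS: -1, "acetate": 0.2, "DOC_r": 0.1, "POC": 0.5,
            "NH4+": 0.2}


def check_balance(
    stoich: dict, registry: SpeciesRegistry, tol: float = 1e-6,
    label: str = "reaction",
) -> None:
    """Element and charge balance of a signed stoichiometry map."""
    for el in ELEMENTS:
        resid = sum(
            nu * registry[name].element_count(el)
            for name, nu in stoich.items()
        )
        if abs(resid) > tol:
            raise BalanceError(
                f"{label}: element {el} unbalanced by {resid:.3e}"
            )
    q = sum(nu * registry[name].charge for name, nu in stoich.items())
    if abs(q) > tol:
        raise BalanceError(f"{label}: charge unbalanced by {q:.3e}")


def build_matrices(
    guilds: list[GuildDefinition],
    registry: SpeciesRegistry,
    validate: bool = True,
):
    """(A_ana, A_cat, A_death) over the full state vector.

    Rows are the state species followed by one biomass row per guild;
    columns are guilds.  Every column is element/charge checked against the
    registry composition maps unless ``validate`` is False.
    """
    n_sp = len(STATE_SPECIES)
    n_g = len(guilds)
    r = n_sp + n_g
    a_ana = np.zeros((r, n_g))
    a_cat = np.zeros((r, n_g))
    a_death = np.zeros((r, n_g))
    idx = {name: i for i, name in enumerate(STATE_SPECIES)}
    death = death_stoichiometry()

    for j, guild in enumerate(guilds):
        if validate:
            check_balance(guild.catabolic_stoich, registry,
                          label=f"{guild.name} catabolism")
            check_balance(guild.anabolic_stoich, registry,
                          label=f"{guild.name} anabolism")
            check_balance(death, registry, label="mortality recycling")
        for stoich, mat in (
            (guild.catabolic_stoich, a_cat),
            (guild.anabolic_stoich, a_ana),
            (death, a_death),
        ):
            for name, nu in stoich.items():
                if name == BIOMASS:
                    mat[n_sp + j, j] = nu
                else:
                    if name not in idx:
                        raise BalanceError(
                            f"{guild.name}: species {name} not a state species"
                        )
                    mat[idx[name], j] += nu
    return a_ana, a_cat, a_death
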