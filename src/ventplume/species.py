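"""Chemical species registry with embedded formation-energy table.

The registry holds every chemical species the model can reference: its phase,
charge, elemental composition over {C, H, O, N, S, Fe, Mn} and standard
Gibbs energy / enthalpy of formation at 25 degC, 1 bar.  The default table is
shipped with the package as a delimited text file; a replacement table with
the same columns can be supplied through configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

ELEMENTS = ("C", "H", "O", "N", "S", "Fe", "Mn")
PHASES = frozenset({"aqueous", "solid", "liquid", "gas"})


class RegistryError(KeyError):
    """Raised when a reaction references a species absent from the registry."""


@dataclass(frozen=True)
class SpeciesRecord:
    """One chemical species and its reference-state formation properties.

    ``dGf0``/``dHf0`` are in kJ/mol at 298.15 K, 1 bar.  ``dHf0`` may be None
    for inert bookkeeping pools that never enter an energy calculation.
    """

    name: str
    phase: str
    charge: int
    composition: dict = field(default_factory=dict)
    dGf0: float = 0.0
    dHf0: float | None = None

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r} for {self.name}")
        for el, n in self.composition.items():
            if el not in ELEMENTS:
                raise ValueError(f"unknown element {el!r} in {self.name}")
            if n < 0:
                raise ValueError(f"negative {el} count in {self.name}")

    def element_count(self, element: str) -> float:
        return self.composition.get(element, 0.0)


class SpeciesRegistry:
    """Ordered, name-unique collection of :class:`SpeciesRecord`."""

    def __init__(self, records):
        self._records: dict[str, SpeciesRecord] = {}
        for rec in records:
            if rec.name in self._records:
                raise ValueError(f"duplicate species name {rec.name!r}")
            self._records[rec.name] = rec

    def __contains__(self, name: str) -> bool:
        return name in self._records

    def __iter__(self):
        return iter(self._records.values())

    def __len__(self):
        return len(self._records)

    @property
    def names(self) -> list[str]:
        return list(self._records)

    def __getitem__(self, name: str) -> SpeciesRecord:
        try:
            return self._records[name]
        except KeyError:
            raise RegistryError(f"species {name!r} not in registry") from None

    def charge_vector(self, names=None):
        names = self.names if names is None else names
        return [float(self[n].charge) for n in names]

    def element_matrix(self, names=None):
        """element x species count matrix (rows follow ELEMENTS order)."""
        names = self.names if names is None else names
        return [[self[n].element_count(el) for n in names] for el in ELEMENTS]


def _parse_composition(text: str) -> dict:
    comp = {}
    for tok in str(text).split():
        el, _, n = tok.partition(":")
        comp[el] = float(n)
    return comp


def load_registry(path: str | Path) -> SpeciesRegistry:
    """Read a species table (CSV with '#' comments) into a registry."""
    df = pd.read_csv(path, comment="#")
    records = []
    for row in df.itertuples(index=False):
        dHf0 = None if pd.isna(row.dHf0) else float(row.dHf0)
        records.append(
            SpeciesRecord(
                name=str(row.name),
                phase=str(row.phase),
                charge=int(row.charge),
                composition=_parse_composition(row.composition),
                dGf0=float(row.dGf0),
                dHf0=dHf0,
            )
        )
    return SpeciesRegistry(records)


def default_registry() -> SpeciesRegistry:
    """The packaged 23-species registry (+ the biomass pseudo-species)."""
    with resources.as_file(
        resources.files("ventplume").joinpath("data/species.csv")
    ) as p:
        return load_registry(p)


#: Species tracked as concentrations in the community state, in canonical
#: order.  ``biomass`` is thermodynamic only; the 18 guild biomasses are
#: separate state variables.
STATE_SPECIES = (
    "O2", "H+", "H2O", "HS-", "S0", "S2O3-2", "SO4-2", "CH4", "H2",
    "CO2", "HCO3-", "NH4+", "NO2-", "NO3-", "N2", "Fe+2", "Fe+3",
    "FeOOH", "Mn+2", "MnO2", "acetate", "DOC_r", "POC",
)

#: Reservoir species held fixed during integration (seawater is buffered);
#: they carry no carbon and are excluded from the growth-rate product.
CHEMOSTAT_SPECIES = ("H2O", "H+")


def carbon_content(registry: SpeciesRegistry, names=None):
    names = STATE_SPECIES if names is None else names
    return [registry[n].element_count("C") for n in names]
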