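"""Synthetic vent sites: end-member chemistry + hydrodynamic source terms.

Real site tables pair high-temperature end-member fluid chemistry with the
vent's physical source terms and the ambient column.  This module generates
synthetic sites with the same structure in literature-plausible ranges so
the whole pipeline is testable without any download, provides the fixed
deep-seawater background, and implements the literature-override procedure
for NBP substrate concentrations.

The synthetic ranges are stand-ins, not measurements; the hand-written
"TAG-like" fixture site (``tag_like_site``) is labelled synthetic as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ventplume.plume import AmbientColumn, VentSource, seawater_density
from ventplume.species import STATE_SPECIES


class SiteError(ValueError):
    pass


#: fields drawn log-uniformly (ranges span more than a decade)
_LOG_FIELDS = {"H2", "CH4", "Fe+2", "Mn+2", "acetate", "NH4+"}


@dataclass
class SiteTemplate:
    """Sampling ranges for one spreading-regime class of vents.

    Concentration ranges are mol/m3 in the end-member fluid.  ``acetate``
    is the labile-DOC carrier (molC arrives as acetate/2 mol).
    """

    regime: str = "slow"
    ranges: dict = field(default_factory=lambda: {
        "T0": (300.0, 400.0),        # degC
        "u0": (0.1, 2.0),            # m/s
        "diameter": (0.05, 0.3),     # m
        "depth": (1500.0, 4000.0),   # m
        "HS-": (1.0, 12.0),
        "H2": (0.01, 16.0),
        "CH4": (0.01, 2.5),
        "Fe+2": (0.005, 25.0),
        "Mn+2": (0.05, 2.5),
        "HCO3-": (2.0, 10.0),        # dissolved inorganic carbon
        # effective end-member labile DOC (molC arrives as acetate/2):
        # lumps fluid volatile acids plus diffuse-flow DOC entrained into
        # the rising plume
        "acetate": (0.05, 0.5),
        "NH4+": (0.01, 1.0),
    })
    seed: int = 0

    def __post_init__(self):
        for name, (lo, hi) in self.ranges.items():
            if not (0 < lo <= hi):
                raise SiteError(f"bad range for {name}: ({lo}, {hi})")


@dataclass
class VentSite:
    """One vent: source terms, ambient column, end-member chemistry."""

    name: str
    source: VentSource
    ambient: AmbientColumn
    endmember: dict     # species -> mol/m3 in the end-member fluid


def seawater_background() -> dict:
    """Deep-Atlantic style background: composition (mol/m3), T, S, rho.

    Oxic deep seawater: reduced species are absent; nutrients and carbonate
    at typical bathypelagic values.  Labile DOC is carried as acetate at the
    tens-of-nanomolar level typical of the deep ocean (5e-5 mol/m3 acetate =
    1e-4 molC/m3).  The listed subset is not a full seawater speciation, so
    its net charge is not zero; only the species the model tracks appear.
    Deterministic (no RNG).
    """
    comp = {name: 0.0 for name in STATE_SPECIES}
    comp.update({
        "O2": 0.25,
        "NO3-": 0.021,
        "NO2-": 5e-6,
        "SO4-2": 28.0,
        "HCO3-": 2.2,
        "CO2": 0.01,
        "NH4+": 5e-5,
        "acetate": 5e-5,
        "N2": 0.59,
        "H+": 10 ** (-7.8) * 1000.0,   # ~pH 7.8 (chemostatted)
        "H2O": 55000.0,
    })
    T, S = 2.5, 35.0
    return {
        "composition": comp,
        "T": T,
        "S": S,
        "rho": seawater_density(T, S),
    }


def _draw(rng: np.random.Generator, lo: float, hi: float,
          log: bool) -> float:
    if lo == hi:
        return lo
    if log:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return float(rng.uniform(lo, hi))


def generate_site(
    template: SiteTemplate, seed: int | None = None, name: str | None = None
) -> VentSite:
    """Draw one synthetic vent site; reproducible under a fixed seed."""
    seed = template.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    draws = {}
    for field_name, (lo, hi) in template.ranges.items():
        draws[field_name] = _draw(
            rng, lo, hi, field_name in _LOG_FIELDS
        )
    bg = seawater_background()
    depth = draws["depth"]
    source = VentSource(
        T0=draws["T0"], S0=bg["S"], u0=draws["u0"],
        r0=draws["diameter"] / 2.0, depth=depth,
    )
    rho_site = bg["rho"]
    # deep-ocean stratification: density decreasing upward with an abyssal
    # N ~ 0.7e-3 s^-1 over the reference separation
    dz_ref = 500.0
    drho = rho_site / 9.81 * (0.7e-3) ** 2 * dz_ref  # from N^2 definition
    ambient = AmbientColumn(
        rho_site=rho_site, rho_ref=rho_site - drho, dz_ref=dz_ref,
        T_sw=bg["T"], S_sw=bg["S"],
    )
    endmember = {name_: 0.0 for name_ in STATE_SPECIES}
    for sp in ("HS-", "H2", "CH4", "Fe+2", "Mn+2", "HCO3-", "acetate",
               "NH4+"):
        endmember[sp] = draws[sp]
    endmember["H2O"] = 55000.0
    endmember["H+"] = 10 ** (-4.0) * 1000.0  # acidic end-member, pH ~ 4
    return VentSite(
        name=name or f"{template.regime}_site_{seed}",
        source=source, ambient=ambient, endmember=endmember,
    )


def tag_like_site() -> VentSite:
    """Hand-written synthetic fixture resembling a TAG-style black smoker.

    Values are literature-plausible for a slow-spreading Mid-Atlantic Ridge
    high-temperature vent; this is a synthetic stand-in, not the measured
    site table.
    """
    bg = seawater_background()
    source = VentSource(T0=363.0, S0=35.0, u0=1.0, r0=0.075, depth=3650.0)
    dz_ref = 500.0
    drho = bg["rho"] / 9.81 * (0.7e-3) ** 2 * dz_ref
    ambient = AmbientColumn(
        rho_site=bg["rho"], rho_ref=bg["rho"] - drho, dz_ref=dz_ref,
        T_sw=bg["T"], S_sw=bg["S"],
    )
    endmember = {name: 0.0 for name in STATE_SPECIES}
    endmember.update({
        "HS-": 3.5, "H2": 0.15, "CH4": 0.15, "Fe+2": 5.0, "Mn+2": 0.7,
        "HCO3-": 3.0, "acetate": 0.5, "NH4+": 0.1,
        "H2O": 55000.0, "H+": 0.1,
    })
    return VentSite(
        name="TAG_like_synthetic", source=source, ambient=ambient,
        endmember=endmember,
    )


#: the species whose NBP concentrations the literature-override procedure
#: may replace
OVERRIDABLE = ("CH4", "H2", "Fe+2", "Mn+2", "HS-", "NH4+", "NO3-", "NO2-")


def apply_overrides(nbp: dict, overrides: dict) -> tuple[dict, dict]:
    """Replace listed NBP species concentrations; returns (updated, deltas).

    Emulates the procedure of substituting literature values for predicted
    NBP substrate concentrations.  Unknown species raise; the delta map
    records old -> new for every override, including zero deltas.
    """
    updated = dict(nbp)
    deltas = {}
    for name, value in overrides.items():
        if name not in nbp:
            raise SiteError(f"override of unknown species {name!r}")
        deltas[name] = value - nbp[name]
        updated[name] = value
    return updated, deltas


# ---------------------------------------------------------------------------
# site-table I/O (the exact CSV layout consumed by the plume stage)

_PHYS_COLS = [
    "name", "T0_C", "S0_psu", "u0_m_s", "vent_diameter_m", "depth_m",
    "rho_site", "rho_ref", "dz_ref",
]


def sites_to_frame(sites: list[VentSite]) -> pd.DataFrame:
    rows = []
    for s in sites:
        row = {
            "name": s.name,
            "T0_C": s.source.T0,
            "S0_psu": s.source.S0,
            "u0_m_s": s.source.u0,
            "vent_diameter_m": 2.0 * s.source.r0,
            "depth_m": s.source.depth,
            "rho_site": s.ambient.rho_site,
            "rho_ref": s.ambient.rho_ref,
            "dz_ref": s.ambient.dz_ref,
        }
        for name in STATE_SPECIES:
            row[f"em_{name}"] = s.endmember.get(name, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def write_site_table(sites: list[VentSite], path) -> None:
    sites_to_frame(sites).to_csv(path, index=False)


def read_site_table(path) -> list[VentSite]:
    df = pd.read_csv(path)
    missing = [c for c in _PHYS_COLS if c not in df.columns]
    if missing:
        raise SiteError(f"site table missing columns: {missing}")
    bg = seawater_background()
    sites = []
    for row in df.to_dict("records"):
        source = VentSource(
            T0=row["T0_C"], S0=row["S0_psu"], u0=row["u0_m_s"],
            r0=row["vent_diameter_m"] / 2.0, depth=row["depth_m"],
        )
        ambient = AmbientColumn(
            rho_site=row["rho_site"], rho_ref=row["rho_ref"],
            dz_ref=row["dz_ref"], T_sw=bg["T"], S_sw=bg["S"],
        )
        endmember = {
            name: float(row.get(f"em_{name}", 0.0))
            for name in STATE_SPECIES
        }
        sites.append(VentSite(
            name=str(row["name"]), source=source, ambient=ambient,
            endmember=endmember,
        ))
    return sites
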