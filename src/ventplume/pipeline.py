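"""Configuration and orchestration: the full site -> plume -> community ->
budget pipeline, plus deterministic file output.

The stages mirror the study design: per site, solve the buoyant plume (or
fall back to the fixed 1e5 dilution when hydrodynamic inputs are missing),
dilute the end-member chemistry into the non-buoyant plume, run the 30-day
community simulation, report production rates; then aggregate the site
rates against per-vent heat flux and evaluate the areal/global budgets.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ventplume.budget import (
    BudgetScenario,
    HeatFluxCurve,
    average_hp,
    areal_production,
    fit_hp_curve,
    global_production_table,
)
from ventplume.community import ModelParams, run_community
from ventplume.plume import (
    EntrainmentParams,
    FALLBACK_DILUTION,
    PlumeError,
    dilute_endmember,
    integrate_plume,
)
from ventplume.species import load_registry, default_registry
from ventplume.synthetic_sites import (
    VentSite,
    read_site_table,
    seawater_background,
)

log = logging.getLogger("ventplume")

SEAWATER_CP = 4000.0  # J/(kg K), representative for the heat-flux estimate
FLUID_RHO_FOR_HEAT = 700.0  # kg/m3, hot end-member scale


@dataclass
class HydroConfig:
    alpha_j: float = 0.08
    alpha_p: float = 0.16
    Fr_p: float = 1.6
    n_cells: int = 300
    fallback_dilution: float = FALLBACK_DILUTION


@dataclass
class BudgetConfig:
    rate: float | None = None      # None -> use fitted/average pipeline rate
    plume_height: float = 200.0
    area_small: float = 1000.0
    area_large: float = 400e3
    large_fraction_mixed: float = 0.10
    Q_sw: float = 0.001            # MW (seawater heat flux)
    Q_vents: float = 1e6           # MW (global vent heat flux, ~1e12 W)


@dataclass
class RunConfig:
    site_table_path: str | None = None
    species_registry_path: str | None = None
    model: ModelParams = field(default_factory=ModelParams)
    hydro: HydroConfig = field(default_factory=HydroConfig)
    budget: BudgetConfig = field(default_factory=BudgetConfig)
    output_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        model = ModelParams(**raw.pop("model", {}))
        hydro = HydroConfig(**raw.pop("hydro", {}))
        budget = BudgetConfig(**raw.pop("budget", {}))
        return cls(model=model, hydro=hydro, budget=budget, **raw)

    def digest(self) -> str:
        blob = json.dumps(
            {
                "site_table_path": self.site_table_path,
                "species_registry_path": self.species_registry_path,
                "model": asdict(self.model),
                "hydro": asdict(self.hydro),
                "budget": asdict(self.budget),
                "seed": self.seed,
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def vent_heat_flux_mw(site: VentSite) -> float:
    """Per-vent heat output (MW) from the source terms.

    Q_heat = rho cp (u0 pi r0^2) (T0 - T_sw); a coarse but standard
    single-orifice estimate used as the predictor of the saturation curve.
    """
    q0 = site.source.u0 * math.pi * site.source.r0 ** 2
    dT = site.source.T0 - site.ambient.T_sw
    return FLUID_RHO_FOR_HEAT * SEAWATER_CP * q0 * dT / 1e6


def run_site(
    site: VentSite,
    model: ModelParams,
    hydro: HydroConfig | None = None,
    registry=None,
) -> dict:
    """Plume solve + NBP chemistry + community simulation for one site."""
    hydro = hydro or HydroConfig()
    bg = seawater_background()
    result = {"site": site.name, "heat_flux_MW": vent_heat_flux_mw(site)}
    try:
        profile = integrate_plume(
            site.source, site.ambient, n_cells=hydro.n_cells,
            ent=EntrainmentParams(hydro.alpha_j, hydro.alpha_p, hydro.Fr_p),
        )
        dilution = profile.nbp_dilution
        result.update(
            nbp_height_m=profile.nbp_height,
            nbp_dilution=dilution,
            rise_time_s=profile.rise_time,
            nbp_T_C=profile.nbp_T,
            nbp_S_psu=profile.nbp_S,
        )
    except PlumeError as exc:
        log.warning("site %s: plume solve failed (%s); fallback dilution",
                    site.name, exc)
        dilution = hydro.fallback_dilution
        result.update(
            nbp_height_m=float("nan"), nbp_dilution=dilution,
            rise_time_s=float("nan"),
            nbp_T_C=bg["T"], nbp_S_psu=bg["S"],
        )
    nbp = dilute_endmember(site.endmember, bg["composition"], dilution)
    t_nbp = result.get("nbp_T_C", bg["T"])
    params = replace(model, T=273.15 + t_nbp)
    traj, rates = run_community(nbp, params, registry=registry)
    result.update(
        php_ugC_L_d=rates["php_ugC_L_d"],
        autotrophic_ugC_L_d=rates["autotrophic_ugC_L_d"],
    )
    result["nbp"] = nbp
    result["rates"] = rates
    return result


def run_seawater_reference(model: ModelParams, registry=None) -> dict:
    """Background deep-seawater community run (no vent input)."""
    bg = seawater_background()
    params = replace(model, T=273.15 + bg["T"])
    traj, rates = run_community(bg["composition"], params, registry=registry)
    return {
        "site": "seawater",
        "php_ugC_L_d": rates["php_ugC_L_d"],
        "autotrophic_ugC_L_d": rates["autotrophic_ugC_L_d"],
        "rates": rates,
    }


def _fmt(x) -> str:
    """Fixed scientific notation, 9 significant digits (stable diffs)."""
    if isinstance(x, float):
        return f"{x:.8e}"
    return str(x)


def run_pipeline(config: RunConfig) -> dict:
    """Full pipeline: all sites, background, curve fit, budget; writes
    artifacts + manifest under ``config.output_dir``."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    registry = (
        load_registry(config.species_registry_path)
        if config.species_registry_path else default_registry()
    )

    sites = []
    if config.site_table_path:
        sites = read_site_table(config.site_table_path)
    if not sites:
        log.warning("empty site table: producing empty results")

    site_rows, failures = [], []
    for site in sites:
        try:
            res = run_site(site, config.model, config.hydro, registry)
            site_rows.append(
                {k: v for k, v in res.items() if not isinstance(v, dict)}
            )
        except Exception as exc:  # per-site isolation
            log.error("site %s failed: %s", site.name, exc)
            failures.append({"site": site.name, "error": str(exc)})

    sw = run_seawater_reference(config.model, registry)

    summary = {
        "seawater_php_ugC_L_d": sw["php_ugC_L_d"],
        "n_sites": len(site_rows),
        "n_failures": len(failures),
    }

    curve = HeatFluxCurve()
    if len(site_rows) >= 3:
        fit = fit_hp_curve(
            [r["php_ugC_L_d"] for r in site_rows],
            [r["heat_flux_MW"] for r in site_rows],
        )
        summary["fit_a"] = fit.curve.a
        summary["fit_K_MW"] = fit.curve.K
        summary["fit_residual_se"] = fit.residual_se
        summary["fit_correlation"] = fit.correlation
        if fit.identifiable:
            curve = fit.curve

    bcfg = config.budget
    mean_rate = average_hp(curve, bcfg.Q_sw, bcfg.Q_vents)
    rate = bcfg.rate if bcfg.rate is not None else mean_rate
    summary["average_hp_ugC_L_d"] = mean_rate
    summary["areal_gC_m2_y"] = areal_production(rate, bcfg.plume_height)
    summary["global_GtC_y"] = global_production_table(
        rate, bcfg.plume_height, bcfg.large_fraction_mixed
    )

    # --- artifacts ---------------------------------------------------------
    if site_rows:
        df = pd.DataFrame(site_rows)
        num = df.select_dtypes("number").columns
        df[num] = df[num].map(lambda v: float(f"{v:.8e}"))
        df.to_csv(out_dir / "site_rates.csv", index=False,
                  float_format="%.8e")
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, default=_fmt) + "\n"
    )
    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_sites": len(site_rows),
        "n_failures": len(failures),
        "records": [r["site"] for r in site_rows],
        "failures": failures,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n"
    )
    return {
        "sites": site_rows,
        "seawater": sw,
        "summary": summary,
        "manifest": manifest,
        "failures": failures,
    }
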