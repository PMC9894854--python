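"""Configuration-driven orchestration of the full carbon-export budget.

Reads the five input tables (real or synthetic CSVs), runs demography →
grazing/egestion → trap fluxes → ²³⁴Th export → dilution rates →
BCP metrics for one cycle, and writes a summary bundle with a provenance
record of every empirical constant used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bcp, demography, dilution, grazing, thorium, trapflux

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for diagnosis."""


#: Empirical constants surfaced in every run report.
PROVENANCE_CONSTANTS = {
    "gpt_slope": grazing.GPT_SLOPE,
    "gpt_offset": grazing.GPT_OFFSET,
    "egestion_efficiency_default": grazing.DEFAULT_EGESTION_EFFICIENCY,
    "iversen_rate_coeff": grazing.IVERSEN_RATE_COEFF,
    "iversen_rate_exp": grazing.IVERSEN_RATE_EXP,
    "iversen_carbon_coeff": grazing.IVERSEN_CARBON_COEFF,
    "iversen_carbon_exp": grazing.IVERSEN_CARBON_EXP,
    "pellet_c_slope": trapflux.PELLET_C_SLOPE,
    "pellet_c_intercept": trapflux.PELLET_C_INTERCEPT,
    "lambda_234": thorium.LAMBDA_234,
}


@dataclass
class PipelineConfig:
    """Paths to the input tables plus every tunable rate parameter."""

    tow_csv: str
    gut_pigment_csv: str
    trap_csv: str
    th_csv: str
    dilution_csv: str
    npp_csv: str
    pellet_csv: str | None = None
    cycle_id: str = "cycle"
    z_eu: float = 70.0  # m
    water_temp: float = 10.0  # °C
    c_to_chl: float = 50.0  # g C : g chl
    chl_fraction: float = 1.0
    egestion_efficiency: float = grazing.DEFAULT_EGESTION_EFFICIENCY
    gpt_q10: grazing.Q10Config = field(
        default_factory=lambda: grazing.Q10Config(2.0, 10.0)
    )
    iversen_q10: grazing.Q10Config = field(
        default_factory=lambda: grazing.Q10Config(2.0, 0.0)
    )
    daynight_hours: tuple[float, float] = (14.0, 10.0)
    biomass_coeffs: tuple[float, float] | None = None
    th_config: thorium.ThModelConfig = field(default_factory=thorium.ThModelConfig)
    c_to_th: float | None = None  # µmol C dpm⁻¹
    mesozoo_grazing: float = 0.0  # mg C m⁻² d⁻¹, provided externally
    pellet_shape: str = "cylinder"
    water_mass: str = ""
    has_salps: bool = True

    def __post_init__(self) -> None:
        for name in ("tow_csv", "gut_pigment_csv", "trap_csv", "th_csv",
                     "dilution_csv", "npp_csv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config error: {name} file not found: {p}")
        if self.pellet_csv is not None and not Path(self.pellet_csv).exists():
            raise PipelineError(
                f"config error: pellet_csv file not found: {self.pellet_csv}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        for key in ("tow_csv", "gut_pigment_csv", "trap_csv", "th_csv",
                    "dilution_csv", "npp_csv", "pellet_csv"):
            if raw.get(key):
                raw[key] = str((base / raw[key]).resolve())
        for key in ("gpt_q10", "iversen_q10"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = grazing.Q10Config(**raw[key])
        if "th_config" in raw and isinstance(raw["th_config"], dict):
            tc = raw["th_config"]
            if "u_coeffs" in tc:
                tc["u_coeffs"] = tuple(tc["u_coeffs"])
            raw["th_config"] = thorium.ThModelConfig(**tc)
        for key in ("daynight_hours", "biomass_coeffs"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        """Stable hash of the configuration, embedded in outputs."""

        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------- loaders

def load_tows(path: str | Path) -> list[demography.TowRecord]:
    df = pd.read_csv(path)
    tows = []
    for tow_id, g in df.groupby("tow_id", sort=False):
        meta = g.iloc[0]
        inds = g.dropna(subset=["length_oal"])[
            ["species", "stage", "length_total", "length_oal"]
        ].reset_index(drop=True)
        tows.append(
            demography.TowRecord(
                tow_id=str(tow_id),
                is_night=bool(meta["is_night"]),
                volume_filtered=float(meta["volume_filtered"]),
                tow_depth=float(meta["tow_depth"]),
                individuals=inds,
            )
        )
    return tows


def load_traps(
    trap_path: str | Path, pellet_path: str | Path | None
) -> list[trapflux.TrapSample]:
    df = pd.read_csv(trap_path)
    pellets = (
        pd.read_csv(pellet_path) if pellet_path is not None else
        pd.DataFrame(columns=["depth", "length", "width"])
    )
    samples = []
    for _, row in df.iterrows():
        per_tube = None
        raw = row.get("per_tube_masses")
        if isinstance(raw, str) and raw.strip():
            per_tube = np.array([float(x) for x in raw.split(";")])
        pel = pellets[pellets["depth"] == row["depth"]][["length", "width"]]
        samples.append(
            trapflux.TrapSample(
                depth=float(row["depth"]),
                duration=float(row["duration"]),
                n_tubes=int(row["n_tubes"]),
                poc_mass=float(row["poc_mass"]),
                tube_inner_diameter=float(
                    row.get("tube_inner_diameter", trapflux.DEFAULT_TUBE_DIAMETER)
                ),
                pellets=pel.reset_index(drop=True),
                per_tube_masses=per_tube,
            )
        )
    return samples


def load_th_profiles(path: str | Path) -> list[thorium.ThProfile]:
    df = pd.read_csv(path)
    out = []
    for date, g in df.groupby("date", sort=True):
        samples = g[["depth", "a_th", "a_th_sd", "salinity"]].sort_values(
            "depth"
        ).reset_index(drop=True)
        out.append(thorium.ThProfile(pd.Timestamp(date), samples))
    return out


def load_dilution(path: str | Path) -> list[dilution.DilutionExperiment]:
    df = pd.read_csv(path)
    out = []
    for depth, g in df.groupby("depth", sort=True):
        chl_rows = g[g["tracer"] == "chl"]
        chl = {
            str(r["bottle"]): (float(r["initial"]), float(r["final"]))
            for _, r in chl_rows.iterrows()
        }
        cyt = {}
        for _, r in g[g["tracer"] == "fl3fsc"].iterrows():
            cyt[str(r["population"])] = {
                "fl3fsc_initial": float(r["initial"]),
                "fl3fsc_final": float(r["final"]),
                "biomass": float(r["biomass"]),
            }
        meta = chl_rows.iloc[0]
        out.append(
            dilution.DilutionExperiment(
                depth=float(depth),
                chl=chl,
                duration=float(meta["duration"]),
                dilution_fraction=float(meta["dilution_fraction"]),
                cytometry=cyt,
            )
        )
    return out


def load_npp(path: str | Path, z_eu: float) -> dilution.RateProfile:
    df = pd.read_csv(path).sort_values("depth")
    return dilution.RateProfile(
        df["depth"].to_numpy(dtype=float), df["npp"].to_numpy(dtype=float), z_eu
    )


# ------------------------------------------------------------------ stages

def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - reraise with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@dataclass
class PipelineResult:
    budget: bcp.CycleBudget
    report: dict
    intermediates: dict


@_stage("salp_demography")
def _run_demography(cfg: PipelineConfig, tows):
    pop = demography.day_night_average(tows, temperature=cfg.water_temp)
    biomass = (
        demography.biomass_from_length(pop, cfg.biomass_coeffs)
        if cfg.biomass_coeffs is not None else None
    )
    return pop, biomass


@_stage("grazing_egestion")
def _run_grazing(cfg: PipelineConfig, pop, pigments):
    fit = grazing.fit_gut_pigment_power(pigments)
    result = grazing.population_grazing(
        pop, fit, cfg.water_temp, cfg.gpt_q10, cfg.daynight_hours,
        cfg.c_to_chl, cfg.chl_fraction,
    )
    eg_gpig = grazing.egestion_gpig(result.total_carbon, cfg.egestion_efficiency)
    eg_iversen = grazing.egestion_iversen(
        pop, cfg.water_temp, cfg.iversen_q10, cfg.daynight_hours
    )
    return fit, result, eg_gpig, eg_iversen


@_stage("trap_flux")
def _run_traps(cfg: PipelineConfig, traps):
    flux_by_depth = {t.depth: trapflux.poc_flux(t).value for t in traps}
    fit = trapflux.fit_attenuation(sorted(flux_by_depth.items()), cfg.z_eu)
    pellet = {t.depth: trapflux.pellet_carbon_flux(t, cfg.pellet_shape)
              for t in traps}
    return flux_by_depth, fit, pellet


@_stage("thorium_export")
def _run_thorium(cfg: PipelineConfig, profiles, depths):
    out = {}
    max_z = min(p.max_depth for p in profiles)
    for z in depths:
        if z > max_z:
            logger.info(
                "no ²³⁴Th export at %.0f m: profiles reach only %.0f m", z, max_z
            )
            continue
        ss = thorium.ss_export(profiles[-1], z, cfg.th_config)
        entry = {"ss_flux": ss.flux, "ss_sd": ss.sd}
        if len(profiles) >= 2:
            nss = thorium.nss_export(profiles[0], profiles[-1], z, cfg.th_config)
            entry.update(nss_flux=nss.flux, nss_sd=nss.sd)
        if cfg.c_to_th is not None:
            entry["ss_poc_flux"] = thorium.poc_flux_from_th(ss.flux, cfg.c_to_th)
        out[z] = entry
    return out


@_stage("plankton_rates")
def _run_dilution(cfg: PipelineConfig, experiments, npp_profile):
    rows = []
    for exp in experiments:
        rates = dilution.dilution_rates(exp)
        phi = dilution.photoacclimation_phi(exp)
        rows.append(
            {
                "depth": exp.depth,
                "mu_nutrient": rates.mu_nutrient,
                "mu_insitu": dilution.correct_growth(rates.mu_insitu, phi),
                "g": rates.g,
                "phi": phi,
                "g_floored": rates.g_floored,
            }
        )
    rates_df = pd.DataFrame(rows).sort_values("depth").reset_index(drop=True)
    npp_int = dilution.integrate_profile(npp_profile)
    ok = rates_df["mu_insitu"] > 0
    frac = (rates_df.loc[ok, "g"] / rates_df.loc[ok, "mu_insitu"]).mean()
    uzoo_c = float(frac * npp_int) if np.isfinite(frac) else 0.0
    return rates_df, npp_int, uzoo_c


def run_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None
) -> PipelineResult:
    """Run every stage for one cycle and assemble the budget and report."""
    tows = load_tows(config.tow_csv)
    pigments = pd.read_csv(config.gut_pigment_csv)
    if pigments.empty:
        raise PipelineError(
            "stage 'grazing_egestion' failed: gut-pigment table is empty"
        )
    traps = load_traps(config.trap_csv, config.pellet_csv)
    profiles = load_th_profiles(config.th_csv)
    experiments = load_dilution(config.dilution_csv)
    npp_profile = load_npp(config.npp_csv, config.z_eu)

    pop, biomass = _run_demography(config, tows)
    fit, graze, eg_gpig, eg_iversen = _run_grazing(config, pop, pigments)
    flux_by_depth, atten, pellet = _run_traps(config, traps)
    th = _run_thorium(config, profiles, sorted(flux_by_depth))
    rates_df, npp_int, uzoo_c = _run_dilution(config, experiments, npp_profile)

    flux_ez = float(atten.flux_at_depth(config.z_eu))
    budget = bcp.CycleBudget(
        cycle_id=config.cycle_id,
        npp=npp_int,
        flux_ez=flux_ez,
        attenuation=atten,
        grazings={
            "uzoo": uzoo_c,
            "mesozoo": config.mesozoo_grazing,
            "salp": graze.total_carbon,
        },
        egestion={"gpig": eg_gpig, "iversen": float(sum(eg_iversen.values()))},
        flux_by_depth=flux_by_depth,
        pellet_flux_by_depth={z: p.flux for z, p in pellet.items()},
        water_mass=config.water_mass,
        has_salps=config.has_salps,
    )
    metrics = bcp.cycle_metrics(budget, config.z_eu)
    accumulation, net = dilution.net_rate_of_change(
        npp_int, uzoo_c, config.mesozoo_grazing, graze.total_carbon
    )

    report = {
        "cycle_id": config.cycle_id,
        "config_hash": config.digest(),
        "npp_mgC_m2_d": npp_int,
        "salp_grazing_pigment_mg_m2_d": graze.total_pigment,
        "salp_grazing_mgC_m2_d": graze.total_carbon,
        "egestion_gpig_mgC_m2_d": eg_gpig,
        "egestion_iversen_mgC_m2_d": float(sum(eg_iversen.values())),
        "egestion_iversen_by_stage": eg_iversen,
        "uzoo_grazing_mgC_m2_d": uzoo_c,
        "mesozoo_grazing_mgC_m2_d": config.mesozoo_grazing,
        "accumulation_mgC_m2_d": accumulation,
        "net_rate_of_change_mgC_m2_d": net,
        "pigment_fit": {"a": fit.a, "b": fit.b, "n": fit.n_points,
                        "fallback_mean": fit.fallback_mean},
        "attenuation": {"f0": atten.f0, "b": atten.b, "z0": atten.z0},
        "flux_by_depth": flux_by_depth,
        "pellet_flux_by_depth": {z: p.flux for z, p in pellet.items()},
        "pellet_fraction_by_depth": {z: p.fraction for z, p in pellet.items()},
        "thorium_by_depth": th,
        "dilution_rates": rates_df.to_dict(orient="records"),
        "metrics": metrics,
        "salp_biomass_gC_m2": biomass,
        "provenance_constants": PROVENANCE_CONSTANTS,
    }
    intermediates = {
        "population": pop,
        "pigment_fit": fit,
        "grazing": graze,
        "rates": rates_df,
        "traps": traps,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "summary.json").write_text(
            json.dumps(report, indent=2, default=_jsonable)
        )
        pop.to_long().to_csv(outdir / "binned_abundance.csv", index=False)
        rates_df.to_csv(outdir / "dilution_rates.csv", index=False)
        pd.DataFrame(
            [{"depth": z, "poc_flux": f,
              "pellet_flux": report["pellet_flux_by_depth"][z],
              "pellet_fraction": report["pellet_fraction_by_depth"][z]}
             for z, f in sorted(flux_by_depth.items())]
        ).to_csv(outdir / "flux_table.csv", index=False)
    return PipelineResult(budget=budget, report=report, intermediates=intermediates)


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
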