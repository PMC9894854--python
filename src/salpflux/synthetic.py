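"""Synthetic Lagrangian-cycle data with recorded ground truth.

Emulates one quasi-Lagrangian process-study cycle: day/night net tows of
a size-structured *Salpa thompsoni* bloom, per-individual gut pigments,
multi-depth particle-interceptor trap samples with pellet morphometrics,
paired ²³⁴Th/salinity profiles, depth-resolved NPP, and two-treatment
dilution bottles.  Every table is generated from a :class:`GroundTruth`
whose parameters the downstream estimators should recover, which makes
the whole pipeline testable without any field data.

Noise models are minimal and conventional: Poisson for tow counts,
lognormal for pigments and per-tube trap POC, Gaussian for ²³⁴Th
activities, lognormal for bottle chl a.  All are configurable and can be
switched off (``NoiseConfig.off()``), in which case the estimators
recover the truth exactly (the ²³⁴Th balance to discretization error).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .demography import BIN_EDGES, STAGES, TowRecord, bin_midpoints
from .dilution import DilutionExperiment, RateProfile
from .thorium import ThModelConfig, ThProfile, u238_from_salinity
from .trapflux import DEFAULT_TUBE_DIAMETER, TrapSample, pellet_carbon_ug, pellet_volume

# Sub-stream keys so each generate_* called with the same seed stays
# consistent inside and outside generate_cycle.
_STREAMS = {"tows": 0, "pigments": 1, "traps": 2, "thorium": 3, "dilution": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


def default_abundance_by_bin(
    oozooid_total: float = 20.0,
    oozooid_mean: float = 60.0,
    oozooid_sd: float = 15.0,
    blastozooid_total: float = 200.0,
    blastozooid_mean: float = 35.0,
    blastozooid_sd: float = 10.0,
) -> dict[str, np.ndarray]:
    """Per-bin areal abundance (ind m⁻²) from truncated-normal length modes.

    Defaults sketch a mid-bloom population: few large solitary oozooids,
    an order of magnitude more aggregate blastozooids around 35 mm.
    """
    mids = bin_midpoints()
    lo, hi = BIN_EDGES[0], BIN_EDGES[-1]
    out = {}
    for stage, total, mean, sd in (
        ("oozooid", oozooid_total, oozooid_mean, oozooid_sd),
        ("blastozooid", blastozooid_total, blastozooid_mean, blastozooid_sd),
    ):
        a, b = (lo - mean) / sd, (hi - mean) / sd
        w = sps.truncnorm.pdf(mids, a, b, loc=mean, scale=sd)
        w = w / w.sum()
        out[stage] = total * w
    return out


@dataclass
class NoiseConfig:
    """Noise magnitudes for each generated table; zeros switch noise off."""

    pigment_sigma: float = 0.2  # lognormal σ on Gpig
    trap_sigma: float = 0.2  # lognormal σ per trap tube
    th_sigma: float = 0.05  # dpm L⁻¹ Gaussian on ²³⁴Th activities
    chl_sigma: float = 0.05  # lognormal σ per bottle chl measurement
    counts: str = "poisson"  # 'poisson' | 'exact' tow counts

    @classmethod
    def off(cls) -> "NoiseConfig":
        return cls(pigment_sigma=0.0, trap_sigma=0.0, th_sigma=0.0,
                   chl_sigma=0.0, counts="exact")


@dataclass
class GroundTruth:
    """Simulation truth every downstream estimator should recover."""

    pigment_power_a: float = 5.0  # ng ind⁻¹ mm⁻ᵇ
    pigment_power_b: float = 2.0
    f0_true: float = 210.0  # mg C m⁻² d⁻¹ at the euphotic depth
    b_true: float = 0.39  # attenuation exponent
    th_export_true: float = 1500.0  # dpm m⁻² d⁻¹ at the euphotic depth
    mu_true: float = 0.6  # d⁻¹
    g_true: float = 0.4  # d⁻¹
    npp_integrated: float = 452.0  # mg C m⁻² d⁻¹
    abundance_by_bin: dict[str, np.ndarray] = field(
        default_factory=default_abundance_by_bin
    )

    def __post_init__(self) -> None:
        for name in ("pigment_power_a", "f0_true", "npp_integrated"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.g_true < 0:
            raise ValueError(f"g_true must be >= 0, got {self.g_true}")
        for name in ("b_true", "th_export_true", "mu_true"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for stage, a in self.abundance_by_bin.items():
            a = np.asarray(a, dtype=float)
            if np.any(a < 0):
                raise ValueError(f"abundance_by_bin[{stage!r}] must be >= 0")
            if len(a) != len(BIN_EDGES) - 1:
                raise ValueError(
                    f"abundance_by_bin[{stage!r}] needs {len(BIN_EDGES) - 1} bins"
                )
            self.abundance_by_bin[stage] = a

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["abundance_by_bin"] = {
            k: list(map(float, v)) for k, v in self.abundance_by_bin.items()
        }
        return d


@dataclass
class CycleScenario:
    """Study conditions of one synthetic Lagrangian cycle."""

    cycle_id: str = "synthetic-salp"
    duration_days: float = 5.0
    water_temp: float = 10.0  # °C, Chatham Rise ambient
    euphotic_depth: float = 70.0  # m
    trap_depths: tuple[float, ...] = (70.0, 100.0, 300.0, 500.0)
    true_params: GroundTruth = field(default_factory=GroundTruth)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    night_day_factor: float = 1.0  # night:day abundance contrast
    tow_depth: float = 200.0  # m
    n_tubes: int = 12  # PIT tubes per cross-frame
    tube_inner_diameter: float = DEFAULT_TUBE_DIAMETER
    pellet_fraction: float = 0.3  # target intact-pellet share of trap POC
    salinity: float = 34.8  # psu, SA–ST transition waters
    dilution_fraction: float = 0.25
    phi_true: float = 0.0  # d⁻¹ photoacclimation signal
    nutrient_boost: float = 0.0  # d⁻¹ added growth under amendment
    max_pigment_per_tow: int = 10  # gut-pigment subsample size

    def __post_init__(self) -> None:
        if not self.duration_days > 0:
            raise ValueError(f"duration_days must be > 0, got {self.duration_days}")
        depths = np.asarray(self.trap_depths, dtype=float)
        if np.any(np.diff(depths) <= 0):
            raise ValueError(f"trap_depths must be strictly increasing: {depths}")
        if self.euphotic_depth > depths.min():
            raise ValueError(
                f"euphotic_depth ({self.euphotic_depth} m) must not exceed the "
                f"shallowest trap ({depths.min()} m)"
            )
        if self.night_day_factor <= 0:
            raise ValueError(
                f"night_day_factor must be > 0, got {self.night_day_factor}"
            )


def generate_salp_tows(
    scenario: CycleScenario, seed: int
) -> list[TowRecord]:
    """Day and night double-oblique tows with per-bin Poisson counts.

    Per tow and bin, the expected count is abundance × volume / tow depth;
    the day/night contrast scales the stated (day/night-averaged)
    abundance by the night:day factor.  Volumes are uniform on 150–500 m³.
    """
    rng = _rng(seed, "tows")
    truth = scenario.true_params
    n_per_period = max(2, round(scenario.duration_days))
    f = scenario.night_day_factor
    period_scale = {"day": 2.0 / (1.0 + f), "night": 2.0 * f / (1.0 + f)}
    mids = bin_midpoints()
    tows = []
    for period in ("day", "night"):
        for i in range(n_per_period):
            volume = float(rng.uniform(150.0, 500.0))
            rows = []
            for stage in STAGES:
                lam = (
                    truth.abundance_by_bin[stage]
                    * period_scale[period]
                    * volume
                    / scenario.tow_depth
                )
                if scenario.noise.counts == "poisson":
                    counts = rng.poisson(lam)
                else:
                    counts = np.round(lam).astype(int)
                for mid, n in zip(mids, counts):
                    if n == 0:
                        continue
                    if scenario.noise.counts == "poisson":
                        lengths = mid + rng.uniform(-2.5, 2.5, size=n)
                    else:
                        lengths = np.full(n, mid)
                    for length in lengths:
                        rows.append(
                            {
                                "species": "Salpa thompsoni",
                                "stage": stage,
                                "length_total": float(length),
                                "length_oal": float(length),
                            }
                        )
            tows.append(
                TowRecord(
                    tow_id=f"{scenario.cycle_id}-{period}-{i + 1}",
                    is_night=period == "night",
                    volume_filtered=volume,
                    tow_depth=scenario.tow_depth,
                    individuals=pd.DataFrame(
                        rows,
                        columns=["species", "stage", "length_total", "length_oal"],
                    ),
                )
            )
    return tows


def generate_gut_pigments(
    scenario: CycleScenario, seed: int, tows: list[TowRecord] | None = None
) -> pd.DataFrame:
    """Per-individual gut pigments, ≤10 animals per stage per tow.

    Gpig = a·L^b × lognormal noise.  Returns a table with columns tow_id,
    stage, length_oal, gpig (ng ind⁻¹).
    """
    if tows is None:
        tows = generate_salp_tows(scenario, seed)
    rng = _rng(seed, "pigments")
    truth = scenario.true_params
    sigma = scenario.noise.pigment_sigma
    rows = []
    for tow in tows:
        for stage in STAGES:
            lengths = tow.individuals.loc[
                tow.individuals["stage"] == stage, "length_oal"
            ].to_numpy(dtype=float)
            if len(lengths) == 0:
                continue
            k = min(scenario.max_pigment_per_tow, len(lengths))
            sample = rng.choice(lengths, size=k, replace=False)
            gpig = truth.pigment_power_a * sample**truth.pigment_power_b
            if sigma > 0:
                gpig = gpig * np.exp(rng.normal(0.0, sigma, size=k))
            for length, g in zip(sample, gpig):
                rows.append(
                    {"tow_id": tow.tow_id, "stage": stage,
                     "length_oal": float(length), "gpig": float(g)}
                )
    return pd.DataFrame(rows, columns=["tow_id", "stage", "length_oal", "gpig"])


#: Sample depths for the ²³⁴Th profiles, merged with the euphotic depth.
_TH_BASE_DEPTHS = (2.0, 10.0, 20.0, 40.0, 60.0, 100.0, 150.0, 200.0, 300.0)


def _th_deficiency(z: np.ndarray, scenario: CycleScenario,
                   cfg: ThModelConfig) -> np.ndarray:
    """Deficiency profile whose steady-state integral to the euphotic depth
    equals th_export_true: uniform above z_eu, linear taper to the next
    sample depth, zero below."""
    z_eu = scenario.euphotic_depth
    delta0 = scenario.true_params.th_export_true / (
        cfg.lambda_234 * 1000.0 * z_eu
    )
    below = z[z > z_eu]
    z_taper = below.min() if len(below) else z_eu
    out = np.zeros_like(z)
    out[z <= z_eu] = delta0
    taper = (z > z_eu) & (z < z_taper)
    out[taper] = delta0 * (z_taper - z[taper]) / (z_taper - z_eu)
    return out


def generate_th_profiles(
    scenario: CycleScenario, seed: int, cfg: ThModelConfig = ThModelConfig()
) -> tuple[ThProfile, ThProfile]:
    """Two ²³⁴Th profiles one cycle apart, built from a known export flux.

    The deficiency is uniform above the euphotic depth and sized so the
    steady-state model integrated to that depth returns ``th_export_true``
    (exactly, under trapezoidal integration); the construction is held in
    steady state so the two profiles differ only in measurement noise.
    """
    rng = _rng(seed, "thorium")
    z = np.unique(np.concatenate([_TH_BASE_DEPTHS, [scenario.euphotic_depth]]))
    a_u = u238_from_salinity(scenario.salinity, cfg)
    deficiency = _th_deficiency(z, scenario, cfg)
    sigma = scenario.noise.th_sigma
    t0 = pd.Timestamp("2018-11-01")
    profiles = []
    for offset in (0.0, scenario.duration_days):
        a_th = a_u - deficiency
        if sigma > 0:
            a_th = np.clip(a_th + rng.normal(0.0, sigma, size=len(z)), 0.0, None)
        samples = pd.DataFrame(
            {
                "depth": z,
                "a_th": a_th,
                "a_th_sd": np.full(len(z), sigma),
                "salinity": np.full(len(z), scenario.salinity),
            }
        )
        profiles.append(ThProfile(t0 + pd.Timedelta(days=offset), samples))
    return profiles[0], profiles[1]


def generate_trap_samples(
    scenario: CycleScenario, seed: int
) -> list[TrapSample]:
    """PIT samples at the scenario trap depths.

    Per-tube POC mass is F0·(z/z_eu)^−b × tube area × days × lognormal
    noise, pooled over tubes.  Intact pellets (nominally 4 × 1 mm
    cylinders with lognormal size scatter) are added until their carbon
    reaches the target pellet fraction of the true flux.
    """
    rng = _rng(seed, "traps")
    truth = scenario.true_params
    sigma = scenario.noise.trap_sigma
    samples = []
    for z in scenario.trap_depths:
        flux = truth.f0_true * (z / scenario.euphotic_depth) ** (-truth.b_true)
        tube_area = np.pi * (scenario.tube_inner_diameter / 2.0) ** 2
        base = flux * tube_area * scenario.duration_days
        if sigma > 0:
            tube_masses = base * np.exp(
                rng.normal(0.0, sigma, size=scenario.n_tubes)
            )
        else:
            tube_masses = np.full(scenario.n_tubes, base)
        area_total = scenario.n_tubes * tube_area
        target_ug = (
            scenario.pellet_fraction * flux * area_total * scenario.duration_days
        ) * 1e3
        pellets = _generate_pellets(rng, target_ug, sigma)
        samples.append(
            TrapSample(
                depth=float(z),
                duration=scenario.duration_days,
                n_tubes=scenario.n_tubes,
                poc_mass=float(tube_masses.sum()),
                tube_inner_diameter=scenario.tube_inner_diameter,
                pellets=pellets,
                per_tube_masses=tube_masses,
            )
        )
    return samples


def _generate_pellets(rng: np.random.Generator, target_ug: float,
                      sigma: float) -> pd.DataFrame:
    if target_ug <= 0:
        return pd.DataFrame(columns=["length", "width"])
    nominal_c = pellet_carbon_ug(pellet_volume(4.0, 1.0))
    if sigma <= 0:
        n = int(round(target_ug / nominal_c))
        return pd.DataFrame({"length": np.full(n, 4.0), "width": np.full(n, 1.0)})
    lengths, widths, total = [], [], 0.0
    while total < target_ug and len(lengths) < 100_000:
        length = float(np.exp(rng.normal(np.log(4.0), 0.25)))
        width = float(length / 4.0 * np.exp(rng.normal(0.0, 0.1)))
        lengths.append(length)
        widths.append(width)
        total += float(pellet_carbon_ug(pellet_volume(length, width)))
    return pd.DataFrame({"length": lengths, "width": widths})


def generate_npp_profile(scenario: CycleScenario) -> RateProfile:
    """Depth-resolved NPP whose euphotic-zone integral equals the truth.

    An exponentially decaying shape over six depths, scaled so the
    trapezoidal integral (constant-extended to the surface) matches
    ``npp_integrated`` exactly.  Deterministic: NPP noise is not part of
    the recovery exercise.
    """
    z_eu = scenario.euphotic_depth
    depths = np.linspace(z_eu / 7.0, z_eu, 6)
    shape = np.exp(-2.0 * depths / z_eu)
    raw = RateProfile(depths, shape, z_eu)
    from .dilution import integrate_profile

    scale = scenario.true_params.npp_integrated / integrate_profile(raw)
    return RateProfile(depths, shape * scale, z_eu)


def generate_dilution_experiments(
    scenario: CycleScenario, seed: int
) -> list[DilutionExperiment]:
    """Two-treatment dilution bottles at six euphotic-zone depths.

    Bottle rates follow the dilution model: k = μ − x·g with x the whole-
    seawater fraction (0.25 diluted, 1 whole); nutrient amendment adds
    ``nutrient_boost`` to μ in bottles A and B.  Finals grow
    exponentially; every chl measurement carries lognormal noise.
    FL3:FSC tracks exp(phi_true·t) for both cytometric populations.
    """
    rng = _rng(seed, "dilution")
    truth = scenario.true_params
    x = scenario.dilution_fraction
    sigma = scenario.noise.chl_sigma
    mu_n = truth.mu_true + scenario.nutrient_boost
    ks = {
        "A": mu_n + scenario.phi_true - x * truth.g_true,
        "B": mu_n + scenario.phi_true - truth.g_true,
        "C": truth.mu_true + scenario.phi_true - truth.g_true,
    }
    depths = np.linspace(scenario.euphotic_depth / 7.0, scenario.euphotic_depth, 6)
    duration = 1.0
    chl0 = 0.4  # µg L⁻¹
    experiments = []
    for z in depths:
        chl = {}
        for bottle, k in ks.items():
            initial, final = chl0, chl0 * np.exp(k * duration)
            if sigma > 0:
                initial *= float(np.exp(rng.normal(0.0, sigma)))
                final *= float(np.exp(rng.normal(0.0, sigma)))
            chl[bottle] = (initial, final)
        fl_final = float(np.exp(scenario.phi_true * duration))
        cytometry = {
            pop: {"fl3fsc_initial": 1.0, "fl3fsc_final": fl_final, "biomass": 1.0}
            for pop in ("picoeukaryote", "nanoeukaryote")
        }
        experiments.append(
            DilutionExperiment(
                depth=float(z),
                chl=chl,
                duration=duration,
                dilution_fraction=x,
                cytometry=cytometry,
            )
        )
    return experiments


@dataclass
class SyntheticCycle:
    """The full generated bundle for one cycle."""

    scenario: CycleScenario
    seed: int
    tows: list[TowRecord]
    gut_pigments: pd.DataFrame
    traps: list[TrapSample]
    th_profiles: tuple[ThProfile, ThProfile]
    dilution: list[DilutionExperiment]
    npp: RateProfile

    @property
    def truth(self) -> GroundTruth:
        return self.scenario.true_params

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all tables as CSV, the scenario as YAML, truth as JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        tow_rows = []
        for tow in self.tows:
            if len(tow.individuals) == 0:
                tow_rows.append(
                    {"tow_id": tow.tow_id, "is_night": tow.is_night,
                     "volume_filtered": tow.volume_filtered,
                     "tow_depth": tow.tow_depth, "species": "", "stage": "",
                     "length_total": np.nan, "length_oal": np.nan}
                )
            for _, ind in tow.individuals.iterrows():
                tow_rows.append(
                    {"tow_id": tow.tow_id, "is_night": tow.is_night,
                     "volume_filtered": tow.volume_filtered,
                     "tow_depth": tow.tow_depth, **ind.to_dict()}
                )
        paths["tows"] = outdir / "tows.csv"
        pd.DataFrame(tow_rows).to_csv(paths["tows"], index=False)

        paths["gut_pigments"] = outdir / "gut_pigments.csv"
        self.gut_pigments.to_csv(paths["gut_pigments"], index=False)

        trap_rows, pellet_rows = [], []
        for t in self.traps:
            trap_rows.append(
                {"depth": t.depth, "duration": t.duration, "n_tubes": t.n_tubes,
                 "tube_inner_diameter": t.tube_inner_diameter,
                 "poc_mass": t.poc_mass,
                 "per_tube_masses": ";".join(
                     f"{m:.10g}" for m in (t.per_tube_masses
                                           if t.per_tube_masses is not None else [])
                 )}
            )
            if t.pellets is not None:
                for _, p in t.pellets.iterrows():
                    pellet_rows.append(
                        {"depth": t.depth, "length": p["length"], "width": p["width"]}
                    )
        paths["traps"] = outdir / "traps.csv"
        pd.DataFrame(trap_rows).to_csv(paths["traps"], index=False)
        paths["pellets"] = outdir / "pellets.csv"
        pd.DataFrame(pellet_rows, columns=["depth", "length", "width"]).to_csv(
            paths["pellets"], index=False
        )

        th_rows = []
        for p in self.th_profiles:
            for _, s in p.samples.iterrows():
                th_rows.append({"date": p.date.isoformat(), **s.to_dict()})
        paths["thorium"] = outdir / "th_profiles.csv"
        pd.DataFrame(th_rows).to_csv(paths["thorium"], index=False)

        dil_rows = []
        for e in self.dilution:
            for bottle, (initial, final) in e.chl.items():
                dil_rows.append(
                    {"depth": e.depth, "duration": e.duration,
                     "dilution_fraction": e.dilution_fraction, "tracer": "chl",
                     "bottle": bottle, "initial": initial, "final": final,
                     "population": "", "biomass": np.nan}
                )
            for pop, c in e.cytometry.items():
                dil_rows.append(
                    {"depth": e.depth, "duration": e.duration,
                     "dilution_fraction": e.dilution_fraction,
                     "tracer": "fl3fsc", "bottle": "",
                     "initial": c["fl3fsc_initial"], "final": c["fl3fsc_final"],
                     "population": pop, "biomass": c["biomass"]}
                )
        paths["dilution"] = outdir / "dilution.csv"
        pd.DataFrame(dil_rows).to_csv(paths["dilution"], index=False)

        paths["npp"] = outdir / "npp.csv"
        pd.DataFrame(
            {"depth": self.npp.depths, "npp": self.npp.values}
        ).to_csv(paths["npp"], index=False)

        paths["scenario"] = outdir / "scenario.yaml"
        paths["scenario"].write_text(yaml.safe_dump(scenario_to_dict(self.scenario)))
        paths["ground_truth"] = outdir / "ground_truth.json"
        paths["ground_truth"].write_text(
            json.dumps(self.truth.to_dict(), indent=2)
        )
        return paths


def generate_cycle(scenario: CycleScenario, seed: int) -> SyntheticCycle:
    """Generate the complete bundle for one cycle, deterministically."""
    tows = generate_salp_tows(scenario, seed)
    return SyntheticCycle(
        scenario=scenario,
        seed=int(seed),
        tows=tows,
        gut_pigments=generate_gut_pigments(scenario, seed, tows),
        traps=generate_trap_samples(scenario, seed),
        th_profiles=generate_th_profiles(scenario, seed),
        dilution=generate_dilution_experiments(scenario, seed),
        npp=generate_npp_profile(scenario),
    )


def scenario_to_dict(scenario: CycleScenario) -> dict:
    d = dataclasses.asdict(scenario)
    d["true_params"] = scenario.true_params.to_dict()
    d["trap_depths"] = list(map(float, scenario.trap_depths))
    return d


def scenario_from_dict(d: dict) -> CycleScenario:
    d = dict(d)
    if "true_params" in d and not isinstance(d["true_params"], GroundTruth):
        tp = dict(d["true_params"])
        if "abundance_by_bin" in tp:
            tp["abundance_by_bin"] = {
                k: np.asarray(v, dtype=float)
                for k, v in tp["abundance_by_bin"].items()
            }
        d["true_params"] = GroundTruth(**tp)
    if "noise" in d and not isinstance(d["noise"], NoiseConfig):
        d["noise"] = NoiseConfig(**d["noise"])
    if "trap_depths" in d:
        d["trap_depths"] = tuple(float(z) for z in d["trap_depths"])
    return CycleScenario(**d)
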