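"""Biological-carbon-pump efficiency metrics and salp vs non-salp comparisons.

The Ez ratio is the fraction of net primary production exported past the
euphotic-zone base; T100 is the flux transmission, i.e. the fraction of
that export surviving an additional 100 m into the mesopelagic; their
product is the BCP efficiency — the fraction of NPP delivered 100 m
below the euphotic zone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trapflux import AttenuationFit

logger = logging.getLogger(__name__)


@dataclass
class CycleBudget:
    """Assembled per-cycle rates and fluxes (all mg C m⁻² d⁻¹)."""

    cycle_id: str
    npp: float
    flux_ez: float  # POC flux at the euphotic-zone base
    attenuation: AttenuationFit | None = None
    grazings: dict[str, float] = field(default_factory=dict)  # uzoo/mesozoo/salp
    egestion: dict[str, float] = field(default_factory=dict)  # gpig/iversen
    flux_by_depth: dict[float, float] = field(default_factory=dict)
    pellet_flux_by_depth: dict[float, float] = field(default_factory=dict)
    water_mass: str = ""
    has_salps: bool = False

    def __post_init__(self) -> None:
        if not self.npp > 0:
            raise ValueError(f"npp must be > 0 for metrics, got {self.npp}")
        if self.flux_ez < 0:
            raise ValueError(f"flux_ez must be >= 0, got {self.flux_ez}")

    def flux_at(self, z: float) -> float:
        """Flux at depth z via the power-law fit (geometric interpolation)."""
        if self.attenuation is None:
            raise ValueError(f"cycle {self.cycle_id!r} has no attenuation fit")
        return float(self.attenuation.flux_at_depth(z))


def ez_ratio(flux_ez: float, npp: float) -> float:
    """Fraction of NPP exported below the euphotic zone."""
    if not npp > 0:
        raise ValueError(f"npp must be > 0, got {npp}")
    return flux_ez / npp


def t100(fit: AttenuationFit, z_eu: float) -> float:
    """Flux transmission to 100 m below the euphotic-zone base."""
    return float(fit.flux_at_depth(z_eu + 100.0) / fit.flux_at_depth(z_eu))


def bcp_efficiency(ez: float, t_100: float) -> float:
    """BCP efficiency: fraction of NPP delivered 100 m below the euphotic zone."""
    return ez * t_100


def salp_nonsalp_ratio(
    budgets: list[CycleBudget],
    pairing: dict[str, tuple[str, str]],
    depths: list[float] | None = None,
) -> pd.DataFrame:
    """Per-depth POC-flux ratios between paired salp and non-salp cycles.

    ``pairing`` maps a water-mass label to (salp cycle_id, non-salp
    cycle_id).  Fluxes are compared at shared measured depths (or the
    given ``depths``) using each cycle's power-law fit, which interpolates
    geometrically in depth.  Pairs with a missing partner are skipped
    with a warning.  Returns a long table (water_mass, depth, ratio) plus
    the overall mean ratio in ``DataFrame.attrs['mean_ratio']``.
    """
    by_id = {b.cycle_id: b for b in budgets}
    rows = []
    for water_mass, (salp_id, nonsalp_id) in pairing.items():
        if salp_id not in by_id or nonsalp_id not in by_id:
            logger.warning(
                "pair %r skipped: missing cycle %r",
                water_mass,
                salp_id if salp_id not in by_id else nonsalp_id,
            )
            continue
        salp, nonsalp = by_id[salp_id], by_id[nonsalp_id]
        if depths is not None:
            zs = sorted(depths)
        else:
            zs = sorted(
                set(salp.flux_by_depth) & set(nonsalp.flux_by_depth)
            )
        if not zs:
            logger.warning("pair %r skipped: no common depths", water_mass)
            continue
        for z in zs:
            rows.append(
                {
                    "water_mass": water_mass,
                    "depth": z,
                    "salp_flux": salp.flux_at(z),
                    "nonsalp_flux": nonsalp.flux_at(z),
                    "ratio": salp.flux_at(z) / nonsalp.flux_at(z),
                }
            )
    out = pd.DataFrame(rows, columns=["water_mass", "depth", "salp_flux",
                                      "nonsalp_flux", "ratio"])
    out.attrs["mean_ratio"] = float(out["ratio"].mean()) if len(out) else float("nan")
    return out


def cycle_metrics(budget: CycleBudget, z_eu: float) -> dict[str, float]:
    """Ez, T100, BCP efficiency and egestion:flux diagnostics for one cycle."""
    ez = ez_ratio(budget.flux_ez, budget.npp)
    out: dict[str, float] = {"ez": ez}
    if budget.attenuation is not None:
        t = t100(budget.attenuation, z_eu)
        out["t100"] = t
        out["bcp_efficiency"] = bcp_efficiency(ez, t)
        flux_200 = budget.flux_at(200.0)
        for method, eg in budget.egestion.items():
            out[f"egestion_{method}_to_flux200"] = (
                eg / flux_200 if flux_200 > 0 else float("nan")
            )
    return out
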