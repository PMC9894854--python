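"""Sediment-trap POC fluxes, power-law depth attenuation, and salp-pellet carbon.

Free-drifting particle-interceptor traps (PIT; cylindrical tubes of 7 cm
inner diameter) collect sinking particles at fixed depths.  Fluxes are the
collected POC mass over collection area × deployment duration; depth
attenuation is fit as the power law Flux(z) = F0·(z/z0)^−b with z0 the
euphotic depth.  Intact salp fecal pellets photographed on the trap
screens are converted from length × width morphometrics to carbon via a
volume–carbon log-log relationship, C(µg) = 10^(0.634·log10 V + 1.43).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Pellet volume (mm³) → carbon (µg): C = 10^(PELLET_C_SLOPE·log10 V + PELLET_C_INTERCEPT)
PELLET_C_SLOPE = 0.634
PELLET_C_INTERCEPT = 1.43

DEFAULT_TUBE_DIAMETER = 0.07  # m


@dataclass
class TrapSample:
    """One PIT depth horizon.

    ``poc_mass`` is the swimmer-removed, blank-corrected POC (mg C) summed
    over ``n_tubes`` tubes; ``per_tube_masses`` optionally carries the
    individual tube masses for an uncertainty estimate.  ``pellets`` is a
    table of intact salp fecal pellets (columns ``length``/``width``, mm).
    """

    depth: float  # m
    duration: float  # days
    n_tubes: int
    poc_mass: float  # mg C, summed over tubes
    tube_inner_diameter: float = DEFAULT_TUBE_DIAMETER  # m
    pellets: pd.DataFrame | None = None
    per_tube_masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.n_tubes < 1:
            raise ValueError(f"n_tubes must be >= 1, got {self.n_tubes}")
        if self.poc_mass < 0:
            raise ValueError(f"poc_mass must be >= 0, got {self.poc_mass}")

    @property
    def tube_area(self) -> float:
        """Collection area of one tube (m²)."""
        return math.pi * (self.tube_inner_diameter / 2.0) ** 2

    @property
    def collection_area(self) -> float:
        """Total collection area (m²) over all tubes."""
        return self.n_tubes * self.tube_area


@dataclass
class FluxEstimate:
    value: float  # mg C m⁻² d⁻¹
    sd: float = float("nan")


def poc_flux(sample: TrapSample) -> FluxEstimate:
    """POC flux (mg C m⁻² d⁻¹): mass / (tube area × tubes × days).

    When per-tube masses are given, the standard error of the mean tube
    flux is reported alongside.
    """
    flux = sample.poc_mass / (sample.collection_area * sample.duration)
    sd = float("nan")
    if sample.per_tube_masses is not None and len(sample.per_tube_masses) > 1:
        tube_fluxes = (
            np.asarray(sample.per_tube_masses, dtype=float)
            / (sample.tube_area * sample.duration)
        )
        sd = float(np.std(tube_fluxes, ddof=1) / np.sqrt(len(tube_fluxes)))
    return FluxEstimate(float(flux), sd)


@dataclass
class AttenuationFit:
    """Power-law flux attenuation Flux(z) = f0·(z/z0)^−b."""

    f0: float  # mg C m⁻² d⁻¹, flux at the euphotic depth z0
    b: float
    z0: float  # m
    f0_sd: float = float("nan")
    b_sd: float = float("nan")

    def __post_init__(self) -> None:
        if not self.f0 > 0:
            raise ValueError(f"f0 must be > 0, got {self.f0}")
        if not self.z0 > 0:
            raise ValueError(f"z0 must be > 0, got {self.z0}")

    def flux_at_depth(self, z) -> float | np.ndarray:
        z = np.asarray(z, dtype=float)
        out = self.f0 * (z / self.z0) ** (-self.b)
        return float(out) if out.ndim == 0 else out


def fit_attenuation(
    fluxes: list[tuple[float, float]], z0: float
) -> AttenuationFit:
    """Fit the power law by unweighted least squares in log-log space.

    ``fluxes`` is a list of (depth m, flux mg C m⁻² d⁻¹); at least two
    depths with positive flux are required.  Parameter uncertainties come
    from the regression standard errors (first-order delta method for f0).
    """
    pts = [(z, f) for z, f in fluxes if f > 0]
    if len(pts) < 2:
        raise ValueError(
            f"need >= 2 depths with positive flux to fit attenuation, got {len(pts)}"
        )
    z = np.array([p[0] for p in pts], dtype=float)
    f = np.array([p[1] for p in pts], dtype=float)
    x = np.log(z / z0)
    y = np.log(f)
    res = stats.linregress(x, y)
    f0 = float(np.exp(res.intercept))
    b = float(-res.slope)
    b_sd = float(res.stderr) if len(pts) > 2 else float("nan")
    f0_sd = f0 * float(res.intercept_stderr) if len(pts) > 2 else float("nan")
    return AttenuationFit(f0, b, float(z0), f0_sd=f0_sd, b_sd=b_sd)


@dataclass
class ExponentialFit:
    """Alternative exponential attenuation Flux(z) = f0·e^(−k(z−z0)).

    Provided to quantify the sensitivity of interpolated fluxes to the
    functional form; the power law is the primary model.
    """

    f0: float
    k: float  # m⁻¹
    z0: float

    def flux_at_depth(self, z) -> float | np.ndarray:
        z = np.asarray(z, dtype=float)
        out = self.f0 * np.exp(-self.k * (z - self.z0))
        return float(out) if out.ndim == 0 else out


def fit_exponential(
    fluxes: list[tuple[float, float]], z0: float
) -> ExponentialFit:
    """Least-squares fit of ln(flux) against depth."""
    pts = [(z, f) for z, f in fluxes if f > 0]
    if len(pts) < 2:
        raise ValueError("need >= 2 depths with positive flux")
    z = np.array([p[0] for p in pts], dtype=float)
    f = np.array([p[1] for p in pts], dtype=float)
    res = stats.linregress(z - z0, np.log(f))
    return ExponentialFit(float(np.exp(res.intercept)), float(-res.slope), float(z0))


def pellet_volume(length_mm, width_mm, shape: str = "cylinder") -> np.ndarray:
    """Pellet volume (mm³) from length × width under a shape rule.

    Salp pellets are elongated, so a cylinder (π·(w/2)²·L) is the default;
    an ellipsoid of revolution (π/6·w²·L) is available.
    """
    length_mm = np.asarray(length_mm, dtype=float)
    width_mm = np.asarray(width_mm, dtype=float)
    if np.any(length_mm <= 0) or np.any(width_mm <= 0):
        raise ValueError("pellet dimensions must be positive")
    if shape == "cylinder":
        return math.pi * (width_mm / 2.0) ** 2 * length_mm
    if shape == "ellipsoid":
        return math.pi / 6.0 * width_mm**2 * length_mm
    raise ValueError(f"unknown pellet shape rule: {shape!r}")


def pellet_carbon_ug(volume_mm3) -> np.ndarray:
    """Per-pellet carbon (µg C) from volume via the log-log C:V relation."""
    volume_mm3 = np.asarray(volume_mm3, dtype=float)
    if np.any(volume_mm3 <= 0):
        raise ValueError("pellet volume must be positive")
    out = 10.0 ** (PELLET_C_SLOPE * np.log10(volume_mm3) + PELLET_C_INTERCEPT)
    return float(out) if out.ndim == 0 else out


@dataclass
class PelletFluxResult:
    flux: float  # mg C m⁻² d⁻¹ from intact pellets
    fraction: float  # pellet flux / total POC flux
    n_pellets: int


def pellet_carbon_flux(
    sample: TrapSample, shape: str = "cylinder"
) -> PelletFluxResult:
    """Intact salp-pellet carbon flux and its fraction of the total flux.

    Fractions above 1 (pellet carbon exceeding bulk POC) are reported
    as-is with a warning — they indicate inconsistent morphometrics or a
    low bulk POC, not a computational error.
    """
    if sample.pellets is None or len(sample.pellets) == 0:
        return PelletFluxResult(0.0, 0.0, 0)
    vol = pellet_volume(
        sample.pellets["length"].to_numpy(dtype=float),
        sample.pellets["width"].to_numpy(dtype=float),
        shape,
    )
    carbon_mg = np.sum(pellet_carbon_ug(vol)) * 1e-3
    flux = float(carbon_mg / (sample.collection_area * sample.duration))
    total = poc_flux(sample).value
    fraction = flux / total if total > 0 else float("inf")
    if fraction > 1:
        logger.warning(
            "pellet carbon flux exceeds total POC flux at %.0f m (fraction %.2f)",
            sample.depth, fraction,
        )
    return PelletFluxResult(flux, float(fraction), int(len(sample.pellets)))
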