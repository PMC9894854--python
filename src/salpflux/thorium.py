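"""Export flux from ²³⁸U:²³⁴Th disequilibrium.

²³⁴Th (half-life 24.1 d) is produced at a known rate from conservative,
salinity-derived ²³⁸U and scavenged onto sinking particles; the water
column deficiency A_U − A_Th integrates particle export over roughly a
month.  The steady-state balance gives

    flux = λ·∫₀^z (A_U − A_Th) dz  [+ mixing term −κ·∂²A_Th/∂z²],

and the non-steady-state variant subtracts the rate of change of the
²³⁴Th inventory between two occupations.  POC flux follows by multiplying
with the particulate C:²³⁴Th ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: ²³⁴Th decay constant (d⁻¹) from the 24.1 d half-life.
LAMBDA_234 = 0.02876

#: dpm L⁻¹ → dpm m⁻³
L_PER_M3 = 1000.0

MG_PER_UMOL_C = 12.011e-3  # mg C per µmol C

PROFILE_COLUMNS = ["depth", "a_th", "a_th_sd", "salinity"]


@dataclass
class ThModelConfig:
    """Constants of the ²³⁴Th export balance.

    ``u_coeffs`` = (slope, intercept) of the salinity→²³⁸U relation
    (dpm L⁻¹ per psu); the default is the standard open-ocean relation
    0.0786·S − 0.315.  ``kappa`` (m² d⁻¹) turns on the turbulent-mixing
    correction; it defaults to 0.
    """

    lambda_234: float = LAMBDA_234
    kappa: float = 0.0
    u_coeffs: tuple[float, float] = (0.0786, -0.315)

    def __post_init__(self) -> None:
        if not self.lambda_234 > 0:
            raise ValueError(f"lambda_234 must be > 0, got {self.lambda_234}")
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")


@dataclass
class ThProfile:
    """Total ²³⁴Th activity profile at one date.

    ``samples`` has columns depth (m, strictly increasing), a_th
    (dpm L⁻¹), a_th_sd (dpm L⁻¹), salinity (psu).
    """

    date: pd.Timestamp
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.date = pd.Timestamp(self.date)
        missing = set(PROFILE_COLUMNS) - set(self.samples.columns)
        if missing:
            raise ValueError(f"samples missing columns: {sorted(missing)}")
        z = self.samples["depth"].to_numpy(dtype=float)
        if np.any(np.diff(z) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(self.samples["a_th"].to_numpy(dtype=float) < 0):
            raise ValueError("activities must be >= 0")

    @property
    def max_depth(self) -> float:
        return float(self.samples["depth"].iloc[-1])


@dataclass
class ExportEstimate:
    flux: float  # dpm m⁻² d⁻¹
    sd: float = float("nan")


def u238_from_salinity(salinity, cfg: ThModelConfig = ThModelConfig()):
    """Salinity-derived ²³⁸U activity (dpm L⁻¹)."""
    salinity = np.asarray(salinity, dtype=float)
    slope, intercept = cfg.u_coeffs
    out = slope * salinity + intercept
    return float(out) if out.ndim == 0 else out


def _second_derivative(z: np.ndarray, a: np.ndarray) -> np.ndarray:
    """∂²a/∂z² by central differences on an irregular grid; endpoints copy
    the nearest interior value (one-sided closure)."""
    n = len(z)
    d2 = np.zeros(n)
    if n < 3:
        return d2
    for i in range(1, n - 1):
        h1 = z[i] - z[i - 1]
        h2 = z[i + 1] - z[i]
        d2[i] = 2.0 * (
            a[i - 1] / (h1 * (h1 + h2))
            - a[i] / (h1 * h2)
            + a[i + 1] / (h2 * (h1 + h2))
        )
    d2[0] = d2[1]
    d2[-1] = d2[-2]
    return d2


def _grid_to_depth(profile: ThProfile, z_int: float):
    """Profile arrays extended to the surface (constant continuation) and
    cut/interpolated at the integration depth."""
    if z_int > profile.max_depth:
        raise ValueError(
            f"integration depth {z_int} m exceeds deepest sample "
            f"({profile.max_depth} m)"
        )
    s = profile.samples
    z = s["depth"].to_numpy(dtype=float)
    a = s["a_th"].to_numpy(dtype=float)
    sd = s["a_th_sd"].to_numpy(dtype=float)
    sal = s["salinity"].to_numpy(dtype=float)
    if z[0] > 0:
        z = np.concatenate([[0.0], z])
        a = np.concatenate([[a[0]], a])
        sd = np.concatenate([[sd[0]], sd])
        sal = np.concatenate([[sal[0]], sal])
    keep = z < z_int
    zi = np.concatenate([z[keep], [z_int]])
    ai = np.concatenate([a[keep], [np.interp(z_int, z, a)]])
    sdi = np.concatenate([sd[keep], [np.interp(z_int, z, sd)]])
    sali = np.concatenate([sal[keep], [np.interp(z_int, z, sal)]])
    return zi, ai, sdi, sali


def _trapz_weights(z: np.ndarray) -> np.ndarray:
    w = np.zeros_like(z)
    w[:-1] += 0.5 * np.diff(z)
    w[1:] += 0.5 * np.diff(z)
    return w


def ss_export(
    profile: ThProfile, z_int: float, cfg: ThModelConfig = ThModelConfig()
) -> ExportEstimate:
    """Steady-state ²³⁴Th export (dpm m⁻² d⁻¹) at ``z_int``.

    Trapezoidal integration of the deficiency with constant continuation
    from the shallowest sample to 0 m and linear interpolation to z_int;
    with κ > 0 the mixing supply −κ·∂²A_Th/∂z² is added to the balance.
    Activity uncertainties propagate in quadrature through the trapezoid
    weights.
    """
    z, a_th, sd, sal = _grid_to_depth(profile, z_int)
    a_u = u238_from_salinity(sal, cfg)
    deficiency = a_u - a_th
    flux = cfg.lambda_234 * np.trapezoid(deficiency, z) * L_PER_M3
    if cfg.kappa > 0:
        mixing = -cfg.kappa * _second_derivative(z, a_th)
        flux += np.trapezoid(mixing, z) * L_PER_M3
    w = _trapz_weights(z)
    flux_sd = cfg.lambda_234 * np.sqrt(np.sum((w * sd) ** 2)) * L_PER_M3
    return ExportEstimate(float(flux), float(flux_sd))


def th_inventory(profile: ThProfile, z_int: float) -> float:
    """Trapezoidal ²³⁴Th inventory (dpm m⁻²) from 0 to ``z_int``."""
    z, a_th, _, _ = _grid_to_depth(profile, z_int)
    return float(np.trapezoid(a_th, z) * L_PER_M3)


def nss_export(
    p1: ThProfile,
    p2: ThProfile,
    z_int: float,
    cfg: ThModelConfig = ThModelConfig(),
) -> ExportEstimate:
    """Non-steady-state export between two occupations of the same site.

    flux = λ·∫(A_U − Ā_Th)dz − (I₂ − I₁)/(t₂ − t₁), with Ā_Th the
    two-profile mean activity and I the ²³⁴Th inventory to z_int.  For
    identical profiles this reduces to the steady-state estimate.
    """
    dt = (p2.date - p1.date).total_seconds() / 86400.0
    if not dt > 0 and not (p1.samples.equals(p2.samples) and dt == 0):
        raise ValueError("p2 must be sampled after p1")
    z1, a1, sd1, sal1 = _grid_to_depth(p1, z_int)
    z2, a2, sd2, sal2 = _grid_to_depth(p2, z_int)
    z = np.union1d(z1, z2)
    a_bar = 0.5 * (np.interp(z, z1, a1) + np.interp(z, z2, a2))
    sal_bar = 0.5 * (np.interp(z, z1, sal1) + np.interp(z, z2, sal2))
    a_u = u238_from_salinity(sal_bar, cfg)
    flux = cfg.lambda_234 * np.trapezoid(a_u - a_bar, z) * L_PER_M3
    if cfg.kappa > 0:
        mixing = -cfg.kappa * _second_derivative(z, a_bar)
        flux += np.trapezoid(mixing, z) * L_PER_M3
    if dt > 0:
        i1 = th_inventory(p1, z_int)
        i2 = th_inventory(p2, z_int)
        flux -= (i2 - i1) / dt
    w = _trapz_weights(z)
    sd_bar = 0.5 * np.sqrt(np.interp(z, z1, sd1) ** 2 + np.interp(z, z2, sd2) ** 2)
    var = np.sum((cfg.lambda_234 * w * sd_bar) ** 2)
    if dt > 0:
        w1 = _trapz_weights(z1)
        w2 = _trapz_weights(z2)
        var += (np.sum((w1 * sd1) ** 2) + np.sum((w2 * sd2) ** 2)) / dt**2
    flux_sd = np.sqrt(var) * L_PER_M3
    return ExportEstimate(float(flux), float(flux_sd))


def poc_flux_from_th(th_flux: float, c_to_th: float) -> float:
    """POC flux (mg C m⁻² d⁻¹) from a ²³⁴Th flux and a C:²³⁴Th ratio.

    ``c_to_th`` is in µmol C dpm⁻¹; carbon mass uses 12.011 g mol⁻¹.
    """
    return th_flux * c_to_th * MG_PER_UMOL_C
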