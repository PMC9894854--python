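"""Size-structured salp population estimates from net-tow records.

Double-oblique net tows (0–200 m) yield one row per individual (species,
stage, length).  Lengths are pooled into 5-mm size bins spanning 1–136 mm,
converted to areal abundance (ind m⁻²) via the volumetric concentration and
the tow depth, averaged day/night, and optionally converted to carbon
biomass with user-supplied length–carbon coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: 5-mm length bins spanning 1–136 mm (27 bins), half-open [lo, hi).
BIN_EDGES: np.ndarray = np.arange(1.0, 137.0, 5.0)

STAGES = ("oozooid", "blastozooid")

INDIVIDUAL_COLUMNS = ["species", "stage", "length_total", "length_oal"]


def bin_midpoints(edges: np.ndarray = BIN_EDGES) -> np.ndarray:
    """Midpoints of the size bins, used for all size-dependent rates."""
    edges = np.asarray(edges, dtype=float)
    return 0.5 * (edges[:-1] + edges[1:])


@dataclass
class TowRecord:
    """One net tow: geometry plus per-individual measurements.

    ``individuals`` has one row per animal with columns ``species``,
    ``stage`` (oozooid|blastozooid), ``length_total`` and ``length_oal``
    (mm).  Lengths must lie in (0, 200].
    """

    tow_id: str
    is_night: bool
    volume_filtered: float  # m3
    tow_depth: float  # m
    individuals: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.volume_filtered > 0:
            raise ValueError(
                f"volume_filtered must be > 0, got {self.volume_filtered}"
            )
        if not self.tow_depth > 0:
            raise ValueError(f"tow_depth must be > 0, got {self.tow_depth}")
        if not isinstance(self.individuals, pd.DataFrame):
            self.individuals = pd.DataFrame(
                self.individuals, columns=INDIVIDUAL_COLUMNS
            )
        missing = set(INDIVIDUAL_COLUMNS) - set(self.individuals.columns)
        if missing:
            raise ValueError(f"individuals missing columns: {sorted(missing)}")
        if len(self.individuals):
            oal = self.individuals["length_oal"].to_numpy(dtype=float)
            if np.any(oal <= 0) or np.any(oal > 200):
                raise ValueError("length_oal must be in (0, 200] mm")


@dataclass
class SizeBinnedPopulation:
    """Day/night areal abundance (ind m⁻²) per 5-mm bin and stage.

    ``abundance`` is indexed by bin lower edge with MultiIndex columns
    (stage, period) where period is 'day' or 'night'.
    """

    abundance: pd.DataFrame
    temperature: float
    bin_edges: np.ndarray = field(default_factory=lambda: BIN_EDGES.copy())

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        widths = np.diff(edges)
        if not np.allclose(widths, 5.0):
            raise ValueError("bin_edges must form contiguous 5-mm bins")
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("abundance must be non-negative")

    @property
    def midpoints(self) -> np.ndarray:
        return bin_midpoints(self.bin_edges)

    def stage_abundance(self, stage: str, period: str) -> np.ndarray:
        """Per-bin abundance for one stage and period ('day'|'night')."""
        if (stage, period) in self.abundance.columns:
            return self.abundance[(stage, period)].to_numpy(dtype=float)
        return np.zeros(len(self.abundance), dtype=float)

    def combined(self, stage: str) -> np.ndarray:
        """Day/night-averaged per-bin abundance for one stage."""
        return 0.5 * (
            self.stage_abundance(stage, "day")
            + self.stage_abundance(stage, "night")
        )

    def total_abundance(self, stage: str) -> float:
        """Day/night-averaged areal abundance summed over bins (ind m⁻²)."""
        return float(self.combined(stage).sum())

    def to_long(self) -> pd.DataFrame:
        """Long-format table (stage, bin_lo, bin_hi, period, ind_m2)."""
        rows = []
        edges = np.asarray(self.bin_edges, dtype=float)
        for (stage, period) in self.abundance.columns:
            vals = self.abundance[(stage, period)].to_numpy(dtype=float)
            for lo, hi, v in zip(edges[:-1], edges[1:], vals):
                rows.append(
                    {"stage": stage, "bin_lo": lo, "bin_hi": hi,
                     "period": period, "ind_m2": v}
                )
        return pd.DataFrame(rows)


def bin_lengths(lengths: np.ndarray, edges: np.ndarray = BIN_EDGES) -> np.ndarray:
    """Histogram lengths into half-open [lo, hi) bins, clipping outliers.

    Individuals outside the binned range are assigned to the nearest edge
    bin (and logged); the result is count-conserving.
    """
    lengths = np.asarray(lengths, dtype=float)
    n_out = int(np.sum((lengths < edges[0]) | (lengths >= edges[-1])))
    if n_out:
        logger.warning(
            "%d individual(s) outside %.0f–%.0f mm assigned to edge bins",
            n_out, edges[0], edges[-1],
        )
    clipped = np.clip(lengths, edges[0], np.nextafter(edges[-1], -np.inf))
    idx = np.digitize(clipped, edges) - 1
    counts = np.bincount(idx, minlength=len(edges) - 1)
    return counts.astype(float)


def areal_abundance(
    tow: TowRecord,
    species: str = "Salpa thompsoni",
    edges: np.ndarray = BIN_EDGES,
) -> pd.DataFrame:
    """Per-bin areal abundance (ind m⁻²) by stage for one tow.

    The volumetric concentration (count / volume filtered) is scaled to an
    areal density over the tow depth: areal = count/volume × tow_depth.
    """
    sub = tow.individuals[tow.individuals["species"] == species]
    scale = tow.tow_depth / tow.volume_filtered
    data = {}
    for stage in STAGES:
        lengths = sub.loc[sub["stage"] == stage, "length_oal"].to_numpy(dtype=float)
        data[stage] = bin_lengths(lengths, edges) * scale
    return pd.DataFrame(data, index=edges[:-1])


def day_night_average(
    tows: list[TowRecord],
    species: str = "Salpa thompsoni",
    temperature: float = float("nan"),
    edges: np.ndarray = BIN_EDGES,
) -> SizeBinnedPopulation:
    """Average per-tow areal abundances within day and night groups.

    Per-bin day (night) values are unweighted means over day (night) tows.
    If one period has no tows its columns are filled from the other period
    with a logged warning, so downstream day/night weighting still applies.
    """
    if not tows:
        raise ValueError("at least one tow is required")
    day = [areal_abundance(t, species, edges) for t in tows if not t.is_night]
    night = [areal_abundance(t, species, edges) for t in tows if t.is_night]
    if not day and night:
        logger.warning("no day tows; night mean used for both periods")
        day = night
    elif not night and day:
        logger.warning("no night tows; day mean used for both periods")
        night = day
    day_mean = sum(day) / len(day)
    night_mean = sum(night) / len(night)
    cols = {}
    for stage in STAGES:
        cols[(stage, "day")] = day_mean[stage]
        cols[(stage, "night")] = night_mean[stage]
    abundance = pd.DataFrame(cols, index=edges[:-1])
    abundance.columns = pd.MultiIndex.from_tuples(
        abundance.columns, names=["stage", "period"]
    )
    return SizeBinnedPopulation(abundance, temperature, edges)


def biomass_from_length(
    pop: SizeBinnedPopulation,
    coeffs: tuple[float, float] | None,
) -> dict[str, float]:
    """Carbon biomass (g C m⁻²) per stage from a length–carbon power law.

    ``coeffs`` = (a_w, b_w) with the per-individual carbon content
    a_w·L^b_w in µg C for L in mm, evaluated at bin midpoints.  The
    coefficients are mandatory configuration — the study's source
    relationship is not bundled here.
    """
    if coeffs is None:
        raise ValueError(
            "length–carbon coefficients (a_w, b_w) are required; set them in "
            "configuration (e.g. biomass_coeffs: [a_w, b_w])"
        )
    a_w, b_w = float(coeffs[0]), float(coeffs[1])
    if not a_w > 0:
        raise ValueError(f"a_w must be > 0, got {a_w}")
    mids = pop.midpoints
    per_ind_ugc = a_w * mids**b_w
    return {
        stage: float(np.sum(pop.combined(stage) * per_ind_ugc)) * 1e-6
        for stage in STAGES
    }
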