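"""Seeded synthetic sample tables with the study's factorial structure.

The field campaign this emulates sampled a desert grassland around a
mine-water discharge point: three zones at increasing distance from the
outlet (littoral 0-20 m, riparian 30-60 m, upland 70-100 m), six replicate
plots per zone, three depth layers (0-10, 10-20, 20-30 cm). Five subsamples
per plot were pooled and the pooled sample split into two laboratory
fractions, one assayed for extracellular enzyme activities and one for
physicochemistry and microbial biomass.

The generator draws one value set per (zone, depth, plot) and emits one row
per fraction, so counts per (zone, depth, fraction) match the sampling
design while every analysis column is available on every row. Pooling of
subsamples is not simulated mechanistically: the per-cell standard
deviation is the post-pooling, between-plot variability.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ZONES = ["littoral", "riparian", "upland"]
DEPTHS = ["0-10", "10-20", "20-30"]
FRACTIONS = ["enzyme", "physicochemical"]

#: Midpoint (m) of each zone's distance band from the discharge point.
ZONE_DISTANCES = {"littoral": 10.0, "riparian": 45.0, "upland": 85.0}

#: Midpoint (cm) of each depth layer, used wherever depth enters numerically.
DEPTH_MIDPOINTS = {"0-10": 5.0, "10-20": 15.0, "20-30": 25.0}

ENZYMES = ["BG", "NAG", "LAP", "ALP"]

#: Variable -> unit, in generation order.
VARIABLES = {
    "BG": "nmol g-1 h-1",
    "NAG": "nmol g-1 h-1",
    "LAP": "nmol g-1 h-1",
    "ALP": "nmol g-1 h-1",
    "pH": "unitless",
    "SMC": "%",
    "salinity": "g kg-1",
    "SOC": "g kg-1",
    "TN": "g kg-1",
    "TP": "g kg-1",
    "AP": "mg kg-1",
    "NO3_N": "mg kg-1",
    "NH4_N": "mg kg-1",
    "MBC": "mg kg-1",
    "MBN": "mg kg-1",
    "MBP": "mg kg-1",
}

#: Hard truncation bounds applied by the truncated-normal family.
_BOUNDS = {"pH": (0.0, 14.0), "SMC": (0.0, 100.0)}

ID_COLUMNS = ["zone", "depth_layer", "plot_id", "fraction", "mining_distance"]


class DesignError(ValueError):
    """Invalid generator design (missing cells, negative sd, bad levels)."""


@dataclass
class DesignSpec:
    """Per-cell distribution parameters for the factorial generator.

    cell_params maps (zone, depth, variable) -> (mean, sd); distribution
    maps variable -> "truncnorm" (truncated at 0, and at physical upper
    bounds for pH/SMC) or "lognormal" (moment-matched to mean/sd,
    structurally positive — the default for enzyme activities, whose
    natural logs must stay positive downstream).
    """

    zones: list[str] = field(default_factory=lambda: list(ZONES))
    depths: list[str] = field(default_factory=lambda: list(DEPTHS))
    plots_per_zone: int = 6
    variables: list[str] = field(default_factory=lambda: list(VARIABLES))
    cell_params: dict[tuple[str, str, str], tuple[float, float]] = field(
        default_factory=dict
    )
    distribution: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.plots_per_zone < 2:
            raise DesignError("plots_per_zone must be >= 2")
        for var in self.variables:
            fam = self.distribution.get(var, "truncnorm")
            if fam not in ("truncnorm", "lognormal"):
                raise DesignError(f"unknown distribution family {fam!r} for {var}")
            for zone in self.zones:
                for depth in self.depths:
                    key = (zone, depth, var)
                    if key not in self.cell_params:
                        raise DesignError(f"missing cell parameters for {key}")
                    mean, sd = self.cell_params[key]
                    if sd < 0:
                        raise DesignError(f"negative sd for {key}: {sd}")
                    if var in ENZYMES and mean <= 0:
                        raise DesignError(
                            f"enzyme mean must be strictly positive for {key}: {mean}"
                        )


def _truncnorm_loc(mean, sd, lo, hi):
    """Location parameter whose [lo, hi]-truncated normal has the given mean.

    Truncation pulls the mean away from the location; left uncorrected this
    bias exceeds sampling error for cells whose mean sits within ~2.5 sd of
    a bound. The truncated mean is strictly increasing in the location, so
    a bracketed root-find on the closed form recovers it.
    """
    from scipy.optimize import brentq

    def trunc_mean(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        num = stats.norm.pdf(a) - stats.norm.pdf(b)
        den = stats.norm.cdf(b) - stats.norm.cdf(a)
        return mu + sd * num / den

    if abs(trunc_mean(mean) - mean) < 1e-12 * max(1.0, abs(mean)):
        return mean
    return brentq(lambda mu: trunc_mean(mu) - mean, mean - 8 * sd, mean + 8 * sd)


def _draw(rng, family, mean, sd, n, bounds):
    if sd == 0:
        return np.full(n, float(mean))
    if family == "lognormal":
        # Moment match: arithmetic mean/sd of the lognormal equal (mean, sd).
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
    lo, hi = bounds
    loc = _truncnorm_loc(mean, sd, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)


def generate_dataset(design: DesignSpec, seed: int | None = None) -> pd.DataFrame:
    """Generate one sample table from a design; deterministic per seed.

    Returns a DataFrame with one row per (zone, depth, plot, fraction) and
    one column per design variable; the two fraction rows of a plot share
    identical measured values (they are splits of one pooled sample).
    """
    design.validate()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    rows = []
    for zone in design.zones:
        for depth in design.depths:
            draws = {}
            for var in design.variables:
                mean, sd = design.cell_params[(zone, depth, var)]
                fam = design.distribution.get(var, "truncnorm")
                draws[var] = _draw(
                    rng, fam, mean, sd, design.plots_per_zone,
                    _BOUNDS.get(var, (0.0, np.inf)),
                )
            for p in range(design.plots_per_zone):
                base = {
                    "zone": zone,
                    "depth_layer": depth,
                    "plot_id": f"{zone[0].upper()}{p + 1}",
                    "mining_distance": ZONE_DISTANCES.get(zone, np.nan),
                }
                base.update({var: draws[var][p] for var in design.variables})
                for fraction in FRACTIONS:
                    rows.append({**base, "fraction": fraction})
    df = pd.DataFrame(rows)
    return df[ID_COLUMNS + list(design.variables)]


def inject_effect(
    design: DesignSpec,
    variable: str,
    factor: str,
    contrast: dict[str, float],
) -> DesignSpec:
    """Return a copy of the design with cell means additively shifted.

    ``factor`` is "zone" or "depth"; ``contrast`` maps factor levels to the
    shift applied to every cell at that level. The input design is unchanged.
    """
    if variable not in design.variables:
        raise DesignError(f"unknown variable {variable!r}")
    levels = design.zones if factor == "zone" else design.depths
    if factor not in ("zone", "depth"):
        raise DesignError(f"factor must be 'zone' or 'depth', got {factor!r}")
    for level in contrast:
        if level not in levels:
            raise DesignError(f"unknown {factor} level {level!r}")
    out = copy.deepcopy(design)
    for zone in out.zones:
        for depth in out.depths:
            level = zone if factor == "zone" else depth
            shift = contrast.get(level, 0.0)
            mean, sd = out.cell_params[(zone, depth, variable)]
            out.cell_params[(zone, depth, variable)] = (mean + shift, sd)
    return out


# --- preset study design ----------------------------------------------------

# Zone multipliers for enzyme activities: the littoral zone, wetted and
# salinized by the discharge, carries the highest activities of all four
# enzymes at every depth; the riparian zone is intermediate.
_ZONE_MULT = {
    "BG": {"littoral": 1.8, "riparian": 1.2, "upland": 1.0},
    "NAG": {"littoral": 1.8, "riparian": 1.15, "upland": 1.0},
    "LAP": {"littoral": 1.8, "riparian": 1.1, "upland": 1.0},
    "ALP": {"littoral": 1.6, "riparian": 1.3, "upland": 1.0},
}

# Upland-baseline depth profiles (nmol g-1 h-1): C-acquisition (BG) falls
# with depth as labile carbon thins out; alkaline phosphatase rises with
# depth as phosphorus limitation intensifies, and exceeds NAG+LAP in every
# cell so expected vector angles sit above 45 degrees.
_ENZ_DEPTH = {
    "BG": {"0-10": 60.0, "10-20": 25.0, "20-30": 8.0},
    "NAG": {"0-10": 12.0, "10-20": 9.0, "20-30": 7.0},
    "LAP": {"0-10": 14.0, "10-20": 10.0, "20-30": 7.0},
    "ALP": {"0-10": 250.0, "10-20": 700.0, "20-30": 1600.0},
}
_ENZ_CV = 0.25

# Physicochemistry and microbial biomass: (mean per zone/depth, sd).
# Patterns: moisture and salinity highest littoral; moisture rising and
# available P falling with depth; SOC highest littoral and falling with
# depth; TN/TP depressed in the riparian zone; biomass C/N falling with
# depth away from the littoral zone; biomass P peaking mid-profile upland.
_PHYS = {
    "pH": ({"littoral": 7.9, "riparian": 8.3, "upland": 8.4}, 0.15),
    "salinity": ({"littoral": 3.5, "riparian": 1.8, "upland": 0.8}, 0.4),
    "TN": ({"littoral": 0.80, "riparian": 0.50, "upland": 0.75}, 0.08),
    "TP": ({"littoral": 0.60, "riparian": 0.40, "upland": 0.55}, 0.05),
    "NO3_N": ({"littoral": 5.0, "riparian": 5.0, "upland": 5.0}, 1.0),
    "NH4_N": ({"littoral": 4.0, "riparian": 4.0, "upland": 4.0}, 0.8),
}
_PHYS_DEPTH = {
    "SMC": (
        {
            "littoral": {"0-10": 12.0, "10-20": 14.0, "20-30": 16.0},
            "riparian": {"0-10": 7.0, "10-20": 9.0, "20-30": 11.0},
            "upland": {"0-10": 4.0, "10-20": 6.0, "20-30": 8.0},
        },
        1.5,
    ),
    "SOC": (
        {
            "littoral": {"0-10": 8.0, "10-20": 7.0, "20-30": 4.0},
            "riparian": {"0-10": 5.0, "10-20": 4.5, "20-30": 3.0},
            "upland": {"0-10": 4.5, "10-20": 4.0, "20-30": 3.0},
        },
        0.8,
    ),
    "AP": (
        {
            z: {"0-10": 12.0, "10-20": 8.0, "20-30": 5.0}
            for z in ZONES
        },
        1.5,
    ),
    "MBC": (
        {
            "littoral": {"0-10": 150.0, "10-20": 150.0, "20-30": 150.0},
            "riparian": {"0-10": 220.0, "10-20": 160.0, "20-30": 110.0},
            "upland": {"0-10": 200.0, "10-20": 150.0, "20-30": 100.0},
        },
        25.0,
    ),
    "MBN": (
        {
            "littoral": {"0-10": 20.0, "10-20": 20.0, "20-30": 20.0},
            "riparian": {"0-10": 30.0, "10-20": 22.0, "20-30": 15.0},
            "upland": {"0-10": 28.0, "10-20": 20.0, "20-30": 14.0},
        },
        4.0,
    ),
    "MBP": (
        {
            "littoral": {"0-10": 12.0, "10-20": 12.0, "20-30": 12.0},
            "riparian": {"0-10": 8.0, "10-20": 8.0, "20-30": 8.0},
            "upland": {"0-10": 7.0, "10-20": 10.0, "20-30": 7.0},
        },
        1.5,
    ),
}


def preset_study_design(seed: int = 0) -> DesignSpec:
    """Fully populated 3-zone x 3-depth x 6-plot design.

    Cell means reproduce, in expectation, the study's qualitative spatial
    patterns: BG monotone decreasing and ALP monotone increasing with depth
    in every zone, littoral highest for all four enzymes at each depth, and
    ALP above NAG+LAP in every cell so that mean vector angles exceed 45
    degrees (phosphorus limitation).
    """
    cell_params: dict[tuple[str, str, str], tuple[float, float]] = {}
    for var in ENZYMES:
        for zone in ZONES:
            for depth in DEPTHS:
                mean = _ENZ_DEPTH[var][depth] * _ZONE_MULT[var][zone]
                cell_params[(zone, depth, var)] = (mean, _ENZ_CV * mean)
    for var, (zone_means, sd) in _PHYS.items():
        for zone in ZONES:
            for depth in DEPTHS:
                cell_params[(zone, depth, var)] = (zone_means[zone], sd)
    for var, (table, sd) in _PHYS_DEPTH.items():
        for zone in ZONES:
            for depth in DEPTHS:
                cell_params[(zone, depth, var)] = (table[zone][depth], sd)
    distribution = {var: "lognormal" for var in ENZYMES}
    distribution.update({var: "truncnorm" for var in VARIABLES if var not in ENZYMES})
    return DesignSpec(
        cell_params=cell_params, distribution=distribution, seed=seed
    )


def write_samples_csv(df: pd.DataFrame, path) -> None:
    """Write the sample table (UTF-8, '.' decimal, empty cell = missing)."""
    df.to_csv(path, index=False)


def read_samples_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
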