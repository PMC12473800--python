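"""Seedable synthetic sediment-sample generator.

The study design this generator emulates is a six-station river survey
split into an upper reach (Yanacancha, San Juan de Jarpa, Colpa) and a
lower reach (Angasmayo, San Blas, La Perla), sampled in the wet-season
months, with a downstream enrichment gradient for most elements.  Only
zone-level summary statistics (mean, SD per element) are published, so
the generator is moment-matched at the zone level: concentrations are
drawn from a lognormal with

    location = ln(m^2 / sqrt(m^2 + s^2)),   scale^2 = ln(1 + s^2 / m^2),

which has exactly mean m and SD s.  The lognormal is the natural choice
for nonnegative, right-skewed geochemical data (several elements here
have SD of the same order as the mean); a truncated-normal alternative
is selectable but is only approximately moment-matched.  Per-site
targets are an interpolation — the output is synthetic, never a
reconstruction of the unpublished raw data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .sample_io import SampleTable

__all__ = [
    "ZONE_STATS",
    "ZoneGeneratorSpec",
    "default_cunas_spec",
    "lognormal_moment_matched",
    "generate",
    "generate_worked_fixture",
    "WORKED_EXPECTED",
]

# Zone-level (mean, SD) in mg/kg for the thirteen measured elements.
# Zn lower-zone mean carries one more significant figure than the summary
# table (101.3 vs 101), taken from the running text.
ZONE_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "upper": {
        "Cu": (6.2, 2.2), "Cr": (7.8, 2.6), "Fe": (9094.0, 1939.0),
        "Mn": (316.0, 140.0), "Mo": (0.5, 0.2), "Ni": (7.1, 4.3),
        "V": (23.4, 4.5), "Cd": (0.2, 0.2), "Hg": (0.2, 0.1),
        "Pb": (11.1, 9.2), "Zn": (35.9, 48.9), "Sb": (0.4, 0.2),
        "As": (7.7, 7.6),
    },
    "lower": {
        "Cu": (8.1, 2.6), "Cr": (9.5, 3.1), "Fe": (9986.0, 1607.0),
        "Mn": (413.0, 197.0), "Mo": (0.9, 0.4), "Ni": (11.0, 4.2),
        "V": (26.9, 2.0), "Cd": (0.4, 0.1), "Hg": (0.1, 0.1),
        "Pb": (23.1, 10.4), "Zn": (101.3, 58.7), "Sb": (1.1, 0.8),
        "As": (15.4, 7.1),
    },
}

UPPER_SITES = ("Yanacancha", "San Juan de Jarpa", "Colpa")
LOWER_SITES = ("Angasmayo", "San Blas", "La Perla")


@dataclass(frozen=True)
class ZoneGeneratorSpec:
    """Parameters of the synthetic survey.

    ``zone_params[zone][element] = (target_mean, target_sd)`` in mg/kg;
    ``sites`` is a sequence of (name, zone) pairs; each site is sampled
    ``replicates_per_site`` times in every month.  ``site_effect_sd`` is
    the log-scale SD of an optional mean-one multiplicative site effect
    (default 0 so zone-level moments are exact).
    """

    zone_params: dict[str, dict[str, tuple[float, float]]]
    sites: tuple[tuple[str, str], ...]
    replicates_per_site: int = 1
    months: tuple[str, ...] = ("February", "March")
    site_effect_sd: float = 0.0
    seed: int = 0
    distribution: str = "lognormal"

    def __post_init__(self) -> None:
        for zone, params in self.zone_params.items():
            for el, (m, s) in params.items():
                if s < 0:
                    raise ValueError(f"{zone}/{el}: target_sd must be >= 0, got {s}")
                if m <= 0 and s > 0:
                    raise ValueError(
                        f"{zone}/{el}: positive SD with non-positive mean is invalid"
                    )
        zones = {zone for _, zone in self.sites}
        missing = zones - set(self.zone_params)
        if missing:
            raise ValueError(f"no zone parameters for zones {sorted(missing)}")
        if self.replicates_per_site < 1:
            raise ValueError("replicates_per_site must be >= 1")
        if self.site_effect_sd < 0:
            raise ValueError("site_effect_sd must be >= 0")
        if self.distribution not in ("lognormal", "truncnorm"):
            raise ValueError(f"unknown distribution {self.distribution!r}")


def default_cunas_spec(
    replicates_per_site: int = 1, seed: int = 0, site_effect_sd: float = 0.0
) -> ZoneGeneratorSpec:
    """The six-station, two-zone survey with the published zone statistics."""
    sites = tuple((s, "upper") for s in UPPER_SITES) + tuple(
        (s, "lower") for s in LOWER_SITES
    )
    return ZoneGeneratorSpec(
        zone_params={z: dict(p) for z, p in ZONE_STATS.items()},
        sites=sites,
        replicates_per_site=replicates_per_site,
        seed=seed,
        site_effect_sd=site_effect_sd,
    )


def lognormal_moment_matched(
    mean: float, sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n lognormal values with exact first two moments (mean, sd).

    sd = 0 degenerates to a point mass at the mean.
    """
    if mean <= 0:
        raise ValueError(f"mean must be > 0, got {mean}")
    if sd == 0:
        return np.full(n, mean, dtype=float)
    mu = math.log(mean * mean / math.sqrt(mean * mean + sd * sd))
    sigma = math.sqrt(math.log(1.0 + (sd * sd) / (mean * mean)))
    return rng.lognormal(mu, sigma, size=n)


def _truncnorm_draws(
    mean: float, sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean, dtype=float)
    a = (0.0 - mean) / sd  # truncate at zero; moments shift slightly upward
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def generate(spec: ZoneGeneratorSpec) -> SampleTable:
    """Generate a synthetic :class:`SampleTable` from *spec*.

    Deterministic for a fixed seed: draw order is (site, element) in spec
    order, one vector of months x replicates per pair.
    """
    rng = np.random.default_rng(spec.seed)
    draw = (
        lognormal_moment_matched
        if spec.distribution == "lognormal"
        else _truncnorm_draws
    )
    n_rows_per_site = len(spec.months) * spec.replicates_per_site
    elements = list(
        dict.fromkeys(
            el for zone in spec.zone_params.values() for el in zone
        )
    )
    frames = []
    for site, zone in spec.sites:
        params = spec.zone_params[zone]
        block = {
            "site": site,
            "zone": zone,
            "month": np.repeat(spec.months, spec.replicates_per_site),
            "replicate": np.tile(
                np.arange(1, spec.replicates_per_site + 1), len(spec.months)
            ),
        }
        for el in elements:
            if el not in params:
                block[el] = np.full(n_rows_per_site, np.nan)
                continue
            m, s = params[el]
            values = draw(m, s, n_rows_per_site, rng)
            if spec.site_effect_sd > 0:
                # mean-one lognormal site effect, one multiplier per (site, element)
                effect = rng.lognormal(
                    -0.5 * spec.site_effect_sd**2, spec.site_effect_sd
                )
                values = values * effect
            block[el] = values
        frames.append(pd.DataFrame(block))
    return SampleTable(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Worked fixture: a tiny deterministic table with hand-computable indices.

_FIXTURE_ROWS = [
    # site, zone, As, Cd, Zn, Fe  (mg/kg; chosen for round Cf under the UCC
    # baseline: As/1.5, Cd/0.1, Zn/95, Fe/47200)
    ("Colpa", "upper", 11.25, 0.35, 95.0, 47200.0),
    ("La Perla", "lower", 3.0, 0.7, 190.0, 23600.0),
]

# Expected values for the fixture under the built-in UCC baseline, default
# toxic response factors (As 10, Cd 30, Zn 1) and default adult exposure /
# dose-response parameters.  Each entry is hand arithmetic (or a literal
# closed form) independent of the pipeline code.
WORKED_EXPECTED = {
    "cf": {
        "Colpa": {"As": 7.5, "Cd": 3.5, "Zn": 1.0, "Fe": 1.0},
        "La Perla": {"As": 2.0, "Cd": 7.0, "Zn": 2.0, "Fe": 0.5},
    },
    "cf_category": {
        "Colpa": {"As": "very high", "Cd": "high", "Zn": "moderate", "Fe": "moderate"},
        "La Perla": {"As": "moderate", "Cd": "very high", "Zn": "moderate", "Fe": "low"},
    },
    "igeo": {  # log2(Cf / 1.5)
        "Colpa": {"As": math.log2(5.0), "Cd": math.log2(3.5 / 1.5), "Zn": math.log2(1 / 1.5)},
        "La Perla": {"As": math.log2(2 / 1.5), "Cd": math.log2(7.0 / 1.5), "Zn": math.log2(2 / 1.5)},
    },
    "er": {  # T * Cf over the {As, Cd, Zn} risk set
        "Colpa": {"As": 75.0, "Cd": 105.0, "Zn": 1.0},
        "La Perla": {"As": 20.0, "Cd": 210.0, "Zn": 2.0},
    },
    "ri": {"Colpa": 181.0, "La Perla": 232.0},
    "ri_category": {"Colpa": "moderate", "La Perla": "considerable"},
    # Pooled ascending ranks of the six {As, Cd, Zn} Cf values:
    # 1.0->1, 2.0&2.0->2.5 each, 3.5->4, 7.0->5, 7.5->6.
    # Colpa: (6+4+1)/6/3*100; La Perla: (2.5+5+2.5)/6/3*100.
    "sri": {"Colpa": 1100.0 / 18.0, "La Perla": 1000.0 / 18.0},
    # Adult, As at Colpa (cm = 11.25), default profile and dose-response:
    # single-expression oracles for the ingestion route.
    "adult_As_Colpa": {
        "cdd_ing_nc": 11.25 * 100 * 24 * 350 / (70 * (24 * 365)) * 1e-6,
        "cdd_ing_ca": 11.25 * 100 * 24 * 350 / (70 * (70 * 365)) * 1e-6,
        "hq_ing": (11.25 * 100 * 24 * 350 / (70 * (24 * 365)) * 1e-6) / 3.0e-4,
        "cr_ing": (11.25 * 100 * 24 * 350 / (70 * (70 * 365)) * 1e-6) * 1.5,
    },
}


def generate_worked_fixture() -> SampleTable:
    """A two-site, four-element deterministic table whose index values are
    hand-computable; the expected values live in :data:`WORKED_EXPECTED`."""
    rows = [
        {
            "site": site, "zone": zone, "month": "February", "replicate": 1,
            "As": as_, "Cd": cd, "Zn": zn, "Fe": fe,
        }
        for site, zone, as_, cd, zn, fe in _FIXTURE_ROWS
    ]
    return SampleTable(pd.DataFrame(rows))
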