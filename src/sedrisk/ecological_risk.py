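"""Ecological risk: Hakanson's Er/RI and the rank-based Site Ranking Index.

Per element, the ecological risk factor is the toxic-response-weighted
contamination factor, Er = T * Cf; the Potential Ecological Risk Index RI
of a site is the sum of its Er values.  RI is classified into four bands
(boundaries follow the source inequalities literally):

    low RI <= 95;  moderate 95 < RI <= 190;
    considerable 190 < RI <= 380;  very high RI > 380.

The Site Ranking Index (SRI) is a nonparametric cross-site summary.  All
(site, contaminant) values in the collection are ranked ascending, once
under Cf and once under Igeo (average ranks on ties); a contaminant's
rank n_i is the mean of its two ranks.  For a site carrying S
contaminants,

    W = sum_i n_i / sum_{i=1..S} i,      SRI = (W / S) * 100,

so a lone site whose contaminants occupy exactly positions 1..S has
W = 1 and SRI = 100/S.  Sites are categorised against the spread of the
collection: low < median-SD; moderate [median-SD, median); high
[median, median+SD]; severe > median+SD.  When every site has the same
SRI the SD is 0 and all sites collapse to the median rule ("high").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .reference_data import ToxicResponseFactors

__all__ = [
    "RI_BANDS",
    "ecological_risk_factor",
    "potential_ecological_risk",
    "sri_from_ranks",
    "pooled_average_ranks",
    "site_ranking_index",
    "sri_categories",
    "EcologicalRiskResult",
]

RI_BANDS = ((95.0, "low"), (190.0, "moderate"), (380.0, "considerable"))


def ecological_risk_factor(tr: ToxicResponseFactors, cf: float, element: str) -> float:
    """Er = T(element) * Cf (dimensionless)."""
    if cf < 0:
        raise ValueError(f"contamination factor must be >= 0, got {cf!r}")
    return tr[element] * cf


def ri_category(ri: float) -> str:
    for upper, label in RI_BANDS:
        if ri <= upper:
            return label
    return "very high"


def potential_ecological_risk(er_values: Mapping[str, float]) -> tuple[float, str]:
    """RI = sum of the per-element risk factors, with its four-band label."""
    if not er_values:
        raise ValueError("RI needs at least one Er value")
    ri = float(sum(er_values.values()))
    return ri, ri_category(ri)


# ---------------------------------------------------------------------------
# Site Ranking Index


def sri_from_ranks(n_ranks: Sequence[float]) -> float:
    """SRI from a site's contaminant ranks: W = sum(n)/sum(1..S), SRI = W/S*100."""
    n = np.asarray(n_ranks, dtype=float)
    s = n.size
    if s < 2:
        raise ValueError(f"SRI needs at least 2 contaminants, got {s}")
    w = float(n.sum()) / (s * (s + 1) / 2.0)
    return w / s * 100.0


def pooled_average_ranks(
    cf_by_site: Mapping[str, Mapping[str, float]],
    igeo_by_site: Mapping[str, Mapping[str, float]],
) -> dict[str, dict[str, float]]:
    """Ascending ranks of every (site, contaminant) value across the pooled
    collection, averaged between the Cf and Igeo orderings (ties -> average
    rank).  Both inputs must cover the same (site, contaminant) pairs."""
    keys = [(site, el) for site, vals in cf_by_site.items() for el in vals]
    if {(s, e) for s, vals in igeo_by_site.items() for e in vals} != set(keys):
        raise ValueError("Cf and Igeo rankings must cover the same (site, element) pairs")
    cf_ranks = rankdata([cf_by_site[s][e] for s, e in keys], method="average")
    igeo_ranks = rankdata([igeo_by_site[s][e] for s, e in keys], method="average")
    avg = (cf_ranks + igeo_ranks) / 2.0
    out: dict[str, dict[str, float]] = {site: {} for site in cf_by_site}
    for (site, el), rank in zip(keys, avg):
        out[site][el] = float(rank)
    return out


def site_ranking_index(
    cf_by_site: Mapping[str, Mapping[str, float]],
    igeo_by_site: Mapping[str, Mapping[str, float]],
) -> dict[str, float]:
    """SRI per site from pooled Cf/Igeo rankings across the site collection."""
    ranks = pooled_average_ranks(cf_by_site, igeo_by_site)
    return {site: sri_from_ranks(list(r.values())) for site, r in ranks.items()}


def sri_categories(sri_by_site: Mapping[str, float]) -> dict[str, str]:
    """Median +/- SD categorisation of a collection of site SRI values.

    Sample (n-1) SD; a single site, or identical sites (SD 0), fall on the
    median and are labelled "high" under the closed [median, median+SD] band.
    """
    values = np.asarray(list(sri_by_site.values()), dtype=float)
    med = float(np.median(values))
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    out = {}
    for site, sri in sri_by_site.items():
        if sri < med - sd:
            label = "low"
        elif sri < med:
            label = "moderate"
        elif sri <= med + sd:
            label = "high"
        else:
            label = "severe"
        out[site] = label
    return out


@dataclass(frozen=True)
class EcologicalRiskResult:
    """Per-site ecological risk bundle."""

    site: str
    er: dict[str, float]
    ri: float
    ri_category: str
    sri: float
    sri_category: str
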