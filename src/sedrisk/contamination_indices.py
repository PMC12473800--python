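"""Sediment contamination indices: Cf, Igeo, EF, PLI, mCd.

All five indices are ratios of measured concentration to a geochemical
background and differ only in aggregation and scaling:

* Cf  = C_sample / C_background                     (contamination factor)
* Igeo = log2(C_sample / (1.5 * C_background))       (geoaccumulation index)
* EF  = (C/Fe)_sample / (C/Fe)_background            (enrichment factor)
* PLI = geometric mean of the Cf values at a site    (pollution load index)
* mCd = arithmetic mean of the Cf values at a site   (modified degree)

The 1.5 factor in Igeo buffers natural lithogenic variability; Fe is the
conventional conservative reference element for EF.  Band boundaries are
left-closed/right-open except where the literature states a strict
inequality (Cf < 1, EF > 1.5), which is honoured literally; the bands in
force are recorded on every returned value as ``scheme_note``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "IndexValue",
    "contamination_factor",
    "geoaccumulation_index",
    "enrichment_factor",
    "pollution_load_index",
    "modified_contamination_degree",
    "CF_BANDS",
    "IGEO_BANDS",
    "MCD_BANDS",
    "EF_ANTHROPOGENIC_THRESHOLD",
    "PLI_CONTAMINATED_THRESHOLD",
    "PLI_SITE_CRITICAL",
]

IGEO_BELOW_SCALE = "below scale"

# (upper bound, label); value belongs to the first band whose upper bound
# strictly exceeds it, i.e. bands are [lower, upper).  Cf < 1 "low" is the
# literal strict form.
CF_BANDS = ((1.0, "low"), (3.0, "moderate"), (6.0, "high"), (math.inf, "very high"))

# Mueller's seven classes: class 0 is Igeo <= 0, then unit-width bands
# (k-1, k] up to class 6 for Igeo > 5.
IGEO_BANDS = (
    (0.0, "unpolluted"),
    (1.0, "unpolluted to moderately polluted"),
    (2.0, "moderately polluted"),
    (3.0, "moderately to heavily polluted"),
    (4.0, "heavily polluted"),
    (5.0, "heavily to extremely polluted"),
    (math.inf, "extremely polluted"),
)

# Abrahim & Parker doubling bands for the modified contamination degree.
MCD_BANDS = (
    (1.5, "nil to very low"),
    (2.0, "low"),
    (4.0, "moderate"),
    (8.0, "high"),
    (16.0, "very high"),
    (32.0, "extremely high"),
    (math.inf, "ultra high"),
)

EF_ANTHROPOGENIC_THRESHOLD = 1.5  # strict: EF > 1.5 flags anthropogenic input
PLI_CONTAMINATED_THRESHOLD = 1.0  # PLI > 1 flags contamination
PLI_SITE_CRITICAL = 1.3           # site-level critical burden flag


@dataclass(frozen=True)
class IndexValue:
    """One computed index with its category under the documented bands."""

    index_name: str
    value: float
    category: str
    scheme_note: str


def _band(value: float, bands) -> str:
    for upper, label in bands:
        if value < upper:
            return label
    return bands[-1][1]


def _igeo_category(value: float) -> str:
    # Igeo bands are (k-1, k]: closed on the right, so <= not <.
    for upper, label in IGEO_BANDS:
        if value <= upper:
            return label
    return IGEO_BANDS[-1][1]


def contamination_factor(c_sample: float, c_background: float) -> IndexValue:
    """Cf = C_sample / C_background with the four-band classification."""
    if not c_background > 0:
        raise ValueError(f"background concentration must be > 0, got {c_background!r}")
    if c_sample < 0:
        raise ValueError(f"sample concentration must be >= 0, got {c_sample!r}")
    value = c_sample / c_background
    return IndexValue(
        "Cf", value, _band(value, CF_BANDS),
        "Cf<1 low; [1,3) moderate; [3,6) high; >=6 very high",
    )


def geoaccumulation_index(c_sample: float, c_background: float) -> IndexValue:
    """Igeo = log2(C_sample / (1.5 * C_background)), seven Mueller classes.

    A zero sample concentration maps to the sentinel category
    ``"below scale"`` with value -inf rather than raising.
    """
    if not c_background > 0:
        raise ValueError(f"background concentration must be > 0, got {c_background!r}")
    if c_sample < 0:
        raise ValueError(f"sample concentration must be >= 0, got {c_sample!r}")
    note = "class 0 <=0, then unit bands (k-1,k] to class 6 >5"
    if c_sample == 0:
        return IndexValue("Igeo", -math.inf, IGEO_BELOW_SCALE, note)
    value = math.log2(c_sample / (1.5 * c_background))
    return IndexValue("Igeo", value, _igeo_category(value), note)


def enrichment_factor(
    c_sample: float, fe_sample: float, c_background: float, fe_background: float
) -> IndexValue:
    """EF = (C/Fe)_sample / (C/Fe)_background; EF > 1.5 is anthropogenic."""
    for name, v in (
        ("c_sample", c_sample), ("fe_sample", fe_sample),
        ("c_background", c_background), ("fe_background", fe_background),
    ):
        if not v > 0:
            raise ValueError(f"{name} must be > 0 for EF, got {v!r}")
    value = (c_sample / fe_sample) / (c_background / fe_background)
    category = "anthropogenic" if value > EF_ANTHROPOGENIC_THRESHOLD else "natural"
    return IndexValue("EF", value, category, "EF>1.5 anthropogenic (strict)")


def pollution_load_index(cf_values: Sequence[float]) -> IndexValue:
    """PLI = geometric mean of the contamination factors at a site.

    Computed as exp(mean(log Cf)) for numerical stability; a zero Cf makes
    the geometric mean degenerate and raises.
    """
    cf = np.asarray(cf_values, dtype=float)
    if cf.size == 0:
        raise ValueError("PLI needs at least one contamination factor")
    if (cf <= 0).any():
        raise ValueError("PLI undefined for non-positive contamination factors")
    value = float(np.exp(np.mean(np.log(cf))))
    category = "contaminated" if value > PLI_CONTAMINATED_THRESHOLD else "uncontaminated"
    return IndexValue(
        "PLI", value, category,
        f"PLI>1 contaminated; PLI>{PLI_SITE_CRITICAL} critical site burden",
    )


def modified_contamination_degree(cf_values: Sequence[float]) -> IndexValue:
    """mCd = arithmetic mean of the contamination factors at a site."""
    cf = np.asarray(cf_values, dtype=float)
    if cf.size == 0:
        raise ValueError("mCd needs at least one contamination factor")
    value = float(np.mean(cf))
    return IndexValue(
        "mCd", value, _band(value, MCD_BANDS),
        "<1.5 nil/very low, then doubling bands (Abrahim & Parker)",
    )
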