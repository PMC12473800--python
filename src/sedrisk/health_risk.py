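"""Human health risk: chronic daily doses, HQ/HI, CR/TCR, contributions.

Exposure to sediment-bound metals is modelled through three routes.  With
CM the sediment concentration (mg/kg), profile parameters as documented
in :class:`~sedrisk.reference_data.ExposureProfile`, and AET the
averaging time for the chosen endpoint (non-carcinogenic: ED x 365 days;
carcinogenic: 70-year lifetime):

    CDD_ing  = CM * IR * ED * EF / (ABW * AET) * CFU
    CDD_inh  = CM * IHR * ED * EF / (ABW * AET * PEF)
    CDD_derm = CM * SA * SAF * DAF * ED * EF / (ABW * AET) * CFU

Non-carcinogenic risk: HQ = CDD / RfD per route, HI = sum of HQs; HI > 1
flags a possible chronic adverse effect.  Carcinogenic risk: CR_ing =
CDD_ing * SF, CR_inh = CDD_inh * IUR, and dermal risk defaults to the
conventional dermal slope factor SF/GIABS (selectable); TCR = sum of CR
over routes, with < 1e-6 no significant risk, 1e-6..1e-4 acceptable,
> 1e-4 unacceptable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .reference_data import (
    DoseResponseTable,
    ElementDoseResponse,
    ExposureProfile,
)

__all__ = [
    "ROUTES",
    "cdd_ingestion",
    "cdd_inhalation",
    "cdd_dermal",
    "chronic_daily_dose",
    "hazard_quotient",
    "hazard_index",
    "hi_category",
    "carcinogenic_risk",
    "tcr_category",
    "risk_contributions",
    "assess_health_risk",
]

ROUTES = ("ing", "inh", "derm")

TCR_NO_SIGNIFICANT = 1.0e-6
TCR_UNACCEPTABLE = 1.0e-4


def cdd_ingestion(cm: float, p: ExposureProfile, averaging: str = "nc") -> float:
    """Chronic daily dose via incidental sediment ingestion (mg/kg/day)."""
    if cm < 0:
        raise ValueError(f"concentration must be >= 0, got {cm!r}")
    return cm * p.IR * p.ED * p.EF_days / (p.ABW * p.aet(averaging)) * p.CFU


def cdd_inhalation(cm: float, p: ExposureProfile, averaging: str = "nc") -> float:
    """Chronic daily dose via inhalation of resuspended particles (mg/kg/day)."""
    if cm < 0:
        raise ValueError(f"concentration must be >= 0, got {cm!r}")
    return cm * p.IHR * p.ED * p.EF_days / (p.ABW * p.aet(averaging) * p.PEF)


def cdd_dermal(
    cm: float, p: ExposureProfile, element: str, averaging: str = "nc"
) -> float:
    """Chronic daily dose via dermal contact (mg/kg/day)."""
    if cm < 0:
        raise ValueError(f"concentration must be >= 0, got {cm!r}")
    daf = p.daf(element)
    return (
        cm * p.SA * p.SAF * daf * p.ED * p.EF_days / (p.ABW * p.aet(averaging)) * p.CFU
    )


def chronic_daily_dose(
    cm: float, p: ExposureProfile, element: str, route: str, averaging: str = "nc"
) -> float:
    if route == "ing":
        return cdd_ingestion(cm, p, averaging)
    if route == "inh":
        return cdd_inhalation(cm, p, averaging)
    if route == "derm":
        return cdd_dermal(cm, p, element, averaging)
    raise ValueError(f"unknown exposure route {route!r}")


def hazard_quotient(cdd: float, rfd: float) -> float:
    """HQ = CDD / RfD (dimensionless)."""
    if not rfd > 0:
        raise ValueError(f"reference dose must be > 0, got {rfd!r}")
    return cdd / rfd


def hi_category(hi: float) -> str:
    # HI > 1 flags a possible effect (strict); the boundary value 1 is
    # therefore still "insignificant".
    return "possible chronic adverse effect" if hi > 1.0 else "insignificant"


def hazard_index(
    hq_by_route: Mapping[str, float] | Sequence[float],
) -> tuple[float, str]:
    """HI = sum of hazard quotients over routes (or elements)."""
    values = list(hq_by_route.values()) if isinstance(hq_by_route, Mapping) else list(hq_by_route)
    if not values:
        raise ValueError("HI needs at least one hazard quotient")
    hi = float(sum(values))
    return hi, hi_category(hi)


def tcr_category(tcr: float) -> str:
    if tcr < TCR_NO_SIGNIFICANT:
        return "no significant risk"
    if tcr > TCR_UNACCEPTABLE:
        return "unacceptable"
    return "acceptable"


def carcinogenic_risk(
    cdd_ca_by_route: Mapping[str, float],
    dr: ElementDoseResponse,
    dermal_mode: str = "giabs",
) -> tuple[dict[str, float], float, str]:
    """Route-specific carcinogenic risks and their total for one element.

    CR_ing = CDD_ing * SF; CR_inh = CDD_inh * IUR.  Dermal risk uses the
    dermal slope factor SF/GIABS (``dermal_mode="giabs"``, default) or the
    plain oral slope factor (``dermal_mode="oral_sf"``).  Routes whose
    potency factor is unavailable are skipped.  Doses must be
    carcinogenic-averaged (lifetime AET).
    """
    cr: dict[str, float] = {}
    if "ing" in cdd_ca_by_route and dr.sf_ing is not None:
        cr["ing"] = cdd_ca_by_route["ing"] * dr.sf_ing
    if "inh" in cdd_ca_by_route and dr.iur is not None:
        cr["inh"] = cdd_ca_by_route["inh"] * dr.iur
    if "derm" in cdd_ca_by_route and dr.sf_ing is not None:
        if dermal_mode == "giabs":
            cr["derm"] = cdd_ca_by_route["derm"] * dr.sf_ing / dr.giabs
        elif dermal_mode == "oral_sf":
            cr["derm"] = cdd_ca_by_route["derm"] * dr.sf_ing
        else:
            raise ValueError(f"unknown dermal_mode {dermal_mode!r}")
    tcr = float(sum(cr.values()))
    return cr, tcr, tcr_category(tcr)


def risk_contributions(per_element: Mapping[str, float]) -> dict[str, float] | None:
    """Percentage share of each element in a positive total; None if the
    total is zero (shares undefined)."""
    total = float(sum(per_element.values()))
    if total == 0:
        return None
    return {el: 100.0 * v / total for el, v in per_element.items()}


@dataclass(frozen=True)
class SiteReceptorRisk:
    """Health-risk bundle for one (site, receptor)."""

    site: str
    receptor: str
    cdd_nc: dict[tuple[str, str], float]   # (element, route) -> dose
    cdd_ca: dict[tuple[str, str], float]
    hq: dict[tuple[str, str], float]
    hi_by_element: dict[str, float]
    hi_total: float
    hi_category: str
    cr: dict[tuple[str, str], float]
    tcr_by_element: dict[str, float]
    tcr_total: float
    tcr_category: str
    hi_contributions: dict[str, float] | None
    tcr_contributions: dict[str, float] | None


def assess_health_risk(
    concentrations: Mapping[str, float],
    profile: ExposureProfile,
    dose_response: DoseResponseTable,
    elements: Iterable[str] | None = None,
    routes: Sequence[str] = ROUTES,
    site: str = "",
    dermal_mode: str = "giabs",
) -> SiteReceptorRisk:
    """Full non-carcinogenic and carcinogenic assessment for one receptor
    at one site, given per-element concentrations (mg/kg, typically site
    means).  Elements without a dose-response entry are skipped."""
    elements = [
        el for el in (elements if elements is not None else concentrations)
        if el in dose_response
    ]
    if not elements:
        raise ValueError("no elements with dose-response data to assess")
    bad = [r for r in routes if r not in ROUTES]
    if bad:
        raise ValueError(f"unknown routes {bad}")

    cdd_nc, cdd_ca, hq, cr = {}, {}, {}, {}
    hi_by_element, tcr_by_element = {}, {}
    for el in elements:
        cm = float(concentrations[el])
        dr = dose_response[el]
        hqs = {}
        for route in routes:
            cdd_nc[(el, route)] = chronic_daily_dose(cm, profile, el, route, "nc")
            cdd_ca[(el, route)] = chronic_daily_dose(cm, profile, el, route, "ca")
            hqs[route] = hazard_quotient(cdd_nc[(el, route)], dr.rfd(route))
            hq[(el, route)] = hqs[route]
        hi_by_element[el], _ = hazard_index(hqs)
        doses_ca = {r: cdd_ca[(el, r)] for r in routes}
        cr_el, tcr_el, _ = carcinogenic_risk(doses_ca, dr, dermal_mode)
        for route, value in cr_el.items():
            cr[(el, route)] = value
        tcr_by_element[el] = tcr_el

    hi_total = float(sum(hi_by_element.values()))
    tcr_total = float(sum(tcr_by_element.values()))
    return SiteReceptorRisk(
        site=site,
        receptor=profile.receptor,
        cdd_nc=cdd_nc,
        cdd_ca=cdd_ca,
        hq=hq,
        hi_by_element=hi_by_element,
        hi_total=hi_total,
        hi_category=hi_category(hi_total),
        cr=cr,
        tcr_by_element=tcr_by_element,
        tcr_total=tcr_total,
        tcr_category=tcr_category(tcr_total),
        hi_contributions=risk_contributions(hi_by_element),
        tcr_contributions=risk_contributions(tcr_by_element),
    )


def risk_to_frame(result: SiteReceptorRisk) -> pd.DataFrame:
    """Long-format frame: one row per (element, route) plus per-element
    summary rows (route='all') carrying HI, TCR, and contribution shares."""
    rows = []
    elements = sorted(result.hi_by_element)
    for el in elements:
        for route in ROUTES:
            if (el, route) not in result.cdd_nc:
                continue
            rows.append(
                {
                    "site": result.site, "receptor": result.receptor,
                    "element": el, "route": route,
                    "cdd_nc": result.cdd_nc[(el, route)],
                    "cdd_ca": result.cdd_ca[(el, route)],
                    "hq": result.hq[(el, route)],
                    "cr": result.cr.get((el, route)),
                }
            )
        rows.append(
            {
                "site": result.site, "receptor": result.receptor,
                "element": el, "route": "all",
                "hi": result.hi_by_element[el],
                "tcr": result.tcr_by_element[el],
                "hi_contrib_pct": (result.hi_contributions or {}).get(el),
                "tcr_contrib_pct": (result.tcr_contributions or {}).get(el),
            }
        )
    rows.append(
        {
            "site": result.site, "receptor": result.receptor,
            "element": "TOTAL", "route": "all",
            "hi": result.hi_total, "hi_category": result.hi_category,
            "tcr": result.tcr_total, "tcr_category": result.tcr_category,
        }
    )
    return pd.DataFrame(rows)
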