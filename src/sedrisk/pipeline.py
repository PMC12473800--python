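"""End-to-end orchestration: samples -> indices -> ecological risk ->
health risk -> reports, plus the between-zone rank-sum comparison.

Outputs are deterministic for a given input table and configuration;
floats in exported tables and JSON are formatted to 6 significant digits
so golden-file comparisons are stable.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from . import contamination_indices as ci
from . import ecological_risk as eco
from . import health_risk as hr
from .reference_data import (
    ECO_RISK_ELEMENTS,
    HEALTH_RISK_ELEMENTS,
    INDEX_ELEMENTS,
    DoseResponseTable,
    ExposureProfile,
    ReferenceSet,
    ToxicResponseFactors,
    builtin_dose_response,
    builtin_exposure_profiles,
    builtin_toxic_response_factors,
    get_reference_set,
    load_dose_response,
    load_exposure_profiles,
    load_toxic_response_factors,
)
from .sample_io import SampleTable

__all__ = [
    "RunConfig",
    "compute_indices",
    "compute_eco_risk",
    "compute_health_risk",
    "run_full_assessment",
    "zone_compare",
    "rank_sum_exact_p",
    "classification_report",
]

logger = logging.getLogger("sedrisk")

FLOAT_FORMAT = "%.6g"
EXACT_N_MAX = 20  # combined sample size up to which the exact null is enumerated


@dataclass
class RunConfig:
    """Configuration of a full assessment run."""

    background: str = "taylor_mclennan_1995"   # built-in name or config path
    toxicity_path: str | None = None
    exposure_path: str | None = None
    dose_response_path: str | None = None
    index_elements: tuple[str, ...] = INDEX_ELEMENTS
    eco_elements: tuple[str, ...] = ECO_RISK_ELEMENTS
    health_elements: tuple[str, ...] = HEALTH_RISK_ELEMENTS
    receptors: tuple[str, ...] = ("child", "adult")
    routes: tuple[str, ...] = hr.ROUTES
    per: str = "site"                          # grouping for index tables
    dermal_mode: str = "giabs"
    output_dir: str | None = None

    def reference(self) -> ReferenceSet:
        return get_reference_set(self.background)

    def toxicity(self) -> ToxicResponseFactors:
        if self.toxicity_path:
            return load_toxic_response_factors(self.toxicity_path)
        return builtin_toxic_response_factors()

    def exposure(self) -> dict[str, ExposureProfile]:
        if self.exposure_path:
            profiles = load_exposure_profiles(self.exposure_path)
        else:
            child, adult = builtin_exposure_profiles()
            profiles = {"child": child, "adult": adult}
        missing = set(self.receptors) - set(profiles)
        if missing:
            raise ValueError(f"no exposure profile for receptors {sorted(missing)}")
        return {r: profiles[r] for r in self.receptors}

    def dose_response(self) -> DoseResponseTable:
        if self.dose_response_path:
            return load_dose_response(self.dose_response_path)
        return builtin_dose_response()


def _group_means(samples: SampleTable, per: str, elements) -> pd.DataFrame:
    """Concentration means grouped per sample / site / zone.

    Returns a frame indexed by group with a 'zone' column and one column
    per element.
    """
    present = [el for el in elements if el in samples.elements]
    if per == "site":
        return samples.site_means(present)
    if per == "zone":
        means = samples.zone_means(present)
        means.insert(0, "zone", means.index)
        return means
    if per == "sample":
        df = samples.data.copy()
        df.index = [
            f"{s}/{m}/r{r}" for s, m, r in zip(df["site"], df["month"], df["replicate"])
        ]
        return df[["zone"] + present]
    raise ValueError(f"per must be 'sample', 'site' or 'zone', got {per!r}")


def compute_indices(
    samples: SampleTable,
    reference: ReferenceSet,
    elements: Iterable[str] = INDEX_ELEMENTS,
    per: str = "site",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-element Cf/Igeo/EF and per-group PLI/mCd.

    Returns ``(per_element, per_group)``.  EF uses Fe as the conservative
    reference element and is reported for every element except Fe itself.
    """
    elements = [el for el in elements if el in samples.elements]
    if not elements:
        raise ValueError("none of the requested elements are in the sample table")
    reference.require(set(elements) | {"Fe"})
    means = _group_means(samples, per, sorted(set(elements) | {"Fe"}))

    el_rows, group_rows = [], []
    for group, row in means.iterrows():
        cf_vector = []
        fe_sample = row.get("Fe", np.nan)
        for el in elements:
            cm = row[el]
            if pd.isna(cm):
                continue
            cf = ci.contamination_factor(cm, reference.background[el])
            igeo = ci.geoaccumulation_index(cm, reference.background[el])
            ef = None
            if el != "Fe" and not pd.isna(fe_sample) and fe_sample > 0 and cm > 0:
                ef = ci.enrichment_factor(
                    cm, fe_sample, reference.background[el], reference.background["Fe"]
                )
            cf_vector.append(cf.value)
            el_rows.append(
                {
                    "group": group, "zone": row["zone"], "element": el,
                    "concentration": cm,
                    "Cf": cf.value, "Cf_category": cf.category,
                    "Igeo": igeo.value, "Igeo_category": igeo.category,
                    "EF": ef.value if ef else np.nan,
                    "EF_category": ef.category if ef else "",
                }
            )
        pli = ci.pollution_load_index(cf_vector)
        mcd = ci.modified_contamination_degree(cf_vector)
        group_rows.append(
            {
                "group": group, "zone": row["zone"],
                "PLI": pli.value, "PLI_category": pli.category,
                "PLI_critical": pli.value > ci.PLI_SITE_CRITICAL,
                "mCd": mcd.value, "mCd_category": mcd.category,
                "n_elements": len(cf_vector),
            }
        )
    return pd.DataFrame(el_rows), pd.DataFrame(group_rows)


def compute_eco_risk(
    samples: SampleTable,
    reference: ReferenceSet,
    toxicity: ToxicResponseFactors,
    elements: Iterable[str] = ECO_RISK_ELEMENTS,
) -> pd.DataFrame:
    """Per-site Er values, RI with band, and SRI with collection category.

    Site means feed the contamination factors (the default convention).
    """
    elements = [el for el in elements if el in samples.elements]
    if not elements:
        raise ValueError("none of the requested elements are in the sample table")
    reference.require(elements)
    means = samples.site_means(elements)

    cf_by_site: dict[str, dict[str, float]] = {}
    igeo_by_site: dict[str, dict[str, float]] = {}
    rows = []
    for site, row in means.iterrows():
        cf_by_site[site] = {}
        igeo_by_site[site] = {}
        er = {}
        for el in elements:
            cm = row[el]
            if pd.isna(cm):
                continue
            cf = ci.contamination_factor(cm, reference.background[el])
            cf_by_site[site][el] = cf.value
            igeo_by_site[site][el] = ci.geoaccumulation_index(
                cm, reference.background[el]
            ).value
            er[el] = eco.ecological_risk_factor(toxicity, cf.value, el)
        ri, ri_cat = eco.potential_ecological_risk(er)
        rows.append({"site": site, "zone": row["zone"], **{f"Er_{e}": v for e, v in er.items()},
                     "RI": ri, "RI_category": ri_cat})

    sri = eco.site_ranking_index(cf_by_site, igeo_by_site)
    sri_cat = eco.sri_categories(sri)
    out = pd.DataFrame(rows)
    out["SRI"] = out["site"].map(sri)
    out["SRI_category"] = out["site"].map(sri_cat)
    return out


def compute_health_risk(
    samples: SampleTable,
    profiles: Mapping[str, ExposureProfile],
    dose_response: DoseResponseTable,
    elements: Iterable[str] = HEALTH_RISK_ELEMENTS,
    routes: Sequence[str] = hr.ROUTES,
    dermal_mode: str = "giabs",
) -> pd.DataFrame:
    """Long-format health-risk table over sites x receptors (site means)."""
    elements = [el for el in elements if el in samples.elements]
    if not elements:
        raise ValueError("none of the requested elements are in the sample table")
    means = samples.site_means(elements)
    frames = []
    for site, row in means.iterrows():
        conc = {el: row[el] for el in elements if not pd.isna(row[el])}
        for receptor, profile in profiles.items():
            result = hr.assess_health_risk(
                conc, profile, dose_response, routes=routes, site=site,
                dermal_mode=dermal_mode,
            )
            frames.append(hr.risk_to_frame(result))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Zone comparison (rank-sum)


def rank_sum_exact_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided rank-sum test by full enumeration of group splits.

    Handles ties through average ranks; the null distribution of the
    Mann-Whitney U statistic is symmetric about n1*n2/2, so the two-sided
    p-value is P(|U - mu| >= |u_obs - mu|) over all C(n, n1) splits.
    Returns (U of the first group, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    d_obs = abs(u_obs - mu)
    hits = total = 0
    offset = n1 * (n1 + 1) / 2.0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(combo)].sum() - offset
        total += 1
        if abs(u - mu) >= d_obs - 1e-12:
            hits += 1
    return u_obs, hits / total


def _rank_sum_asymptotic_p(x, y) -> tuple[float, float]:
    """Normal approximation with tie correction (no continuity correction)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = rankdata(np.concatenate([x, y]))
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:  # all observations identical
        return u, 1.0
    z = (u - mu) / math.sqrt(var)
    return u, float(min(1.0, 2.0 * norm.sf(abs(z))))


def zone_compare(samples: SampleTable, element: str) -> tuple[float, float]:
    """Two-sided rank-sum comparison of *element* between the two zones.

    Exact (full enumeration, tie-aware) when the combined sample size is
    at most 20; normal approximation with tie correction otherwise.
    Returns (U statistic of the upper-zone group, p-value).  The p-value
    depends on the observations only through their ranks, so it is
    invariant under strictly monotone transforms of the data.
    """
    if element not in samples.elements:
        raise ValueError(f"element {element!r} not in sample table")
    by_zone = {
        zone: group[element].dropna().to_numpy()
        for zone, group in samples.data.groupby("zone", sort=False)
    }
    if len(by_zone) != 2 or any(len(v) == 0 for v in by_zone.values()):
        raise ValueError("zone comparison needs observations in both zones")
    x = by_zone.get("upper", next(iter(by_zone.values())))
    y = by_zone.get("lower", list(by_zone.values())[-1])
    if len(x) + len(y) <= EXACT_N_MAX:
        return rank_sum_exact_p(x, y)
    return _rank_sum_asymptotic_p(x, y)


def zone_compare_all(
    samples: SampleTable, elements: Iterable[str] | None = None, holm: bool = False
) -> pd.DataFrame:
    """Rank-sum comparison for every element.

    Raw p-values by default (no multiplicity correction, matching common
    reporting practice); ``holm=True`` appends a Holm-adjusted column.
    """
    elements = list(elements) if elements is not None else samples.elements
    rows = []
    for el in elements:
        try:
            u, p = zone_compare(samples, el)
        except ValueError:
            continue
        rows.append({"element": el, "U": u, "p_value": p, "significant_05": p < 0.05})
    out = pd.DataFrame(rows)
    if holm and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_holm"] = multipletests(out["p_value"], method="holm")[1]
    return out


# ---------------------------------------------------------------------------
# Full run + classification report


def _round_sig(value, digits=6):
    if isinstance(value, dict):
        return {k: _round_sig(v, digits) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_round_sig(v, digits) for v in value]
    if isinstance(value, (float, np.floating)):
        if not math.isfinite(value):
            return str(value)
        return float(f"{value:.{digits}g}")
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.bool_,)):
        return bool(value)
    return value


def run_full_assessment(samples: SampleTable, cfg: RunConfig) -> dict:
    """Run every stage and (optionally) write the output bundle.

    Returns a dict with keys ``indices_per_element``, ``indices_per_group``,
    ``eco_risk``, ``health_risk``, ``zone_tests`` (DataFrames) and
    ``summary`` (JSON-ready dict).  With ``cfg.output_dir`` set, writes
    indices.csv, eco_risk.csv, health_risk.csv, zone_tests.csv and
    summary.json; any stage error aborts and removes partial outputs.
    """
    reference = cfg.reference()
    stage = "indices"
    written: list[Path] = []
    try:
        per_element, per_group = compute_indices(
            samples, reference, cfg.index_elements, cfg.per
        )
        logger.info("indices: %d element rows, %d groups", len(per_element), len(per_group))
        stage = "eco-risk"
        eco_risk = compute_eco_risk(samples, reference, cfg.toxicity(), cfg.eco_elements)
        logger.info("eco-risk: %d sites", len(eco_risk))
        stage = "health-risk"
        health = compute_health_risk(
            samples, cfg.exposure(), cfg.dose_response(), cfg.health_elements,
            cfg.routes, cfg.dermal_mode,
        )
        stage = "zone-compare"
        zone_tests = zone_compare_all(samples, cfg.index_elements)
        stage = "summary"
        summary = _build_summary(per_element, per_group, eco_risk, health, cfg)
        bundle = {
            "indices_per_element": per_element,
            "indices_per_group": per_group,
            "eco_risk": eco_risk,
            "health_risk": health,
            "zone_tests": zone_tests,
            "summary": summary,
        }
        if cfg.output_dir is not None:
            out = Path(cfg.output_dir)
            out.mkdir(parents=True, exist_ok=True)
            stage = "write"
            for name, frame in (
                ("indices.csv", pd.concat([per_element, per_group])),
                ("eco_risk.csv", eco_risk),
                ("health_risk.csv", health),
                ("zone_tests.csv", zone_tests),
            ):
                path = out / name
                frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
                written.append(path)
            path = out / "summary.json"
            path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
            written.append(path)
        return bundle
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"assessment failed at stage {stage!r}: {exc}") from exc


def _build_summary(per_element, per_group, eco_risk, health, cfg) -> dict:
    summary: dict = {"background": cfg.background, "per": cfg.per, "sites": {}}
    for group, block in per_element.groupby("group"):
        summary["sites"][str(group)] = {
            "zone": block["zone"].iloc[0],
            "Cf_category": dict(zip(block["element"], block["Cf_category"])),
            "Igeo_category": dict(zip(block["element"], block["Igeo_category"])),
            "EF_category": {
                e: c for e, c in zip(block["element"], block["EF_category"]) if c
            },
        }
    for _, row in per_group.iterrows():
        entry = summary["sites"].setdefault(str(row["group"]), {"zone": row["zone"]})
        entry["PLI"] = _round_sig(row["PLI"])
        entry["PLI_category"] = row["PLI_category"]
        entry["PLI_critical"] = bool(row["PLI_critical"])
        entry["mCd"] = _round_sig(row["mCd"])
        entry["mCd_category"] = row["mCd_category"]
    for _, row in eco_risk.iterrows():
        entry = summary["sites"].setdefault(str(row["site"]), {"zone": row["zone"]})
        entry["RI"] = _round_sig(row["RI"])
        entry["RI_category"] = row["RI_category"]
        entry["SRI"] = _round_sig(row["SRI"])
        entry["SRI_category"] = row["SRI_category"]
    totals = health[health["element"] == "TOTAL"]
    for _, row in totals.iterrows():
        entry = summary["sites"].setdefault(str(row["site"]), {})
        entry.setdefault("health", {})[row["receptor"]] = {
            "HI": _round_sig(row["hi"]),
            "HI_category": row["hi_category"],
            "TCR": _round_sig(row["tcr"]),
            "TCR_category": row["tcr_category"],
        }
    return summary


def classification_report(bundle: Mapping) -> tuple[str, dict]:
    """Human-readable per-site category table (text) plus its JSON form."""
    summary = bundle["summary"]
    lines = [f"Classification report (background: {summary['background']})", ""]
    for site, entry in summary["sites"].items():
        lines.append(f"{site} [{entry.get('zone', '?')}]")
        cf_cats = entry.get("Cf_category", {})
        if cf_cats:
            cf_line = ", ".join(f"{el}: {cat}" for el, cat in cf_cats.items())
            lines.append(f"  Cf: {cf_line}")
        if "PLI" in entry:
            lines.append(
                f"  PLI {entry['PLI']} ({entry['PLI_category']}"
                f"{', critical' if entry.get('PLI_critical') else ''}); "
                f"mCd {entry['mCd']} ({entry['mCd_category']})"
            )
        if "RI" in entry:
            lines.append(
                f"  RI {entry['RI']} ({entry['RI_category']}); "
                f"SRI {entry['SRI']} ({entry['SRI_category']})"
            )
        for receptor, block in entry.get("health", {}).items():
            lines.append(
                f"  {receptor}: HI {block['HI']} ({block['HI_category']}); "
                f"TCR {block['TCR']} ({block['TCR_category']})"
            )
        lines.append("")
    return "\n".join(lines), dict(summary)
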