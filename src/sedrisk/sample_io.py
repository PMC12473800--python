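"""Reading, validating, and summarising tabular sediment-sample data.

The canonical on-disk format is UTF-8 CSV with a period decimal mark and
columns ``site,zone,month,replicate,<element>...``, one row per
(site, month, replicate).  Concentrations are mg/kg dry weight.  A cell
written as ``<0.01`` marks a value below the method limit of
quantification (LOQ); by default such values are substituted by LOQ/2.
Missing values stay missing (``NaN``) — they are never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .reference_data import ELEMENT_SYMBOLS

__all__ = [
    "META_COLUMNS",
    "DEFAULT_LOQ",
    "SampleTable",
    "SampleValidationError",
    "read_samples",
    "write_samples",
    "summarize_by_zone",
]

META_COLUMNS = ("site", "zone", "month", "replicate")
ZONES = ("upper", "lower")

# Method limits of quantification (mg/kg) for the ICP-MS protocol used in
# the source study; applied when a cell is flagged "<LOQ" without a number.
DEFAULT_LOQ = {
    "As": 0.01, "Cd": 0.01, "Cr": 0.01, "Cu": 0.01, "Mn": 0.01, "Ni": 0.01,
    "Pb": 0.02, "Sb": 0.02, "Mo": 0.05, "Zn": 0.10, "Fe": 0.50,
}


class SampleValidationError(ValueError):
    pass


@dataclass
class SampleTable:
    """Validated sediment-sample records.

    Wraps a :class:`pandas.DataFrame` with the metadata columns of
    :data:`META_COLUMNS` followed by one column per element (mg/kg dw).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = _validate(self.data)

    @property
    def elements(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def sites(self) -> list[str]:
        return list(dict.fromkeys(self.data["site"]))

    def __len__(self) -> int:
        return len(self.data)

    def site_means(self, elements: Iterable[str] | None = None) -> pd.DataFrame:
        """Per-site mean concentration (rows: site, cols: element); keeps
        the zone label as a column."""
        elements = list(elements) if elements is not None else self.elements
        grouped = self.data.groupby("site", sort=False)
        means = grouped[elements].mean()
        means.insert(0, "zone", grouped["zone"].first())
        return means

    def zone_means(self, elements: Iterable[str] | None = None) -> pd.DataFrame:
        elements = list(elements) if elements is not None else self.elements
        return self.data.groupby("zone", sort=False)[elements].mean()


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SampleValidationError(f"missing metadata columns: {missing}")
    if len(df) == 0:
        raise SampleValidationError("sample table is empty")
    elements = [c for c in df.columns if c not in META_COLUMNS]
    if not elements:
        raise SampleValidationError("sample table has no element columns")
    bad = [c for c in elements if c not in ELEMENT_SYMBOLS]
    if bad:
        raise SampleValidationError(f"unknown element columns: {bad}")
    df = df.copy()
    df["replicate"] = df["replicate"].astype(int)
    if (df["replicate"] < 1).any():
        raise SampleValidationError("replicate numbers must be >= 1")
    unknown_zones = set(df["zone"]) - set(ZONES)
    if unknown_zones:
        raise SampleValidationError(
            f"zone labels must be one of {ZONES}, got {sorted(unknown_zones)}"
        )
    keys = df[["site", "month", "replicate"]].apply(tuple, axis=1)
    dup = keys[keys.duplicated()]
    if not dup.empty:
        raise SampleValidationError(
            f"duplicate (site, month, replicate) triples: {sorted(set(dup))}"
        )
    for el in elements:
        values = pd.to_numeric(df[el], errors="coerce")
        neg = values[values < 0]
        if not neg.empty:
            row = int(neg.index[0])
            raise SampleValidationError(
                f"negative concentration for {el} at row {row}: {neg.iloc[0]}"
            )
        df[el] = values.astype(float)
    return df.reset_index(drop=True)


def _substitute_loq(raw: str, element: str, policy: str, loq_table: dict) -> float:
    """Resolve a '<LOQ' flagged cell according to *policy*."""
    text = raw.strip().lstrip("<").strip()
    loq = float(text) if text else loq_table.get(element, np.nan)
    if np.isnan(loq):
        raise SampleValidationError(
            f"below-LOQ flag for {element} but no LOQ known; provide '<value'"
        )
    return {"half": loq / 2.0, "loq": loq, "zero": 0.0, "drop": np.nan}[policy]


def read_samples(
    path,
    loq_policy: str = "half",
    loq_table: dict | None = None,
    strict: bool = True,
) -> SampleTable:
    """Read a sample CSV into a validated :class:`SampleTable`.

    Parameters
    ----------
    loq_policy : how to substitute cells flagged below the limit of
        quantification (``"<0.01"`` or bare ``"<"``): one of
        ``half`` (LOQ/2, default), ``loq``, ``zero``, ``drop`` (NaN).
    strict : if True (default), unknown element columns raise; otherwise
        they are kept with a warning.
    """
    if loq_policy not in ("half", "loq", "zero", "drop"):
        raise ValueError(f"unknown loq_policy {loq_policy!r}")
    loq_table = dict(DEFAULT_LOQ if loq_table is None else loq_table)
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    value_cols = [c for c in df.columns if c not in META_COLUMNS]
    if strict:
        bad = [c for c in value_cols if c not in ELEMENT_SYMBOLS]
        if bad:
            raise SampleValidationError(
                f"unknown element columns {bad}; pass strict=False to keep them"
            )
    for col in value_cols:
        flagged = df[col].astype(str).str.startswith("<") & df[col].notna()
        if flagged.any():
            df.loc[flagged, col] = [
                _substitute_loq(v, col, loq_policy, loq_table)
                for v in df.loc[flagged, col]
            ]
    return SampleTable(df)


def write_samples(table: SampleTable, path) -> None:
    """Write a sample table back to canonical CSV (row order preserved)."""
    table.data.to_csv(path, index=False)


def summarize_by_zone(table: SampleTable) -> pd.DataFrame:
    """Per-zone descriptive statistics: mean, SD, max for every element.

    The standard deviation uses the sample (n-1) convention; a zone with a
    single observation reports SD 0 for exact-replicate degeneracy checks.

    Returns a long-format frame with columns
    ``zone, element, mean, sd, max, n``.
    """
    rows = []
    for zone, group in table.data.groupby("zone", sort=False):
        for el in table.elements:
            values = group[el].dropna()
            if len(values) == 0:
                continue
            sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
            rows.append(
                {
                    "zone": zone,
                    "element": el,
                    "mean": float(values.mean()),
                    "sd": sd,
                    "max": float(values.max()),
                    "n": int(len(values)),
                }
            )
    return pd.DataFrame(rows)
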