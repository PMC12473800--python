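"""Constant tables used throughout the assessment.

Four kinds of reference data feed the pipeline: geochemical background
concentrations (the denominator of every contamination factor), toxic
response factors for the ecological risk index, receptor exposure
parameters for the dose models, and dose--response constants (reference
doses, slope factors, inhalation unit risks, gastrointestinal absorption
fractions).  Each table ships as an editable YAML document under
``sedrisk/data`` and can be replaced by a user file of the same shape.

A note on symbols: the exposure equations use a mass unit conversion
factor (kg/mg) that much of the literature also calls "Cf", colliding
with the contamination factor.  Here the conversion factor is always
named ``CFU`` and the contamination factor is always ``Cf``.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "ELEMENT_SYMBOLS",
    "ReferenceSet",
    "ToxicResponseFactors",
    "ExposureProfile",
    "ElementDoseResponse",
    "DoseResponseTable",
    "load_reference_set",
    "write_reference_set",
    "builtin_references",
    "builtin_toxic_response_factors",
    "builtin_exposure_profiles",
    "builtin_dose_response",
    "load_toxic_response_factors",
    "load_exposure_profiles",
    "load_dose_response",
]

# Canonical chemical element symbols (H..Og); used to reject typos such as
# "CD" or "Arsenic" in user-supplied tables and sample headers.
ELEMENT_SYMBOLS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)


class ReferenceDataError(ValueError):
    """Raised when a reference table fails validation."""


def _check_elements(mapping: Mapping[str, float], table: str) -> None:
    for el in mapping:
        if el not in ELEMENT_SYMBOLS:
            raise ReferenceDataError(f"{table}: unknown element symbol {el!r}")


@dataclass(frozen=True)
class ReferenceSet:
    """Named geochemical background: element -> concentration (mg/kg dw)."""

    name: str
    background: dict[str, float]
    source_note: str = ""

    def __post_init__(self) -> None:
        _check_elements(self.background, f"reference set {self.name!r}")
        for el, value in self.background.items():
            if not value > 0:
                raise ReferenceDataError(
                    f"reference set {self.name!r}: background for {el} must be "
                    f"strictly positive, got {value!r}"
                )

    def require(self, elements) -> None:
        """Fail loudly if any requested element lacks a background value."""
        missing = sorted(set(elements) - set(self.background))
        if missing:
            raise ReferenceDataError(
                f"reference set {self.name!r} lacks background values for: "
                + ", ".join(missing)
            )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "source_note": self.source_note,
            "background": {el: float(self.background[el]) for el in sorted(self.background)},
        }


@dataclass(frozen=True)
class ToxicResponseFactors:
    """Dimensionless toxic response factors T per element (Hakanson lineage)."""

    factors: dict[str, float]
    name: str = "hakanson_1980"

    def __post_init__(self) -> None:
        _check_elements(self.factors, "toxic response factors")
        for el, t in self.factors.items():
            if not t > 0:
                raise ReferenceDataError(
                    f"toxic response factor for {el} must be > 0, got {t!r}"
                )

    def __getitem__(self, element: str) -> float:
        try:
            return self.factors[element]
        except KeyError:
            raise ReferenceDataError(
                f"no toxic response factor available for element {element!r}"
            ) from None


@dataclass(frozen=True)
class ExposureProfile:
    """Receptor-specific exposure parameters for the chronic daily dose models.

    Parameters
    ----------
    receptor : "child" or "adult"
    ABW : average body weight, kg
    IR : sediment ingestion rate, mg/day
    IHR : inhalation rate, m3/day
    SA : exposed skin surface area, cm2
    SAF : skin adherence factor, mg/(cm2 day)
    DAF : dermal absorption fraction per element; key "default" is the
        fallback for elements without an entry
    ED : exposure duration, years
    EF_days : exposure frequency, days/year
    AET_nc : averaging time for non-carcinogenic effects, days (ED x 365
        under the default convention)
    AET_ca : averaging time for carcinogenic effects, days (70-year lifetime
        by default)
    PEF : particle emission factor, m3/kg
    CFU : mass unit conversion, kg/mg (1e-6)
    """

    receptor: str
    ABW: float
    IR: float
    IHR: float
    SA: float
    SAF: float
    DAF: dict[str, float]
    ED: float
    EF_days: float
    AET_nc: float
    AET_ca: float
    PEF: float
    CFU: float = 1.0e-6

    def __post_init__(self) -> None:
        scalars = {
            "ABW": self.ABW, "IR": self.IR, "IHR": self.IHR, "SA": self.SA,
            "SAF": self.SAF, "ED": self.ED, "EF_days": self.EF_days,
            "AET_nc": self.AET_nc, "AET_ca": self.AET_ca, "PEF": self.PEF,
            "CFU": self.CFU,
        }
        for key, value in scalars.items():
            if not value > 0:
                raise ReferenceDataError(
                    f"exposure profile {self.receptor!r}: {key} must be strictly "
                    f"positive, got {value!r}"
                )
        if self.AET_ca < self.AET_nc:
            raise ReferenceDataError(
                f"exposure profile {self.receptor!r}: AET_ca ({self.AET_ca}) must "
                f"be >= AET_nc ({self.AET_nc})"
            )
        for el, frac in self.DAF.items():
            if el != "default":
                _check_elements({el: frac}, "DAF")
            if not 0 < frac <= 1:
                raise ReferenceDataError(
                    f"DAF for {el!r} must be in (0, 1], got {frac!r}"
                )

    def daf(self, element: str) -> float:
        """Dermal absorption fraction for *element* (falls back to 'default')."""
        if element in self.DAF:
            return self.DAF[element]
        if "default" in self.DAF:
            return self.DAF["default"]
        raise ReferenceDataError(
            f"exposure profile {self.receptor!r}: no DAF for element {element!r} "
            "and no 'default' entry"
        )

    def aet(self, averaging: str) -> float:
        if averaging == "nc":
            return self.AET_nc
        if averaging == "ca":
            return self.AET_ca
        raise ValueError(f"averaging must be 'nc' or 'ca', got {averaging!r}")


@dataclass(frozen=True)
class ElementDoseResponse:
    """Per-element dose-response constants.

    ``rfd_derm`` is derived as ``rfd_ing * giabs`` unless supplied
    explicitly; carcinogenic constants may be absent (``None``) for
    elements without published slope factors.
    """

    element: str
    rfd_ing: float | None = None
    rfd_inh: float | None = None
    rfd_derm: float | None = None
    sf_ing: float | None = None
    iur: float | None = None
    giabs: float = 1.0

    def __post_init__(self) -> None:
        _check_elements({self.element: 1.0}, "dose-response table")
        if not 0 < self.giabs <= 1:
            raise ReferenceDataError(
                f"GIABS for {self.element} must be in (0, 1], got {self.giabs!r}"
            )
        for key in ("rfd_ing", "rfd_inh", "rfd_derm", "sf_ing", "iur"):
            value = getattr(self, key)
            if value is not None and not value > 0:
                raise ReferenceDataError(
                    f"{key} for {self.element} must be strictly positive, got {value!r}"
                )
        if self.rfd_derm is None and self.rfd_ing is not None:
            object.__setattr__(self, "rfd_derm", self.rfd_ing * self.giabs)

    def rfd(self, route: str) -> float:
        value = {"ing": self.rfd_ing, "inh": self.rfd_inh, "derm": self.rfd_derm}[route]
        if value is None:
            raise ReferenceDataError(
                f"no {route} reference dose available for {self.element}"
            )
        return value


@dataclass(frozen=True)
class DoseResponseTable:
    """Collection of :class:`ElementDoseResponse` records keyed by element."""

    elements: dict[str, ElementDoseResponse]
    name: str = "user"

    def __getitem__(self, element: str) -> ElementDoseResponse:
        try:
            return self.elements[element]
        except KeyError:
            raise ReferenceDataError(
                f"dose-response table {self.name!r} has no entry for {element!r}"
            ) from None

    def __contains__(self, element: str) -> bool:
        return element in self.elements


# ---------------------------------------------------------------------------
# Loading / serialisation


def _load_yaml(source) -> dict:
    """Accept a path, file-like object, or already-parsed mapping."""
    if isinstance(source, Mapping):
        return dict(source)
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    if isinstance(source, io.IOBase) or hasattr(source, "read"):
        return yaml.safe_load(source)
    raise TypeError(f"cannot load config from {type(source).__name__}")


def _builtin_yaml(filename: str) -> dict:
    text = resources.files("sedrisk.data").joinpath(filename).read_text("utf-8")
    return yaml.safe_load(text)


def _parse_background_doc(doc: dict) -> ReferenceSet:
    if "name" not in doc or "background" not in doc or not doc["background"]:
        raise ReferenceDataError(
            "background config must provide 'name' and a non-empty 'background' map"
        )
    raw = doc["background"]
    if len(set(raw)) != len(raw):  # yaml merges duplicates; guard dict input too
        raise ReferenceDataError("duplicate element in background map")
    return ReferenceSet(
        name=str(doc["name"]),
        background={el: float(v) for el, v in raw.items()},
        source_note=str(doc.get("source_note", "")),
    )


def load_reference_set(source) -> ReferenceSet:
    """Load and validate a background reference set from a YAML document."""
    return _parse_background_doc(_load_yaml(source))


def write_reference_set(ref: ReferenceSet, path) -> None:
    """Serialise *ref* with canonical (sorted) element ordering."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(ref.to_dict(), fh, sort_keys=False)


def builtin_references() -> list[ReferenceSet]:
    """The two built-in baselines, Taylor & McLennan UCC first."""
    return [
        _parse_background_doc(_builtin_yaml("backgrounds_taylor_mclennan_1995.yaml")),
        _parse_background_doc(_builtin_yaml("backgrounds_turekian_wedepohl_1961.yaml")),
    ]


def get_reference_set(name_or_path: str) -> ReferenceSet:
    """Resolve a ``--background`` argument: built-in name or a file path."""
    for ref in builtin_references():
        if ref.name == name_or_path:
            return ref
    if os.path.exists(name_or_path):
        return load_reference_set(name_or_path)
    raise ReferenceDataError(
        f"unknown reference set {name_or_path!r}; use a built-in name "
        "('taylor_mclennan_1995', 'turekian_wedepohl_1961') or a config path"
    )


def load_toxic_response_factors(source) -> ToxicResponseFactors:
    doc = _load_yaml(source)
    if "factors" not in doc or not doc["factors"]:
        raise ReferenceDataError("toxicity config must provide a non-empty 'factors' map")
    return ToxicResponseFactors(
        factors={el: float(v) for el, v in doc["factors"].items()},
        name=str(doc.get("name", "user")),
    )


def builtin_toxic_response_factors() -> ToxicResponseFactors:
    return load_toxic_response_factors(_builtin_yaml("toxic_response_hakanson.yaml"))


def _parse_profile(receptor: str, raw: dict) -> ExposureProfile:
    daf = {str(k): float(v) for k, v in raw.get("DAF", {}).items()}
    return ExposureProfile(
        receptor=receptor,
        ABW=float(raw["ABW"]), IR=float(raw["IR"]), IHR=float(raw["IHR"]),
        SA=float(raw["SA"]), SAF=float(raw["SAF"]), DAF=daf,
        ED=float(raw["ED"]), EF_days=float(raw["EF_days"]),
        AET_nc=float(raw.get("AET_nc", float(raw["ED"]) * 365.0)),
        AET_ca=float(raw.get("AET_ca", 70.0 * 365.0)),
        PEF=float(raw["PEF"]), CFU=float(raw.get("CFU", 1.0e-6)),
    )


def load_exposure_profiles(source) -> dict[str, ExposureProfile]:
    doc = _load_yaml(source)
    if "profiles" not in doc:
        raise ReferenceDataError("exposure config must provide a 'profiles' map")
    return {r: _parse_profile(r, raw) for r, raw in doc["profiles"].items()}


def builtin_exposure_profiles() -> tuple[ExposureProfile, ExposureProfile]:
    """Default (child, adult) exposure profiles."""
    profiles = load_exposure_profiles(_builtin_yaml("exposure_default.yaml"))
    return profiles["child"], profiles["adult"]


def load_dose_response(source) -> DoseResponseTable:
    doc = _load_yaml(source)
    if "elements" not in doc or not doc["elements"]:
        raise ReferenceDataError("dose-response config must provide an 'elements' map")
    records = {}
    for el, raw in doc["elements"].items():
        records[el] = ElementDoseResponse(
            element=el,
            rfd_ing=raw.get("rfd_ing"),
            rfd_inh=raw.get("rfd_inh"),
            rfd_derm=raw.get("rfd_derm"),
            sf_ing=raw.get("sf_ing"),
            iur=raw.get("iur"),
            giabs=float(raw.get("giabs", 1.0)),
        )
    return DoseResponseTable(elements=records, name=str(doc.get("name", "user")))


def builtin_dose_response() -> DoseResponseTable:
    return load_dose_response(_builtin_yaml("dose_response_default.yaml"))


# Default element scopes.  Twelve elements enter the contamination indices
# (Hg is measured but excluded, following the study design); ten carry
# defensible toxic response factors into the ecological risk index; five
# priority metals enter the human health assessment.
INDEX_ELEMENTS: tuple[str, ...] = (
    "Cu", "Cr", "Fe", "Mn", "Mo", "Ni", "Pb", "V", "Zn", "Sb", "As", "Cd",
)
ECO_RISK_ELEMENTS: tuple[str, ...] = (
    "As", "Cd", "Cr", "Cu", "Mn", "Ni", "Pb", "Sb", "V", "Zn",
)
HEALTH_RISK_ELEMENTS: tuple[str, ...] = ("As", "Cd", "Cr", "Ni", "Pb")
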