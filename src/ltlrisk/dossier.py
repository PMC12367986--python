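"""Chemical dossiers: toxicological constants, uncertainty factors and TTC thresholds.

A :class:`ChemicalDossier` collects everything the hazard decision trees need
for one substance — reference values with their derivation (point of
departure and uncertainty factors), an acute reference dose, a cancer slope
factor, elimination half-lives, mode-of-action evidence and a Cramer class
for threshold-of-toxicological-concern (TTC) screening.

Internal units are fixed: doses in mg/kg bw/day, water concentrations in
µg/L.  Dossier files may declare µg/kg/day doses in their ``units:`` block
and are converted on load.
"""

from __future__ import annotations

import enum
import json
import math
from pathlib import Path
from types import MappingProxyType
from typing import List, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

SCHEMA_VERSION = 1

# Classic uncertainty-factor subdivision: the inter-species factor of 10
# splits into 4.0 (toxicokinetics) x 2.5 (toxicodynamics); the intra-human
# factor of 10 into 3.16 x 3.16.
INTERSPECIES_TK_SUBDIVIDED = 4.0
INTERSPECIES_TD_SUBDIVIDED = 2.5
INTRASPECIES_TK_SUBDIVIDED = 3.16
INTRASPECIES_TD_SUBDIVIDED = 3.16


class DurationClass(str, enum.Enum):
    acute = "acute"
    short = "short"
    intermediate = "intermediate"
    chronic = "chronic"


class CarcinogenClass(str, enum.Enum):
    non_carcinogen = "non_carcinogen"
    threshold_carcinogen = "threshold_carcinogen"
    non_threshold_carcinogen = "non_threshold_carcinogen"
    unknown = "unknown"


class CramerClass(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    organophosphate_carbamate = "organophosphate_carbamate"
    carcinogen = "carcinogen"
    genotoxic = "genotoxic"


class PodType(str, enum.Enum):
    BMDL10 = "BMDL10"
    NOAEL = "NOAEL"
    LOAEL = "LOAEL"


class TriState(str, enum.Enum):
    positive = "positive"
    negative = "negative"
    unknown = "unknown"


class InVivoScope(str, enum.Enum):
    multi_species_multi_organ = "multi_species_multi_organ"
    single_species_single_organ = "single_species_single_organ"
    unknown = "unknown"


class DossierError(ValueError):
    """Raised when a dossier file violates the schema or an invariant."""


class UncertaintyFactorSet(BaseModel):
    """Multiplicative uncertainty factors applied to a point of departure.

    Every component defaults to 1 (i.e. not applied); the composite is the
    product of all components and is order-independent by construction.
    """

    model_config = ConfigDict(frozen=True)

    interspecies_tk: float = 1.0
    interspecies_td: float = 1.0
    intraspecies_tk: float = 1.0
    intraspecies_td: float = 1.0
    duration_extrapolation: float = 1.0
    loael_to_noael: float = 1.0
    database_deficiency: float = 1.0

    @model_validator(mode="after")
    def _check_range(self) -> "UncertaintyFactorSet":
        for name, value in self.components().items():
            if not value >= 1.0:
                raise DossierError(f"uncertainty factor {name} must be >= 1, got {value}")
        return self

    def components(self) -> dict:
        return {
            "interspecies_tk": self.interspecies_tk,
            "interspecies_td": self.interspecies_td,
            "intraspecies_tk": self.intraspecies_tk,
            "intraspecies_td": self.intraspecies_td,
            "duration_extrapolation": self.duration_extrapolation,
            "loael_to_noael": self.loael_to_noael,
            "database_deficiency": self.database_deficiency,
        }

    @property
    def composite(self) -> float:
        return math.prod(self.components().values())

    @classmethod
    def default_100(cls) -> "UncertaintyFactorSet":
        """The classic default composite of 100 (10 inter-species x 10 intra-human)."""
        return cls(interspecies_tk=10.0, intraspecies_tk=10.0)

    @classmethod
    def who_subdivided(cls) -> "UncertaintyFactorSet":
        """The chemical-specific-adjustment subdivision (4.0x2.5 and 3.16x3.16)."""
        return cls(
            interspecies_tk=INTERSPECIES_TK_SUBDIVIDED,
            interspecies_td=INTERSPECIES_TD_SUBDIVIDED,
            intraspecies_tk=INTRASPECIES_TK_SUBDIVIDED,
            intraspecies_td=INTRASPECIES_TD_SUBDIVIDED,
        )

    def without(self, *names: str) -> "UncertaintyFactorSet":
        """Copy with the named components reset to 1 (factor removed)."""
        return self.model_copy(update={n: 1.0 for n in names})


class PODRecord(BaseModel):
    """A candidate point of departure from one study."""

    model_config = ConfigDict(frozen=True)

    pod_type: PodType
    value: float = Field(gt=0, description="mg/kg bw/day")
    study_duration_class: DurationClass = DurationClass.chronic


class HBGVRecord(BaseModel):
    """A health-based guidance value (reference value) with its derivation.

    ``pod_type``/``pod_value``/``uf`` are optional because literature
    reference values are often reported without their derivation.
    """

    model_config = ConfigDict(frozen=True)

    value: float = Field(gt=0, description="mg/kg bw/day")
    duration_class: DurationClass = DurationClass.chronic
    pod_type: Optional[PodType] = None
    pod_value: Optional[float] = Field(default=None, gt=0)
    uf: Optional[UncertaintyFactorSet] = None
    study_duration_class: Optional[DurationClass] = None
    source: str = ""

    @model_validator(mode="after")
    def _check_consistency(self) -> "HBGVRecord":
        if self.pod_value is not None:
            if self.value > self.pod_value * (1 + 1e-12):
                raise DossierError("reference value exceeds its point of departure")
            if self.uf is not None:
                derived = self.pod_value / self.uf.composite
                if abs(derived - self.value) > 0.01 * self.value:
                    raise DossierError(
                        "reference value inconsistent with POD/UF by more than 1%: "
                        f"{self.value} vs {derived}"
                    )
        return self


class MoAEvidence(BaseModel):
    """Mode-of-action evidence lines for carcinogen linearity classification."""

    model_config = ConfigDict(frozen=True)

    structural_alert: TriState = TriState.unknown
    ames: TriState = TriState.unknown
    in_vivo_scope: InVivoScope = InVivoScope.unknown
    mechanism_notes: str = ""

    @property
    def all_unknown(self) -> bool:
        return (
            self.structural_alert is TriState.unknown
            and self.ames is TriState.unknown
            and self.in_vivo_scope is InVivoScope.unknown
        )


class TTCEntry(BaseModel):
    """One row of the TTC registry (intake threshold, optional water target)."""

    model_config = ConfigDict(frozen=True)

    cramer_or_class: CramerClass
    ttc_ug_per_day: float = Field(gt=0)
    dw_target_ug_per_L: Optional[float] = Field(default=None, gt=0)
    dw_target_options: dict = Field(default_factory=dict)


def _ttc_registry() -> MappingProxyType:
    rows = [
        TTCEntry(cramer_or_class=CramerClass.I, ttc_ug_per_day=1800.0, dw_target_ug_per_L=37.7),
        TTCEntry(cramer_or_class=CramerClass.II, ttc_ug_per_day=540.0),
        TTCEntry(cramer_or_class=CramerClass.III, ttc_ug_per_day=90.0, dw_target_ug_per_L=4.0),
        TTCEntry(cramer_or_class=CramerClass.organophosphate_carbamate, ttc_ug_per_day=18.0),
        TTCEntry(cramer_or_class=CramerClass.carcinogen, ttc_ug_per_day=1.5, dw_target_ug_per_L=0.1),
        # Two published water targets exist for genotoxic substances; the
        # lower one is the default (more conservative).
        TTCEntry(
            cramer_or_class=CramerClass.genotoxic,
            ttc_ug_per_day=0.15,
            dw_target_ug_per_L=0.01,
            dw_target_options={"signal-value": 0.01, "screening-value": 0.02},
        ),
    ]
    return MappingProxyType({row.cramer_or_class: row for row in rows})


#: Immutable TTC registry keyed by structural class.
TTC_REGISTRY = _ttc_registry()


def ttc_lookup(cls: Union[CramerClass, str]) -> TTCEntry:
    """Return the TTC registry row for a structural class.

    Raises ``KeyError`` for a class not in the registry.
    """
    cls = CramerClass(cls)
    if cls not in TTC_REGISTRY:
        raise KeyError(f"no TTC entry for class {cls.value}")
    return TTC_REGISTRY[cls]


class ChemicalDossier(BaseModel):
    """All toxicological constants and evidence for one substance."""

    model_config = ConfigDict(frozen=True)

    name: str
    cas: Optional[str] = None
    carcinogen_class: CarcinogenClass = CarcinogenClass.unknown
    moa_evidence: Optional[MoAEvidence] = None
    rfv_records: List[HBGVRecord] = Field(default_factory=list)
    pods: List[PODRecord] = Field(default_factory=list)
    arfd: Optional[float] = Field(default=None, gt=0, description="mg/kg bw/day")
    csf: Optional[float] = Field(default=None, gt=0, description="(mg/kg/day)^-1")
    elimination_half_lives_h: List[float] = Field(default_factory=list)
    cramer_class: Optional[CramerClass] = None
    glv_ug_per_L: Optional[float] = Field(default=None, gt=0)
    saturated_elimination: bool = False
    effects_persist: bool = False
    assume_genotoxic_default: bool = False
    iarc_group: Optional[str] = None  # metadata only, never routes the workflow
    notes: str = ""

    @model_validator(mode="after")
    def _check_invariants(self) -> "ChemicalDossier":
        hl = self.elimination_half_lives_h
        if any(h <= 0 for h in hl):
            raise DossierError("elimination half-lives must be strictly positive")
        if list(hl) != sorted(hl):
            raise DossierError("elimination half-lives must be sorted ascending")
        if self.carcinogen_class is CarcinogenClass.non_threshold_carcinogen:
            if self.moa_evidence is None and not self.assume_genotoxic_default:
                raise DossierError(
                    "non_threshold_carcinogen requires moa_evidence or the "
                    "assume_genotoxic_default flag"
                )
        return self

    def chronic_rfv(self) -> Optional[HBGVRecord]:
        """The chronic (lifetime) reference value, if any."""
        for rec in self.rfv_records:
            if rec.duration_class is DurationClass.chronic:
                return rec
        return None


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_DOSE_UNIT_TO_MG = {"mg_per_kg_day": 1.0, "ug_per_kg_day": 1e-3}
_CONC_UNIT_TO_UG_L = {"ug_per_L": 1.0, "mg_per_L": 1e3}

_DOSE_FIELDS = ("arfd",)
_CONC_FIELDS = ("glv_ug_per_L",)


def load_dossier(path: Union[str, Path]) -> ChemicalDossier:
    """Load and validate a dossier from a YAML or JSON file.

    The file must carry ``schema: 1``.  Doses may be declared in µg/kg/day
    through the ``units:`` block; everything is normalised to mg/kg bw/day
    and µg/L internally.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    try:
        raw = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise DossierError(f"cannot parse {path.name}: {exc}") from exc
    if not isinstance(raw, dict):
        raise DossierError(f"{path.name}: expected a mapping at top level")
    return dossier_from_dict(raw)


def dossier_from_dict(raw: dict) -> ChemicalDossier:
    raw = dict(raw)
    schema = raw.pop("schema", SCHEMA_VERSION)
    if schema != SCHEMA_VERSION:
        raise DossierError(f"unsupported dossier schema: {schema}")
    units = raw.pop("units", {}) or {}
    dose_unit = units.get("dose", "mg_per_kg_day")
    conc_unit = units.get("concentration", "ug_per_L")
    if dose_unit not in _DOSE_UNIT_TO_MG:
        raise DossierError(f"unknown dose unit: {dose_unit}")
    if conc_unit not in _CONC_UNIT_TO_UG_L:
        raise DossierError(f"unknown concentration unit: {conc_unit}")
    dscale = _DOSE_UNIT_TO_MG[dose_unit]
    cscale = _CONC_UNIT_TO_UG_L[conc_unit]

    def scale_dose(x):
        return None if x is None else x * dscale

    for f in _DOSE_FIELDS:
        if f in raw:
            raw[f] = scale_dose(raw[f])
    if "csf" in raw and raw["csf"] is not None:
        raw["csf"] = raw["csf"] / dscale  # slope factor is per unit dose
    for f in _CONC_FIELDS:
        if f in raw and raw[f] is not None:
            raw[f] = raw[f] * cscale
    for rec in raw.get("rfv_records", []) or []:
        if isinstance(rec, dict):
            if rec.get("value") is not None:
                rec["value"] = rec["value"] * dscale
            if rec.get("pod_value") is not None:
                rec["pod_value"] = rec["pod_value"] * dscale
    for rec in raw.get("pods", []) or []:
        if isinstance(rec, dict) and rec.get("value") is not None:
            rec["value"] = rec["value"] * dscale

    try:
        return ChemicalDossier.model_validate(raw)
    except DossierError:
        raise
    except Exception as exc:  # pydantic ValidationError names the field
        raise DossierError(str(exc)) from exc


def dossier_to_dict(d: ChemicalDossier) -> dict:
    """Serialise a dossier to a plain dict in internal units (mg/kg/day, µg/L)."""
    out = {"schema": SCHEMA_VERSION, "units": {"dose": "mg_per_kg_day", "concentration": "ug_per_L"}}
    data = d.model_dump(mode="json", exclude_none=True, exclude_defaults=True)
    data.pop("name", None)
    out["name"] = d.name
    out.update(data)
    return out


def write_dossier(d: ChemicalDossier, path: Union[str, Path]) -> Path:
    """Write a dossier as YAML (or JSON if the suffix is ``.json``)."""
    path = Path(path)
    payload = dossier_to_dict(d)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")
    return path
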