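"""Instrument registry: threshold rules and dichotomization.

The assessment battery for lower-limb vascular amputees comprises ten
instruments tied to mobility *modulators* (personal/environmental factors
that, past a published threshold, count as limiting), four tied to
*potential* mobility (capability measured in a clinic-like setting) and
three tied to *effective* mobility (mobility realised in the person's own
environment).  Every instrument carries a fail rule on its native scale;
:func:`dichotomize` turns a raw measurement into success (1) / fail (0) /
missing-with-reason outcomes that the scoring engine aggregates.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional, Sequence, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigurationError, MeasurementError, NormLookupError

__all__ = [
    "Dimension",
    "MissingCode",
    "Archetype",
    "RuleKind",
    "ThresholdRule",
    "SubItem",
    "InstrumentSpec",
    "NormStratum",
    "NormTable",
    "ParticipantAttrs",
    "RawMeasurement",
    "BinaryOutcome",
    "InstrumentRegistry",
    "default_registry",
    "default_norms",
    "load_registry",
    "dichotomize",
    "lookup_norm",
    "fatigue_check",
    "resolve_alternates",
]


class Dimension(str, enum.Enum):
    MODULATOR = "modulator"
    POTENTIAL = "potential"
    EFFECTIVE = "effective"


class MissingCode(str, enum.Enum):
    """Missing-data codes mirroring the source table's 'n.e.', 'n.a.', '-'."""

    NONE = "none"
    NOT_EVALUATED = "ne"
    NOT_APPLICABLE = "na"
    NOT_COLLECTED = "nc"


class Archetype(str, enum.Enum):
    """Mobility mode driving instrument applicability."""

    PROSTHESIS_WALKER = "prosthesis_walker"
    AID_WALKER = "aid_walker"
    WHEELCHAIR_USER = "wheelchair_user"


AMBULATORY = frozenset({Archetype.PROSTHESIS_WALKER, Archetype.AID_WALKER})


class RuleKind(str, enum.Enum):
    """How a raw value is compared to its cut.  Satisfying the comparison
    marks the item FAIL/negative; every published rule is stated as a fail
    condition."""

    GREATER_THAN = "greater_than"
    GREATER_EQUAL = "greater_equal"
    LESS_THAN = "less_than"
    LESS_EQUAL = "less_equal"
    BOOLEAN_FLAG = "boolean_flag"
    ANY_SITE_MISSED = "any_site_missed"
    NORM_BELOW = "norm_below"
    NORM_PERCENTILE_LE = "norm_percentile_le"


_THRESHOLD_KINDS = {
    RuleKind.GREATER_THAN,
    RuleKind.GREATER_EQUAL,
    RuleKind.LESS_THAN,
    RuleKind.LESS_EQUAL,
}
_NORM_KINDS = {RuleKind.NORM_BELOW, RuleKind.NORM_PERCENTILE_LE}


class ThresholdRule(BaseModel):
    """A single fail rule.  ``threshold`` is required for comparison kinds,
    forbidden for boolean/site/norm kinds (norm cuts come from a
    :class:`NormTable` at evaluation time)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    kind: RuleKind
    threshold: Optional[float] = None

    @model_validator(mode="after")
    def _check_threshold(self) -> "ThresholdRule":
        if self.kind in _THRESHOLD_KINDS and self.threshold is None:
            raise ValueError(f"rule kind {self.kind.value} requires a threshold")
        if self.kind not in _THRESHOLD_KINDS and self.threshold is not None:
            raise ValueError(f"rule kind {self.kind.value} takes no threshold")
        return self

    def fails(self, value: float, norm_cut: Optional[float] = None) -> bool:
        """True iff ``value`` satisfies the fail condition."""
        k = self.kind
        if k is RuleKind.GREATER_THAN:
            return value > self.threshold
        if k is RuleKind.GREATER_EQUAL:
            return value >= self.threshold
        if k is RuleKind.LESS_THAN:
            return value < self.threshold
        if k is RuleKind.LESS_EQUAL:
            return value <= self.threshold
        if k is RuleKind.NORM_BELOW:
            if norm_cut is None:
                raise NormLookupError("norm_below rule evaluated without a norm cut")
            return value < norm_cut
        if k is RuleKind.NORM_PERCENTILE_LE:
            if norm_cut is None:
                raise NormLookupError(
                    "norm_percentile_le rule evaluated without a norm cut"
                )
            return value <= norm_cut
        raise MeasurementError(f"rule kind {k.value} is not value-based")


class SubItem(BaseModel):
    """One dichotomous item an instrument contributes to its composite."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    item_id: str
    rule: ThresholdRule
    name: str = ""


class InstrumentSpec(BaseModel):
    """Registry entry: an instrument, its scale, fail rule(s), applicability
    and (optional) membership in an alternates group.

    ``applicability`` is the set of archetypes the instrument applies to;
    ``None`` means everyone.  Instruments sharing an ``alternates_group``
    occupy one composite slot; the member with the highest
    ``alternates_priority`` wins when more than one was assessed.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    instrument_id: str
    name: str
    dimension: Dimension
    items: tuple[SubItem, ...] = Field(min_length=1)
    scale_min: Optional[float] = None
    scale_max: Optional[float] = None
    value_type: str = "numeric"  # numeric | boolean | sites
    n_sites: int = 0
    applicability: Optional[frozenset[Archetype]] = None
    alternates_group: Optional[str] = None
    alternates_priority: int = 0

    @model_validator(mode="after")
    def _check(self) -> "InstrumentSpec":
        if self.value_type == "numeric":
            if self.scale_min is None or self.scale_max is None:
                raise ValueError(f"{self.instrument_id}: numeric scale needs bounds")
            if not self.scale_min < self.scale_max:
                raise ValueError(f"{self.instrument_id}: scale_min must be < scale_max")
        if self.value_type == "sites" and self.n_sites < 1:
            raise ValueError(f"{self.instrument_id}: sites instrument needs n_sites")
        return self

    @property
    def item_count_in_composite(self) -> int:
        return len(self.items)

    def item_ids(self) -> list[str]:
        """Fully-qualified item ids ('instrument' or 'instrument:sub')."""
        if len(self.items) == 1:
            return [self.instrument_id]
        return [f"{self.instrument_id}:{it.item_id}" for it in self.items]

    def applies_to(self, archetype: Archetype) -> bool:
        return self.applicability is None or archetype in self.applicability

    @property
    def uses_norms(self) -> bool:
        return any(it.rule.kind in _NORM_KINDS for it in self.items)


class NormStratum(BaseModel):
    """One (age band, optional sex) -> cut row of a norm table.  The age
    band is ``[age_min, age_max)``."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    age_min: float
    age_max: float
    sex: Optional[str] = None  # 'M' | 'F' | None (both)
    cut: float

    @model_validator(mode="after")
    def _check(self) -> "NormStratum":
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be < age_max")
        return self

    def matches(self, age: float, sex: Optional[str]) -> bool:
        if not (self.age_min <= age < self.age_max):
            return False
        return self.sex is None or self.sex == sex


class NormTable(BaseModel):
    """Age(/sex)-stratified cut values for a norm-referenced instrument.

    Strata must not overlap: lookup for any in-range (age, sex) returns
    exactly one cut.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    instrument_id: str
    strata: tuple[NormStratum, ...] = Field(min_length=1)

    @model_validator(mode="after")
    def _no_overlap(self) -> "NormTable":
        for i, a in enumerate(self.strata):
            for b in self.strata[i + 1 :]:
                sexes_clash = a.sex is None or b.sex is None or a.sex == b.sex
                ages_clash = a.age_min < b.age_max and b.age_min < a.age_max
                if sexes_clash and ages_clash:
                    raise ValueError(
                        f"{self.instrument_id}: overlapping norm strata "
                        f"[{a.age_min},{a.age_max}) and [{b.age_min},{b.age_max})"
                    )
        return self

    def lookup(self, age: float, sex: Optional[str] = None) -> float:
        hits = [s for s in self.strata if s.matches(age, sex)]
        if not hits:
            raise NormLookupError(
                f"{self.instrument_id}: no norm stratum for age={age}, sex={sex}"
            )
        return hits[0].cut


@dataclass(frozen=True)
class ParticipantAttrs:
    """Attributes that gate applicability and norm lookups."""

    participant_id: str
    age: float
    sex: str  # 'M' | 'F'
    archetype: Archetype


SiteVector = tuple[bool, ...]
Value = Union[float, bool, SiteVector]


@dataclass(frozen=True)
class RawMeasurement:
    """One participant x instrument(-subitem) observation on its native
    scale, or a coded missing value.  ``value`` is populated iff
    ``missing_code`` is NONE."""

    participant_id: str
    instrument_id: str
    value: Optional[Value] = None
    subitem_id: Optional[str] = None
    missing_code: MissingCode = MissingCode.NONE

    def __post_init__(self) -> None:
        if (self.value is None) != (self.missing_code is not MissingCode.NONE):
            raise MeasurementError(
                f"{self.participant_id}/{self.instrument_id}: value must be "
                "populated iff missing_code is none"
            )


@dataclass(frozen=True)
class BinaryOutcome:
    """Dichotomized result for one composite item: success=1, fail=0, or
    missing with a reason."""

    participant_id: str
    item_id: str
    instrument_id: str
    dimension: Dimension
    value: Optional[int] = None  # 1 success, 0 fail, None missing
    missing_reason: Optional[MissingCode] = None

    def __post_init__(self) -> None:
        if (self.value is None) != (self.missing_reason is not None):
            raise MeasurementError(
                f"{self.item_id}: outcome must be 0/1 xor carry a missing reason"
            )
        if self.value is not None and self.value not in (0, 1):
            raise MeasurementError(f"{self.item_id}: outcome value must be 0 or 1")

    @property
    def is_missing(self) -> bool:
        return self.value is None


class InstrumentRegistry:
    """The instrument battery plus its norm tables."""

    def __init__(
        self,
        specs: Iterable[InstrumentSpec],
        norms: Optional[Mapping[str, NormTable]] = None,
    ) -> None:
        self._specs: dict[str, InstrumentSpec] = {}
        for spec in specs:
            if spec.instrument_id in self._specs:
                raise ConfigurationError(
                    f"duplicate instrument_id: {spec.instrument_id}"
                )
            self._specs[spec.instrument_id] = spec
        self.norms: dict[str, NormTable] = dict(norms or {})
        self._validate()

    # -- access ---------------------------------------------------------
    def __contains__(self, instrument_id: str) -> bool:
        return instrument_id in self._specs

    def __getitem__(self, instrument_id: str) -> InstrumentSpec:
        try:
            return self._specs[instrument_id]
        except KeyError:
            raise ConfigurationError(f"unknown instrument_id: {instrument_id}") from None

    def __iter__(self):
        return iter(self._specs.values())

    def instrument_ids(self) -> list[str]:
        return list(self._specs)

    def specs_for_dimension(self, dimension: Dimension) -> list[InstrumentSpec]:
        return [s for s in self if s.dimension == dimension]

    def composite_slots(self, dimension: Dimension) -> list[str]:
        """Composite item slots for a dimension; an alternates group is one
        slot regardless of how many instruments can fill it."""
        slots: list[str] = []
        seen_groups: set[str] = set()
        for spec in self.specs_for_dimension(dimension):
            if spec.alternates_group is not None:
                if spec.alternates_group in seen_groups:
                    continue
                seen_groups.add(spec.alternates_group)
                slots.append(spec.alternates_group)
            else:
                slots.extend(spec.item_ids())
        return slots

    def alternates_winner(self, group: str) -> InstrumentSpec:
        members = [s for s in self if s.alternates_group == group]
        return max(members, key=lambda s: s.alternates_priority)

    # -- validation / serialization -------------------------------------
    def _validate(self) -> None:
        for dim in Dimension:
            if not self.specs_for_dimension(dim):
                raise ConfigurationError(f"dimension {dim.value} has no instruments")
        for spec in self:
            if spec.uses_norms and spec.instrument_id not in self.norms:
                raise ConfigurationError(
                    f"{spec.instrument_id}: norm-based rule but no norm table"
                )

    def to_dict(self) -> dict[str, Any]:
        def _spec_dict(s: InstrumentSpec) -> dict[str, Any]:
            d = s.model_dump(mode="json", exclude_none=True, exclude_defaults=True)
            d["instrument_id"] = s.instrument_id
            d["dimension"] = s.dimension.value
            if s.applicability is not None:
                d["applicability"] = sorted(a.value for a in s.applicability)
            return d

        return {
            "instruments": [_spec_dict(self._specs[i]) for i in sorted(self._specs)],
            "norms": {
                i: self.norms[i].model_dump(mode="json", exclude_none=True)
                for i in sorted(self.norms)
            },
        }


# ---------------------------------------------------------------------------
# Default battery
# ---------------------------------------------------------------------------

def _rule(kind: RuleKind, threshold: Optional[float] = None) -> ThresholdRule:
    return ThresholdRule(kind=kind, threshold=threshold)


def _single(item_rule: ThresholdRule) -> tuple[SubItem, ...]:
    return (SubItem(item_id="score", rule=item_rule),)


#: The ten boolean risk-factor items collected by the study questionnaire.
QUESTIONNAIRE_ITEMS: tuple[str, ...] = (
    "age_over_60",
    "below_knee_amputation",
    "adl_fatigue",
    "daily_cigarettes",
    "daily_alcohol",
    "lives_alone_or_care_centre",
    "inaccessible_environment",
    "device_dissatisfaction",
    "other_physical_problem",
    "lack_of_services",
)


def default_registry(norms: Optional[Mapping[str, NormTable]] = None) -> InstrumentRegistry:
    """The published battery with its fail thresholds.

    Modulators (21 composite items): questionnaire (10 boolean flags),
    Charlson comorbidity >= 2, social support (ISEL < 1 or its replacement
    MOS < 75 — one slot), WCQ coping (3 aspect means), BPI pain (Q5 > 5,
    Q9a > 7), BMI > 30, GDS-30 >= 11, grip strength at or below the
    30th age/sex percentile, Semmes-Weinstein monofilament (any of 4 sites
    unfelt).  Potential mobility (4 slots): LCI <= 21/42, ambulatory
    TUG > 14 s or wheelchair TUG > 34 s (gated by archetype), balance
    (BBT < 45 or its replacement AMP < 25 — one slot).  Effective mobility
    (4 items): LIFE-H daily activities and social roles (mean < 7/9 each),
    LSA below age norm, HAP maximum activity score below age norm.
    """
    M, P, E = Dimension.MODULATOR, Dimension.POTENTIAL, Dimension.EFFECTIVE
    specs = [
        InstrumentSpec(
            instrument_id="sdq",
            name="Sociodemographic/clinical questionnaire (risk-factor flags)",
            dimension=M,
            value_type="boolean",
            items=tuple(
                SubItem(item_id=i, rule=_rule(RuleKind.BOOLEAN_FLAG))
                for i in QUESTIONNAIRE_ITEMS
            ),
        ),
        InstrumentSpec(
            instrument_id="charlson",
            name="Charlson Comorbidity Index (geriatric adaptation)",
            dimension=M,
            scale_min=0,
            scale_max=37,
            items=_single(_rule(RuleKind.GREATER_EQUAL, 2)),
        ),
        InstrumentSpec(
            instrument_id="isel",
            name="Interpersonal Support Evaluation List (mean of 3 supports)",
            dimension=M,
            scale_min=0,
            scale_max=3,
            items=_single(_rule(RuleKind.LESS_THAN, 1)),
            alternates_group="social_support",
            alternates_priority=0,
        ),
        InstrumentSpec(
            instrument_id="mos",
            name="MOS Social Support Survey (total)",
            dimension=M,
            scale_min=0,
            scale_max=95,
            items=_single(_rule(RuleKind.LESS_THAN, 75)),
            alternates_group="social_support",
            alternates_priority=1,
        ),
        InstrumentSpec(
            instrument_id="wcq",
            name="Ways of Coping Questionnaire (3 aspect means)",
            dimension=M,
            scale_min=0,
            scale_max=3,
            items=(
                SubItem(
                    item_id="distancing_avoidance",
                    rule=_rule(RuleKind.GREATER_THAN, 1.5),
                ),
                SubItem(
                    item_id="seeking_social_support",
                    rule=_rule(RuleKind.LESS_THAN, 1.5),
                ),
                SubItem(
                    item_id="positive_reappraisal",
                    rule=_rule(RuleKind.LESS_THAN, 1.5),
                ),
            ),
        ),
        InstrumentSpec(
            instrument_id="bpi",
            name="Modified Brief Pain Inventory (intensity Q5, interference Q9a)",
            dimension=M,
            scale_min=0,
            scale_max=10,
            items=(
                SubItem(item_id="q5", rule=_rule(RuleKind.GREATER_THAN, 5)),
                SubItem(item_id="q9a", rule=_rule(RuleKind.GREATER_THAN, 7)),
            ),
        ),
        InstrumentSpec(
            instrument_id="bmi",
            name="Body Mass Index",
            dimension=M,
            scale_min=10,
            scale_max=70,
            items=_single(_rule(RuleKind.GREATER_THAN, 30)),
        ),
        InstrumentSpec(
            instrument_id="gds",
            name="Yesavage Geriatric Depression Scale (30-item)",
            dimension=M,
            scale_min=0,
            scale_max=30,
            items=_single(_rule(RuleKind.GREATER_EQUAL, 11)),
        ),
        InstrumentSpec(
            instrument_id="grip",
            name="Jamar grip strength (mean of 2 trials, kg)",
            dimension=M,
            scale_min=0,
            scale_max=90,
            items=_single(_rule(RuleKind.NORM_PERCENTILE_LE)),
        ),
        InstrumentSpec(
            instrument_id="monofilament",
            name="Semmes-Weinstein 10 g monofilament, intact foot (4 sites)",
            dimension=M,
            value_type="sites",
            n_sites=4,
            items=_single(_rule(RuleKind.ANY_SITE_MISSED)),
        ),
        # -- potential mobility ----------------------------------------
        InstrumentSpec(
            instrument_id="lci",
            name="Locomotor Capabilities Index (total /42; adapted form for "
            "non-prosthesis users)",
            dimension=P,
            scale_min=0,
            scale_max=42,
            items=_single(_rule(RuleKind.LESS_EQUAL, 21)),
        ),
        InstrumentSpec(
            instrument_id="tug_ab",
            name="Timed Up and Go (prosthesis or walking aid), seconds",
            dimension=P,
            scale_min=0,
            scale_max=300,
            items=_single(_rule(RuleKind.GREATER_THAN, 14)),
            applicability=AMBULATORY,
        ),
        InstrumentSpec(
            instrument_id="tug_c",
            name="Wheelchair-adapted TUG (transfer + 3 m propel), seconds",
            dimension=P,
            scale_min=0,
            scale_max=300,
            items=_single(_rule(RuleKind.GREATER_THAN, 34)),
            applicability=frozenset({Archetype.WHEELCHAIR_USER}),
        ),
        InstrumentSpec(
            instrument_id="bbt",
            name="Berg Balance Test (total /56)",
            dimension=P,
            scale_min=0,
            scale_max=56,
            items=_single(_rule(RuleKind.LESS_THAN, 45)),
            alternates_group="balance",
            alternates_priority=0,
        ),
        InstrumentSpec(
            instrument_id="amp",
            name="Amputee Mobility Predictor (total /47)",
            dimension=P,
            scale_min=0,
            scale_max=47,
            items=_single(_rule(RuleKind.LESS_THAN, 25)),
            alternates_group="balance",
            alternates_priority=1,
        ),
        # -- effective mobility ----------------------------------------
        InstrumentSpec(
            instrument_id="lifeh",
            name="Assessment of Life Habits 3.1 (mean /9 per domain)",
            dimension=E,
            scale_min=0,
            scale_max=9,
            items=(
                SubItem(item_id="daily_activities", rule=_rule(RuleKind.LESS_THAN, 7)),
                SubItem(item_id="social_roles", rule=_rule(RuleKind.LESS_THAN, 7)),
            ),
        ),
        InstrumentSpec(
            instrument_id="lsa",
            name="Life Space Assessment (total /120)",
            dimension=E,
            scale_min=0,
            scale_max=120,
            items=_single(_rule(RuleKind.NORM_BELOW)),
        ),
        InstrumentSpec(
            instrument_id="hap",
            name="Human Activity Profile — Maximum Activity Score (/94)",
            dimension=E,
            scale_min=0,
            scale_max=94,
            items=_single(_rule(RuleKind.NORM_BELOW)),
        ),
    ]
    return InstrumentRegistry(specs, norms if norms is not None else default_norms())


def default_norms() -> dict[str, NormTable]:
    """Placeholder norm tables for the three norm-referenced instruments.

    The study cites external standards (LSA and HAP age norms, grip-strength
    age/sex percentiles) without printing them, so these strata are
    *synthetic placeholders* chosen at plausible magnitudes; replace them
    with published tables for real analyses.  They are editable config, not
    scientific claims.
    """
    return {
        "lsa": NormTable(
            instrument_id="lsa",
            strata=(
                NormStratum(age_min=50, age_max=65, cut=64.0),
                NormStratum(age_min=65, age_max=120, cut=56.0),
            ),
        ),
        "hap": NormTable(
            instrument_id="hap",
            strata=(
                NormStratum(age_min=50, age_max=65, cut=68.0),
                NormStratum(age_min=65, age_max=75, cut=60.0),
                NormStratum(age_min=75, age_max=120, cut=53.0),
            ),
        ),
        "grip": NormTable(
            instrument_id="grip",
            strata=(
                NormStratum(age_min=50, age_max=65, sex="M", cut=38.0),
                NormStratum(age_min=65, age_max=75, sex="M", cut=32.0),
                NormStratum(age_min=75, age_max=120, sex="M", cut=27.0),
                NormStratum(age_min=50, age_max=65, sex="F", cut=23.0),
                NormStratum(age_min=65, age_max=75, sex="F", cut=19.0),
                NormStratum(age_min=75, age_max=120, sex="F", cut=16.0),
            ),
        ),
    }


# ---------------------------------------------------------------------------
# Registry loading / overrides
# ---------------------------------------------------------------------------

class _ItemPatch(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Optional[RuleKind] = None
    threshold: Optional[float] = None


class _InstrumentPatch(BaseModel):
    model_config = ConfigDict(extra="forbid")
    instrument_id: str
    threshold: Optional[float] = None
    kind: Optional[RuleKind] = None
    items: dict[str, _ItemPatch] = {}
    applicability: Optional[list[Archetype]] = None


class _RegistryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    instruments: list[_InstrumentPatch] = []
    norms: dict[str, list[NormStratum]] = {}


def _patched_rule(rule: ThresholdRule, patch: _ItemPatch) -> ThresholdRule:
    kind = patch.kind or rule.kind
    threshold = patch.threshold if patch.threshold is not None else rule.threshold
    if kind not in _THRESHOLD_KINDS:
        threshold = None
    return ThresholdRule(kind=kind, threshold=threshold)


def load_registry(
    config_source: Union[None, str, Path, Mapping[str, Any]] = None,
) -> InstrumentRegistry:
    """Build the instrument registry, optionally overriding default rules.

    ``config_source`` may be ``None`` (pure defaults), a mapping, or a path
    to a YAML/JSON file with top-level keys ``instruments`` (list of per-id
    patches: ``threshold``, ``kind``, per-subitem ``items`` patches,
    ``applicability``) and ``norms`` (instrument_id -> list of strata,
    replacing that instrument's default table).  An empty config is a
    configuration error.
    """
    if config_source is None:
        return default_registry()

    if isinstance(config_source, (str, Path)):
        text = Path(config_source).read_text()
        raw = yaml.safe_load(text)
    else:
        raw = dict(config_source)
    if not raw:
        raise ConfigurationError("empty registry config")
    try:
        cfg = _RegistryConfig.model_validate(raw)
    except Exception as exc:  # pydantic error -> our error type
        raise ConfigurationError(f"invalid registry config: {exc}") from exc

    seen: set[str] = set()
    patches: dict[str, _InstrumentPatch] = {}
    for patch in cfg.instruments:
        if patch.instrument_id in seen:
            raise ConfigurationError(f"duplicate instrument_id: {patch.instrument_id}")
        seen.add(patch.instrument_id)
        patches[patch.instrument_id] = patch

    base = default_registry()
    unknown = seen - set(base.instrument_ids())
    if unknown:
        raise ConfigurationError(f"unknown instrument_id in config: {sorted(unknown)}")

    new_specs: list[InstrumentSpec] = []
    for spec in base:
        patch = patches.get(spec.instrument_id)
        if patch is None:
            new_specs.append(spec)
            continue
        items = list(spec.items)
        if patch.threshold is not None or patch.kind is not None:
            if len(items) != 1:
                raise ConfigurationError(
                    f"{spec.instrument_id}: top-level threshold patch on a "
                    "multi-item instrument; patch items individually"
                )
            items[0] = SubItem(
                item_id=items[0].item_id,
                rule=_patched_rule(
                    items[0].rule,
                    _ItemPatch(kind=patch.kind, threshold=patch.threshold),
                ),
                name=items[0].name,
            )
        for sub_id, sub_patch in patch.items.items():
            idx = next(
                (i for i, it in enumerate(items) if it.item_id == sub_id), None
            )
            if idx is None:
                raise ConfigurationError(
                    f"{spec.instrument_id}: unknown sub-item {sub_id!r} in config"
                )
            items[idx] = SubItem(
                item_id=sub_id,
                rule=_patched_rule(items[idx].rule, sub_patch),
                name=items[idx].name,
            )
        update: dict[str, Any] = {"items": tuple(items)}
        if patch.applicability is not None:
            update["applicability"] = frozenset(patch.applicability)
        new_specs.append(spec.model_copy(update=update))

    norms = dict(base.norms)
    for inst_id, strata in cfg.norms.items():
        norms[inst_id] = NormTable(instrument_id=inst_id, strata=tuple(strata))
    return InstrumentRegistry(new_specs, norms)


# ---------------------------------------------------------------------------
# Dichotomization
# ---------------------------------------------------------------------------

def lookup_norm(
    norms: Union[NormTable, Mapping[str, NormTable]],
    instrument_id: str,
    age: float,
    sex: Optional[str] = None,
) -> float:
    """Return the unique norm cut for (instrument, age[, sex])."""
    if isinstance(norms, NormTable):
        table = norms
    else:
        try:
            table = norms[instrument_id]
        except KeyError:
            raise NormLookupError(f"no norm table for {instrument_id}") from None
    if table.instrument_id != instrument_id:
        raise NormLookupError(
            f"norm table is for {table.instrument_id}, not {instrument_id}"
        )
    return table.lookup(age, sex)


def _missing_outcomes(
    spec: InstrumentSpec, participant_id: str, reason: MissingCode
) -> list[BinaryOutcome]:
    return [
        BinaryOutcome(
            participant_id=participant_id,
            item_id=item_id,
            instrument_id=spec.instrument_id,
            dimension=spec.dimension,
            missing_reason=reason,
        )
        for item_id in spec.item_ids()
    ]


def _validate_value(spec: InstrumentSpec, value: Value) -> None:
    if spec.value_type == "boolean":
        if not isinstance(value, bool):
            raise MeasurementError(
                f"{spec.instrument_id}: expected a boolean flag, got {value!r}"
            )
        return
    if spec.value_type == "sites":
        if (
            not isinstance(value, (tuple, list))
            or len(value) != spec.n_sites
            or not all(isinstance(v, bool) for v in value)
        ):
            raise MeasurementError(
                f"{spec.instrument_id}: expected {spec.n_sites} felt/not-felt "
                f"site booleans, got {value!r}"
            )
        return
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise MeasurementError(
            f"{spec.instrument_id}: expected a numeric value, got {value!r}"
        )
    if math.isnan(value) or not spec.scale_min <= value <= spec.scale_max:
        raise MeasurementError(
            f"{spec.instrument_id}: value {value} outside native scale "
            f"[{spec.scale_min}, {spec.scale_max}]"
        )


def dichotomize(
    measurements: Union[RawMeasurement, Sequence[RawMeasurement]],
    spec: InstrumentSpec,
    norms: Optional[Mapping[str, NormTable]] = None,
    participant_attrs: Optional[ParticipantAttrs] = None,
) -> list[BinaryOutcome]:
    """Dichotomize an instrument's raw measurement(s) for one participant.

    Returns one :class:`BinaryOutcome` per composite sub-item (1 for most
    instruments, 3 for WCQ, 2 for BPI, 2 for LIFE-H).  A coded-missing
    measurement propagates its reason; an instrument inapplicable to the
    participant's archetype yields missing(not_applicable); a sub-item with
    no measurement at all yields missing(not_collected).  Deterministic and
    side-effect free.
    """
    if isinstance(measurements, RawMeasurement):
        measurements = [measurements]
    if not measurements:
        raise MeasurementError("dichotomize called with no measurements")
    pid = measurements[0].participant_id
    for m in measurements:
        if m.instrument_id != spec.instrument_id:
            raise MeasurementError(
                f"measurement for {m.instrument_id} passed with spec "
                f"{spec.instrument_id}"
            )
        if m.participant_id != pid:
            raise MeasurementError("measurements span multiple participants")

    if spec.applicability is not None:
        if participant_attrs is None:
            raise MeasurementError(
                f"{spec.instrument_id}: applicability-gated instrument needs "
                "participant attributes"
            )
        if not spec.applies_to(participant_attrs.archetype):
            return _missing_outcomes(spec, pid, MissingCode.NOT_APPLICABLE)

    norm_cut: Optional[float] = None
    if spec.uses_norms:
        if norms is None:
            raise NormLookupError(f"{spec.instrument_id}: norm table required")
        if participant_attrs is None:
            raise NormLookupError(
                f"{spec.instrument_id}: norm lookup needs participant attributes"
            )
        norm_cut = lookup_norm(
            norms, spec.instrument_id, participant_attrs.age, participant_attrs.sex
        )

    by_sub: dict[Optional[str], RawMeasurement] = {}
    for m in measurements:
        if m.subitem_id in by_sub:
            raise MeasurementError(
                f"{spec.instrument_id}: duplicate measurement for sub-item "
                f"{m.subitem_id!r}"
            )
        by_sub[m.subitem_id] = m

    outcomes: list[BinaryOutcome] = []
    single = len(spec.items) == 1
    instrument_level = by_sub.get(None)
    if instrument_level is not None and not single:
        # a bare instrument row on a multi-item instrument may only carry a
        # missing code (the whole instrument was skipped), never a value
        if instrument_level.missing_code is MissingCode.NONE:
            raise MeasurementError(
                f"{spec.instrument_id}: value without a sub-item id on a "
                "multi-item instrument"
            )
    for sub, item_id in zip(spec.items, spec.item_ids()):
        m = by_sub.get(sub.item_id)
        if m is None:
            m = instrument_level
        if m is None:
            outcomes.append(
                BinaryOutcome(
                    participant_id=pid,
                    item_id=item_id,
                    instrument_id=spec.instrument_id,
                    dimension=spec.dimension,
                    missing_reason=MissingCode.NOT_COLLECTED,
                )
            )
            continue
        if m.missing_code is not MissingCode.NONE:
            outcomes.append(
                BinaryOutcome(
                    participant_id=pid,
                    item_id=item_id,
                    instrument_id=spec.instrument_id,
                    dimension=spec.dimension,
                    missing_reason=m.missing_code,
                )
            )
            continue
        _validate_value(spec, m.value)
        if sub.rule.kind is RuleKind.BOOLEAN_FLAG:
            failed = bool(m.value)
        elif sub.rule.kind is RuleKind.ANY_SITE_MISSED:
            failed = not all(m.value)
        else:
            failed = sub.rule.fails(float(m.value), norm_cut)
        outcomes.append(
            BinaryOutcome(
                participant_id=pid,
                item_id=item_id,
                instrument_id=spec.instrument_id,
                dimension=spec.dimension,
                value=0 if failed else 1,
            )
        )
    return outcomes


def resolve_alternates(
    outcomes: Sequence[BinaryOutcome], registry: InstrumentRegistry
) -> list[BinaryOutcome]:
    """Collapse each alternates group to one contribution per participant.

    When both members of a group (ISEL/MOS, BBT/AMP) carry a non-missing
    outcome — which never happens in a well-formed battery — the replacement
    instrument (higher priority) wins and the superseded outcome is dropped.
    When only one is non-missing, the missing sibling is dropped so the
    group occupies exactly one composite slot.
    """
    group_of = {
        s.instrument_id: s.alternates_group
        for s in registry
        if s.alternates_group is not None
    }
    priority = {s.instrument_id: s.alternates_priority for s in registry}

    kept: list[BinaryOutcome] = []
    grouped: dict[tuple[str, str], list[BinaryOutcome]] = {}
    for o in outcomes:
        grp = group_of.get(o.instrument_id)
        if grp is None:
            kept.append(o)
        else:
            grouped.setdefault((o.participant_id, grp), []).append(o)

    for (_, _grp), members in grouped.items():
        assessed = [o for o in members if not o.is_missing]
        if assessed:
            kept.append(max(assessed, key=lambda o: priority[o.instrument_id]))
        else:
            # keep one missing placeholder (the highest-priority member)
            kept.append(max(members, key=lambda o: priority[o.instrument_id]))
    return kept


# ---------------------------------------------------------------------------
# Session fatigue check
# ---------------------------------------------------------------------------

#: Fatigue VAS is a 5-inch line: 0 = no fatigue, 5 = lots of fatigue.
FATIGUE_VAS_MAX = 5.0
FATIGUE_PAUSE_THRESHOLD = 2.5


def fatigue_check(vas_inches: float) -> str:
    """Decide whether testing may continue after a fatigue VAS reading.

    A longer pause is required only when the mark *exceeds* 2.5 inches;
    2.5 itself allows the session to continue.
    """
    if not 0 <= vas_inches <= FATIGUE_VAS_MAX:
        raise MeasurementError(
            f"fatigue VAS {vas_inches} outside [0, {FATIGUE_VAS_MAX}]"
        )
    return "longer_pause" if vas_inches > FATIGUE_PAUSE_THRESHOLD else "continue"
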