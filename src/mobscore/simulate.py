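"""Synthetic amputee-cohort generator.

Emulates the heterogeneous cohort the scoring pipeline expects — prosthesis
walkers, walking-aid users and wheelchair users — with raw instrument
scores on their native scales, configurable prevalence of each negative
modulator, structural missingness (inapplicable instruments, mid-study
instrument replacement) and random missingness (not evaluated / not
collected).

Each threshold instrument is sampled by first drawing fail/success with the
configured probability and then drawing the raw value from a truncated
normal restricted to the corresponding side of the cut, so configured
prevalences are recovered exactly in expectation.  Distribution families
default to truncated normals centred mid-scale (simple, bounded support);
means/SDs are overridable per instrument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import ndtr, ndtri

from .errors import ConfigurationError
from .registry import (
    Archetype,
    InstrumentRegistry,
    InstrumentSpec,
    MissingCode,
    ParticipantAttrs,
    RawMeasurement,
    RuleKind,
    default_registry,
    lookup_norm,
)

__all__ = ["CohortConfig", "ParticipantRecord", "generate_cohort", "sample_participant"]


#: Instruments scored as whole numbers on their native scale.
_INTEGER_SCALED = {"lci", "bbt", "amp", "charlson", "gds", "lsa", "hap", "mos", "bpi"}

#: Default probability that a given modulator item is negative (fails).
#: Chosen once at magnitudes plausible for an elderly vascular-amputee
#: cohort (high comorbidity, ~30% obesity, frequent neuropathy, most aged
#: over 60, most not referred to rehabilitation).
DEFAULT_MODULATOR_PREVALENCE: dict[str, float] = {
    "sdq:age_over_60": 0.8,
    "sdq:below_knee_amputation": 0.6,
    "sdq:adl_fatigue": 0.4,
    "sdq:daily_cigarettes": 0.3,
    "sdq:daily_alcohol": 0.2,
    "sdq:lives_alone_or_care_centre": 0.4,
    "sdq:inaccessible_environment": 0.3,
    "sdq:device_dissatisfaction": 0.2,
    "sdq:other_physical_problem": 0.5,
    "sdq:lack_of_services": 0.6,
    "charlson": 0.6,
    "isel": 0.2,
    "mos": 0.2,
    "wcq:distancing_avoidance": 0.3,
    "wcq:seeking_social_support": 0.3,
    "wcq:positive_reappraisal": 0.3,
    "bpi:q5": 0.3,
    "bpi:q9a": 0.15,
    "bmi": 0.3,
    "gds": 0.25,
    "grip": 0.4,
    "monofilament": 0.4,
}

#: Default fail probabilities for the potential/effective instruments.
DEFAULT_MOBILITY_FAIL_PROB: dict[str, float] = {
    "lci": 0.6,
    "tug_ab": 0.5,
    "tug_c": 0.5,
    "bbt": 0.5,
    "amp": 0.5,
    "lifeh:daily_activities": 0.4,
    "lifeh:social_roles": 0.5,
    "lsa": 0.5,
    "hap": 0.6,
}


class CohortConfig(BaseModel):
    """Stated world of the generator.

    Defaults mirror the pilot demography (ages 51-83 with mean ~71, 80%
    male, mixed mobility modes, half the cohort assessed with the original
    ISEL/BBT battery and half with the replacement MOS/AMP battery)
    without claiming representativeness.
    """

    model_config = ConfigDict(extra="forbid")

    n_participants: int = Field(gt=0)
    seed: int = Field(default=0, ge=0)
    archetype_weights: dict[Archetype, float] = {
        Archetype.PROSTHESIS_WALKER: 0.4,
        Archetype.AID_WALKER: 0.3,
        Archetype.WHEELCHAIR_USER: 0.3,
    }
    age_mean: float = 71.0
    age_sd: float = 9.0
    age_min: float = 51.0
    age_max: float = 83.0
    prop_male: float = Field(default=0.8, ge=0, le=1)
    modulator_prevalence: dict[str, float] = dict(DEFAULT_MODULATOR_PREVALENCE)
    mobility_fail_prob: dict[str, float] = dict(DEFAULT_MOBILITY_FAIL_PROB)
    #: optional per-instrument (mean, sd) overrides on the native scale
    score_distributions: dict[str, tuple[float, float]] = {}
    not_evaluated_rate: float = Field(default=0.02, ge=0, le=1)
    not_collected_rate: float = Field(default=0.01, ge=0, le=1)
    #: fraction assessed with the original ISEL + BBT battery
    legacy_battery_fraction: float = Field(default=0.5, ge=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        total = sum(self.archetype_weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"archetype weights sum to {total}, expected 1")
        for name, probs in (
            ("modulator_prevalence", self.modulator_prevalence),
            ("mobility_fail_prob", self.mobility_fail_prob),
        ):
            for key, p in probs.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"{name}[{key}] = {p} outside [0, 1]")
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be < age_max")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")
        return self


@dataclass(frozen=True)
class ParticipantRecord:
    """A synthetic participant: demographics plus raw measurements."""

    participant_id: str
    age: float
    sex: str
    archetype: Archetype
    measurements: tuple[RawMeasurement, ...]

    @property
    def attrs(self) -> ParticipantAttrs:
        return ParticipantAttrs(
            participant_id=self.participant_id,
            age=self.age,
            sex=self.sex,
            archetype=self.archetype,
        )


def _truncnorm(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    """One draw from N(mean, sd) truncated to [lo, hi] via inverse CDF."""
    if not lo < hi:
        return lo
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    if b - a < 1e-12:  # cut far in a tail: fall back to uniform on the side
        return float(rng.uniform(lo, hi))
    u = rng.uniform(a, b)
    return float(mean + sd * ndtri(u))


def _side_bounds(
    kind: RuleKind, cut: float, lo: float, hi: float, integer: bool, fail: bool
) -> tuple[float, float]:
    """Value interval for the fail (or success) side of a threshold rule."""
    eps = 1e-9 * max(1.0, abs(cut))
    if kind in (RuleKind.LESS_THAN, RuleKind.NORM_BELOW):
        fail_lo, fail_hi = (lo, math.ceil(cut) - 1) if integer else (lo, cut - eps)
        succ_lo, succ_hi = (math.ceil(cut), hi) if integer else (cut, hi)
    elif kind in (RuleKind.LESS_EQUAL, RuleKind.NORM_PERCENTILE_LE):
        fail_lo, fail_hi = (lo, math.floor(cut)) if integer else (lo, cut)
        succ_lo, succ_hi = (math.floor(cut) + 1, hi) if integer else (cut + eps, hi)
    elif kind is RuleKind.GREATER_THAN:
        fail_lo, fail_hi = (math.floor(cut) + 1, hi) if integer else (cut + eps, hi)
        succ_lo, succ_hi = (lo, math.floor(cut)) if integer else (lo, cut)
    elif kind is RuleKind.GREATER_EQUAL:
        fail_lo, fail_hi = (math.ceil(cut), hi) if integer else (cut, hi)
        succ_lo, succ_hi = (lo, math.ceil(cut) - 1) if integer else (lo, cut - eps)
    else:
        raise ConfigurationError(f"cannot sample a value for rule kind {kind}")
    return (fail_lo, fail_hi) if fail else (succ_lo, succ_hi)


def _sample_value(
    rng: np.random.Generator,
    spec: InstrumentSpec,
    kind: RuleKind,
    cut: float,
    fail: bool,
    config: CohortConfig,
) -> float:
    lo, hi = spec.scale_min, spec.scale_max
    integer = spec.instrument_id in _INTEGER_SCALED
    mean, sd = config.score_distributions.get(
        spec.instrument_id, ((lo + hi) / 2, (hi - lo) / 4)
    )
    a, b = _side_bounds(kind, cut, lo, hi, integer, fail)
    if a > b:  # side empty (cut at a scale edge): collapse onto the cut
        a = b = max(lo, min(hi, cut))
    x = _truncnorm(rng, mean, sd, a, b)
    if integer:
        x = float(int(round(x)))
        x = max(a, min(b, x))
    return x


def _fail_prob(spec: InstrumentSpec, item_id: str, config: CohortConfig) -> float:
    table = (
        config.modulator_prevalence
        if spec.dimension.value == "modulator"
        else config.mobility_fail_prob
    )
    if item_id in table:
        return table[item_id]
    if spec.instrument_id in table:
        return table[spec.instrument_id]
    return 0.5


def _missing_draw(rng: np.random.Generator, config: CohortConfig) -> Optional[MissingCode]:
    u = rng.uniform()
    if u < config.not_evaluated_rate:
        return MissingCode.NOT_EVALUATED
    if u < config.not_evaluated_rate + config.not_collected_rate:
        return MissingCode.NOT_COLLECTED
    return None


def sample_participant(
    archetype: Archetype,
    config: CohortConfig,
    rng: np.random.Generator,
    registry: Optional[InstrumentRegistry] = None,
    participant_id: str = "p001",
) -> ParticipantRecord:
    """Draw one participant of the given archetype.

    The instrument set matches the archetype (a wheelchair user gets the
    wheelchair TUG and a not-applicable ambulatory TUG, and vice versa);
    exactly one member of each alternates pair (ISEL/MOS, BBT/AMP) is
    assessed per participant, the other recorded as not collected.
    """
    if registry is None:
        registry = default_registry()
    age = float(
        round(_truncnorm(rng, config.age_mean, config.age_sd, config.age_min, config.age_max))
    )
    sex = "M" if rng.uniform() < config.prop_male else "F"
    legacy = rng.uniform() < config.legacy_battery_fraction
    skipped_alternates = {"mos", "amp"} if legacy else {"isel", "bbt"}

    measurements: list[RawMeasurement] = []
    for spec in registry:
        if not spec.applies_to(archetype):
            measurements.append(
                RawMeasurement(
                    participant_id=participant_id,
                    instrument_id=spec.instrument_id,
                    missing_code=MissingCode.NOT_APPLICABLE,
                )
            )
            continue
        if spec.instrument_id in skipped_alternates:
            measurements.append(
                RawMeasurement(
                    participant_id=participant_id,
                    instrument_id=spec.instrument_id,
                    missing_code=MissingCode.NOT_COLLECTED,
                )
            )
            continue

        norm_cut: Optional[float] = None
        if spec.uses_norms:
            norm_cut = lookup_norm(registry.norms, spec.instrument_id, age, sex)

        single = len(spec.items) == 1
        for sub, item_id in zip(spec.items, spec.item_ids()):
            missing = _missing_draw(rng, config)
            subitem_id = None if single else sub.item_id
            if missing is not None:
                measurements.append(
                    RawMeasurement(
                        participant_id=participant_id,
                        instrument_id=spec.instrument_id,
                        subitem_id=subitem_id,
                        missing_code=missing,
                    )
                )
                continue
            fail = rng.uniform() < _fail_prob(spec, item_id, config)
            value: object
            if sub.rule.kind is RuleKind.BOOLEAN_FLAG:
                value = bool(fail)
            elif sub.rule.kind is RuleKind.ANY_SITE_MISSED:
                if fail:
                    sites = [True] * spec.n_sites
                    sites[int(rng.integers(spec.n_sites))] = False
                    value = tuple(sites)
                else:
                    value = (True,) * spec.n_sites
            else:
                cut = norm_cut if norm_cut is not None else sub.rule.threshold
                value = _sample_value(rng, spec, sub.rule.kind, cut, fail, config)
            measurements.append(
                RawMeasurement(
                    participant_id=participant_id,
                    instrument_id=spec.instrument_id,
                    subitem_id=subitem_id,
                    value=value,
                )
            )
    return ParticipantRecord(
        participant_id=participant_id,
        age=age,
        sex=sex,
        archetype=archetype,
        measurements=tuple(measurements),
    )


def generate_cohort(
    config: CohortConfig, registry: Optional[InstrumentRegistry] = None
) -> list[ParticipantRecord]:
    """Generate a reproducible synthetic cohort.

    Identical config (including seed) yields an identical cohort.  Raw
    scores respect their native scale bounds; archetype gating is enforced;
    each modulator's marginal fail rate converges to its configured
    prevalence as n grows.
    """
    if registry is None:
        registry = default_registry()
    rng = np.random.default_rng(config.seed)
    archetypes = list(config.archetype_weights)
    weights = np.array([config.archetype_weights[a] for a in archetypes], dtype=float)
    weights = weights / weights.sum()
    width = max(3, len(str(config.n_participants)))
    records = []
    for i in range(config.n_participants):
        archetype = archetypes[int(rng.choice(len(archetypes), p=weights))]
        records.append(
            sample_participant(
                archetype,
                config,
                rng,
                registry=registry,
                participant_id=f"p{i + 1:0{width}d}",
            )
        )
    return records
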