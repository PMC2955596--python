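"""Instrument registry: thresholds, applicability, norms, missingness."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mobscore import (
    Archetype,
    ConfigurationError,
    Dimension,
    MeasurementError,
    MissingCode,
    NormLookupError,
    NormStratum,
    NormTable,
    ParticipantAttrs,
    RawMeasurement,
    default_registry,
    dichotomize,
    fatigue_check,
    load_registry,
    lookup_norm,
    resolve_alternates,
)

# ---------------------------------------------------------------------------
# The boundary ledger: every threshold rule probed at the cut and just
# either side of it, per the published comparator (strict vs inclusive).
# Expected outcome: 1 = success/positive, 0 = fail/negative.
# ---------------------------------------------------------------------------

BOUNDARY_CASES = [
    # instrument, subitem, value, expected outcome
    ("lci", None, 21, 0),        # fail iff <= 21/42
    ("lci", None, 20.9, 0),
    ("lci", None, 21.1, 1),
    ("lci", None, 42, 1),
    ("tug_ab", None, 14, 1),     # fail iff > 14 s (strict)
    ("tug_ab", None, 14.1, 0),
    ("tug_ab", None, 13.9, 1),
    ("tug_ab", None, 15, 0),
    ("tug_c", None, 34, 1),      # wheelchair variant: fail iff > 34 s
    ("tug_c", None, 34.1, 0),
    ("tug_c", None, 33.9, 1),
    ("amp", None, 25, 1),        # fail iff under 25/47, so 25 itself passes
    ("amp", None, 24.9, 0),
    ("amp", None, 25.1, 1),
    ("bbt", None, 45, 1),        # fail iff < 45
    ("bbt", None, 44.9, 0),
    ("lifeh", "daily_activities", 7, 1),   # fail iff mean < 7/9
    ("lifeh", "daily_activities", 6.9, 0),
    ("lifeh", "social_roles", 7, 1),
    ("lifeh", "social_roles", 6.9, 0),
    ("isel", None, 1, 1),        # fail iff < 1
    ("isel", None, 0.9, 0),
    ("mos", None, 75, 1),        # fail iff < 75/95
    ("mos", None, 74.9, 0),
    ("wcq", "distancing_avoidance", 1.5, 1),   # fail iff mean > 1.5
    ("wcq", "distancing_avoidance", 1.6, 0),
    ("wcq", "seeking_social_support", 1.5, 1),  # fail iff mean < 1.5
    ("wcq", "seeking_social_support", 1.4, 0),
    ("wcq", "positive_reappraisal", 1.5, 1),
    ("wcq", "positive_reappraisal", 1.4, 0),
    ("bpi", "q5", 5, 1),         # fail iff > 5/10
    ("bpi", "q5", 5.1, 0),
    ("bpi", "q5", 6, 0),
    ("bpi", "q9a", 7, 1),        # fail iff > 7/10
    ("bpi", "q9a", 7.1, 0),
    ("bpi", "q9a", 3, 1),
    ("bmi", None, 30, 1),        # fail iff > 30
    ("bmi", None, 30.1, 0),
    ("gds", None, 11, 0),        # fail iff >= 11/30
    ("gds", None, 10.9, 1),
    ("gds", None, 12, 0),
    ("charlson", None, 2, 0),    # fail iff >= 2
    ("charlson", None, 1.9, 1),
    ("charlson", None, 1, 1),
    # norm-referenced rules at the age-70 male defaults:
    # grip 30th-percentile cut 32 kg (fail iff <= cut)
    ("grip", None, 32, 0),
    ("grip", None, 32.1, 1),
    ("grip", None, 31.9, 0),
    # LSA age-65+ cut 56 (fail iff strictly below the standard value)
    ("lsa", None, 56, 1),
    ("lsa", None, 55.9, 0),
    # HAP MAS age 65-74 cut 60
    ("hap", None, 60, 1),
    ("hap", None, 59.9, 0),
]


@pytest.mark.parametrize("instrument,subitem,value,expected", BOUNDARY_CASES)
def test_boundary_ledger(registry, walker_attrs, wheelchair_attrs,
                         instrument, subitem, value, expected):
    """Each fail rule classifies the cut value itself per its printed
    comparator, and flips just either side of it."""
    attrs = wheelchair_attrs if instrument == "tug_c" else walker_attrs
    m = RawMeasurement(
        participant_id="p1", instrument_id=instrument, value=float(value),
        subitem_id=subitem,
    )
    outcomes = dichotomize(m, registry[instrument], registry.norms, attrs)
    target = instrument if subitem is None else f"{instrument}:{subitem}"
    got = {o.item_id: o for o in outcomes}[target]
    assert got.value == expected
    assert got.dimension == registry[instrument].dimension


@pytest.mark.parametrize(
    "sites,expected",
    [
        ((True, True, True, True), 1),
        ((True, True, False, True), 0),   # any unfelt site -> negative
        ((False, False, False, False), 0),
        ((True, True, True, False), 0),
    ],
)
def test_monofilament_any_site_missed(registry, walker_attrs, sites, expected):
    m = RawMeasurement(participant_id="p1", instrument_id="monofilament", value=sites)
    (o,) = dichotomize(m, registry["monofilament"], participant_attrs=walker_attrs)
    assert o.value == expected


@pytest.mark.parametrize("flag,expected", [(True, 0), (False, 1)])
def test_questionnaire_flags(registry, walker_attrs, flag, expected):
    """Each questionnaire risk factor is negative exactly when flagged."""
    m = RawMeasurement(
        participant_id="p1", instrument_id="sdq", value=flag,
        subitem_id="lives_alone_or_care_centre",
    )
    outcomes = dichotomize(m, registry["sdq"], participant_attrs=walker_attrs)
    assert len(outcomes) == 10  # all ten flags, unmeasured ones missing
    by_id = {o.item_id: o for o in outcomes}
    assert by_id["sdq:lives_alone_or_care_centre"].value == expected
    assert by_id["sdq:daily_alcohol"].missing_reason is MissingCode.NOT_COLLECTED


def test_bpi_contributes_two_items(registry, walker_attrs):
    """BPI Q5=6 (pain intensity above 5) fails while Q9a=3 passes."""
    ms = [
        RawMeasurement("p1", "bpi", 6.0, subitem_id="q5"),
        RawMeasurement("p1", "bpi", 3.0, subitem_id="q9a"),
    ]
    outcomes = dichotomize(ms, registry["bpi"], participant_attrs=walker_attrs)
    assert [(o.item_id, o.value) for o in outcomes] == [("bpi:q5", 0), ("bpi:q9a", 1)]


def test_wcq_contributes_three_items(registry, walker_attrs):
    ms = [
        RawMeasurement("p1", "wcq", 2.0, subitem_id="distancing_avoidance"),
        RawMeasurement("p1", "wcq", 2.0, subitem_id="seeking_social_support"),
        RawMeasurement("p1", "wcq", 1.0, subitem_id="positive_reappraisal"),
    ]
    outcomes = dichotomize(ms, registry["wcq"], participant_attrs=walker_attrs)
    assert [o.value for o in outcomes] == [0, 1, 0]


# ---------------------------------------------------------------------------
# Missing propagation & applicability gating
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "code", [MissingCode.NOT_EVALUATED, MissingCode.NOT_APPLICABLE,
             MissingCode.NOT_COLLECTED]
)
@pytest.mark.parametrize("instrument", ["lci", "bpi", "monofilament", "sdq"])
def test_missing_propagates_reason(registry, walker_attrs, code, instrument):
    m = RawMeasurement(participant_id="p1", instrument_id=instrument,
                       missing_code=code)
    outcomes = dichotomize(m, registry[instrument], registry.norms, walker_attrs)
    assert len(outcomes) == registry[instrument].item_count_in_composite
    assert all(o.is_missing and o.missing_reason is code for o in outcomes)


def test_archetype_gating(registry, walker_attrs, wheelchair_attrs):
    """The ambulatory TUG is not applicable to wheelchair users and vice
    versa, regardless of any recorded value."""
    m = RawMeasurement(participant_id="p1", instrument_id="tug_ab", value=12.0)
    (o,) = dichotomize(m, registry["tug_ab"], participant_attrs=wheelchair_attrs)
    assert o.missing_reason is MissingCode.NOT_APPLICABLE
    mc = RawMeasurement(participant_id="p1", instrument_id="tug_c", value=30.0)
    (o2,) = dichotomize(mc, registry["tug_c"], participant_attrs=walker_attrs)
    assert o2.missing_reason is MissingCode.NOT_APPLICABLE


def test_out_of_range_value_rejected(registry, walker_attrs):
    m = RawMeasurement(participant_id="p1", instrument_id="lci", value=43.0)
    with pytest.raises(MeasurementError, match="native scale"):
        dichotomize(m, registry["lci"], participant_attrs=walker_attrs)


@settings(max_examples=50, deadline=None)
@given(value=st.floats(min_value=0, max_value=300))
def test_dichotomize_deterministic(value):
    """Identical inputs always yield identical outcomes (ambulatory TUG)."""
    registry = default_registry()
    attrs = ParticipantAttrs("p1", 70, "M", Archetype.PROSTHESIS_WALKER)
    m = RawMeasurement(participant_id="p1", instrument_id="tug_ab", value=value)
    first = dichotomize(m, registry["tug_ab"], participant_attrs=attrs)
    second = dichotomize(m, registry["tug_ab"], participant_attrs=attrs)
    assert first == second
    assert first[0].value == (1 if value <= 14 else 0)


# ---------------------------------------------------------------------------
# Norm tables
# ---------------------------------------------------------------------------

def test_lookup_norm_direct_and_band():
    table = NormTable(
        instrument_id="lsa",
        strata=(NormStratum(age_min=65, age_max=120, cut=56.0),),
    )
    assert lookup_norm(table, "lsa", 70) == 56.0
    two_band = NormTable(
        instrument_id="hap",
        strata=(
            NormStratum(age_min=55, age_max=65, cut=70.0),
            NormStratum(age_min=65, age_max=120, cut=60.0),
        ),
    )
    assert lookup_norm(two_band, "hap", 70) == 60.0
    assert lookup_norm(two_band, "hap", 64.9) == 70.0


def test_lookup_norm_out_of_range():
    table = NormTable(
        instrument_id="lsa",
        strata=(NormStratum(age_min=65, age_max=120, cut=56.0),),
    )
    with pytest.raises(NormLookupError, match="age=40"):
        lookup_norm(table, "lsa", 40)


def test_norm_strata_must_not_overlap():
    with pytest.raises(Exception, match="overlap"):
        NormTable(
            instrument_id="lsa",
            strata=(
                NormStratum(age_min=50, age_max=70, cut=60.0),
                NormStratum(age_min=65, age_max=120, cut=56.0),
            ),
        )


def test_grip_norm_uses_sex_strata(registry):
    """The same grip value can fail for a man and pass for a woman."""
    value = 25.0
    for sex, expected in [("M", 0), ("F", 1)]:
        attrs = ParticipantAttrs("p1", 70, sex, Archetype.AID_WALKER)
        m = RawMeasurement(participant_id="p1", instrument_id="grip", value=value)
        (o,) = dichotomize(m, registry["grip"], registry.norms, attrs)
        assert o.value == expected


# ---------------------------------------------------------------------------
# Fatigue VAS
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "vas,decision",
    [(0, "continue"), (2.5, "continue"), (2.6, "longer_pause"), (5, "longer_pause")],
)
def test_fatigue_check(vas, decision):
    """A longer pause only when the mark exceeds 2.5 of the 5-inch line."""
    assert fatigue_check(vas) == decision


@pytest.mark.parametrize("vas", [-0.1, 5.1])
def test_fatigue_check_out_of_range(vas):
    with pytest.raises(MeasurementError):
        fatigue_check(vas)


# ---------------------------------------------------------------------------
# Registry loading and completeness
# ---------------------------------------------------------------------------

EXPECTED_IDS = {
    "sdq", "charlson", "isel", "mos", "wcq", "bpi", "bmi", "gds", "grip",
    "monofilament", "lci", "tug_ab", "tug_c", "bbt", "amp", "lifeh", "lsa",
    "hap",
}


def test_default_registry_complete(registry):
    """The default battery covers every published instrument."""
    assert set(registry.instrument_ids()) == EXPECTED_IDS
    assert registry.composite_slots(Dimension.POTENTIAL) == [
        "lci", "tug_ab", "tug_c", "balance",
    ]
    assert registry.composite_slots(Dimension.EFFECTIVE) == [
        "lifeh:daily_activities", "lifeh:social_roles", "lsa", "hap",
    ]
    assert len(registry.composite_slots(Dimension.MODULATOR)) == 21


def test_load_registry_empty_config_errors():
    with pytest.raises(ConfigurationError, match="empty"):
        load_registry({})


def test_load_registry_unknown_instrument_errors():
    with pytest.raises(ConfigurationError, match="unknown instrument"):
        load_registry({"instruments": [{"instrument_id": "xyz", "threshold": 1}]})


def test_load_registry_duplicate_errors():
    with pytest.raises(ConfigurationError, match="duplicate"):
        load_registry(
            {"instruments": [
                {"instrument_id": "bmi", "threshold": 28},
                {"instrument_id": "bmi", "threshold": 32},
            ]}
        )


def test_load_registry_threshold_override(walker_attrs):
    """Overriding a cut (BMI > 28) changes classification accordingly."""
    reg = load_registry({"instruments": [{"instrument_id": "bmi", "threshold": 28}]})
    m = RawMeasurement(participant_id="p1", instrument_id="bmi", value=29.0)
    (o,) = dichotomize(m, reg["bmi"], participant_attrs=walker_attrs)
    assert o.value == 0
    (o_default,) = dichotomize(
        m, default_registry()["bmi"], participant_attrs=walker_attrs
    )
    assert o_default.value == 1


def test_load_registry_norm_override(walker_attrs):
    reg = load_registry(
        {"norms": {"lsa": [{"age_min": 50, "age_max": 120, "cut": 40.0}]}}
    )
    m = RawMeasurement(participant_id="p1", instrument_id="lsa", value=45.0)
    (o,) = dichotomize(m, reg["lsa"], reg.norms, walker_attrs)
    assert o.value == 1  # above the lowered cut


# ---------------------------------------------------------------------------
# Alternates groups
# ---------------------------------------------------------------------------

def test_alternates_one_contribution(registry, walker_attrs):
    """ISEL and MOS occupy one social-support slot; the assessed member
    contributes and the missing sibling is dropped."""
    isel = dichotomize(
        RawMeasurement("p1", "isel", missing_code=MissingCode.NOT_COLLECTED),
        registry["isel"], participant_attrs=walker_attrs,
    )
    mos = dichotomize(
        RawMeasurement("p1", "mos", 80.0), registry["mos"],
        participant_attrs=walker_attrs,
    )
    resolved = resolve_alternates(isel + mos, registry)
    assert len(resolved) == 1
    assert resolved[0].instrument_id == "mos" and resolved[0].value == 1


def test_alternates_replacement_wins_when_both_assessed(registry, walker_attrs):
    """If both members were somehow assessed, the replacement instrument
    (AMP over BBT) wins deterministically."""
    bbt = dichotomize(RawMeasurement("p1", "bbt", 50.0), registry["bbt"],
                      participant_attrs=walker_attrs)
    amp = dichotomize(RawMeasurement("p1", "amp", 20.0), registry["amp"],
                      participant_attrs=walker_attrs)
    resolved = resolve_alternates(bbt + amp, registry)
    assert len(resolved) == 1
    assert resolved[0].instrument_id == "amp" and resolved[0].value == 0
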