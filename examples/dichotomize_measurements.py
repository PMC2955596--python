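"""Dichotomize raw instrument measurements for one participant.

Builds a handful of raw scores on their native scales — a Timed Up and Go
time, a pain inventory pair, a monofilament site vector, a norm-referenced
grip strength — and shows how each becomes a success (1) / fail (0) /
missing outcome against its published threshold.
"""

from mobscore import (
    Archetype,
    ParticipantAttrs,
    RawMeasurement,
    default_registry,
    dichotomize,
    fatigue_check,
)

registry = default_registry()
attrs = ParticipantAttrs(
    participant_id="demo", age=72, sex="M", archetype=Archetype.PROSTHESIS_WALKER
)

measurements = {
    "tug_ab": [RawMeasurement("demo", "tug_ab", 15.2)],          # > 14 s -> fail
    "bpi": [
        RawMeasurement("demo", "bpi", 6.0, subitem_id="q5"),     # > 5 -> fail
        RawMeasurement("demo", "bpi", 3.0, subitem_id="q9a"),    # <= 7 -> success
    ],
    "monofilament": [RawMeasurement("demo", "monofilament",
                                    (True, True, False, True))],  # any unfelt -> fail
    "grip": [RawMeasurement("demo", "grip", 33.5)],  # vs 30th-percentile age/sex cut
    "lci": [RawMeasurement("demo", "lci", 21.0)],    # <= 21/42 -> fail
}

for instrument_id, ms in measurements.items():
    outcomes = dichotomize(ms, registry[instrument_id], registry.norms, attrs)
    for o in outcomes:
        state = {1: "success", 0: "fail"}.get(o.value, f"missing({o.missing_reason})")
        print(f"{o.item_id:<16} ({o.dimension.value:<9}) -> {state}")

# The session-level fatigue check: testing pauses only when the visual
# analogue mark exceeds 2.5 of the 5-inch line.
print("\nfatigue VAS 1.8 ->", fatigue_check(1.8))
print("fatigue VAS 3.0 ->", fatigue_check(3.0))
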