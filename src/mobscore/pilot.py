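"""Deterministic 10-participant pilot fixture.

The original study's per-participant raw instrument values (its
supplementary table) are not publicly available, so this fixture encodes
the cohort at the *dichotomized-outcome* level: for each participant, the
success/fail/missing vector per dimension, reconstructed so that scoring
it reproduces every published aggregate exactly —

* potential mobility categories: 6 low (0/4), 3 moderate (1.33 or 2.67),
  1 high (4/4);
* effective mobility weighted scores: 4/4 x2, 3/4 x1, 2/4 x3, 1/4 x3,
  0/4 x1 (3 high / 6 moderate / 1 low);
* modulators: 9 moderate (including the extremes 7/16 -> 1.75 and
  17/24 -> 2.83) and 1 high (19/24 -> 3.17);
* profile groups A:1, B:2, C:6, D:1, with the group-A participant jointly
  high on all three dimensions.

Modulator items use generic ids (``mod01``..``mod24``) because the exact
enumeration of the battery's "24 possible items" is not recoverable; the
potential and effective vectors use the registry's real item ids.  The
fixture is seed-free and exact: scoring it is a regression test.
"""

from __future__ import annotations

from dataclasses import dataclass

from .registry import Archetype, BinaryOutcome, Dimension, MissingCode, ParticipantAttrs
from .scoring import ParticipantProfile, build_profile

__all__ = ["PilotParticipant", "generate_fixture_pilot", "pilot_profiles"]

MOD_BATTERY = "modulator_battery"


@dataclass(frozen=True)
class PilotParticipant:
    """One fixture participant: attributes plus dichotomized outcomes."""

    attrs: ParticipantAttrs
    outcomes: tuple[BinaryOutcome, ...]

    @property
    def participant_id(self) -> str:
        return self.attrs.participant_id


def _mod_outcomes(
    pid: str, n_success: int, n_assessed: int, n_missing: int = 0,
    missing_reasons: tuple[MissingCode, ...] = (),
) -> list[BinaryOutcome]:
    out = []
    for i in range(n_assessed):
        out.append(
            BinaryOutcome(
                participant_id=pid,
                item_id=f"mod{i + 1:02d}",
                instrument_id=MOD_BATTERY,
                dimension=Dimension.MODULATOR,
                value=1 if i < n_success else 0,
            )
        )
    for j in range(n_missing):
        reason = (
            missing_reasons[j] if j < len(missing_reasons) else MissingCode.NOT_COLLECTED
        )
        out.append(
            BinaryOutcome(
                participant_id=pid,
                item_id=f"mod{n_assessed + j + 1:02d}",
                instrument_id=MOD_BATTERY,
                dimension=Dimension.MODULATOR,
                missing_reason=reason,
            )
        )
    return out


def _potential_outcomes(
    pid: str, archetype: Archetype, lci: int, tug: int, balance: int, balance_id: str
) -> list[BinaryOutcome]:
    P = Dimension.POTENTIAL
    wheel = archetype is Archetype.WHEELCHAIR_USER
    tug_done, tug_na = ("tug_c", "tug_ab") if wheel else ("tug_ab", "tug_c")
    return [
        BinaryOutcome(pid, "lci", "lci", P, value=lci),
        BinaryOutcome(pid, tug_done, tug_done, P, value=tug),
        BinaryOutcome(pid, tug_na, tug_na, P, missing_reason=MissingCode.NOT_APPLICABLE),
        BinaryOutcome(pid, balance_id, balance_id, P, value=balance),
    ]


def _effective_outcomes(
    pid: str, daily: int, social: int, lsa: int, hap: int
) -> list[BinaryOutcome]:
    E = Dimension.EFFECTIVE
    return [
        BinaryOutcome(pid, "lifeh:daily_activities", "lifeh", E, value=daily),
        BinaryOutcome(pid, "lifeh:social_roles", "lifeh", E, value=social),
        BinaryOutcome(pid, "lsa", "lsa", E, value=lsa),
        BinaryOutcome(pid, "hap", "hap", E, value=hap),
    ]


# participant_id: (age, sex, archetype, balance instrument,
#                  potential (lci, tug, balance),
#                  effective (daily, social, lsa, hap),
#                  modulators (n_success, n_assessed, n_missing))
# The balance slot is BBT for the first five participants and AMP for the
# last five, mirroring the mid-study instrument replacement.
_FIXTURE = {
    "s01": (74, "M", Archetype.AID_WALKER, "bbt", (0, 0, 0), (1, 1, 0, 0), (7, 16, 5)),
    "s02": (62, "M", Archetype.PROSTHESIS_WALKER, "bbt", (1, 1, 0), (1, 1, 1, 1), (17, 24, 0)),
    "s03": (83, "M", Archetype.WHEELCHAIR_USER, "bbt", (1, 0, 0), (1, 1, 0, 0), (10, 21, 0)),
    "s04": (68, "F", Archetype.AID_WALKER, "bbt", (0, 1, 0), (1, 1, 0, 0), (9, 21, 0)),
    "s05": (51, "M", Archetype.AID_WALKER, "bbt", (0, 0, 0), (1, 1, 1, 0), (12, 21, 0)),
    "s06": (77, "M", Archetype.WHEELCHAIR_USER, "amp", (0, 0, 0), (1, 0, 0, 0), (8, 21, 0)),
    "s07": (70, "M", Archetype.PROSTHESIS_WALKER, "amp", (0, 0, 0), (1, 0, 0, 0), (11, 21, 0)),
    "s08": (56, "M", Archetype.PROSTHESIS_WALKER, "amp", (1, 1, 1), (1, 1, 1, 1), (19, 24, 0)),
    "s09": (79, "F", Archetype.AID_WALKER, "amp", (0, 0, 0), (1, 0, 0, 0), (6, 21, 0)),
    "s10": (81, "M", Archetype.WHEELCHAIR_USER, "amp", (0, 0, 0), (0, 0, 0, 0), (7, 21, 0)),
}


def generate_fixture_pilot() -> list[PilotParticipant]:
    """Return the 10 fixture participants with their outcome vectors."""
    participants = []
    for pid, (age, sex, arch, bal_id, pot, eff, mod) in _FIXTURE.items():
        attrs = ParticipantAttrs(participant_id=pid, age=age, sex=sex, archetype=arch)
        outcomes = (
            _potential_outcomes(pid, arch, *pot, balance_id=bal_id)
            + _effective_outcomes(pid, *eff)
            + _mod_outcomes(
                pid,
                *mod,
                missing_reasons=(
                    MissingCode.NOT_EVALUATED,
                    MissingCode.NOT_EVALUATED,
                    MissingCode.NOT_EVALUATED,
                    MissingCode.NOT_COLLECTED,
                    MissingCode.NOT_COLLECTED,
                ),
            )
        )
        participants.append(PilotParticipant(attrs=attrs, outcomes=tuple(outcomes)))
    return participants


def pilot_profiles() -> list[ParticipantProfile]:
    """Score the fixture: one profile per participant."""
    return [
        build_profile(p.participant_id, p.outcomes) for p in generate_fixture_pilot()
    ]
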