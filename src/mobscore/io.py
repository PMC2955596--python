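"""File-format surface: cohort CSV dialect, pipeline runners, manifests.

Cohort tables are UTF-8 CSV, one row per participant-instrument(-subitem),
with a "." decimal separator and columns::

    participant_id, age, sex, archetype, instrument_id, subitem_id,
    value, missing_code

``missing_code`` is one of "" (observed), "ne" (not evaluated), "na" (not
applicable) or "nc" (not collected); ``value`` is empty when a missing
code is set.  Boolean items use 1/0; the monofilament's four felt/not-felt
sites are semicolon-joined (e.g. ``1;1;0;1``).

:func:`run_score` and :func:`run_simulate` are the end-to-end entry points
(the package is used from Python; there is no shell command).  Scored
outputs are bit-stable across runs — the manifest carries the only
timestamp.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence, Union

import yaml

from . import __version__
from .errors import CohortFormatError, ConfigurationError
from .registry import (
    Archetype,
    BinaryOutcome,
    InstrumentRegistry,
    MissingCode,
    RawMeasurement,
    dichotomize,
    load_registry,
    resolve_alternates,
)
from .scoring import CohortSummary, ParticipantProfile, build_profile, summarize_cohort
from .simulate import CohortConfig, ParticipantRecord, generate_cohort

__all__ = [
    "COHORT_COLUMNS",
    "RunManifest",
    "read_cohort_table",
    "write_cohort",
    "score_cohort",
    "run_score",
    "run_simulate",
]

logger = logging.getLogger("mobscore")

COHORT_COLUMNS = [
    "participant_id",
    "age",
    "sex",
    "archetype",
    "instrument_id",
    "subitem_id",
    "value",
    "missing_code",
]

SCHEMA_VERSION = 1

_MISSING_BY_CODE = {"": MissingCode.NONE, "ne": MissingCode.NOT_EVALUATED,
                    "na": MissingCode.NOT_APPLICABLE, "nc": MissingCode.NOT_COLLECTED}


@dataclass
class RunManifest:
    """Provenance record emitted once per pipeline run."""

    tool_version: str
    registry_checksum: str
    inputs: dict[str, str]
    seed: Optional[int]
    timestamp: str
    n_read: int = 0
    n_scored: int = 0
    n_excluded: int = 0
    exclusions: list[dict[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": SCHEMA_VERSION,
            "tool_version": self.tool_version,
            "registry_checksum": self.registry_checksum,
            "inputs": self.inputs,
            "seed": self.seed,
            "timestamp": self.timestamp,
            "n_read": self.n_read,
            "n_scored": self.n_scored,
            "n_excluded": self.n_excluded,
            "exclusions": self.exclusions,
        }


def registry_checksum(registry: InstrumentRegistry) -> str:
    blob = json.dumps(registry.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _new_manifest(
    registry: InstrumentRegistry,
    inputs: Mapping[str, str],
    seed: Optional[int] = None,
) -> RunManifest:
    return RunManifest(
        tool_version=__version__,
        registry_checksum=registry_checksum(registry),
        inputs=dict(inputs),
        seed=seed,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )


# ---------------------------------------------------------------------------
# Cohort CSV
# ---------------------------------------------------------------------------

def _format_value(value: Any) -> str:
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, (tuple, list)):
        return ";".join("1" if v else "0" for v in value)
    return repr(float(value))  # shortest exact round-trip form


def _parse_bool(token: str, row: int) -> bool:
    if token in ("1", "true", "True"):
        return True
    if token in ("0", "false", "False"):
        return False
    raise CohortFormatError(f"row {row}: unparseable boolean value {token!r}")


def write_cohort(
    records: Sequence[ParticipantRecord], path: Union[str, Path]
) -> Path:
    """Write participant records in the documented CSV dialect."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(COHORT_COLUMNS)
        for rec in records:
            for m in rec.measurements:
                writer.writerow(
                    [
                        rec.participant_id,
                        repr(float(rec.age)),
                        rec.sex,
                        rec.archetype.value,
                        m.instrument_id,
                        m.subitem_id or "",
                        "" if m.value is None else _format_value(m.value),
                        "" if m.missing_code is MissingCode.NONE else m.missing_code.value,
                    ]
                )
    return path


def read_cohort_table(
    path: Union[str, Path], registry: InstrumentRegistry
) -> list[ParticipantRecord]:
    """Read and validate a cohort CSV against the registry.

    Malformed rows are rejected with row-numbered diagnostics; unknown
    instrument ids and out-of-vocabulary missing codes are errors.
    """
    path = Path(path)
    records: dict[str, dict[str, Any]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != COHORT_COLUMNS:
            raise CohortFormatError(
                f"{path}: header {header!r} does not match expected "
                f"{COHORT_COLUMNS!r}"
            )
        for row_no, row in enumerate(reader, start=2):
            if not row or all(not c for c in row):
                continue
            if len(row) != len(COHORT_COLUMNS):
                raise CohortFormatError(
                    f"row {row_no}: expected {len(COHORT_COLUMNS)} columns, "
                    f"got {len(row)}"
                )
            pid, age_s, sex, arch_s, inst, sub, value_s, code_s = row
            if inst not in registry:
                raise CohortFormatError(
                    f"row {row_no}: unknown instrument_id {inst!r}"
                )
            spec = registry[inst]
            if code_s not in _MISSING_BY_CODE:
                raise CohortFormatError(
                    f"row {row_no}: unknown missing_code {code_s!r}"
                )
            code = _MISSING_BY_CODE[code_s]
            value: Any = None
            if code is MissingCode.NONE:
                if value_s == "":
                    raise CohortFormatError(
                        f"row {row_no}: empty value without a missing_code"
                    )
                try:
                    if spec.value_type == "boolean":
                        value = _parse_bool(value_s, row_no)
                    elif spec.value_type == "sites":
                        value = tuple(
                            _parse_bool(tok, row_no) for tok in value_s.split(";")
                        )
                    else:
                        value = float(value_s)
                except CohortFormatError:
                    raise
                except ValueError:
                    raise CohortFormatError(
                        f"row {row_no}: unparseable value {value_s!r} for "
                        f"instrument {inst!r}"
                    ) from None
            try:
                measurement = RawMeasurement(
                    participant_id=pid,
                    instrument_id=inst,
                    subitem_id=sub or None,
                    value=value,
                    missing_code=code,
                )
                age = float(age_s)
                archetype = Archetype(arch_s)
            except Exception as exc:
                raise CohortFormatError(f"row {row_no}: {exc}") from exc
            rec = records.setdefault(
                pid, {"age": age, "sex": sex, "archetype": archetype, "ms": []}
            )
            rec["ms"].append(measurement)
    return [
        ParticipantRecord(
            participant_id=pid,
            age=rec["age"],
            sex=rec["sex"],
            archetype=rec["archetype"],
            measurements=tuple(rec["ms"]),
        )
        for pid, rec in records.items()
    ]


# ---------------------------------------------------------------------------
# Scoring pipeline
# ---------------------------------------------------------------------------

def dichotomize_record(
    record: ParticipantRecord, registry: InstrumentRegistry
) -> list[BinaryOutcome]:
    """Dichotomize every registry instrument for one participant.

    Instruments with no measurement at all yield missing(not_collected)
    outcomes so every composite slot is represented; alternates groups are
    collapsed to one contribution.
    """
    by_inst: dict[str, list[RawMeasurement]] = {}
    for m in record.measurements:
        by_inst.setdefault(m.instrument_id, []).append(m)
    outcomes: list[BinaryOutcome] = []
    for spec in registry:
        ms = by_inst.get(spec.instrument_id)
        if ms is None:
            ms = [
                RawMeasurement(
                    participant_id=record.participant_id,
                    instrument_id=spec.instrument_id,
                    missing_code=MissingCode.NOT_COLLECTED,
                )
            ]
        outcomes.extend(
            dichotomize(ms, spec, norms=registry.norms, participant_attrs=record.attrs)
        )
    return resolve_alternates(outcomes, registry)


def score_cohort(
    records: Sequence[ParticipantRecord], registry: InstrumentRegistry
) -> tuple[list[ParticipantProfile], CohortSummary]:
    """Dichotomize and profile a cohort; incomplete profiles are logged,
    kept in the returned list, and excluded from the summary."""
    profiles = [
        build_profile(rec.participant_id, dichotomize_record(rec, registry))
        for rec in records
    ]
    for p in profiles:
        if not p.is_complete:
            logger.warning(
                "participant %s excluded from grouping: %s",
                p.participant_id,
                p.incomplete_reason,
            )
    summary = summarize_cohort(profiles)
    return profiles, summary


def run_score(
    cohort_path: Union[str, Path],
    output_dir: Union[str, Path],
    registry: Union[None, str, Path, Mapping[str, Any], InstrumentRegistry] = None,
) -> tuple[list[ParticipantProfile], CohortSummary, RunManifest]:
    """Score a cohort CSV and write profiles, summary, long-format scores
    and a manifest into ``output_dir``.

    Outputs: ``profiles.json`` (per participant: exact fraction, 2-dp
    display, category, group), ``summary.json``, ``scores_long.csv`` (one
    row per participant-dimension, for charting), ``manifest.json``.
    """
    if not isinstance(registry, InstrumentRegistry):
        registry = load_registry(registry)
    cohort_path = Path(cohort_path)
    records = read_cohort_table(cohort_path, registry)
    if not records:
        raise CohortFormatError(f"{cohort_path}: no participant rows")
    profiles, summary = score_cohort(records, registry)

    manifest = _new_manifest(registry, {"cohort": str(cohort_path)})
    manifest.n_read = len(records)
    manifest.n_scored = summary.n_profiled
    incomplete = [p for p in profiles if not p.is_complete]
    manifest.n_excluded = len(incomplete)
    manifest.exclusions = [
        {"participant_id": p.participant_id, "reason": p.incomplete_reason}
        for p in incomplete
    ]
    logger.info(
        "scored %d/%d participants (%d excluded)",
        manifest.n_scored,
        manifest.n_read,
        manifest.n_excluded,
    )

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "profiles.json").write_text(
        json.dumps(
            {"schema_version": SCHEMA_VERSION,
             "profiles": [p.to_dict() for p in profiles]},
            indent=2,
        )
    )
    (out / "summary.json").write_text(
        json.dumps({"schema_version": SCHEMA_VERSION, **summary.to_dict()}, indent=2)
    )
    summary.long_table.to_csv(out / "scores_long.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2))
    return profiles, summary, manifest


def run_simulate(
    config: Union[str, Path, Mapping[str, Any], CohortConfig],
    output_dir: Union[str, Path],
    registry: Optional[InstrumentRegistry] = None,
) -> tuple[Path, RunManifest]:
    """Generate a synthetic cohort and write ``cohort.csv`` plus a manifest
    recording the seed.  Deterministic per (config, seed)."""
    if isinstance(config, (str, Path)):
        raw = yaml.safe_load(Path(config).read_text())
        if not raw:
            raise ConfigurationError(f"empty simulation config: {config}")
        config = raw
    if not isinstance(config, CohortConfig):
        try:
            config = CohortConfig.model_validate(dict(config))
        except Exception as exc:
            raise ConfigurationError(f"invalid simulation config: {exc}") from exc
    if registry is None:
        registry = load_registry()
    records = generate_cohort(config, registry)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_path = write_cohort(records, out / "cohort.csv")
    manifest = _new_manifest(registry, {"cohort": str(cohort_path)}, seed=config.seed)
    manifest.n_read = len(records)
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2))
    logger.info("simulated %d participants (seed=%d)", len(records), config.seed)
    return cohort_path, manifest
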