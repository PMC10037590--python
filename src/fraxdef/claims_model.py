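"""Domain types and delimited-table I/O for patients, claims, and episodes.

The pipeline consumes three administrative claims tables (inpatient,
emergency department, outpatient fee claims) plus a patient/cohort table.
These mirror the structure of the Ontario sources (DAD for hospital
discharges, NACRS for emergency visits, OHIP for physician fee claims)
without reproducing any institution-specific format: each table is a plain
CSV with ISO-8601 dates and packed sub-fields for diagnoses and procedures.

All date windows in the package are inclusive of both endpoints, and all
codes are stored normalized (uppercase, dot-free, no wildcard markers).
"""

from __future__ import annotations

import csv
import datetime as dt
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

__all__ = [
    "PatientRecord",
    "DiagnosisEntry",
    "ProcedureEntry",
    "ClaimRecord",
    "Episode",
    "InvalidCodeError",
    "SchemaError",
    "RowParseError",
    "normalize_code",
    "read_patients",
    "write_patients",
    "read_claims",
    "write_claims",
    "build_episodes",
    "follow_up_end",
]

Setting = Literal["inpatient", "emergency", "outpatient"]
CodeSystem = Literal["ICD10CA", "OHIP_FEE", "CCI"]

PATIENT_COLUMNS = [
    "patient_id",
    "sex",
    "age_at_index",
    "index_date",
    "death_date",
    "study_end_date",
]
CLAIM_COLUMNS = [
    "claim_id",
    "patient_id",
    "setting",
    "service_date",
    "discharge_date",
    "episode_id",
    "diagnoses",
    "procedures",
]

MIN_COHORT_AGE = 66  # drug-coverage design: cohort members are 66+


class InvalidCodeError(ValueError):
    """A raw code normalizes to the empty string."""


class SchemaError(ValueError):
    """A table is missing a required column or violates a structural rule."""


class RowParseError(ValueError):
    """A table row cannot be parsed; carries the 0-based row index."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


def normalize_code(raw: str) -> str:
    """Normalize a diagnosis/procedure/fee code to its canonical form.

    Uppercases, strips whitespace and dots, and removes trailing wildcard
    markers (``x``, ``X``, ``*``) so that ``"S72.0x"`` and ``"S720"`` are the
    same code.  Wildcards belong in code-set patterns, never in claims.
    """
    code = raw.strip().upper().replace(".", "").replace(" ", "")
    code = code.rstrip("X*")
    if not code:
        raise InvalidCodeError(f"code {raw!r} is empty after normalization")
    return code


@dataclass(frozen=True)
class PatientRecord:
    """One cohort member with the censoring inputs for person-time.

    ``index_date`` is cohort entry (the date drug-exposure criteria were
    met); follow-up runs to death or ``study_end_date``, whichever is first.
    """

    patient_id: str
    sex: str
    age_at_index: int
    index_date: dt.date
    death_date: dt.date | None
    study_end_date: dt.date

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        if self.age_at_index < MIN_COHORT_AGE:
            raise ValueError(
                f"age_at_index {self.age_at_index} below cohort minimum {MIN_COHORT_AGE}"
            )
        if self.death_date is not None and self.index_date > self.death_date:
            raise ValueError("index_date after death_date")
        if self.index_date > self.study_end_date:
            raise ValueError("index_date after study_end_date")


def follow_up_end(patient: PatientRecord) -> dt.date:
    """Censoring date: the earlier of death and administrative study end."""
    if patient.death_date is None:
        return patient.study_end_date
    return min(patient.death_date, patient.study_end_date)


@dataclass(frozen=True)
class DiagnosisEntry:
    """One coded diagnosis on a claim; position 1 is primary/most responsible."""

    code: str
    code_system: str
    position: int = 1

    def __post_init__(self) -> None:
        if not self.code or self.code != self.code.upper() or "." in self.code:
            raise ValueError(f"code {self.code!r} is not normalized")
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.code_system == "OHIP_FEE" and self.position != 1:
            raise ValueError("fee claims carry a single service code at position 1")


@dataclass(frozen=True)
class ProcedureEntry:
    code: str
    procedure_date: dt.date

    def __post_init__(self) -> None:
        if not self.code or self.code != self.code.upper() or "." in self.code:
            raise ValueError(f"code {self.code!r} is not normalized")


@dataclass(frozen=True)
class ClaimRecord:
    """One administrative claim in one of the three settings.

    Inpatient claims carry an ``episode_id`` grouping the records of one
    hospitalization, with ``service_date`` the admission date. Outpatient
    fee claims never carry an episode.
    """

    claim_id: str
    patient_id: str
    setting: Setting
    service_date: dt.date
    discharge_date: dt.date | None = None
    episode_id: str | None = None
    diagnoses: tuple[DiagnosisEntry, ...] = ()
    procedures: tuple[ProcedureEntry, ...] = ()

    def __post_init__(self) -> None:
        if self.setting not in ("inpatient", "emergency", "outpatient"):
            raise ValueError(f"unknown setting {self.setting!r}")
        if self.setting == "inpatient":
            if self.episode_id is None:
                raise SchemaError(f"inpatient claim {self.claim_id} lacks episode_id")
            if self.discharge_date is None:
                raise SchemaError(f"inpatient claim {self.claim_id} lacks discharge_date")
            if self.discharge_date < self.service_date:
                raise ValueError("discharge before admission")
        if self.setting == "outpatient" and self.episode_id is not None:
            raise SchemaError(f"outpatient claim {self.claim_id} carries episode_id")
        if not self.diagnoses and not self.procedures:
            raise ValueError(f"claim {self.claim_id} has no diagnoses and no procedures")


@dataclass
class Episode:
    """One hospitalization: the linkage scope for 'same hospitalization' rules.

    An episode is real (anchored on inpatient claims) or a singleton
    pseudo-episode wrapping an emergency visit that was not followed by an
    admission within the linkage window.
    """

    episode_id: str
    patient_id: str
    admit_date: dt.date
    discharge_date: dt.date
    member_claim_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.admit_date > self.discharge_date:
            raise ValueError("admit after discharge")


# ---------------------------------------------------------------------------
# Delimited-table I/O


def _parse_date(text: str, row_index: int, column: str) -> dt.date:
    try:
        return dt.date.fromisoformat(text)
    except ValueError as exc:
        raise RowParseError(row_index, f"bad date {text!r} in {column}") from exc


def _require_columns(header: Sequence[str], required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")


def read_patients(path) -> list[PatientRecord]:
    """Read the patient table (CSV). Dates are ISO-8601; empty death = alive."""
    records: list[PatientRecord] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        _require_columns(reader.fieldnames or [], PATIENT_COLUMNS, str(path))
        for i, row in enumerate(reader):
            death = row["death_date"].strip()
            records.append(
                PatientRecord(
                    patient_id=row["patient_id"],
                    sex=row["sex"],
                    age_at_index=int(row["age_at_index"]),
                    index_date=_parse_date(row["index_date"], i, "index_date"),
                    death_date=_parse_date(death, i, "death_date") if death else None,
                    study_end_date=_parse_date(row["study_end_date"], i, "study_end_date"),
                )
            )
    return records


def write_patients(records: Iterable[PatientRecord], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(PATIENT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.sex,
                    r.age_at_index,
                    r.index_date.isoformat(),
                    r.death_date.isoformat() if r.death_date else "",
                    r.study_end_date.isoformat(),
                ]
            )


def _pack_diagnoses(diagnoses: Sequence[DiagnosisEntry]) -> str:
    return ";".join(f"{d.code}:{d.code_system}:{d.position}" for d in diagnoses)


def _unpack_diagnoses(packed: str, row_index: int) -> tuple[DiagnosisEntry, ...]:
    if not packed.strip():
        return ()
    entries = []
    for part in packed.split(";"):
        fields = part.split(":")
        if len(fields) != 3:
            raise RowParseError(row_index, f"bad diagnosis sub-field {part!r}")
        entries.append(DiagnosisEntry(fields[0], fields[1], int(fields[2])))
    return tuple(entries)


def _pack_procedures(procedures: Sequence[ProcedureEntry]) -> str:
    return ";".join(f"{p.code}:{p.procedure_date.isoformat()}" for p in procedures)


def _unpack_procedures(packed: str, row_index: int) -> tuple[ProcedureEntry, ...]:
    if not packed.strip():
        return ()
    entries = []
    for part in packed.split(";"):
        fields = part.split(":")
        if len(fields) != 2:
            raise RowParseError(row_index, f"bad procedure sub-field {part!r}")
        entries.append(ProcedureEntry(fields[0], _parse_date(fields[1], row_index, "procedures")))
    return tuple(entries)


def read_claims(path, setting: Setting | None = None) -> list[ClaimRecord]:
    """Read a claims table (CSV).

    Diagnoses are packed as ``code:system:position`` separated by ``;``;
    procedures as ``code:date`` pairs.  When ``setting`` is given, every row
    must match it (one file per source).
    """
    claims: list[ClaimRecord] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        _require_columns(reader.fieldnames or [], CLAIM_COLUMNS, str(path))
        for i, row in enumerate(reader):
            row_setting = row["setting"]
            if setting is not None and row_setting != setting:
                raise RowParseError(i, f"expected setting {setting}, got {row_setting}")
            discharge = row["discharge_date"].strip()
            episode = row["episode_id"].strip() or None
            claims.append(
                ClaimRecord(
                    claim_id=row["claim_id"],
                    patient_id=row["patient_id"],
                    setting=row_setting,  # type: ignore[arg-type]
                    service_date=_parse_date(row["service_date"], i, "service_date"),
                    discharge_date=_parse_date(discharge, i, "discharge_date") if discharge else None,
                    episode_id=episode,
                    diagnoses=_unpack_diagnoses(row["diagnoses"], i),
                    procedures=_unpack_procedures(row["procedures"], i),
                )
            )
    return claims


def write_claims(claims: Iterable[ClaimRecord], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(CLAIM_COLUMNS)
        for c in claims:
            writer.writerow(
                [
                    c.claim_id,
                    c.patient_id,
                    c.setting,
                    c.service_date.isoformat(),
                    c.discharge_date.isoformat() if c.discharge_date else "",
                    c.episode_id or "",
                    _pack_diagnoses(c.diagnoses),
                    _pack_procedures(c.procedures),
                ]
            )


# ---------------------------------------------------------------------------
# Episode construction


def build_episodes(
    claims: Sequence[ClaimRecord], ed_linkage_days: int = 1
) -> tuple[list[Episode], dict[str, str]]:
    """Group claims into hospitalization episodes.

    Inpatient claims sharing an ``episode_id`` form one episode spanning
    admission to discharge.  An emergency claim is attached to an episode of
    the same patient when its service date falls in
    ``[admit_date - ed_linkage_days, admit_date]`` (both ends inclusive): an
    ED visit immediately preceding, or on the day of, admission is part of
    the same hospitalization.  Unattached ED claims become singleton
    pseudo-episodes spanning their own service date.  Outpatient claims are
    never episode members.

    Returns the episode list and a claim_id -> episode_id map covering every
    inpatient and emergency claim.
    """
    if ed_linkage_days < 0:
        raise ValueError("ed_linkage_days must be >= 0")

    episodes: dict[str, Episode] = {}
    claim_to_episode: dict[str, str] = {}

    for claim in claims:
        if claim.setting != "inpatient":
            continue
        assert claim.episode_id is not None and claim.discharge_date is not None
        ep = episodes.get(claim.episode_id)
        if ep is None:
            ep = Episode(
                episode_id=claim.episode_id,
                patient_id=claim.patient_id,
                admit_date=claim.service_date,
                discharge_date=claim.discharge_date,
            )
            episodes[claim.episode_id] = ep
        else:
            if ep.patient_id != claim.patient_id:
                raise ValueError(
                    f"episode {claim.episode_id} spans patients {ep.patient_id} and {claim.patient_id}"
                )
            ep.admit_date = min(ep.admit_date, claim.service_date)
            ep.discharge_date = max(ep.discharge_date, claim.discharge_date)
        ep.member_claim_ids.append(claim.claim_id)
        claim_to_episode[claim.claim_id] = claim.episode_id

    # warn on overlapping inpatient episodes for one patient; keep both
    by_patient: dict[str, list[Episode]] = {}
    for ep in episodes.values():
        by_patient.setdefault(ep.patient_id, []).append(ep)
    for patient_eps in by_patient.values():
        patient_eps.sort(key=lambda e: (e.admit_date, e.episode_id))
        for a, b in zip(patient_eps, patient_eps[1:]):
            if b.admit_date <= a.discharge_date:
                warnings.warn(
                    f"overlapping inpatient episodes {a.episode_id}/{b.episode_id} "
                    f"for patient {a.patient_id}",
                    stacklevel=2,
                )

    linkage = dt.timedelta(days=ed_linkage_days)
    ordered_eps = sorted(episodes.values(), key=lambda e: (e.admit_date, e.episode_id))
    for claim in claims:
        if claim.setting != "emergency":
            continue
        attached = None
        for ep in ordered_eps:
            if ep.patient_id != claim.patient_id:
                continue
            if ep.admit_date - linkage <= claim.service_date <= ep.admit_date:
                attached = ep
                break
        if attached is None:
            pseudo = Episode(
                episode_id=f"ed:{claim.claim_id}",
                patient_id=claim.patient_id,
                admit_date=claim.service_date,
                discharge_date=claim.service_date,
                member_claim_ids=[claim.claim_id],
            )
            episodes[pseudo.episode_id] = pseudo
            claim_to_episode[claim.claim_id] = pseudo.episode_id
        else:
            attached.member_claim_ids.append(claim.claim_id)
            claim_to_episode[claim.claim_id] = attached.episode_id

    return list(episodes.values()), claim_to_episode
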