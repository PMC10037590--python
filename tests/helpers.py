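"""Small builders for hand-written patients and claims in tests."""

from __future__ import annotations

import datetime as dt

from fraxdef.claims_model import ClaimRecord, DiagnosisEntry, PatientRecord, ProcedureEntry


def d(iso: str) -> dt.date:
    return dt.date.fromisoformat(iso)


def make_patient(
    pid: str = "P1",
    index: str = "2005-01-01",
    death: str | None = None,
    end: str = "2020-03-31",
    age: int = 74,
    sex: str = "F",
) -> PatientRecord:
    return PatientRecord(pid, sex, age, d(index), d(death) if death else None, d(end))


def dx(code: str, system: str = "ICD10CA", position: int = 1) -> DiagnosisEntry:
    return DiagnosisEntry(code, system, position)


def px(code: str, date: str) -> ProcedureEntry:
    return ProcedureEntry(code, d(date))


def ip_claim(cid, pid, admit, discharge, episode, dxs=(), pxs=()) -> ClaimRecord:
    return ClaimRecord(cid, pid, "inpatient", d(admit), d(discharge), episode, tuple(dxs), tuple(pxs))


def ed_claim(cid, pid, date, dxs=(), pxs=()) -> ClaimRecord:
    return ClaimRecord(cid, pid, "emergency", d(date), None, None, tuple(dxs), tuple(pxs))


def op_claim(cid, pid, date, dxs=(), pxs=()) -> ClaimRecord:
    return ClaimRecord(cid, pid, "outpatient", d(date), None, None, tuple(dxs), tuple(pxs))
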