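"""Sensitivity analyses as event-table recomputations and code-set variants.

Four analyses probe how fragile a definition's event count is:

* ``washout_180`` — discard an event when the same site shows a fracture
  claim in the preceding 180 days (including claims before the index
  date), the usual guard against prevalent or follow-up fractures being
  recounted as incident.
* ``trauma_exclusion`` — discard events associated with external-cause
  (V/W) codes in inpatient or emergency records; outpatient fee claims
  carry no cause-of-injury information.
* ``no_subtrochanteric`` (hip only) — drop the S72.2 diagnosis code, the
  femur region where bisphosphonate-associated atypical fractures occur.
* ``no_hip_replacement`` (hip only) — drop the 1VA53 procedure code from
  the confirmation sets, as many published definitions do.

Exclusion analyses re-identify the first fracture among the remaining
qualifying hits: a patient whose earliest event is excluded may still
contribute a later one.  Code-set analyses re-run the definition engine
against a derived registry.  Either way a variant's per-definition count
can never exceed the primary count.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .claims_model import ClaimRecord, PatientRecord
from .codesets import CodeSet, derive_variant, matches
from .definitions import (
    FractureDefinition,
    FractureEvent,
    run_definitions,
    trauma_linked,
)

__all__ = [
    "SensitivitySpec",
    "SENSITIVITY_KINDS",
    "fracture_claim_dates",
    "apply_washout",
    "trauma_linked",
    "apply_sensitivity",
]

SENSITIVITY_KINDS = ("washout_180", "trauma_exclusion", "no_subtrochanteric", "no_hip_replacement")
HIP_ONLY_KINDS = ("no_subtrochanteric", "no_hip_replacement")


@dataclass(frozen=True)
class SensitivitySpec:
    kind: str
    washout_days: int = 180
    trauma_linkage_days: int = 7

    def __post_init__(self) -> None:
        if self.kind not in SENSITIVITY_KINDS:
            raise ValueError(f"unknown sensitivity kind {self.kind!r}")
        if self.washout_days <= 0:
            raise ValueError("washout_days must be positive")


def fracture_claim_dates(
    patient: PatientRecord,
    claims: Sequence[ClaimRecord],
    site: str,
    registry: Mapping[str, CodeSet],
    include_preindex: bool = True,
) -> list[dt.date]:
    """Sorted dates of every claim carrying a site fracture diagnosis.

    Scans all sources valid for the site (hip: inpatient/emergency ICD
    codes; radius/ulna: ICD codes anywhere plus the outpatient fee code),
    optionally including claims before the index date — the lookback data
    washout needs.
    """
    if site == "hip":
        icd_set, fee_set = registry.get("hip_dx"), None
        settings = {"inpatient", "emergency"}
    elif site == "radius_ulna":
        icd_set, fee_set = registry.get("radius_dx_icd"), registry.get("radius_dx_fee")
        settings = {"inpatient", "emergency", "outpatient"}
    else:
        raise ValueError(f"unknown site {site!r}")

    dates = []
    for claim in claims:
        if claim.setting not in settings:
            continue
        if not include_preindex and claim.service_date < patient.index_date:
            continue
        for entry in claim.diagnoses:
            if entry.code_system == "ICD10CA" and icd_set is not None and matches(entry.code, "ICD10CA", icd_set):
                dates.append(claim.service_date)
                break
            if (
                entry.code_system == "OHIP_FEE"
                and fee_set is not None
                and claim.setting == "outpatient"
                and matches(entry.code, "OHIP_FEE", fee_set)
            ):
                dates.append(claim.service_date)
                break
    return sorted(dates)


def apply_washout(event: FractureEvent, prior_dates: Sequence[dt.date], washout_days: int) -> bool:
    """Keep/drop decision: False (drop) iff a prior same-site fracture claim
    falls within ``[event_date - washout_days, event_date - 1]``, inclusive."""
    low = event.event_date - dt.timedelta(days=washout_days)
    return not any(low <= d <= event.event_date - dt.timedelta(days=1) for d in prior_dates)


def apply_sensitivity(
    event_table: pd.DataFrame,
    spec: SensitivitySpec,
    cohort: Sequence[PatientRecord],
    claims: Sequence[ClaimRecord],
    registry: Mapping[str, CodeSet],
    definitions: Sequence[FractureDefinition],
    ed_linkage_days: int = 1,
) -> pd.DataFrame:
    """Recompute the event table under one sensitivity specification.

    The primary ``event_table`` is used only for validation (the variant is
    recomputed from the claims so exclusions can fall through to later
    qualifying events); its schema is shared by the output, plus a
    ``variant`` label column.
    """
    sites = {d.site for d in definitions}
    if spec.kind in HIP_ONLY_KINDS and sites != {"hip"}:
        raise ValueError(f"{spec.kind} applies to hip definitions only")

    if spec.kind == "no_subtrochanteric":
        variant_registry = derive_variant(registry, ["S722"])
        table = run_definitions(cohort, claims, definitions, variant_registry,
                                ed_linkage_days=ed_linkage_days,
                                trauma_linkage_days=spec.trauma_linkage_days)
    elif spec.kind == "no_hip_replacement":
        variant_registry = derive_variant(registry, ["1VA53"])
        table = run_definitions(cohort, claims, definitions, variant_registry,
                                ed_linkage_days=ed_linkage_days,
                                trauma_linkage_days=spec.trauma_linkage_days)
    elif spec.kind == "trauma_exclusion":
        def factory(patient, pclaims, definition):
            return lambda event: not event.trauma_associated

        table = run_definitions(cohort, claims, definitions, registry,
                                ed_linkage_days=ed_linkage_days,
                                trauma_linkage_days=spec.trauma_linkage_days,
                                event_filter_factory=factory)
    elif spec.kind == "washout_180":
        date_cache: dict[tuple[str, str], list[dt.date]] = {}

        def factory(patient, pclaims, definition):
            key = (patient.patient_id, definition.site)
            if key not in date_cache:
                date_cache[key] = fracture_claim_dates(
                    patient, pclaims, definition.site, registry, include_preindex=True
                )
            dates = date_cache[key]
            return lambda event: apply_washout(event, dates, spec.washout_days)

        table = run_definitions(cohort, claims, definitions, registry,
                                ed_linkage_days=ed_linkage_days,
                                trauma_linkage_days=spec.trauma_linkage_days,
                                event_filter_factory=factory)
    else:  # pragma: no cover - guarded by SensitivitySpec
        raise ValueError(spec.kind)

    table = table.copy()
    table["variant"] = spec.kind
    return table
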