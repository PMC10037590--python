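"""Declarative fracture-definition model and the first-fracture evaluator.

A claims-based fracture definition says which data sources may contribute a
qualifying diagnosis (I = inpatient, E = emergency department, O =
outpatient fee claims), whether outpatient diagnoses must be corroborated
(two within 90 days), and whether the diagnosis must be confirmed by a site
procedure — or by death, the proxy for patients too frail to undergo
surgery — linked to the diagnosis within a day window or within the same
hospitalization episode.

Thirteen hip and seven radius/ulna definitions ship built in, ordered from
most to least inclusive; definition 1 of each site is the referent.  Hip
definitions never use outpatient data (Ontario has no outpatient diagnosis
code for hip fracture); radius/ulna definitions lean on OHIP fee code 813
because wrist fractures are mostly treated out of hospital.

The evaluator identifies each patient's first qualifying fracture during
follow-up (index date to death or study end, inclusive), with deterministic
tie-breaking for same-day hits: inpatient before emergency before
outpatient, then claim id.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import pandas as pd
import yaml

from .claims_model import (
    ClaimRecord,
    Episode,
    PatientRecord,
    build_episodes,
    follow_up_end,
)
from .codesets import CodeSet, matches

__all__ = [
    "FractureDefinition",
    "FractureEvent",
    "DiagnosisHit",
    "EpisodeIndex",
    "builtin_definitions",
    "diagnosis_hits",
    "resolve_outpatient_rule",
    "confirm",
    "identify_first_fracture",
    "run_definitions",
    "trauma_linked",
    "definitions_to_yaml",
    "definitions_from_yaml",
]

SOURCE_SETTING = {"I": "inpatient", "E": "emergency", "O": "outpatient"}
SETTING_PRIORITY = {"inpatient": 0, "emergency": 1, "outpatient": 2}

LINKAGE_MODES = ("same_episode", "within_days", "same_episode_or_within_days", "any_time")


@dataclass(frozen=True)
class OutpatientRule:
    """Corroboration rule: an outpatient diagnosis only counts when a second
    outpatient diagnosis falls within ``window_days`` of it (either side)."""

    required_count: int = 2
    window_days: int = 90


@dataclass(frozen=True)
class FractureDefinition:
    definition_id: str
    site: str  # hip | radius_ulna
    dx_sources: frozenset[str]
    primary_dx_only: bool = False
    outpatient_rule: OutpatientRule | None = None
    confirmation: str = "none"  # none | procedure | procedure_or_death
    confirmation_sources: frozenset[str] = frozenset()
    linkage: str | None = None
    linkage_days: int | None = None  # the k of within_days variants
    description: str = ""

    def __post_init__(self) -> None:
        if self.site not in ("hip", "radius_ulna"):
            raise ValueError(f"unknown site {self.site!r}")
        if not self.dx_sources or not self.dx_sources <= {"I", "E", "O"}:
            raise ValueError(f"bad dx_sources {set(self.dx_sources)!r}")
        if self.site == "hip" and "O" in self.dx_sources:
            raise ValueError("hip has no outpatient diagnosis code")
        if self.outpatient_rule is not None and "O" not in self.dx_sources:
            raise ValueError("outpatient_rule without outpatient source")
        if self.confirmation == "none":
            if self.linkage is not None:
                raise ValueError("linkage given without confirmation")
        else:
            if self.confirmation not in ("procedure", "procedure_or_death"):
                raise ValueError(f"unknown confirmation {self.confirmation!r}")
            if self.linkage not in LINKAGE_MODES:
                raise ValueError(f"unknown linkage {self.linkage!r}")
            if "within_days" in self.linkage and self.linkage_days is None:
                raise ValueError("linkage_days required for day-window linkage")

    @property
    def confirmation_window_days(self) -> int | None:
        """Day window applied to death confirmation, where one applies."""
        return self.linkage_days


@dataclass(frozen=True)
class DiagnosisHit:
    """One claim carrying a qualifying site diagnosis inside follow-up."""

    claim_id: str
    date: dt.date
    source: str  # setting
    subtrochanteric: bool
    matched_codes: tuple[str, ...]

    @property
    def sort_key(self):
        return (self.date, SETTING_PRIORITY[self.source], self.claim_id)


@dataclass(frozen=True)
class FractureEvent:
    patient_id: str
    definition_id: str
    site: str
    event_date: dt.date
    qualifying_claim_ids: tuple[str, ...]
    confirmation_kind: str = "none"  # none | procedure | death
    confirming_procedure_codes: tuple[str, ...] = ()
    trauma_associated: bool = False
    subtrochanteric_involved: bool = False
    replacement_confirmed: bool = False


class EpisodeIndex:
    """Episodes of one patient with claim-id lookup."""

    def __init__(self, episodes: Sequence[Episode], claim_to_episode: Mapping[str, str]):
        self._episodes = {e.episode_id: e for e in episodes}
        self._claim_map = dict(claim_to_episode)

    @classmethod
    def build(cls, claims: Sequence[ClaimRecord], ed_linkage_days: int = 1) -> "EpisodeIndex":
        episodes, claim_map = build_episodes(claims, ed_linkage_days)
        return cls(episodes, claim_map)

    def episode_of(self, claim_id: str) -> Episode | None:
        ep_id = self._claim_map.get(claim_id)
        return self._episodes.get(ep_id) if ep_id is not None else None


# ---------------------------------------------------------------------------
# Built-in definitions


def _hip(defn_id, sources, desc, **kw) -> FractureDefinition:
    return FractureDefinition(defn_id, "hip", frozenset(sources), description=desc, **kw)


def _ru(defn_id, sources, desc, **kw) -> FractureDefinition:
    return FractureDefinition(defn_id, "radius_ulna", frozenset(sources), description=desc, **kw)


def builtin_definitions(site: str, secondary_cohort_mode: bool = False) -> list[FractureDefinition]:
    """The built-in definitions, ordered most to least inclusive.

    ``secondary_cohort_mode`` models a data environment where emergency
    department records carry no procedure codes: E is removed from every
    confirmation source set, and definitions whose confirmation relied
    solely on emergency procedures are dropped as untestable.
    """
    if site == "hip":
        defs = [
            _hip("hip-01", "IE", "IE, dx"),
            _hip("hip-02", "I", "I, dx"),
            _hip("hip-03", "E", "E, dx"),
            _hip("hip-04", "IE", "IE, dx + (px/death) in 7 days or same hospitalization",
                 confirmation="procedure_or_death", confirmation_sources=frozenset("IE"),
                 linkage="same_episode_or_within_days", linkage_days=7),
            _hip("hip-05", "IE", "IE, dx + (px/death) in same hospitalization",
                 confirmation="procedure_or_death", confirmation_sources=frozenset("IE"),
                 linkage="same_episode"),
            _hip("hip-06", "I", "I, dx + (px/death) in same hospitalization",
                 confirmation="procedure_or_death", confirmation_sources=frozenset("I"),
                 linkage="same_episode"),
            _hip("hip-07", "IE", "IE, dx + px within 7 days",
                 confirmation="procedure", confirmation_sources=frozenset("IE"),
                 linkage="within_days", linkage_days=7),
            _hip("hip-08", "IE", "IE, dx + px in same hospitalization",
                 confirmation="procedure", confirmation_sources=frozenset("IE"),
                 linkage="same_episode"),
            _hip("hip-09", "I", "I, dx + (px/death) in 7 days",
                 confirmation="procedure_or_death", confirmation_sources=frozenset("I"),
                 linkage="within_days", linkage_days=7),
            _hip("hip-10", "I", "I, dx + px within 7 days",
                 confirmation="procedure", confirmation_sources=frozenset("I"),
                 linkage="within_days", linkage_days=7),
            _hip("hip-11", "E", "E, dx + (px/death) in 7 days",
                 confirmation="procedure_or_death", confirmation_sources=frozenset("E"),
                 linkage="within_days", linkage_days=7),
            _hip("hip-12", "E", "E, dx + px",
                 confirmation="procedure", confirmation_sources=frozenset("E"),
                 linkage="any_time"),
            _hip("hip-13", "E", "E, dx + px in 7 days",
                 confirmation="procedure", confirmation_sources=frozenset("E"),
                 linkage="within_days", linkage_days=7),
        ]
    elif site == "radius_ulna":
        defs = [
            _ru("ru-01", "IEO", "IEO, dx"),
            _ru("ru-02", "IO", "IO, dx"),
            _ru("ru-03", "IO", "IO, dx; two outpatient dx within 90 days",
                outpatient_rule=OutpatientRule(2, 90)),
            _ru("ru-04", "IEO", "IEO, dx + px in 7 days",
                confirmation="procedure", confirmation_sources=frozenset("IEO"),
                linkage="within_days", linkage_days=7),
            _ru("ru-05", "IE", "IE, dx"),
            _ru("ru-06", "IEO", "IEO, dx + px within 90 days",
                confirmation="procedure", confirmation_sources=frozenset("IEO"),
                linkage="within_days", linkage_days=90),
            _ru("ru-07", "I", "I, dx"),
        ]
    else:
        raise ValueError(f"unknown site {site!r}")

    if secondary_cohort_mode:
        adjusted = []
        for d in defs:
            if d.confirmation == "none":
                adjusted.append(d)
                continue
            sources = d.confirmation_sources - {"E"}
            if not sources:
                continue  # untestable without ED procedures
            adjusted.append(replace(d, confirmation_sources=sources))
        defs = adjusted
    return defs


# ---------------------------------------------------------------------------
# Evaluation


def _site_dx_sets(site: str, registry: Mapping[str, CodeSet]) -> tuple[CodeSet, CodeSet | None]:
    if site == "hip":
        return registry["hip_dx"], None
    return registry["radius_dx_icd"], registry.get("radius_dx_fee")


def _site_px_set(site: str, registry: Mapping[str, CodeSet]) -> CodeSet | None:
    name = "hip_px" if site == "hip" else "radius_px"
    return registry.get(name)


def diagnosis_hits(
    patient: PatientRecord,
    claims: Sequence[ClaimRecord],
    definition: FractureDefinition,
    registry: Mapping[str, CodeSet],
) -> list[DiagnosisHit]:
    """Dated qualifying diagnoses for one patient under one definition.

    A claim yields at most one hit: its setting must be among the
    definition's diagnosis sources, it must carry a site diagnosis (ICD-10
    in any setting; the outpatient fee code for radius/ulna), and its
    service date must fall within follow-up.  Under ``primary_dx_only``
    only position-1 diagnosis entries count.
    """
    icd_set, fee_set = _site_dx_sets(definition.site, registry)
    subtroch_set = registry.get("hip_subtrochanteric") if definition.site == "hip" else None
    settings = {SOURCE_SETTING[s] for s in definition.dx_sources}
    start, end = patient.index_date, follow_up_end(patient)

    hits: list[DiagnosisHit] = []
    for claim in claims:
        if claim.setting not in settings:
            continue
        if not (start <= claim.service_date <= end):
            continue
        matched: list[str] = []
        subtroch = False
        for entry in claim.diagnoses:
            if definition.primary_dx_only and entry.position != 1:
                continue
            if entry.code_system == "ICD10CA" and icd_set is not None and matches(entry.code, "ICD10CA", icd_set):
                matched.append(entry.code)
                if subtroch_set is not None and matches(entry.code, "ICD10CA", subtroch_set):
                    subtroch = True
            elif (
                entry.code_system == "OHIP_FEE"
                and fee_set is not None
                and claim.setting == "outpatient"
                and matches(entry.code, "OHIP_FEE", fee_set)
            ):
                matched.append(entry.code)
        if matched:
            hits.append(
                DiagnosisHit(claim.claim_id, claim.service_date, claim.setting, subtroch, tuple(matched))
            )
    hits.sort(key=lambda h: h.sort_key)
    return hits


def _outpatient_partner(hit: DiagnosisHit, hits: Sequence[DiagnosisHit], rule: OutpatientRule) -> DiagnosisHit | None:
    window = dt.timedelta(days=rule.window_days)
    for other in hits:
        if other.claim_id == hit.claim_id or other.source != "outpatient":
            continue
        if abs(other.date - hit.date) <= window:
            return other
    return None


def _passes_outpatient_rule(hit: DiagnosisHit, hits: Sequence[DiagnosisHit], rule: OutpatientRule | None) -> bool:
    if rule is None or hit.source != "outpatient":
        return True  # inpatient (and any non-outpatient) diagnoses bypass the rule
    return _outpatient_partner(hit, hits, rule) is not None


def resolve_outpatient_rule(hits: Sequence[DiagnosisHit], rule: OutpatientRule | None) -> dt.date | None:
    """Earliest date at which the outpatient corroboration rule is satisfied.

    Non-outpatient hits qualify at their own date; an outpatient hit
    qualifies when another outpatient hit lies within the rule's window
    before or after it (inclusive).  Returns None when no hit qualifies.
    """
    for hit in sorted(hits, key=lambda h: h.sort_key):
        if _passes_outpatient_rule(hit, hits, rule):
            return hit.date
    return None


@dataclass(frozen=True)
class Confirmation:
    kind: str  # procedure | death
    claim_ids: tuple[str, ...]
    procedure_codes: tuple[str, ...]
    replacement: bool


def confirm(
    hit: DiagnosisHit,
    patient: PatientRecord,
    claims: Sequence[ClaimRecord],
    definition: FractureDefinition,
    registry: Mapping[str, CodeSet],
    episode_index: EpisodeIndex,
) -> Confirmation | None:
    """Check the definition's confirmation requirement for one diagnosis hit.

    Procedure confirmation: a site procedure on a claim from an eligible
    source whose date (or hospitalization episode) satisfies the linkage —
    ``within_days(k)`` means the procedure date lies in [dx, dx + k];
    ``same_episode`` means the procedure's claim shares the hit's episode;
    ``any_time`` means on or after the diagnosis.  Death confirmation (where
    allowed): death within the day window, or before episode discharge for
    same-hospitalization linkage.
    """
    if definition.confirmation == "none":
        return None
    px_set = _site_px_set(definition.site, registry)
    replacement_set = registry.get("hip_replacement") if definition.site == "hip" else None
    settings = {SOURCE_SETTING[s] for s in definition.confirmation_sources}
    hit_episode = episode_index.episode_of(hit.claim_id)
    k = definition.linkage_days
    window = dt.timedelta(days=k) if k is not None else None

    def linked(proc_date: dt.date, claim_id: str) -> bool:
        mode = definition.linkage
        if mode == "within_days":
            return hit.date <= proc_date <= hit.date + window
        if mode == "any_time":
            return proc_date >= hit.date
        same_ep = (
            hit_episode is not None
            and (ep := episode_index.episode_of(claim_id)) is not None
            and ep.episode_id == hit_episode.episode_id
        )
        if mode == "same_episode":
            return same_ep
        # same_episode_or_within_days
        return same_ep or hit.date <= proc_date <= hit.date + window

    codes: list[str] = []
    claim_ids: list[str] = []
    replacement = False
    if px_set is not None:
        for claim in claims:
            if claim.setting not in settings:
                continue
            for proc in claim.procedures:
                if matches(proc.code, "CCI", px_set) and linked(proc.procedure_date, claim.claim_id):
                    codes.append(proc.code)
                    claim_ids.append(claim.claim_id)
                    if replacement_set is not None and matches(proc.code, "CCI", replacement_set):
                        replacement = True
    if codes:
        return Confirmation("procedure", tuple(dict.fromkeys(claim_ids)), tuple(sorted(set(codes))), replacement)

    if definition.confirmation == "procedure_or_death" and patient.death_date is not None:
        death = patient.death_date
        mode = definition.linkage
        by_window = window is not None and hit.date <= death <= hit.date + window
        by_episode = hit_episode is not None and death <= hit_episode.discharge_date
        if (
            (mode == "within_days" and by_window)
            or (mode == "same_episode" and by_episode)
            or (mode == "same_episode_or_within_days" and (by_window or by_episode))
            or (mode == "any_time" and death >= hit.date)
        ):
            return Confirmation("death", (), (), False)
    return None


def trauma_linked(
    event: FractureEvent,
    claims: Sequence[ClaimRecord],
    registry: Mapping[str, CodeSet],
    episode_index: EpisodeIndex,
    linkage_days: int = 7,
) -> bool:
    """Whether a fracture event is associated with an external-cause code.

    True when a V/W trauma diagnosis appears on a qualifying claim of the
    event, on any claim of the event's hospitalization episode, or on any
    inpatient or emergency claim within ±``linkage_days`` of the event.
    Outpatient claims never count: fee claims carry no external-cause codes.
    """
    trauma_set = registry.get("trauma")
    if trauma_set is None:
        return False

    def has_trauma(claim: ClaimRecord) -> bool:
        if claim.setting == "outpatient":
            return False
        return any(
            e.code_system == "ICD10CA" and matches(e.code, "ICD10CA", trauma_set)
            for e in claim.diagnoses
        )

    qualifying = set(event.qualifying_claim_ids)
    episode_ids = {
        ep.episode_id
        for cid in qualifying
        if (ep := episode_index.episode_of(cid)) is not None
    }
    window = dt.timedelta(days=linkage_days)
    for claim in claims:
        if claim.setting == "outpatient":
            continue
        in_scope = (
            claim.claim_id in qualifying
            or ((ep := episode_index.episode_of(claim.claim_id)) is not None and ep.episode_id in episode_ids)
            or abs(claim.service_date - event.event_date) <= window
        )
        if in_scope and has_trauma(claim):
            return True
    return False


def identify_first_fracture(
    patient: PatientRecord,
    claims: Sequence[ClaimRecord],
    definition: FractureDefinition,
    registry: Mapping[str, CodeSet],
    episode_index: EpisodeIndex | None = None,
    event_filter: Callable[[FractureEvent], bool] | None = None,
    trauma_linkage_days: int = 7,
) -> FractureEvent | None:
    """The patient's first fracture qualifying under the definition.

    Hits are evaluated in chronological order (same-day ties: inpatient,
    then emergency, then outpatient, then claim id); the first hit passing
    the outpatient corroboration rule and the confirmation requirement
    yields the event.  ``event_filter`` lets sensitivity analyses veto a
    candidate (e.g. washout, trauma exclusion), in which case evaluation
    continues with the next qualifying hit.
    """
    if episode_index is None:
        episode_index = EpisodeIndex.build(claims)
    hits = diagnosis_hits(patient, claims, definition, registry)
    for hit in hits:
        if not _passes_outpatient_rule(hit, hits, definition.outpatient_rule):
            continue
        qualifying = [hit.claim_id]
        subtroch = hit.subtrochanteric
        if definition.outpatient_rule is not None and hit.source == "outpatient":
            partner = _outpatient_partner(hit, hits, definition.outpatient_rule)
            if partner is not None:
                qualifying.append(partner.claim_id)
        conf_kind, conf_codes, replacement = "none", (), False
        if definition.confirmation != "none":
            conf = confirm(hit, patient, claims, definition, registry, episode_index)
            if conf is None:
                continue
            conf_kind = conf.kind
            conf_codes = conf.procedure_codes
            replacement = conf.replacement
            qualifying.extend(cid for cid in conf.claim_ids if cid not in qualifying)
        event = FractureEvent(
            patient_id=patient.patient_id,
            definition_id=definition.definition_id,
            site=definition.site,
            event_date=hit.date,
            qualifying_claim_ids=tuple(qualifying),
            confirmation_kind=conf_kind,
            confirming_procedure_codes=conf_codes,
            subtrochanteric_involved=subtroch,
            replacement_confirmed=replacement,
        )
        event = replace(
            event,
            trauma_associated=trauma_linked(event, claims, registry, episode_index, trauma_linkage_days),
        )
        if event_filter is not None and not event_filter(event):
            continue
        return event
    return None


EVENT_TABLE_COLUMNS = [
    "patient_id",
    "definition_id",
    "site",
    "event_date",
    "confirmation_kind",
    "confirming_procedure_codes",
    "qualifying_claim_ids",
    "trauma_associated",
    "subtrochanteric_involved",
    "replacement_confirmed",
]


def run_definitions(
    cohort: Sequence[PatientRecord],
    claims: Sequence[ClaimRecord],
    definitions: Sequence[FractureDefinition],
    registry: Mapping[str, CodeSet],
    ed_linkage_days: int = 1,
    trauma_linkage_days: int = 7,
    event_filter_factory: Callable[[PatientRecord, Sequence[ClaimRecord], FractureDefinition], Callable[[FractureEvent], bool] | None] | None = None,
) -> pd.DataFrame:
    """Evaluate every definition for every patient; one row per pair.

    Rows with a null ``event_date`` record explicit absence.  Output order
    (definitions in the given order, patients sorted by id) and content are
    deterministic for identical inputs.
    """
    patient_ids = {p.patient_id for p in cohort}
    unknown = sorted({c.patient_id for c in claims} - patient_ids)
    if unknown:
        raise ValueError(f"claims reference unknown patient id(s): {', '.join(unknown[:5])}")

    claims_by_patient: dict[str, list[ClaimRecord]] = {p.patient_id: [] for p in cohort}
    for claim in claims:
        claims_by_patient[claim.patient_id].append(claim)

    rows = []
    for patient in sorted(cohort, key=lambda p: p.patient_id):
        pclaims = claims_by_patient[patient.patient_id]
        episode_index = EpisodeIndex.build(pclaims, ed_linkage_days)
        for definition in definitions:
            event_filter = None
            if event_filter_factory is not None:
                event_filter = event_filter_factory(patient, pclaims, definition)
            event = identify_first_fracture(
                patient, pclaims, definition, registry, episode_index,
                event_filter=event_filter, trauma_linkage_days=trauma_linkage_days,
            )
            if event is None:
                rows.append(
                    (patient.patient_id, definition.definition_id, definition.site,
                     None, "", "", "", False, False, False)
                )
            else:
                rows.append(
                    (
                        event.patient_id,
                        event.definition_id,
                        event.site,
                        event.event_date,
                        event.confirmation_kind,
                        ";".join(event.confirming_procedure_codes),
                        ";".join(event.qualifying_claim_ids),
                        event.trauma_associated,
                        event.subtrochanteric_involved,
                        event.replacement_confirmed,
                    )
                )
    table = pd.DataFrame(rows, columns=EVENT_TABLE_COLUMNS)
    table["event_date"] = pd.to_datetime(table["event_date"])
    return table


# ---------------------------------------------------------------------------
# Config serialization


def definitions_to_yaml(definitions: Sequence[FractureDefinition], path) -> None:
    """Write definitions as a YAML config so users can add jurisdictional
    variants; the built-in twenty serve as the default config."""
    blocks = []
    for d in definitions:
        block = {
            "definition_id": d.definition_id,
            "site": d.site,
            "dx_sources": "".join(sorted(d.dx_sources)),
            "description": d.description,
        }
        if d.primary_dx_only:
            block["primary_dx_only"] = True
        if d.outpatient_rule is not None:
            block["outpatient_rule"] = {
                "required_count": d.outpatient_rule.required_count,
                "window_days": d.outpatient_rule.window_days,
            }
        if d.confirmation != "none":
            block["confirmation"] = d.confirmation
            block["confirmation_sources"] = "".join(sorted(d.confirmation_sources))
            block["linkage"] = d.linkage
            if d.linkage_days is not None:
                block["linkage_days"] = d.linkage_days
        blocks.append(block)
    with open(path, "w") as handle:
        yaml.safe_dump(blocks, handle, sort_keys=False)


def definitions_from_yaml(path) -> list[FractureDefinition]:
    with open(path) as handle:
        blocks = yaml.safe_load(handle)
    defs = []
    for block in blocks:
        rule = block.get("outpatient_rule")
        defs.append(
            FractureDefinition(
                definition_id=block["definition_id"],
                site=block["site"],
                dx_sources=frozenset(block["dx_sources"]),
                primary_dx_only=block.get("primary_dx_only", False),
                outpatient_rule=OutpatientRule(**rule) if rule else None,
                confirmation=block.get("confirmation", "none"),
                confirmation_sources=frozenset(block.get("confirmation_sources", "")),
                linkage=block.get("linkage"),
                linkage_days=block.get("linkage_days"),
                description=block.get("description", ""),
            )
        )
    return defs
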