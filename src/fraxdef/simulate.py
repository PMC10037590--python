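"""Seeded synthetic cohort and claims generator with ground truth.

Emulates the statistical structure of an Ontario-style administrative
environment for an older osteoporosis-treatment cohort: patients aged 66+
entering between April 2003 and December 2016 and followed to March 2020
or death; hip and radius/ulna fragility fractures arising as first-event
exponential processes; and each true fracture expanding — through a
per-site coding model — into the emergency, inpatient, and outpatient
claims the definition engine consumes, with diagnosis positions,
hospitalization episodes, CCI procedures, external-cause co-codes, death
linkage, and optional pre-index fracture history for washout testing.

The generator makes no attempt to reproduce any real cohort's absolute
counts or rates; its purpose is a controlled environment where the
engine's capture behaviour has known closed forms (``expected_capture``)
and the qualitative source-importance contrasts of real data hold: hip
fractures are almost always hospitalized, radius/ulna fractures mostly
outpatient.

Every draw comes from one ``numpy`` generator seeded from the config, so
identical configs give byte-identical tables.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .claims_model import (
    ClaimRecord,
    DiagnosisEntry,
    PatientRecord,
    ProcedureEntry,
)

__all__ = [
    "CodingModel",
    "SimulationConfig",
    "TruthRecord",
    "simulate",
    "expected_capture",
    "write_truth",
    "read_truth",
    "UnsupportedDefinitionError",
]

HIP_DX_CODES = ["S7200", "S7208", "S7210", "S7211"]
HIP_SUBTROCH_CODES = ["S7220", "S7221"]
RADIUS_DX_CODES = ["S5250", "S5251", "S5230", "S5200", "S5260"]
TRAUMA_CODES = ["W010", "W060", "W180", "V031", "V184"]
# background morbidity: chapters that never touch the fracture or trauma sets
BACKGROUND_ICD = ["I109", "E119", "J189", "I500", "N390", "K590", "M545", "C509"]
BACKGROUND_FEE = ["903", "A003", "K005"]


class UnsupportedDefinitionError(ValueError):
    """No closed-form capture probability exists for this definition."""


@dataclass(frozen=True)
class CodingModel:
    """How a true fracture event turns into claims, per site.

    Probabilities are per true event and independent of each other (the
    independence is what makes ``expected_capture`` closed-form).
    """

    p_ed_dx: float
    p_inpatient: float
    p_primary_position: float
    p_procedure_given_inpatient: float
    p_procedure_given_ed: float
    procedure_mix: dict[str, float]
    p_death_within_7d: float
    p_trauma: float
    subtrochanteric_fraction: float = 0.0
    p_outpatient_dx: float = 0.0
    p_second_outpatient_within_90d: float = 0.0
    ed_procedure_available: bool = True

    def __post_init__(self) -> None:
        probs = [
            self.p_ed_dx, self.p_inpatient, self.p_primary_position,
            self.p_procedure_given_inpatient, self.p_procedure_given_ed,
            self.p_death_within_7d, self.p_trauma,
            self.subtrochanteric_fraction, self.p_outpatient_dx,
            self.p_second_outpatient_within_90d,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all coding probabilities must lie in [0, 1]")
        total = sum(self.procedure_mix.values())
        if self.procedure_mix and abs(total - 1.0) > 1e-9:
            raise ValueError(f"procedure_mix sums to {total}, expected 1")


def default_hip_coding() -> CodingModel:
    """Hip fractures: almost always seen in the ED and admitted; surgical
    management dominates, with replacement a substantial share of procedures."""
    return CodingModel(
        p_ed_dx=0.85,
        p_inpatient=0.92,
        p_primary_position=0.90,
        p_procedure_given_inpatient=0.88,
        p_procedure_given_ed=0.04,
        procedure_mix={
            "1VA74": 0.25, "1VC74": 0.05,  # fixation
            "1VA73": 0.08, "1VC73": 0.04,  # reduction
            "1VA80": 0.15, "1VC80": 0.08,  # repair
            "1VA53": 0.35,                 # replacement
        },
        p_death_within_7d=0.06,
        p_trauma=0.02,
        subtrochanteric_fraction=0.05,
    )


def default_radius_coding() -> CodingModel:
    """Radius/ulna fractures: mostly managed out of hospital, so outpatient
    fee claims dominate and admissions are uncommon."""
    return CodingModel(
        p_ed_dx=0.60,
        p_inpatient=0.25,
        p_primary_position=0.85,
        p_procedure_given_inpatient=0.85,
        p_procedure_given_ed=0.35,
        procedure_mix={
            "1TV74": 0.15,  # fixation
            "1TV73": 0.30,  # reduction
            "1TV03": 0.40,  # immobilization
            "1TV80": 0.10, "1TV82": 0.05,  # repair
        },
        p_death_within_7d=0.01,
        p_trauma=0.05,
        p_outpatient_dx=0.90,
        p_second_outpatient_within_90d=0.70,
    )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_patients: int = 5000
    accrual_start: dt.date = dt.date(2003, 4, 1)
    accrual_end: dt.date = dt.date(2016, 12, 31)
    study_end: dt.date = dt.date(2020, 3, 31)
    female_fraction: float = 0.80
    age_median: int = 74  # ages drawn 66 + Poisson(age_median − 66)
    annual_death_hazard: float = 0.03
    site_hazards: dict[str, float] = field(
        default_factory=lambda: {"hip": 0.012, "radius_ulna": 0.010}
    )
    preindex_fracture_prob: float = 0.05
    background_claim_rate: float = 0.5  # non-fracture claims per person-year
    coding: dict[str, CodingModel] = field(
        default_factory=lambda: {"hip": default_hip_coding(), "radius_ulna": default_radius_coding()}
    )
    mean_length_of_stay: float = 7.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ValueError("female_fraction must lie in [0, 1]")
        if not (0.0 <= self.preindex_fracture_prob <= 1.0):
            raise ValueError("preindex_fracture_prob must lie in [0, 1]")
        if self.annual_death_hazard < 0 or self.background_claim_rate < 0:
            raise ValueError("rates must be >= 0")
        if any(h < 0 for h in self.site_hazards.values()):
            raise ValueError("site hazards must be >= 0")
        if not (self.accrual_start <= self.accrual_end <= self.study_end):
            raise ValueError("accrual window must precede study end")
        if self.age_median < 66:
            raise ValueError("age_median below cohort minimum 66")


@dataclass(frozen=True)
class TruthRecord:
    patient_id: str
    site: str
    true_event_date: dt.date
    mechanism: str  # fragility | trauma
    subtrochanteric: bool
    generated_claims: tuple[str, ...]


class _IdFactory:
    def __init__(self) -> None:
        self.claim = 0
        self.episode = 0

    def next_claim(self) -> str:
        self.claim += 1
        return f"C{self.claim:07d}"

    def next_episode(self) -> str:
        self.episode += 1
        return f"H{self.episode:06d}"


def _days(rng: np.random.Generator, low: int, high: int) -> int:
    return int(rng.integers(low, high + 1))


def simulate(
    config: SimulationConfig,
) -> tuple[list[PatientRecord], dict[str, list[ClaimRecord]], list[TruthRecord]]:
    """Generate (patients, claims by setting, truth records) for one config."""
    rng = np.random.default_rng(config.seed)
    ids = _IdFactory()
    patients: list[PatientRecord] = []
    claims: dict[str, list[ClaimRecord]] = {"inpatient": [], "emergency": [], "outpatient": []}
    truths: list[TruthRecord] = []

    accrual_days = (config.accrual_end - config.accrual_start).days

    for i in range(config.n_patients):
        patient_id = f"P{i + 1:06d}"
        sex = "F" if rng.random() < config.female_fraction else "M"
        age = 66 + int(rng.poisson(config.age_median - 66))
        index_date = config.accrual_start + dt.timedelta(days=_days(rng, 0, accrual_days))

        death_date: dt.date | None = None
        if config.annual_death_hazard > 0:
            death_years = rng.exponential(1.0 / config.annual_death_hazard)
            candidate = index_date + dt.timedelta(days=int(death_years * 365.25))
            if candidate <= config.study_end:
                death_date = candidate

        fu_end = min(death_date, config.study_end) if death_date else config.study_end

        # first-event time per site, accepted when inside follow-up
        events: dict[str, dict] = {}
        for site, hazard in config.site_hazards.items():
            if hazard <= 0:
                continue
            event_years = rng.exponential(1.0 / hazard)
            event_date = index_date + dt.timedelta(days=int(event_years * 365.25))
            if event_date <= fu_end:
                coding = config.coding[site]
                info = {
                    "date": event_date,
                    "mechanism": "trauma" if rng.random() < coding.p_trauma else "fragility",
                    "subtrochanteric": rng.random() < coding.subtrochanteric_fraction,
                    "death_adj": None,
                }
                if rng.random() < coding.p_death_within_7d:
                    info["death_adj"] = event_date + dt.timedelta(days=_days(rng, 0, 7))
                events[site] = info

        # acute mortality can move the death date forward; re-filter events
        adjustments = [e["death_adj"] for e in events.values() if e["death_adj"] is not None]
        if adjustments:
            new_death = min(adjustments)
            if death_date is None or new_death < death_date:
                death_date = new_death
        fu_end = min(death_date, config.study_end) if death_date else config.study_end
        events = {s: e for s, e in events.items() if e["date"] <= fu_end}

        patient = PatientRecord(patient_id, sex, age, index_date, death_date, config.study_end)
        patients.append(patient)

        for site, info in sorted(events.items()):
            coding = config.coding[site]
            event_date: dt.date = info["date"]
            generated: list[str] = []
            is_trauma = info["mechanism"] == "trauma"
            if site == "hip":
                dx_pool = HIP_SUBTROCH_CODES if info["subtrochanteric"] else HIP_DX_CODES
            else:
                dx_pool = RADIUS_DX_CODES
            dx_code = dx_pool[_days(rng, 0, len(dx_pool) - 1)]
            trauma_code = TRAUMA_CODES[_days(rng, 0, len(TRAUMA_CODES) - 1)]

            hospitalized = rng.random() < coding.p_inpatient
            episode_id = None
            if hospitalized:
                episode_id = ids.next_episode()
                los = int(rng.geometric(1.0 / config.mean_length_of_stay))
                discharge = event_date + dt.timedelta(days=los)
                dxs: list[DiagnosisEntry] = []
                if rng.random() < coding.p_primary_position:
                    dxs.append(DiagnosisEntry(dx_code, "ICD10CA", 1))
                else:
                    filler = BACKGROUND_ICD[_days(rng, 0, len(BACKGROUND_ICD) - 1)]
                    dxs.append(DiagnosisEntry(filler, "ICD10CA", 1))
                    dxs.append(DiagnosisEntry(dx_code, "ICD10CA", _days(rng, 2, 5)))
                if is_trauma:
                    dxs.append(DiagnosisEntry(trauma_code, "ICD10CA", 9))
                procedures = ()
                if rng.random() < coding.p_procedure_given_inpatient:
                    px_code = rng.choice(
                        list(coding.procedure_mix), p=list(coding.procedure_mix.values())
                    )
                    px_date = event_date + dt.timedelta(days=min(_days(rng, 0, 2), los))
                    procedures = (ProcedureEntry(str(px_code), px_date),)
                cid = ids.next_claim()
                claims["inpatient"].append(
                    ClaimRecord(cid, patient_id, "inpatient", event_date, discharge,
                                episode_id, tuple(dxs), procedures)
                )
                generated.append(cid)

            if rng.random() < coding.p_ed_dx:
                # the ED visit of a hospitalized event lands on the admission
                # day, exercising the same-hospitalization linkage
                dxs = [DiagnosisEntry(dx_code, "ICD10CA", 1)]
                if is_trauma:
                    dxs.append(DiagnosisEntry(trauma_code, "ICD10CA", 9))
                procedures = ()
                if coding.ed_procedure_available and rng.random() < coding.p_procedure_given_ed:
                    px_code = rng.choice(
                        list(coding.procedure_mix), p=list(coding.procedure_mix.values())
                    )
                    px_date = event_date + dt.timedelta(days=_days(rng, 0, 10))
                    procedures = (ProcedureEntry(str(px_code), px_date),)
                cid = ids.next_claim()
                claims["emergency"].append(
                    ClaimRecord(cid, patient_id, "emergency", event_date, None, None,
                                tuple(dxs), procedures)
                )
                generated.append(cid)

            if coding.p_outpatient_dx > 0 and rng.random() < coding.p_outpatient_dx:
                cid = ids.next_claim()
                claims["outpatient"].append(
                    ClaimRecord(cid, patient_id, "outpatient", event_date, None, None,
                                (DiagnosisEntry("813", "OHIP_FEE", 1),), ())
                )
                generated.append(cid)
                if rng.random() < coding.p_second_outpatient_within_90d:
                    second_date = event_date + dt.timedelta(days=_days(rng, 1, 90))
                    cid = ids.next_claim()
                    claims["outpatient"].append(
                        ClaimRecord(cid, patient_id, "outpatient", second_date, None, None,
                                    (DiagnosisEntry("813", "OHIP_FEE", 1),), ())
                    )
                    generated.append(cid)

            truths.append(
                TruthRecord(patient_id, site, event_date, info["mechanism"],
                            info["subtrochanteric"], tuple(generated))
            )

        # pre-index fracture history (lookback data for washout)
        for site in sorted(config.site_hazards):
            if config.preindex_fracture_prob <= 0 or rng.random() >= config.preindex_fracture_prob:
                continue
            prior_date = index_date - dt.timedelta(days=_days(rng, 1, 365))
            if site == "hip":
                cid = ids.next_claim()
                claims["emergency"].append(
                    ClaimRecord(cid, patient_id, "emergency", prior_date, None, None,
                                (DiagnosisEntry(HIP_DX_CODES[0], "ICD10CA", 1),), ())
                )
            else:
                cid = ids.next_claim()
                claims["outpatient"].append(
                    ClaimRecord(cid, patient_id, "outpatient", prior_date, None, None,
                                (DiagnosisEntry("813", "OHIP_FEE", 1),), ())
                )

        # background (non-fracture) claims over follow-up
        py = max((fu_end - index_date).days, 0) / 365.25
        n_background = int(rng.poisson(config.background_claim_rate * py)) if py > 0 else 0
        for _ in range(n_background):
            service = index_date + dt.timedelta(days=_days(rng, 0, max((fu_end - index_date).days, 0)))
            setting = ["inpatient", "emergency", "outpatient"][
                int(rng.choice(3, p=[0.15, 0.35, 0.50]))
            ]
            cid = ids.next_claim()
            if setting == "outpatient":
                fee = BACKGROUND_FEE[_days(rng, 0, len(BACKGROUND_FEE) - 1)]
                claims["outpatient"].append(
                    ClaimRecord(cid, patient_id, "outpatient", service, None, None,
                                (DiagnosisEntry(fee, "OHIP_FEE", 1),), ())
                )
            elif setting == "emergency":
                code = BACKGROUND_ICD[_days(rng, 0, len(BACKGROUND_ICD) - 1)]
                claims["emergency"].append(
                    ClaimRecord(cid, patient_id, "emergency", service, None, None,
                                (DiagnosisEntry(code, "ICD10CA", 1),), ())
                )
            else:
                code = BACKGROUND_ICD[_days(rng, 0, len(BACKGROUND_ICD) - 1)]
                los = int(rng.geometric(1.0 / config.mean_length_of_stay))
                claims["inpatient"].append(
                    ClaimRecord(cid, patient_id, "inpatient", service,
                                service + dt.timedelta(days=los), ids.next_episode(),
                                (DiagnosisEntry(code, "ICD10CA", 1),), ())
                )

    return patients, claims, truths


# ---------------------------------------------------------------------------
# Closed-form capture probabilities (the generator/engine cross-check)

_ANALYTIC = {
    "hip-01": lambda c: 1 - (1 - c.p_ed_dx) * (1 - c.p_inpatient),
    "hip-02": lambda c: c.p_inpatient,
    "hip-03": lambda c: c.p_ed_dx,
    "ru-01": lambda c: 1 - (1 - c.p_ed_dx) * (1 - c.p_inpatient) * (1 - c.p_outpatient_dx),
    "ru-02": lambda c: 1 - (1 - c.p_inpatient) * (1 - c.p_outpatient_dx),
    "ru-05": lambda c: 1 - (1 - c.p_ed_dx) * (1 - c.p_inpatient),
    "ru-07": lambda c: c.p_inpatient,
}


def expected_capture(definition_id: str, config: SimulationConfig) -> float:
    """Closed-form probability that the engine captures a true event.

    Exists only for diagnosis-only definitions, where capture is a simple
    function of the per-source coding probabilities under the generator's
    independence assumption (each source codes an event independently).
    """
    if definition_id not in _ANALYTIC:
        raise UnsupportedDefinitionError(
            f"no closed-form capture probability for {definition_id}"
        )
    site = "hip" if definition_id.startswith("hip") else "radius_ulna"
    return float(_ANALYTIC[definition_id](config.coding[site]))


# ---------------------------------------------------------------------------
# Truth table I/O

TRUTH_COLUMNS = ["patient_id", "site", "true_event_date", "mechanism", "subtrochanteric", "generated_claims"]


def write_truth(truths: Sequence[TruthRecord], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(TRUTH_COLUMNS)
        for t in truths:
            writer.writerow(
                [t.patient_id, t.site, t.true_event_date.isoformat(), t.mechanism,
                 int(t.subtrochanteric), ";".join(t.generated_claims)]
            )


def read_truth(path) -> list[TruthRecord]:
    out = []
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle):
            out.append(
                TruthRecord(
                    row["patient_id"], row["site"],
                    dt.date.fromisoformat(row["true_event_date"]), row["mechanism"],
                    bool(int(row["subtrochanteric"])),
                    tuple(c for c in row["generated_claims"].split(";") if c),
                )
            )
    return out
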