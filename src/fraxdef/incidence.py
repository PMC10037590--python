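"""Person-time, incidence rates, capture proportions, and report assembly.

The headline comparison for each fracture site is a table with one row per
definition: events captured (N), percent of the referent (the most
inclusive definition), crude incidence per 10,000 person-years, and median
time to fracture with interquartile range — plus, for each sensitivity
variant, the percent of the primary count retained and the absolute change
in incidence.

Person-time is censored on death or administrative end of follow-up and is
NOT censored at fracture, so every definition shares one denominator and
the ratio of two definitions' displayed rates equals the ratio of their
counts up to display rounding.  Years are 365.25 days; table cells use
half-up rounding at one decimal.
"""

from __future__ import annotations

import io
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .claims_model import PatientRecord, follow_up_end

__all__ = [
    "person_years",
    "total_person_years",
    "incidence_rate",
    "pct_captured",
    "median_time_to_fracture",
    "build_report",
    "render",
    "round_half_up",
    "REPORT_COLUMNS",
]

DAYS_PER_YEAR = 365.25


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (5 rounds away from zero), as printed tables use."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def person_years(patient: PatientRecord) -> float:
    """Follow-up time: (min(death, study end) − index) / 365.25.

    The same for every definition — fracture does not censor.
    """
    span = (follow_up_end(patient) - patient.index_date).days
    if span < 0:
        raise ValueError(f"negative follow-up for patient {patient.patient_id}")
    return span / DAYS_PER_YEAR


def total_person_years(cohort: Sequence[PatientRecord]) -> float:
    return float(sum(person_years(p) for p in cohort))


def incidence_rate(n: int, total_py: float) -> float:
    """Crude rate per 10,000 person-years (unrounded; round for display)."""
    if total_py <= 0:
        raise ValueError("total person-years must be positive")
    return n / total_py * 10_000


def pct_captured(n_def: int, n_ref: int, decimals: int = 1) -> float:
    """Percent of the referent definition's events captured, half-up rounded."""
    if n_ref <= 0:
        raise ValueError("referent count must be positive")
    return round_half_up(100.0 * n_def / n_ref, decimals)


def median_time_to_fracture(
    events: pd.DataFrame, patients: Sequence[PatientRecord]
) -> tuple[float, tuple[float, float]] | None:
    """Median years from index to event, with [Q1, Q3], over patients with an
    event; quartiles by linear interpolation.  None when there are no events."""
    with_event = events[events["event_date"].notna()]
    if with_event.empty:
        return None
    index_by_id = {p.patient_id: pd.Timestamp(p.index_date) for p in patients}
    years = np.array(
        [
            (row.event_date - index_by_id[row.patient_id]).days / DAYS_PER_YEAR
            for row in with_event.itertuples()
        ]
    )
    q1, med, q3 = np.percentile(years, [25, 50, 75])  # linear interpolation
    return float(med), (float(q1), float(q3))


REPORT_COLUMNS = [
    "definition_id",
    "variant",
    "n_fractures",
    "pct_of_referent",
    "person_years",
    "rate_per_10k_py",
    "median_years",
    "iqr_low",
    "iqr_high",
    "pct_of_primary",
    "delta_incidence",
]


def build_report(
    event_tables: Mapping[str, pd.DataFrame],
    cohort: Sequence[PatientRecord],
    referent_id: str,
    definition_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-definition report from the primary and variant tables.

    ``event_tables`` maps variant labels to event tables and must contain
    ``"primary"``.  Sensitivity rows carry percent-of-primary and the
    absolute incidence change (primary rate − variant rate); a variant
    listed with no table is reported as absent, never as zero.
    """
    if "primary" not in event_tables:
        raise ValueError("event_tables must contain a 'primary' table")
    primary = event_tables["primary"]
    if definition_order is None:
        definition_order = list(dict.fromkeys(primary["definition_id"]))
    if referent_id not in set(primary["definition_id"]):
        raise ValueError(f"referent {referent_id!r} not in the primary table")

    total_py = total_person_years(cohort)

    def counts(table: pd.DataFrame) -> dict[str, int]:
        with_event = table[table["event_date"].notna()]
        found = with_event.groupby("definition_id").size().to_dict()
        return {d: int(found.get(d, 0)) for d in definition_order}

    primary_counts = counts(primary)
    n_ref = primary_counts[referent_id]

    rows = []
    for variant, table in event_tables.items():
        if table is None:
            continue  # absent variant: no rows, not zeros
        variant_counts = counts(table) if variant != "primary" else primary_counts
        for defn in definition_order:
            n = variant_counts[defn]
            rate = round_half_up(incidence_rate(n, total_py), 1)
            med = median_time_to_fracture(table[table["definition_id"] == defn], cohort)
            if med is None:
                med_years = iqr_low = iqr_high = np.nan
            else:
                med_years = round_half_up(med[0], 1)
                iqr_low, iqr_high = (round_half_up(q, 1) for q in med[1])
            row = {
                "definition_id": defn,
                "variant": variant,
                "n_fractures": n,
                "pct_of_referent": pct_captured(n, n_ref) if variant == "primary" else np.nan,
                "person_years": round_half_up(total_py, 1),
                "rate_per_10k_py": rate,
                "median_years": med_years,
                "iqr_low": iqr_low,
                "iqr_high": iqr_high,
                "pct_of_primary": np.nan,
                "delta_incidence": np.nan,
            }
            if variant != "primary":
                n_primary = primary_counts[defn]
                primary_rate = round_half_up(incidence_rate(n_primary, total_py), 1)
                row["pct_of_primary"] = (
                    pct_captured(n, n_primary) if n_primary > 0 else np.nan
                )
                row["delta_incidence"] = round_half_up(primary_rate - rate, 1)
            rows.append(row)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def render(rows: pd.DataFrame, fmt: str = "csv") -> str:
    """Serialize a report as CSV (round-trip parseable) or a markdown table."""
    if fmt == "csv":
        buffer = io.StringIO()
        rows.to_csv(buffer, index=False)
        return buffer.getvalue()
    if fmt == "markdown":
        header = "| " + " | ".join(REPORT_COLUMNS) + " |"
        rule = "| " + " | ".join("---" for _ in REPORT_COLUMNS) + " |"
        lines = [header, rule]
        for row in rows.itertuples(index=False):
            cells = ["" if (isinstance(v, float) and np.isnan(v)) else str(v) for v in row]
            lines.append("| " + " | ".join(cells) + " |")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {fmt!r}")
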