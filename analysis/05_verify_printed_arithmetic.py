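"""Verify the published-table arithmetic from the printed counts.

The published Ontario-cohort results cannot be recomputed (the person-level
data are not redistributable), but every percent-captured, rate, and
percent-reduction cell is an exact function of the printed counts and the
shared person-time denominator.  This script feeds the printed counts
through the report arithmetic and checks each derived cell against the
printed one.
"""

from fraxdef import ontario_reference as ref
from fraxdef.incidence import incidence_rate, pct_captured, round_half_up


def check(label: str, got: float, printed: float) -> bool:
    ok = got == printed
    print(f"  {label}: computed {got} / printed {printed} {'OK' if ok else 'MISMATCH'}")
    return ok


def main() -> None:
    failures = 0
    print("hip: percent captured relative to the referent definition")
    n_ref = ref.HIP_COUNTS["hip-01"]
    for defn, n in ref.HIP_COUNTS.items():
        failures += not check(defn, pct_captured(n, n_ref), ref.HIP_PCT_CAPTURED[defn])

    print("hip: incidence from the shared person-time denominator "
          f"({ref.implied_person_years('hip'):.0f} PY)")
    py = ref.implied_person_years("hip")
    for defn, n in ref.HIP_COUNTS.items():
        failures += not check(
            defn, round_half_up(incidence_rate(n, py), 1), ref.HIP_RATES[defn])

    print("radius/ulna: percent captured")
    n_ref = ref.RU_COUNTS["ru-01"]
    for defn, n in ref.RU_COUNTS.items():
        failures += not check(defn, pct_captured(n, n_ref), ref.RU_PCT_CAPTURED[defn])

    print("radius/ulna: incidence (definitions with consistent printed cells)")
    py = ref.implied_person_years("radius_ulna")
    for defn, rate in ref.RU_RATES.items():
        failures += not check(
            defn, round_half_up(incidence_rate(ref.RU_COUNTS[defn], py), 1), rate)

    print("prose-style reductions")
    failures += not check(
        "inpatient-only hip definition identifies 8% fewer",
        round_half_up(100 * (ref.HIP_COUNTS["hip-01"] - ref.HIP_COUNTS["hip-02"]) / ref.HIP_COUNTS["hip-01"], 0),
        8.0)
    failures += not check(
        "primary-diagnosis restriction keeps 94% of the inpatient definition",
        round_half_up(100 * ref.HIP_02_PRIMARY_DX_COUNT / ref.HIP_COUNTS["hip-02"], 0),
        94.0)
    failures += not check(
        "inpatient/emergency-only radius definition captures 78%",
        round_half_up(100 * ref.RU_COUNTS["ru-05"] / ref.RU_COUNTS["ru-01"], 0),
        78.0)

    print(f"\n{failures} mismatch(es)")
    raise SystemExit(1 if failures else 0)


if __name__ == "__main__":
    main()
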