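"""Evaluate all twenty fracture definitions over the simulated claims.

Reads the tables written by 01_simulate.py, runs the definition engine for
both sites, writes the per-(patient, definition) event tables, and prints
each definition's event count together with the share of ground-truth
events it captured.
"""

import argparse
from pathlib import Path

from fraxdef.claims_model import read_claims, read_patients
from fraxdef.codesets import default_registry
from fraxdef.definitions import builtin_definitions, run_definitions
from fraxdef.simulate import read_truth


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--secondary-cohort-mode", action="store_true",
                        help="no procedure codes in emergency data")
    args = parser.parse_args()

    patients = read_patients(args.data / "patients.csv")
    claims = []
    for setting in ("inpatient", "emergency", "outpatient"):
        claims.extend(read_claims(args.data / f"claims_{setting}.csv", setting))
    truths = read_truth(args.data / "truth.csv")
    registry = default_registry()

    args.out.mkdir(parents=True, exist_ok=True)
    for site, tag in (("hip", "hip"), ("radius_ulna", "ru")):
        defs = builtin_definitions(site, secondary_cohort_mode=args.secondary_cohort_mode)
        table = run_definitions(patients, claims, defs, registry)
        table.to_csv(args.out / f"events_{tag}.csv", index=False)
        n_true = sum(t.site == site for t in truths)
        found = table[table.event_date.notna()].groupby("definition_id").size()
        print(f"\n{site}: {n_true} true events")
        for d in defs:
            n = int(found.get(d.definition_id, 0))
            print(f"  {d.definition_id} ({d.description}): {n} events, "
                  f"{100 * n / n_true:.1f}% of truth")
    print(f"\nevent tables written to {args.out}/")


if __name__ == "__main__":
    main()
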