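"""Generate the synthetic cohort and claims tables.

Draws a cohort of older adults (index dates April 2003 - December 2016,
followed to March 2020 or death) with hip and radius/ulna fracture events,
expands each event into inpatient/emergency/outpatient claims through the
per-site coding models, and writes the four tables plus the ground-truth
event list under results/data/.
"""

import argparse
from pathlib import Path

from fraxdef.claims_model import write_claims, write_patients
from fraxdef.simulate import SimulationConfig, simulate, write_truth


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-patients", type=int, default=10_000)
    parser.add_argument("--out", type=Path, default=Path("results/data"))
    args = parser.parse_args()

    config = SimulationConfig(seed=args.seed, n_patients=args.n_patients)
    patients, claims, truths = simulate(config)

    args.out.mkdir(parents=True, exist_ok=True)
    write_patients(patients, args.out / "patients.csv")
    for setting in ("inpatient", "emergency", "outpatient"):
        write_claims(claims[setting], args.out / f"claims_{setting}.csv")
    write_truth(truths, args.out / "truth.csv")

    n_hip = sum(t.site == "hip" for t in truths)
    n_ru = len(truths) - n_hip
    print(f"cohort: {len(patients)} patients (seed {args.seed})")
    print(f"true events: {n_hip} hip, {n_ru} radius/ulna")
    for setting in ("inpatient", "emergency", "outpatient"):
        print(f"claims[{setting}]: {len(claims[setting])}")
    print(f"tables written to {args.out}/")


if __name__ == "__main__":
    main()
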