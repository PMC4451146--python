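"""Build the four analysis cohorts with eligibility filtering.

Applies the eligibility chain (born before 1900; father and both
grandfathers' ages known; social class known; outcome-specific follow-up
rules) to the simulated pedigree and writes each cohort plus its attrition
ledger to results/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SCRATCH, get_population

from lineage_load.pedigree import OUTCOMES, build_cohort


def main() -> None:
    sim = get_population()
    attrition_rows = []
    for outcome in OUTCOMES:
        result = build_cohort(sim.pedigree, outcome)
        result.table.to_csv(SCRATCH / f"cohort_{outcome}.csv", index=False)
        print(f"{outcome}: {result.n_candidates} candidates -> {len(result.table)} rows")
        for step, n in result.attrition.items():
            attrition_rows.append({"outcome": outcome, "filter": step, "excluded": n})
            if n:
                print(f"  -{n:6d}  {step}")
    pd.DataFrame(attrition_rows).to_csv(RESULTS / "attrition.csv", index=False)
    print("\ncohorts written to scratch/, attrition ledger to results/attrition.csv")


if __name__ == "__main__":
    main()
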