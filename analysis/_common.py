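"""Shared setup for the analysis scripts: one default simulated population,
cached under scratch/ so the numbered steps can be run independently."""

from pathlib import Path

import pandas as pd

from lineage_load.pedigree import Pedigree, read_pedigree, write_pedigree
from lineage_load.synthetic_data import SimulatedCohort, SimulationConfig, simulate_population

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

#: The study population analysed by scripts 01-05: five generations under
#: default demography and selection.  The ancestral-age effect on survival
#: is only ~-0.02 per WMAMA year on the logit scale, so the narrative run
#: uses a population large enough (~30k probands) for the point estimate to
#: be resolved against its standard error; calibration across many smaller
#: replicates lives in 06_calibration.py and the test-suite.
STUDY_CONFIG = SimulationConfig(n_founder_couples=6000, n_generations=5, seed=20150601)


def get_population() -> SimulatedCohort:
    """Simulate (or reload) the study population; deterministic in the seed."""
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    ped_path = SCRATCH / "pedigree.tsv"
    truth_path = SCRATCH / "truth.csv"
    if ped_path.exists() and truth_path.exists():
        pedigree = read_pedigree(ped_path)
        truth = pd.read_csv(truth_path)
        return SimulatedCohort(pedigree=pedigree, truth=truth, config=STUDY_CONFIG)
    sim = simulate_population(STUDY_CONFIG)
    write_pedigree(sim.pedigree, ped_path)
    sim.truth.to_csv(truth_path, index=False)
    return sim
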