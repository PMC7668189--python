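"""Shared study configuration for the numbered analysis scripts.

One mid-scale synthetic cohort (300 genes, ~45k discovery variants,
~5k validation variants, 24 protein classes) stands in for the study
cohort; the seed is fixed so every script sees the same data. Full
study-scale generation (1,330 genes) is a one-line config change but
adds nothing to the narrative here.
"""

from pathlib import Path

from var3d.simulate import SimulationConfig, simulate_cohort

STUDY_SEED = 20

REPO = Path(__file__).resolve().parents[1]
RESULTS = REPO / "results"
SCRATCH = REPO / "scratch"


def study_config(seed: int = STUDY_SEED) -> SimulationConfig:
    return SimulationConfig(seed=seed, n_genes=300)


def study_cohort(seed: int = STUDY_SEED):
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    return simulate_cohort(study_config(seed))
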