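"""Shared paths and study configurations for the numbered analysis scripts.

Two synthetic cohorts at the default study scale (827 ancient + 250 modern
samples, 1,200 variants, 20 trait QTLs): one whose trait-increasing alleles
experience genic selection (s = 0.05) through the post-Neolithic epoch, and
one fully neutral control. Raw cohort files live under scratch/ (regenerated
on demand); result tables go to results/.
"""

import os

from paleoprs.simulate import SimulationConfig

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
SCRATCH = os.path.join(ROOT, "scratch", "cohorts")
RESULTS = os.path.join(ROOT, "results")

SEED = 20260923

COHORTS = {
    "selected": SimulationConfig(seed=SEED, selection_coeff=0.05),
    "neutral": SimulationConfig(seed=SEED + 1),
}


def cohort_dir(name: str) -> str:
    return os.path.join(SCRATCH, name)


def ensure_dirs() -> None:
    os.makedirs(SCRATCH, exist_ok=True)
    os.makedirs(RESULTS, exist_ok=True)
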