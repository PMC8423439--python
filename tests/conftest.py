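"""Shared fixtures: tiny hand-built panels and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from paleoprs.panels import GenotypePanel
from paleoprs.simulate import SimulationConfig, generate_panel


def make_panel(dosage, chrom=None, pos=None, allele1=None, allele2=None,
               ploidy=None, sample_ids=None) -> GenotypePanel:
    """Build a small panel from a dosage matrix with sensible defaults."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    variants = pd.DataFrame({
        "id": [f"v{j}" for j in range(m)],
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
        "allele1": allele1 if allele1 is not None else ["A"] * m,
        "allele2": allele2 if allele2 is not None else ["G"] * m,
    })
    return GenotypePanel(
        sample_ids=sample_ids or [f"s{i}" for i in range(n)],
        variants=variants,
        dosage=dosage,
        ploidy=np.array(ploidy, dtype=object) if ploidy is not None else None,
    )


def small_config(**overrides) -> SimulationConfig:
    """A fast cohort: four periods, 200 variants, defaults otherwise."""
    kwargs = dict(
        seed=11,
        n_variants=200,
        n_trait_variants=20,
        sample_counts={"Mesolithic": 20, "Neolithic": 30, "PostNeolithic": 30, "Modern": 20},
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def sim_neutral():
    """One neutral simulated cohort reused across read-only tests."""
    return generate_panel(small_config())


@pytest.fixture(scope="session")
def sim_selected():
    """One cohort with directional selection planted on the trait alleles."""
    return generate_panel(small_config(seed=12, selection_coeff=0.05, n_variants=300))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
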