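"""Shared fixtures: small simulated cohorts built fresh per session."""

import numpy as np
import pandas as pd
import pytest

from stratlab import (
    GenotypeMatrix,
    PopulationModel,
    simulate_covariates,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def two_pop_model():
    return PopulationModel.from_divergences(
        [0.01, 0.01], n_variants=2000, pop_labels=["a", "b"],
        pop_scores=[0.0, 1.0],
    )


@pytest.fixture(scope="session")
def two_pop_cohort(two_pop_model):
    """600-sample, 2,000-variant cohort from two populations (pairwise F=0.01)."""
    geno = simulate_genotypes(two_pop_model, [300, 300], seed=11)
    samples = simulate_covariates(geno, two_pop_model, seed=12)
    return geno, samples


@pytest.fixture(scope="session")
def unstructured_cohort():
    """Single-population (F=0) cohort: no structure by construction."""
    model = PopulationModel.from_divergences(
        [0.0], n_variants=1500, pop_labels=["only"]
    )
    geno = simulate_genotypes(model, [500], seed=21)
    samples = simulate_covariates(geno, model, seed=22)
    return geno, samples


def make_genotypes(dosages, chrom=None, pos=None, a1=None, a2=None, ids=None):
    """Hand-built GenotypeMatrix for toy examples."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "variant_id": ids if ids is not None else [f"v{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
            "allele1": a1 if a1 is not None else ["A"] * m,
            "allele2": a2 if a2 is not None else ["G"] * m,
        }
    )
    sample_ids = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(dosages, variants, sample_ids)


@pytest.fixture
def toy_genotypes():
    rng = np.random.default_rng(5)
    return make_genotypes(rng.integers(0, 3, size=(40, 12)).astype(float))
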