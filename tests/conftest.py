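import numpy as np
import pandas as pd
import pytest

from heightprs.containers import GenotypeMatrix, TrioCohort
from heightprs.simulate import SimulationParams, simulate_cohort


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    return SimulationParams(n_families=600, n_loci=120, n_causal=15, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    """A 600-family cohort with genotypes, reused across read-only tests."""
    return simulate_cohort(small_params)


@pytest.fixture(scope="session")
def medium_cohort():
    """20k families for moment-level checks (variance shares, correlations)."""
    params = SimulationParams(n_families=20_000, n_loci=400, n_causal=40, seed=5)
    cohort, _ = simulate_cohort(params, with_growth=False)
    return cohort, params


@pytest.fixture()
def toy_genotypes() -> GenotypeMatrix:
    variants = pd.DataFrame(
        {
            "id": ["v1", "v2", "v3"],
            "chrom": "1",
            "pos": [100, 200, 300],
            "effect_allele": ["A", "C", "G"],
            "other_allele": ["G", "T", "A"],
        }
    )
    dosages = np.array([[0, 1, 2], [1, 0, 1], [2, 2, 0]], dtype=np.int8)
    return GenotypeMatrix(
        sample_ids=np.array(["s1", "s2", "s3"], dtype=object),
        variants=variants,
        dosages=dosages,
    )


@pytest.fixture()
def tiny_cohort() -> TrioCohort:
    fam = pd.DataFrame(
        {
            "family_id": ["f1", "f2", "f3", "f4"],
            "child_id": ["c1", "c2", "c3", "c4"],
            "mother_id": ["m1", "m2", "m3", "m4"],
            "father_id": ["p1", "p2", "p3", "p4"],
            "sex": ["F", "M", "F", "M"],
            "adult_height_cm": [162.0, 177.5, 158.4, 181.2],
            "mother_height_cm": [160.0, 165.2, np.nan, 170.0],
            "father_height_cm": [173.0, 180.1, 175.5, np.nan],
            "true_genetic_value_cm": [0.5, 1.2, -2.0, 3.1],
        }
    )
    return TrioCohort(families=fam)
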