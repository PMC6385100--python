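import numpy as np
import pandas as pd
import pytest

from clinstrat import align_tables, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact planted-structure cohort shared by read-only tests."""
    return simulate_cohort(
        n_samples=60,
        n_genes=200,
        n_subtypes=3,
        n_informative_per_subtype=20,
        effect_size=2.0,
        clinical_link_strength=0.9,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_cohort):
    c = small_cohort
    return align_tables(c.expression, c.clinical, c.outcomes, c.labels)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_expression(values, gene_ids=None, sample_ids=None):
    from clinstrat import ExpressionMatrix

    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
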