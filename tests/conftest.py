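import numpy as np
import pandas as pd
import pytest

from planmet import GeneratorConfig, generate_metabolomics


def make_sheet(rows):
    """Helper: sheet rows are (sample_id, tissue, genotype, treatment,
    age_days, replicate, is_blank)."""
    return pd.DataFrame(rows, columns=["sample_id", "tissue", "genotype",
                                       "treatment", "age_days", "replicate",
                                       "is_blank"])


@pytest.fixture
def tiny_sheet():
    """2 design cells (2 samples each) plus one extraction blank."""
    return make_sheet([
        ("s1", "brain", "g1", "control", 7, 1, False),
        ("s2", "brain", "g1", "control", 7, 2, False),
        ("s3", "brain", "g1", "DA", 7, 1, False),
        ("s4", "brain", "g1", "DA", 7, 2, False),
        ("b1", "", "", "", 0, 1, True),
    ])


@pytest.fixture(scope="session")
def small_design():
    """One tissue, both genotypes, reduced panel: fast but full-featured."""
    cfg = GeneratorConfig(n_metabolites=60, n_pathways=6,
                          tissues=("brain",), n_contaminants=5, seed=7)
    return generate_metabolomics(cfg)


@pytest.fixture(scope="session")
def full_design():
    """The emulated study design at its default size."""
    return generate_metabolomics(GeneratorConfig(seed=11))


@pytest.fixture
def balanced_data():
    """Random balanced 2 x 4 x 3 factorial response."""
    rng = np.random.default_rng(42)
    treatment = np.repeat(["control", "DA"], 12)
    age = np.tile(np.repeat([7, 14, 19, 24], 3), 2)
    values = rng.normal(size=24)
    return values, treatment, age
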