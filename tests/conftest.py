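import pandas as pd
import pytest

from motera import (ExpressionMatrix, SampleTable, SimulationConfig,
                    generate_cohort, generate_gene_sets)


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 genes x 2 samples with hand-typed values."""
    values = pd.DataFrame(
        {"s1": [1.0, 4.0, 9.5], "s2": [2.0, 0.0, 7.25]},
        index=["GREB1", "TFF1", "PGR"],
    )
    return ExpressionMatrix(values, "linear_TPM")


@pytest.fixture
def toy_samples() -> SampleTable:
    return SampleTable(pd.DataFrame({
        "sample_id": ["s1", "s2"],
        "group": ["g1", "g2"],
        "group_class": ["active", "control"],
        "e2": ["minus_E2", "minus_E2"],
        "truth_active": [True, False],
    }))


@pytest.fixture(scope="session")
def training_cohort():
    """Default T47D-like training design, one fixed seed."""
    cfg = SimulationConfig(seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def training_gene_sets():
    return generate_gene_sets(SimulationConfig(seed=7), extra_random_sets=2)
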