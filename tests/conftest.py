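import warnings

import numpy as np
import pandas as pd
import pytest

from pairlnc.datatypes import ExpressionMatrix
from pairlnc.synthetic_data import (SimulationConfig, generate_immune_panel,
                                    generate_tumor_cohort)

# lifelines emits convergence chatter on tiny fixtures; keep test output clean
warnings.filterwarnings("ignore", category=UserWarning, module="lifelines")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Down-scaled study conditions shared by the unit tests."""
    return SimulationConfig(
        seed=7,
        n_lncrnas=60,
        n_specific=8,
        n_patients=150,
        n_normals=12,
        n_mrnas=120,
        n_de_mrnas=15,
        immune_set_size=15,
        n_mirnas=20,
        n_planted_triads=4,
    )


@pytest.fixture(scope="session")
def panel(small_config):
    return generate_immune_panel(small_config)


@pytest.fixture(scope="session")
def cohort(small_config):
    return generate_tumor_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_expression(rng, n_genes=6, n_samples=10, biotype="lncRNA"):
    genes = [f"G{i:02d}" for i in range(n_genes)]
    samples = [f"s{j:02d}" for j in range(n_samples)]
    vals = rng.normal(5.0, 2.0, (n_genes, n_samples))
    return ExpressionMatrix(
        pd.DataFrame(vals, index=genes, columns=samples),
        pd.Series(biotype, index=genes),
    )
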