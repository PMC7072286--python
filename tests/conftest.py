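import numpy as np
import pandas as pd
import pytest

from gbpal import (
    CNRMatrix,
    ExpressionMatrix,
    PathwayDB,
    PathwayDefinition,
    SyntheticConfig,
    simulate_cohort,
)


@pytest.fixture
def small_db() -> PathwayDB:
    return PathwayDB(
        [
            PathwayDefinition("P1", "activator only", {"A": 1.0}),
            PathwayDefinition("P2", "mixed", {"A": 1.0, "B": -0.5}),
            PathwayDefinition("P3", "balanced", {"A": 1.0, "B": -1.0}),
            PathwayDefinition("P4", "with neutral", {"A": 1.0, "C": 0.0, "D": 0.5}),
        ]
    )


@pytest.fixture
def unit_cnr() -> CNRMatrix:
    genes = ["A", "B", "C", "D"]
    return CNRMatrix(pd.DataFrame(1.0, index=genes, columns=["s1", "s2"]))


def expr(values, genes=None, samples=None, normalized=False) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), is_normalized=normalized
    )


@pytest.fixture(scope="session")
def demo_cohort():
    """A mid-sized seeded cohort with planted recurrence signal, shared
    across tests that only read from it."""
    cfg = SyntheticConfig(
        seed=7,
        n_genes=800,
        n_pathways=40,
        n_patients=12,
        regions_per_tumor=2,
        paired_fraction=0.5,
        gsc_fraction=0.5,
        n_normals=6,
        planted_pathways=[("P005", "recGB-up", 1.0), ("P006", "recGB-down", 1.0)],
        planted_genes=[("MGMT", "recGB-up", 1.0)],
    )
    return simulate_cohort(cfg)
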