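import numpy as np
import pandas as pd
import pytest

from mgtkit import ExpressionMatrix, GeneModel, SimulationConfig
from mgtkit.simulate import generate_annotation, sample_table, simulate_expression


def random_genes(rng: np.random.Generator, n: int, chrom_len: int = 40_000) -> list[GeneModel]:
    """Random, possibly tightly packed single-exon genes for oracle tests.

    Unlike the study generator, genes here may overlap each other so the
    exclusion logic is exercised hard.
    """
    genes = []
    for i in range(n):
        start = int(rng.integers(0, chrom_len - 3000))
        length = int(rng.integers(200, 3000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"G{i:03d}", "chr1", strand, start, start + length))
    return genes


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 tumour + 3 normal samples, 4 genes, hand-set FPKM."""
    meta = pd.DataFrame({
        "animal_id": ["a1", "a2", "a3"] * 2,
        "condition": ["tumor"] * 3 + ["normal"] * 3,
        "subtype": ["complex"] * 6,
    }, index=[f"s{i}" for i in range(6)])
    values = pd.DataFrame(
        [[8.0, 8.0, 8.0, 2.0, 2.0, 2.0],
         [5.0, 5.0, 5.0, 5.0, 5.0, 5.0],
         [1.0, 2.0, 3.0, 1.5, 2.5, 2.0],
         [0.0, 0.1, 0.0, 9.0, 8.0, 10.0]],
        index=["up_gene", "flat_gene", "noisy_gene", "down_gene"],
        columns=meta.index,
    )
    return ExpressionMatrix(values=values, meta=meta)


@pytest.fixture
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture
def simulated(default_config):
    genes = generate_annotation(default_config)
    expr = simulate_expression(genes, default_config)
    return genes, expr
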