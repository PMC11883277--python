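import numpy as np
import pandas as pd
import pytest

from arftargets import FactorialTargetModel, SimulationConfig
from arftargets.de import ContrastTable


@pytest.fixture(scope="session")
def study_model():
    """Synthetic experiment at the study design: 4x2x3, planted classes."""
    return FactorialTargetModel.simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def study_results(study_model):
    return study_model.fit()


@pytest.fixture
def tiny_counts():
    """4 genes x 4 samples, hand-sized."""
    return pd.DataFrame(
        {
            "WT_mock_r1": [10, 0, 5, 100],
            "WT_mock_r2": [12, 0, 7, 90],
            "ett_mock_r1": [11, 0, 40, 95],
            "ett_mock_r2": [9, 0, 50, 105],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )


def make_contrast(contrast_id: str, genes, log2fc, padj, base_mean=100.0):
    """Hand-built contrast table for classifier fixtures."""
    log2fc = np.asarray(log2fc, dtype=float)
    padj = np.asarray(padj, dtype=float)
    table = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "stat": np.where(padj < 0.5, np.sign(log2fc) * 5.0, 0.0),
            "p": padj,
            "padj": padj,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return ContrastTable(contrast_id=contrast_id, table=table,
                         excluded=pd.Index([]))
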