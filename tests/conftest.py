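import numpy as np
import pytest

from pathcord import ExpressionDataset


def make_dataset(values, genes=None, reporters=None, n_tumor=None, platform="A"):
    """Small literal dataset builder for unit tests."""
    values = np.asarray(values, dtype=float)
    n_rep, n_smp = values.shape
    if genes is None:
        genes = [f"G{i}" for i in range(n_rep)]
    if reporters is None:
        reporters = [f"{g}_r{i}" for i, g in enumerate(genes)]
    if n_tumor is None:
        n_tumor = n_smp // 2
    labels = ["tumor"] * n_tumor + ["normal"] * (n_smp - n_tumor)
    samples = [f"S{j}" for j in range(n_smp)]
    return ExpressionDataset(
        reporter_ids=list(reporters),
        gene_symbols=list(genes),
        values=values,
        sample_ids=samples,
        class_labels=labels,
        platform=platform,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
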