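import numpy as np
import pandas as pd
import pytest

from azasynergy import ShRNACountMatrix


def make_screen_matrix(counts: np.ndarray, genes: list[str], n_control: int, n_treated: int) -> ShRNACountMatrix:
    """Assemble a count matrix from a raw array and a gene list."""
    sample_names = [f"control_{i + 1}" for i in range(n_control)] + [
        f"treated_{i + 1}" for i in range(n_treated)
    ]
    idx = pd.Index([f"sh{i + 1}" for i in range(len(genes))], name="shrna_id")
    counts_df = pd.DataFrame(np.asarray(counts), index=idx, columns=sample_names)
    samples = pd.DataFrame(
        {
            "condition": ["control"] * n_control + ["treated"] * n_treated,
            "replicate": list(range(1, n_control + 1)) + list(range(1, n_treated + 1)),
        },
        index=pd.Index(sample_names, name="sample_id"),
    )
    return ShRNACountMatrix(counts=counts_df, genes=pd.Series(genes, index=idx), samples=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
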