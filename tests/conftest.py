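import numpy as np
import pandas as pd
import pytest

from tscoex import GeneratorParams, SampleExpressionMatrix, generate


def make_matrix(values, biotype, tissue_of_sample, is_pseudogene=None):
    """Build a SampleExpressionMatrix from plain dicts/frames.

    ``values``: mapping rna_id -> list of per-sample values (or a DataFrame);
    ``biotype``: mapping rna_id -> biotype; ``tissue_of_sample``: mapping
    sample_id -> tissue (ordered).
    """
    samples = list(tissue_of_sample)
    if not isinstance(values, pd.DataFrame):
        values = pd.DataFrame.from_dict(values, orient="index", columns=samples)
    rnas = list(values.index)
    if is_pseudogene is None:
        is_pseudogene = {r: False for r in rnas}
    return SampleExpressionMatrix(
        values=values.astype(float),
        biotype=pd.Series({r: biotype[r] for r in rnas}).reindex(rnas),
        is_pseudogene=pd.Series({r: bool(is_pseudogene[r]) for r in rnas}).reindex(rnas),
        tissue_of_sample=pd.Series(tissue_of_sample).reindex(samples),
    )


@pytest.fixture
def tiny_matrix():
    """3 RNAs x 4 samples over 2 tissues."""
    return make_matrix(
        values={
            "mi1": [1.0, 2.0, 0.0, 0.0],
            "ln1": [5.0, 5.0, 5.0, 5.0],
            "mr1": [0.0, 0.0, 3.0, 9.0],
        },
        biotype={"mi1": "miRNA", "ln1": "lncRNA", "mr1": "mRNA"},
        tissue_of_sample={"a1": "tissueA", "a2": "tissueA", "b1": "tissueB", "b2": "tissueB"},
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Default-parameter synthetic dataset (shared, read-only)."""
    return generate(GeneratorParams(seed=42))


def single_tissue_matrix(X, biotypes, tissue="tissueX", prefix="r"):
    """Matrix with one tissue from a raw (RNAs x samples) array."""
    m, n = X.shape
    rnas = [f"{prefix}{i}" for i in range(m)]
    samples = [f"s{i}" for i in range(n)]
    return make_matrix(
        values=pd.DataFrame(X, index=rnas, columns=samples),
        biotype=dict(zip(rnas, biotypes)),
        tissue_of_sample={s: tissue for s in samples},
    )
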