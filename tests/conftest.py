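import numpy as np
import pandas as pd
import pytest

from rasactivity import normalize, simulate
from rasactivity.datamodel import ExpressionMatrix, GeneSignature, Scale


@pytest.fixture(scope="session")
def cell_cohort():
    """Small cell-line cohort with a planted two-state activity factor."""
    return simulate.generate_cell_line_cohort(
        n_samples=120, n_genes=1200, n_signature_genes=80, effect_size=2.0,
        mutation_or=10.0, seed=11,
    )


@pytest.fixture(scope="session")
def vst_cohort(cell_cohort):
    expr, mutations, truth = cell_cohort
    return normalize.vst_like_transform(expr), mutations, truth


@pytest.fixture(scope="session")
def founder_signature(cell_cohort):
    """Planted genes plus 40 background decoys, as a founder signature."""
    expr, _, truth = cell_cohort
    decoys = [g for g in expr.gene_ids if g.startswith("BG")][:40]
    return GeneSignature(
        name="founder", genes=tuple(list(truth.planted_genes) + decoys),
        provenance="synthetic",
    ), decoys


@pytest.fixture(scope="session")
def rag_cohort():
    """Well-separated five-class cohort for classifier tests."""
    return simulate.generate_rag_cohort(
        n_samples=250, n_genes=25, n_informative=8, separation=3.0, seed=7
    )


@pytest.fixture()
def tiny_matrix():
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
        index=["g1", "g2"], columns=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(values=values, scale=Scale.vst_like)
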