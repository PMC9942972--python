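import numpy as np
import pandas as pd
import pytest

import attractorscape as ats
from attractorscape import pca


@pytest.fixture(scope="session")
def desk_tissue():
    """One default synthetic tissue run end-to-end through the pipeline."""
    m, s, truth = ats.generate_tissue(ats.SyntheticSpec(), seed=1)
    folds, ref = ats.fold_pipeline(m, s.normals)
    model = pca.orient(pca.top_components(pca.covariance_factor(folds)), folds, s)
    proj = pca.project(folds, model, s)
    return {
        "matrix": m,
        "samples": s,
        "truth": truth,
        "folds": folds,
        "ref": ref,
        "model": model,
        "proj": proj,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_expression(rng, n_genes=20, n_samples=6, zero_rows=0):
    vals = rng.lognormal(mean=1.0, sigma=1.0, size=(n_genes, n_samples))
    if zero_rows:
        vals[:zero_rows] = 0.0
    return ats.ExpressionMatrix(
        pd.DataFrame(
            vals,
            index=[f"G{i}" for i in range(n_genes)],
            columns=[f"S{j}" for j in range(n_samples)],
        )
    )


@pytest.fixture()
def small_matrix(rng):
    return random_expression(rng)
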