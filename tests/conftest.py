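import numpy as np
import pandas as pd
import pytest

import stacksdm as s


@pytest.fixture(scope="session")
def small_landscape() -> s.Landscape:
    return s.generate_landscape(
        s.LandscapeConfig(n_rows=20, n_cols=20, n_covariates=3, autocorr_range=3.0, seed=11)
    )


@pytest.fixture(scope="session")
def separable_design() -> s.DesignMatrix:
    """300 points whose label is a step function of the first covariate."""
    rng = np.random.default_rng(42)
    X = pd.DataFrame({"a": rng.uniform(-1, 1, 300), "b": rng.uniform(-1, 1, 300)})
    y = (X["a"].to_numpy() > 0).astype(int)
    return s.DesignMatrix(X=X, y=y)


@pytest.fixture(scope="session")
def separable_model(separable_design) -> s.BARTModel:
    return s.fit_bart(separable_design, s.BARTConfig.test_size(seed=7))


@pytest.fixture(scope="session")
def balanced_tree():
    import dendropy

    return dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
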