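import numpy as np
import pandas as pd
import pytest

import oxistress as ox


@pytest.fixture(scope="session")
def small_dataset():
    """A modest cohort with stage structure, shared across read-only tests."""
    cfg = ox.SyntheticConfig(n_samples=150, n_genes=80, n_controls=20,
                             n_stages=4, stage_effect=0.002, seed=11)
    return ox.generate(cfg)


@pytest.fixture(scope="session")
def trained(small_dataset):
    """A model trained on the small cohort's tumor samples, plus its inputs."""
    d = small_dataset
    rates = ox.mutation_rates(d.variants, list(d.expression.columns))
    annot = ox.EnzymeAnnotation(d.ec_map)
    tumor = d.metadata.index[d.metadata["group"] == "tumor"]
    model = ox.train_predictor(d.expression[tumor], rates.loc[tumor], annot,
                               ox.TrainConfig(n_restarts=2, seed=1))
    return d, rates, annot, model


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def random_regression_instance(rng, n, m, sigma=1.0):
    """A dense random OLS instance with known design and response."""
    X = pd.DataFrame(rng.standard_normal((n, m)),
                     columns=[f"g{j}" for j in range(m)])
    beta = rng.standard_normal(m)
    y = pd.Series(X.to_numpy() @ beta + sigma * rng.standard_normal(n))
    return X, y
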