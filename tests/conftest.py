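import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import phylou as pl

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

TRAIT_PAIR = ("promoter_methylation", "expression")


@pytest.fixture
def cherry():
    return pl.parse_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    return pl.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ou2_params():
    """Generic stable bivariate OU with cross-trait coupling."""
    return pl.OUParams(
        A=np.array([[2.0, 0.3], [1.0, 1.2]]),
        Sigma=np.array([[0.8, 0.0], [0.3, 0.8]]),
        theta=np.array([0.5, 5.0]),
        x0=np.array([0.5, 5.0]),
        model_class="OU_NONSTATIONARY",
    )


def make_trait_table(genes, traits, means, condition="control", variance=0.01, n=20):
    means = np.asarray(means, dtype=float)
    rows = []
    for i, g in enumerate(genes):
        for d, tr in enumerate(traits):
            rows.append(
                dict(gene=g, condition=condition, trait=tr,
                     mean=means[i, d], variance=variance, n=n)
            )
    return pl.TraitTable(pd.DataFrame(rows))


@pytest.fixture
def make_traits():
    return make_trait_table
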