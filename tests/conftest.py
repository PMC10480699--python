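import warnings

import numpy as np
import pytest

import phylorange as pr

# default candidate set used across pipeline tests: the six continuous
# correlates, the binary predation trait, and DD:AD (log, negative
# prediction: itinerant species fare worse)
CANDIDATES = (
    pr.Term("body_mass", sign="+"),
    pr.Term("metabolic_need", sign="+"),
    pr.Term("population_density", sign="-"),
    pr.Term("habitat_productivity", sign="-"),
    pr.Term("trophic_level", sign="+"),
    pr.Term("hippocampal_volume", sign="+"),
    pr.Term("predation_risk", sign="-"),
    pr.Term("ddad", "log", "-"),
)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*not ultrametric.*")
        warnings.filterwarnings("ignore", message=".*zero home-range.*")
        warnings.filterwarnings("ignore", message=".*log1p applied.*")
        yield


@pytest.fixture(scope="session")
def three_tip_tree():
    return pr.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def strong_study():
    """One strong-preset synthetic study reused by read-only tests."""
    return pr.simulate_study(pr.strong_preset(seed=3))


@pytest.fixture
def pipeline_config():
    return pr.PipelineConfig(candidates=CANDIDATES)


def random_regression(seed, n=40, lam=0.5, slope=1.0, sigma2=1.0):
    """A (tree, table) pair with a single planted linear effect x -> y."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    tree = pr.simulate_tree(n, seed=seed + 77_000)
    x = pr.simulate_bm_trait(tree, sigma2, lam, rng)
    noise = pr.simulate_bm_trait(tree, sigma2, lam, rng)
    y = slope * x + noise
    table = pd.DataFrame({"x": x, "y": y})
    table.index.name = "species"
    return tree, table
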