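import numpy as np
import pytest

from multinep.network import FeatureSet, MultiOmicsNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_features():
    return FeatureSet(genes=["G1", "G2", "G3"], metabolites=["M1", "M2"])


@pytest.fixture
def toy_network(toy_features):
    gg = np.array([[0, 900, 0], [900, 0, 300], [0, 300, 0]], dtype=float)
    mm = np.array([[0, 10], [10, 0]], dtype=float)
    gm = np.array([[500, 0], [0, 250], [100, 0]], dtype=float)
    return MultiOmicsNetwork(
        features=toy_features, gg=gg, mm=mm, gm=gm, weight_scale="raw_confidence"
    )


def random_network(rng, n_genes=8, n_metabolites=4, density=0.5, scale="raw_confidence"):
    """Random valid block network for property-style tests."""
    feats = FeatureSet(
        genes=[f"g{i}" for i in range(n_genes)],
        metabolites=[f"m{i}" for i in range(n_metabolites)],
    )
    top = 999 if scale == "raw_confidence" else 1
    gg = np.triu(rng.random((n_genes, n_genes)) * top, k=1)
    gg[np.triu(rng.random((n_genes, n_genes)), k=1) > density] = 0
    gg = gg + gg.T
    mm = np.triu(rng.random((n_metabolites, n_metabolites)) * top, k=1)
    mm = mm + mm.T
    gm = rng.random((n_genes, n_metabolites)) * top
    gm[rng.random((n_genes, n_metabolites)) > density] = 0
    return MultiOmicsNetwork(features=feats, gg=gg, mm=mm, gm=gm, weight_scale=scale)
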