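"""Shared fixtures: a miniature simulated SC/ST pair and a fitted model.

Everything is generated programmatically and seeded; the miniature pair
(120+120 cells, 400 genes, 3 populations) keeps per-test cost low while
exercising the full pipeline.
"""

from __future__ import annotations

import numpy as np
import pytest

from pseudospace import PseudoSpaceModel, SimConfig, simulate_paired


@pytest.fixture(scope="session")
def mini_pair():
    return simulate_paired(SimConfig(
        n_genes=400, n_sc=120, n_st=120, n_pops=3, seed=11,
    ))


@pytest.fixture(scope="session")
def mini_results(mini_pair):
    model = PseudoSpaceModel(
        mini_pair.sc, mini_pair.st, m=20, n_hvg=None, seed=11,
    )
    return model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
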