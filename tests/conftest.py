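"""Shared fixtures.

The benchmark fit (2000 simulated cells, 100 epochs) takes ~20 s and is
shared session-wide by the end-to-end tests; small fixtures are rebuilt per
test where mutation matters.
"""

from __future__ import annotations

import numpy as np
import pytest

import omicfuse as of


@pytest.fixture(scope="session")
def tiny_dataset():
    spec = of.SimulationSpec(
        K_true=3, n_cells=30, feature_dims=(8, 12), n_clusters=2,
        paired_fraction=0.5, seed=11,
    )
    return of.simulate(spec)


@pytest.fixture(scope="session")
def small_fit():
    """A quick but non-trivial fit used by several contract tests."""
    spec = of.SimulationSpec(
        K_true=3, n_cells=300, feature_dims=(80, 160), n_clusters=3,
        paired_fraction=0.3, seed=5,
    )
    dataset, truth = of.simulate(spec)
    config = of.TrainingConfig(K=5, epochs=60, annealing_epochs=20, seed=5)
    model = of.fit(dataset, config)
    return dataset, truth, model


@pytest.fixture(scope="session")
def benchmark_fit():
    """The full desk-scale benchmark: simulate, fit 100 epochs, embed, correct."""
    dataset, truth = of.simulate(of.default_benchmark_spec(seed=0))
    model = of.fit(dataset, of.TrainingConfig(K=10, seed=0))
    latents = of.posterior_means(model, dataset, subset_policy="with_singles")
    ids, Z, groups, corr_model = of.integrate(latents, seed=0)
    return {
        "dataset": dataset,
        "truth": truth,
        "model": model,
        "latents": latents,
        "ids": ids,
        "Z": Z,
        "groups": groups,
    }


def hidden_pair_views(ids: np.ndarray, Z: np.ndarray, truth: of.GroundTruth):
    """Query/reference coordinate blocks for the hidden pairs, identity pairing."""
    index = {c: i for i, c in enumerate(ids)}
    q_ids = list(truth.pairing.keys())
    r_ids = [truth.pairing[q] for q in q_ids]
    Zq = Z[[index[c] for c in q_ids]]
    Zr = Z[[index[c] for c in r_ids]]
    return Zq, Zr, np.arange(len(q_ids))
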