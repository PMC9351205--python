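"""Shared fixtures: phantoms and the planted-signal cohort are generated once.

The 400-patient cohort and its trained models are expensive (minutes), so
they are session-scoped and shared between the GCN unit tests and the
acceptance suite.
"""

from __future__ import annotations

import copy

import numpy as np
import pytest

from lunggraph.gcn import ModelConfig, TrainConfig, train
from lunggraph.phantom import CohortSpec, PhantomSpec, generate_phantom
from lunggraph.pipeline import build_cohort_graphs


@pytest.fixture(scope="session")
def phantom_noise_free():
    return generate_phantom(PhantomSpec(noise_sd_hu=0.0, seed=0))


@pytest.fixture(scope="session")
def phantom_default():
    return generate_phantom(PhantomSpec(seed=0))


COHORT_N = 400
COHORT_SEED = 11


@pytest.fixture(scope="session")
def cohort400():
    """400 planted-signal phantom graphs (beta = ln2 per cm), split 75/12.5/12.5."""
    cs = CohortSpec(n_patients=COHORT_N, seed=COHORT_SEED)
    return build_cohort_graphs(cs, split_seed=COHORT_SEED)


def _permute_labels(graphs, seed):
    rng = np.random.default_rng(seed)
    out = [copy.deepcopy(g) for g in graphs]
    perm = rng.permutation([g.label for g in out])
    for g, l in zip(out, perm):
        g.label = int(l)
    return out


@pytest.fixture(scope="session")
def cohort400_models(cohort400):
    """Trained + permuted-label models for three fixed seeds on the shared cohort."""
    tr = cohort400.subset(cohort400.split.train)
    va = cohort400.subset(cohort400.split.val)
    mc = ModelConfig(n_blocks=2, hidden_dim=32, dropout_p=0.3)
    results = {}
    for seed in (0, 1, 3):
        tc = TrainConfig(epochs=60, seed=seed)
        trained = train(tr, va, mc, tc)
        control = train(_permute_labels(tr, seed), _permute_labels(va, seed), mc, tc)
        results[seed] = (trained, control)
    return results
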