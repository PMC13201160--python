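"""Shared fixtures: synthetic bundles at two scales and fitted results.

The heavier fixtures are session-scoped so the parameter-recovery and
interpretability suites share one fit.
"""

import numpy as np
import pytest

from midas import GINConfig, SynthConfig, TargetDiscoveryModel, generate


@pytest.fixture(scope="session")
def small_bundle():
    """500-gene fixture with the default planted signal."""
    return generate(SynthConfig(n_genes=500, n_positives=40, n_timesliced=15,
                                pathway_size=40, seed=7))


@pytest.fixture(scope="session")
def small_results(small_bundle):
    """Fast fit (2x5 CV, 40 epochs) used by invariant and interpretability
    tests."""
    model = TargetDiscoveryModel.from_synthetic(
        small_bundle, config=GINConfig(d_in=20, epochs=40)
    )
    return model.fit(seed=7, repeats=2, folds=5)


@pytest.fixture(scope="session")
def desk_bundle():
    """The benchmark study conditions: 2,000 genes, 100 positives,
    effect 1.5 SD on 3 of 20 features, homophily 0.3."""
    return generate(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def desk_results(desk_bundle):
    """Full protocol at desk scale with a 2x5 CV plan."""
    model = TargetDiscoveryModel.from_synthetic(desk_bundle)
    return model.fit(seed=11, repeats=2, folds=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
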