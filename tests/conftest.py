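import numpy as np
import pytest

from designscreen import library, surrogate, synthetic

STRATEGIES = ["MD", "CONCOORD", "Backrub"]


@pytest.fixture(scope="session")
def gt():
    return synthetic.make_ground_truth(seed=11)


@pytest.fixture(scope="session")
def candidates(gt):
    return synthetic.simulate_design_candidates(gt, STRATEGIES, 2000, seed=12)


@pytest.fixture(scope="session")
def selected(candidates):
    return library.select_top_candidates(candidates, 300)


@pytest.fixture(scope="session")
def count_table(selected, gt):
    return synthetic.simulate_selection_counts(selected, gt, rounds=4, depth=100_000, seed=13)


@pytest.fixture(scope="session")
def small_ensemble(count_table):
    """A quick 10-forest surrogate for unit tests (full protocol lives in
    the acceptance suite)."""
    counts = count_table.counts(count_table.channels[0]).sort_values(ascending=False)
    positives = [(s, float(c)) for s, c in counts.head(120).items()]
    with pytest.warns(UserWarning, match="degenerate"):
        return surrogate.train(positives, n_models=10, grid=((3,), (7,)), seed=14, n_trees=30)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


from hypothesis import HealthCheck, settings as _hyp_settings

_hyp_settings.register_profile(
    "default", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
_hyp_settings.load_profile("default")
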