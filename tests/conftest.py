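import pytest

from elderhealth import pipeline, synthetic


@pytest.fixture(scope="session")
def demo_truth():
    return pipeline.demo_truth(seed=7)


@pytest.fixture(scope="session")
def small_panel(demo_truth):
    """A 2,000-person two-wave panel from the demo ground truth."""
    return synthetic.simulate_panel(demo_truth, n=2000)


@pytest.fixture(scope="session")
def big_panel(demo_truth):
    """A 50,000-person panel for convergence/recovery checks."""
    return synthetic.simulate_panel(demo_truth, n=50_000)
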