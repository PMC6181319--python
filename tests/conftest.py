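import pytest

import thermobind as tb


@pytest.fixture(scope="session")
def schedule():
    """Default 28 x 10 uL titration program."""
    return tb.default_schedule()


@pytest.fixture(scope="session")
def egcg_truth():
    """Strongest natural gallated catechin: K_D 2.2 uM, dH -4.7 kcal/mol."""
    return tb.GroundTruth("EGCg", n_sites=1.1, kd=2.2e-6, dh=-4.7)


@pytest.fixture(scope="session")
def sparse_complex():
    """Toy pocket with exact analytic BSA ground truth."""
    return tb.synth_toy_complex(seed=11)


@pytest.fixture(scope="session")
def dense_complex():
    """Concave cradle pocket with a genuinely mating surface."""
    return tb.synth_toy_complex(seed=11, pocket_style="dense")
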