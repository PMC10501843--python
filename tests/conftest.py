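import numpy as np
import pytest

from relaxedcq.datasets import SyntheticSpec, make_classification_table, make_sfp_instance


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def feasible_l2_instance():
    """A 20x10 feasible SFP instance with an L2-ball C and a planted solution."""
    return make_sfp_instance(m=20, n=10, constraint="l2_ball", seed=42)


@pytest.fixture(scope="session")
def feasible_l1_instance():
    return make_sfp_instance(m=20, n=10, constraint="l1_ball", seed=43)


@pytest.fixture(scope="session")
def separable_table():
    """Planted strongly separable two-class table (n=400, d=5)."""
    spec = SyntheticSpec(
        n_samples=400, class_balance=0.5, cluster_separation=4.0, seed=7
    )
    return make_classification_table(spec)


@pytest.fixture(scope="session")
def mammo_csv(tmp_path_factory):
    """Tiny UCI-dialect fixture file with known missing entries."""
    lines = [
        "5,67,3,5,3,1",
        "4,43,1,1,?,1",
        "5,58,4,5,3,1",
        "4,28,1,1,3,0",
        "5,74,1,5,?,1",
    ]
    path = tmp_path_factory.mktemp("data") / "mammo.csv"
    path.write_text("\n".join(lines) + "\n")
    return path
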