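import numpy as np
import pytest

from csdgi import ExpressionMatrix, SyntheticScenario, generate


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    values = rng.gamma(2.0, 0.5, (8, 5))
    return ExpressionMatrix(
        values,
        [f"g{j}" for j in range(5)],
        [f"c{i}" for i in range(8)],
    )


@pytest.fixture(scope="session")
def default_scenario_data():
    """One draw of the standing parameter-recovery scenario."""
    X, truth = generate(SyntheticScenario(seed=0))
    return X, truth
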