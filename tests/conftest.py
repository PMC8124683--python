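import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def group_map(columns) -> dict[str, str]:
    return {c: ("case" if c.startswith("case") else "control") for c in columns}


@pytest.fixture
def expression_16fold():
    """Planted 16-fold dataset at the 3+3 design with truth labels."""
    from stemdis import synthetic

    counts, truth = synthetic.gen_expression(
        2000, 100, 100, fold=16, dispersion=0.1, reps_per_group=3, seed=3
    )
    return counts, truth


@pytest.fixture
def de_results_16fold(expression_16fold):
    from stemdis import de

    counts, truth = expression_16fold
    matrix = de.ExpressionMatrix(counts=counts, groups=group_map(counts.columns))
    return de.de_test(matrix), truth
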