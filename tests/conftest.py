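import numpy as np
import pandas as pd
import pytest

import memoryscan as ms


@pytest.fixture
def config():
    return ms.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def toy_genome():
    cfg = ms.SimulationConfig(seed=7)
    return ms.simulate_toy_genome(cfg)


@pytest.fixture(scope="session")
def meth_tables(toy_genome):
    cfg = ms.SimulationConfig(seed=7)
    return ms.simulate_methylation_dynamics(toy_genome, cfg)


@pytest.fixture(scope="session")
def expression_default():
    cfg = ms.SimulationConfig(seed=7)
    return ms.simulate_expression(cfg)


def make_expression(means: dict[str, list[float]], n_reps: int = 3,
                    noise: float = 0.0, seed: int = 0) -> ms.ExpressionMatrix:
    """Expression matrix with exact (or lognormal-noised) condition means."""
    conditions = ("naive_0h", "first_12h", "sustained_12d", "recovery_10d", "second_12h")
    rng = np.random.default_rng(seed)
    cols = pd.MultiIndex.from_tuples(
        [(c, f"rep{r}") for c in conditions for r in range(n_reps)],
        names=["condition", "replicate"],
    )
    rows = {}
    for gene, vals in means.items():
        cells = []
        for v in vals:
            for _ in range(n_reps):
                cells.append(v * 2 ** rng.normal(0, noise) if noise else v)
        rows[gene] = cells
    return ms.ExpressionMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=cols))
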