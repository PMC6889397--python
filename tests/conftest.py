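import numpy as np
import pytest

import nbstrat as nb


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_view():
    """3 genes x 4 samples view, samples x genes orientation."""
    return nb.ExpressionView(
        name="toy",
        platform="rnaseq",
        genes=["G1", "G2", "G3"],
        samples=["S1", "S2", "S3", "S4"],
        values=np.arange(12, dtype=float).reshape(4, 3),
    )


@pytest.fixture
def small_cohort():
    """Tiny synthetic cohort with a strong 2-cluster signal."""
    cfg = nb.SyntheticConfig(
        n_samples=60,
        views=[nb.ViewSpec("expr", n_genes=300, n_informative=80, effect_size=2.5)],
        seed=7,
    )
    return nb.simulate_cohort(cfg)


def simplex_grid(m: int, step: float = 1e-3) -> np.ndarray:
    """All m-dim simplex points at the given resolution (m in {2, 3})."""
    w1 = np.arange(0.0, 1.0 + step / 2, step)
    if m == 2:
        grid = np.column_stack([w1, 1.0 - w1])
    elif m == 3:
        parts = []
        for a in w1:
            b = np.arange(0.0, 1.0 - a + step / 2, step)
            parts.append(np.column_stack([np.full(len(b), a), b, 1.0 - a - b]))
        grid = np.vstack(parts)
    else:
        raise ValueError("simplex_grid supports m in {2, 3}")
    return np.clip(grid, 0.0, None)
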