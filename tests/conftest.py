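import numpy as np
import pytest

from rgmeta import TransformedEffect, make_fixture
from rgmeta.pooling import restricted_loglik


def make_effects(t_values, variances):
    """Build TransformedEffect records with fixed-effect weights."""
    return [
        TransformedEffect(f"s{i}", float(t), float(v), 1.0 / float(v))
        for i, (t, v) in enumerate(zip(t_values, variances))
    ]


def grid_golden_reml(effects, design=None, n_grid=400):
    """Independent REML oracle: coarse grid + golden-section refinement.

    Maximizes the restricted log-likelihood over tau^2 >= 0 without
    using the package's optimizer.
    """
    v = np.array([e.variance for e in effects])
    t = np.array([e.t_value for e in effects])
    upper = 10.0 * (v.max() + np.var(t, ddof=1))
    grid = np.linspace(0.0, upper, n_grid)
    vals = np.array([restricted_loglik(g, effects, design) for g in grid])
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    # hand-rolled golden-section maximization on [lo, hi]
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = restricted_loglik(c, effects, design)
    fd = restricted_loglik(d, effects, design)
    while b - a > 1e-14 * max(1.0, upper):
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = restricted_loglik(c, effects, design)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = restricted_loglik(d, effects, design)
    best = 0.5 * (a + b)
    # the boundary tau^2 = 0 competes with any interior optimum
    if restricted_loglik(0.0, effects, design) >= restricted_loglik(best, effects, design):
        return 0.0
    return best


@pytest.fixture(scope="session")
def fixture_records():
    records, _ = make_fixture(0)
    return records
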