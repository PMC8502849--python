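"""Egger regression test for funnel-plot asymmetry.

The classical formulation: ordinary least squares of the standardized
effect ``T_i / sqrt(v_i)`` on the precision ``1 / sqrt(v_i)``.  Under no
small-study effect the regression line passes through the origin, so the
test is the t statistic of the intercept with ``k - 2`` degrees of
freedom.  With 25 studies this gives the t(23) reference distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .transform import TransformedEffect, effect_arrays


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    se: float
    t_stat: float
    df: int
    p: float


def funnel_data(effects: Sequence[TransformedEffect]) -> tuple[np.ndarray, np.ndarray]:
    """(precision, standardized effect) pairs for funnel plotting."""
    t, v = effect_arrays(effects)
    s = np.sqrt(v)
    return 1.0 / s, t / s


def egger_test(effects: Sequence[TransformedEffect]) -> EggerResult:
    """Test of funnel-plot asymmetry (publication / small-study bias).

    Returns the intercept of the OLS fit of standardized effect on
    precision, its standard error, the t statistic, ``df = k - 2`` and a
    two-sided p-value.  Requires ``k >= 3`` studies; equal variances make
    the precision column constant and the design singular, which raises.
    """
    k = len(effects)
    if k < 3:
        raise ValueError("egger_test requires at least 3 studies")
    x, y = funnel_data(effects)
    if np.ptp(x) < 1e-12 * max(abs(x[0]), 1.0):
        raise ValueError(
            "all sampling variances are (numerically) equal: the precision "
            "predictor is constant and the Egger regression is singular"
        )
    fit = stats.linregress(x, y)
    df = k - 2
    t_stat = fit.intercept / fit.intercept_stderr
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    return EggerResult(
        intercept=float(fit.intercept),
        se=float(fit.intercept_stderr),
        t_stat=float(t_stat),
        df=df,
        p=float(p),
    )
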