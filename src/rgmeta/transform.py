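"""Variance-stabilizing transformation of Cronbach's alpha.

Reliability-generalization meta-analysis pools coefficient alpha on a
transformed scale where its sampling distribution is close to normal.
The transform used throughout this package is the cube-root transform

    T = (1 - alpha)^(1/3)

which is strictly decreasing in alpha (a *higher* reliability gives a
*smaller* T).  Its large-sample sampling variance is the Hakstian-Whalen
approximation

    Var(T) = 18 J (n - 1) (1 - alpha)^(2/3) / ((J - 1) (9 n - 11)^2)

with ``n`` the number of respondents and ``J`` the number of items of the
scale form scored.  All pooling and meta-regression in :mod:`rgmeta`
happen on the T scale; results are back-transformed for reporting, with
interval endpoints swapped because the transform is decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class TransformedEffect:
    """One study's effect on the transformed (T) scale.

    Attributes
    ----------
    study_id : str
        Label of the source study record.
    t_value : float
        Cube-root transformed alpha, ``(1 - alpha)**(1/3)``.
    variance : float
        Hakstian-Whalen sampling variance of ``t_value``.
    weight : float
        Inverse-variance weight: ``1/variance`` under a fixed-effect view,
        ``1/(variance + tau2)`` once a between-study variance is supplied.
    """

    study_id: str
    t_value: float
    variance: float
    weight: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.t_value) or self.t_value < 0:
            raise ValueError(f"t_value must be finite and >= 0, got {self.t_value}")
        if not np.isfinite(self.variance) or self.variance <= 0:
            raise ValueError(f"variance must be finite and > 0, got {self.variance}")
        if not np.isfinite(self.weight) or self.weight <= 0:
            raise ValueError(f"weight must be finite and > 0, got {self.weight}")


def transform_alpha(alpha):
    """Cube-root transform ``T = (1 - alpha)**(1/3)``.

    Accepts scalars or arrays.  Defined for any ``alpha < 1`` (values at or
    above 1 have no real transform and raise).  Strictly decreasing in
    alpha; ``transform_alpha(0.0) == 1.0``.
    """
    a = np.asarray(alpha, dtype=float)
    if np.any(a >= 1.0):
        raise ValueError("alpha must be < 1 for the cube-root transform")
    t = np.cbrt(1.0 - a)
    return float(t) if np.isscalar(alpha) or a.ndim == 0 else t


def back_transform(t_value):
    """Inverse transform ``alpha = 1 - T**3`` for ``T >= 0``."""
    t = np.asarray(t_value, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_value must be >= 0 for back-transformation")
    a = 1.0 - t**3
    return float(a) if np.isscalar(t_value) or t.ndim == 0 else a


def sampling_variance(alpha, n, n_items):
    """Hakstian-Whalen sampling variance of the transformed alpha.

    Parameters
    ----------
    alpha : float or array
        Reliability coefficient, in (0, 1).
    n : int or array
        Number of respondents, >= 2.
    n_items : int or array
        Number of items J of the scale form, >= 2.

    Returns
    -------
    float or ndarray
        ``18 J (n-1) (1-alpha)^(2/3) / ((J-1) (9n-11)^2)``.  Strictly
        decreasing in ``n`` (approximately 1/n for large n) and shrinking
        as alpha approaches 1.
    """
    a = np.asarray(alpha, dtype=float)
    nn = np.asarray(n, dtype=float)
    jj = np.asarray(n_items, dtype=float)
    if np.any(a <= 0.0) or np.any(a >= 1.0):
        raise ValueError("alpha must lie in the open interval (0, 1)")
    if np.any(nn < 2):
        raise ValueError("sample size n must be >= 2")
    if np.any(jj < 2):
        raise ValueError("item count n_items must be >= 2")
    v = 18.0 * jj * (nn - 1.0) * (1.0 - a) ** (2.0 / 3.0) / ((jj - 1.0) * (9.0 * nn - 11.0) ** 2)
    scalar = all(np.isscalar(x) or np.asarray(x).ndim == 0 for x in (alpha, n, n_items))
    return float(v) if scalar else v


def study_ci(alpha: float, n: int, n_items: int, level: float = 0.95) -> tuple[float, float]:
    """Per-study confidence interval for alpha.

    A normal-approximation interval is built on the T scale,
    ``T +- z * sqrt(Var(T))``, and back-transformed.  Because the
    transform is decreasing the endpoints swap, so the returned pair is
    ordered ``(alpha_low, alpha_high)`` and always contains ``alpha``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    t = transform_alpha(alpha)
    se = np.sqrt(sampling_variance(alpha, n, n_items))
    z = stats.norm.ppf(0.5 + level / 2.0)
    t_lo, t_hi = t - z * se, t + z * se
    # truncate at T = 0 (alpha = 1) before back-transforming
    return back_transform(max(t_hi, 0.0)), back_transform(max(t_lo, 0.0))


def transform_studies(studies: Iterable, tau2: float = 0.0) -> list[TransformedEffect]:
    """Build :class:`TransformedEffect` records from study records.

    ``studies`` is any iterable with ``study_id``, ``alpha``, ``n`` and
    ``n_items`` attributes (see :mod:`rgmeta.ingest`).  ``tau2`` sets the
    weighting view: 0 gives fixed-effect inverse-variance weights,
    a positive value gives random-effects weights ``1/(v + tau2)``.
    """
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    out = []
    for s in studies:
        v = sampling_variance(s.alpha, s.n, s.n_items)
        out.append(
            TransformedEffect(
                study_id=s.study_id,
                t_value=transform_alpha(s.alpha),
                variance=v,
                weight=1.0 / (v + tau2),
            )
        )
    return out


def effect_arrays(effects: Sequence[TransformedEffect]) -> tuple[np.ndarray, np.ndarray]:
    """Return (t_values, variances) as float arrays, in input order."""
    t = np.array([e.t_value for e in effects], dtype=float)
    v = np.array([e.variance for e in effects], dtype=float)
    return t, v
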