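"""Random-effects pooling of transformed reliability coefficients.

The model for the transformed per-study coefficients is

    T_i ~ Normal(mu, v_i + tau^2)

with known sampling variances ``v_i`` (Hakstian-Whalen) and between-study
variance ``tau^2`` estimated by restricted maximum likelihood (REML).
The pooled mean uses inverse-variance weights ``w_i = 1/(v_i + tau^2)``;
its confidence interval uses the Knapp-Hartung small-sample adjustment
(weighted residual variance, t reference distribution with k - 1 df).

Heterogeneity is summarized by Cochran's Q (fixed-effect weights,
chi-square with k - 1 df under homogeneity) and by two I^2 variants:

* ``i2_q``   = 100 * max(0, (Q - df) / Q)
* ``i2_tau`` = 100 * tau^2 / (tau^2 + s^2)

where ``s^2`` is the Higgins-Thompson "typical" within-study variance
``(k-1) * sum(w) / (sum(w)^2 - sum(w^2))`` with fixed-effect weights.
Both are always computed; the tau^2-based variant is the package default
for headline reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .transform import TransformedEffect, back_transform, effect_arrays

logger = logging.getLogger("rgmeta")

#: REML solver settings: relative tolerance of the scalar search and the
#: iteration cap of the bounded minimizer.
REML_RTOL = 1e-10
REML_MAXITER = 200


@dataclass
class MetaResult:
    """Pooled random-effects summary on both the T and the alpha scale."""

    k: int
    mu_t: float
    tau2: float
    se_kh: float
    level: float
    ci_t: tuple[float, float]
    alpha_pooled: float
    ci_alpha: tuple[float, float]
    q_stat: float
    q_df: int
    q_p: float
    i2_tau: float
    i2_q: float
    weights: np.ndarray = field(repr=False)

    @property
    def weight_percents(self) -> np.ndarray:
        """Per-study weights normalized to percentages (sum to 100)."""
        return 100.0 * self.weights / self.weights.sum()


def _design(effects: Sequence[TransformedEffect], design) -> np.ndarray:
    k = len(effects)
    if design is None:
        return np.ones((k, 1))
    X = np.atleast_2d(np.asarray(design, dtype=float))
    if X.shape[0] != k:
        X = X.T
    if X.shape[0] != k:
        raise ValueError(f"design matrix has {X.shape[0]} rows for {k} effects")
    return X


def cochran_q(effects: Sequence[TransformedEffect]) -> tuple[float, int, float]:
    """Cochran's homogeneity test with fixed-effect weights.

    Returns ``(Q, df, p)`` with ``Q = sum w_i (T_i - T_bar_w)^2``,
    ``w_i = 1/v_i``, ``df = k - 1`` and p from the chi-square upper tail.
    """
    k = len(effects)
    if k < 2:
        raise ValueError("cochran_q requires at least 2 studies")
    t, v = effect_arrays(effects)
    w = 1.0 / v
    tbar = np.sum(w * t) / np.sum(w)
    q = float(np.sum(w * (t - tbar) ** 2))
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


def typical_within_variance(variances) -> float:
    """Higgins-Thompson typical within-study variance s^2.

    ``s^2 = (k - 1) sum(w) / (sum(w)^2 - sum(w^2))`` with ``w = 1/v``.
    """
    v = np.asarray(variances, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 variances")
    w = 1.0 / v
    sw = w.sum()
    return float((v.size - 1) * sw / (sw**2 - np.sum(w**2)))


def i_squared(q_stat: float, q_df: int, tau2: float, typical_v: float) -> tuple[float, float]:
    """Both I^2 heterogeneity indices, as percentages clamped to [0, 100].

    Returns ``(i2_q, i2_tau)``.  ``i2_q`` is 0 by convention when Q = 0.
    """
    if q_stat < 0 or tau2 < 0 or typical_v < 0 or q_df < 1:
        raise ValueError("inputs must be nonnegative with q_df >= 1")
    i2_q = 0.0 if q_stat == 0 else 100.0 * max(0.0, (q_stat - q_df) / q_stat)
    i2_tau = 0.0 if tau2 == 0 else 100.0 * tau2 / (tau2 + typical_v)
    return float(np.clip(i2_q, 0.0, 100.0)), float(np.clip(i2_tau, 0.0, 100.0))


def restricted_loglik(tau2: float, effects: Sequence[TransformedEffect], design=None) -> float:
    """Restricted log-likelihood of the normal model at a given tau^2.

    With ``W = diag(1/(v_i + tau2))`` and residuals r from the weighted
    least-squares fit of T on the design X (an intercept column when
    ``design`` is None):

        ll = -1/2 [ sum log(v_i + tau2) + log det(X'WX) + sum w_i r_i^2 ]

    Additive constants are omitted; only differences in ``tau2`` matter.
    """
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    t, v = effect_arrays(effects)
    X = _design(effects, design)
    k, p = X.shape
    if k <= p:
        raise ValueError(f"need more studies ({k}) than design columns ({p})")
    w = 1.0 / (v + tau2)
    xtwx = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(xtwx, X.T @ (w * t))
    r = t - X @ beta
    sign, logdet = np.linalg.slogdet(xtwx)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'WX is not positive definite")
    return float(-0.5 * (np.sum(np.log(v + tau2)) + logdet + np.sum(w * r * r)))


def reml_tau2(effects: Sequence[TransformedEffect], design=None) -> float:
    """REML estimate of the between-study variance tau^2.

    The profiled restricted log-likelihood (regression coefficients
    solved by weighted least squares at each tau^2) is maximized by
    bounded scalar search on ``[0, 10 * (max v_i + var(T))]`` with
    relative tolerance :data:`REML_RTOL`.  The boundary value 0 is
    compared explicitly so homogeneous data return exactly 0.
    """
    t, v = effect_arrays(effects)
    X = _design(effects, design)
    k, p = X.shape
    if k <= p:
        raise ValueError(f"REML needs k > p (got k={k}, p={p} design columns)")
    spread = float(np.var(t, ddof=1)) if k > 1 else 0.0
    upper = 10.0 * (float(np.max(v)) + spread)
    if upper <= 0:  # pragma: no cover - variances are validated positive
        return 0.0

    def neg_ll(tau2: float) -> float:
        return -restricted_loglik(tau2, effects, design)

    res = optimize.minimize_scalar(
        neg_ll,
        bounds=(0.0, upper),
        method="bounded",
        options={"xatol": REML_RTOL * upper, "maxiter": REML_MAXITER},
    )
    if not res.success:
        raise RuntimeError(f"REML did not converge within {REML_MAXITER} iterations: {res}")
    tau2_hat = float(res.x)
    # snap to the boundary when 0 is at least as likely
    if neg_ll(0.0) <= res.fun:
        tau2_hat = 0.0
    return tau2_hat


def pool_random(
    effects: Sequence[TransformedEffect],
    tau2: Optional[float] = None,
    level: float = 0.95,
) -> MetaResult:
    """Random-effects pooled mean with the Knapp-Hartung interval.

    Parameters
    ----------
    effects : sequence of TransformedEffect
    tau2 : float, optional
        Between-study variance; estimated by REML when omitted.
    level : float
        Two-sided confidence level, default 0.95.

    Notes
    -----
    Weights are ``w_i = 1/(v_i + tau2)``; the pooled mean is
    ``mu = sum(w T)/sum(w)``.  The Knapp-Hartung variance is
    ``[sum w (T - mu)^2 / (k-1)] / sum(w)`` and the interval uses
    ``t_{k-1}``.  No truncation of the adjustment factor is applied.
    The alpha-scale interval back-transforms the swapped T endpoints.
    """
    k = len(effects)
    if k < 2:
        raise ValueError("pooling requires at least 2 studies")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if tau2 is None:
        tau2 = reml_tau2(effects)
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    t, v = effect_arrays(effects)
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * t) / np.sum(w))
    se2 = float(np.sum(w * (t - mu) ** 2) / (k - 1) / np.sum(w))
    se = np.sqrt(se2)
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=k - 1)
    ci_t = (float(mu - tcrit * se), float(mu + tcrit * se))
    q, qdf, qp = cochran_q(effects)
    i2_q, i2_tau = i_squared(q, qdf, tau2, typical_within_variance(v))
    return MetaResult(
        k=k,
        mu_t=mu,
        tau2=float(tau2),
        se_kh=float(se),
        level=level,
        ci_t=ci_t,
        alpha_pooled=back_transform(max(mu, 0.0)),
        ci_alpha=(
            back_transform(max(ci_t[1], 0.0)),
            back_transform(max(ci_t[0], 0.0)),
        ),
        q_stat=q,
        q_df=qdf,
        q_p=qp,
        i2_tau=i2_tau,
        i2_q=i2_q,
        weights=w,
    )
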