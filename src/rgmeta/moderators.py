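"""Moderator analysis: meta-regression, weighted subgroup ANOVA, Pearson.

Each moderator is analyzed in isolation on the subset of studies that
report it (listwise deletion per moderator), with the between-study
variance tau^2 re-estimated by REML *within that subset* — never
inherited from the full-dataset fit.

Model: T_i ~ Normal(x_i' beta, v_i + tau^2), fitted by weighted least
squares at the REML tau^2.  Inference uses the Knapp-Hartung adjustment:
the coefficient covariance is scaled by the weighted residual mean
square ``sum(w r^2) / (k - p)`` and referred to t / F distributions with
``k - p`` denominator degrees of freedom.

The dependent variable is always the transformed T, so coefficient
signs invert on the alpha scale (the transform is decreasing): a
positive T-scale slope means reliability *falls* as the moderator
rises.  The Pearson follow-up deliberately correlates the *raw* alpha
with the moderator, so its sign is directly interpretable.

Explained between-study variance:
``R^2 = 100 * max(0, (tau2_null - tau2_residual) / tau2_null)`` with
``tau2_null`` the intercept-only REML estimate on the same subset; 0 by
definition when ``tau2_null = 0``.  REML can legitimately *increase*
tau^2 when a moderator is added, hence the truncation at 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .ingest import (
    CATEGORICAL_MODERATORS,
    CONTINUOUS_MODERATORS,
    StudyRecord,
    moderator_availability,
)
from .transform import TransformedEffect, back_transform, effect_arrays, transform_studies
from .pooling import reml_tau2

logger = logging.getLogger("rgmeta")

#: Below this many studies a moderator analysis proceeds with a warning.
SMALL_SAMPLE_K = 8


@dataclass(frozen=True)
class CoefEstimate:
    """One regression term: estimate, Knapp-Hartung CI and t test."""

    term: str
    b: float
    se: float
    ci_low: float
    ci_high: float
    t_stat: float
    p: float


@dataclass(frozen=True)
class LevelMean:
    """Model-implied mean effect of one factor level, on both scales."""

    level: str
    k: int
    mean_t: float
    alpha: float
    ci_alpha: tuple[float, float]


@dataclass
class ModeratorResult:
    moderator: str
    kind: str  # "continuous" | "categorical"
    k_used: int
    coefficients: list[CoefEstimate]
    omnibus_f: float
    omnibus_df: tuple[int, int]
    omnibus_p: float
    qe: float
    qe_df: int
    qe_p: float
    tau2_residual: float
    tau2_null: float
    r2_percent: float
    level_means: Optional[list[LevelMean]] = None
    notes: list[str] = field(default_factory=list)


def _wls(t: np.ndarray, v: np.ndarray, X: np.ndarray, tau2: float):
    w = 1.0 / (v + tau2)
    xtwx = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(xtwx, X.T @ (w * t))
    resid = t - X @ beta
    return w, xtwx, beta, resid


def _kh_fit(effects: Sequence[TransformedEffect], X: np.ndarray, level: float):
    """REML + weighted fit + Knapp-Hartung covariance; returns a dict."""
    t, v = effect_arrays(effects)
    k, p = X.shape
    tau2 = reml_tau2(effects, design=X)
    w, xtwx, beta, resid = _wls(t, v, X, tau2)
    df = k - p
    s2_kh = float(np.sum(w * resid**2) / df)  # unmodified: no truncation at 1
    cov = s2_kh * np.linalg.inv(xtwx)
    # residual heterogeneity with fixed-effect weights, as in Cochran's Q
    _, _, _, resid_fe = _wls(t, v, X, 0.0)
    qe = float(np.sum(resid_fe**2 / v))
    return {
        "tau2": tau2, "beta": beta, "cov": cov, "df": df,
        "qe": qe, "qe_df": df, "qe_p": float(stats.chi2.sf(qe, df)),
    }


def _coef_table(names, beta, cov, df, level) -> list[CoefEstimate]:
    tcrit = stats.t.ppf(0.5 + level / 2.0, df)
    out = []
    for j, name in enumerate(names):
        se = float(np.sqrt(cov[j, j]))
        tstat = beta[j] / se if se > 0 else np.inf * np.sign(beta[j])
        out.append(
            CoefEstimate(
                term=name,
                b=float(beta[j]),
                se=se,
                ci_low=float(beta[j] - tcrit * se),
                ci_high=float(beta[j] + tcrit * se),
                t_stat=float(tstat),
                p=float(2.0 * stats.t.sf(abs(tstat), df)),
            )
        )
    return out


def _omnibus(beta, cov, df, slope_idx) -> tuple[float, tuple[int, int], float]:
    q = len(slope_idx)
    bs = beta[slope_idx]
    cs = cov[np.ix_(slope_idx, slope_idx)]
    f = float(bs @ np.linalg.solve(cs, bs) / q)
    return f, (q, df), float(stats.f.sf(f, q, df))


def _r2_percent(tau2_null: float, tau2_res: float) -> float:
    if tau2_null <= 0.0:
        return 0.0
    return float(100.0 * max(0.0, (tau2_null - tau2_res) / tau2_null))


def meta_regression(
    effects: Sequence[TransformedEffect],
    x,
    level: float = 0.95,
    moderator: str = "x",
) -> ModeratorResult:
    """Simple mixed-effects meta-regression of T on one continuous moderator.

    Fits ``T_i ~ N(b0 + b1 x_i, v_i + tau^2)`` (REML tau^2), with
    Knapp-Hartung standard errors, per-term t tests on ``k - 2`` df, an
    omnibus F on ``(1, k - 2)`` df, residual heterogeneity Q_E, and the
    explained between-study variance R^2 against the intercept-only
    model on the same subset.
    """
    x = np.asarray(x, dtype=float)
    k = len(effects)
    if x.shape != (k,):
        raise ValueError("x must have one value per effect")
    if k < 3:
        raise ValueError("meta_regression requires k >= 3 after listwise deletion")
    if np.ptp(x) == 0:
        raise ValueError(f"moderator {moderator!r} has no variance")
    if k < SMALL_SAMPLE_K:
        logger.warning(
            "moderator %r analyzed with only k=%d studies; estimates are fragile", moderator, k
        )
    X = np.column_stack([np.ones(k), x])
    fit = _kh_fit(effects, X, level)
    coefs = _coef_table(["intercept", moderator], fit["beta"], fit["cov"], fit["df"], level)
    f, fdf, fp = _omnibus(fit["beta"], fit["cov"], fit["df"], [1])
    tau2_null = reml_tau2(effects)
    return ModeratorResult(
        moderator=moderator,
        kind="continuous",
        k_used=k,
        coefficients=coefs,
        omnibus_f=f,
        omnibus_df=fdf,
        omnibus_p=fp,
        qe=fit["qe"],
        qe_df=fit["qe_df"],
        qe_p=fit["qe_p"],
        tau2_residual=fit["tau2"],
        tau2_null=tau2_null,
        r2_percent=_r2_percent(tau2_null, fit["tau2"]),
    )


def subgroup_anova(
    effects: Sequence[TransformedEffect],
    groups,
    level: float = 0.95,
    moderator: str = "group",
) -> ModeratorResult:
    """Weighted ANOVA (mixed-effects subgroup model) for a categorical moderator.

    Dummy-codes group membership against a reference level (the largest
    group, ties broken alphabetically) with a *common* REML tau^2, and
    tests the ``m - 1`` group contrasts jointly by a Knapp-Hartung
    adjusted F on ``(m - 1, k - m)`` df.  Each level's model-implied
    mean effect is also reported, back-transformed to the alpha scale.
    A level with a single study is allowed but logged as a warning.
    """
    labels = np.asarray([str(g) for g in groups])
    k = len(effects)
    if labels.shape != (k,):
        raise ValueError("groups must have one label per effect")
    levels, counts = np.unique(labels, return_counts=True)
    m = len(levels)
    if m < 2:
        raise ValueError(f"moderator {moderator!r} has a single level; nothing to compare")
    if k < m + 1:
        raise ValueError(f"subgroup analysis needs k >= m + 1 (got k={k}, m={m})")
    notes = []
    for lev, c in zip(levels, counts):
        if c == 1:
            msg = f"moderator {moderator!r}: level {str(lev)!r} has a single study"
            logger.warning(msg)
            notes.append(msg)
    # reference = largest group, alphabetical tie-break
    ref = levels[np.lexsort((levels, -counts))[0]]
    others = [lev for lev in levels if lev != ref]
    X = np.column_stack([np.ones(k)] + [(labels == lev).astype(float) for lev in others])
    fit = _kh_fit(effects, X, level)
    names = [f"intercept[{ref}]"] + [f"{lev} - {ref}" for lev in others]
    coefs = _coef_table(names, fit["beta"], fit["cov"], fit["df"], level)
    f, fdf, fp = _omnibus(fit["beta"], fit["cov"], fit["df"], list(range(1, m)))
    tau2_null = reml_tau2(effects)
    tcrit = stats.t.ppf(0.5 + level / 2.0, fit["df"])
    level_means = []
    for lev, c in zip(levels, counts):
        contrast = np.zeros(m)
        contrast[0] = 1.0
        if lev != ref:
            contrast[1 + others.index(lev)] = 1.0
        mt = float(contrast @ fit["beta"])
        se = float(np.sqrt(contrast @ fit["cov"] @ contrast))
        lo_t, hi_t = mt - tcrit * se, mt + tcrit * se
        level_means.append(
            LevelMean(
                level=str(lev),
                k=int(c),
                mean_t=mt,
                alpha=back_transform(max(mt, 0.0)),
                ci_alpha=(back_transform(max(hi_t, 0.0)), back_transform(max(lo_t, 0.0))),
            )
        )
    return ModeratorResult(
        moderator=moderator,
        kind="categorical",
        k_used=k,
        coefficients=coefs,
        omnibus_f=f,
        omnibus_df=fdf,
        omnibus_p=fp,
        qe=fit["qe"],
        qe_df=fit["qe_df"],
        qe_p=fit["qe_p"],
        tau2_residual=fit["tau2"],
        tau2_null=tau2_null,
        r2_percent=_r2_percent(tau2_null, fit["tau2"]),
        level_means=level_means,
        notes=notes,
    )


def pearson_followup(alphas, x) -> tuple[float, float]:
    """Pearson correlation of *raw* alpha with a moderator.

    Used as a follow-up to a significant meta-regression; works on the
    untransformed coefficients so the sign reads directly (and is
    opposite to the T-scale slope's sign for a monotone relation).
    Returns ``(r, p)`` with a two-sided p from t on ``k - 2`` df.
    """
    a = np.asarray(alphas, dtype=float)
    xv = np.asarray(x, dtype=float)
    if a.shape != xv.shape or a.ndim != 1:
        raise ValueError("alphas and x must be 1-d arrays of equal length")
    if a.size < 3:
        raise ValueError("pearson_followup requires k >= 3")
    if np.ptp(a) == 0 or np.ptp(xv) == 0:
        raise ValueError("inputs must be non-constant")
    r, p = stats.pearsonr(a, xv)
    return float(r), float(p)


DEFAULT_MODERATOR_SPEC = [(name, "continuous") for name in CONTINUOUS_MODERATORS] + [
    (name, "categorical") for name in CATEGORICAL_MODERATORS
]


@dataclass
class ModeratorBatch:
    """Results of a batch run plus any moderators that had to be skipped."""

    results: list[ModeratorResult]
    skipped: list[tuple[str, str]]  # (moderator, reason)

    def __iter__(self):
        return iter(self.results)


def run_all_moderators(
    studies: Sequence[StudyRecord],
    spec: Optional[list[tuple[str, str]]] = None,
    level: float = 0.95,
) -> ModeratorBatch:
    """Analyze every moderator in ``spec`` in isolation.

    Each analysis listwise-deletes studies missing that moderator and
    re-estimates tau^2 on its own subset.  A failing moderator (too few
    studies, constant values, ...) is logged and reported as skipped;
    it never aborts the batch.
    """
    if spec is None:
        spec = DEFAULT_MODERATOR_SPEC
    results: list[ModeratorResult] = []
    skipped: list[tuple[str, str]] = []
    for name, kind in spec:
        try:
            subset = moderator_availability(studies, name)
            if not subset:
                raise ValueError(f"moderator {name!r} is missing in every study")
            effects = transform_studies(subset)
            values = [getattr(s, name) for s in subset]
            if kind == "continuous":
                res = meta_regression(effects, np.asarray(values, dtype=float),
                                      level=level, moderator=name)
            elif kind == "categorical":
                res = subgroup_anova(effects, values, level=level, moderator=name)
            else:
                raise ValueError(f"unknown moderator kind {kind!r}")
            results.append(res)
        except Exception as exc:  # noqa: BLE001 - batch must survive any failure
            logger.warning("moderator %r skipped: %s", name, exc)
            skipped.append((name, str(exc)))
    return ModeratorBatch(results=results, skipped=skipped)
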