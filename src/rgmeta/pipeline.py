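"""End-to-end reliability-generalization pipeline and report writers.

Stages, in order: ingest -> transform -> REML pooling with the
Knapp-Hartung interval -> Egger asymmetry test -> per-moderator
mixed-effects analyses (continuous meta-regressions, categorical
weighted ANOVAs) -> Pearson follow-up on any significant continuous
moderator.  The report collects every stage's output; regenerating it
from the same input and configuration is bit-identical except for the
timestamp.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bias import EggerResult, egger_test
from .ingest import (
    CATEGORICAL_MODERATORS,
    CONTINUOUS_MODERATORS,
    StudyRecord,
    read_studies,
)
from .moderators import (
    ModeratorBatch,
    ModeratorResult,
    pearson_followup,
    run_all_moderators,
)
from .pooling import MetaResult, pool_random
from .transform import study_ci, transform_studies

logger = logging.getLogger("rgmeta")


@dataclass
class PipelineConfig:
    """Analysis settings; defaults mirror the package's reporting choices."""

    level: float = 0.95
    headline_i2: str = "tau2"  # "tau2" | "q"
    continuous_moderators: list[str] = field(default_factory=lambda: list(CONTINUOUS_MODERATORS))
    categorical_moderators: list[str] = field(default_factory=lambda: list(CATEGORICAL_MODERATORS))
    pearson_p_threshold: float = 0.05
    strict: bool = True
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")
        if self.headline_i2 not in ("tau2", "q"):
            raise ValueError("headline_i2 must be 'tau2' or 'q'")


@dataclass
class PipelineReport:
    k: int
    total_n: int
    forest: pd.DataFrame
    pooled: MetaResult
    egger: Optional[EggerResult]
    egger_note: str
    moderators: ModeratorBatch
    pearson: dict[str, tuple[float, float]]
    config: PipelineConfig
    version: str
    timestamp: str

    def to_dict(self) -> dict:
        """JSON-serializable form; deterministic apart from ``timestamp``."""
        pooled = dataclasses.asdict(self.pooled)
        pooled["weights"] = self.pooled.weights.tolist()
        return {
            "dataset": {"k": self.k, "total_n": self.total_n},
            "forest": self.forest.to_dict(orient="records"),
            "pooled": pooled,
            "headline_i2": (
                self.pooled.i2_tau if self.config.headline_i2 == "tau2" else self.pooled.i2_q
            ),
            "egger": dataclasses.asdict(self.egger) if self.egger else None,
            "egger_note": self.egger_note,
            "moderators": [dataclasses.asdict(m) for m in self.moderators.results],
            "moderators_skipped": self.moderators.skipped,
            "pearson_followup": self.pearson,
            "n_moderator_tests": len(self.moderators.results),
            "multiplicity_note": (
                f"{len(self.moderators.results)} moderator tests were run; "
                "no multiple-testing correction is applied"
            ),
            "run": {
                "version": self.version,
                "timestamp": self.timestamp,
                "config": dataclasses.asdict(self.config),
            },
        }


def forest_table(studies: Sequence[StudyRecord], pooled: MetaResult, level: float) -> pd.DataFrame:
    """Plot-ready per-study table: alpha, CI, N and weight percentage."""
    rows = []
    for s, wpct in zip(studies, pooled.weight_percents):
        lo, hi = study_ci(s.alpha, s.n, s.n_items, level)
        rows.append(
            {
                "study_id": s.study_id,
                "alpha": s.alpha,
                "ci_low": lo,
                "ci_high": hi,
                "n": s.n,
                "weight_pct": float(wpct),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    input_path=None,
    config: Optional[PipelineConfig] = None,
    studies: Optional[Sequence[StudyRecord]] = None,
) -> PipelineReport:
    """Run every stage on a CSV (or pre-loaded records) and collect a report.

    Moderator failures are logged and reported as skipped; ingest
    failures and an unpoolable dataset (fewer than 2 studies) raise.
    """
    if config is None:
        config = PipelineConfig()
    if studies is None:
        if input_path is None:
            raise ValueError("provide input_path or studies")
        studies = read_studies(input_path, strict=config.strict)
    if len(studies) < 2:
        raise ValueError("at least 2 studies required")
    logger.info(
        "defaults in force: Hakstian-Whalen sampling variance; REML tau^2; "
        "Knapp-Hartung t intervals; headline I^2 = %s; reference-cell dummy coding",
        config.headline_i2,
    )
    effects = transform_studies(studies)
    pooled = pool_random(effects, level=config.level)
    egger = None
    egger_note = ""
    try:
        egger = egger_test(effects)
    except ValueError as exc:
        egger_note = f"Egger test skipped: {exc}"
        logger.warning(egger_note)

    spec = [(m, "continuous") for m in config.continuous_moderators] + [
        (m, "categorical") for m in config.categorical_moderators
    ]
    batch = run_all_moderators(studies, spec=spec, level=config.level)

    pearson: dict[str, tuple[float, float]] = {}
    for res in batch.results:
        if res.kind == "continuous" and res.omnibus_p < config.pearson_p_threshold:
            sub = [s for s in studies if getattr(s, res.moderator) is not None]
            try:
                pearson[res.moderator] = pearson_followup(
                    [s.alpha for s in sub], [getattr(s, res.moderator) for s in sub]
                )
            except ValueError as exc:
                logger.warning("Pearson follow-up for %r skipped: %s", res.moderator, exc)

    return PipelineReport(
        k=len(studies),
        total_n=int(sum(s.n for s in studies)),
        forest=forest_table(studies, pooled, config.level),
        pooled=pooled,
        egger=egger,
        egger_note=egger_note,
        moderators=batch,
        pearson=pearson,
        config=config,
        version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )


def _fmt_ci(lo: float, hi: float) -> str:
    return f"{lo:.4f} to {hi:.4f}"


def moderator_table(results: Sequence[ModeratorResult], kind: str) -> pd.DataFrame:
    """Tabulate moderator analyses with the conventional column heads.

    Continuous rows show the slope; categorical rows show the omnibus
    block followed by one row per level with its model-implied mean
    (alpha scale) and contrast against the reference level.
    """
    rows = []
    for res in results:
        if res.kind != kind:
            continue
        if kind == "continuous":
            slope = res.coefficients[1]
            rows.append(
                {
                    "IV": res.moderator,
                    "k": res.k_used,
                    "b": slope.b,
                    "ci_95_b": _fmt_ci(slope.ci_low, slope.ci_high),
                    "p": slope.p,
                    "F": res.omnibus_f,
                    "Q_E": res.qe,
                    "R2_pct": res.r2_percent,
                }
            )
        else:
            rows.append(
                {
                    "IV": res.moderator,
                    "k": res.k_used,
                    "level": "",
                    "b": np.nan,
                    "ci_95_b": "",
                    "p": res.omnibus_p,
                    "F": res.omnibus_f,
                    "Q_E": res.qe,
                    "R2_pct": res.r2_percent,
                    "alpha_level": np.nan,
                }
            )
            contrasts = {c.term.split(" - ")[0]: c for c in res.coefficients[1:]}
            for lm in res.level_means or []:
                c = contrasts.get(lm.level)
                rows.append(
                    {
                        "IV": "",
                        "k": lm.k,
                        "level": lm.level,
                        "b": c.b if c else 0.0,
                        "ci_95_b": _fmt_ci(c.ci_low, c.ci_high) if c else "(reference)",
                        "p": c.p if c else np.nan,
                        "F": np.nan,
                        "Q_E": np.nan,
                        "R2_pct": np.nan,
                        "alpha_level": lm.alpha,
                    }
                )
    return pd.DataFrame(rows)


def write_report(report: PipelineReport, outdir) -> dict[str, Path]:
    """Write report.json, forest.tsv and the two moderator TSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "report": outdir / "report.json",
        "forest": outdir / "forest.tsv",
        "continuous": outdir / "moderators_continuous.tsv",
        "categorical": outdir / "moderators_categorical.tsv",
    }
    with open(paths["report"], "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    report.forest.to_csv(paths["forest"], sep="\t", index=False)
    moderator_table(report.moderators.results, "continuous").to_csv(
        paths["continuous"], sep="\t", index=False
    )
    moderator_table(report.moderators.results, "categorical").to_csv(
        paths["categorical"], sep="\t", index=False
    )
    return paths
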