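"""Reading, validating and coding study-level reliability records.

One row of input = one administered sample of the P-CAT (Person-Centered
Care Assessment Tool: 13 Likert items, three subscales, total score
13-65): its Cronbach's alpha, the number of respondents, the number of
items of the form scored, and optional study-level moderators.

Coding conventions
------------------
* CSV, UTF-8, comma-separated, header row; empty cell = missing.
* Category labels are matched case-insensitively after trimming.
* A study reporting only subscale alphas is entered as separate rows,
  one per subscale score, with distinct ``study_id`` values and the
  subscale's item count in ``n_items``.  The reader does not detect or
  enforce this; it is a coding convention for the analyst.
* ``alpha <= 0`` is rejected: it is theoretically possible but outside
  the intended domain of the cube-root transform's variance model here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger("rgmeta")

#: Exact CSV column order of the study schema.
CSV_COLUMNS = [
    "study_id", "alpha", "n", "n_items", "year", "continent", "version",
    "admin_method", "care_context", "n_women", "n_men", "age_mean",
    "age_sd", "score_mean", "score_sd",
]

CONTINUOUS_MODERATORS = [
    "year", "n_women", "n_men", "age_mean", "age_sd", "score_mean", "score_sd",
]
CATEGORICAL_MODERATORS = ["continent", "version", "admin_method", "care_context"]
MODERATORS = CONTINUOUS_MODERATORS + CATEGORICAL_MODERATORS

CATEGORY_LEVELS = {
    "continent": ("asia", "europe", "americas", "oceania"),
    "version": ("original", "free_translation", "validated"),
    "admin_method": ("face_to_face", "other"),
    "care_context": ("geriatric_residence", "other"),
}


class StudyValidationError(ValueError):
    """A study record violates the schema; the message names the row."""


@dataclass
class StudyRecord:
    """One coded sample: reliability coefficient plus moderators.

    ``alpha`` must lie strictly inside (0, 1); ``n >= 2`` respondents;
    ``n_items >= 2`` (default 13, the full P-CAT).  Every moderator is
    optional and ``None`` when the source study does not report it.
    """

    study_id: str
    alpha: float
    n: int
    n_items: int = 13
    year: Optional[int] = None
    continent: Optional[str] = None
    version: Optional[str] = None
    admin_method: Optional[str] = None
    care_context: Optional[str] = None
    n_women: Optional[int] = None
    n_men: Optional[int] = None
    age_mean: Optional[float] = None
    age_sd: Optional[float] = None
    score_mean: Optional[float] = None
    score_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise StudyValidationError(
                f"study {self.study_id!r}: alpha must lie in (0, 1), got {self.alpha}"
            )
        if self.n < 2:
            raise StudyValidationError(f"study {self.study_id!r}: n must be >= 2, got {self.n}")
        if self.n_items < 2:
            raise StudyValidationError(
                f"study {self.study_id!r}: n_items must be >= 2, got {self.n_items}"
            )
        for name in ("n_women", "n_men"):
            val = getattr(self, name)
            if val is not None and val < 0:
                raise StudyValidationError(f"study {self.study_id!r}: {name} must be >= 0")
        for name in ("age_sd", "score_sd"):
            val = getattr(self, name)
            if val is not None and val < 0:
                raise StudyValidationError(f"study {self.study_id!r}: {name} must be >= 0")
        if self.score_mean is not None and self.n_items == 13:
            if not (13.0 <= self.score_mean <= 65.0):
                raise StudyValidationError(
                    f"study {self.study_id!r}: score_mean {self.score_mean} outside the "
                    "13-65 range of the 13-item total score"
                )
        for name in CATEGORICAL_MODERATORS:
            val = getattr(self, name)
            if val is None:
                continue
            norm = str(val).strip().lower()
            if norm not in CATEGORY_LEVELS[name]:
                raise StudyValidationError(
                    f"study {self.study_id!r}: {name}={val!r} not one of "
                    f"{CATEGORY_LEVELS[name]}"
                )
            object.__setattr__(self, name, norm)


def _parse_cell(value, kind):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    if s == "":
        return None
    if kind is int:
        return int(round(float(s)))
    if kind is float:
        return float(s)
    return s


_FIELD_KINDS = {
    "study_id": str, "alpha": float, "n": int, "n_items": int, "year": int,
    "continent": str, "version": str, "admin_method": str, "care_context": str,
    "n_women": int, "n_men": int, "age_mean": float, "age_sd": float,
    "score_mean": float, "score_sd": float,
}


def read_studies(path, strict: bool = True) -> list[StudyRecord]:
    """Read a CSV of study records, preserving row order.

    Rows missing ``alpha`` or ``n`` are always a hard error naming the
    row.  Other validation failures (alpha outside (0,1), n < 2, bad
    category label, score out of range) are hard errors in strict mode;
    otherwise the row is skipped with a logged warning.  A duplicated
    ``study_id`` is always a hard error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = {"alpha", "n"} - set(df.columns)
    if missing_cols:
        raise StudyValidationError(f"input is missing required column(s): {sorted(missing_cols)}")
    unknown = [c for c in df.columns if c not in CSV_COLUMNS]
    if unknown:
        logger.warning("ignoring unrecognized column(s): %s", unknown)

    records: list[StudyRecord] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        raw = dict(zip(df.columns, row))
        if _parse_cell(raw.get("alpha"), float) is None or _parse_cell(raw.get("n"), int) is None:
            raise StudyValidationError(f"row {i}: alpha and n are required and must be non-empty")
        kwargs = {}
        try:
            for f in fields(StudyRecord):
                if f.name in raw:
                    val = _parse_cell(raw[f.name], _FIELD_KINDS[f.name])
                    if val is not None or f.name not in ("study_id", "n_items"):
                        kwargs[f.name] = val
            if kwargs.get("study_id") is None:
                kwargs["study_id"] = f"row{i}"
            if kwargs.get("n_items") is None:
                kwargs.pop("n_items", None)
            rec = StudyRecord(**kwargs)
        except (StudyValidationError, ValueError) as exc:
            if strict:
                raise StudyValidationError(f"row {i}: {exc}") from exc
            logger.warning("row %d skipped: %s", i, exc)
            continue
        if rec.study_id in seen_ids:
            raise StudyValidationError(f"row {i}: duplicate study_id {rec.study_id!r}")
        seen_ids.add(rec.study_id)
        records.append(rec)
    return records


def write_studies(studies: Sequence[StudyRecord], path) -> None:
    """Write records to CSV in the schema order; round-trips exactly."""
    rows = []
    for s in studies:
        rows.append({c: getattr(s, c) for c in CSV_COLUMNS})
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False, na_rep="", float_format=lambda x: repr(float(x)))


def moderator_availability(studies: Iterable[StudyRecord], moderator: str) -> list[StudyRecord]:
    """Records with the named moderator present (listwise deletion).

    The size of the returned subset is the per-moderator ``k`` that each
    moderator analysis reports.  Unknown names raise, listing the valid
    moderator names.
    """
    if moderator not in MODERATORS:
        raise ValueError(f"unknown moderator {moderator!r}; valid names: {MODERATORS}")
    return [s for s in studies if getattr(s, moderator) is not None]
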