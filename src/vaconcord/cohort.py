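"""Paired-coded death records: parsing, validation, age groups, strata.

A cohort holds one row per death with a reference assignment (physician-coded
VA, the study's reference standard) and one assignment per automated coder.
The cohort file is plain CSV with required columns
``id,age_value,age_unit,sex,place,ref_cause`` and, for each coder ``K``, a
``K_cause`` column (the cause after the coder's indeterminate rule) plus
optional ``K_rank1..K_rank3`` / ``K_score1..K_score3`` ranked-cause columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .causes import CauseList

logger = logging.getLogger(__name__)

__all__ = [
    "AGE_GROUPS",
    "SEXES",
    "PLACES",
    "AssignmentSet",
    "DeathRecord",
    "StratumSpec",
    "STANDARD_STRATA",
    "Cohort",
    "CohortValidationError",
    "derive_age_group",
    "read_cohort",
]

AGE_GROUPS = ("neonate", "child", "adult", "elder")
SEXES = ("female", "male", "unknown")
PLACES = ("in_facility", "out_of_facility", "unknown")

DAYS_PER_YEAR = 365.25
#: age-group boundaries: neonate 0-27 completed days, child 28 days to <12 y,
#: adult 12 to <50 y, elder 50+ y
_NEONATE_MAX_DAYS = 28
_CHILD_MAX_YEARS = 12
_ADULT_MAX_YEARS = 50

REQUIRED_COLUMNS = ("id", "age_value", "age_unit", "sex", "place", "ref_cause")


class CohortValidationError(ValueError):
    pass


def derive_age_group(age_value: float, age_unit: str) -> str:
    """Age group from an age with its unit (``"days"`` or ``"years"``).

    Neonates are 0-27 completed days; children 28 days to under 12 years;
    adults 12 to under 50 years; elders 50 years and over.
    """
    if age_value < 0:
        raise ValueError(f"age must be non-negative, got {age_value}")
    if age_unit not in {"days", "years"}:
        raise ValueError(f"age_unit must be 'days' or 'years', got {age_unit!r}")
    days = age_value if age_unit == "days" else age_value * DAYS_PER_YEAR
    years = days / DAYS_PER_YEAR
    if days < _NEONATE_MAX_DAYS:
        return "neonate"
    if years < _CHILD_MAX_YEARS:
        return "child"
    if years < _ADULT_MAX_YEARS:
        return "adult"
    return "elder"


@dataclass(frozen=True)
class AssignmentSet:
    """One coder's output for one death: ranked causes (most likely first),
    optional non-increasing scores, and the cause after the coder's
    indeterminate cutoff."""

    coder: str
    ranked_causes: tuple[str, ...]
    scores: tuple[float, ...] | None
    thresholded_cause: str

    def __post_init__(self) -> None:
        if self.scores is not None:
            if len(self.scores) != len(self.ranked_causes):
                raise ValueError("scores must parallel ranked_causes")
            if any(a < b for a, b in zip(self.scores, self.scores[1:])):
                raise ValueError("scores must be non-increasing")


@dataclass(frozen=True)
class DeathRecord:
    id: str
    age_value: float
    age_unit: str
    sex: str
    place: str
    reference: AssignmentSet
    coder_assignments: dict[str, AssignmentSet]

    @property
    def age_group(self) -> str:
        return derive_age_group(self.age_value, self.age_unit)


@dataclass(frozen=True)
class StratumSpec:
    """A named subset predicate over (age group, sex, place).

    ``column is None`` denotes the distinguished total stratum.
    """

    name: str
    column: str | None = None
    value: str | None = None

    def mask(self, frame: pd.DataFrame) -> pd.Series:
        if self.column is None:
            return pd.Series(True, index=frame.index)
        return frame[self.column] == self.value


#: the standard report strata: total, four age groups, both sexes, in/out of facility
STANDARD_STRATA: tuple[StratumSpec, ...] = (
    StratumSpec("total"),
    *(StratumSpec(g, "age_group", g) for g in AGE_GROUPS),
    StratumSpec("male", "sex", "male"),
    StratumSpec("female", "sex", "female"),
    StratumSpec("in_facility", "place", "in_facility"),
    StratumSpec("out_of_facility", "place", "out_of_facility"),
)


class Cohort:
    """A validated table of paired-coded deaths bound to an analysis cause list.

    Parameters
    ----------
    frame
        One row per death in the cohort CSV schema.
    cause_list
        The analysis cause list all cause codes are validated against.
    coders
        Names of the automated coders; inferred from ``*_cause`` columns when
        omitted.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        cause_list: CauseList,
        coders: Sequence[str] | None = None,
    ):
        frame = frame.reset_index(drop=True).copy()
        if coders is None:
            coders = [
                c[: -len("_cause")]
                for c in frame.columns
                if c.endswith("_cause") and c != "ref_cause"
            ]
        self.cause_list = cause_list
        self.coders = tuple(coders)
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise CohortValidationError(f"missing required columns: {missing}")
        for k in self.coders:
            if f"{k}_cause" not in frame.columns:
                raise CohortValidationError(f"coder {k!r} has no {k}_cause column")
        self._validate_ids(frame)
        self._validate_values(frame)
        if "age_group" not in frame.columns:
            frame["age_group"] = [
                derive_age_group(v, u)
                for v, u in zip(frame["age_value"], frame["age_unit"])
            ]
        self.frame = frame

    # -- validation ---------------------------------------------------------------
    @staticmethod
    def _validate_ids(frame: pd.DataFrame) -> None:
        dup = frame["id"][frame["id"].duplicated()]
        if not dup.empty:
            raise CohortValidationError(f"duplicate ids: {sorted(set(dup))[:10]}")

    def _validate_values(self, frame: pd.DataFrame) -> None:
        if (frame["age_value"] < 0).any():
            bad = frame.loc[frame["age_value"] < 0, "id"].tolist()
            raise CohortValidationError(f"negative ages for ids {bad[:10]}")
        bad_sex = ~frame["sex"].isin(SEXES)
        if bad_sex.any():
            raise CohortValidationError(
                f"invalid sex values: {sorted(frame.loc[bad_sex, 'sex'].unique())}"
            )
        bad_place = ~frame["place"].isin(PLACES)
        if bad_place.any():
            raise CohortValidationError(
                f"invalid place values: {sorted(frame.loc[bad_place, 'place'].unique())}"
            )
        valid = set(self.cause_list.codes)
        cause_cols = ["ref_cause"] + [f"{k}_cause" for k in self.coders]
        rank_cols = [
            c
            for c in frame.columns
            if any(c.startswith(f"{k}_rank") for k in self.coders)
        ]
        for col in cause_cols + rank_cols:
            vals = frame[col].fillna("")
            bad = ~vals.isin(valid) & (vals != "")
            if col in cause_cols:
                bad |= vals == ""  # thresholded cause is mandatory
            if bad.any():
                rows = frame.loc[bad, "id"].tolist()
                raise CohortValidationError(
                    f"column {col!r}: cause codes not in list "
                    f"{self.cause_list.name!r} for ids {rows[:10]}"
                )

    # -- container protocol -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n(self) -> int:
        return len(self.frame)

    def record(self, i: int) -> DeathRecord:
        """Materialise row ``i`` as a :class:`DeathRecord`."""
        row = self.frame.iloc[i]
        assignments = {}
        for k in self.coders:
            ranked, scores = [], []
            for r in range(1, 10):
                col = f"{k}_rank{r}"
                if col not in self.frame.columns or not row.get(col):
                    break
                ranked.append(row[col])
                scol = f"{k}_score{r}"
                if scol in self.frame.columns and pd.notna(row.get(scol)):
                    scores.append(float(row[scol]))
            if not ranked:
                ranked = [row[f"{k}_cause"]]
                scores = []
            assignments[k] = AssignmentSet(
                k, tuple(ranked), tuple(scores) or None, row[f"{k}_cause"]
            )
        ref = AssignmentSet("reference", (row["ref_cause"],), None, row["ref_cause"])
        return DeathRecord(
            row["id"], float(row["age_value"]), row["age_unit"], row["sex"],
            row["place"], ref, assignments,
        )

    def _with(self, frame: pd.DataFrame) -> "Cohort":
        out = object.__new__(Cohort)
        out.cause_list = self.cause_list
        out.coders = self.coders
        out.frame = frame.reset_index(drop=True)
        return out

    # -- filtering and stratification ---------------------------------------------
    def exclude_reference_undetermined(self) -> tuple["Cohort", int]:
        """Drop deaths whose reference cause is undetermined.

        Returns the filtered cohort and the number removed; the original
        cohort is untouched. Ill-defined reference causes carry no signal
        about coder performance, so they are removed before any individual- or
        population-level agreement computation.
        """
        undet = self.cause_list.undetermined_code
        if undet is None:
            return self._with(self.frame.copy()), 0
        mask = self.frame["ref_cause"] == undet
        excluded = int(mask.sum())
        if excluded == len(self.frame) and excluded > 0:
            logger.warning("all %d records are reference-undetermined", excluded)
        return self._with(self.frame.loc[~mask].copy()), excluded

    def reference_undetermined_subset(self) -> "Cohort":
        """The complement of :meth:`exclude_reference_undetermined`."""
        undet = self.cause_list.undetermined_code
        mask = (
            self.frame["ref_cause"] == undet
            if undet is not None
            else pd.Series(False, index=self.frame.index)
        )
        return self._with(self.frame.loc[mask].copy())

    def stratify(self, spec: StratumSpec) -> "Cohort":
        """Subset to the records satisfying the stratum predicate."""
        return self._with(self.frame.loc[spec.mask(self.frame)].copy())

    # -- IO -----------------------------------------------------------------------
    def write(self, path: str | Path) -> None:
        cols = [c for c in self.frame.columns if c != "age_group"]
        self.frame[cols].to_csv(path, index=False)


def read_cohort(
    path: str | Path,
    cause_list: CauseList,
    coders: Sequence[str] | None = None,
) -> Cohort:
    """Read and validate a cohort CSV against an analysis cause list.

    Coders default to every ``K_cause`` column present. Per-column
    missingness is logged so silent data gaps surface in the run log.
    """
    frame = pd.read_csv(path, dtype={"id": str}, keep_default_na=False, na_values=[])
    if frame.empty:
        logger.warning("cohort file %s contains a header but no records", path)
    frame["age_value"] = pd.to_numeric(frame["age_value"], errors="raise")
    score_cols = [c for c in frame.columns if "_score" in c]
    for c in score_cols:
        frame[c] = pd.to_numeric(frame[c].replace("", np.nan), errors="coerce")
    for col in frame.columns:
        if frame[col].dtype == object:
            n_missing = int((frame[col] == "").sum())
        else:
            n_missing = int(frame[col].isna().sum())
        if n_missing:
            logger.info("column %s: %d missing values", col, n_missing)
    return Cohort(frame, cause_list, coders)
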