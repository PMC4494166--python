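"""Domain types, coding schemes and record validation for urothelial-carcinoma test cohorts.

A cohort is held as a :class:`pandas.DataFrame` with one row per subject and the
columns of :data:`COHORT_COLUMNS`.  The four diagnostic tests — urine cytology,
NMP22, UroVysion FISH and Cxbladder Detect — are stored as small integer codes:

* cytology: 1 negative, 2 atypical, 3 suspicious, 4 positive
  (1-2 count as binary-negative for UC, 3-4 as binary-positive);
* NMP22 / FISH / Cxbladder Detect: 1 negative, 2 positive.

Missing test cells are NA.  Each test column ``t`` is paired with a provenance
column ``t_src`` in {measured, imputed, missing}: a non-missing cell is either
measured or imputed, a missing cell carries provenance "missing".  Age (years)
and gender (1 male, 2 female) are never missing.  The cystoscopy truth label is
one of UC | nonUC | other | unknown ("other" marks an other-cause diagnosis such
as kidney stones, reclassified to nonUC at integration time).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

TESTS: tuple[str, ...] = ("cytology", "nmp22", "fish", "cxbladder")

#: human-readable test labels, used in report tables
TEST_LABELS: Mapping[str, str] = {
    "cytology": "Cytology",
    "nmp22": "NMP22",
    "fish": "FISH",
    "cxbladder": "Cxbladder Detect",
}

ALPHABETS: Mapping[str, tuple[int, ...]] = {
    "cytology": (1, 2, 3, 4),
    "nmp22": (1, 2),
    "fish": (1, 2),
    "cxbladder": (1, 2),
}

#: lowest code that maps to a binary-positive outcome, per test
_POSITIVE_FROM: Mapping[str, int] = {"cytology": 3, "nmp22": 2, "fish": 2, "cxbladder": 2}

TRUTH_VALUES: tuple[str, ...] = ("UC", "nonUC", "other", "unknown")
PROVENANCE_VALUES: tuple[str, ...] = ("measured", "imputed", "missing")
GENDER_CODES: tuple[int, ...] = (1, 2)  # 1 male, 2 female

SRC_COLUMNS: tuple[str, ...] = tuple(f"{t}_src" for t in TESTS)
COHORT_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "dataset_id",
    "age",
    "gender",
    "truth",
    *TESTS,
    *SRC_COLUMNS,
)


class CodingError(ValueError):
    """A test code outside its alphabet, or an unknown test name."""


def to_binary(test_kind: str, code: int) -> str:
    """Map a coded test result to its binary outcome for UC.

    Cytology codes 1 (negative) and 2 (atypical) are binary-negative; 3
    (suspicious) and 4 (positive) are binary-positive.  For the other three
    tests code 1 is negative and 2 positive.

    Parameters
    ----------
    test_kind : one of ``TESTS``
    code : int
        A code in the test's alphabet.

    Returns
    -------
    str
        ``"positive"`` or ``"negative"``.
    """
    if test_kind not in ALPHABETS:
        raise CodingError(f"unknown test {test_kind!r}; expected one of {TESTS}")
    code = int(code)
    if code not in ALPHABETS[test_kind]:
        raise CodingError(
            f"code {code} is outside the {test_kind} alphabet {ALPHABETS[test_kind]}"
        )
    return "positive" if code >= _POSITIVE_FROM[test_kind] else "negative"


def binary_codes(test_kind: str, codes: "pd.Series | np.ndarray") -> pd.Series:
    """Vectorised binary mapping: 1 for positive, 0 for negative, NA passed through."""
    s = pd.Series(codes).astype("Float64")
    if test_kind not in ALPHABETS:
        raise CodingError(f"unknown test {test_kind!r}")
    valid = s.dropna()
    bad = valid[~valid.isin([float(c) for c in ALPHABETS[test_kind]])]
    if len(bad):
        raise CodingError(
            f"code {int(bad.iloc[0])} is outside the {test_kind} alphabet"
        )
    return (s >= _POSITIVE_FROM[test_kind]).astype("Float64").where(s.notna())


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts of a binary test against the cystoscopy truth."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_uc(self) -> int:
        return self.tp + self.fn

    @property
    def n_nonuc(self) -> int:
        return self.tn + self.fp


@dataclass
class SubjectRecord:
    """One subject's coded test results, covariates, truth and provenance."""

    subject_id: str
    dataset_id: int
    age: float
    gender: int
    truth: str
    cytology: int | None = None
    nmp22: int | None = None
    fish: int | None = None
    cxbladder: int | None = None
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in TESTS:
            self.provenance.setdefault(
                t, "missing" if getattr(self, t) is None else "measured"
            )

    @classmethod
    def from_series(cls, row: pd.Series) -> "SubjectRecord":
        def cell(t: str) -> int | None:
            v = row[t]
            return None if pd.isna(v) else int(v)

        return cls(
            subject_id=str(row["subject_id"]),
            dataset_id=int(row["dataset_id"]),
            age=float(row["age"]) if pd.notna(row["age"]) else float("nan"),
            gender=int(row["gender"]) if pd.notna(row["gender"]) else -1,
            truth=str(row["truth"]),
            cytology=cell("cytology"),
            nmp22=cell("nmp22"),
            fish=cell("fish"),
            cxbladder=cell("cxbladder"),
            provenance={t: str(row[f"{t}_src"]) for t in TESTS},
        )


def validate_record(record: SubjectRecord) -> list[str]:
    """Return the list of invariant violations for one record (empty if valid)."""
    violations: list[str] = []
    if not (1 <= record.dataset_id <= 5):
        violations.append(f"dataset_id: {record.dataset_id} not in 1..5")
    if not np.isfinite(record.age) or record.age <= 0:
        violations.append(f"age: missing or non-positive ({record.age})")
    if record.gender not in GENDER_CODES:
        violations.append(f"gender: {record.gender} not in {GENDER_CODES}")
    if record.truth not in TRUTH_VALUES:
        violations.append(f"truth: {record.truth!r} not in {TRUTH_VALUES}")
    for t in TESTS:
        code = getattr(record, t)
        src = record.provenance.get(t, "missing")
        if src not in PROVENANCE_VALUES:
            violations.append(f"{t}: provenance {src!r} not in {PROVENANCE_VALUES}")
        if code is None:
            if src != "missing":
                violations.append(f"{t}: missing cell with provenance {src!r}")
        else:
            if code not in ALPHABETS[t]:
                violations.append(f"{t}: code {code} outside alphabet {ALPHABETS[t]}")
            if src == "missing":
                violations.append(f"{t}: non-missing cell with provenance 'missing'")
    return violations


def validate_cohort(df: pd.DataFrame) -> list[str]:
    """Validate every row of a cohort frame; violations are prefixed by subject id."""
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        return [f"cohort: missing columns {missing_cols}"]
    out: list[str] = []
    for _, row in df.iterrows():
        for v in validate_record(SubjectRecord.from_series(row)):
            out.append(f"{row['subject_id']}: {v}")
    return out


def new_cohort_frame(rows: Iterable[dict]) -> pd.DataFrame:
    """Build a cohort frame with canonical dtypes from an iterable of row dicts."""
    df = pd.DataFrame(list(rows), columns=list(COHORT_COLUMNS))
    return coerce_cohort_dtypes(df)


def coerce_cohort_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    df["dataset_id"] = df["dataset_id"].astype(np.int64)
    df["age"] = df["age"].astype(np.float64)
    df["gender"] = df["gender"].astype(np.int64)
    df["truth"] = df["truth"].astype(str)
    for t in TESTS:
        df[t] = df[t].astype("Int64")
        df[f"{t}_src"] = df[f"{t}_src"].astype(str)
    return df[list(COHORT_COLUMNS)]


def read_cohort(path: str | Path, validate: bool = True) -> pd.DataFrame:
    """Read a cohort CSV (missing test cells as empty fields) into a typed frame.

    With ``validate=True`` (default) any record violating the cohort invariants
    raises, naming the subject, field and reason.
    """
    df = pd.read_csv(path, dtype={t: "Int64" for t in TESTS})
    for c in SRC_COLUMNS:
        if c not in df.columns:
            # provenance sidecars are optional on input; reconstruct from missingness
            t = c[: -len("_src")]
            df[c] = np.where(df[t].isna(), "missing", "measured")
    df = coerce_cohort_dtypes(df)
    if validate:
        violations = validate_cohort(df)
        if violations:
            raise CodingError(
                "invalid cohort: " + "; ".join(violations[:10])
                + ("..." if len(violations) > 10 else "")
            )
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort frame to CSV; missing cells serialize as empty fields."""
    coerce_cohort_dtypes(df).to_csv(path, index=False)
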