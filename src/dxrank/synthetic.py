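"""Seeded generator of multi-study cohorts with a prescribed missingness design.

The study design describes five contributing datasets: three primary-detection
hematuria cohorts and two surveillance cohorts, each measuring a different
subset of the four diagnostic tests.  The generator emits one record per
original subject, including the records that the integration stage will
discard (subjects without a cystoscopy truth, subjects with a single test
result), a configurable fraction of other-cause diagnoses among the non-UC
subjects, and individually missing cells inside otherwise-measured test
blocks.  All randomness flows through one :class:`numpy.random.Generator`, so
a seed fully determines the output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats

from .cohort import TESTS, coerce_cohort_dtypes
import pandas as pd


class DesignError(ValueError):
    """An inconsistent study design or generator parameterisation."""


@dataclass(frozen=True)
class DatasetDesign:
    """Blueprint of one contributing dataset."""

    dataset_id: int
    original_n: int
    analyzed_uc: int
    analyzed_nonuc: int
    measured_tests: tuple[str, ...]
    individual_missing: Mapping[str, int] = field(default_factory=dict)
    invalid_no_truth: int = 0
    invalid_single_test: int = 0
    setting: str = "primary"

    @property
    def invalid_records(self) -> int:
        return self.invalid_no_truth + self.invalid_single_test

    @property
    def analyzed_n(self) -> int:
        return self.analyzed_uc + self.analyzed_nonuc

    def validate(self) -> None:
        if self.analyzed_n + self.invalid_records != self.original_n:
            raise DesignError(
                f"dataset {self.dataset_id}: analyzed ({self.analyzed_n}) + invalid "
                f"({self.invalid_records}) != original_n ({self.original_n})"
            )
        unknown = set(self.measured_tests) - set(TESTS)
        if unknown:
            raise DesignError(f"dataset {self.dataset_id}: unknown tests {unknown}")
        if len(self.measured_tests) < 1:
            raise DesignError(f"dataset {self.dataset_id}: no measured tests")
        for t, m in self.individual_missing.items():
            if t not in self.measured_tests and m != 0:
                raise DesignError(
                    f"dataset {self.dataset_id}: individual_missing[{t}]={m} "
                    "but the test is not measured there"
                )
            if m < 0 or m > self.analyzed_n:
                raise DesignError(
                    f"dataset {self.dataset_id}: individual_missing[{t}]={m} out of range"
                )
        if self.setting not in ("primary", "surveillance"):
            raise DesignError(f"dataset {self.dataset_id}: setting {self.setting!r}")


@dataclass(frozen=True)
class StudyDesign:
    """Multi-dataset blueprint: sizes, prevalence, availability, invalid counts."""

    datasets: tuple[DatasetDesign, ...]

    def validate(self) -> None:
        if not self.datasets:
            raise DesignError("empty design")
        for d in self.datasets:
            d.validate()

    @property
    def total_original(self) -> int:
        return sum(d.original_n for d in self.datasets)

    @property
    def total_analyzed_uc(self) -> int:
        return sum(d.analyzed_uc for d in self.datasets)

    @property
    def total_analyzed_nonuc(self) -> int:
        return sum(d.analyzed_nonuc for d in self.datasets)

    def to_json(self, path: str | Path) -> None:
        payload = [asdict(d) for d in self.datasets]
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyDesign":
        payload = json.loads(Path(path).read_text())
        ds = tuple(
            DatasetDesign(
                **{
                    **d,
                    "measured_tests": tuple(d["measured_tests"]),
                    "individual_missing": dict(d.get("individual_missing", {})),
                }
            )
            for d in payload
        )
        design = cls(ds)
        design.validate()
        return design


def canonical_design() -> StudyDesign:
    """The five-dataset design of the UC case study.

    Dataset sizes, analyzed UC/non-UC counts and the test-availability pattern:

    ========  ==========  ===========  ==================================
    dataset   original n  UC / non-UC  measured tests
    ========  ==========  ===========  ==================================
    1         476         63 / 411     cytology, NMP22, Cxbladder Detect
    2          94          6 / 74      cytology, Cxbladder Detect
    3          84          5 / 63      cytology, Cxbladder Detect
    4         200          6 / 187     cytology, NMP22, FISH
    5         124          9 / 115     all four (+5 individually missing:
                                       2 NMP22, 3 cytology)
    ========  ==========  ===========  ==================================

    The difference between original and analyzed counts is split evenly between
    no-truth and single-test records (odd remainders go to no-truth).
    """
    rows = [
        (1, 476, 63, 411, ("cytology", "nmp22", "cxbladder"), {}, "primary"),
        (2, 94, 6, 74, ("cytology", "cxbladder"), {}, "primary"),
        (3, 84, 5, 63, ("cytology", "cxbladder"), {}, "primary"),
        (4, 200, 6, 187, ("cytology", "nmp22", "fish"), {}, "surveillance"),
        (
            5,
            124,
            9,
            115,
            ("cytology", "nmp22", "fish", "cxbladder"),
            {"nmp22": 2, "cytology": 3},
            "surveillance",
        ),
    ]
    datasets = []
    for ds_id, orig, uc, nonuc, tests, indiv, setting in rows:
        invalid = orig - uc - nonuc
        no_truth = (invalid + 1) // 2
        datasets.append(
            DatasetDesign(
                dataset_id=ds_id,
                original_n=orig,
                analyzed_uc=uc,
                analyzed_nonuc=nonuc,
                measured_tests=tests,
                individual_missing=indiv,
                invalid_no_truth=no_truth,
                invalid_single_test=invalid - no_truth,
                setting=setting,
            )
        )
    design = StudyDesign(tuple(datasets))
    design.validate()
    return design


#: per-test accuracies used as generator defaults: the measured sensitivities and
#: specificities observed on the integrated case-study data (fractions).
DEFAULT_ACCURACIES: Mapping[str, tuple[float, float]] = {
    "cytology": (0.455, 0.963),
    "nmp22": (0.449, 0.890),
    "fish": (0.400, 0.873),
    "cxbladder": (0.795, 0.822),
}


@dataclass(frozen=True)
class GeneratorParams:
    """Marginal accuracies and covariate distributions for the generator.

    ``sensitivity[t]`` / ``specificity[t]`` are P(test positive | UC) and
    P(test negative | non-UC).  ``atypical_frac`` is the share of atypical
    (code 2) among binary-negative cytology calls and ``suspicious_frac`` the
    share of suspicious (code 3) among binary-positive ones.  ``correlation``
    is the loading of a shared latent severity variable in a Gaussian copula
    across the tests of one subject; 0 makes the tests conditionally
    independent given truth (the default).
    """

    sensitivity: Mapping[str, float] = field(
        default_factory=lambda: {t: s for t, (s, _) in DEFAULT_ACCURACIES.items()}
    )
    specificity: Mapping[str, float] = field(
        default_factory=lambda: {t: p for t, (_, p) in DEFAULT_ACCURACIES.items()}
    )
    atypical_frac: float = 0.4
    suspicious_frac: float = 0.5
    age_mean: float = 65.0
    age_sd: float = 12.0
    age_floor: float = 18.0
    male_frac: float = 0.7
    other_cause_frac: float = 0.1
    correlation: float = 0.0

    def validate(self) -> None:
        for t in TESTS:
            for name, table in (("sensitivity", self.sensitivity), ("specificity", self.specificity)):
                v = table.get(t)
                if v is None or not (0.0 < v < 1.0):
                    raise DesignError(f"{name}[{t}]={v} must be in (0,1)")
        for name in ("atypical_frac", "suspicious_frac", "male_frac", "other_cause_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DesignError(f"{name}={v} must be in [0,1]")
        if not (0.0 <= self.correlation < 1.0):
            raise DesignError(f"correlation={self.correlation} must be in [0,1)")
        if self.age_sd <= 0 or self.age_floor <= 0:
            raise DesignError("age_sd and age_floor must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorParams":
        payload = json.loads(Path(path).read_text())
        params = cls(**payload)
        params.validate()
        return params


def _draw_ages(rng: np.random.Generator, n: int, params: GeneratorParams) -> np.ndarray:
    a = (params.age_floor - params.age_mean) / params.age_sd
    ages = stats.truncnorm.rvs(
        a, np.inf, loc=params.age_mean, scale=params.age_sd, size=n, random_state=rng
    )
    return np.round(ages, 1)

def _draw_test_positives(
    rng: np.random.Generator,
    is_uc: np.ndarray,
    tests: tuple[str, ...],
    params: GeneratorParams,
) -> dict[str, np.ndarray]:
    """Draw binary positivity per test via a Gaussian copula with shared loading."""
    n = is_uc.size
    rho = params.correlation
    z_shared = rng.standard_normal(n)
    out: dict[str, np.ndarray] = {}
    for t in tests:
        z = rho * z_shared + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        u = stats.norm.cdf(z)
        p_pos = np.where(is_uc, params.sensitivity[t], 1.0 - params.specificity[t])
        out[t] = u < p_pos
    return out


def _code_tests(
    rng: np.random.Generator,
    positives: dict[str, np.ndarray],
    params: GeneratorParams,
) -> dict[str, np.ndarray]:
    codes: dict[str, np.ndarray] = {}
    for t, pos in positives.items():
        n = pos.size
        if t == "cytology":
            u = rng.random(n)
            code = np.where(
                pos,
                np.where(u < params.suspicious_frac, 3, 4),
                np.where(u < params.atypical_frac, 2, 1),
            )
        else:
            code = np.where(pos, 2, 1)
        codes[t] = code.astype(np.int64)
    return codes


def generate(
    design: StudyDesign | None = None,
    params: GeneratorParams | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Generate a full multi-study cohort frame from a design and parameters.

    Emits exactly ``original_n`` records per dataset: the analyzed UC and
    non-UC subjects (a fraction of the latter labelled as other-cause
    diagnoses), plus the invalid records — unknown-truth subjects with all of
    the dataset's tests measured, and single-test subjects with a known truth.
    Individually-missing cells are blanked in distinct analyzed records so
    that no record loses more than one measured value.

    Returns a cohort frame (see :mod:`dxrank.cohort`) whose rows are shuffled
    within each dataset.
    """
    design = design or canonical_design()
    params = params or GeneratorParams()
    design.validate()
    params.validate()
    rng = np.random.default_rng(seed)

    frames = []
    for d in design.datasets:
        n = d.original_n
        truth = np.empty(n, dtype=object)
        latent_uc = np.zeros(n, dtype=bool)

        i0 = 0
        # analyzed UC
        truth[i0 : i0 + d.analyzed_uc] = "UC"
        latent_uc[i0 : i0 + d.analyzed_uc] = True
        i0 += d.analyzed_uc
        # analyzed non-UC, with an other-cause slice (reclassified at integration)
        n_other = int(round(params.other_cause_frac * d.analyzed_nonuc))
        truth[i0 : i0 + n_other] = "other"
        truth[i0 + n_other : i0 + d.analyzed_nonuc] = "nonUC"
        i0 += d.analyzed_nonuc
        prevalence = d.analyzed_uc / max(d.analyzed_n, 1)
        # invalid: no cystoscopy truth (all tests measured)
        nt = d.invalid_no_truth
        truth[i0 : i0 + nt] = "unknown"
        latent_uc[i0 : i0 + nt] = rng.random(nt) < prevalence
        i0 += nt
        # invalid: single available test (truth known)
        st = d.invalid_single_test
        st_uc = rng.random(st) < prevalence
        truth[i0 : i0 + st] = np.where(st_uc, "UC", "nonUC")
        latent_uc[i0 : i0 + st] = st_uc
        single_test_rows = np.arange(i0, i0 + st)
        single_test_keep = rng.choice(len(d.measured_tests), size=st)

        latent_uc[: d.analyzed_uc + d.analyzed_nonuc] = (
            truth[: d.analyzed_uc + d.analyzed_nonuc] == "UC"
        )

        positives = _draw_test_positives(rng, latent_uc, d.measured_tests, params)
        codes = _code_tests(rng, positives, params)

        cols: dict[str, np.ndarray] = {}
        for t in TESTS:
            col = np.full(n, np.nan)
            src = np.full(n, "missing", dtype=object)
            if t in d.measured_tests:
                col[:] = codes[t]
                src[:] = "measured"
            cols[t] = col
            cols[f"{t}_src"] = src

        # single-test records keep exactly one measured test
        for row, keep_idx in zip(single_test_rows, single_test_keep):
            keep = d.measured_tests[keep_idx]
            for t in d.measured_tests:
                if t != keep:
                    cols[t][row] = np.nan
                    cols[f"{t}_src"][row] = "missing"

        # individually missing cells among analyzed records, in distinct rows
        total_indiv = sum(d.individual_missing.values())
        if total_indiv:
            pool = rng.choice(d.analyzed_n, size=total_indiv, replace=False)
            k = 0
            for t in sorted(d.individual_missing):
                for _ in range(d.individual_missing[t]):
                    row = pool[k]
                    k += 1
                    cols[t][row] = np.nan
                    cols[f"{t}_src"][row] = "missing"

        ages = _draw_ages(rng, n, params)
        gender = np.where(rng.random(n) < params.male_frac, 1, 2)

        order = rng.permutation(n)
        frame = {
            "subject_id": np.array([f"D{d.dataset_id}-{j:04d}" for j in range(n)]),
            "dataset_id": np.full(n, d.dataset_id, dtype=np.int64),
            "age": ages,
            "gender": gender,
            "truth": truth,
            **cols,
        }
        frames.append(pd.DataFrame(frame).iloc[order].reset_index(drop=True))

    df = pd.concat(frames, ignore_index=True)
    for t in TESTS:
        df[t] = df[t].round().astype("Int64")
    return coerce_cohort_dtypes(df)
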