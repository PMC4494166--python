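"""Merging per-study cohorts into one integrated dataset.

Two discard rules and one reclassification are applied, in a fixed order so
audit reasons are unambiguous: records lacking a cystoscopy gold-standard
truth are discarded first, then records with fewer than two non-missing test
results; surviving other-cause diagnoses (e.g. kidney stones) are reclassified
to non-UC.  Age and gender never count toward the two-test threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .cohort import TESTS, coerce_cohort_dtypes


class IntegrationError(ValueError):
    def __init__(self, message: str, audit: Mapping | None = None):
        super().__init__(message)
        self.audit = dict(audit or {})


@dataclass
class IntegratedDataset:
    """Integrated records (truth restricted to UC/nonUC) plus a discard audit."""

    records: pd.DataFrame
    audit: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_uc(self) -> int:
        return int((self.records["truth"] == "UC").sum())

    @property
    def n_nonuc(self) -> int:
        return int((self.records["truth"] == "nonUC").sum())


def _as_frame(data: "pd.DataFrame | IntegratedDataset") -> pd.DataFrame:
    return data.records if isinstance(data, IntegratedDataset) else data


def integrate(records: "pd.DataFrame | IntegratedDataset") -> IntegratedDataset:
    """Apply the discard and reclassification rules and return the merged dataset.

    Raises :class:`IntegrationError` on empty input or when every record is
    discarded (the audit is attached to the exception).  Integration is
    idempotent: integrating an already-integrated dataset leaves it unchanged.
    """
    df = _as_frame(records)
    if len(df) == 0:
        raise IntegrationError("cannot integrate an empty record set")
    df = coerce_cohort_dtypes(df)

    n_tests = df[list(TESTS)].notna().sum(axis=1)
    no_truth = df["truth"] == "unknown"
    single_test = ~no_truth & (n_tests < 2)
    keep = ~(no_truth | single_test)

    per_dataset = {}
    for ds_id, grp in df.groupby("dataset_id"):
        idx = grp.index
        per_dataset[int(ds_id)] = {
            "input": int(len(grp)),
            "discarded_no_truth": int(no_truth[idx].sum()),
            "discarded_single_test": int(single_test[idx].sum()),
            "retained": int(keep[idx].sum()),
        }

    out = df.loc[keep].copy()
    reclassified = out["truth"] == "other"
    out.loc[reclassified, "truth"] = "nonUC"

    audit = {
        "input": int(len(df)),
        "discarded_no_truth": int(no_truth.sum()),
        "discarded_single_test": int(single_test.sum()),
        "reclassified_other": int(reclassified.sum()),
        "retained": int(len(out)),
        "per_dataset": per_dataset,
    }
    if len(out) == 0:
        raise IntegrationError("all records were discarded during integration", audit)
    return IntegratedDataset(records=out.reset_index(drop=True), audit=audit)


@dataclass(frozen=True)
class MissingnessSummary:
    """Missing-cell counts per test and per (dataset, test) block."""

    per_test: Mapping[str, int]
    per_block: pd.DataFrame  # index dataset_id, columns the four tests

    def block(self, dataset_id: int, test: str) -> int:
        return int(self.per_block.loc[dataset_id, test])


def missingness_summary(ds: IntegratedDataset) -> MissingnessSummary:
    """Exact missing-cell counts in an integrated dataset.

    Age and gender are complete by construction and carry no entry.
    """
    df = ds.records
    per_test = {t: int(df[t].isna().sum()) for t in TESTS}
    per_block = (
        df.groupby("dataset_id")[list(TESTS)]
        .apply(lambda g: g.isna().sum())
        .astype(int)
    )
    return MissingnessSummary(per_test=per_test, per_block=per_block)
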