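"""Signal-to-noise (SNR) separation index and test ranking.

The index treats the mean of a variable among UC subjects as "signal" and its
mean among non-UC subjects as "noise":

    snr = |mean_UC - mean_nonUC| / (sd_UC + sd_nonUC)

with population (ddof=0) standard deviations.  Larger values mean better
separation between the two diagnostic groups.  Missing values are removed per
variable (complete cases per column), so the ranking can be computed on
measured data before any imputation as well as on fully imputed data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import TESTS, binary_codes
from .integration import IntegratedDataset

#: variables entering the ranking besides the four tests
COVARIATES: tuple[str, ...] = ("age", "gender")


class RankingError(ValueError):
    pass


def snr_index(values, labels) -> float:
    """SNR separation index of one variable between the UC and non-UC groups.

    Parameters
    ----------
    values : array-like of numbers, NaN marks missing cells
    labels : array-like of the same length; truthy / "UC" marks the UC group

    Raises
    ------
    RankingError
        if a group is empty after missing-value removal, or if both group
        standard deviations are zero while the means differ (undefined ratio).
    """
    v = np.asarray(pd.Series(values, dtype="Float64").astype(float))
    lab = np.asarray(labels)
    if lab.dtype.kind in ("U", "O"):
        is_uc = lab == "UC"
    else:
        is_uc = lab.astype(bool)
    ok = np.isfinite(v)
    uc, nonuc = v[ok & is_uc], v[ok & ~is_uc]
    if uc.size == 0 or nonuc.size == 0:
        raise RankingError("a group is empty after missing-value removal")
    m1, m2 = uc.mean(), nonuc.mean()
    s1, s2 = uc.std(ddof=0), nonuc.std(ddof=0)
    if s1 + s2 == 0.0:
        if m1 == m2:
            return 0.0
        raise RankingError("both group standard deviations are zero with unequal means")
    return float(abs(m1 - m2) / (s1 + s2))


@dataclass
class SNRRanking:
    """Per-variable SNR indices plus the descending ordering.

    ``table`` has one row per variable with columns
    variable, n_uc, n_nonuc, mean_uc, mean_nonuc, sd_uc, sd_nonuc, snr, rank;
    variables without data in one group get NaN snr and no rank.
    ``ordering`` lists the ranked variables by descending index (alphabetical
    tie-break).
    """

    table: pd.DataFrame
    ordering: list[str]

    def index_of(self, variable: str) -> float:
        return float(self.table.set_index("variable").loc[variable, "snr"])

    @property
    def top(self) -> str:
        return self.ordering[0]


def _variable_values(df: pd.DataFrame, variable: str, coding: str) -> pd.Series:
    if variable in TESTS and coding == "binary":
        # negative -> 1, positive -> 2, keeping the 1-based code style
        return binary_codes(variable, df[variable]) + 1
    return df[variable].astype("Float64")


def rank_tests(
    ds: "IntegratedDataset | pd.DataFrame",
    coding: str = "multilevel",
    variables: tuple[str, ...] = TESTS + COVARIATES,
) -> SNRRanking:
    """Rank the diagnostic tests (plus age and gender) by SNR index.

    ``coding='multilevel'`` (default) uses the raw codes — cytology on its
    four-level 1-4 scale; ``coding='binary'`` collapses every test to its
    binary outcome first.  Ordering is by descending index with alphabetical
    tie-break.  A variable with no data in one group is reported with an
    undefined (NaN) index and excluded from the ordering.
    """
    if coding not in ("multilevel", "binary"):
        raise RankingError(f"unknown coding {coding!r}")
    df = ds.records if isinstance(ds, IntegratedDataset) else ds
    is_uc = df["truth"] == "UC"
    rows = []
    for var in variables:
        vals = _variable_values(df, var, coding).astype(float)
        ok = np.isfinite(vals)
        uc, nonuc = vals[ok & is_uc], vals[ok & ~is_uc]
        row = {
            "variable": var,
            "n_uc": int(uc.size),
            "n_nonuc": int(nonuc.size),
            "mean_uc": uc.mean() if uc.size else np.nan,
            "mean_nonuc": nonuc.mean() if nonuc.size else np.nan,
            "sd_uc": uc.std(ddof=0) if uc.size else np.nan,
            "sd_nonuc": nonuc.std(ddof=0) if nonuc.size else np.nan,
        }
        if uc.size == 0 or nonuc.size == 0:
            row["snr"] = np.nan
        elif row["sd_uc"] + row["sd_nonuc"] == 0.0 and row["mean_uc"] != row["mean_nonuc"]:
            # a perfectly separating constant-in-each-group variable: unbounded
            # separation, ranked first (snr_index itself raises on this input)
            row["snr"] = np.inf
        else:
            row["snr"] = snr_index(vals.values, is_uc.values)
        rows.append(row)
    table = pd.DataFrame(rows)
    ranked = table.dropna(subset=["snr"]).sort_values(
        ["snr", "variable"], ascending=[False, True], kind="stable"
    )
    ordering = ranked["variable"].tolist()
    table["rank"] = table["variable"].map(
        {v: i + 1 for i, v in enumerate(ordering)}
    ).astype("Int64")
    return SNRRanking(table=table, ordering=ordering)
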