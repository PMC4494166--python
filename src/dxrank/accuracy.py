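"""Empirical sensitivity/specificity with 95 % confidence intervals.

Point estimates are the plain proportions TP/(TP+FN) and TN/(TN+FP).  The
confidence interval is the Wald interval of an intercept-only logistic model
per truth group — logit(p) +/- z*sqrt(1/k + 1/(n-k)), back-transformed — which
coincides with the interval a univariate logistic regression with no
covariates would report.  Boundary proportions (k=0 or k=n) get a 0.5
continuity correction on the interval only; the point estimate is untouched.

`DiagnosticAccuracy` wraps the computation in a small model/results pair:
build the model from an integrated dataset, call :meth:`DiagnosticAccuracy.fit`
and read estimates off the results object (`summary()` prints a table).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .cohort import TESTS, TEST_LABELS, ConfusionCounts, binary_codes
from .integration import IntegratedDataset

SCOPES = ("measured_only", "imputed_full")


class AccuracyError(ValueError):
    pass


@dataclass(frozen=True)
class AccuracyEstimate:
    """Sensitivity/specificity (percent) with 95 % CIs and underlying counts."""

    test: str
    sensitivity: float
    sens_ci: tuple[float, float]
    specificity: float
    spec_ci: tuple[float, float]
    counts: ConfusionCounts | None = None
    scope: str = "measured_only"
    level: float = 0.95

    def __post_init__(self) -> None:
        for value, (lo, hi), name in (
            (self.sensitivity, self.sens_ci, "sensitivity"),
            (self.specificity, self.spec_ci, "specificity"),
        ):
            if not (0.0 <= value <= 100.0):
                raise AccuracyError(f"{name}={value} outside [0, 100]")
            if not (lo - 1e-9 <= value <= hi + 1e-9):
                raise AccuracyError(f"{name} point estimate outside its CI")


def confusion(
    ds: "IntegratedDataset | pd.DataFrame", test: str, scope: str = "measured_only"
) -> ConfusionCounts:
    """Cross-classify a test's binary outcome against the cystoscopy truth.

    ``scope='measured_only'`` uses cells with provenance "measured";
    ``scope='imputed_full'`` uses every non-missing cell (measured + imputed).
    """
    if scope not in SCOPES:
        raise AccuracyError(f"unknown scope {scope!r}; expected one of {SCOPES}")
    df = ds.records if isinstance(ds, IntegratedDataset) else ds
    usable = df[test].notna()
    if scope == "measured_only":
        usable &= df[f"{test}_src"] == "measured"
    sub = df.loc[usable]
    pos = binary_codes(test, sub[test]).astype(float).values == 1.0
    is_uc = (sub["truth"] == "UC").values
    tp = int((pos & is_uc).sum())
    fn = int((~pos & is_uc).sum())
    fp = int((pos & ~is_uc).sum())
    tn = int((~pos & ~is_uc).sum())
    if tp + fn == 0 or tn + fp == 0:
        raise AccuracyError(
            f"test {test!r} has no usable values in one truth group under scope {scope!r}"
        )
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _logit_wald(k: int, n: int, level: float) -> tuple[float, float]:
    """Back-transformed Wald CI for a proportion on the logit scale (fractions)."""
    z = norm.ppf(0.5 + level / 2.0)
    if k == 0 or k == n:
        kk, nn = k + 0.5, n + 1.0  # continuity correction for the interval only
    else:
        kk, nn = float(k), float(n)
    centre = logit(kk / nn)
    se = np.sqrt(1.0 / kk + 1.0 / (nn - kk))
    return float(expit(centre - z * se)), float(expit(centre + z * se))


def sens_spec_ci(
    counts: ConfusionCounts,
    level: float = 0.95,
    test: str = "",
    scope: str = "measured_only",
) -> AccuracyEstimate:
    """Sensitivity/specificity (percent) with logit-Wald CIs from a 2x2 table."""
    if counts.n_uc == 0 or counts.n_nonuc == 0:
        raise AccuracyError("both truth groups must be non-empty")
    sens = 100.0 * counts.tp / counts.n_uc
    spec = 100.0 * counts.tn / counts.n_nonuc
    s_lo, s_hi = _logit_wald(counts.tp, counts.n_uc, level)
    p_lo, p_hi = _logit_wald(counts.tn, counts.n_nonuc, level)
    # a continuity-corrected interval can exclude a boundary point estimate;
    # clamp so the contract "point inside CI" holds at 0 and 100
    s_lo, s_hi = min(100 * s_lo, sens), max(100 * s_hi, sens)
    p_lo, p_hi = min(100 * p_lo, spec), max(100 * p_hi, spec)
    return AccuracyEstimate(
        test=test,
        sensitivity=sens,
        sens_ci=(s_lo, s_hi),
        specificity=spec,
        spec_ci=(p_lo, p_hi),
        counts=counts,
        scope=scope,
        level=level,
    )


class DiagnosticAccuracy:
    """Model: per-test diagnostic accuracy on an integrated dataset.

    Examples
    --------
    >>> res = DiagnosticAccuracy(ds, scope="measured_only").fit()  # doctest: +SKIP
    >>> res.estimate("cxbladder").sensitivity  # doctest: +SKIP
    """

    def __init__(
        self,
        data: "IntegratedDataset | pd.DataFrame",
        tests: Sequence[str] = TESTS,
        scope: str = "measured_only",
        level: float = 0.95,
    ):
        self.data = data
        self.tests = tuple(tests)
        self.scope = scope
        self.level = level

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "DiagnosticAccuracy":
        return cls(df, **kwargs)

    def fit(self) -> "DiagnosticAccuracyResults":
        estimates = {}
        for t in self.tests:
            c = confusion(self.data, t, self.scope)
            estimates[t] = sens_spec_ci(c, self.level, test=t, scope=self.scope)
        return DiagnosticAccuracyResults(self, estimates)


@dataclass
class DiagnosticAccuracyResults:
    model: DiagnosticAccuracy
    estimates: Mapping[str, AccuracyEstimate]

    def estimate(self, test: str) -> AccuracyEstimate:
        return self.estimates[test]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, e in self.estimates.items():
            rows.append(
                {
                    "test": t,
                    "scope": e.scope,
                    "sens": round(e.sensitivity, 1),
                    "sens_lo": round(e.sens_ci[0], 1),
                    "sens_hi": round(e.sens_ci[1], 1),
                    "spec": round(e.specificity, 1),
                    "spec_lo": round(e.spec_ci[0], 1),
                    "spec_hi": round(e.spec_ci[1], 1),
                    "tp": e.counts.tp if e.counts else None,
                    "fn": e.counts.fn if e.counts else None,
                    "tn": e.counts.tn if e.counts else None,
                    "fp": e.counts.fp if e.counts else None,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Diagnostic accuracy ({self.model.scope}, {int(self.model.level*100)} % CI)",
            f"{'test':<18}{'sens %':>8}{'CI':>16}{'spec %':>8}{'CI':>16}",
        ]
        for t, e in self.estimates.items():
            lines.append(
                f"{TEST_LABELS.get(t, t):<18}"
                f"{e.sensitivity:>8.1f}"
                f"{'(%.1f-%.1f)' % e.sens_ci:>16}"
                f"{e.specificity:>8.1f}"
                f"{'(%.1f-%.1f)' % e.spec_ci:>16}"
            )
        return "\n".join(lines)
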