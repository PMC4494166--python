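"""Validation of the imputation methods.

Two complementary checks:

* leave-one-out (LOO) cross-validation — each complete record in a training
  pool is held out in turn, its target imputed from the rest, and accuracy is
  the percentage of correctly imputed values.  Correctness is judged on the
  binary diagnostic mapping by default (sensitivity/specificity are the
  downstream use); a strict-code option compares the raw codes, which matters
  only for four-level cytology.
* measured-vs-imputed distortion — the change in a test's sensitivity and
  specificity between the measured-only dataset and the fully imputed one
  (sign convention: measured minus imputed, percentage points), plus the
  average absolute difference (|sens_diff| + |spec_diff|) / 2.

``validate_methods`` produces the full report over backends x modes, with a
"mean for method" row per combination, and ``select_best`` picks the method
under the lexicographic objective (highest mean LOO accuracy, then lowest
mean average absolute difference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accuracy import confusion, sens_spec_ci
from .cohort import TESTS, _POSITIVE_FROM
from .imputation import (
    BackendConfig,
    ImputationPlan,
    ImputationStep,
    canonical_plan,
    knn_impute,
    model_impute,
    run_plan,
    _training_pool,
)
from .integration import IntegratedDataset


class ValidationError(ValueError):
    pass


def _binary(target: str, codes: np.ndarray) -> np.ndarray:
    return codes >= _POSITIVE_FROM[target]


def loo_accuracy(
    pool: pd.DataFrame,
    inputs,
    target: str,
    backend: BackendConfig,
    strict: bool = False,
    max_eval: int | None = None,
    seed: int = 0,
) -> float:
    """Leave-one-out accuracy (%) of one backend on a complete training pool.

    Every pool row must be complete on inputs and target.  With ``max_eval``
    set, accuracy is evaluated on a seeded random subsample of held-out rows
    (each still imputed from the full remainder) — an economy for the costly
    model backends on large pools.
    """
    cols = list(inputs) + [target]
    if pool[cols].isna().any().any():
        raise ValidationError("LOO pool must be complete on inputs and target")
    n = len(pool)
    need = backend.k + 1 if backend.kind == "knn" else len(inputs) + 2
    if n < need:
        raise ValidationError(f"LOO pool too small: {n} records, need >= {need}")
    rows = np.arange(n)
    if max_eval is not None and max_eval < n:
        rng = np.random.default_rng(seed)
        rows = np.sort(rng.choice(n, size=max_eval, replace=False))
    correct = 0
    for i in rows:
        train = pool.iloc[np.delete(np.arange(n), i)]
        query = pool.iloc[[i]]
        if backend.kind == "knn":
            pred = knn_impute(train, query, inputs, target, backend.k, backend.supervised)
        else:
            pred = model_impute(train, query, inputs, target, backend)
        truth_code = int(query[target].iloc[0])
        if strict:
            hit = int(pred[0]) == truth_code
        else:
            hit = _binary(target, pred)[0] == _binary(target, np.array([truth_code]))[0]
        correct += int(hit)
    return 100.0 * correct / len(rows)


def before_after(
    measured: IntegratedDataset, imputed: IntegratedDataset, test: str
) -> tuple[float, float, float]:
    """(sens_diff, spec_diff, avg_abs_diff) between measured and imputed data.

    Differences are in percentage points, signed measured minus imputed;
    ``avg_abs_diff`` = (|sens_diff| + |spec_diff|) / 2.
    """
    if len(measured) != len(imputed):
        raise ValidationError("measured and imputed datasets must cover the same subjects")
    em = sens_spec_ci(confusion(measured, test, "measured_only"), test=test)
    ei = sens_spec_ci(confusion(imputed, test, "imputed_full"), test=test, scope="imputed_full")
    sens_diff = em.sensitivity - ei.sensitivity
    spec_diff = em.specificity - ei.specificity
    return sens_diff, spec_diff, (abs(sens_diff) + abs(spec_diff)) / 2.0


def method_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Append a "mean for method" row per (backend, mode) to a validation report.

    Signed columns are averaged with sign; ``avg_abs_diff`` is averaged as is.
    """
    num_cols = ["loo_acc", "sens_diff", "spec_diff", "avg_abs_diff"]
    out = []
    for (backend, mode), grp in report.groupby(["backend", "mode"], sort=False):
        out.append(grp)
        mean_row = {c: grp[c].mean() for c in num_cols}
        mean_row.update({"test": "mean_for_method", "backend": backend, "mode": mode})
        out.append(pd.DataFrame([mean_row], columns=report.columns))
    return pd.concat(out, ignore_index=True)


def _loo_step_for(plan: ImputationPlan, test: str) -> ImputationStep:
    """The plan's final step targeting a test: the largest training pool for it."""
    steps = [s for s in plan.steps if s.target_variable == test]
    if not steps:
        raise ValidationError(f"plan has no step imputing {test!r}")
    return steps[-1]


def validate_methods(
    ds: IntegratedDataset,
    backends=("3nn", "5nn", "10nn", "mlr", "mlp"),
    modes=("supervised", "unsupervised"),
    plan: ImputationPlan | None = None,
    seed: int = 0,
    max_eval: int | None = None,
) -> pd.DataFrame:
    """Full validation report: LOO accuracy and measured-vs-imputed distortion.

    For each backend and mode, the plan is executed once on the integrated
    dataset, the per-test accuracy differences computed, and per-test LOO
    accuracy evaluated on the training pool of the plan's final step for that
    test (measured data only).  Returns rows
    (test, backend, mode, loo_acc, sens_diff, spec_diff, avg_abs_diff) plus
    mean_for_method rows.
    """
    plan = plan or canonical_plan()
    rows = []
    for name in backends:
        for mode in modes:
            backend = BackendConfig.from_name(name, supervised=(mode == "supervised"), seed=seed)
            run = run_plan(ds, plan, backend)
            for test in TESTS:
                step = _loo_step_for(plan, test)
                pool = _training_pool(ds.records, step)
                acc = loo_accuracy(
                    pool, step.input_variables, test, backend,
                    max_eval=max_eval, seed=seed,
                )
                sd, pd_, aad = before_after(ds, run.dataset, test)
                rows.append(
                    {
                        "test": test,
                        "backend": name,
                        "mode": mode,
                        "loo_acc": acc,
                        "sens_diff": sd,
                        "spec_diff": pd_,
                        "avg_abs_diff": aad,
                    }
                )
    return method_summary(pd.DataFrame(rows))


def select_best(report: pd.DataFrame) -> tuple[str, str]:
    """Best (backend, mode) under the lexicographic combined objective.

    Maximise mean LOO accuracy; break ties by minimal mean avg_abs_diff.
    """
    means = report[report["test"] == "mean_for_method"]
    if means.empty:
        raise ValidationError("report has no mean_for_method rows")
    ordered = means.sort_values(
        ["loo_acc", "avg_abs_diff", "backend", "mode"],
        ascending=[False, True, True, True],
        kind="stable",
    )
    top = ordered.iloc[0]
    return str(top["backend"]), str(top["mode"])
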