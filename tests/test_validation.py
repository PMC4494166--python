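"""Leave-one-out validation and measured-vs-imputed accuracy distortion."""

import numpy as np
import pandas as pd
import pytest

from dxrank import (
    BackendConfig,
    before_after,
    canonical_plan,
    integrate,
    loo_accuracy,
    method_summary,
    run_plan,
    select_best,
    validate_methods,
)
from dxrank.imputation import _encode, _standardize
from dxrank.validation import ValidationError

from conftest import make_pool, noisy_truth_pool


class TestLooAccuracy:
    def test_single_class_pool_is_perfect(self):
        rows = [dict(truth="UC", age=50.0 + i, fish=2, cytology=1) for i in range(6)]
        pool = make_pool(rows)
        for name in ("3nn", "mlr", "mlp"):
            cfg = BackendConfig.from_name(name)
            assert loo_accuracy(pool, ("age",), "fish", cfg) == 100.0

    def test_noiseless_supervised_is_perfect(self, noiseless_pool):
        for name in ("3nn", "5nn", "mlr", "mlp"):
            cfg = BackendConfig.from_name(name, supervised=True)
            assert loo_accuracy(noiseless_pool, ("age",), "fish", cfg) == 100.0

    def test_six_record_pool_matches_hand_enumeration(self):
        """3NN LOO on a 6-record pool equals an exhaustive per-record scan."""
        rng = np.random.default_rng(12)
        rows = [
            dict(
                truth="UC" if i % 2 else "nonUC",
                age=float(rng.integers(40, 80)),
                cytology=int(rng.integers(1, 5)),
                fish=int(rng.integers(1, 3)),
            )
            for i in range(6)
        ]
        pool = make_pool(rows)
        inputs = ("age", "cytology")
        cfg = BackendConfig.from_name("3nn")
        got = loo_accuracy(pool, inputs, "fish", cfg)

        correct = 0
        for i in range(6):
            train = pool.drop(index=i)
            Xtr = _encode(train, inputs, False)
            Xq = _encode(pool.iloc[[i]], inputs, False)
            Xtr, Xq = _standardize(Xtr, Xq)
            y = train["fish"].astype(int).to_numpy()
            d = np.sqrt(((Xtr - Xq[0]) ** 2).sum(axis=1))
            order = sorted(range(5), key=lambda j: (d[j], j))[:3]
            votes = {}
            for j in order:
                votes.setdefault(y[j], []).append(d[j])
            pred = min(votes, key=lambda c: (-len(votes[c]), sum(votes[c]), c))
            correct += int(pred == int(pool["fish"].iloc[i]))
        assert got == pytest.approx(100.0 * correct / 6)

    def test_supervised_at_least_as_accurate_when_truth_determines_target(self):
        """Averaged over seeds, adding the truth input cannot hurt a target
        that is a deterministic function of the truth."""
        diffs = []
        for seed in range(4):
            pool = noisy_truth_pool(seed)
            sup = loo_accuracy(pool, ("age", "gender", "cytology"), "nmp22",
                               BackendConfig.from_name("3nn", supervised=True))
            uns = loo_accuracy(pool, ("age", "gender", "cytology"), "nmp22",
                               BackendConfig.from_name("3nn", supervised=False))
            diffs.append(sup - uns)
        assert np.mean(diffs) >= 0

    def test_pool_too_small_raises(self):
        pool = make_pool([dict(truth="UC", age=50.0, fish=2, cytology=1)] * 3)
        with pytest.raises(ValidationError):
            loo_accuracy(pool, ("age",), "fish", BackendConfig.from_name("10nn"))

    def test_max_eval_subsamples_deterministically(self):
        pool = noisy_truth_pool(3, n=30)
        cfg = BackendConfig.from_name("3nn")
        a = loo_accuracy(pool, ("age",), "nmp22", cfg, max_eval=10, seed=5)
        b = loo_accuracy(pool, ("age",), "nmp22", cfg, max_eval=10, seed=5)
        assert a == b


class TestBeforeAfter:
    def test_identity_when_nothing_is_missing(self):
        pool = make_pool(
            [dict(truth="UC", cytology=4, nmp22=2, fish=2, cxbladder=2)] * 5
            + [dict(truth="nonUC", cytology=1, nmp22=1, fish=1, cxbladder=1)] * 5
        )
        ds = integrate(pool)
        assert before_after(ds, ds, "fish") == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize(
        "sens_diff,spec_diff,expected",
        [(2.68, 0.02, 1.35), (-1.38, 0.67, 1.03), (2.0, -2.0, 2.0)],
    )
    def test_average_absolute_difference_definition(self, sens_diff, spec_diff, expected):
        # expected values are quoted at two printed decimals (half-up rounding)
        assert (abs(sens_diff) + abs(spec_diff)) / 2 == pytest.approx(expected, abs=0.0051)

    def test_sign_convention_measured_minus_imputed(self, integrated):
        run = run_plan(integrated, canonical_plan(), BackendConfig.from_name("3nn"))
        from dxrank import confusion, sens_spec_ci

        sd, _, aad = before_after(integrated, run.dataset, "fish")
        em = sens_spec_ci(confusion(integrated, "fish", "measured_only"))
        ei = sens_spec_ci(confusion(run.dataset, "fish", "imputed_full"))
        assert sd == pytest.approx(em.sensitivity - ei.sensitivity)
        assert aad >= abs(sd) / 2

    def test_avg_abs_diff_invariant_to_sign_flip(self, integrated):
        run = run_plan(integrated, canonical_plan(), BackendConfig.from_name("5nn"))
        sd, pdiff, aad = before_after(integrated, run.dataset, "nmp22")
        assert aad == pytest.approx((abs(-sd) + abs(-pdiff)) / 2)


class TestMethodSummary:
    def _report(self, diffs):
        rows = []
        for i, (sd, pdiff) in enumerate(diffs):
            rows.append(
                dict(
                    test=f"t{i}",
                    backend="3nn",
                    mode="supervised",
                    loo_acc=90.0,
                    sens_diff=sd,
                    spec_diff=pdiff,
                    avg_abs_diff=(abs(sd) + abs(pdiff)) / 2,
                )
            )
        return pd.DataFrame(rows)

    def test_mean_of_identical_rows_equals_any_row(self):
        report = self._report([(2.0, 1.0)] * 4)
        out = method_summary(report)
        mean = out[out["test"] == "mean_for_method"].iloc[0]
        assert mean["sens_diff"] == 2.0 and mean["avg_abs_diff"] == 1.5

    def test_signed_columns_average_with_sign(self):
        report = self._report([(2.0, 0.0), (-2.0, 0.0), (2.0, 0.0), (-2.0, 0.0)])
        mean = method_summary(report).query("test == 'mean_for_method'").iloc[0]
        assert mean["sens_diff"] == 0.0
        assert mean["avg_abs_diff"] == 1.0  # mean of per-test absolute averages

    def test_matches_independent_column_averaging(self):
        rng = np.random.default_rng(2)
        diffs = [(float(rng.normal()), float(rng.normal())) for _ in range(4)]
        report = self._report(diffs)
        mean = method_summary(report).query("test == 'mean_for_method'").iloc[0]
        for col in ("loo_acc", "sens_diff", "spec_diff", "avg_abs_diff"):
            assert mean[col] == pytest.approx(float(np.mean(report[col])))


def test_select_best_is_lexicographic():
    rows = [
        dict(test="mean_for_method", backend="3nn", mode="supervised",
             loo_acc=90.0, sens_diff=0, spec_diff=0, avg_abs_diff=2.0),
        dict(test="mean_for_method", backend="mlr", mode="supervised",
             loo_acc=90.0, sens_diff=0, spec_diff=0, avg_abs_diff=1.0),
        dict(test="mean_for_method", backend="mlp", mode="unsupervised",
             loo_acc=85.0, sens_diff=0, spec_diff=0, avg_abs_diff=0.1),
    ]
    assert select_best(pd.DataFrame(rows)) == ("mlr", "supervised")


def test_validate_methods_report_shape(integrated):
    report = validate_methods(
        integrated, backends=("3nn",), modes=("supervised", "unsupervised"),
        max_eval=15, seed=0,
    )
    per_test = report[report["test"] != "mean_for_method"]
    assert len(per_test) == 8  # 4 tests x 2 modes
    assert ((report["loo_acc"] >= 0) & (report["loo_acc"] <= 100)).all()
    means = report[report["test"] == "mean_for_method"]
    assert len(means) == 2
    backend, mode = select_best(report)
    assert backend == "3nn" and mode in ("supervised", "unsupervised")
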