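"""Imputation plans, kNN/MLR/MLP backends, and plan execution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dxrank import (
    BackendConfig,
    auto_plan,
    canonical_plan,
    integrate,
    knn_impute,
    model_impute,
    run_plan,
)
from dxrank.cohort import ALPHABETS, TESTS
from dxrank.imputation import (
    ImputationError,
    ImputationStep,
    mlr_coefficients,
    _encode,
    _standardize,
)

from conftest import make_pool


class TestCanonicalPlan:
    def test_seven_steps(self):
        assert len(canonical_plan()) == 7

    def test_step_targets_in_order(self):
        steps = canonical_plan().steps
        got = [(s.target_datasets, s.target_variable) for s in steps]
        assert got == [
            ((5,), "nmp22"),
            ((5,), "cytology"),
            ((4,), "cxbladder"),
            ((2, 3), "nmp22"),
            ((3,), "fish"),
            ((2,), "fish"),
            ((1,), "fish"),
        ]

    def test_first_step_expects_two_cells(self):
        s1 = canonical_plan().steps[0]
        assert s1.expected_count == 2
        assert s1.training_datasets == (5,)
        assert set(s1.input_variables) == {"age", "gender", "cytology", "fish", "cxbladder"}

    def test_final_step_is_fish_in_dataset1(self):
        s7 = canonical_plan().steps[-1]
        assert s7.target_datasets == (1,) and s7.target_variable == "fish"
        assert s7.expected_count == 474
        assert s7.training_datasets == (1, 4, 5)

    def test_target_never_among_inputs(self):
        with pytest.raises(ImputationError):
            ImputationStep(1, (1,), ("age", "fish"), (2,), "fish")

    def test_json_roundtrip(self, tmp_path):
        plan = canonical_plan()
        plan.to_json(tmp_path / "plan.json")
        from dxrank.imputation import ImputationPlan

        back = ImputationPlan.from_json(tmp_path / "plan.json")
        assert back.steps == plan.steps and back.mode == "canonical"


class TestAutoPlan:
    def test_smallest_block_first_on_canonical_fixture(self, integrated):
        plan = auto_plan(integrated)
        first = plan.steps[0]
        assert first.target_datasets == (5,)
        assert first.target_variable == "nmp22"
        assert first.expected_count == 2

    def test_complete_dataset_gives_empty_plan(self):
        pool = make_pool(
            [dict(truth="UC", cytology=4, nmp22=2, fish=2, cxbladder=2)] * 4
        )
        assert len(auto_plan(integrate(pool))) == 0

    def test_equal_blocks_tie_break_by_test_name(self):
        rows = [dict(truth="UC", cytology=4, nmp22=2, fish=2, cxbladder=2)] * 6
        rows += [dict(truth="nonUC", cytology=1, nmp22=1, fish=None, cxbladder=None)] * 2
        plan = auto_plan(integrate(make_pool(rows)))
        assert [s.target_variable for s in plan.steps] == ["cxbladder", "fish"]

    def test_plan_covers_all_missing_blocks(self, integrated):
        plan = auto_plan(integrated)
        blocks = {(s.target_datasets[0], s.target_variable) for s in plan.steps}
        assert blocks == {
            (5, "nmp22"), (5, "cytology"), (4, "cxbladder"),
            (2, "nmp22"), (3, "nmp22"),
            (1, "fish"), (2, "fish"), (3, "fish"),
        }


def _toy_train(n=8, seed=0, target="fish"):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        rows.append(
            dict(
                truth="UC" if i % 2 else "nonUC",
                age=float(rng.integers(40, 80)),
                gender=int(rng.integers(1, 3)),
                cytology=int(rng.integers(1, 5)),
                nmp22=int(rng.integers(1, 3)),
                fish=int(rng.integers(1, 3)),
                cxbladder=int(rng.integers(1, 3)),
            )
        )
    return make_pool(rows)


class TestKnn:
    def test_unanimous_neighbourhood(self):
        train = make_pool(
            [dict(truth="UC", age=60 + i, fish=2, cytology=1) for i in range(3)]
            + [dict(truth="UC", age=90.0, fish=1, cytology=1)]
        )
        query = make_pool([dict(truth="UC", age=61.0, cytology=1)])
        assert knn_impute(train, query, ("age",), "fish", k=3)[0] == 2

    def test_identical_record_is_nearest(self):
        train = _toy_train(6)
        query = train.iloc[[2]].copy()
        pred = knn_impute(train, query, ("age", "gender", "cytology"), "fish", k=1)
        assert pred[0] == int(train["fish"].iloc[2])

    def test_vote_tie_broken_by_summed_distance_then_code(self):
        # two codes with one neighbour each at k=2: closer neighbour wins
        train = make_pool(
            [
                dict(truth="UC", age=50.0, fish=2),
                dict(truth="UC", age=70.0, fish=1),
                dict(truth="UC", age=100.0, fish=1),
            ]
        )
        query = make_pool([dict(truth="UC", age=55.0)])
        assert knn_impute(train, query, ("age",), "fish", k=2)[0] == 2
        # exact distance tie between codes: lowest code wins
        train2 = make_pool(
            [dict(truth="UC", age=50.0, fish=2), dict(truth="UC", age=70.0, fish=1)]
        )
        query2 = make_pool([dict(truth="UC", age=60.0)])
        assert knn_impute(train2, query2, ("age",), "fish", k=2)[0] == 1

    def test_fewer_than_k_records_raises(self):
        train = _toy_train(2)
        with pytest.raises(ImputationError):
            knn_impute(train, train.iloc[[0]], ("age",), "fish", k=3)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(4, 20),
        k=st.sampled_from([3, 5, 10]),
    )
    def test_agrees_with_exhaustive_oracle(self, seed, n, k):
        """Prediction equals a brute-force scan over every training record."""
        if n < k:
            return
        train = _toy_train(n, seed=seed)
        query = _toy_train(3, seed=seed + 1)
        inputs = ("age", "gender", "cytology")
        pred = knn_impute(train, query, inputs, "fish", k=k)

        Xtr = _encode(train, inputs, False)
        Xq = _encode(query, inputs, False)
        Xtr, Xq = _standardize(Xtr, Xq)
        y = train["fish"].astype(int).to_numpy()
        for j, x in enumerate(Xq):
            d = np.array([np.sqrt(((x - r) ** 2).sum()) for r in Xtr])
            order = sorted(range(n), key=lambda i: (d[i], i))[:k]
            codes = {}
            for i in order:
                codes.setdefault(y[i], []).append(d[i])
            expected = min(
                codes, key=lambda c: (-len(codes[c]), sum(codes[c]), c)
            )
            assert pred[j] == expected


class TestModelImpute:
    def test_mlr_matches_normal_equations(self):
        train = _toy_train(6, seed=3)
        inputs = ("age", "cytology")
        beta = mlr_coefficients(train, inputs, "fish")
        X = np.column_stack(
            [np.ones(6), train["age"].astype(float), train["cytology"].astype(float)]
        )
        y = train["fish"].astype(float).to_numpy()
        expected = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(beta, expected)

    def test_mlr_predictions_rounded_to_alphabet(self):
        train = _toy_train(12, seed=4)
        queries = _toy_train(5, seed=5)
        for target in ("fish", "cytology"):
            inputs = tuple(v for v in ("age", "gender", "nmp22") if v != target)
            pred = model_impute(train, queries, inputs, target, BackendConfig(kind="mlr"))
            assert set(pred).issubset(set(ALPHABETS[target]))

    def test_constant_target_predicts_constant(self):
        train = _toy_train(6)
        train["fish"] = 2
        queries = _toy_train(4, seed=9)
        for kind in ("mlr", "mlp"):
            pred = model_impute(train, queries, ("age",), "fish", BackendConfig(kind=kind))
            assert (pred == 2).all()

    def test_singular_design_matrix_names_collinear_inputs(self):
        train = _toy_train(6)
        train["gender"] = 1  # constant column
        with pytest.raises(ImputationError, match="gender"):
            mlr_coefficients(train, ("age", "gender"), "fish")

    def test_mlp_is_deterministic_given_seed(self):
        train = _toy_train(30, seed=6)
        queries = _toy_train(10, seed=7)
        cfg = BackendConfig(kind="mlp", seed=42)
        a = model_impute(train, queries, ("age", "gender", "cytology"), "fish", cfg)
        b = model_impute(train, queries, ("age", "gender", "cytology"), "fish", cfg)
        assert (a == b).all()

    def test_logistic_variant_stays_in_alphabet(self):
        train = _toy_train(20, seed=8)
        queries = _toy_train(6, seed=9)
        cfg = BackendConfig(kind="mlr", logistic=True)
        pred = model_impute(train, queries, ("age", "cytology"), "fish", cfg)
        assert set(pred).issubset({1, 2})


@pytest.mark.parametrize("backend_name", ["3nn", "5nn", "10nn", "mlr", "mlp"])
@pytest.mark.parametrize("supervised", [False, True])
class TestRunPlan:
    def test_canonical_plan_fills_everything(self, integrated, backend_name, supervised):
        cfg = BackendConfig.from_name(backend_name, supervised=supervised, seed=1)
        run = run_plan(integrated, canonical_plan(), cfg)
        df = run.dataset.records
        assert int(df[list(TESTS)].isna().sum().sum()) == 0
        assert run.steps[-1].n_imputed == 474
        # measured cells bit-identical before and after
        for t in TESTS:
            measured = integrated.records[f"{t}_src"] == "measured"
            pd.testing.assert_series_equal(
                integrated.records.loc[measured, t], df.loc[measured, t]
            )
            assert (df.loc[measured, f"{t}_src"] == "measured").all()
        # imputed cells flagged and inside the alphabet
        for t in TESTS:
            imputed = df[f"{t}_src"] == "imputed"
            assert df.loc[imputed, t].notna().all()
            assert df.loc[imputed, t].isin(ALPHABETS[t]).all()


def test_step_counts_match_missing_blocks(integrated):
    run = run_plan(integrated, canonical_plan(), BackendConfig.from_name("3nn"))
    by_step = [s.n_imputed for s in run.steps]
    assert by_step == [2, 3, 193, 148, 68, 80, 474]


def test_seventy_percent_known_data_rule_logged(integrated):
    run = run_plan(integrated, canonical_plan(), BackendConfig.from_name("3nn"))
    assert all(s.known_data_ok for s in run.steps)
    assert all(s.measured_fraction >= 0.7 for s in run.steps)


def test_empty_training_pool_raises():
    rows = [dict(truth="UC", cytology=4, cxbladder=2, dataset_id=1)] * 3
    ds = integrate(make_pool(rows))
    step = ImputationStep(1, (1,), ("age", "gender"), (1,), "fish")
    from dxrank.imputation import ImputationPlan

    with pytest.raises(ImputationError, match="training pool"):
        run_plan(ds, ImputationPlan([step]), BackendConfig.from_name("3nn"))
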