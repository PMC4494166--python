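import numpy as np
import pytest

from dxrank import GeneratorParams, canonical_design, generate, integrate
from dxrank.cohort import TESTS, new_cohort_frame

COHORT_SEED = 11


@pytest.fixture(scope="session")
def design():
    return canonical_design()


@pytest.fixture(scope="session")
def cohort(design):
    """One canonical synthetic cohort, shared read-only across tests."""
    return generate(design, GeneratorParams(), seed=COHORT_SEED)


@pytest.fixture(scope="session")
def integrated(cohort):
    return integrate(cohort)


def make_pool(rows):
    """Cohort frame from shorthand row dicts; all cells marked measured."""
    full = []
    for i, r in enumerate(rows):
        rec = dict(
            subject_id=r.get("subject_id", f"s{i}"),
            dataset_id=r.get("dataset_id", 1),
            age=float(r.get("age", 60.0)),
            gender=int(r.get("gender", 1)),
            truth=r.get("truth", "nonUC"),
        )
        for t in TESTS:
            rec[t] = r.get(t)
            rec[f"{t}_src"] = "missing" if r.get(t) is None else "measured"
        full.append(rec)
    return new_cohort_frame(full)


@pytest.fixture
def noiseless_pool():
    """Tests and truth fully aligned; age carries a tiny within-group jitter."""
    rows = []
    for i in range(12):
        uc = i < 6
        rows.append(
            dict(
                age=(70.0 if uc else 50.0) + 0.1 * i,
                gender=1,
                truth="UC" if uc else "nonUC",
                cytology=4 if uc else 1,
                nmp22=2 if uc else 1,
                fish=2 if uc else 1,
                cxbladder=2 if uc else 1,
            )
        )
    return make_pool(rows)


def noisy_truth_pool(seed, n=40):
    """Random inputs, truth-determined target (nmp22); for supervised-mode checks."""
    r = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        uc = i < n // 2
        rows.append(
            dict(
                age=float(round(r.normal(60, 10), 1)),
                gender=int(r.integers(1, 3)),
                truth="UC" if uc else "nonUC",
                cytology=int(r.integers(1, 5)),
                nmp22=2 if uc else 1,
                fish=2 if uc else 1,
                cxbladder=int(r.integers(1, 3)),
            )
        )
    return make_pool(rows)
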