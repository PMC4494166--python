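"""Bayesian sensitivity/specificity via a two-group 16-cell multinomial model.

Subjects are split by cystoscopy truth into a Tumor (UC) and a Normal
(non-UC) group.  Within each group the joint outcome of the four binary tests
(cytology, NMP22, FISH, Cxbladder Detect — cytology on its binary mapping) is
one of 16 cells; the cell probabilities get a flat Dirichlet(1, ..., 1) prior
on the simplex.  Missing test results are treated as latent: a Gibbs /
data-augmentation chain alternates between (a) assigning every incomplete
subject a cell drawn from the current group probabilities restricted and
renormalized over the cells compatible with the subject's observed outcomes,
and (b) redrawing each group's probability vector from the conjugate
Dirichlet posterior given the augmented counts.  Sensitivity of a test is the
marginal probability of the 8 test-positive cells in the Tumor group;
specificity the marginal of the 8 negative cells in the Normal group.

Cell indexing: cytology is the most significant bit, Cxbladder the least —
cell = 8*cytology + 4*nmp22 + 2*fish + 1*cxbladder with 1 = positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .accuracy import AccuracyEstimate
from .cohort import TESTS, binary_codes
from .integration import IntegratedDataset

N_CELLS = 16
GROUPS = ("Tumor", "Normal")

#: bit position of each test in the cell index (MSB first)
_BITS: Mapping[str, int] = {"cytology": 3, "nmp22": 2, "fish": 1, "cxbladder": 0}


class BayesError(ValueError):
    pass


def cell_index(outcomes: Sequence[int]) -> int:
    """Cell index of a complete 4-tuple of binary outcomes (1 positive, 0 negative)."""
    return int(sum(int(o) << _BITS[t] for t, o in zip(TESTS, outcomes)))


def cells_where(test: str, positive: bool) -> np.ndarray:
    """The 8 cell indices where a test is positive (or negative)."""
    bit = _BITS[test]
    cells = np.arange(N_CELLS)
    mask = ((cells >> bit) & 1) == (1 if positive else 0)
    return cells[mask]


def compatible_cells(partial: Sequence) -> np.ndarray:
    """Cells agreeing with every observed outcome of a partial test profile.

    ``partial`` lists, in test order, 1 (positive), 0 (negative) or None/NaN
    (missing).  The result has 2**(number missing) cells.
    """
    cells = np.arange(N_CELLS)
    keep = np.ones(N_CELLS, dtype=bool)
    for t, o in zip(TESTS, partial):
        if o is None or (isinstance(o, float) and np.isnan(o)):
            continue
        keep &= ((cells >> _BITS[t]) & 1) == int(o)
    return cells[keep]


@dataclass
class PosteriorDraws:
    """Retained Gibbs draws: (n_kept, 2 groups, 16 cells) probability arrays."""

    draws: np.ndarray
    groups: tuple[str, str] = GROUPS
    seed: int | None = None
    burn_in: int = 0
    n_iter: int = 0

    def __post_init__(self) -> None:
        if self.draws.ndim != 3 or self.draws.shape[1:] != (2, N_CELLS):
            raise BayesError(f"draws must be (n, 2, 16), got {self.draws.shape}")

    def __len__(self) -> int:
        return self.draws.shape[0]


def _group_patterns(df: pd.DataFrame, group_mask: np.ndarray):
    """Complete-cell base counts + (compatible cells, multiplicity) per unique partial."""
    B = np.column_stack(
        [binary_codes(t, df[t]).astype(float).to_numpy() for t in TESTS]
    )[group_mask]
    base = np.zeros(N_CELLS, dtype=np.int64)
    incomplete: dict[tuple, int] = {}
    for row in B:
        key = tuple(-1 if np.isnan(v) else int(v) for v in row)
        if -1 not in key:
            base[cell_index(key)] += 1
        else:
            incomplete[key] = incomplete.get(key, 0) + 1
    patterns = [
        (compatible_cells([None if v == -1 else v for v in key]), m)
        for key, m in incomplete.items()
    ]
    return base, patterns, int(group_mask.sum())


def gibbs_run(
    ds: "IntegratedDataset | pd.DataFrame",
    n_iter: int = 2000,
    burn_in: int = 500,
    seed: int | None = None,
    allow_empty_groups: bool = False,
) -> PosteriorDraws:
    """Run the data-augmentation Gibbs chain and return post-burn-in draws.

    ``allow_empty_groups=True`` permits a group with no subjects, in which
    case its draws come from the prior alone (useful for prior-predictive
    checks); the default raises instead.
    """
    if burn_in >= n_iter:
        raise BayesError("burn_in must be smaller than n_iter")
    df = ds.records if isinstance(ds, IntegratedDataset) else ds
    is_uc = (df["truth"] == "UC").to_numpy()
    groups = []
    for name, mask in (("Tumor", is_uc), ("Normal", ~is_uc)):
        base, patterns, n = _group_patterns(df, mask)
        if n == 0 and not allow_empty_groups:
            raise BayesError(f"group {name!r} has zero subjects")
        groups.append((base, patterns))

    rng = np.random.default_rng(seed)
    theta = np.vstack([rng.dirichlet(np.ones(N_CELLS)) for _ in range(2)])
    draws = np.empty((n_iter, 2, N_CELLS))
    for it in range(n_iter):
        for g, (base, patterns) in enumerate(groups):
            counts = base.copy()
            for cells, m in patterns:
                p = theta[g, cells]
                counts[cells] += rng.multinomial(m, p / p.sum())
            theta[g] = rng.dirichlet(counts + 1.0)
        draws[it] = theta
    return PosteriorDraws(
        draws=draws[burn_in:], seed=seed, burn_in=burn_in, n_iter=n_iter
    )


def marginal_sens_spec(
    draws: PosteriorDraws, test: str, level: float = 0.95
) -> AccuracyEstimate:
    """Posterior sensitivity/specificity (percent) of one test.

    Per draw, sensitivity sums the Tumor-group probabilities of the 8
    test-positive cells; specificity the Normal-group probabilities of the 8
    negative cells.  Point estimate is the posterior mean; the CI the
    2.5/97.5 posterior percentiles (for the default level).
    """
    if len(draws) == 0:
        raise BayesError("no post-burn-in draws")
    lo_q, hi_q = 100 * (0.5 - level / 2), 100 * (0.5 + level / 2)
    sens = draws.draws[:, 0, cells_where(test, True)].sum(axis=1) * 100.0
    spec = draws.draws[:, 1, cells_where(test, False)].sum(axis=1) * 100.0
    return AccuracyEstimate(
        test=test,
        sensitivity=float(sens.mean()),
        sens_ci=(float(np.percentile(sens, lo_q)), float(np.percentile(sens, hi_q))),
        specificity=float(spec.mean()),
        spec_ci=(float(np.percentile(spec, lo_q)), float(np.percentile(spec, hi_q))),
        counts=None,
        scope="bayes",
        level=level,
    )


class BayesianAccuracy:
    """Model: Bayesian multinomial missing-data estimator of test accuracy.

    Parameters
    ----------
    data : IntegratedDataset or cohort frame
        Integrated records (binary truth); missing test cells are handled by
        data augmentation, no imputation required.

    ``fit`` runs the Gibbs chain and returns a results object.
    """

    def __init__(self, data: "IntegratedDataset | pd.DataFrame", tests: Sequence[str] = TESTS):
        self.data = data
        self.tests = tuple(tests)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "BayesianAccuracy":
        return cls(df, **kwargs)

    def fit(
        self,
        n_iter: int = 2000,
        burn_in: int = 500,
        seed: int | None = None,
        allow_empty_groups: bool = False,
    ) -> "BayesianAccuracyResults":
        draws = gibbs_run(
            self.data, n_iter=n_iter, burn_in=burn_in, seed=seed,
            allow_empty_groups=allow_empty_groups,
        )
        return BayesianAccuracyResults(self, draws)


@dataclass
class BayesianAccuracyResults:
    model: BayesianAccuracy
    draws: PosteriorDraws

    def estimate(self, test: str, level: float = 0.95) -> AccuracyEstimate:
        return marginal_sens_spec(self.draws, test, level)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.model.tests:
            e = self.estimate(t)
            rows.append(
                {
                    "test": t,
                    "sens": round(e.sensitivity, 1),
                    "sens_lo": round(e.sens_ci[0], 1),
                    "sens_hi": round(e.sens_ci[1], 1),
                    "spec": round(e.specificity, 1),
                    "spec_lo": round(e.spec_ci[0], 1),
                    "spec_hi": round(e.spec_ci[1], 1),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Bayesian accuracy ({len(self.draws)} draws kept of "
            f"{self.draws.n_iter}, burn-in {self.draws.burn_in})",
            f"{'test':<12}{'sens %':>8}{'95% CI':>16}{'spec %':>8}{'95% CI':>16}",
        ]
        for t in self.model.tests:
            e = self.estimate(t)
            lines.append(
                f"{t:<12}{e.sensitivity:>8.1f}"
                f"{'(%.1f-%.1f)' % e.sens_ci:>16}"
                f"{e.specificity:>8.1f}"
                f"{'(%.1f-%.1f)' % e.spec_ci:>16}"
            )
        return "\n".join(lines)
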