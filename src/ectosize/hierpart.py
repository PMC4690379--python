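"""Hierarchical partitioning of regression goodness-of-fit.

For k predictors, the R² of all 2^k predictor subsets is computed and each
predictor's *independent* contribution is the average, over hierarchy levels
h = 0..k-1, of the mean increment R²(S ∪ {x}) − R²(S) across all subsets S of
size h not containing x.  This level-averaged increment is exactly the
Shapley value of x for the characteristic function R², so the independent
contributions sum to the full-model R² (efficiency).  The *joint*
contribution is the univariate R² minus the independent contribution; it may
be negative under suppression and is deliberately not clamped.

Rank-deficient designs (e.g. a duplicated predictor) are handled with a
least-squares pseudo-inverse fallback and flagged rather than rejected: R² is
still well defined because the fitted values are unique even when the
coefficients are not.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import EctosizeError

MAX_PREDICTORS = 12  # 2^k enumeration guard


@dataclass
class HPResult:
    """Independent/joint contributions per predictor, in R² units."""

    predictors: tuple[str, ...]
    independent: dict[str, float]
    joint: dict[str, float]
    independent_pct: dict[str, float]
    total_r2: float
    rank_deficient: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": list(self.predictors),
                "independent": [self.independent[p] for p in self.predictors],
                "joint": [self.joint[p] for p in self.predictors],
                "independent_pct": [self.independent_pct[p] for p in self.predictors],
            }
        )


def _subset_r2(y: np.ndarray, X: np.ndarray, cols: tuple[int, ...]) -> float:
    n = len(y)
    design = np.column_stack([np.ones(n)] + [X[:, j] for j in cols])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise EctosizeError("response is constant; R² undefined")
    return 1.0 - float(resid @ resid) / tss


def all_subsets_r2(y, X) -> dict[frozenset, float]:
    """R² of every predictor subset (the empty subset has R² = 0).

    ``X`` is a DataFrame (keys are column-name frozensets) or 2-D array
    (keys are column-index frozensets).  Refuses k > 12.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(float)
    else:
        Xa = np.asarray(X, float)
        names = list(range(Xa.shape[1]))
    y = np.asarray(y, float)
    k = Xa.shape[1]
    if k > MAX_PREDICTORS:
        raise EctosizeError(f"{k} predictors would need 2^{k} fits; limit is {MAX_PREDICTORS}")
    out: dict[frozenset, float] = {frozenset(): 0.0}
    for r in range(1, k + 1):
        for cols in itertools.combinations(range(k), r):
            out[frozenset(names[j] for j in cols)] = _subset_r2(y, Xa, cols)
    return out


def independent_contributions(subset_r2: dict[frozenset, float],
                              rank_deficient: bool = False) -> HPResult:
    """Shapley decomposition of the full-model R² from a complete subset map."""
    keys = set(subset_r2)
    predictors = tuple(sorted(frozenset().union(*keys) if keys else frozenset()))
    k = len(predictors)
    expected = {frozenset(c) for r in range(k + 1)
                for c in itertools.combinations(predictors, r)}
    missing = expected - keys
    if missing:
        raise EctosizeError(
            f"subset map incomplete; missing {len(missing)} subset(s), "
            f"e.g. {sorted(tuple(sorted(s)) for s in missing)[:3]}"
        )
    fact = [math.factorial(i) for i in range(k + 1)]
    independent: dict[str, float] = {}
    for x in predictors:
        others = [p for p in predictors if p != x]
        total = 0.0
        for r in range(k):
            w = fact[r] * fact[k - r - 1] / fact[k]
            for S in itertools.combinations(others, r):
                S = frozenset(S)
                total += w * (subset_r2[S | {x}] - subset_r2[S])
        independent[x] = total
    total_r2 = subset_r2[frozenset(predictors)]
    joint = {x: subset_r2[frozenset([x])] - independent[x] for x in predictors}
    sum_ind = sum(independent.values())
    if sum_ind != 0:
        pct = {x: 100.0 * independent[x] / sum_ind for x in predictors}
    else:
        pct = {x: math.nan for x in predictors}
    return HPResult(predictors, independent, joint, pct, total_r2, rank_deficient)


def hierarchical_partitioning(y, X) -> HPResult:
    """All-subset R² enumeration followed by the Shapley decomposition."""
    if isinstance(X, pd.DataFrame):
        Xa = X.to_numpy(float)
    else:
        Xa = np.asarray(X, float)
    n = Xa.shape[0]
    design = np.column_stack([np.ones(n), Xa])
    deficient = np.linalg.matrix_rank(design) < design.shape[1]
    return independent_contributions(all_subsets_r2(y, X), rank_deficient=deficient)


class HierarchicalPartitioning(BaseEstimator):
    """Estimator wrapper: ``fit(X, y)`` exposes the decomposition as attributes.

    Attributes
    ----------
    independent_, joint_, independent_pct_ : dict per predictor
    total_r2_ : float
    subset_r2_ : dict frozenset -> float
    rank_deficient_ : bool
    """

    def fit(self, X, y) -> "HierarchicalPartitioning":
        self.subset_r2_ = all_subsets_r2(y, X)
        if isinstance(X, pd.DataFrame):
            Xa = X.to_numpy(float)
        else:
            Xa = np.asarray(X, float)
        design = np.column_stack([np.ones(Xa.shape[0]), Xa])
        deficient = np.linalg.matrix_rank(design) < design.shape[1]
        res = independent_contributions(self.subset_r2_, rank_deficient=deficient)
        self.result_ = res
        self.independent_ = res.independent
        self.joint_ = res.joint
        self.independent_pct_ = res.independent_pct
        self.total_r2_ = res.total_r2
        self.rank_deficient_ = res.rank_deficient
        return self
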