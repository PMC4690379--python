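"""Moran's I spatial autocorrelation with permutation tests and correlograms.

Global Moran's I for site values x and nonnegative symmetric weights W:

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with S0 = sum_ij w_ij and null expectation E[I] = -1/(n-1).  Significance is
assessed by Monte-Carlo permutation of x across sites with the add-one
estimator p = (b + 1)/(m + 1), so the smallest attainable p with m = 199
permutations is exactly 1/200 = 0.005.  Correlograms evaluate I within
distance classes built from great-circle distances (sphere radius
6371.0088 km), with binary 0/1 membership weights per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.metrics.pairwise import haversine_distances

from .exceptions import DegenerateDataError, EctosizeError

EARTH_RADIUS_KM = 6371.0088


def _coords_array(coords) -> np.ndarray:
    if isinstance(coords, pd.DataFrame):
        coords = coords[["lat", "lon"]].to_numpy(float)
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise EctosizeError("coords must be an (n, 2) array of lat, lon in decimal degrees")
    lat, lon = coords[:, 0], coords[:, 1]
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise EctosizeError("coordinates out of range: |lat| <= 90, |lon| <= 180 required")
    return coords


def haversine_matrix(coords) -> np.ndarray:
    """Pairwise great-circle distances in km (symmetric, zero diagonal)."""
    coords = _coords_array(coords)
    D = haversine_distances(np.radians(coords)) * EARTH_RADIUS_KM
    np.fill_diagonal(D, 0.0)
    return D


def distance_classes(
    distances: np.ndarray, n_classes: int, method: str = "equal_width"
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each unordered site pair to one of ``n_classes`` distance classes.

    Returns ``(pair_class, bounds)`` where ``pair_class`` is an int array over
    the condensed upper triangle (row-major i<j order, 0-based class index)
    and ``bounds`` has shape (n_classes, 2) with each class's (lower, upper]
    distance bounds in km.  ``equal_width`` bins span (0, max]; the
    ``equal_count`` alternative gives classes of near-equal pair counts.
    """
    if n_classes < 1:
        raise EctosizeError("n_classes must be >= 1")
    D = np.asarray(distances, float)
    iu, ju = np.triu_indices(D.shape[0], k=1)
    d = D[iu, ju]
    if len(d) == 0 or d.max() <= 0:
        raise EctosizeError("need at least one pair with nonzero distance")
    if method == "equal_width":
        edges = np.linspace(0.0, d.max(), n_classes + 1)
        cls = np.clip(np.searchsorted(edges, d, side="left") - 1, 0, n_classes - 1)
        bounds = np.column_stack([edges[:-1], edges[1:]])
    elif method == "equal_count":
        order = np.argsort(d, kind="mergesort")
        cls = np.empty(len(d), int)
        chunks = np.array_split(order, n_classes)
        bounds = np.zeros((n_classes, 2))
        prev_hi = 0.0
        for c, idx in enumerate(chunks):
            cls[idx] = c
            if len(idx):
                bounds[c] = (prev_hi, d[idx].max())
                prev_hi = d[idx].max()
            else:
                bounds[c] = (prev_hi, prev_hi)
    else:
        raise EctosizeError(f"unknown binning method {method!r}")
    return cls, bounds


def _check_moran_inputs(x: np.ndarray, W: np.ndarray) -> None:
    n = len(x)
    if n < 3:
        raise EctosizeError("Moran's I needs at least 3 sites")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant values: Moran's I undefined")
    if W.shape != (n, n):
        raise EctosizeError("W must be n x n")
    if not np.allclose(W, W.T):
        raise EctosizeError("W must be symmetric")
    if np.any(np.diag(W) != 0):
        raise EctosizeError("W must have a zero diagonal")
    if W.sum() <= 0:
        raise EctosizeError("W has no positive entries")


def morans_i(x, W) -> float:
    """Global Moran's I for values ``x`` under weight matrix ``W``."""
    x = np.asarray(x, float)
    W = np.asarray(W, float)
    _check_moran_inputs(x, W)
    n = len(x)
    z = x - x.mean()
    s0 = W.sum()
    return float((n / s0) * (z @ W @ z) / (z @ z))


def expected_i(n: int) -> float:
    """Null expectation of Moran's I: -1/(n-1)."""
    return -1.0 / (n - 1)


def _permuted_i(x, W, n_permutations, rng) -> tuple[float, np.ndarray]:
    """Observed I and the permutation distribution, vectorised."""
    x = np.asarray(x, float)
    W = np.asarray(W, float)
    n = len(x)
    obs = morans_i(x, W)
    s0 = W.sum()
    perms = np.empty((n_permutations, n))
    for i in range(n_permutations):
        perms[i] = x[rng.permutation(n)]
    Z = perms - perms.mean(axis=1, keepdims=True)
    num = np.einsum("ki,ij,kj->k", Z, W, Z)
    den = np.einsum("ki,ki->k", Z, Z)
    return obs, (n / s0) * num / den


def permutation_test(
    x, W, n_permutations: int = 199, seed=None, alternative: str = "two-sided"
) -> float:
    """Monte-Carlo permutation p-value for Moran's I.

    ``p = (b + 1)/(m + 1)`` where b counts permutations at least as extreme as
    the observed statistic; two-sided extremeness is measured as
    |I - E[I]|.  p can never be 0; its floor is 1/(m+1).
    """
    if n_permutations < 1:
        raise EctosizeError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    obs, sims = _permuted_i(x, W, n_permutations, rng)
    e = expected_i(len(np.asarray(x)))
    tol = 1e-12
    if alternative == "two-sided":
        b = int(np.sum(np.abs(sims - e) >= np.abs(obs - e) - tol))
    elif alternative == "greater":
        b = int(np.sum(sims >= obs - tol))
    elif alternative == "less":
        b = int(np.sum(sims <= obs + tol))
    else:
        raise EctosizeError(f"unknown alternative {alternative!r}")
    return (b + 1) / (n_permutations + 1)


@dataclass
class CorrelogramResult:
    """Per-distance-class Moran's I with permutation p-values."""

    frame: pd.DataFrame  # class, d_min_km, d_max_km, n_pairs, morans_i, expected_i, p_value
    n_sites: int
    n_permutations: int
    seed: object
    binning: str = "equal_width"
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def class_weight_matrix(pair_class: np.ndarray, n: int, c: int) -> np.ndarray:
    """Binary weight matrix selecting the pairs of distance class ``c``."""
    iu, ju = np.triu_indices(n, k=1)
    W = np.zeros((n, n))
    sel = pair_class == c
    W[iu[sel], ju[sel]] = 1.0
    W[ju[sel], iu[sel]] = 1.0
    return W


def correlogram(
    x,
    coords,
    n_classes: int = 10,
    n_permutations: int = 199,
    seed=None,
    binning: str = "equal_width",
    alternative: str = "two-sided",
) -> CorrelogramResult:
    """Moran correlogram over great-circle distance classes.

    Classes with zero pairs are reported with NaN statistics, never dropped.
    Each class's permutation test draws from an independent child seed of
    ``seed`` so results are reproducible and class-order independent.
    """
    x = np.asarray(x, float)
    D = haversine_matrix(coords)
    n = len(x)
    if D.shape[0] != n:
        raise EctosizeError("x and coords disagree on the number of sites")
    pair_class, bounds = distance_classes(D, n_classes, method=binning)
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seeds = seq.spawn(n_classes)
    rows = []
    for c in range(n_classes):
        n_pairs = int(np.sum(pair_class == c))
        if n_pairs == 0:
            rows.append((c + 1, bounds[c, 0], bounds[c, 1], 0, np.nan, expected_i(n), np.nan))
            continue
        W = class_weight_matrix(pair_class, n, c)
        i_val = morans_i(x, W)
        p = permutation_test(
            x, W, n_permutations=n_permutations, seed=child_seeds[c], alternative=alternative
        )
        rows.append((c + 1, bounds[c, 0], bounds[c, 1], n_pairs, i_val, expected_i(n), p))
    frame = pd.DataFrame(
        rows,
        columns=["class", "d_min_km", "d_max_km", "n_pairs", "morans_i", "expected_i", "p_value"],
    )
    return CorrelogramResult(
        frame, n_sites=n, n_permutations=n_permutations, seed=seed, binning=binning
    )


class MoranCorrelogram(BaseEstimator):
    """Estimator wrapper: ``fit(coords, x)`` computes the correlogram.

    Parameters mirror :func:`correlogram`; the fitted attribute ``result_``
    holds a :class:`CorrelogramResult` and ``frame_`` its table.
    """

    def __init__(
        self,
        n_classes: int = 10,
        n_permutations: int = 199,
        binning: str = "equal_width",
        alternative: str = "two-sided",
        random_state=None,
    ):
        self.n_classes = n_classes
        self.n_permutations = n_permutations
        self.binning = binning
        self.alternative = alternative
        self.random_state = random_state

    def fit(self, X, y) -> "MoranCorrelogram":
        self.result_ = correlogram(
            y,
            X,
            n_classes=self.n_classes,
            n_permutations=self.n_permutations,
            seed=self.random_state,
            binning=self.binning,
            alternative=self.alternative,
        )
        self.frame_ = self.result_.frame
        return self
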