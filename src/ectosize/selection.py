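"""AICc multimodel inference over hypothesis-mapped linear regression models.

Candidate models are Gaussian linear regressions of a per-site response (mean
adult SVL or mean adult SMI) on subsets of four site covariates (BIO1, BIO4,
BIO12, NDVI), each subset mapped to one or more biogeographic hypotheses with
a predicted coefficient sign.  Models are compared with the small-sample
Akaike information criterion

    AICc = -2*loglik + 2K + 2K(K+1)/(n - K - 1)

where K counts the intercept, the slopes and the residual variance, and the
Gaussian log-likelihood is evaluated at the ML variance RSS/n:

    loglik = -(n/2) * (ln(2*pi*RSS/n) + 1).

From the AICc come the differences Delta_i = AICc_i - AICc_min, the Akaike
weights w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2), evidence ratios
w_a/w_b = exp((Delta_b - Delta_a)/2), and per-variable summed weights.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .exceptions import CollinearityError, InsufficientDataError

#: Table-1-style hypothesis tags: variable -> ((hypothesis, predicted sign), ...)
HYPOTHESIS_TAGS: dict[str, tuple[tuple[str, str], ...]] = {
    "BIO1": (
        ("heat-balance", "-"),
        ("temperature-size-rule", "-"),
        ("optimal-body-temperature", "+"),
    ),
    "BIO4": (("starvation-resistance", "+"), ("growing-season-length", "-")),
    "BIO12": (("water-availability", "-"), ("reverse-water-availability", "+")),
    "NDVI": (("primary-productivity", "+"),),
}

PREDICTOR_NAMES = ("BIO1", "BIO4", "BIO12", "NDVI")


@dataclass(frozen=True)
class CandidateModel:
    """A predictor subset with its hypothesis tags."""

    label: str
    predictors: tuple[str, ...]
    hypothesis_tags: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError(f"duplicate predictors in model {self.label!r}")


def _make_candidate(predictors: tuple[str, ...]) -> CandidateModel:
    tags = tuple(t for p in predictors for t in HYPOTHESIS_TAGS.get(p, ()))
    return CandidateModel("+".join(predictors) or "intercept", predictors, tags)


def default_candidate_sets() -> tuple[list[CandidateModel], list[CandidateModel]]:
    """The 11 additive candidate models, for body size and body condition.

    The published candidate list is additive only (no interactions and not all
    15 nonempty subsets); the same set serves both responses.
    """
    combos = [
        ("BIO4",),
        ("BIO1", "BIO4"),
        ("BIO4", "BIO12"),
        ("BIO1", "BIO4", "BIO12"),
        ("BIO1",),
        ("BIO12",),
        ("NDVI",),
        ("BIO12", "NDVI"),
        ("BIO1", "NDVI"),
        ("BIO1", "BIO12"),
        ("BIO1", "BIO12", "NDVI"),
    ]
    body_size = [_make_candidate(c) for c in combos]
    body_condition = [_make_candidate(c) for c in combos]
    return body_size, body_condition


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitResult:
    """One fitted Gaussian linear model, ready for AICc ranking."""

    label: str
    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    sigma2_ml: float
    loglik: float
    K: int
    n: int
    r2: float
    r2_adj: float
    aicc: float
    perfect_fit: bool = False


def aicc(loglik: float, K: int, n: int) -> float:
    """Small-sample AIC.  Undefined (raises) when n - K - 1 <= 0."""
    if n - K - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, K={K} (n - K - 1 <= 0)")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def _dependent_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns expressible as combinations of the preceding ones."""
    dep = []
    for j in range(1, X.shape[1]):
        sub = X[:, :j]
        beta, *_ = np.linalg.lstsq(sub, X[:, j], rcond=None)
        resid = X[:, j] - sub @ beta
        scale = max(np.linalg.norm(X[:, j]), 1.0)
        if np.linalg.norm(resid) < 1e-8 * scale:
            dep.append(names[j])
    return dep


def ols_fit(y, X, label: str | None = None) -> FitResult:
    """OLS fit of ``y`` on covariate columns ``X`` (DataFrame or 2-D array).

    Uses the ML residual variance RSS/n in the likelihood so that the
    AIC-family formulas apply in their standard form.  A zero-residual fit is
    flagged ``perfect_fit`` with infinite log-likelihood rather than reported
    as a (meaningless) finite AICc.
    """
    y = np.asarray(y, float)
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(float)
    else:
        Xa = np.atleast_2d(np.asarray(X, float))
        if Xa.shape[0] == 1 and len(y) != 1:
            Xa = Xa.T
        names = [f"x{j + 1}" for j in range(Xa.shape[1])]
    n, p = len(y), Xa.shape[1]
    K = p + 2  # intercept + slopes + residual variance
    if n <= p + 1:
        raise InsufficientDataError(
            f"n={n} sites cannot determine {p + 1} regression coefficients"
        )
    design = np.column_stack([np.ones(n), Xa])
    if np.linalg.matrix_rank(design) < p + 1:
        dep = _dependent_columns(design, ["intercept"] + names)
        raise CollinearityError(f"design matrix is rank deficient; dependent columns: {dep}")
    res = sm.OLS(y, design).fit()
    rss = float(res.ssr)
    sigma2 = rss / n
    coef = {"intercept": float(res.params[0])}
    coef.update({nm: float(b) for nm, b in zip(names, res.params[1:])})
    tss = float(np.sum((y - y.mean()) ** 2))
    perfect = sigma2 <= 1e-13 * max(tss / n, 1e-30) or sigma2 == 0.0
    if perfect:
        ll, ic = math.inf, -math.inf
    else:
        ll = -(n / 2.0) * (math.log(2.0 * math.pi * sigma2) + 1.0)
        # AICc is undefined when its correction denominator vanishes; the fit
        # itself is still returned (NaN criterion, unusable for ranking)
        ic = aicc(ll, K, n) if n - K - 1 > 0 else math.nan
    return FitResult(
        label=label or "+".join(names),
        predictors=tuple(names),
        coefficients=coef,
        sigma2_ml=sigma2,
        loglik=ll,
        K=K,
        n=n,
        r2=float(res.rsquared) if p > 0 else 0.0,
        r2_adj=float(res.rsquared_adj) if p > 0 else 0.0,
        aicc=ic,
        perfect_fit=perfect,
    )


# ---------------------------------------------------------------------------


class SelectionTable:
    """AICc-ranked candidate set with Delta_i and Akaike weights.

    ``frame`` columns: model, predictors, r2_adj, K, aicc, delta, weight —
    sorted by AICc ascending (ties: smaller K, then label).
    """

    def __init__(self, frame: pd.DataFrame, n: int | None = None):
        self.frame = frame.reset_index(drop=True)
        self.n = n

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def best(self) -> str:
        return str(self.frame.loc[0, "model"])

    def _delta(self, label: str) -> float:
        row = self.frame[self.frame["model"] == label]
        if row.empty:
            raise KeyError(f"model {label!r} not in selection table")
        return float(row["delta"].iloc[0])

    def evidence_ratio(self, a: str, b: str) -> float:
        """w_a / w_b computed from the Deltas as exp((Delta_b - Delta_a)/2).

        Overflow of the exponent is reported as +inf, not raised.
        """
        da, db = self._delta(a), self._delta(b)
        arg = (db - da) / 2.0
        if arg > 700:  # exp would overflow the float64 range
            return math.inf
        return math.exp(arg)

    def summed_weight(self, variable: str) -> float:
        """Sum of Akaike weights over models whose predictor set contains ``variable``."""
        if variable not in PREDICTOR_NAMES:
            raise KeyError(f"unknown variable {variable!r}; expected one of {PREDICTOR_NAMES}")
        total = 0.0
        for _, row in self.frame.iterrows():
            preds = row["predictors"].split("+") if row["predictors"] else []
            if variable in preds:
                total += float(row["weight"])
        return total

    def render(self, hide_below: float = 0.0, clamp_negative_r2: bool = True) -> str:
        """Publication-style text table: Delta/weights to 3 dp, negative
        adjusted R² printed as 0.000, rows with weight < ``hide_below`` hidden
        (the full table is always retained in ``frame``)."""
        lines = [f"{'model':<18}{'adj R2':>8}{'K':>4}{'AICc':>10}{'Delta':>8}{'w':>8}"]
        hidden = 0
        for _, row in self.frame.iterrows():
            if row["weight"] < hide_below:
                hidden += 1
                continue
            r2a = row["r2_adj"]
            if pd.isna(r2a):
                r2s = "     ---"
            else:
                r2v = max(r2a, 0.0) if clamp_negative_r2 else r2a
                r2s = f"{r2v:8.3f}"
            lines.append(
                f"{row['model']:<18}{r2s}{int(row['K']):>4}"
                f"{row['aicc']:>10.3f}{row['delta']:>8.3f}{row['weight']:>8.3f}"
            )
        if hidden:
            lines.append(f"({hidden} model(s) with w < {hide_below:g} not shown)")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _table_from_rows(rows: list[dict], n: int | None) -> SelectionTable:
    df = pd.DataFrame(rows)
    df = df.sort_values(["aicc", "K", "model"], kind="mergesort").reset_index(drop=True)
    amin = df["aicc"].min()
    df["delta"] = df["aicc"] - amin
    rel = np.exp(-df["delta"].to_numpy(float) / 2.0)
    df["weight"] = rel / rel.sum()
    cols = ["model", "predictors", "r2_adj", "K", "aicc", "delta", "weight"]
    return SelectionTable(df[cols], n=n)


def rank_models(fits: list[FitResult]) -> SelectionTable:
    """Rank fitted candidate models by AICc and attach Deltas and weights."""
    if len(fits) < 2:
        raise InsufficientDataError("ranking needs at least 2 fitted models")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError(f"fits are on different numbers of sites: {sorted(ns)}")
    bad = [f.label for f in fits if math.isnan(f.aicc)]
    if bad:
        raise ValueError(f"AICc undefined (too few sites) for model(s): {bad}")
    rows = [
        {
            "model": f.label,
            "predictors": "+".join(f.predictors),
            "r2_adj": f.r2_adj,
            "K": f.K,
            "aicc": f.aicc,
        }
        for f in fits
    ]
    return _table_from_rows(rows, n=ns.pop())


def selection_table_from_aicc(
    labels: list[str],
    aicc_values: list[float],
    K: list[int] | None = None,
    r2_adj: list[float] | None = None,
) -> SelectionTable:
    """Build a selection table directly from externally supplied AICc values
    (e.g. a published table)."""
    rows = []
    for i, (lab, a) in enumerate(zip(labels, aicc_values)):
        rows.append(
            {
                "model": lab,
                "predictors": lab if lab != "intercept" else "",
                "r2_adj": (r2_adj[i] if r2_adj is not None else np.nan),
                "K": (K[i] if K is not None else lab.count("+") + 3),
                "aicc": float(a),
            }
        )
    return _table_from_rows(rows, n=None)


def evidence_ratio(table: SelectionTable, a: str, b: str) -> float:
    return table.evidence_ratio(a, b)


def summed_weights(table: SelectionTable, variable: str) -> float:
    return table.summed_weight(variable)


def compare_functional_forms(y, x, rel_threshold: float = 0.01) -> dict:
    """Linear vs quadratic screening on a single covariate.

    Fits y ~ x and y ~ x + x^2 and reports the ML residual variance of each,
    with a flag set when the quadratic reduces sigma2 by more than
    ``rel_threshold`` (relative)."""
    x = np.asarray(x, float)
    lin = ols_fit(y, x[:, None], label="linear")
    quad = ols_fit(y, np.column_stack([x, x**2]), label="quadratic")
    s_lin, s_quad = lin.sigma2_ml, quad.sigma2_ml
    improvement = (s_lin - s_quad) / s_lin if s_lin > 0 else (1.0 if s_quad < s_lin else 0.0)
    return {
        "sigma2_linear": s_lin,
        "sigma2_quadratic": s_quad,
        "relative_reduction": improvement,
        "quadratic_improves": bool(improvement > rel_threshold),
    }


# ---------------------------------------------------------------------------


class AICcModelSelector(BaseEstimator):
    """Fit a candidate model set and rank it by AICc.

    Parameters
    ----------
    candidates : list of CandidateModel or None
        Defaults to the 11-model additive set of :func:`default_candidate_sets`.

    Attributes
    ----------
    results_ : dict mapping model label to :class:`FitResult`
    table_ : :class:`SelectionTable`
    best_model_ : str
    """

    def __init__(self, candidates: list[CandidateModel] | None = None):
        self.candidates = candidates

    def fit(self, X: pd.DataFrame, y) -> "AICcModelSelector":
        """``X`` must carry one column per predictor name used by the candidates."""
        cands = self.candidates if self.candidates is not None else default_candidate_sets()[0]
        missing = {p for c in cands for p in c.predictors} - set(X.columns)
        if missing:
            raise KeyError(f"X lacks predictor column(s): {sorted(missing)}")
        self.results_ = {}
        fits = []
        for c in cands:
            f = ols_fit(y, X[list(c.predictors)], label=c.label)
            self.results_[c.label] = f
            fits.append(f)
        self.table_ = rank_models(fits)
        self.best_model_ = self.table_.best
        return self

    def best_fit_(self) -> FitResult:
        return self.results_[self.best_model_]

    def evidence_ratio(self, a: str, b: str) -> float:
        return self.table_.evidence_ratio(a, b)

    def summed_weight(self, variable: str) -> float:
        return self.table_.summed_weight(variable)

    def residuals(self, X: pd.DataFrame, y, label: str | None = None) -> np.ndarray:
        """Residuals of one candidate (default: the best-ranked model)."""
        label = label or self.best_model_
        f = self.results_[label]
        y = np.asarray(y, float)
        pred = np.full(len(y), f.coefficients["intercept"])
        for p in f.predictors:
            pred = pred + f.coefficients[p] * X[p].to_numpy(float)
        return y - pred


def all_predictor_subsets(predictors=PREDICTOR_NAMES) -> list[tuple[str, ...]]:
    """All nonempty subsets of the predictor pool (used by custom candidate sets)."""
    out = []
    for r in range(1, len(predictors) + 1):
        out.extend(itertools.combinations(predictors, r))
    return out
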