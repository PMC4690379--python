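"""Body condition via the scaled mass index (SMI).

The SMI standardises each animal's body mass to what it would be at a common
body length ``L0``::

    SMI = mass * (L0 / svl) ** b_sma

where ``b_sma`` is the standardised major axis (SMA) slope of ln(mass) on
ln(svl).  SMA symmetrises error in both variables; its slope equals the OLS
slope divided by |Pearson r|.  Brooding males (males carrying tadpoles in the
vocal sac) are excluded from every SMI computation because the brood inflates
body mass, but they still contribute to body-*size* (SVL) summaries.
Juveniles may enter the allometric fit — sampling the full SVL range improves
the slope estimate — but never enter adult summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import DegenerateDataError, InsufficientDataError, IntegrityError


@dataclass(frozen=True)
class SMIParams:
    """Allometric exponent and standardisation length for the SMI."""

    b_sma: float
    l0: float  # mm

    def __post_init__(self):
        if self.b_sma <= 0 or self.l0 <= 0:
            raise ValueError("b_sma and l0 must be positive")


@dataclass(frozen=True)
class SMAFit:
    """Result of a standardised major axis fit of ln(mass) on ln(svl)."""

    slope_ols: float
    pearson_r: float
    b_sma: float
    intercept: float  # natural-log scale (ln g at ln svl = 0)
    n: int


class SMAAllometry(BaseEstimator):
    """Standardised major axis allometry of body mass against body length.

    Fit on log-transformed data: OLS of ln(mass) on ln(svl), with the SMA
    slope ``b_sma = slope_ols / |r|`` (sign taken from the OLS slope).

    Parameters
    ----------
    include_juveniles : bool, default True
        Whether juvenile records enter the fit.  Including them samples a
        wider SVL range and stabilises the exponent.
    l0 : float or None, default None
        SMI standardisation length (mm).  If None, the mean adult SVL of the
        fitted data is used.

    Attributes
    ----------
    slope_ols_, pearson_r_, b_sma_, intercept_, n_ : fitted SMA quantities
    l0_ : float
        Standardisation length actually used by :meth:`scaled_mass_index`.
    """

    def __init__(self, include_juveniles: bool = True, l0: float | None = None):
        self.include_juveniles = include_juveniles
        self.l0 = l0

    def fit(self, individuals: pd.DataFrame, y=None) -> "SMAAllometry":
        """Fit the SMA from an individual table.

        ``individuals`` needs columns ``svl_mm``, ``mass_g``, ``stage`` and
        ``brooding``.  Records with missing mass are skipped; brooding males
        are excluded (their mass is inflated by the brood).
        """
        df = individuals
        usable = df["mass_g"].notna() & ~df["brooding"].astype(bool)
        if not self.include_juveniles:
            usable &= df["stage"] == "adult"
        sub = df.loc[usable]
        fit = _sma_from_arrays(sub["svl_mm"].to_numpy(float), sub["mass_g"].to_numpy(float))
        self.slope_ols_ = fit.slope_ols
        self.pearson_r_ = fit.pearson_r
        self.b_sma_ = fit.b_sma
        self.intercept_ = fit.intercept
        self.n_ = fit.n
        adults = df.loc[df["stage"] == "adult", "svl_mm"]
        self.l0_ = float(self.l0) if self.l0 is not None else float(adults.mean())
        return self

    @property
    def params_(self) -> SMIParams:
        return SMIParams(b_sma=self.b_sma_, l0=self.l0_)

    def scaled_mass_index(self, mass, svl):
        """SMI of (mass, svl) pairs at the fitted exponent and L0."""
        return scaled_mass_index(mass, svl, self.params_)

    def predict(self, svl):
        """Expected body mass (g) at the given SVL under the fitted power law."""
        svl = np.asarray(svl, float)
        return np.exp(self.intercept_ + self.b_sma_ * np.log(svl))


def _sma_from_arrays(svl: np.ndarray, mass: np.ndarray) -> SMAFit:
    ok = np.isfinite(svl) & np.isfinite(mass)
    svl, mass = svl[ok], mass[ok]
    if len(svl) < 3:
        raise InsufficientDataError(
            f"SMA fit needs >= 3 records with both mass and SVL, got {len(svl)}"
        )
    if np.ptp(svl) == 0:
        raise DegenerateDataError("all SVL values identical; SMA slope undefined")
    x, y = np.log(svl), np.log(mass)
    slope, intercept = np.polyfit(x, y, 1)
    r = float(np.corrcoef(x, y)[0, 1])
    if r == 0:
        raise DegenerateDataError("zero correlation between ln(svl) and ln(mass)")
    b_sma = float(np.sign(slope) * abs(slope) / abs(r))
    # intercept re-expressed for the SMA line through the centroid
    sma_intercept = float(np.mean(y) - b_sma * np.mean(x))
    return SMAFit(float(slope), r, b_sma, sma_intercept, int(len(svl)))


def fit_sma(individuals: pd.DataFrame, include_juveniles: bool = True) -> SMAFit:
    """Functional wrapper over :class:`SMAAllometry` returning an :class:`SMAFit`."""
    est = SMAAllometry(include_juveniles=include_juveniles).fit(individuals)
    return SMAFit(est.slope_ols_, est.pearson_r_, est.b_sma_, est.intercept_, est.n_)


def scaled_mass_index(mass, svl, params: SMIParams):
    """SMI = mass * (L0 / svl) ** b_sma, elementwise; scalar in, scalar out."""
    mass_a, svl_a = np.asarray(mass, float), np.asarray(svl, float)
    if np.any(mass_a <= 0) or np.any(svl_a <= 0):
        raise ValueError("mass and svl must be strictly positive")
    out = mass_a * (params.l0 / svl_a) ** params.b_sma
    if np.isscalar(mass) and np.isscalar(svl):
        return float(out)
    return out


def site_summaries(
    individuals: pd.DataFrame,
    params: SMIParams,
    sites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-site adult morphometric summaries.

    Mean/SD SVL are computed over *all* adults (brooding males included:
    carrying a brood does not change body length).  Mean SMI is computed over
    non-brooding adults with mass data; sites with none get NaN, not zero.
    If ``sites`` is given, every individual's site_id must appear in it.
    """
    if sites is not None:
        known = set(sites["site_id"])
        unknown = sorted(set(individuals["site_id"]) - known)
        if unknown:
            raise IntegrityError(f"individual site_id(s) not in site table: {unknown}")
    rows = []
    for site_id, grp in individuals.groupby("site_id", sort=True):
        adults = grp[grp["stage"] == "adult"]
        smi_grp = adults[~adults["brooding"].astype(bool) & adults["mass_g"].notna()]
        if len(smi_grp):
            smi = scaled_mass_index(
                smi_grp["mass_g"].to_numpy(), smi_grp["svl_mm"].to_numpy(), params
            )
            mean_smi = float(np.mean(smi))
        else:
            mean_smi = np.nan
        rows.append(
            {
                "site_id": site_id,
                "n_adult": int(len(adults)),
                "mean_svl_mm": float(adults["svl_mm"].mean()) if len(adults) else np.nan,
                "sd_svl_mm": float(adults["svl_mm"].std(ddof=1)) if len(adults) > 1 else np.nan,
                "n_smi": int(len(smi_grp)),
                "mean_smi_g": mean_smi,
            }
        )
    return pd.DataFrame(rows)


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise InsufficientDataError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
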