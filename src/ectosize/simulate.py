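"""Synthetic site and individual tables for a transect-sampled terrestrial frog.

The study system is a small ectotherm sampled at a handful of sites along a
north-south climatic gradient.  No raw field data are published, so this module
generates tables with the same statistical structure the downstream analyses
assume:

* site-level bioclimatic covariates (BIO1 annual mean temperature, BIO4
  temperature seasonality, BIO12 annual precipitation, mean annual NDVI, plus
  the mean temperature of the coldest quarter ``t_winter``) drawn from a
  multivariate normal with configurable means, SDs and pairwise correlations;
* adult snout-vent length (SVL, mm) responding linearly to BIO4 with
  between-site and within-site Gaussian noise;
* body mass (g) following a power-law allometry ``a * svl**b`` with
  multiplicative lognormal noise;
* juveniles (smaller SVL, used only for the allometric fit downstream) and
  brooding males (male parental care inflates body mass, so they are excluded
  from condition analyses downstream).

Everything is deterministic given ``ScenarioSpec.seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import EctosizeError

#: canonical covariate order in the site table
COVARIATES = ("bio1", "bio4", "bio12", "ndvi", "t_winter")

#: covariates that enter candidate regression models (t_winter is diagnostic only)
MODEL_COVARIATES = ("bio1", "bio4", "bio12", "ndvi")


def _corr_key(a: str, b: str) -> str:
    return "~".join(sorted((a, b)))


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic study scenario.

    Correlation targets are keyed ``"var_a~var_b"`` (order-insensitive);
    unspecified pairs default to zero.  ``smi_l0`` is the SVL (mm) to which the
    scaled mass index standardises body mass.
    """

    n_sites: int = 14
    n_per_site: tuple[int, int] = (10, 271)
    covariate_means: dict[str, float] = field(
        default_factory=lambda: {
            "bio1": 9.5, "bio4": 380.0, "bio12": 2200.0, "ndvi": 0.78, "t_winter": 5.5,
        }
    )
    covariate_sds: dict[str, float] = field(
        default_factory=lambda: {
            "bio1": 1.5, "bio4": 60.0, "bio12": 600.0, "ndvi": 0.06, "t_winter": 1.8,
        }
    )
    covariate_correlations: dict[str, float] = field(
        default_factory=lambda: {
            "bio1~bio4": -0.40, "bio1~bio12": -0.30, "bio1~ndvi": 0.20,
            "bio1~t_winter": 0.80, "bio12~bio4": -0.20, "bio4~ndvi": -0.10,
            "bio4~t_winter": -0.65, "bio12~ndvi": 0.30, "bio12~t_winter": -0.10,
            "ndvi~t_winter": 0.10,
        }
    )
    beta0: float = 13.06          # mm; intercept of site mean adult SVL
    beta_bio4: float = 0.028      # mm per BIO4 unit
    site_sd: float = 0.4          # mm; between-site residual SD
    ind_sd: float = 1.5           # mm; within-site adult SVL SD
    allometry_a: float = 23.7 ** -3.278  # g * mm^-b, so a 23.7 mm adult weighs ~1 g
    allometry_b: float = 3.278
    mass_noise_sd: float = 0.1    # SD of lognormal mass noise
    juvenile_fraction: float = 0.2
    brooding_fraction: float = 0.3   # fraction of adult males carrying tadpoles
    juvenile_svl_scale: float = 0.62  # juvenile mean SVL as a fraction of adult site mean
    juvenile_svl_sd: float = 2.0  # mm
    lat_range: tuple[float, float] = (-43.4, -35.2)
    lon_range: tuple[float, float] = (-73.8, -71.5)
    smi_l0: float = 23.7          # mm; SMI standardisation length
    seed: int = 0

    # -- validation ---------------------------------------------------------

    def correlation_matrix(self) -> np.ndarray:
        k = len(COVARIATES)
        R = np.eye(k)
        for key, r in self.covariate_correlations.items():
            a, b = key.split("~")
            if a not in COVARIATES or b not in COVARIATES:
                raise EctosizeError(f"unknown covariate in correlation key {key!r}")
            i, j = COVARIATES.index(a), COVARIATES.index(b)
            R[i, j] = R[j, i] = r
        return R

    def validate(self) -> None:
        if self.n_sites < 3:
            raise EctosizeError(f"n_sites must be >= 3, got {self.n_sites}")
        lo, hi = self.n_per_site
        if lo < 2 or hi < lo:
            raise EctosizeError(f"n_per_site range invalid: {self.n_per_site}")
        if self.allometry_b <= 0:
            raise EctosizeError("allometry_b must be positive")
        for name in ("site_sd", "ind_sd", "mass_noise_sd", "juvenile_svl_sd"):
            if getattr(self, name) < 0:
                raise EctosizeError(f"{name} must be >= 0")
        for name in ("juvenile_fraction", "brooding_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise EctosizeError(f"{name} must lie in [0, 1], got {v}")
        for v in COVARIATES:
            if v not in self.covariate_means or v not in self.covariate_sds:
                raise EctosizeError(f"missing mean/SD for covariate {v!r}")
            if self.covariate_sds[v] < 0:
                raise EctosizeError(f"SD of {v!r} must be >= 0")
        R = self.correlation_matrix()
        eig = np.linalg.eigvalsh(R)
        if eig.min() <= 1e-10:
            # name the most plausible offender: the largest |r| requested
            key = max(self.covariate_correlations,
                      key=lambda k: abs(self.covariate_correlations[k]))
            raise EctosizeError(
                "correlation targets are not positive definite "
                f"(min eigenvalue {eig.min():.3g}); check pair {key!r} "
                f"(r = {self.covariate_correlations[key]})"
            )

    # -- (de)serialisation --------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["n_per_site"] = list(d["n_per_site"])
        d["lat_range"] = list(d["lat_range"])
        d["lon_range"] = list(d["lon_range"])
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScenarioSpec":
        d = json.loads(Path(path).read_text())
        for key in ("n_per_site", "lat_range", "lon_range"):
            if key in d:
                d[key] = tuple(d[key])
        spec = cls(**d)
        spec.validate()
        return spec


def darwinii_like_scenario(seed: int = 0) -> ScenarioSpec:
    """Scenario emulating the Darwin's frog study conditions.

    14 sites, per-site sample sizes between 10 and 271, mass-length allometric
    exponent 3.278, SMI standardisation length 23.7 mm, a positive BIO4 effect
    strong enough that site mean SVL spans roughly 21-27 mm, and a negative
    BIO4 / winter-temperature correlation of -0.65.
    """
    spec = ScenarioSpec(seed=seed)
    spec.validate()
    return spec


# ---------------------------------------------------------------------------


def generate_sites(spec: ScenarioSpec) -> pd.DataFrame:
    """Generate the site table: id, coordinates, elevation and covariates.

    Covariates are drawn from a multivariate normal with the requested
    means/SDs/correlations; NDVI is clipped to [0, 1].  Coordinates form a
    roughly latitudinal transect (synthetic WGS84 decimal degrees).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    k = len(COVARIATES)
    mean = np.array([spec.covariate_means[v] for v in COVARIATES])
    sd = np.array([spec.covariate_sds[v] for v in COVARIATES])
    cov = spec.correlation_matrix() * np.outer(sd, sd)
    X = rng.multivariate_normal(mean, cov, size=spec.n_sites, method="cholesky")
    X[:, COVARIATES.index("ndvi")] = np.clip(X[:, COVARIATES.index("ndvi")], 0.0, 1.0)

    lat = np.linspace(spec.lat_range[0], spec.lat_range[1], spec.n_sites)
    lat = lat + rng.uniform(-0.05, 0.05, spec.n_sites)
    lat = np.clip(lat, *spec.lat_range)
    lon = rng.uniform(spec.lon_range[0], spec.lon_range[1], spec.n_sites)
    elev = rng.uniform(9.0, 1120.0, spec.n_sites)

    df = pd.DataFrame(
        {
            "site_id": [f"S{i + 1:02d}" for i in range(spec.n_sites)],
            "lat": lat,
            "lon": lon,
            "elevation_m": elev,
        }
    )
    for j, v in enumerate(COVARIATES):
        df[v] = X[:, j]
    return df


def _positive_normal(rng: np.random.Generator, mean, sd, size) -> np.ndarray:
    """Normal draws with non-positive values redrawn (not truncated in place)."""
    x = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = x <= 0
        if not bad.any():
            return x
        x[bad] = rng.normal(np.broadcast_to(mean, x.shape)[bad], sd, bad.sum())
    raise EctosizeError("could not draw positive values; check means and SDs")


def generate_individuals(sites: pd.DataFrame, spec: ScenarioSpec) -> pd.DataFrame:
    """Generate the individual table for each site in ``sites``.

    Per-site sample size is log-uniform on ``n_per_site`` (field sampling of
    this kind is strongly right-skewed).  Adult SVL is
    ``beta0 + beta_bio4*BIO4 + site effect + individual noise``; juveniles are
    drawn around ``juvenile_svl_scale`` times the adult site mean.  Mass is
    ``allometry_a * svl**allometry_b`` with multiplicative lognormal noise.
    Brooding status is assigned to ``brooding_fraction`` of adult males.
    """
    spec.validate()
    if len(sites) == 0:
        raise EctosizeError("site table is empty")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    lo, hi = spec.n_per_site
    rows = []
    for _, site in sites.iterrows():
        n = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        n = int(np.clip(n, lo, hi))
        n_juv = int(round(spec.juvenile_fraction * n))
        n_adult = max(n - n_juv, 2)
        site_mu = spec.beta0 + spec.beta_bio4 * site["bio4"] + rng.normal(0.0, spec.site_sd)
        svl_ad = _positive_normal(rng, site_mu, spec.ind_sd, n_adult)
        svl_juv = _positive_normal(
            rng, spec.juvenile_svl_scale * site_mu, spec.juvenile_svl_sd, n_juv
        )
        svl = np.concatenate([svl_ad, svl_juv])
        mass = spec.allometry_a * svl ** spec.allometry_b
        mass = mass * np.exp(rng.normal(0.0, spec.mass_noise_sd, len(svl)))
        stage = ["adult"] * n_adult + ["juvenile"] * n_juv
        sex = np.where(rng.random(n_adult + n_juv) < 0.5, "m", "f")
        brooding = np.zeros(n_adult + n_juv, bool)
        male_adults = np.flatnonzero((sex == "m") & (np.arange(len(svl)) < n_adult))
        brooding[male_adults] = rng.random(len(male_adults)) < spec.brooding_fraction
        for i in range(len(svl)):
            rows.append(
                (site["site_id"], svl[i], mass[i], stage[i], sex[i], bool(brooding[i]))
            )
    return pd.DataFrame(
        rows, columns=["site_id", "svl_mm", "mass_g", "stage", "sex", "brooding"]
    )


def simulate_tables(spec: ScenarioSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: generate (sites, individuals) in one call."""
    sites = generate_sites(spec)
    return sites, generate_individuals(sites, spec)
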