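"""End-to-end orchestration: simulate/ingest -> condition -> selection -> HP -> spatial.

``run_pipeline`` sequences the full analysis and writes its artifacts
(CSV/JSON) to an output directory; every random stage draws from a child seed
of the single run seed, so reruns with the same config are byte-identical.
``render_report`` formats the ranked candidate tables and headline statistics
as a plain-text report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .condition import SMAAllometry, SMIParams, site_summaries
from .exceptions import EctosizeError
from .hierpart import HierarchicalPartitioning
from .selection import AICcModelSelector, CandidateModel, default_candidate_sets
from .simulate import MODEL_COVARIATES, ScenarioSpec, darwinii_like_scenario, simulate_tables
from .spatial import correlogram

#: site-table column -> candidate-model predictor name
COLUMN_TO_PREDICTOR = {"bio1": "BIO1", "bio4": "BIO4", "bio12": "BIO12", "ndvi": "NDVI"}


@dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults mirror the study settings
    (199 permutations, 10 distance classes)."""

    scenario: str | None = None          # "darwinii" or None (then paths required)
    sites_path: str | None = None
    individuals_path: str | None = None
    responses: tuple[str, ...] = ("svl", "smi")
    candidates: list[CandidateModel] | None = None
    n_permutations: int = 199
    n_distance_classes: int = 10
    seed: int = 0
    out_dir: str = "ectosize_run"
    hide_small_weights: bool = True
    clamp_negative_r2: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if "responses" in d:
            d["responses"] = tuple(d["responses"])
        return cls(**d)


@dataclass
class RunArtifacts:
    """In-memory results plus the paths of everything written to disk."""

    out_dir: Path
    sites: pd.DataFrame
    individuals: pd.DataFrame
    summaries: pd.DataFrame
    smi_params: SMIParams | None
    sma: dict | None
    selectors: dict = field(default_factory=dict)       # response -> AICcModelSelector
    hp: object | None = None
    correlograms: dict = field(default_factory=dict)    # name -> CorrelogramResult
    evidence_ratios: dict = field(default_factory=dict)
    run_log: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)


def _load_or_simulate(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, ScenarioSpec | None]:
    if config.scenario is not None:
        if config.scenario != "darwinii":
            raise EctosizeError(f"unknown scenario {config.scenario!r}")
        spec = darwinii_like_scenario(seed=config.seed)
        sites, individuals = simulate_tables(spec)
        return sites, individuals, spec
    for name, path in (("sites", config.sites_path), ("individuals", config.individuals_path)):
        if path is None:
            raise EctosizeError(f"no scenario named and no {name} path given")
        if not Path(path).exists():
            raise FileNotFoundError(f"{name} table not found: {path}")
    sites = pd.read_csv(config.sites_path)
    individuals = pd.read_csv(config.individuals_path)
    if "brooding" not in individuals:
        individuals["brooding"] = False
    if "mass_g" not in individuals:
        individuals["mass_g"] = np.nan
    return sites, individuals, None


def run_pipeline(config: RunConfig) -> RunArtifacts:
    """Run the full analysis and write artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sites, individuals, spec = _load_or_simulate(config)
    sites.to_csv(out / "sites.csv", index=False)
    individuals.to_csv(out / "individuals.csv", index=False)

    log: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "n_permutations": config.n_permutations,
        "n_distance_classes": config.n_distance_classes,
        "n_sites": int(len(sites)),
        "n_individuals": int(len(individuals)),
        "n_adults": int((individuals["stage"] == "adult").sum()),
        "n_juveniles": int((individuals["stage"] == "juvenile").sum()),
        "n_brooding_excluded_from_smi": int(individuals["brooding"].astype(bool).sum()),
    }
    skipped: list[str] = []

    # ---- body condition ---------------------------------------------------
    has_mass = individuals["mass_g"].notna() & ~individuals["brooding"].astype(bool)
    sma_dict = None
    smi_params = None
    if has_mass.sum() >= 3:
        l0 = spec.smi_l0 if spec is not None else None
        est = SMAAllometry(include_juveniles=True, l0=l0).fit(individuals)
        smi_params = est.params_
        sma_dict = {
            "b_sma": est.b_sma_, "slope_ols": est.slope_ols_, "pearson_r": est.pearson_r_,
            "intercept_ln": est.intercept_, "n": est.n_, "l0_mm": est.l0_,
        }
        log["n_sma_records"] = est.n_
    else:
        skipped.append("sma_fit (no usable mass data)")
        smi_params = None

    if smi_params is not None:
        summaries = site_summaries(individuals, smi_params, sites=sites)
    else:
        # SVL-only data: summarise without an SMI column
        summaries = site_summaries(individuals, SMIParams(b_sma=1.0, l0=1.0), sites=sites)
        summaries["mean_smi_g"] = np.nan
        summaries["n_smi"] = 0
    summaries.to_csv(out / "site_summaries.csv", index=False)
    log["n_smi"] = int(summaries["n_smi"].sum())

    # ---- model selection --------------------------------------------------
    merged = sites.merge(summaries, on="site_id", validate="one_to_one")
    X = merged[list(MODEL_COVARIATES)].rename(columns=COLUMN_TO_PREDICTOR)
    size_set, cond_set = default_candidate_sets()
    candidates = {"svl": size_set, "smi": cond_set}
    if config.candidates is not None:
        candidates = {r: config.candidates for r in candidates}
    responses = {"svl": merged["mean_svl_mm"], "smi": merged["mean_smi_g"]}

    selectors: dict = {}
    evidence: dict = {}
    for resp in config.responses:
        y = responses[resp]
        if y.isna().any():
            skipped.append(f"model_selection[{resp}] (missing response values)")
            continue
        sel = AICcModelSelector(candidates=candidates[resp]).fit(X, y)
        selectors[resp] = sel
        sel.table_.to_csv(out / f"selection_table_{resp}.csv")
        tbl = sel.table_.frame
        ev = {}
        for rank, key in ((1, "best_vs_second"), (2, "best_vs_third")):
            if len(tbl) > rank:
                ev[key] = sel.table_.evidence_ratio(tbl.loc[0, "model"], tbl.loc[rank, "model"])
        ev["summed_weight_BIO4"] = sel.table_.summed_weight("BIO4")
        evidence[resp] = ev

    with open(out / "evidence_ratios.json", "w") as fh:
        json.dump(evidence, fh, indent=2)

    # ---- hierarchical partitioning (body size) ----------------------------
    hp = None
    if "svl" in selectors:
        hp = HierarchicalPartitioning().fit(X, merged["mean_svl_mm"])
        hp.result_.to_frame().to_csv(out / "hp_result.csv", index=False)

    # ---- spatial diagnostics ----------------------------------------------
    coords = merged[["lat", "lon"]]
    seed_seq = np.random.SeedSequence([config.seed, 2]).spawn(3)
    correlograms: dict = {}
    targets = {"svl": merged["mean_svl_mm"]}
    if "smi" in selectors:
        targets["smi"] = merged["mean_smi_g"]
    if "svl" in selectors:
        targets["residuals"] = pd.Series(
            selectors["svl"].residuals(X, merged["mean_svl_mm"])
        )
    for (name, values), child in zip(targets.items(), seed_seq):
        cg = correlogram(
            values.to_numpy(float),
            coords,
            n_classes=config.n_distance_classes,
            n_permutations=config.n_permutations,
            seed=child,
        )
        correlograms[name] = cg
        cg.to_csv(out / f"correlogram_{name}.csv")

    log["skipped"] = skipped
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)

    artifacts = RunArtifacts(
        out_dir=out, sites=sites, individuals=individuals, summaries=summaries,
        smi_params=smi_params, sma=sma_dict, selectors=selectors, hp=hp,
        correlograms=correlograms, evidence_ratios=evidence, run_log=log,
        skipped=skipped,
    )
    (out / "report.txt").write_text(render_report(artifacts, config))
    return artifacts


def render_report(artifacts: RunArtifacts, config: RunConfig | None = None) -> str:
    """Plain-text report in the style of published candidate-model tables."""
    config = config or RunConfig()
    hide = 0.01 if config.hide_small_weights else 0.0
    lines = [f"ectosize analysis report (package {__version__})", ""]
    if artifacts.sma is not None:
        s = artifacts.sma
        lines += [
            f"Allometry: b_SMA = {s['b_sma']:.3f} (OLS slope {s['slope_ols']:.3f}, "
            f"r = {s['pearson_r']:.3f}, n = {s['n']}); SMI standardised to "
            f"L0 = {s['l0_mm']:.1f} mm", "",
        ]
    titles = {"svl": "Body size (mean adult SVL)", "smi": "Body condition (mean adult SMI)"}
    for resp, sel in artifacts.selectors.items():
        lines.append(titles.get(resp, resp))
        lines.append(sel.table_.render(hide_below=hide,
                                       clamp_negative_r2=config.clamp_negative_r2))
        ev = artifacts.evidence_ratios.get(resp, {})
        if "best_vs_second" in ev and "best_vs_third" in ev:
            lines.append(
                f"The best model was {ev['best_vs_second']:.1f} and "
                f"{ev['best_vs_third']:.1f} times more likely than the second and "
                f"third ranked models."
            )
        lines.append("")
    if artifacts.hp is not None:
        lines.append("Hierarchical partitioning of body-size R2 (independent %, "
                     f"total R2 = {artifacts.hp.total_r2_:.3f}):")
        for p, pct in sorted(artifacts.hp.independent_pct_.items(),
                             key=lambda kv: -kv[1]):
            lines.append(f"  {p:<6} {pct:6.1f} %")
        lines.append("")
    for name, cg in artifacts.correlograms.items():
        first = cg.frame.dropna(subset=["morans_i"]).head(1)
        if len(first):
            lines.append(
                f"Correlogram [{name}]: class 1 Moran's I = "
                f"{first['morans_i'].iloc[0]:.3f} (P = {first['p_value'].iloc[0]:.3f}, "
                f"{cg.n_permutations} permutations, {len(cg.frame)} classes)"
            )
    if artifacts.skipped:
        lines.append("")
        lines.append("Skipped stages: " + "; ".join(artifacts.skipped))
    return "\n".join(lines) + "\n"
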