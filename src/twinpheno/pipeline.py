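"""End-to-end orchestration: simulate/load -> randomize twin order -> bifactor
CFA -> invariance across co-twin subsamples -> factor scores -> twin models.

Every stage is seeded from the pipeline seed; a completed run is
reproducible bit-for-bit from config + seed + input.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import simulate as sim
from .cfa import FactorModelSpec, fit_with_indices
from .invariance import invariance_ladder
from .scores import (regression_scores, screen_outliers,
                     subsample_error_variances)
from .twin import (TwinModelSpec, compare_models, fit_model_set,
                   fit_twin_model, paired_phenotype)

GENERAL_INDICATORS = ["urgency", "premed", "ss", "predict", "paralysis",
                      "perfect", "threat", "thoughts"]  # persev dropped
GROUP_FACTORS = {"impulsivity": ["urgency", "premed", "persev"],
                 "obsessiveness": ["perfect", "threat", "thoughts"]}
REFERENCES = {"general": "predict", "impulsivity": "persev",
              "obsessiveness": "perfect"}
DEFAULT_ERROR_COVS = [("urgency", "ss"), ("premed", "ss"),
                      ("predict", "paralysis"), ("perfect", "predict"),
                      ("thoughts", "paralysis")]


def default_bifactor_spec(error_covariances=None) -> FactorModelSpec:
    """The orthogonal bifactor measurement model of the nine subscales."""
    if error_covariances is None:
        error_covariances = DEFAULT_ERROR_COVS
    return FactorModelSpec.bifactor(
        indicators=sim.INDICATORS,
        general_loadings=GENERAL_INDICATORS,
        group_loadings=GROUP_FACTORS,
        references=REFERENCES,
        error_covariances=error_covariances)


@dataclass
class PipelineConfig:
    input_path: str | None = None
    simulation: sim.SimulationConfig | None = None
    seed: int = 0
    randomize_twin_order: bool = True
    outlier_threshold: float = 3.29
    twin_models: tuple = ("ACE", "ADE", "AE", "CE", "E")
    covariate_policy: str = "age_on_general"   # or "test", "none"
    bic_n: str = "individuals"                 # or "pairs"
    theta_convention: str = "rho"              # or "rho_squared"
    output_dir: str | None = None

    def __post_init__(self):
        if self.input_path is None and self.simulation is None:
            self.simulation = sim.SimulationConfig(seed=self.seed)

    def config_hash(self) -> str:
        # analytic settings only: where the output lands does not change it
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    dataset_summary: dict
    measurement: dict
    invariance: pd.DataFrame
    latent_mean_tests: dict
    invariance_detail: dict
    score_diagnostics: dict
    comparisons: dict
    descriptives: dict
    parameter_table: pd.DataFrame | None = None

    def summary_json(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "dataset": self.dataset_summary,
            "measurement": self.measurement,
            "invariance": self.invariance.to_dict(orient="records"),
            "invariance_detail": self.invariance_detail,
            "latent_means": self.latent_mean_tests,
            "scores": self.score_diagnostics,
            "twin_models": {
                ph: {
                    "posterior": comp.posterior,
                    "preferred": list(comp.preferred),
                    "fits": {m: f.summary_row() | {
                        "standardized": f.standardized,
                        "covariates": f.covariate_effects}
                        for m, f in comp.fits.items()},
                } for ph, comp in self.comparisons.items()},
            "descriptives": self.descriptives,
        }

    def write(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.invariance.to_csv(outdir / "invariance.csv", index=False)
        if self.parameter_table is not None:
            self.parameter_table.to_csv(outdir / "measurement_parameters.csv",
                                        index=False)
        rows = []
        for ph, comp in self.comparisons.items():
            t = comp.table()
            t["phenotype"] = ph
            rows.append(t[["phenotype"] + [c for c in t.columns
                                           if c != "phenotype"]])
        if rows:
            pd.concat(rows, ignore_index=True).to_csv(
                outdir / "twin_models.csv", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.summary_json(), fh, indent=2, default=_jsonify)


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, tuple):
        return list(x)
    return str(x)


def randomize_twin_order(data: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Reassign twin index 1/2 uniformly at random within each pair;
    singletons drawn into a subsample uniformly."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 917]))
    out = data.copy()
    for pid, idx in out.groupby("pair_id").groups.items():
        idx = list(idx)
        if len(idx) == 2:
            if rng.random() < 0.5:
                out.loc[idx[0], "twin"], out.loc[idx[1], "twin"] = 1, 2
            else:
                out.loc[idx[0], "twin"], out.loc[idx[1], "twin"] = 2, 1
        else:
            out.loc[idx[0], "twin"] = 1 if rng.random() < 0.5 else 2
    out["twin"] = out["twin"].astype(int)
    return out


def two_sample_t(stats1: dict, stats2: dict) -> dict:
    """Pooled-variance two-sample t test from summary statistics
    ({mean, sd, n} per group); 95% CI on the mean difference."""
    m1, s1, n1 = stats1["mean"], stats1["sd"], stats1["n"]
    m2, s2, n2 = stats2["mean"], stats2["sd"], stats2["n"]
    if min(n1, n2) < 2 or min(s1, s2) <= 0:
        raise ValueError("each group needs n >= 2 and sd > 0")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df
    sed = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    diff = m1 - m2
    t = diff / sed
    q = sps.t.ppf(0.975, df)
    return {"t": float(t), "df": int(df), "p": float(2 * sps.t.sf(abs(t), df)),
            "mean_diff": float(diff),
            "ci95": (float(diff - q * sed), float(diff + q * sed))}


def _stage_logger(output_dir):
    log = logging.getLogger("twinpheno.pipeline")
    log.setLevel(logging.INFO)
    log.handlers = []
    if output_dir:
        Path(output_dir).mkdir(parents=True, exist_ok=True)
        h = logging.FileHandler(Path(output_dir) / "run.log", mode="w")
        h.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        log.addHandler(h)
    else:
        log.addHandler(logging.NullHandler())
    return log


def run_pipeline(config: PipelineConfig,
                 run_invariance: bool = True) -> RunReport:
    seed = config.seed
    log = _stage_logger(config.output_dir)
    t_start = time.time()
    log.info("start seed=%d config=%s", seed, config.config_hash())
    if config.input_path is not None:
        data = sim.read_csv(config.input_path)
    else:
        data = sim.simulate_dataset(config.simulation)
    if config.randomize_twin_order:
        data = randomize_twin_order(data, seed)
    log.info("data ready: %d rows", len(data))

    pair_sizes = data.groupby("pair_id").size()
    complete = pair_sizes[pair_sizes == 2].index
    by_zyg = data[data.pair_id.isin(complete)].drop_duplicates("pair_id") \
        .groupby("zygosity").size().to_dict()
    dataset_summary = {
        "n_rows": int(len(data)),
        "n_complete_pairs": int(len(complete)),
        "pairs_by_zygosity": {k: int(v) for k, v in by_zyg.items()},
        "n_singletons": int((pair_sizes == 1).sum()),
        "age_mean": float(data.drop_duplicates("pair_id")["age"].mean()),
    }

    spec = default_bifactor_spec()
    sub1 = data[data["twin"] == 1]
    sub2 = data[data["twin"] == 2]

    model1, fi1 = fit_with_indices(spec, sub1, seed=seed)
    measurement = {"subsample1_fit": fi1.as_dict(),
                   "converged": model1.converged,
                   "admissible": model1.admissible,
                   "n_params": model1.n_params}
    log.info("subsample-1 CFA: converged=%s chi2=%.3f df=%d",
             model1.converged, fi1.chi2, fi1.df)

    inv_detail = {}
    if run_invariance:
        ladder = invariance_ladder(spec, {"twin1": sub1, "twin2": sub2},
                                   seed=seed)
        inv_table = ladder.to_dataframe()
        latent_means = ladder.latent_mean_tests
        inv_detail = {"freed_residual_variances": list(ladder.freed_residuals)}
        log.info("invariance ladder done: freed=%s", ladder.freed_residuals)
    else:
        inv_table = pd.DataFrame()
        latent_means = {}

    combined, fi_c = fit_with_indices(spec, data, seed=seed)
    measurement["combined_fit"] = fi_c.as_dict()
    log.info("combined CFA: converged=%s chi2=%.3f df=%d",
             combined.converged, fi_c.chi2, fi_c.df)

    score_set = regression_scores(combined, data)
    score_set = subsample_error_variances(score_set, data["twin"],
                                          convention=config.theta_convention)
    screened = screen_outliers(score_set, data["twin"],
                               z_threshold=config.outlier_threshold)
    score_diag = {
        "determinacy": score_set.determinacy,
        "theta_delta": score_set.fixed_error_variances,
        "theta_convention": config.theta_convention,
        "subsample_variances": score_set.subsample_variances,
        "n_outliers_recoded": screened.n_outliers(),
        "score_correlations": (score_set.score_correlations.round(4).to_dict()
                               if score_set.score_correlations is not None else None),
    }

    comparisons = {}
    for pheno in sim.PHENOTYPES:
        pairs = paired_phenotype(data, screened.scores, pheno)
        covs = _covariates_for(config, pheno, pairs)
        theta = {t: screened.fixed_error_variances[pheno][t] for t in (1, 2)}
        fits = fit_model_set(pairs, config.twin_models, covariates=covs,
                             fixed_error=theta, phenotype_name=pheno,
                             n_obs_convention=config.bic_n)
        comparisons[pheno] = compare_models(fits)
        log.info("twin models %s: preferred=%s", pheno,
                 comparisons[pheno].preferred)

    # descriptive MZ-DZ age comparison among complete pairs
    pair_meta = data[data.pair_id.isin(complete)].drop_duplicates("pair_id")
    g = {z: {"mean": float(d["age"].mean()), "sd": float(d["age"].std(ddof=1)),
             "n": int(len(d))}
         for z, d in pair_meta.groupby("zygosity")}
    descriptives = {}
    if set(g) == {"MZ", "DZ"} and min(v["n"] for v in g.values()) >= 2:
        descriptives["age_mz_vs_dz"] = two_sample_t(g["MZ"], g["DZ"])
        descriptives["age_by_zygosity"] = g

    report = RunReport(config_hash=config.config_hash(), seed=seed,
                       dataset_summary=dataset_summary,
                       measurement=measurement, invariance=inv_table,
                       latent_mean_tests=latent_means,
                       invariance_detail=inv_detail,
                       score_diagnostics=score_diag,
                       comparisons=comparisons, descriptives=descriptives,
                       parameter_table=combined.parameter_table())
    log.info("done in %.1fs", time.time() - t_start)
    if config.output_dir:
        report.write(config.output_dir)
    return report


def _covariates_for(config: PipelineConfig, pheno: str,
                    pairs: pd.DataFrame) -> tuple:
    if config.covariate_policy == "none":
        return ()
    if config.covariate_policy == "age_on_general":
        return ("age",) if pheno == "general" else ()
    if config.covariate_policy == "test":
        # retain age if its slope is significant at alpha=0.05 in an ACE fit
        tspec = TwinModelSpec(components=("A", "C", "E"), covariates=("age",),
                              phenotype_name=pheno)
        fit = fit_twin_model(tspec, pairs, compute_se=True)
        beta = fit.covariate_effects.get("age", 0.0)
        se = fit.standard_errors.get("age", np.nan)
        if np.isfinite(se) and se > 0:
            z = beta / se
            if 2 * sps.norm.sf(abs(z)) < 0.05:
                return ("age",)
        return ()
    raise ValueError(f"unknown covariate policy {config.covariate_policy!r}")
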