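"""Confirmatory factor analysis with FIML, fit indices, bootstrap and post hoc fitting.

The central object is the orthogonal bifactor model of the nine questionnaire
subscales: every indicator loads on a general factor and at most one group
factor, factor intercorrelations fixed to zero, scaling by the reference
variable method (one unstandardised loading per factor fixed to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sem import (Param, SemModel, independence_loglik, mvn_fiml_mle,
                  saturated_loglik)


@dataclass
class FactorModelSpec:
    """Pattern of a confirmatory factor model.

    ``loading_pattern`` maps ``(factor, indicator)`` to ``"free"`` or a fixed
    value; the reference indicator of each factor must be fixed to 1.
    ``factor_covariances`` maps ``(f1, f2)`` off-diagonal cells to ``"free"``
    or a fixed value; omitted cells are fixed to 0 (orthogonal factors).
    """

    indicators: list[str]
    factors: list[str]
    loading_pattern: dict[tuple[str, str], object]
    references: dict[str, str]
    error_covariances: list[tuple[str, str]] = field(default_factory=list)
    factor_covariances: dict[tuple[str, str], object] = field(default_factory=dict)
    mean_structure: bool = True

    def __post_init__(self):
        seen = set()
        for a, b in self.error_covariances:
            if a == b:
                raise ValueError("error covariance requires two distinct indicators")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate error covariance {a},{b}")
            seen.add(key)
        for f in self.factors:
            ref = self.references.get(f)
            if ref is None:
                raise ValueError(f"factor {f!r} has no reference indicator")
            if self.loading_pattern.get((f, ref)) != 1.0 and \
                    self.loading_pattern.get((f, ref)) != "free":
                # the reference loading must be present; force fixed 1
                self.loading_pattern[(f, ref)] = 1.0
            indicators_of_f = [i for (ff, i) in self.loading_pattern if ff == f]
            if not indicators_of_f:
                raise ValueError(f"factor {f!r} has no indicators")

    def with_error_covariance(self, pair: tuple[str, str]) -> "FactorModelSpec":
        return FactorModelSpec(
            indicators=list(self.indicators), factors=list(self.factors),
            loading_pattern=dict(self.loading_pattern),
            references=dict(self.references),
            error_covariances=list(self.error_covariances) + [pair],
            factor_covariances=dict(self.factor_covariances),
            mean_structure=self.mean_structure)

    def to_dict(self) -> dict:
        return {
            "indicators": list(self.indicators),
            "factors": list(self.factors),
            "loadings": {f"{f}:{i}": ("free" if v == "free" else float(v))
                         for (f, i), v in self.loading_pattern.items()},
            "references": dict(self.references),
            "error_covariances": [list(p) for p in self.error_covariances],
            "factor_covariances": {f"{a}:{b}": v for (a, b), v
                                   in self.factor_covariances.items()},
            "mean_structure": self.mean_structure,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FactorModelSpec":
        pattern = {tuple(k.split(":")): v for k, v in d["loadings"].items()}
        fcov = {tuple(k.split(":")): v
                for k, v in d.get("factor_covariances", {}).items()}
        return cls(indicators=list(d["indicators"]),
                   factors=list(d["factors"]),
                   loading_pattern=pattern,
                   references=dict(d["references"]),
                   error_covariances=[tuple(p) for p
                                      in d.get("error_covariances", [])],
                   factor_covariances=fcov,
                   mean_structure=d.get("mean_structure", True))

    def to_yaml(self, path):
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FactorModelSpec":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @staticmethod
    def bifactor(indicators, general_loadings, group_loadings,
                 references, error_covariances=()):
        """Build an orthogonal bifactor spec.

        ``general_loadings``: indicators loading on the general factor;
        ``group_loadings``: mapping group-factor name -> its indicators;
        ``references``: factor -> reference indicator (loading fixed to 1).
        """
        factors = ["general"] + list(group_loadings)
        pattern: dict[tuple[str, str], object] = {}
        for ind in general_loadings:
            pattern[("general", ind)] = "free"
        for f, inds in group_loadings.items():
            for ind in inds:
                pattern[(f, ind)] = "free"
        for f, ref in references.items():
            pattern[(f, ref)] = 1.0
        return FactorModelSpec(indicators=list(indicators), factors=factors,
                               loading_pattern=pattern,
                               references=dict(references),
                               error_covariances=list(error_covariances))


@dataclass
class FittedFactorModel:
    spec: FactorModelSpec
    lam: np.ndarray
    nu: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    alpha: np.ndarray
    loglik: float
    n_params: int
    n_obs: int
    implied_mean: np.ndarray
    implied_cov: np.ndarray
    converged: bool
    heywood: bool
    standard_errors: dict[str, float] = field(default_factory=dict)
    estimates: dict[str, float] = field(default_factory=dict)
    loglik_saturated: float | None = None

    @property
    def admissible(self) -> bool:
        return self.converged and not self.heywood

    def standardized_loadings(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.implied_cov))
        fsd = np.sqrt(np.diag(self.phi))
        return self.lam * fsd[None, :] / sd[:, None]

    def standardized_theta(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.implied_cov))
        return self.theta / np.outer(sd, sd)

    def parameter_table(self) -> pd.DataFrame:
        rows = []
        std_l = self.standardized_loadings()
        std_t = self.standardized_theta()
        ind, fac = self.spec.indicators, self.spec.factors
        for (f, i), kind in self.spec.loading_pattern.items():
            r, c = ind.index(i), fac.index(f)
            name = f"{f}=~{i}"
            rows.append({"parameter": name, "estimate": self.lam[r, c],
                         "se": self.standard_errors.get(name, np.nan),
                         "standardized": std_l[r, c],
                         "free": kind == "free"})
        for k, i in enumerate(ind):
            name = f"theta[{i}]"
            rows.append({"parameter": name, "estimate": self.theta[k, k],
                         "se": self.standard_errors.get(name, np.nan),
                         "standardized": std_t[k, k], "free": True})
        for a, b in self.spec.error_covariances:
            r, c = ind.index(a), ind.index(b)
            name = f"theta[{a},{b}]"
            rows.append({"parameter": name, "estimate": self.theta[r, c],
                         "se": self.standard_errors.get(name, np.nan),
                         "standardized": std_t[r, c], "free": True})
        for k, f in enumerate(fac):
            name = f"phi[{f}]"
            rows.append({"parameter": name, "estimate": self.phi[k, k],
                         "se": self.standard_errors.get(name, np.nan),
                         "standardized": 1.0, "free": True})
        return pd.DataFrame(rows)


@dataclass
class FitIndices:
    chi2: float
    df: int
    p: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    cfi: float
    srmr: float

    def as_dict(self) -> dict:
        return {"chi2": self.chi2, "df": self.df, "p": self.p,
                "rmsea": self.rmsea, "rmsea_lo": self.rmsea_ci[0],
                "rmsea_hi": self.rmsea_ci[1], "cfi": self.cfi,
                "srmr": self.srmr}


# ---------------------------------------------------------------------
# Parameter-table construction
# ---------------------------------------------------------------------

def build_params(spec: FactorModelSpec, data: np.ndarray | None, group: int = 0,
                 shared: frozenset = frozenset(),
                 latent_means_free: bool = False,
                 freed_residuals: frozenset = frozenset()) -> list[Param]:
    """Translate a spec into the engine's parameter table for one group.

    ``shared`` names the parameter families constrained equal across groups
    ("loadings", "intercepts", "residual_variances", "factor_variances",
    "error_covariances"); shared parameters carry group-free labels.
    ``freed_residuals`` lists indicators whose residual variance stays
    group-specific under an otherwise shared residual constraint (partial
    strict invariance).
    """
    ind, fac = spec.indicators, spec.factors
    p = len(ind)
    if data is None:
        col_mean = np.zeros(p)
        col_var = np.ones(p)
    else:
        col_mean = np.array([np.nanmean(data[:, j]) if np.any(~np.isnan(data[:, j]))
                             else 0.0 for j in range(p)])
        col_var = np.array([max(np.nanvar(data[:, j]), 1e-3) for j in range(p)])
    params: list[Param] = []

    def lab(base, family):
        return base if family in shared else f"g{group}.{base}"

    for (f, i), kind in spec.loading_pattern.items():
        r, c = ind.index(i), fac.index(f)
        if kind == "free":
            params.append(Param(group, "lam", r, c, True, 0.5,
                                label=lab(f"lam[{f},{i}]", "loadings")))
        else:
            params.append(Param(group, "lam", r, c, False, float(kind)))
    for j, i in enumerate(ind):
        params.append(Param(group, "nu", j, 0, True, col_mean[j],
                            label=lab(f"nu[{i}]", "intercepts")))
        res_shared = "residual_variances" in shared and i not in freed_residuals
        base = f"theta[{i}]"
        params.append(Param(group, "theta", j, j, True, col_var[j] / 2,
                            label=base if res_shared else f"g{group}.{base}",
                            positive=True))
    for a, b in spec.error_covariances:
        r, c = ind.index(a), ind.index(b)
        params.append(Param(group, "theta", r, c, True, 0.0,
                            label=lab(f"theta[{a},{b}]", "error_covariances")))
    for k, f in enumerate(fac):
        ref_var = col_var[ind.index(spec.references[f])]
        params.append(Param(group, "phi", k, k, True, ref_var / 2,
                            label=lab(f"phi[{f}]", "factor_variances"),
                            positive=True))
        for k2 in range(k + 1, len(fac)):
            kind = spec.factor_covariances.get((f, fac[k2]),
                                               spec.factor_covariances.get((fac[k2], f), 0.0))
            if kind == "free":
                params.append(Param(group, "phi", k, k2, True, 0.0,
                                    label=lab(f"phi[{f},{fac[k2]}]", "factor_covariances")))
            else:
                params.append(Param(group, "phi", k, k2, False, float(kind)))
    for k, f in enumerate(fac):
        if latent_means_free:
            params.append(Param(group, "alpha", k, 0, True, 0.0,
                                label=f"g{group}.alpha[{f}]"))
        else:
            params.append(Param(group, "alpha", k, 0, False, 0.0))
    return params


def _check_identified(spec: FactorModelSpec, model: SemModel):
    p = len(spec.indicators)
    moments = model.n_groups * p * (p + 3) // 2
    if model.n_free > moments:
        raise ValueError(
            f"model not identified by the t-rule: {model.n_free} free "
            f"parameters exceed {moments} sample moments")


def fit_cfa(spec: FactorModelSpec, data: pd.DataFrame | np.ndarray,
            compute_se: bool = False, max_restarts: int = 50,
            seed: int = 0, x0: np.ndarray | None = None) -> FittedFactorModel:
    """Fit a CFA by FIML over rows with arbitrary missingness patterns."""
    y = _as_matrix(data, spec.indicators)
    params = build_params(spec, y)
    model = SemModel(params, [y], n_factors=len(spec.factors))
    _check_identified(spec, model)
    natural, neg2ll, converged = model.fit(max_restarts=max_restarts,
                                           seed=seed, x0=x0)
    lam, nu, theta, phi, alpha = model.matrices(natural)[0]
    heywood = bool(np.any(np.diag(theta) < -1e-8) or np.any(np.diag(phi) < -1e-8))
    estimates = {lab: natural[k] for lab, k in model.labels.items()}
    fitted = FittedFactorModel(
        spec=spec, lam=lam, nu=nu, theta=theta, phi=phi, alpha=alpha,
        loglik=-0.5 * neg2ll, n_params=model.n_free, n_obs=model.n_obs[0],
        implied_mean=nu + lam @ alpha,
        implied_cov=lam @ phi @ lam.T + theta,
        converged=converged, heywood=heywood,
        estimates={_strip_group(k): v for k, v in estimates.items()})
    fitted.loglik_saturated = saturated_loglik(y)
    if compute_se:
        ses = model.standard_errors(natural)
        by_label = {}
        for lab, k in model.labels.items():
            by_label[_strip_group(lab)] = float(ses[k])
        fitted.standard_errors = _relabel_se(by_label, spec)
    fitted._engine = (model, natural)  # kept for score tests / bootstrap refits
    return fitted


def _strip_group(label: str) -> str:
    return label.split(".", 1)[1] if label.startswith("g0.") else label


def _relabel_se(by_label: dict, spec: FactorModelSpec) -> dict:
    out = {}
    for lab, se in by_label.items():
        if lab.startswith("lam["):
            f, i = lab[4:-1].split(",")
            out[f"{f}=~{i}"] = se
        else:
            out[lab] = se
    return out


def _as_matrix(data, indicators) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        return data.loc[:, indicators].to_numpy(dtype=float)
    return np.asarray(data, dtype=float)


# ---------------------------------------------------------------------
# Fit indices
# ---------------------------------------------------------------------

def chi2_vs_saturated(model: FittedFactorModel) -> tuple[float, int]:
    """Likelihood-ratio statistic 2*(LL_sat - LL_model) and its df."""
    p = len(model.spec.indicators)
    moments = p * (p + 3) // 2
    df = moments - model.n_params
    chi2 = max(2.0 * (model.loglik_saturated - model.loglik), 0.0)
    return chi2, df


def rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90):
    """RMSEA 90% CI by inverting the noncentral chi-square distribution."""
    if df == 0:
        return (np.nan, np.nan)
    lo_q, hi_q = (1 + level) / 2, (1 - level) / 2

    def solve(q):
        # find lambda with ncx2.cdf(chi2, df, lambda) = q
        if stats.chi2.cdf(chi2, df) < q:
            return 0.0
        f = lambda lam: stats.ncx2.cdf(chi2, df, lam) - q
        hi = max(chi2 * 2, 10.0)
        while f(hi) > 0:
            hi *= 2
            if hi > 1e8:
                break
        from scipy.optimize import brentq
        try:
            return brentq(f, 0.0, hi)
        except ValueError:
            return 0.0

    lam_lo = solve(lo_q)
    lam_hi = solve(hi_q)
    return (np.sqrt(lam_lo / (df * n)), np.sqrt(lam_hi / (df * n)))


def fit_indices(model: FittedFactorModel, baseline_loglik: float,
                baseline_n_params: int, n: int,
                sample_mean: np.ndarray | None = None,
                sample_cov: np.ndarray | None = None) -> FitIndices:
    """Chi-square battery against the saturated model and the independence
    baseline fit to the same rows."""
    chi2, df = chi2_vs_saturated(model)
    p_ind = len(model.spec.indicators)
    if df == 0:
        return FitIndices(chi2=chi2, df=0, p=np.nan, rmsea=np.nan,
                          rmsea_ci=(np.nan, np.nan), cfi=np.nan,
                          srmr=_srmr(model, sample_cov))
    p = float(stats.chi2.sf(chi2, df))
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * n)))
    ci = rmsea_ci(chi2, df, n)
    chi2_b = max(2.0 * (model.loglik_saturated - baseline_loglik), 0.0)
    df_b = p_ind * (p_ind + 3) // 2 - baseline_n_params
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - df, 0.0) / denom
    cfi = float(np.clip(cfi, 0.0, 1.0))
    return FitIndices(chi2=chi2, df=df, p=p, rmsea=rmsea, rmsea_ci=ci,
                      cfi=cfi, srmr=_srmr(model, sample_cov))


def baseline_fit(data: pd.DataFrame | np.ndarray, indicators) -> tuple[float, int]:
    """Independence model (free means and variances, zero covariances)."""
    y = _as_matrix(data, indicators)
    return independence_loglik(y), 2 * y.shape[1]


def _srmr(model: FittedFactorModel, sample_cov: np.ndarray | None) -> float:
    if sample_cov is None:
        return np.nan
    s, sig = sample_cov, model.implied_cov
    d = np.sqrt(np.diag(s))
    resid = (s - sig) / np.outer(d, d)
    iu = np.triu_indices_from(resid)
    return float(np.sqrt(np.mean(resid[iu] ** 2)))


def fit_with_indices(spec: FactorModelSpec, data: pd.DataFrame | np.ndarray,
                     **kw) -> tuple[FittedFactorModel, FitIndices]:
    y = _as_matrix(data, spec.indicators)
    model = fit_cfa(spec, y, **kw)
    bl_ll, bl_k = baseline_fit(y, spec.indicators)
    _, s_cov, _ = mvn_fiml_mle(y)
    n = int(np.sum(np.any(~np.isnan(y), axis=1)))
    fi = fit_indices(model, bl_ll, bl_k, n, sample_cov=s_cov)
    return model, fi


# ---------------------------------------------------------------------
# Bollen-Stine bootstrap
# ---------------------------------------------------------------------

def bollen_stine_p(model: FittedFactorModel, spec: FactorModelSpec,
                   data: pd.DataFrame | np.ndarray, n_draws: int,
                   seed: int = 0) -> tuple[float, dict]:
    """Bootstrap p-value for exact fit.

    Complete-case rows are transformed so the fitted model holds exactly
    (Y* = (Y - ybar) S^{-1/2} Sigma_hat^{1/2} + mu_hat), resampled with
    replacement, and refit; the returned p is the proportion of bootstrap
    chi-square statistics at or above the observed one.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    y = _as_matrix(data, spec.indicators)
    complete = y[~np.isnan(y).any(axis=1)]
    if complete.shape[0] < len(spec.indicators) + 1:
        raise ValueError("too few complete rows for the bootstrap transform")
    ybar = complete.mean(axis=0)
    s = np.cov(complete.T, bias=True)
    s_inv_half = _matrix_power(s, -0.5)
    sig_half = _matrix_power(model.implied_cov, 0.5)
    z = (complete - ybar) @ s_inv_half @ sig_half + model.implied_mean
    chi2_obs, _ = chi2_vs_saturated(model)
    rng = np.random.default_rng(seed)
    count = 0
    fails = 0
    warm = getattr(model, "_engine", (None, None))[1]
    for _ in range(n_draws):
        idx = rng.integers(0, z.shape[0], size=z.shape[0])
        boot = z[idx]
        try:
            m = fit_cfa(spec, boot, max_restarts=2, x0=warm)
            if not m.converged:
                fails += 1
                continue
            c, _ = chi2_vs_saturated(m)
        except Exception:
            fails += 1
            continue
        if c >= chi2_obs - 1e-12:
            count += 1
    used = n_draws - fails
    status = {"n_draws": n_draws, "failures": fails,
              "warning": fails > 0.1 * n_draws}
    p = count / used if used else np.nan
    return p, status


def _matrix_power(a: np.ndarray, power: float) -> np.ndarray:
    w, v = np.linalg.eigh(a)
    w = np.maximum(w, 1e-12)
    return v @ np.diag(w ** power) @ v.T


# ---------------------------------------------------------------------
# Benjamini-Hochberg and post hoc error-covariance freeing
# ---------------------------------------------------------------------

def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up; returns boolean rejection flags."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = q * (np.arange(1, m + 1)) / m
    passed = np.where(p[order] <= thresh)[0]
    flags = np.zeros(m, dtype=bool)
    if passed.size:
        flags[order[: passed[-1] + 1]] = True
    return flags


def modification_indices(model: FittedFactorModel,
                         candidate_pairs) -> dict[tuple[str, str], float]:
    """Univariate score tests (expected chi-square(1) improvement) for freeing
    each candidate error covariance, evaluated at the restricted optimum."""
    engine, natural = model._engine
    spec = model.spec
    out = {}
    for pair in candidate_pairs:
        aug_spec = spec.with_error_covariance(tuple(pair))
        aug_params = build_params(aug_spec, None, 0)
        aug_model = SemModel(aug_params, [np.zeros((1, engine.p))],
                             n_factors=len(spec.factors))
        aug_model.pats = engine.pats  # reuse the fitted data's statistics
        aug_model.n_obs = engine.n_obs
        nat_aug = _carry_estimates(engine, natural, aug_model)
        out[tuple(pair)] = aug_model.score_test(nat_aug)
    return out


def _carry_estimates(src: SemModel, natural_src: np.ndarray,
                     dst: SemModel) -> np.ndarray:
    by_label = {lab: natural_src[k] for lab, k in src.labels.items()}
    nat = np.array(dst.x_start, dtype=float)
    for lab, k in dst.labels.items():
        if lab in by_label:
            nat[k] = by_label[lab]
        else:
            nat[k] = 0.0  # newly released parameter at its constrained value
    return nat


def post_hoc_free_covariances(spec: FactorModelSpec,
                              data: pd.DataFrame | np.ndarray,
                              candidate_pairs, q: float = 0.05,
                              target_rmsea: float = 0.05,
                              max_added: int | None = None,
                              seed: int = 0):
    """Free candidate error covariances one at a time by largest modification
    index; stop at close approximate fit or exhausted candidates; the added
    set must jointly survive Benjamini-Hochberg at rate ``q``.

    Returns (augmented spec, report dict).
    """
    candidates = [tuple(c) for c in candidate_pairs]
    added: list[tuple[str, str]] = []
    report = {"steps": [], "added": [], "dropped": []}
    current = spec
    y = _as_matrix(data, spec.indicators)
    if max_added is None:
        max_added = len(candidates)
    while candidates and len(added) < max_added:
        model, fi = fit_with_indices(current, y, seed=seed)
        if fi.df == 0 or (fi.rmsea is not np.nan and fi.rmsea <= target_rmsea):
            break
        mis = modification_indices(model, candidates)
        best = max(mis, key=mis.get)
        report["steps"].append({"candidate": best, "mi": mis[best],
                                "all_mi": {f"{a},{b}": v
                                           for (a, b), v in mis.items()}})
        current = current.with_error_covariance(best)
        added.append(best)
        candidates.remove(best)
    if not added:
        return spec, report
    # joint significance screen on the final model's added parameters
    final = fit_cfa(current, y, compute_se=True, seed=seed)
    pvals = []
    for a, b in added:
        est = final.theta[spec.indicators.index(a), spec.indicators.index(b)]
        se = final.standard_errors.get(f"theta[{a},{b}]", np.nan)
        z = est / se if se and np.isfinite(se) and se > 0 else 0.0
        pvals.append(2 * stats.norm.sf(abs(z)))
    flags = bh_fdr(pvals, q)
    kept = [pair for pair, f in zip(added, flags) if f]
    report["added"] = kept
    report["dropped"] = [pair for pair, f in zip(added, flags) if not f]
    report["p_values"] = dict(zip([f"{a},{b}" for a, b in added], pvals))
    final_spec = spec
    for pair in kept:
        final_spec = final_spec.with_error_covariance(pair)
    return final_spec, report
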