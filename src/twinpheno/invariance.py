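"""Measurement-invariance testing across the twin-1 and twin-2 subsamples.

Fits the cumulative ladder of multi-group models — configural (same pattern),
weak (equal loadings), strong (equal intercepts), strict (equal residual
variances, with a partial-strict fallback freeing offending residuals one at
a time), equality of factor variances — and reports the nested chi-square
difference tests between adjacent levels.  Error covariances are always kept
group-specific.  Latent means are tested after strong invariance via
two-tailed z tests on the second group's latent means (first group fixed at
zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cfa import (FactorModelSpec, FitIndices, baseline_fit, build_params,
                  rmsea_ci, _as_matrix, _carry_estimates)
from .sem import SemModel, mvn_fiml_mle, saturated_loglik

LADDER = ["configural", "weak", "strong", "strict", "equal_factor_variances"]

_SHARED = {
    "configural": frozenset(),
    "weak": frozenset({"loadings"}),
    "strong": frozenset({"loadings", "intercepts"}),
    "strict": frozenset({"loadings", "intercepts", "residual_variances"}),
    "equal_factor_variances": frozenset({"loadings", "intercepts",
                                         "residual_variances",
                                         "factor_variances"}),
}


@dataclass
class InvarianceLevel:
    name: str
    shared: frozenset
    freed_parameters: tuple = ()
    latent_means_free: bool = False

    @classmethod
    def named(cls, name: str, freed: tuple = ()) -> "InvarianceLevel":
        if name == "partial_strict":
            if not freed:
                raise ValueError("partial_strict must name freed residual variances")
            return cls("partial_strict", _SHARED["strict"], tuple(freed))
        if name == "equal_latent_means":
            return cls("equal_latent_means", _SHARED["strong"])
        if name not in _SHARED:
            raise ValueError(f"unknown invariance level {name!r}")
        return cls(name, _SHARED[name])


@dataclass
class MultiGroupFit:
    level: InvarianceLevel
    loglik: float
    loglik_saturated: float
    n_params: int
    n_obs: int
    df: int
    chi2: float
    p: float
    indices: FitIndices
    converged: bool
    group_matrices: list
    _engine: tuple = None

    def natural(self):
        return self._engine[1]


def _build_joint(spec: FactorModelSpec, ys: list[np.ndarray],
                 level: InvarianceLevel) -> SemModel:
    params = []
    for g, y in enumerate(ys):
        params += build_params(
            spec, y, group=g, shared=level.shared,
            latent_means_free=(level.latent_means_free and g > 0),
            freed_residuals=frozenset(level.freed_parameters))
    return SemModel(params, ys, n_factors=len(spec.factors))


def _warm_start(src: SemModel, natural_src: np.ndarray, dst: SemModel):
    by_label = {lab: natural_src[k] for lab, k in src.labels.items()}
    nat = np.array(dst.x_start, dtype=float)
    for lab, k in dst.labels.items():
        if lab in by_label:
            nat[k] = by_label[lab]
            continue
        # constraining step: average the source's group-specific copies
        vals = [v for l2, v in by_label.items()
                if l2.split(".", 1)[-1] == lab.split(".", 1)[-1]]
        if vals:
            nat[k] = float(np.mean(vals))
    return nat


def fit_multigroup(spec: FactorModelSpec, data_by_group: dict,
                   level: InvarianceLevel | str,
                   warm: tuple | None = None, seed: int = 0,
                   max_restarts: int = 20) -> MultiGroupFit:
    """Joint FIML fit over groups with the level's equality constraints."""
    if isinstance(level, str):
        level = InvarianceLevel.named(level)
    names = list(data_by_group)
    if len(names) < 2:
        raise ValueError("invariance testing requires at least two groups")
    ys = [_as_matrix(data_by_group[g], spec.indicators) for g in names]
    for g, y in zip(names, ys):
        if np.sum(np.any(~np.isnan(y), axis=1)) < 2:
            raise ValueError(f"group {g!r} has fewer than two usable rows")
    model = _build_joint(spec, ys, level)
    x0 = _warm_start(*warm, model) if warm is not None else None
    natural, neg2ll, converged = model.fit(max_restarts=max_restarts,
                                           seed=seed, x0=x0)
    ll = -0.5 * neg2ll
    ll_sat = sum(saturated_loglik(y) for y in ys)
    p_ind = len(spec.indicators)
    moments = len(ys) * p_ind * (p_ind + 3) // 2
    df = moments - model.n_free
    chi2 = max(2.0 * (ll_sat - ll), 0.0)
    pval = float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan
    n_total = sum(model.n_obs)
    # joint baseline: independence model per group
    bl = sum(baseline_fit(y, spec.indicators)[0] for y in ys)
    bl_k = sum(2 * p_ind for _ in ys)
    chi2_b = max(2.0 * (ll_sat - bl), 0.0)
    df_b = moments - bl_k
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else float(np.clip(1 - max(chi2 - df, 0) / denom, 0, 1))
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * n_total))) if df > 0 else np.nan
    ci = rmsea_ci(chi2, df, n_total) if df > 0 else (np.nan, np.nan)
    srmr = _multigroup_srmr(model, natural, ys)
    indices = FitIndices(chi2=chi2, df=df, p=pval, rmsea=rmsea, rmsea_ci=ci,
                         cfi=cfi, srmr=srmr)
    return MultiGroupFit(level=level, loglik=ll, loglik_saturated=ll_sat,
                         n_params=model.n_free, n_obs=n_total, df=df,
                         chi2=chi2, p=pval, indices=indices,
                         converged=converged,
                         group_matrices=model.matrices(natural),
                         _engine=(model, natural))


def _multigroup_srmr(model: SemModel, natural, ys) -> float:
    resid_sq = []
    for g, (mu, sigma) in enumerate(model.implied_moments(natural)):
        _, s, _ = mvn_fiml_mle(ys[g])
        d = np.sqrt(np.diag(s))
        r = (s - sigma) / np.outer(d, d)
        iu = np.triu_indices_from(r)
        resid_sq.extend(r[iu] ** 2)
    return float(np.sqrt(np.mean(resid_sq)))


@dataclass
class InvarianceReport:
    levels: list[MultiGroupFit]
    deltas: list[dict]
    latent_mean_tests: dict
    freed_residuals: tuple = ()

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for k, fit in enumerate(self.levels):
            fi = fit.indices
            row = {"level": fit.level.name, "df": fit.df, "chi2": fit.chi2,
                   "p": fit.p, "rmsea": fi.rmsea, "rmsea_lo": fi.rmsea_ci[0],
                   "rmsea_hi": fi.rmsea_ci[1], "cfi": fi.cfi, "srmr": fi.srmr}
            if k > 0:
                d = self.deltas[k - 1]
                row.update({"delta_df": d["delta_df"],
                            "delta_chi2": d["delta_chi2"],
                            "delta_p": d["delta_p"]})
            rows.append(row)
        return pd.DataFrame(rows)


def repair_monotone(spec: FactorModelSpec, data_by_group: dict,
                    fits: list, seed: int = 0) -> list:
    """Restore likelihood monotonicity along a nested sequence.

    A freer model can never truly fit worse than a model nested within it;
    when it does, the freer fit sits in a local optimum.  Refitting it
    warm-started from the restricted solution (a feasible point of the freer
    parameter space) repairs the inversion.  ``fits`` is ordered freest
    first.
    """
    fits = list(fits)
    for _pass in range(len(fits)):
        changed = False
        for k in range(len(fits) - 1):
            if fits[k].chi2 - fits[k + 1].chi2 > 1e-8:  # freer fits worse
                refit = fit_multigroup(spec, data_by_group, fits[k].level,
                                       warm=fits[k + 1]._engine, seed=seed)
                if refit.chi2 < fits[k].chi2 - 1e-10:
                    fits[k] = refit
                    changed = True
        if not changed:
            break
    return fits


def delta_chi2(fit_restricted: MultiGroupFit,
               fit_freer: MultiGroupFit) -> dict:
    """Nested difference test between adjacent ladder levels."""
    dchi = fit_restricted.chi2 - fit_freer.chi2
    if dchi < -1e-8:
        raise ValueError("restricted model fits better than the freer model "
                         f"(delta chi2 = {dchi:.3g}); check convergence")
    dchi = max(dchi, 0.0)
    ddf = fit_restricted.df - fit_freer.df
    if ddf <= 0:
        raise ValueError("constraining step must add degrees of freedom")
    return {"delta_chi2": dchi, "delta_df": ddf,
            "delta_p": float(stats.chi2.sf(dchi, ddf))}


def latent_mean_tests(spec: FactorModelSpec, data_by_group: dict,
                      warm: tuple | None = None, seed: int = 0) -> dict:
    """Two-tailed z tests on the second group's latent means under strong
    invariance (first group's means fixed at zero)."""
    level = InvarianceLevel("latent_means", _SHARED["strong"],
                            latent_means_free=True)
    fit = fit_multigroup(spec, data_by_group, level, warm=warm, seed=seed)
    model, natural = fit._engine
    ses = model.standard_errors(natural)
    out = {}
    for f in spec.factors:
        for g in range(1, len(data_by_group)):
            lab = f"g{g}.alpha[{f}]"
            if lab not in model.labels:
                continue
            k = model.labels[lab]
            z = natural[k] / ses[k] if ses[k] > 0 else np.nan
            out[f] = {"estimate": float(natural[k]), "se": float(ses[k]),
                      "z": float(z), "p": float(2 * stats.norm.sf(abs(z)))}
    return out


def _residual_release_mi(strict_fit: MultiGroupFit, spec: FactorModelSpec,
                         ys: list[np.ndarray], already_freed: tuple) -> dict:
    """Score-test modification indices for letting each still-constrained
    residual variance differ between groups."""
    model, natural = strict_fit._engine
    out = {}
    for ind in spec.indicators:
        if ind in already_freed:
            continue
        level = InvarianceLevel("partial_strict", _SHARED["strict"],
                                tuple(already_freed) + (ind,))
        aug = _build_joint(spec, ys, level)
        nat_aug = _carry_estimates(model, natural, aug)
        # the split copies start at the shared estimate
        shared_lab = f"theta[{ind}]"
        shared_val = None
        for lab, k in model.labels.items():
            if lab == shared_lab:
                shared_val = natural[k]
        if shared_val is not None:
            for lab, k in aug.labels.items():
                if lab.endswith(f".{shared_lab}") or lab == shared_lab:
                    nat_aug[k] = shared_val
        out[ind] = aug.score_test(nat_aug)
    return out


def invariance_ladder(spec: FactorModelSpec, data_by_group: dict,
                      alpha: float = 0.05, seed: int = 0) -> InvarianceReport:
    """Fit the cumulative invariance sequence with the partial-strict
    fallback, then test factor-variance equality and latent means."""
    names = list(data_by_group)
    ys = [_as_matrix(data_by_group[g], spec.indicators) for g in names]
    fits: list[MultiGroupFit] = []
    freed: tuple = ()
    warm = None

    def run(level, warm):
        f = fit_multigroup(spec, data_by_group, level, warm=warm, seed=seed)
        if not f.converged:
            raise RuntimeError(f"level {level if isinstance(level, str) else level.name} "
                               "did not converge; ladder halted")
        return f

    for name in ("configural", "weak", "strong"):
        fits.append(run(name, warm))
        fits = repair_monotone(spec, data_by_group, fits, seed)
        warm = fits[-1]._engine

    # strict step with partial fallback
    strict_level = InvarianceLevel.named("strict")
    strict_fit = run(strict_level, warm)
    fits = repair_monotone(spec, data_by_group, fits + [strict_fit], seed)
    fits, strict_fit = fits[:-1], fits[-1]
    d = delta_chi2(strict_fit, fits[-1])
    while d["delta_p"] <= alpha and len(freed) < len(spec.indicators) - 1:
        mis = _residual_release_mi(strict_fit, spec, ys, freed)
        if not mis:
            break
        worst = max(mis, key=mis.get)
        freed = freed + (worst,)
        strict_fit = run(InvarianceLevel.named("partial_strict", freed),
                         strict_fit._engine)
        d = delta_chi2(strict_fit, fits[-1])
    strict_fit.level.name = "partial_strict" if freed else "strict"
    fits.append(strict_fit)

    # equality of factor variances, on top of the (partial) strict solution
    fv_level = InvarianceLevel("equal_factor_variances",
                               _SHARED["equal_factor_variances"], freed)
    fits.append(run(fv_level, strict_fit._engine))
    fits = repair_monotone(spec, data_by_group, fits, seed)
    deltas = [delta_chi2(b, a) for a, b in zip(fits, fits[1:])]

    means = latent_mean_tests(spec, data_by_group, warm=fits[2]._engine,
                              seed=seed)
    return InvarianceReport(levels=fits, deltas=deltas,
                            latent_mean_tests=means, freed_residuals=freed)
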