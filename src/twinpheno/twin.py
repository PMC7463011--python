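"""Classical twin variance-components models (ACE, ADE, AE, CE, E).

Each phenotype enters as two single-indicator latent variables (twin-1 and
twin-2 factor-score estimates) with measurement-error variance fixed at
theta_delta per subsample.  The latent pair covariance follows the standard
biometric expectations

    diag:      a^2 + c^2 + d^2 + e^2
    MZ cross:  a^2 + c^2 + d^2
    DZ cross:  0.5 a^2 + c^2 + 0.25 d^2

and the mean structure is nu_twin + beta * covariates.  The two-group (MZ,
DZ) bivariate-normal likelihood is maximized by quasi-Newton in path
coefficients (a, c, d, e), so every variance component is non-negative by
construction.  Pairs with one missing member contribute through their
univariate marginal (FIML).  Models are compared by the chi-square test
against a per-zygosity saturated model, by BIC, and by equal-prior BIC
weights (Bayesian conditional posterior probabilities Pr(Hi|D)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

MODEL_SETS = {"ACE": ("A", "C", "E"), "ADE": ("A", "D", "E"),
              "AE": ("A", "E"), "CE": ("C", "E"), "E": ("E",)}


@dataclass
class TwinModelSpec:
    components: tuple = ("A", "C", "E")
    covariates: tuple = ()            # subset of ("age",)
    fixed_error: dict = field(default_factory=lambda: {1: 0.0, 2: 0.0})
    phenotype_name: str = ""

    def __post_init__(self):
        comps = set(self.components)
        if "E" not in comps:
            raise ValueError("E must always be present")
        if {"C", "D"} <= comps:
            raise ValueError("C and D are mutually exclusive")
        if not comps <= {"A", "C", "D", "E"}:
            raise ValueError(f"unknown components {comps - {'A','C','D','E'}}")
        if any(v < 0 for v in self.fixed_error.values()):
            raise ValueError("fixed error variances must be non-negative")

    @property
    def name(self) -> str:
        order = [c for c in ("A", "C", "D", "E") if c in self.components]
        return "".join(order)


@dataclass
class TwinModelFit:
    spec: TwinModelSpec
    paths: dict[str, float]           # a, c, d, e point estimates
    components: dict[str, float]      # unstandardized A2, C2, D2, E2
    standardized: dict[str, float]
    intercepts: tuple
    covariate_effects: dict
    minus2LL: float
    n_params: int
    df: int
    chi2: float
    p: float
    bic: float
    h2: float
    n_obs: int
    converged: bool
    boundary: bool
    standard_errors: dict = field(default_factory=dict)

    def summary_row(self) -> dict:
        return {"phenotype": self.spec.phenotype_name, "model": self.spec.name,
                "minus2LL": self.minus2LL, "df": self.df, "chi2": self.chi2,
                "p": self.p, "bic": self.bic, "h2": self.h2}


def expected_pair_covariance(spec: TwinModelSpec, params: dict,
                             zygosity: str) -> np.ndarray:
    """Observed-scale 2x2 covariance of a twin pair's phenotype scores."""
    if zygosity not in ("MZ", "DZ"):
        raise ValueError("zygosity must be 'MZ' or 'DZ'")
    a2 = params.get("a", 0.0) ** 2
    c2 = params.get("c", 0.0) ** 2
    d2 = params.get("d", 0.0) ** 2
    e2 = params.get("e", 0.0) ** 2
    diag = a2 + c2 + d2 + e2
    if zygosity == "MZ":
        off = a2 + c2 + d2
    else:
        off = 0.5 * a2 + c2 + 0.25 * d2
    out = np.array([[diag + spec.fixed_error.get(1, 0.0), off],
                    [off, diag + spec.fixed_error.get(2, 0.0)]])
    return out


# ---------------------------------------------------------------------
# Likelihood machinery on pair-level sufficient statistics
# ---------------------------------------------------------------------

@dataclass
class _GroupStats:
    """Moment sums per (zygosity, missingness-pattern) cell, sufficient for a
    linear mean model in one pair-level covariate."""
    obs: tuple            # observed member indices within the pair
    n: int
    sy: np.ndarray        # sum of y
    syy: np.ndarray       # sum of y y'
    sx: float             # sum of covariate
    sxx: float
    sxy: np.ndarray       # sum of x * y


def _group_stats(pairs: pd.DataFrame, use_age: bool) -> dict:
    """Split pair rows (columns y1, y2, age, zygosity) into stats cells."""
    out: dict[tuple, _GroupStats] = {}
    x = pairs["age_c"].to_numpy() if use_age else np.zeros(len(pairs))
    y = pairs[["y1", "y2"]].to_numpy(dtype=float)
    zyg = pairs["zygosity"].to_numpy()
    obs_mask = ~np.isnan(y)
    for z in ("MZ", "DZ"):
        sel_z = zyg == z
        for pattern in ((True, True), (True, False), (False, True)):
            sel = sel_z & (obs_mask[:, 0] == pattern[0]) & (obs_mask[:, 1] == pattern[1])
            if not sel.any():
                continue
            idx = tuple(i for i, o in enumerate(pattern) if o)
            yy = y[np.ix_(sel, idx)]
            xx = x[sel]
            out[(z, idx)] = _GroupStats(
                obs=idx, n=int(sel.sum()), sy=yy.sum(0), syy=yy.T @ yy,
                sx=float(xx.sum()), sxx=float(xx @ xx), sxy=xx @ yy)
    return out


def _neg2ll_from_stats(stats_cells: dict, mu_fn, cov_fn) -> float:
    """-2LL given callables mu_fn(zygosity) -> (nu1, nu2, beta) and
    cov_fn(zygosity) -> 2x2 covariance."""
    f = 0.0
    for (z, idx), st in stats_cells.items():
        sigma = cov_fn(z)[np.ix_(idx, idx)]
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return np.inf
        w = np.linalg.inv(sigma)
        nu, beta = mu_fn(z)
        nu = nu[list(idx)]
        b = beta[list(idx)]
        # sum_i (y_i - nu - b x_i)' W (y_i - nu - b x_i) expanded in moments
        q = (np.einsum("ij,ij->", w, st.syy)
             - 2 * nu @ w @ st.sy - 2 * b @ w @ st.sxy
             + 2 * (nu @ w @ b) * st.sx
             + st.n * nu @ w @ nu + st.sxx * b @ w @ b)
        f += st.n * (len(idx) * np.log(2 * np.pi) + logdet) + q
    return float(f)


def _path_components(spec: TwinModelSpec, path_vals: np.ndarray) -> dict:
    comps = {"A": 0.0, "C": 0.0, "D": 0.0, "E": 0.0}
    for name, v in zip(spec.components, path_vals):
        comps[name] = float(v ** 2)
    return comps


def _minimize(obj, x0):
    """BFGS with a Nelder-Mead fallback for the small twin likelihoods."""
    res = optimize.minimize(obj, x0, method="BFGS",
                            options={"gtol": 1e-9, "maxiter": 2000})
    if not res.success or not np.isfinite(res.fun):
        nm = optimize.minimize(obj, x0, method="Nelder-Mead",
                               options={"xatol": 1e-9, "fatol": 1e-11,
                                        "maxiter": 5000, "maxfev": 5000})
        res2 = optimize.minimize(obj, nm.x, method="BFGS",
                                 options={"gtol": 1e-9, "maxiter": 2000})
        cands = [r for r in (res, nm, res2) if np.isfinite(r.fun)]
        res = min(cands, key=lambda r: r.fun)
    return res


def fit_twin_model(spec: TwinModelSpec, pairs: pd.DataFrame,
                   n_obs_convention: str = "individuals",
                   compute_se: bool = False,
                   saturated: tuple | None = None) -> TwinModelFit:
    """Fit one variance-components model to paired phenotype scores.

    ``pairs`` must contain columns zygosity, y1, y2 and (if the spec uses the
    age covariate) age; age is centered at the sample mean of the pairs used.
    """
    pairs = pairs.copy()
    use_age = "age" in spec.covariates
    if use_age:
        pairs["age_c"] = pairs["age"] - pairs["age"].mean()
    else:
        pairs["age_c"] = 0.0
    have = ~pairs[["y1", "y2"]].isna().to_numpy()
    pairs = pairs[have.any(axis=1)]
    n_mz = int((pairs["zygosity"] == "MZ").sum())
    n_dz = int((pairs["zygosity"] == "DZ").sum())
    if n_mz < 2 or n_dz < 2:
        raise ValueError("need at least two MZ and two DZ pairs")
    cells = _group_stats(pairs, use_age)
    n_individuals = int((~pairs[["y1", "y2"]].isna()).to_numpy().sum())

    k_paths = len(spec.components)
    k = 2 + (1 if use_age else 0) + k_paths

    pooled = np.concatenate([pairs["y1"].dropna(), pairs["y2"].dropna()])
    v0 = max(float(np.var(pooled)) - np.mean(list(spec.fixed_error.values())), 0.05)
    x0 = np.concatenate([
        [float(pairs["y1"].mean(skipna=True)), float(pairs["y2"].mean(skipna=True))],
        [0.0] if use_age else [],
        np.full(k_paths, np.sqrt(v0 / k_paths))])

    def unpack(vec):
        nu = vec[:2]
        off = 2
        beta = np.zeros(2)
        if use_age:
            beta[:] = vec[2]
            off = 3
        paths = vec[off:]
        return nu, beta, paths

    def obj(vec):
        nu, beta, pathv = unpack(vec)
        pdict = dict(zip([c.lower() for c in spec.components], pathv))
        cov = {z: expected_pair_covariance(spec, pdict, z) for z in ("MZ", "DZ")}
        return _neg2ll_from_stats(cells, lambda z: (nu, beta),
                                  lambda z: cov[z])

    best = _minimize(obj, x0)
    converged = bool(np.isfinite(best.fun))
    nu, beta, pathv = unpack(best.x)
    comps = _path_components(spec, pathv)
    total = sum(comps.values())
    standardized = {f"{k2}2": v / total for k2, v in comps.items()}
    boundary = any(v < 1e-6 * total for cname, v in comps.items()
                   if cname in spec.components and cname != "E")

    minus2ll = float(best.fun)
    sat_m2ll, k_sat = saturated if saturated is not None \
        else _saturated_fit(cells, use_age)
    chi2 = max(minus2ll - sat_m2ll, 0.0)
    df = k_sat - k
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan
    n_for_bic = n_individuals if n_obs_convention == "individuals" else len(pairs)
    bic_val = bic(minus2ll, k, n_for_bic)
    h2 = heritability_from_components(standardized)

    fit = TwinModelFit(
        spec=spec,
        paths=dict(zip([c.lower() for c in spec.components], map(float, pathv))),
        components={f"{k2}2": v for k2, v in comps.items()},
        standardized=standardized,
        intercepts=(float(nu[0]), float(nu[1])),
        covariate_effects=({"age": float(beta[0])} if use_age else {}),
        minus2LL=minus2ll, n_params=k, df=df, chi2=chi2, p=p, bic=bic_val,
        h2=h2, n_obs=n_for_bic, converged=converged, boundary=boundary)
    if compute_se:
        fit.standard_errors = _numeric_se(obj, best.x, spec, use_age)
    return fit


def _numeric_se(obj, x, spec, use_age) -> dict:
    d = len(x)
    h = 1e-4
    hess = np.zeros((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h * max(1, abs(x[i]))
            ej = np.zeros(d); ej[j] = h * max(1, abs(x[j]))
            fpp = obj(x + ei + ej); fpm = obj(x + ei - ej)
            fmp = obj(x - ei + ej); fmm = obj(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * ei[i] * ej[j])
    cov = 2 * np.linalg.pinv(hess)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    names = ["nu1", "nu2"] + (["age"] if use_age else []) \
        + [c.lower() for c in spec.components]
    return dict(zip(names, se.tolist()))


def _saturated_fit(cells: dict, use_age: bool) -> tuple[float, int]:
    """Per-zygosity unstructured means/covariance (plus per-twin slopes when
    a covariate is modeled), fit numerically; returns (-2LL, param count)."""
    total = 0.0
    k = 0
    for z in ("MZ", "DZ"):
        sub = {key: st for key, st in cells.items() if key[0] == z}
        if not sub:
            continue
        kz = 5 + (2 if use_age else 0)
        k += kz

        def unpack(vec):
            nu = vec[:2]
            beta = vec[2:4] if use_age else np.zeros(2)
            off = 4 if use_age else 2
            l11, l21, l22 = vec[off], vec[off + 1], vec[off + 2]
            chol = np.array([[np.exp(l11), 0.0], [l21, np.exp(l22)]])
            return nu, beta, chol @ chol.T

        def obj(vec):
            nu, beta, sigma = unpack(vec)
            return _neg2ll_from_stats(sub, lambda _: (nu, beta),
                                      lambda _: sigma)

        # start at complete-pair moments
        comp = sub.get((z, (0, 1)))
        if comp is not None and comp.n > 1:
            mu0 = comp.sy / comp.n
            s0 = comp.syy / comp.n - np.outer(mu0, mu0)
        else:
            any_cell = next(iter(sub.values()))
            mu_val = any_cell.sy.mean() / any_cell.n
            mu0 = np.array([mu_val, mu_val])
            s0 = np.eye(2)
        s0 = s0 + 1e-6 * np.eye(2)
        chol0 = np.linalg.cholesky(s0)
        x0 = np.concatenate([mu0, [0.0, 0.0] if use_age else [],
                             [np.log(chol0[0, 0]), chol0[1, 0],
                              np.log(chol0[1, 1])]])
        total += _minimize(obj, x0).fun
    return float(total), k


def fit_model_set(pairs: pd.DataFrame, model_names=("ACE", "ADE", "AE", "CE", "E"),
                  covariates: tuple = (), fixed_error: dict | None = None,
                  phenotype_name: str = "",
                  n_obs_convention: str = "individuals") -> dict[str, TwinModelFit]:
    """Fit a family of nested models to the same pairs, computing the shared
    saturated reference only once."""
    fixed_error = fixed_error if fixed_error is not None else {1: 0.0, 2: 0.0}
    fits: dict[str, TwinModelFit] = {}
    sat = None
    for name in model_names:
        spec = TwinModelSpec(components=MODEL_SETS[name], covariates=covariates,
                             fixed_error=fixed_error,
                             phenotype_name=phenotype_name)
        fits[name] = fit_twin_model(spec, pairs, n_obs_convention,
                                    saturated=sat)
        if sat is None:
            f0 = fits[name]
            sat = (f0.minus2LL - f0.chi2, f0.df + f0.n_params)
    return fits


# ---------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------

def bic(minus2LL: float, n_free_params: int, n_obs: int) -> float:
    """Schwarz criterion -2LL + k ln(n)."""
    if n_obs < 1:
        raise ValueError("n_obs must be at least 1")
    return float(minus2LL + n_free_params * np.log(n_obs))


def heritability_from_components(standardized: dict) -> float:
    num = standardized.get("A2", 0.0) + standardized.get("D2", 0.0)
    den = num + standardized.get("C2", 0.0) + standardized.get("E2", 0.0)
    return float(num / den) if den > 0 else 0.0


def heritability(fit: TwinModelFit) -> float:
    """h2 = (A2 + D2) / (A2 + D2 + C2 + E2) on the standardized scale."""
    return heritability_from_components(fit.standardized)


def posterior_probabilities(bics: dict[str, float]) -> dict[str, float]:
    """Equal-prior BIC weights Pr(Hi|D), numerically stabilized."""
    if len(bics) < 2:
        raise ValueError("need at least two models to compare")
    names = list(bics)
    b = np.array([bics[n] for n in names], dtype=float)
    w = np.exp(-(b - b.min()) / 2.0)
    w /= w.sum()
    return dict(zip(names, w.tolist()))


def nested_chi2(fit_restricted: TwinModelFit, fit_full: TwinModelFit) -> dict:
    """Likelihood-ratio difference test between nested variance-components
    models (restricted's components must be a subset of the full's)."""
    r, f = set(fit_restricted.spec.components), set(fit_full.spec.components)
    if not r < f:
        raise ValueError(f"{fit_restricted.spec.name} is not nested in "
                         f"{fit_full.spec.name}")
    d = fit_restricted.minus2LL - fit_full.minus2LL
    if d < -1e-6:
        raise ValueError("restricted model has higher likelihood; "
                         "check convergence")
    d = max(d, 0.0)
    ddf = fit_full.n_params - fit_restricted.n_params
    return {"delta_chi2": d, "delta_df": ddf,
            "delta_p": float(stats.chi2.sf(d, ddf))}


@dataclass
class ModelComparison:
    fits: dict[str, TwinModelFit]
    posterior: dict[str, float]
    pairwise_posteriors: dict = field(default_factory=dict)
    nested_tests: dict = field(default_factory=dict)
    preferred: tuple = ()

    def table(self) -> pd.DataFrame:
        rows = []
        for name, fit in self.fits.items():
            row = fit.summary_row()
            row["posterior"] = self.posterior[name]
            rows.append(row)
        return pd.DataFrame(rows)


def compare_models(fits: dict[str, TwinModelFit],
                   preference_margin: float = 0.05) -> ModelComparison:
    post = posterior_probabilities({n: f.bic for n, f in fits.items()})
    pairwise = {}
    for m1, m2 in combinations(fits, 2):
        pairwise[(m1, m2)] = posterior_probabilities(
            {m1: fits[m1].bic, m2: fits[m2].bic})
    nested = {}
    for m1, m2 in combinations(fits, 2):
        r, f = sorted((m1, m2), key=lambda n: fits[n].n_params)
        if set(fits[r].spec.components) < set(fits[f].spec.components):
            try:
                nested[(r, f)] = nested_chi2(fits[r], fits[f])
            except ValueError:
                pass
    ranked = sorted(post, key=post.get, reverse=True)
    top = ranked[0]
    preferred = tuple(n for n in ranked
                      if post[top] - post[n] <= preference_margin)
    return ModelComparison(fits=fits, posterior=post,
                           pairwise_posteriors=pairwise,
                           nested_tests=nested, preferred=preferred)


def paired_phenotype(data: pd.DataFrame, scores: pd.DataFrame,
                     factor: str) -> pd.DataFrame:
    """Wide pair table (zygosity, age, y1, y2) for one phenotype.

    Only complete pairs (both co-twins present in the dataset) are retained;
    a member whose score was recoded missing still leaves its pair in, with
    the pair contributing through the remaining member.
    """
    df = data[["pair_id", "twin", "zygosity", "age"]].copy()
    df["score"] = scores[factor].to_numpy()
    counts = df.groupby("pair_id")["twin"].nunique()
    full_pairs = counts[counts == 2].index
    df = df[df["pair_id"].isin(full_pairs)]
    wide = df.pivot_table(index="pair_id", columns="twin", values="score",
                          dropna=False)
    meta = df.drop_duplicates("pair_id").set_index("pair_id")
    out = pd.DataFrame({"zygosity": meta["zygosity"], "age": meta["age"],
                        "y1": wide.get(1), "y2": wide.get(2)})
    return out.reset_index()
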