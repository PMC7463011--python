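"""Low-level structural-equation engine: FIML likelihood, gradients, optimization.

Implements the confirmatory-factor measurement model

    y = nu + Lambda eta + eps,   eta ~ N(alpha, Phi),  eps ~ N(0, Theta)

so that the implied moments are mu = nu + Lambda alpha and
Sigma = Lambda Phi Lambda' + Theta.  Estimation is full-information maximum
likelihood (FIML): the casewise multivariate-normal log-likelihood is summed
over missingness patterns, each pattern contributing through its own
sufficient statistics (count, mean, scatter), which makes the cost of one
likelihood evaluation independent of the number of rows.  Variance parameters
are log-transformed during optimization to enforce positivity; analytic
gradients are propagated through the chain rule.

Multiple groups are supported through a flat parameter table in which free
parameters carrying the same label share a single optimization coordinate
(cross-group equality constraints for invariance testing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

LOG2PI = float(np.log(2.0 * np.pi))

# matrices recognised in the parameter table
_MATS = ("lam", "nu", "theta", "phi", "alpha")
_SYMMETRIC = {"theta", "phi"}


@dataclass
class Param:
    """One cell of one model matrix in one group.

    ``label`` ties free parameters together across cells/groups (equality
    constraint); ``positive`` marks variances that are log-transformed in the
    optimization vector.
    """

    group: int
    mat: str
    i: int
    j: int
    free: bool
    value: float
    label: str | None = None
    positive: bool = False

    def default_label(self) -> str:
        return f"g{self.group}.{self.mat}[{self.i},{self.j}]"


@dataclass
class PatternStats:
    """Sufficient statistics of one missingness pattern."""

    idx: np.ndarray  # observed column indices
    n: int
    mean: np.ndarray
    scatter: np.ndarray  # ML (divide-by-n) covariance of the pattern's rows


def pattern_stats(y: np.ndarray) -> list[PatternStats]:
    """Group rows of ``y`` (NaN = missing) by missingness pattern.

    Rows with no observed entries are dropped.
    """
    y = np.asarray(y, dtype=float)
    obs = ~np.isnan(y)
    keep = obs.any(axis=1)
    y, obs = y[keep], obs[keep]
    out: list[PatternStats] = []
    codes = [o.tobytes() for o in obs]  # pattern key per row
    order: dict[bytes, list[int]] = {}
    for r, c in enumerate(codes):
        order.setdefault(c, []).append(r)
    for rows in order.values():
        rows_a = np.asarray(rows)
        idx = np.where(obs[rows_a[0]])[0]
        block = y[np.ix_(rows_a, idx)]
        n = block.shape[0]
        mean = block.mean(axis=0)
        d = block - mean
        out.append(PatternStats(idx=idx, n=n, mean=mean, scatter=d.T @ d / n))
    return out


def _pattern_neg2ll(mu: np.ndarray, sigma: np.ndarray,
                    pats: Sequence[PatternStats]) -> float:
    f = 0.0
    for pk in pats:
        o = pk.idx
        s_oo = sigma[np.ix_(o, o)]
        sign, logdet = np.linalg.slogdet(s_oo)
        if sign <= 0:
            return np.inf
        w = np.linalg.inv(s_oo)
        d = pk.mean - mu[o]
        f += pk.n * (len(o) * LOG2PI + logdet
                     + float(np.trace(w @ pk.scatter)) + float(d @ w @ d))
    return f


def _pattern_neg2ll_grad(mu: np.ndarray, sigma: np.ndarray,
                         pats: Sequence[PatternStats]):
    """Value plus full-matrix derivatives of -2LL w.r.t. Sigma and mu."""
    p = len(mu)
    g_sigma = np.zeros((p, p))
    g_mu = np.zeros(p)
    f = 0.0
    for pk in pats:
        o = pk.idx
        s_oo = sigma[np.ix_(o, o)]
        sign, logdet = np.linalg.slogdet(s_oo)
        if sign <= 0:
            return np.inf, g_sigma, g_mu
        w = np.linalg.inv(s_oo)
        d = pk.mean - mu[o]
        m = pk.scatter + np.outer(d, d)
        f += pk.n * (len(o) * LOG2PI + logdet
                     + float(np.trace(w @ (pk.scatter))) + float(d @ w @ d))
        g_sigma[np.ix_(o, o)] += pk.n * (w - w @ m @ w)
        g_mu[o] += -2.0 * pk.n * (w @ d)
    return f, g_sigma, g_mu


class SemModel:
    """A (possibly multi-group) factor model bound to data, ready to fit."""

    def __init__(self, params: Sequence[Param], data_by_group: Sequence[np.ndarray],
                 n_factors: int):
        self.params = list(params)
        self.n_groups = len(data_by_group)
        self.p = data_by_group[0].shape[1]
        self.m = n_factors
        self.pats = [pattern_stats(y) for y in data_by_group]
        self.n_obs = [int(sum(pk.n for pk in g)) for g in self.pats]
        # map labels -> x coordinates
        labels: dict[str, int] = {}
        self.x_index: list[int] = []
        self.x_start: list[float] = []
        self.x_positive: list[bool] = []
        for pr in self.params:
            if pr.mat not in _MATS:
                raise ValueError(f"unknown matrix {pr.mat!r}")
            if not pr.free:
                self.x_index.append(-1)
                continue
            lab = pr.label or pr.default_label()
            if lab not in labels:
                labels[lab] = len(self.x_start)
                self.x_start.append(pr.value)
                self.x_positive.append(pr.positive)
            self.x_index.append(labels[lab])
        self.labels = labels
        self.n_free = len(self.x_start)

    # -- parameter vector handling ------------------------------------
    def start_vector(self) -> np.ndarray:
        v = np.asarray(self.x_start, dtype=float)
        return self._to_transformed(v)

    def _to_transformed(self, natural: np.ndarray) -> np.ndarray:
        x = np.array(natural, dtype=float)
        pos = np.asarray(self.x_positive)
        x[pos] = np.log(np.maximum(x[pos], 1e-10))
        return x

    def _to_natural(self, x: np.ndarray) -> np.ndarray:
        v = np.array(x, dtype=float)
        pos = np.asarray(self.x_positive)
        v[pos] = np.exp(np.clip(v[pos], -40.0, 40.0))
        return v

    def matrices(self, natural: np.ndarray):
        """Return per-group (Lambda, nu, Theta, Phi, alpha)."""
        p, m = self.p, self.m
        out = []
        for _ in range(self.n_groups):
            out.append([np.zeros((p, m)), np.zeros(p), np.zeros((p, p)),
                        np.zeros((m, m)), np.zeros(m)])
        mat_pos = {"lam": 0, "nu": 1, "theta": 2, "phi": 3, "alpha": 4}
        for pr, xi in zip(self.params, self.x_index):
            val = natural[xi] if pr.free else pr.value
            tgt = out[pr.group][mat_pos[pr.mat]]
            if pr.mat in ("nu", "alpha"):
                tgt[pr.i] = val
            else:
                tgt[pr.i, pr.j] = val
                if pr.mat in _SYMMETRIC and pr.i != pr.j:
                    tgt[pr.j, pr.i] = val
        return [tuple(g) for g in out]

    def implied_moments(self, natural: np.ndarray):
        res = []
        for lam, nu, theta, phi, alpha in self.matrices(natural):
            res.append((nu + lam @ alpha, lam @ phi @ lam.T + theta))
        return res

    # -- likelihood ----------------------------------------------------
    def neg2ll_natural(self, natural: np.ndarray) -> float:
        f = 0.0
        for g, (mu, sigma) in enumerate(self.implied_moments(natural)):
            f += _pattern_neg2ll(mu, sigma, self.pats[g])
            if not np.isfinite(f):
                return np.inf
        return f

    def neg2ll_grad_natural(self, natural: np.ndarray):
        """(-2LL, gradient w.r.t. the natural free-parameter vector)."""
        grad = np.zeros(self.n_free)
        mats = self.matrices(natural)
        f = 0.0
        per_group = []
        for g, (lam, nu, theta, phi, alpha) in enumerate(mats):
            mu = nu + lam @ alpha
            sigma = lam @ phi @ lam.T + theta
            fg, g_sigma, g_mu = _pattern_neg2ll_grad(mu, sigma, self.pats[g])
            if not np.isfinite(fg):
                return np.inf, grad
            f += fg
            g_lam = 2.0 * g_sigma @ lam @ phi + np.outer(g_mu, alpha)
            g_phi = lam.T @ g_sigma @ lam
            g_alpha = lam.T @ g_mu
            per_group.append({"lam": g_lam, "nu": g_mu, "theta": g_sigma,
                              "phi": g_phi, "alpha": g_alpha})
        for pr, xi in zip(self.params, self.x_index):
            if not pr.free:
                continue
            gm = per_group[pr.group][pr.mat]
            if pr.mat in ("nu", "alpha"):
                contrib = gm[pr.i]
            elif pr.mat in _SYMMETRIC and pr.i != pr.j:
                contrib = gm[pr.i, pr.j] + gm[pr.j, pr.i]
            else:
                contrib = gm[pr.i, pr.j]
            grad[xi] += contrib
        return f, grad

    def _objective(self, x: np.ndarray):
        natural = self._to_natural(x)
        f, g_nat = self.neg2ll_grad_natural(natural)
        if not np.isfinite(f):
            return 1e12, np.zeros_like(x)
        # chain rule through the log transform
        g = np.array(g_nat)
        pos = np.asarray(self.x_positive)
        g[pos] *= natural[pos]
        return f, g

    def fit(self, max_restarts: int = 50, gtol: float = 1e-6,
            seed: int = 0, x0: np.ndarray | None = None):
        """Minimize -2LL; returns (natural params, -2LL, converged flag)."""
        rng = np.random.default_rng(seed)
        x = self.start_vector() if x0 is None else self._to_transformed(x0)
        best = None
        for attempt in range(max_restarts + 1):
            res = optimize.minimize(self._objective, x, jac=True,
                                    method="L-BFGS-B",
                                    options={"maxiter": 5000, "ftol": 1e-14,
                                             "gtol": 1e-10})
            xr, fr, gnorm = self._newton_polish(res.x, gtol)
            cand = (fr, gnorm, xr)
            if best is None or cand[0] < best[0]:
                best = cand
            if best[1] < gtol:
                break
            x = self.start_vector() + rng.normal(scale=0.2 + 0.1 * attempt,
                                                 size=self.n_free)
        fval, gnorm, xbest = best
        return self._to_natural(xbest), float(fval), bool(gnorm < gtol)

    def _newton_polish(self, x, gtol, max_iter: int = 15):
        """Drive the gradient max-norm below ``gtol`` with damped Newton steps
        on the transformed scale (L-BFGS-B stops earlier than we require)."""
        x = np.array(x, dtype=float)
        f, g = self._objective(x)
        for _ in range(max_iter):
            gnorm = float(np.max(np.abs(g)))
            if gnorm < gtol * 0.1 or not np.isfinite(f):
                break
            hess = self.hessian_transformed(x)
            # regularize if not positive definite
            w = np.linalg.eigvalsh(hess)
            if w[0] <= 1e-10:
                hess = hess + (1e-8 + abs(w[0]) * 2) * np.eye(len(x))
            step = np.linalg.solve(hess, g)
            t = 1.0
            improved = False
            for _ls in range(30):
                f2, g2 = self._objective(x - t * step)
                if np.isfinite(f2) and f2 <= f + 1e-12 * abs(f):
                    x, f, g = x - t * step, f2, g2
                    improved = True
                    break
                t *= 0.5
            if not improved:
                break
        return x, f, float(np.max(np.abs(g)))

    # -- inference helpers --------------------------------------------
    def hessian_natural(self, natural: np.ndarray, h: float = 1e-5) -> np.ndarray:
        """Central finite differences of the analytic gradient of -2LL."""
        d = self.n_free
        hess = np.zeros((d, d))
        for k in range(d):
            step = h * max(1.0, abs(natural[k]))
            vp = np.array(natural); vp[k] += step
            vm = np.array(natural); vm[k] -= step
            _, gp = self.neg2ll_grad_natural(vp)
            _, gm = self.neg2ll_grad_natural(vm)
            hess[k] = (gp - gm) / (2 * step)
        return (hess + hess.T) / 2

    def standard_errors(self, natural: np.ndarray) -> np.ndarray:
        """SEs from the observed information (Hessian of -2LL is 2*info)."""
        hess = self.hessian_natural(natural)
        cov = 2.0 * np.linalg.pinv(hess)
        var = np.diag(cov).copy()
        var[var < 0] = np.nan
        return np.sqrt(var)

    def score_test(self, natural_aug: np.ndarray) -> float:
        """Modification index: score statistic 0.5 * g' H^{-1} g of -2LL.

        Evaluate on an *augmented* model at the restricted optimum (new free
        parameters set to their constrained values); the gradient is nonzero
        only in the released directions.
        """
        x = self._to_transformed(natural_aug)
        nat = self._to_natural(x)
        _, g_nat = self.neg2ll_grad_natural(nat)
        g = np.array(g_nat)
        pos = np.asarray(self.x_positive)
        g[pos] *= nat[pos]
        hess = self.hessian_transformed(x)
        mi = 0.5 * float(g @ np.linalg.pinv(hess) @ g)
        return max(mi, 0.0)

    def hessian_transformed(self, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
        d = self.n_free
        hess = np.zeros((d, d))
        for k in range(d):
            step = h * max(1.0, abs(x[k]))
            xp = np.array(x); xp[k] += step
            xm = np.array(x); xm[k] -= step
            _, gp = self._objective(xp)
            _, gm = self._objective(xm)
            hess[k] = (gp - gm) / (2 * step)
        return (hess + hess.T) / 2


# ---------------------------------------------------------------------
# Unstructured (saturated) and independence reference models
# ---------------------------------------------------------------------

def mvn_fiml_mle(y: np.ndarray, tol: float = 1e-10, max_iter: int = 1000):
    """ML mean and covariance of a MVN sample with missing values, by EM.

    Returns (mu, sigma, loglik).  For complete data this is the closed-form
    sample mean and divide-by-n covariance in one pass.
    """
    y = np.asarray(y, dtype=float)
    obs = ~np.isnan(y)
    keep = obs.any(axis=1)
    y = y[keep]
    n, p = y.shape
    pats = pattern_stats(y)
    if len(pats) == 1 and len(pats[0].idx) == p:
        mu = pats[0].mean
        sigma = pats[0].scatter
        ll = -0.5 * _pattern_neg2ll(mu, sigma, pats)
        return mu, sigma, ll
    # EM start: available-case means/variances, zero covariances
    mu = np.array([np.nanmean(y[:, j]) if obs[:, j].any() else 0.0
                   for j in range(p)])
    var = np.array([max(np.nanvar(y[:, j]), 1e-6) for j in range(p)])
    sigma = np.diag(var)
    last = -np.inf
    for _ in range(max_iter):
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        for pk in pats:
            o = pk.idx
            miss = np.setdiff1d(np.arange(p), o)
            w = np.linalg.inv(sigma[np.ix_(o, o)])
            b = sigma[np.ix_(miss, o)] @ w  # regression of missing on observed
            d = pk.mean - mu[o]
            em = mu[miss] + b @ d  # conditional mean at pattern mean
            c_mm = sigma[np.ix_(miss, miss)] - b @ sigma[np.ix_(o, miss)]
            # per-pattern expected sums (moments around pattern stats)
            s1_o = pk.n * pk.mean
            s1_m = pk.n * em
            s1[o] += s1_o
            s1[miss] += s1_m
            # E[y y'] summed over the pattern's rows
            e_oo = pk.n * (pk.scatter + np.outer(pk.mean, pk.mean))
            cross = pk.scatter @ b.T  # cov(y_o, y_m) within pattern
            e_om = pk.n * (cross + np.outer(pk.mean, em))
            e_mm = pk.n * (c_mm + b @ pk.scatter @ b.T + np.outer(em, em))
            s2[np.ix_(o, o)] += e_oo
            s2[np.ix_(o, miss)] += e_om
            s2[np.ix_(miss, o)] += e_om.T
            s2[np.ix_(miss, miss)] += e_mm
        mu = s1 / n
        sigma = s2 / n - np.outer(mu, mu)
        sigma = (sigma + sigma.T) / 2
        ll = -0.5 * _pattern_neg2ll(mu, sigma, pats)
        if abs(ll - last) < tol * (1 + abs(ll)):
            last = ll
            break
        last = ll
    return mu, sigma, last


def saturated_loglik(y: np.ndarray) -> float:
    return float(mvn_fiml_mle(y)[2])


def independence_loglik(y: np.ndarray) -> float:
    """FIML log-likelihood of the independence model (free means/variances,
    zero covariances): separates into univariate normal likelihoods."""
    y = np.asarray(y, dtype=float)
    ll = 0.0
    for j in range(y.shape[1]):
        col = y[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        v = max(float(np.var(col)), 1e-12)
        ll += -0.5 * col.size * (LOG2PI + np.log(v) + 1.0)
    return ll
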