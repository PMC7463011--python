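"""Regression-method factor scores, determinacy, fixed error variances, outliers.

Scores are the conditional expectation of the latent factors given the
observed indicators under the fitted model,

    eta_hat = alpha + Phi Lambda' Sigma^{-1} (y - mu),

computed with pattern-specific submatrices for rows with missing indicators.
The determinacy rho of each factor is the model-implied correlation between
the estimated and the true factor; downstream single-indicator twin models
fix the measurement-error variance of the scores per twin subsample as
theta_delta = (1 - rho) * sigma^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cfa import FittedFactorModel


@dataclass
class FactorScoreSet:
    scores: pd.DataFrame                       # rows aligned with the input
    determinacy: dict[str, float]
    subsample_variances: dict[str, dict] = field(default_factory=dict)
    fixed_error_variances: dict[str, dict] = field(default_factory=dict)
    outlier_flags: pd.DataFrame | None = None
    score_correlations: pd.DataFrame | None = None

    def n_outliers(self) -> int:
        return 0 if self.outlier_flags is None else int(self.outlier_flags.to_numpy().sum())


def determinacies(model: FittedFactorModel) -> dict[str, float]:
    """rho per factor: sqrt of diag(Phi Lam' Sigma^-1 Lam Phi) / Phi."""
    sig_inv = np.linalg.inv(model.implied_cov)
    cov_est = model.phi @ model.lam.T @ sig_inv @ model.lam @ model.phi
    rho = np.sqrt(np.clip(np.diag(cov_est) / np.diag(model.phi), 0.0, 1.0))
    return dict(zip(model.spec.factors, rho.tolist()))


def regression_scores(model: FittedFactorModel,
                      data: pd.DataFrame) -> FactorScoreSet:
    """Score every row; rows with all indicators missing get missing scores."""
    if not model.admissible:
        raise ValueError("factor scores require a converged, admissible model")
    ind = model.spec.indicators
    y = data.loc[:, ind].to_numpy(dtype=float)
    n = y.shape[0]
    m = len(model.spec.factors)
    scores = np.full((n, m), np.nan)
    obs_mask = ~np.isnan(y)
    patterns = {}
    for r in range(n):
        patterns.setdefault(obs_mask[r].tobytes(), []).append(r)
    for key, rows in patterns.items():
        o = np.where(np.frombuffer(key, dtype=bool))[0]
        if o.size == 0:
            continue
        sig_oo = model.implied_cov[np.ix_(o, o)]
        w = np.linalg.inv(sig_oo)
        coef = model.phi @ model.lam[o].T @ w
        d = y[np.ix_(rows, o)] - model.implied_mean[o]
        scores[rows] = model.alpha + d @ coef.T
    frame = pd.DataFrame(scores, columns=model.spec.factors, index=data.index)
    rho = determinacies(model)
    valid = frame.dropna()
    corr = valid.corr() if len(valid) > 2 else None
    return FactorScoreSet(scores=frame, determinacy=rho,
                          score_correlations=corr)


def fixed_error_variance(rho: float, sigma2: float) -> float:
    """theta_delta = (1 - rho) * sigma^2 for a single-indicator latent
    variable measured by a factor score of determinacy rho."""
    if not 0 <= rho <= 1:
        raise ValueError("determinacy must lie in [0, 1]")
    if sigma2 < 0:
        raise ValueError("variance must be non-negative")
    return (1.0 - rho) * sigma2


def fixed_error_variance_squared(rho: float, sigma2: float) -> float:
    """Alternative convention (1 - rho^2) * sigma^2 using the squared
    determinacy (the proportion of factor variance the scores reproduce)."""
    if not 0 <= rho <= 1:
        raise ValueError("determinacy must lie in [0, 1]")
    if sigma2 < 0:
        raise ValueError("variance must be non-negative")
    return (1.0 - rho ** 2) * sigma2


def subsample_error_variances(score_set: FactorScoreSet,
                              subsample: pd.Series,
                              convention: str = "rho") -> FactorScoreSet:
    """Per factor x twin-subsample variance and fixed error variance.

    ``convention`` selects (1-rho)*sigma^2 ("rho", as printed in the study
    this pipeline mirrors) or (1-rho^2)*sigma^2 ("rho_squared").
    """
    fn = {"rho": fixed_error_variance,
          "rho_squared": fixed_error_variance_squared}[convention]
    variances: dict[str, dict] = {}
    theta: dict[str, dict] = {}
    for f in score_set.scores.columns:
        variances[f] = {}
        theta[f] = {}
        for sub in sorted(pd.unique(subsample).tolist()):
            vals = score_set.scores.loc[subsample == sub, f].dropna()
            s2 = float(np.var(vals, ddof=1)) if len(vals) > 1 else np.nan
            variances[f][sub] = s2
            theta[f][sub] = fn(score_set.determinacy[f], s2) if np.isfinite(s2) else np.nan
    score_set.subsample_variances = variances
    score_set.fixed_error_variances = theta
    return score_set


def screen_outliers(score_set: FactorScoreSet, subsample: pd.Series,
                    z_threshold: float = 3.29) -> FactorScoreSet:
    """Standardize scores per factor x subsample and recode |z| > threshold
    as missing; flags recorded, unflagged values untouched."""
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    scores = score_set.scores.copy()
    flags = pd.DataFrame(False, index=scores.index, columns=scores.columns)
    for f in scores.columns:
        for sub in sorted(pd.unique(subsample).tolist()):
            sel = (subsample == sub) & scores[f].notna()
            vals = scores.loc[sel, f]
            sd = vals.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                continue
            z = (vals - vals.mean()) / sd
            bad = z.index[np.abs(z) > z_threshold]
            flags.loc[bad, f] = True
            scores.loc[bad, f] = np.nan
    return FactorScoreSet(scores=scores, determinacy=dict(score_set.determinacy),
                          subsample_variances=dict(score_set.subsample_variances),
                          fixed_error_variances=dict(score_set.fixed_error_variances),
                          outlier_flags=flags,
                          score_correlations=score_set.score_correlations)
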