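"""Variance-components models: biometric expectations, ML fits, comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinpheno import (SimulationConfig, TwinModelSpec, bic, compare_models,
                       expected_pair_covariance, fit_model_set,
                       fit_twin_model, heritability, nested_chi2,
                       posterior_probabilities)
from twinpheno.twin import heritability_from_components

from conftest import latent_pair_table

# Printed desk-scale inputs used across the comparison tests: BIC values of
# the nested model families for the three phenotypes.
BICS_GENERAL = {"ACE": 906.714, "AE": 903.973, "CE": 901.560, "E": 915.739}
BICS_IMPULSIVITY = {"ACE": 878.972, "AE": 873.819, "ADE": 877.494,
                    "CE": 876.987, "E": 876.884}
BICS_OBSESSIVENESS = {"ACE": 840.752, "AE": 835.777, "CE": 835.621,
                      "E": 836.663}


def pair_table(a2, c2, e2, n_mz, n_dz, seed, phenotype="impulsivity"):
    cfg = SimulationConfig(
        n_mz_pairs=n_mz, n_dz_pairs=n_dz, n_singletons=0,
        missing_rate=0.0, outlier_rate=0.0, age_effect_general=0.0,
        variance_shares={"general": (a2, c2, e2),
                         "impulsivity": (a2, c2, e2),
                         "obsessiveness": (a2, c2, e2)},
        seed=seed)
    return latent_pair_table(cfg, phenotype)


# ------------------------------------------------------- expectations

def test_expected_pair_covariance_definitional_cases():
    spec = TwinModelSpec(components=("A", "E"))
    mz = expected_pair_covariance(spec, {"a": 1.0, "e": 0.0}, "MZ")
    dz = expected_pair_covariance(spec, {"a": 1.0, "e": 0.0}, "DZ")
    assert mz[0, 1] == pytest.approx(1.0)
    assert dz[0, 1] == pytest.approx(0.5)
    ce = expected_pair_covariance(TwinModelSpec(components=("C", "E")),
                                  {"c": 0.6, "e": 0.8}, "DZ")
    assert ce[0, 1] == pytest.approx(0.36)
    ce_mz = expected_pair_covariance(TwinModelSpec(components=("C", "E")),
                                     {"c": 0.6, "e": 0.8}, "MZ")
    assert ce_mz[0, 1] == pytest.approx(0.36)
    ade = expected_pair_covariance(
        TwinModelSpec(components=("A", "D", "E")),
        {"a": np.sqrt(0.4), "d": np.sqrt(0.2), "e": np.sqrt(0.4)}, "DZ")
    assert ade[0, 1] == pytest.approx(0.5 * 0.4 + 0.25 * 0.2)
    assert ade[0, 0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        expected_pair_covariance(spec, {"a": 1.0}, "OS")


def test_fixed_error_enters_diagonal_only():
    spec = TwinModelSpec(components=("A", "E"),
                         fixed_error={1: 0.1, 2: 0.2})
    m = expected_pair_covariance(spec, {"a": 0.7, "e": 0.5}, "MZ")
    lat = 0.49 + 0.25
    assert m[0, 0] == pytest.approx(lat + 0.1)
    assert m[1, 1] == pytest.approx(lat + 0.2)
    assert m[0, 1] == pytest.approx(0.49)


def test_spec_validation():
    with pytest.raises(ValueError):
        TwinModelSpec(components=("A", "C"))       # no E
    with pytest.raises(ValueError):
        TwinModelSpec(components=("A", "C", "D", "E"))  # C and D together
    with pytest.raises(ValueError):
        TwinModelSpec(components=("A", "E"), fixed_error={1: -0.1, 2: 0.0})


# ------------------------------------------------------- fitting

def test_ae_parameter_recovery():
    pairs = pair_table(0.5, 0.0, 0.5, n_mz=2000, n_dz=1000, seed=101)
    fit = fit_twin_model(TwinModelSpec(components=("A", "E")), pairs)
    assert fit.converged
    assert fit.standardized["A2"] == pytest.approx(0.5, abs=0.05)
    assert fit.standardized["A2"] + fit.standardized["E2"] == pytest.approx(1, abs=1e-8)


def test_saturated_reference_matches_closed_form_moments():
    """For complete balanced data the two-group saturated ML solution equals
    the per-group sample means and divide-by-n covariances."""
    pairs = pair_table(0.4, 0.2, 0.4, n_mz=300, n_dz=300, seed=55)
    fit = fit_twin_model(TwinModelSpec(components=("A", "C", "E")), pairs)
    sat_m2ll = fit.minus2LL - fit.chi2
    direct = 0.0
    for z in ("MZ", "DZ"):
        y = pairs.loc[pairs.zygosity == z, ["y1", "y2"]].to_numpy()
        mu = y.mean(axis=0)
        s = np.cov(y.T, bias=True)
        n = len(y)
        direct += n * (2 * np.log(2 * np.pi) + np.linalg.slogdet(s)[1] + 2)
    assert sat_m2ll == pytest.approx(direct, abs=1e-6)
    assert fit.df == 10 - fit.n_params


def test_ce_consistent_point_reproduces_common_correlation():
    """When MZ and DZ cross-twin covariances agree, the CE model absorbs the
    common covariance as C^2 and fits the saturated moments closely."""
    pairs = pair_table(0.0, 0.36, 0.64, n_mz=4000, n_dz=4000, seed=66)
    fit = fit_twin_model(TwinModelSpec(components=("C", "E")), pairs)
    assert fit.standardized["C2"] == pytest.approx(0.36, abs=0.03)
    assert fit.chi2 < stats.chi2.ppf(0.999, fit.df)


def test_e_model_reduces_to_pooled_variance():
    pairs = pair_table(0.0, 0.0, 1.0, n_mz=500, n_dz=500, seed=77)
    fit = fit_twin_model(TwinModelSpec(components=("E",)), pairs)
    pooled = np.concatenate([pairs.y1.dropna(), pairs.y2.dropna()])
    # ML variance of pooled scores around the two intercepts
    assert fit.components["E2"] == pytest.approx(np.var(pooled), rel=0.02)
    mz = expected_pair_covariance(fit.spec,
                                  {k: v for k, v in fit.paths.items()}, "MZ")
    assert mz[0, 1] == 0.0


def test_age_covariate_recovers_generating_slope():
    cfg = SimulationConfig(n_mz_pairs=3000, n_dz_pairs=1500, n_singletons=0,
                           missing_rate=0.0, outlier_rate=0.0,
                           age_effect_general=-0.02, seed=88)
    pairs = latent_pair_table(cfg, "general")
    fit = fit_twin_model(TwinModelSpec(components=("C", "E"),
                                       covariates=("age",)), pairs)
    assert fit.covariate_effects["age"] == pytest.approx(-0.02, abs=0.005)


def test_fiml_uses_pairs_with_one_missing_member():
    pairs = pair_table(0.5, 0.0, 0.5, n_mz=1500, n_dz=800, seed=91)
    pairs.loc[pairs.index[:200], "y2"] = np.nan
    fit = fit_twin_model(TwinModelSpec(components=("A", "E")), pairs)
    assert fit.converged
    assert fit.standardized["A2"] == pytest.approx(0.5, abs=0.06)
    assert fit.n_obs == int((~pairs[["y1", "y2"]].isna()).to_numpy().sum())


# ------------------------------------------------------- heritability / BIC

def test_heritability_formula_cases():
    assert heritability_from_components(
        {"A2": 0.33, "E2": 0.67}) == pytest.approx(0.33)
    assert heritability_from_components(
        {"C2": 0.36, "E2": 0.64}) == pytest.approx(0.0)
    assert heritability_from_components(
        {"A2": 0.3, "D2": 0.2, "C2": 0.0, "E2": 0.5}) == pytest.approx(0.5)


def test_bic_arithmetic_and_shift_invariance():
    assert bic(0.0, 0, 10) == 0.0
    assert bic(100.0, 3, 100) == pytest.approx(113.8155105580, abs=1e-6)
    d0 = bic(100.0, 3, 50) - bic(120.0, 4, 50)
    d1 = bic(100.0 + 7.3, 3, 50) - bic(120.0 + 7.3, 4, 50)
    assert d0 == pytest.approx(d1, abs=1e-12)
    with pytest.raises(ValueError):
        bic(10.0, 1, 0)


# ------------------------------------------------------- comparison

def test_posterior_probabilities_from_printed_bic_tables():
    post = posterior_probabilities(BICS_IMPULSIVITY)
    expect = {"ACE": 0.046, "AE": 0.604, "ADE": 0.096, "CE": 0.124,
              "E": 0.130}
    for k, v in expect.items():
        assert post[k] == pytest.approx(v, abs=5e-4)
    assert sum(post.values()) == pytest.approx(1.0, abs=1e-10)


def test_pairwise_posterior_renormalizes_two_models():
    post = posterior_probabilities({"AE": 835.777, "CE": 835.621})
    assert post["AE"] == pytest.approx(0.481, abs=5e-4)
    assert post["CE"] == pytest.approx(0.519, abs=5e-4)


def test_posterior_symmetry_and_order_invariance():
    assert posterior_probabilities({"m1": 10.0, "m2": 10.0}) == \
        {"m1": 0.5, "m2": 0.5}
    a = posterior_probabilities(BICS_GENERAL)
    b = posterior_probabilities(dict(reversed(list(BICS_GENERAL.items()))))
    for k in a:
        assert a[k] == pytest.approx(b[k], abs=1e-14)
    with pytest.raises(ValueError):
        posterior_probabilities({"only": 1.0})


def test_nested_chi2_requires_nesting_and_handles_ties():
    pairs = pair_table(0.3, 0.2, 0.5, n_mz=400, n_dz=200, seed=30)
    fits = fit_model_set(pairs, ("ACE", "AE", "CE", "E"))
    d = nested_chi2(fits["AE"], fits["ACE"])
    assert d["delta_df"] == 1
    assert d["delta_chi2"] >= 0
    assert d["delta_p"] == pytest.approx(
        stats.chi2.sf(d["delta_chi2"], 1), abs=1e-12)
    with pytest.raises(ValueError):
        nested_chi2(fits["AE"], fits["CE"])   # not nested
    same = nested_chi2(fits["AE"], fits["ACE"])
    assert 0 <= same["delta_p"] <= 1


def test_nested_test_type_i_rate_for_e_true_data():
    """AE vs E on E-true data: with a^2 on the boundary the nominal-alpha
    rejection rate is conservative (at most ~alpha, mixture null)."""
    rejections = 0
    n_rep = 200
    rng = np.random.default_rng(9)
    for _ in range(n_rep):
        pairs = pair_table(0.0, 0.0, 1.0, n_mz=150, n_dz=80,
                           seed=int(rng.integers(2**31)))
        fits = fit_model_set(pairs, ("AE", "E"))
        d = nested_chi2(fits["E"], fits["AE"])
        if d["delta_p"] < 0.05:
            rejections += 1
    rate = rejections / n_rep
    assert rate <= 0.08  # boundary-adjusted: expected ~ alpha/2


def test_compare_models_preference_rule():
    comp_fits = {}
    pairs = pair_table(0.5, 0.0, 0.5, n_mz=1000, n_dz=500, seed=300)
    comp_fits = fit_model_set(pairs, ("ACE", "AE", "CE", "E"))
    comp = compare_models(comp_fits)
    assert sum(comp.posterior.values()) == pytest.approx(1.0, abs=1e-10)
    assert comp.preferred[0] == max(comp.posterior, key=comp.posterior.get)
    pair = comp.pairwise_posteriors[("AE", "CE")]
    direct = posterior_probabilities({"AE": comp_fits["AE"].bic,
                                      "CE": comp_fits["CE"].bic})
    assert pair == direct


def test_falconer_agrees_with_ml_at_scale():
    """ACE maximum likelihood vs Falconer's 2(rMZ - rDZ) on the same large
    sample of latent phenotype pairs."""
    pairs = pair_table(0.4, 0.2, 0.4, n_mz=50_000, n_dz=50_000, seed=500)
    fit = fit_twin_model(TwinModelSpec(components=("A", "C", "E")), pairs)
    mz = pairs[pairs.zygosity == "MZ"]
    dz = pairs[pairs.zygosity == "DZ"]
    r_mz = np.corrcoef(mz.y1, mz.y2)[0, 1]
    r_dz = np.corrcoef(dz.y1, dz.y2)[0, 1]
    falconer = 2 * (r_mz - r_dz)
    assert fit.standardized["A2"] == pytest.approx(falconer, abs=0.01)
    assert fit.standardized["A2"] == pytest.approx(0.4, abs=0.03)


def test_dz_share_controls_ae_ce_discrimination():
    """Mean posterior of the true AE model falls as the DZ share shrinks at
    fixed total pair count (power to separate A from C weakens)."""
    total = 172   # paper-scale pair count, where discrimination is not saturated
    mean_post = []
    rng = np.random.default_rng(11)
    for dz_share in (0.5, 0.33, 0.2):
        n_dz = int(total * dz_share)
        posts = []
        for _ in range(200):
            pairs = pair_table(0.5, 0.0, 0.5, n_mz=total - n_dz, n_dz=n_dz,
                               seed=int(rng.integers(2**31)))
            fits = {}
            for name in ("AE", "CE"):
                # AE and CE have equal parameter counts, so their BIC
                # difference needs no saturated reference; skip it
                fits[name] = fit_twin_model(
                    TwinModelSpec(components=("A", "E") if name == "AE"
                                  else ("C", "E")),
                    pairs, saturated=(0.0, 10))
            posts.append(posterior_probabilities(
                {n: f.bic for n, f in fits.items()})["AE"])
        mean_post.append(np.mean(posts))
    assert mean_post[0] > mean_post[1] > mean_post[2]
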