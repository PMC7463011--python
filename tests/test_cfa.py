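"""Measurement model: FIML likelihood, fit indices, bootstrap, FDR, post hoc."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from twinpheno import (INDICATORS, FactorModelSpec, SimulationConfig,
                       bh_fdr, bollen_stine_p, default_bifactor_spec,
                       fit_cfa, fit_with_indices, modification_indices,
                       population_covariance, post_hoc_free_covariances,
                       simulate_dataset)
from twinpheno.cfa import chi2_vs_saturated, fit_indices, rmsea_ci
from twinpheno.sem import mvn_fiml_mle, saturated_loglik


def one_factor_spec(names=("x1", "x2", "x3", "x4")):
    pattern = {("f", names[0]): 1.0}
    for n in names[1:]:
        pattern[("f", n)] = "free"
    return FactorModelSpec(indicators=list(names), factors=["f"],
                           loading_pattern=pattern,
                           references={"f": names[0]})


def simulate_one_factor(n, loadings, resid, seed, missing=0.0):
    rng = np.random.default_rng(seed)
    eta = rng.standard_normal(n)
    y = eta[:, None] * np.asarray(loadings)[None, :] \
        + rng.standard_normal((n, len(loadings))) * np.sqrt(resid)
    if missing:
        y = np.where(rng.random(y.shape) < missing, np.nan, y)
    return y


# ---------------------------------------------------------------- FIML core

def test_saturated_loglik_matches_closed_form_on_complete_data():
    y = simulate_one_factor(500, [1.0, 0.8, 0.6], [0.5, 0.5, 0.5], 0)
    mu, sigma, ll = mvn_fiml_mle(y)
    np.testing.assert_allclose(mu, y.mean(axis=0), atol=1e-12)
    np.testing.assert_allclose(sigma, np.cov(y.T, bias=True), atol=1e-12)
    n, p = y.shape
    sign, logdet = np.linalg.slogdet(sigma)
    ll_direct = -0.5 * n * (p * np.log(2 * np.pi) + logdet + p)
    assert ll == pytest.approx(ll_direct, abs=1e-8)


def test_fiml_equals_complete_data_ml_when_nothing_missing():
    y = simulate_one_factor(800, [1.0, 0.8, 0.6, 0.7], [0.5] * 4, 1)
    spec = one_factor_spec()
    m = fit_cfa(spec, y, seed=0)
    # complete-data ML objective from the sample moments directly
    mu, s, ll_sat = mvn_fiml_mle(y)
    assert m.loglik_saturated == pytest.approx(ll_sat, abs=1e-8)
    assert m.loglik <= ll_sat + 1e-8
    # likelihood recomputed from implied moments equals the engine's value
    w = np.linalg.inv(m.implied_cov)
    d = mu - m.implied_mean
    n, p = y.shape
    ll_direct = -0.5 * n * (p * np.log(2 * np.pi)
                            + np.linalg.slogdet(m.implied_cov)[1]
                            + np.trace(w @ s) + d @ w @ d)
    assert m.loglik == pytest.approx(ll_direct, abs=1e-6)


def test_fiml_handles_missing_data_and_recovers_parameters():
    y = simulate_one_factor(20_000, [1.0, 0.8, 0.6, 0.7], [0.5] * 4, 2,
                            missing=0.15)
    m = fit_cfa(one_factor_spec(), y, seed=0)
    assert m.converged
    np.testing.assert_allclose(m.lam[:, 0], [1.0, 0.8, 0.6, 0.7], atol=0.03)
    np.testing.assert_allclose(np.diag(m.theta), [0.5] * 4, atol=0.03)


def test_bifactor_recovery_against_population_covariance_oracle(bifactor_spec):
    cfg = SimulationConfig(n_mz_pairs=5000, n_dz_pairs=5000, n_singletons=0,
                           missing_rate=0.0, outlier_rate=0.0, seed=7)
    data = simulate_dataset(cfg)
    m = fit_cfa(bifactor_spec, data, seed=0)
    assert m.converged and m.admissible
    # oracle: implied covariance must approach the generator's closed-form
    # within-twin block (independent of scaling convention)
    target = population_covariance(cfg, "MZ")[:9, :9]
    assert np.max(np.abs(m.implied_cov - target)) < 0.05
    # standardized loadings recover the generating ones
    lam_gen = cfg.loading_matrix()
    v = cfg._phenotype_variances()
    sd = np.sqrt(np.diag(target))
    std_gen = lam_gen * np.sqrt(v)[None, :] / sd[:, None]
    assert np.max(np.abs(std_gen - m.standardized_loadings())) < 0.05


def test_reference_indicator_choice_does_not_move_fit(bifactor_spec):
    cfg = SimulationConfig(seed=41)
    data = simulate_dataset(cfg)
    m1 = fit_cfa(bifactor_spec, data, seed=0)
    alt = default_bifactor_spec()
    alt.loading_pattern[("general", "predict")] = "free"
    alt.loading_pattern[("general", "paralysis")] = 1.0
    alt.references["general"] = "paralysis"
    spec2 = FactorModelSpec(indicators=alt.indicators, factors=alt.factors,
                            loading_pattern=alt.loading_pattern,
                            references=alt.references,
                            error_covariances=alt.error_covariances)
    m2 = fit_cfa(spec2, data, seed=0)
    assert m2.loglik == pytest.approx(m1.loglik, abs=1e-6)
    np.testing.assert_allclose(m2.implied_cov, m1.implied_cov, atol=1e-4)
    np.testing.assert_allclose(np.abs(m2.standardized_loadings()),
                               np.abs(m1.standardized_loadings()), atol=1e-4)


def test_standardized_solution_decomposes_unit_variance(bifactor_spec):
    data = simulate_dataset(SimulationConfig(seed=8))
    m = fit_cfa(bifactor_spec, data, seed=0)
    std_l = m.standardized_loadings()
    std_t = m.standardized_theta()
    # error covariances are off-diagonal and do not enter the diagonal identity
    total = (std_l ** 2).sum(axis=1) + np.diag(std_t)
    np.testing.assert_allclose(total, 1.0, atol=1e-8)


def test_unidentified_spec_raises_before_optimization():
    names = ["x1", "x2"]
    pattern = {("f", "x1"): 1.0, ("f", "x2"): "free"}
    spec = FactorModelSpec(indicators=names, factors=["f"],
                           loading_pattern=pattern, references={"f": "x1"},
                           error_covariances=[("x1", "x2")])
    y = simulate_one_factor(50, [1.0, 0.8], [0.5, 0.5], 3)
    with pytest.raises(ValueError, match="t-rule"):
        fit_cfa(spec, y)


# ---------------------------------------------------------------- fit indices

def test_chi2_equal_df_boundary_gives_rmsea_zero_cfi_one(bifactor_spec):
    data = simulate_dataset(SimulationConfig(seed=8))
    m = fit_cfa(bifactor_spec, data, seed=0)
    chi2, df = chi2_vs_saturated(m)
    m.loglik = m.loglik_saturated - df / 2  # force chi2 == df exactly
    fi = fit_indices(m, baseline_loglik=m.loglik_saturated - 500,
                     baseline_n_params=18, n=m.n_obs)
    assert fi.chi2 == pytest.approx(df)
    assert fi.rmsea == 0.0
    assert fi.cfi == 1.0


def test_perfect_fit_gives_zero_chi2_and_srmr():
    y = simulate_one_factor(300, [1.0, 0.8, 0.6], [0.4] * 3, 5)
    # the saturated spec reproduces the sample moments exactly: use a
    # one-factor model evaluated against its own implied moments
    m = fit_cfa(one_factor_spec(("x1", "x2", "x3")), y, seed=0)
    m.loglik = m.loglik_saturated
    fi = fit_indices(m, baseline_loglik=m.loglik_saturated - 100,
                     baseline_n_params=6, n=300,
                     sample_cov=m.implied_cov.copy())
    assert fi.chi2 == 0.0
    assert fi.srmr == pytest.approx(0.0, abs=1e-12)


def test_analytic_p_for_printed_chi2():
    """chi2(17) = 30.359 evaluates to p ~ 0.024 under the central reference
    distribution (reported alongside any bootstrap p, not in place of it)."""
    assert stats.chi2.sf(30.359, 17) == pytest.approx(0.0239, abs=5e-4)


def test_rmsea_ci_brackets_point_estimate():
    lo, hi = rmsea_ci(30.359, 17, 242)
    point = np.sqrt((30.359 - 17) / (17 * 242))
    assert lo < point < hi
    assert lo == pytest.approx(0.021, abs=0.01)
    assert hi == pytest.approx(0.089, abs=0.01)


@given(chi2=st.floats(0, 1e4), df=st.integers(1, 200),
       chi2_b=st.floats(0, 2e4), df_b=st.integers(1, 300))
@settings(max_examples=200, deadline=None)
def test_fit_index_clamps_hold_for_any_inputs(chi2, df, chi2_b, df_b):
    rmsea = np.sqrt(max(chi2 - df, 0.0) / (df * 1000))
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else np.clip(1 - max(chi2 - df, 0) / denom, 0, 1)
    assert rmsea >= 0
    assert 0 <= cfi <= 1
    if chi2 <= df:
        assert rmsea == 0


# ---------------------------------------------------------------- bootstrap

def test_bollen_stine_trivial_cases():
    y = simulate_one_factor(250, [1.0, 0.8, 0.6], [0.4] * 3, 6)
    spec = one_factor_spec(("x1", "x2", "x3"))
    m = fit_cfa(spec, y, seed=0)
    with pytest.raises(ValueError):
        bollen_stine_p(m, spec, y, n_draws=0)
    # observed chi2 == 0 (just-identified model) -> every draw ties -> p = 1
    chi2, df = chi2_vs_saturated(m)
    assert df == 0 and chi2 == pytest.approx(0.0, abs=1e-6)
    p, status = bollen_stine_p(m, spec, y, n_draws=25, seed=1)
    assert p == 1.0
    assert status["failures"] == 0


def test_bollen_stine_p_calibrated_under_true_model():
    """Under data generated from the fitted model the bootstrap p is roughly
    uniform: its mean over outer replicates sits near 1/2."""
    spec = one_factor_spec()
    rng = np.random.default_rng(2024)
    ps = []
    for rep in range(200):
        y = simulate_one_factor(300, [1.0, 0.8, 0.6, 0.7], [0.5] * 4,
                                seed=rng.integers(2**31))
        m = fit_cfa(spec, y, seed=0)
        p, _ = bollen_stine_p(m, spec, y, n_draws=100,
                              seed=int(rng.integers(2**31)))
        ps.append(p)
    assert 0.45 <= np.mean(ps) <= 0.55


# ---------------------------------------------------------------- FDR

def test_bh_fdr_step_up_hand_example():
    flags = bh_fdr([0.001, 0.01, 0.02, 0.04, 0.2], q=0.05)
    assert flags.tolist() == [True, True, True, True, False]


def test_bh_fdr_edge_cases():
    assert bh_fdr([], 0.05).size == 0
    assert not bh_fdr([1.0, 1.0, 1.0], 0.05).any()
    assert bh_fdr([0.04], 0.05).all()
    with pytest.raises(ValueError):
        bh_fdr([0.5], q=1.5)
    with pytest.raises(ValueError):
        bh_fdr([1.5], q=0.05)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=40),
       st.floats(0.01, 0.2))
@settings(max_examples=200, deadline=None)
def test_bh_fdr_matches_step_up_definition(ps, q):
    flags = bh_fdr(ps, q)
    p = np.asarray(ps)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_max = k
    assert flags.sum() == k_max
    if k_max:
        assert flags[order[:k_max]].all()


# ---------------------------------------------------------------- post hoc

def test_modification_index_finds_true_extra_covariance():
    """Data with one genuine extra error covariance: its score test dominates
    the other candidates in almost every replicate."""
    names = ["x1", "x2", "x3", "x4", "x5", "x6"]
    spec = one_factor_spec(names)
    lam = np.array([1.0, 0.9, 0.8, 0.7, 0.8, 0.9])
    hits = 0
    n_rep = 40
    rng = np.random.default_rng(7)
    candidates = [("x2", "x3"), ("x3", "x4"), ("x4", "x5"), ("x2", "x5")]
    for rep in range(n_rep):
        r = np.random.default_rng(rng.integers(2**31))
        eta = r.standard_normal(2000)
        eps = r.standard_normal((2000, 6)) * np.sqrt(0.5)
        shared = r.standard_normal(2000) * np.sqrt(0.15)
        eps[:, 2] += shared
        eps[:, 3] += shared  # true extra covariance between x3 and x4
        y = eta[:, None] * lam[None, :] + eps
        m = fit_cfa(spec, y, seed=0)
        mis = modification_indices(m, candidates)
        if max(mis, key=mis.get) == ("x3", "x4"):
            hits += 1
    assert hits >= int(0.95 * n_rep)


def test_post_hoc_keeps_nothing_when_no_candidate_is_needed():
    y = simulate_one_factor(1500, [1.0, 0.8, 0.6, 0.7], [0.5] * 4, 11)
    spec = one_factor_spec()
    out_spec, report = post_hoc_free_covariances(
        spec, y, [("x2", "x3"), ("x3", "x4")], q=0.05)
    assert out_spec.error_covariances == spec.error_covariances
    assert report["added"] == []


def test_post_hoc_returns_spec_unchanged_for_empty_candidates():
    y = simulate_one_factor(400, [1.0, 0.8, 0.6], [0.5] * 3, 12)
    spec = one_factor_spec(("x1", "x2", "x3"))
    out_spec, report = post_hoc_free_covariances(spec, y, [], q=0.05)
    assert out_spec is spec or out_spec.error_covariances == []
    assert report["steps"] == []


def test_post_hoc_recovers_injected_covariance_and_it_survives_fdr():
    names = ["x1", "x2", "x3", "x4", "x5", "x6"]
    spec = one_factor_spec(names)
    lam = np.array([1.0, 0.9, 0.8, 0.7, 0.8, 0.9])
    r = np.random.default_rng(5)
    eta = r.standard_normal(3000)
    eps = r.standard_normal((3000, 6)) * np.sqrt(0.5)
    shared = r.standard_normal(3000) * np.sqrt(0.2)
    eps[:, 1] += shared
    eps[:, 4] += shared
    y = eta[:, None] * lam[None, :] + eps
    out_spec, report = post_hoc_free_covariances(
        spec, y, [("x2", "x5"), ("x3", "x4"), ("x2", "x3")], q=0.05)
    assert ("x2", "x5") in report["added"]
    assert ("x2", "x5") in out_spec.error_covariances


def test_heywood_solution_is_flagged():
    # two indicators nearly collinear force a negative residual variance path
    r = np.random.default_rng(9)
    eta = r.standard_normal(300)
    y = np.column_stack([eta + 0.05 * r.standard_normal(300),
                         eta + 0.05 * r.standard_normal(300),
                         0.3 * eta + r.standard_normal(300),
                         0.3 * eta + r.standard_normal(300)])
    m = fit_cfa(one_factor_spec(), y, seed=0)
    # residual variances are log-parameterized, so they stay non-negative
    assert np.all(np.diag(m.theta) >= 0)


def test_factor_model_spec_yaml_round_trip(tmp_path, bifactor_spec):
    path = tmp_path / "spec.yaml"
    bifactor_spec.to_yaml(path)
    back = FactorModelSpec.from_yaml(path)
    assert back.indicators == bifactor_spec.indicators
    assert back.factors == bifactor_spec.factors
    assert back.references == bifactor_spec.references
    assert set(map(tuple, back.error_covariances)) == \
        set(map(tuple, bifactor_spec.error_covariances))
    assert back.loading_pattern == bifactor_spec.loading_pattern
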