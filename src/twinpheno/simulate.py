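"""Synthetic twin-pair questionnaire data with known structure.

Generates wide per-individual tables of nine questionnaire subscales
(UPPS-P urgency, lack of premeditation, lack of perseverance, sensation
seeking; IUS-12 predictability, paralysis; OBQ-44 perfectionism, threat,
thoughts) driven by a 3-factor orthogonal bifactor measurement model whose
latent phenotypes have a known additive-genetic / common-environment /
unique-environment (ACE) decomposition:

    P = a*A + c*C + e*E,   a^2 + c^2 + e^2 = 1

with A shared within monozygotic pairs and correlated 0.5 within dizygotic
pairs, C shared within every pair, and E independent.  The defaults mirror
the study conditions the pipeline is designed for: 118 MZ + 55 DZ complete
pairs plus singletons, ages 18-55, a weak negative age effect on the general
phenotype, MCAR missingness and rare extreme outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats

INDICATORS = ["urgency", "premed", "persev", "ss",
              "predict", "paralysis", "perfect", "threat", "thoughts"]
PHENOTYPES = ["general", "impulsivity", "obsessiveness"]
IMPULSIVITY_POS = [0, 1, 2, 3]     # urgency, premed, persev, ss
OBSESSIVENESS_POS = [6, 7, 8]      # perfect, threat, thoughts
CSV_COLUMNS = ["pair_id", "twin", "zygosity", "age", "sex"] + INDICATORS


@dataclass
class SimulationConfig:
    """Generating conditions for one synthetic twin dataset.

    Loadings follow the bifactor pattern in which lack of perseverance does
    not load on the general factor, sensation seeking does not load on the
    impulsivity group factor, and the two intolerance-of-uncertainty
    subscales load only on the general factor.
    """

    n_mz_pairs: int = 118
    n_dz_pairs: int = 55
    n_singletons: int = 141
    loadings_general: tuple = (0.62, 0.51, 0.0, 0.34, 0.79, 0.73, 0.68, 0.73, 0.62)
    loadings_impulsivity: tuple = (0.63, 0.69, 0.57, 0.0)
    loadings_obsessiveness: tuple = (0.51, 0.56, 0.62)
    residual_variances: tuple = (0.22, 0.26, 0.68, 0.88, 0.38, 0.47,
                                 0.28, 0.15, 0.23)
    error_covariance_pairs: tuple = (
        ("urgency", "ss", 0.10), ("premed", "ss", 0.12),
        ("predict", "paralysis", 0.10), ("perfect", "predict", 0.08),
        ("thoughts", "paralysis", 0.08))
    variance_shares: dict = field(default_factory=lambda: {
        "general": (0.0, 0.36, 0.64),
        "impulsivity": (0.33, 0.0, 0.67),
        "obsessiveness": (0.25, 0.0, 0.75)})
    age_effect_general: float = -0.02
    age_mean: float = 40.0
    age_sd: float = 10.5
    age_min: float = 18.0
    age_max: float = 55.0
    missing_rate: float = 0.05
    outlier_rate: float = 0.002
    outlier_magnitude: float = 5.0
    # optional discretization to summed-Likert-style integer ranges,
    # off by default (the analysis treats subscales as continuous)
    likert_bounds: tuple | None = None   # per-indicator (lo, hi) integer range
    seed: int = 0

    def validate(self):
        for name, (a2, c2, e2) in self.variance_shares.items():
            if min(a2, c2, e2) < 0 or abs(a2 + c2 + e2 - 1) > 1e-12:
                raise ValueError(
                    f"variance shares for {name!r} must be non-negative and "
                    f"sum to 1, got ({a2}, {c2}, {e2})")
        if np.any(np.asarray(self.residual_variances) <= 0):
            raise ValueError("residual variances must be strictly positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate must lie in [0, 1)")
        sigma = self._within_covariance()
        if np.min(np.linalg.eigvalsh(sigma)) <= 0:
            raise ValueError("implied indicator covariance is not positive definite")

    # -- structure ----------------------------------------------------
    def loading_matrix(self) -> np.ndarray:
        lam = np.zeros((9, 3))
        lam[:, 0] = self.loadings_general
        lam[IMPULSIVITY_POS, 1] = self.loadings_impulsivity
        lam[OBSESSIVENESS_POS, 2] = self.loadings_obsessiveness
        return lam

    def residual_matrix(self) -> np.ndarray:
        theta = np.diag(np.asarray(self.residual_variances, dtype=float))
        for a, b, cov in self.error_covariance_pairs:
            i, j = INDICATORS.index(a), INDICATORS.index(b)
            theta[i, j] = theta[j, i] = cov
        return theta

    def _age_variance(self) -> float:
        a = (self.age_min - self.age_mean) / self.age_sd
        b = (self.age_max - self.age_mean) / self.age_sd
        return float(stats.truncnorm.var(a, b, loc=self.age_mean,
                                         scale=self.age_sd))

    def _phenotype_variances(self) -> np.ndarray:
        """Total latent variance per phenotype (1 plus any age contribution)."""
        v = np.ones(3)
        v[0] += self.age_effect_general ** 2 * self._age_variance()
        return v

    def _within_covariance(self) -> np.ndarray:
        lam = self.loading_matrix()
        return lam @ np.diag(self._phenotype_variances()) @ lam.T \
            + self.residual_matrix()

    # -- serialization ------------------------------------------------
    def to_yaml(self, path):
        d = asdict(self)
        d["error_covariance_pairs"] = [list(t) for t in self.error_covariance_pairs]
        d["variance_shares"] = {k: list(v) for k, v in self.variance_shares.items()}
        for key in ("loadings_general", "loadings_impulsivity",
                    "loadings_obsessiveness", "residual_variances"):
            d[key] = list(d[key])
        if d["likert_bounds"] is not None:
            d["likert_bounds"] = [list(b) for b in d["likert_bounds"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["error_covariance_pairs"] = tuple(
            (a, b, float(c)) for a, b, c in d.get("error_covariance_pairs", ()))
        d["variance_shares"] = {k: tuple(v)
                                for k, v in d["variance_shares"].items()}
        for key in ("loadings_general", "loadings_impulsivity",
                    "loadings_obsessiveness", "residual_variances"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("likert_bounds") is not None:
            d["likert_bounds"] = tuple(tuple(b) for b in d["likert_bounds"])
        return cls(**d)


def _component_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Named deterministic sub-streams spawned from one root seed."""
    root = np.random.SeedSequence(seed)
    names = ["A", "C", "E", "eps", "age", "sex", "missing", "outlier", "assign"]
    children = root.spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _draw_ace(rng_a, rng_c, rng_e, n_pairs: int, r_a: float):
    """Latent standard-normal components for both members of n pairs; the
    additive component is correlated ``r_a`` across co-twins."""
    a1 = rng_a.standard_normal(n_pairs)
    if r_a >= 1.0:
        a2 = a1.copy()
    else:
        a2 = r_a * a1 + np.sqrt(1 - r_a ** 2) * rng_a.standard_normal(n_pairs)
    c = rng_c.standard_normal(n_pairs)
    e1 = rng_e.standard_normal(n_pairs)
    e2 = rng_e.standard_normal(n_pairs)
    return (a1, a2), (c, c), (e1, e2)


def simulate_dataset(config: SimulationConfig,
                     return_latents: bool = False):
    """Generate one per-individual wide table (see CSV_COLUMNS).

    Reproducible bit-for-bit from ``config.seed``.  With
    ``return_latents=True`` also returns the noiseless latent phenotype
    values per individual (for oracle checks).
    """
    config.validate()
    rngs = _component_rngs(config.seed)
    lam = config.loading_matrix()
    theta = config.residual_matrix()
    theta_chol = np.linalg.cholesky(theta + 1e-12 * np.eye(9))

    blocks = []
    latent_blocks = []
    pair_counter = 0
    for zyg, n_pairs, r_a in (("MZ", config.n_mz_pairs, 1.0),
                              ("DZ", config.n_dz_pairs, 0.5)):
        if n_pairs == 0:
            continue
        eta = np.zeros((2, n_pairs, 3))
        for k, pheno in enumerate(PHENOTYPES):
            a2, c2, e2 = config.variance_shares[pheno]
            (A1, A2), (C1, C2), (E1, E2) = _draw_ace(
                rngs["A"], rngs["C"], rngs["E"], n_pairs, r_a)
            a, c, e = np.sqrt(a2), np.sqrt(c2), np.sqrt(e2)
            eta[0, :, k] = a * A1 + c * C1 + e * E1
            eta[1, :, k] = a * A2 + c * C2 + e * E2
        age = _truncated_ages(rngs["age"], n_pairs, config)
        eta[:, :, 0] += config.age_effect_general * (age - config.age_mean)
        sex1 = rngs["sex"].integers(0, 2, size=n_pairs)
        sex2 = sex1 if zyg == "MZ" else rngs["sex"].integers(0, 2, size=n_pairs)
        for t, sex in ((0, sex1), (1, sex2)):
            blocks.append(pd.DataFrame({
                "pair_id": [f"{zyg}{pair_counter + i:05d}" for i in range(n_pairs)],
                "twin": t + 1,
                "zygosity": zyg,
                "age": age,
                "sex": np.where(sex == 0, "F", "M")}))
            latent_blocks.append(eta[t])
        pair_counter += n_pairs
    # singletons: independent individuals, zygosity recorded from registry
    n_s = config.n_singletons
    if n_s:
        eta_s = np.zeros((n_s, 3))
        for k, pheno in enumerate(PHENOTYPES):
            a2, c2, e2 = config.variance_shares[pheno]
            comp = (np.sqrt(a2) * rngs["A"].standard_normal(n_s)
                    + np.sqrt(c2) * rngs["C"].standard_normal(n_s)
                    + np.sqrt(e2) * rngs["E"].standard_normal(n_s))
            eta_s[:, k] = comp
        age_s = _truncated_ages(rngs["age"], n_s, config)
        eta_s[:, 0] += config.age_effect_general * (age_s - config.age_mean)
        zyg_s = np.where(rngs["sex"].random(n_s) < 0.6, "MZ", "DZ")
        blocks.append(pd.DataFrame({
            "pair_id": [f"S{i:05d}" for i in range(n_s)],
            "twin": 1, "zygosity": zyg_s, "age": age_s,
            "sex": np.where(rngs["sex"].integers(0, 2, size=n_s) == 0, "F", "M")}))
        latent_blocks.append(eta_s)

    meta = pd.concat(blocks, ignore_index=True)
    eta_all = np.vstack(latent_blocks)
    n = len(meta)

    # rare extreme outliers: displace one latent phenotype
    if config.outlier_rate > 0:
        mask = rngs["outlier"].random((n, 3)) < config.outlier_rate
        signs = np.where(rngs["outlier"].random((n, 3)) < 0.5, -1.0, 1.0)
        eta_all = eta_all + mask * signs * config.outlier_magnitude

    eps = rngs["eps"].standard_normal((n, 9)) @ theta_chol.T
    y = eta_all @ lam.T + eps
    if config.likert_bounds is not None:
        # map each standardized column onto its integer summed-score range
        for j, (lo, hi) in enumerate(config.likert_bounds):
            center, half = (hi + lo) / 2.0, (hi - lo) / 2.0
            sd = np.sqrt(np.sum(lam[j] ** 2) + config.residual_variances[j])
            y[:, j] = np.clip(np.rint(center + y[:, j] / sd * half / 3.0),
                              lo, hi)
    if config.missing_rate > 0:
        miss = rngs["missing"].random((n, 9)) < config.missing_rate
        y = np.where(miss, np.nan, y)

    data = pd.concat([meta, pd.DataFrame(y, columns=INDICATORS)], axis=1)
    if return_latents:
        return data, pd.DataFrame(eta_all, columns=PHENOTYPES)
    return data


def _truncated_ages(rng, n, config: SimulationConfig) -> np.ndarray:
    a = (config.age_min - config.age_mean) / config.age_sd
    b = (config.age_max - config.age_mean) / config.age_sd
    u = rng.random(n)
    lo, hi = stats.norm.cdf(a), stats.norm.cdf(b)
    return config.age_mean + config.age_sd * stats.norm.ppf(lo + u * (hi - lo))


def population_covariance(config: SimulationConfig, zygosity: str) -> np.ndarray:
    """Closed-form 18x18 covariance of two co-twins' nine indicators."""
    config.validate()
    if zygosity not in ("MZ", "DZ"):
        raise ValueError("zygosity must be 'MZ' or 'DZ'")
    lam = config.loading_matrix()
    within = config._within_covariance()
    r_a = 1.0 if zygosity == "MZ" else 0.5
    cross_lat = np.zeros(3)
    for k, pheno in enumerate(PHENOTYPES):
        a2, c2, _ = config.variance_shares[pheno]
        cross_lat[k] = r_a * a2 + c2
    # co-twins share age, so the age pathway is fully shared within pairs
    cross_lat[0] += config.age_effect_general ** 2 * config._age_variance()
    cross = lam @ np.diag(cross_lat) @ lam.T
    out = np.empty((18, 18))
    out[:9, :9] = within
    out[9:, 9:] = within
    out[:9, 9:] = cross
    out[9:, :9] = cross
    return out


# -- CSV round trip ----------------------------------------------------

def write_csv(data: pd.DataFrame, path):
    data.loc[:, CSV_COLUMNS].to_csv(path, index=False, na_rep="")


def read_csv(path) -> pd.DataFrame:
    data = pd.read_csv(path, dtype={"pair_id": str, "zygosity": str, "sex": str})
    missing = [c for c in CSV_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"dataset is missing columns: {missing}")
    validate_dataset(data)
    return data


def validate_dataset(data: pd.DataFrame):
    if not set(data["twin"]).issubset({1, 2}):
        raise ValueError("twin index must be 1 or 2")
    if not set(data["zygosity"]).issubset({"MZ", "DZ"}):
        raise ValueError("zygosity must be MZ or DZ")
    counts = data.groupby("pair_id").size()
    if (counts > 2).any():
        raise ValueError("a pair_id occurs more than twice")
    for col in ("zygosity", "age"):
        per_pair = data.groupby("pair_id")[col].nunique()
        if (per_pair > 1).any():
            raise ValueError(f"co-twins must share {col}")
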