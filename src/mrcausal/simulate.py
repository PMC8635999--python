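"""Synthetic GWAS summary statistics with known ground truth.

Two-sample Mendelian randomization works entirely from per-SNP summary
associations: an exposure GWAS supplies SNP-exposure effects (gamma_j) and
an independent outcome GWAS supplies SNP-outcome effects (Gamma_j).  This
module fabricates matched pairs (and multi-exposure panels) of such tables
in which the true causal effect theta, the per-SNP direct (pleiotropic)
effects alpha_j, and the allele bookkeeping are all known, so that every
estimator downstream has a parameter-recovery oracle.

The generative model for a single exposure:

    gamma_j   fixed magnitude with random sign, scaled so the instrument
              set explains a target fraction of exposure variance
    Gamma_j = theta * gamma_j + alpha_j          (noiseless means)
    beta_hat = truth + N(0, se^2)
    se      = 1 / sqrt(2 * EAF * (1 - EAF) * N)  (standardized trait)

For a binary outcome analysed on the log-odds scale the standard error
carries the usual case-fraction attenuation 1/sqrt(2p(1-p) N K(1-K)).
Alleles are drawn so that a configurable fraction of SNPs is palindromic
(A/T or C/G) and a fraction of outcome rows is emitted with swapped
effect/other alleles or on the complementary strand, exercising the
harmonization logic.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimulationConfig",
    "LdscSimConfig",
    "simulate_two_sample",
    "simulate_mv_exposures",
    "simulate_ldsc_zscores",
]

GWAS_COLUMNS = ["snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
# ordered palindromic pairs
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
# ordered non-palindromic pairs (distinct, not strand complements)
_PLAIN_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a two-sample summary-statistics simulation.

    Defaults mirror the scale of a SpiroMeta-sized lung-function exposure
    GWAS (N ~ 79,055; instruments explaining ~2% of variance) paired with
    a very large case-control atrial-fibrillation outcome GWAS
    (N ~ 1,030,836 with 60,620 cases).

    Parameters
    ----------
    n_snps
        Number of candidate instruments.
    n_exposure, n_outcome
        GWAS sample sizes for the exposure and outcome samples.
    theta
        True causal effect of the exposure on the outcome (log-odds per SD
        of exposure when ``binary_outcome``).  A sequence is only accepted
        by :func:`simulate_mv_exposures`.
    maf_range
        Minor/effect allele frequencies are drawn uniformly on this
        interval, which must lie within (0, 0.5].
    target_r2
        Total exposure variance explained by the instrument set (split
        evenly across SNPs); default 0.0198 keeps F statistics in a
        realistic range for an N ~ 79k exposure GWAS.
    pleiotropy_mean, pleiotropy_sd
        Mean and SD of the direct SNP->outcome effects alpha_j given to
        invalid instruments.
    invalid_fraction
        Fraction of SNPs with a nonzero direct effect; exactly
        ``round(invalid_fraction * n_snps)`` SNPs are made invalid.
    palindromic_fraction
        Fraction of SNPs assigned A/T or C/G allele pairs.
    flip_fraction
        Fraction of outcome rows emitted with swapped effect/other alleles
        or complementary-strand coding (split at random between the two).
    binary_outcome, case_fraction
        Whether the outcome is a case-control trait and its case fraction
        K; outcome betas are then log odds ratios.
    aligned_effects
        When True all true SNP-exposure effects are positive (effect
        alleles aligned to the trait-increasing direction), so that
        directional pleiotropy keeps a common sign under the Egger
        orientation convention; default False draws random signs.
    se_scale
        Multiplier applied to all standard errors (and to the matching
        sampling noise); values << 1 give a noiseless limit.
    seed
        Seed for the single generator stream governing all draws.
    """

    n_snps: int = 20
    n_exposure: int = 79_055
    n_outcome: int = 1_030_836
    theta: float | Sequence[float] = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    target_r2: float = 0.0198
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 0.0
    palindromic_fraction: float = 0.0
    flip_fraction: float = 0.0
    binary_outcome: bool = True
    case_fraction: float = 60_620 / 1_030_836
    aligned_effects: bool = False
    se_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise ConfigurationError("sample sizes must be >= 2")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        for name in ("invalid_fraction", "palindromic_fraction", "flip_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or not math.isfinite(v):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if not (0.0 <= self.target_r2 < 1.0):
            raise ConfigurationError("target_r2 must be in [0, 1)")
        if self.binary_outcome and not (0.0 < self.case_fraction < 1.0):
            raise ConfigurationError("case_fraction must be in (0, 1)")
        if self.se_scale <= 0 or not math.isfinite(self.se_scale):
            raise ConfigurationError("se_scale must be positive and finite")
        theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if not np.all(np.isfinite(theta)):
            raise ConfigurationError("theta must be finite")
        for name in ("pleiotropy_mean", "pleiotropy_sd"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(z))
    # keep p in (0, 1] even for astronomically large z
    return np.clip(p, np.nextafter(0.0, 1.0), 1.0)


def _gwas_frame(snp, ea, oa, eaf, beta, se, n) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp": snp,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": _two_sided_p(beta / se),
            "n": n,
        }
    )


def simulate_mv_exposures(
    config: SimulationConfig,
    n_exposures: int,
    cross_loadings: Sequence[Sequence[float]] | np.ndarray,
    exposure_names: Sequence[str] | None = None,
) -> tuple[list[pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Simulate K correlated exposure GWAS tables plus one outcome table.

    Each SNP receives K independent base effects (each column scaled so
    its instrument set explains ``target_r2`` of the corresponding base
    factor); the effective SNP-exposure effects are the linear mixture

        gamma[j, k] = sum_m cross_loadings[k, m] * base[j, m]

    so off-diagonal loadings create SNPs significant for several exposures
    at once.  The noiseless outcome mean is sum_k theta_k * gamma[j, k] +
    alpha_j.

    Returns ``(exposure_tables, outcome_table, truth_table)``.  With
    ``n_exposures=1`` and identity loadings the output coincides with
    :func:`simulate_two_sample` for the same config and seed.
    """
    L = np.asarray(cross_loadings, dtype=float)
    if L.shape != (n_exposures, n_exposures):
        raise ConfigurationError(
            f"cross_loadings must be {n_exposures}x{n_exposures}, got {L.shape}"
        )
    if not np.all(np.isfinite(L)):
        raise ConfigurationError("cross_loadings must be finite")
    theta = np.atleast_1d(np.asarray(config.theta, dtype=float))
    if theta.size == 1:
        theta = np.repeat(theta, n_exposures)
    if theta.size != n_exposures:
        raise ConfigurationError(
            f"theta has length {theta.size}, expected {n_exposures}"
        )
    if exposure_names is None:
        exposure_names = [f"x{k + 1}" for k in range(n_exposures)]

    n = config.n_snps
    rng = np.random.default_rng(config.seed)

    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=n)

    n_pal = round(config.palindromic_fraction * n)
    pal_idx = rng.choice(n, size=n_pal, replace=False)
    is_pal = np.zeros(n, dtype=bool)
    is_pal[pal_idx] = True

    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    pal_choice = rng.integers(0, len(_PALINDROMIC_PAIRS), size=n)
    plain_choice = rng.integers(0, len(_PLAIN_PAIRS), size=n)
    for j in range(n):
        pair = (
            _PALINDROMIC_PAIRS[pal_choice[j]]
            if is_pal[j]
            else _PLAIN_PAIRS[plain_choice[j]]
        )
        ea[j], oa[j] = pair

    # base effects: equal per-SNP variance contribution, random signs
    per_snp_r2 = config.target_r2 / n
    magnitude = np.sqrt(per_snp_r2 / (2.0 * maf * (1.0 - maf)))
    signs = rng.choice([-1.0, 1.0], size=(n, n_exposures))
    if config.aligned_effects:
        signs = np.ones_like(signs)
    base = magnitude[:, None] * signs
    gamma = base @ L.T

    n_invalid = round(config.invalid_fraction * n)
    invalid_idx = rng.choice(n, size=n_invalid, replace=False)
    alpha = np.zeros(n)
    alpha[invalid_idx] = config.pleiotropy_mean + config.pleiotropy_sd * rng.standard_normal(n_invalid)
    is_valid = np.ones(n, dtype=bool)
    is_valid[invalid_idx] = False

    se_x = config.se_scale / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exposure)
    if config.binary_outcome:
        k = config.case_fraction
        se_y = config.se_scale / np.sqrt(
            2.0 * maf * (1.0 - maf) * config.n_outcome * k * (1.0 - k)
        )
    else:
        se_y = config.se_scale / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_outcome)

    beta_x = gamma + se_x[:, None] * rng.standard_normal((n, n_exposures))
    big_gamma = gamma @ theta + alpha
    beta_y = big_gamma + se_y * rng.standard_normal(n)

    n_flip = round(config.flip_fraction * n)
    flip_idx = rng.choice(n, size=n_flip, replace=False)
    flip_mode = rng.integers(0, 2, size=n_flip)  # 0: allele swap, 1: strand

    snp = np.array([f"rs{j + 1}" for j in range(n)], dtype=object)

    exposures = [
        _gwas_frame(snp, ea, oa, maf, beta_x[:, k], se_x, config.n_exposure)
        for k in range(n_exposures)
    ]

    out_ea = ea.copy()
    out_oa = oa.copy()
    out_eaf = maf.copy()
    out_beta = beta_y.copy()
    for i, j in enumerate(flip_idx):
        if flip_mode[i] == 0:
            out_ea[j], out_oa[j] = out_oa[j], out_ea[j]
            out_beta[j] = -out_beta[j]
            out_eaf[j] = 1.0 - out_eaf[j]
        else:
            out_ea[j] = _COMPLEMENT[out_ea[j]]
            out_oa[j] = _COMPLEMENT[out_oa[j]]
    outcome = _gwas_frame(snp, out_ea, out_oa, out_eaf, out_beta, se_y, config.n_outcome)

    truth = pd.DataFrame({"snp": snp})
    if n_exposures == 1:
        truth["gamma_true"] = gamma[:, 0]
    else:
        for k, name in enumerate(exposure_names):
            truth[f"gamma_true_{name}"] = gamma[:, k]
    truth["alpha_true"] = alpha
    truth["is_valid"] = is_valid
    truth["effect_allele"] = ea
    truth["other_allele"] = oa

    return exposures, outcome, truth


def simulate_two_sample(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one exposure GWAS table, one outcome GWAS table, and truth.

    Thin single-exposure front-end of :func:`simulate_mv_exposures`;
    identical draws for identical config and seed.
    """
    theta = np.atleast_1d(np.asarray(config.theta, dtype=float))
    if theta.size != 1:
        raise ConfigurationError("simulate_two_sample needs a scalar theta")
    exposures, outcome, truth = simulate_mv_exposures(config, 1, [[1.0]])
    return exposures[0], outcome, truth


@dataclasses.dataclass(frozen=True)
class LdscSimConfig:
    """Conditions for simulating per-SNP z-scores for two traits.

    The marginal and cross moments follow the LD score regression model:

        E[z1_j^2]     = 1 + N1 * h2_1 * l_j / M
        E[z1_j z2_j]  = sqrt(N1 N2) * rho_g * l_j / M + rho * Ns / sqrt(N1 N2)

    with rho_g = rg_true * sqrt(h2_1 * h2_2).  The phenotypic correlation
    rho of overlapping samples is taken equal to ``rg_true`` (only the
    product rho * Ns enters the intercept, so any confounded pair would
    do; this choice keeps one fewer knob).
    """

    n_snps: int = 5000
    ld_scores: np.ndarray | None = None
    h2_trait1: float = 0.4
    h2_trait2: float = 0.4
    rg_true: float = 0.0
    n1: int = 50_000
    n2: int = 50_000
    n_overlap: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2_trait1 <= 1.0 and 0.0 <= self.h2_trait2 <= 1.0):
            raise ConfigurationError("heritabilities must be in [0, 1]")
        if not (-1.0 <= self.rg_true <= 1.0):
            raise ConfigurationError("|rg_true| must be <= 1")
        if self.n_snps < 2:
            raise ConfigurationError("n_snps must be >= 2")
        if self.n1 < 2 or self.n2 < 2:
            raise ConfigurationError("sample sizes must be >= 2")
        if not (0 <= self.n_overlap <= min(self.n1, self.n2)):
            raise ConfigurationError("n_overlap must be within both samples")
        if self.ld_scores is not None:
            ell = np.asarray(self.ld_scores, dtype=float)
            if ell.shape != (self.n_snps,):
                raise ConfigurationError("ld_scores length must equal n_snps")
            if np.any(ell < 1.0):
                raise ConfigurationError("LD scores must be >= 1")


def simulate_ldsc_zscores(
    config: LdscSimConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw paired z-score vectors (and the LD scores used) for two traits.

    Returns ``(z1, z2, ld_scores)``.  When ``config.ld_scores`` is None a
    right-skewed LD score distribution (1 + Gamma(shape=3, scale=13),
    mean ~ 40) is drawn from the same seed, loosely mimicking genome-wide
    LD score spread.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    if config.ld_scores is None:
        ell = 1.0 + rng.gamma(shape=3.0, scale=13.0, size=m)
    else:
        ell = np.asarray(config.ld_scores, dtype=float)

    var1 = 1.0 + config.n1 * config.h2_trait1 * ell / m
    var2 = 1.0 + config.n2 * config.h2_trait2 * ell / m
    rho_g = config.rg_true * math.sqrt(config.h2_trait1 * config.h2_trait2)
    cov = (
        math.sqrt(config.n1 * config.n2) * rho_g * ell / m
        + config.rg_true * config.n_overlap / math.sqrt(config.n1 * config.n2)
    )
    resid_var = var2 - cov**2 / var1
    if np.any(resid_var <= 0):
        raise ConfigurationError("implied z-score covariance is not positive definite")

    u = rng.standard_normal(m)
    v = rng.standard_normal(m)
    z1 = np.sqrt(var1) * u
    z2 = (cov / np.sqrt(var1)) * u + np.sqrt(resid_var) * v
    return z1, z2, ell
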