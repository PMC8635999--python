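"""Univariable two-sample MR estimators and diagnostics.

All estimators consume a :class:`~mrcausal.harmonize.HarmonizedSet` (or
any DataFrame with ``beta_exposure``, ``se_exposure``, ``beta_outcome``,
``se_outcome`` columns) and weight SNPs by the reciprocal of the outcome
variance, w_j = 1 / se_outcome_j^2:

* IVW: weighted regression of outcome on exposure betas through the
  origin.  The default multiplicative random-effects model inflates the
  SE by max(1, sqrt(Q / (J - 1))); fixed effects leaves it untouched.
  Point estimates are identical under both.
* MR-Egger: the same regression with a free intercept, inputs oriented so
  all exposure betas are non-negative; a nonzero intercept indicates
  average directional pleiotropy.  Inference uses the t distribution with
  J - 2 df (instrument counts are typically small).
* Weighted median: consistent when SNPs carrying more than half the
  weight are valid; SE by seeded parametric bootstrap.

Heterogeneity is summarized by Cochran's Q (the weighted residual sum of
squares about the IVW fit) and I^2 = max(0, (Q - df) / Q).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import HarmonizedSet

logger = logging.getLogger(__name__)

__all__ = [
    "MrEstimate",
    "HeterogeneityStats",
    "PleiotropyStats",
    "LeaveOneOutResult",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "leave_one_out",
    "funnel_data",
]


@dataclasses.dataclass(frozen=True)
class MrEstimate:
    """One estimator's causal effect on the log-odds (or SD-unit) scale."""

    method: str
    beta: float
    se: float
    or_point: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int

    @classmethod
    def from_beta(
        cls, method: str, beta: float, se: float, n_snps: int, df: int | None = None
    ) -> "MrEstimate":
        """Assemble OR, 95% CI and two-sided p from a beta and its SE.

        ``df`` switches the reference distribution from normal to t."""
        if df is None:
            crit = stats.norm.ppf(0.975)
            pval = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else 0.0
        else:
            crit = stats.t.ppf(0.975, df)
            pval = 2.0 * stats.t.sf(abs(beta) / se, df) if se > 0 else 0.0
        pval = float(np.clip(pval, np.nextafter(0.0, 1.0), 1.0))
        return cls(
            method=method,
            beta=float(beta),
            se=float(se),
            or_point=float(np.exp(beta)),
            ci_low=float(np.exp(beta - crit * se)),
            ci_high=float(np.exp(beta + crit * se)),
            pval=pval,
            n_snps=n_snps,
        )


@dataclasses.dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q about a fitted slope, with df, p, and I^2."""

    q: float
    df: int
    q_pval: float
    i2: float

    @classmethod
    def from_q(cls, q: float, df: int) -> "HeterogeneityStats":
        q_pval = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
        i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
        return cls(q=float(q), df=df, q_pval=q_pval, i2=i2)


@dataclasses.dataclass(frozen=True)
class PleiotropyStats:
    """MR-Egger intercept estimate with its SE and two-sided p."""

    intercept: float
    se: float
    pval: float


@dataclasses.dataclass
class LeaveOneOutResult:
    """Per-SNP IVW re-fits with each instrument excluded in turn."""

    table: pd.DataFrame  # snp, beta, se, or, ci_low, ci_high, max_influence


def _arrays(instrument_set) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list]:
    table = instrument_set.table if isinstance(instrument_set, HarmonizedSet) else instrument_set
    g = np.asarray(table["beta_exposure"], dtype=float)
    se_g = np.asarray(table["se_exposure"], dtype=float)
    big = np.asarray(table["beta_outcome"], dtype=float)
    se_big = np.asarray(table["se_outcome"], dtype=float)
    snps = list(table["snp"]) if "snp" in table else [f"rs{i+1}" for i in range(g.size)]
    return g, se_g, big, se_big, snps


def wald_ratio(instrument_set) -> MrEstimate:
    """Single-SNP causal estimate Gamma/gamma with first-order SE."""
    g, _, big, se_big, _ = _arrays(instrument_set)
    if g.size != 1:
        raise ValueError("wald_ratio expects exactly one SNP")
    if g[0] == 0:
        raise ValueError("exposure beta is zero: Wald ratio undefined")
    beta = big[0] / g[0]
    se = se_big[0] / abs(g[0])
    return MrEstimate.from_beta("Wald ratio", beta, se, 1)


def _ivw_fit(g, big, w):
    """Zero-intercept weighted slope plus Q (weighted residual SS)."""
    sxx = np.sum(w * g * g)
    sxy = np.sum(w * g * big)
    beta = sxy / sxx
    resid = big - beta * g
    q = float(np.sum(w * resid * resid))
    return float(beta), float(sxx), q


def ivw(
    instrument_set, effects_model: str = "multiplicative_random"
) -> tuple[MrEstimate, HeterogeneityStats]:
    """Inverse-variance-weighted estimate with Cochran Q heterogeneity."""
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ValueError("effects_model must be 'fixed' or 'multiplicative_random'")
    g, _, big, se_big, _ = _arrays(instrument_set)
    j = g.size
    if j < 1:
        raise ValueError("IVW needs at least one SNP")
    if j == 1:
        logger.info("single SNP: IVW falls back to the Wald ratio")
        est = wald_ratio(instrument_set)
        est = dataclasses.replace(est, method="IVW")
        return est, HeterogeneityStats.from_q(0.0, 0)
    w = 1.0 / se_big**2
    beta, sxx, q = _ivw_fit(g, big, w)
    se = np.sqrt(1.0 / sxx)
    if effects_model == "multiplicative_random":
        se *= max(1.0, np.sqrt(q / (j - 1)))
    est = MrEstimate.from_beta("IVW", beta, se, j)
    return est, HeterogeneityStats.from_q(q, j - 1)


def egger(instrument_set) -> tuple[MrEstimate, PleiotropyStats]:
    """MR-Egger regression: free-intercept WLS on orientation-fixed betas."""
    g, _, big, se_big, _ = _arrays(instrument_set)
    j = g.size
    if j < 3:
        raise ValueError(f"MR-Egger needs at least 3 SNPs, got {j}")
    # orient exposure effects to be non-negative
    sign = np.where(g < 0, -1.0, 1.0)
    g = g * sign
    big = big * sign
    w = 1.0 / se_big**2

    x = np.column_stack([np.ones(j), g])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * big)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = big - x @ coef
    q = float(np.sum(w * resid * resid))
    scale = max(1.0, np.sqrt(q / (j - 2)))
    cov = np.linalg.inv(xtwx) * scale**2
    se_int, se_slope = np.sqrt(np.diag(cov))

    est = MrEstimate.from_beta("MR-Egger", coef[1], se_slope, j, df=j - 2)
    p_int = float(2.0 * stats.t.sf(abs(coef[0]) / se_int, j - 2))
    pleio = PleiotropyStats(intercept=float(coef[0]), se=float(se_int), pval=max(p_int, np.nextafter(0.0, 1.0)))
    return est, pleio


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    # cumulative midpoint percentiles
    p = np.cumsum(w) - w / 2.0
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    return float(np.interp(0.5, p, r))


def weighted_median(
    instrument_set, n_boot: int = 1000, seed: int = 0
) -> MrEstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Per-SNP Wald ratios are ordered and the estimate interpolates the
    ratio at the 50th percentile of the normalized inverse-variance
    weights' cumulative midpoints.  The SE resamples exposure and outcome
    betas from their Gaussian errors ``n_boot`` times under ``seed``.
    """
    g, se_g, big, se_big, _ = _arrays(instrument_set)
    j = g.size
    if j < 3:
        raise ValueError(f"weighted median needs at least 3 SNPs, got {j}")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    ratios = big / g
    weights = (g / se_big) ** 2  # inverse variance of the ratio, first order
    point = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    g_star = g + se_g * rng.standard_normal((n_boot, j))
    big_star = big + se_big * rng.standard_normal((n_boot, j))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        r = big_star[b] / g_star[b]
        w = (g_star[b] / se_big) ** 2
        boots[b] = _weighted_median_point(r, w)
    se = float(np.std(boots, ddof=1))
    return MrEstimate.from_beta("Weighted median", point, se, j)


def leave_one_out(
    instrument_set, effects_model: str = "multiplicative_random"
) -> LeaveOneOutResult:
    """IVW re-fit excluding each SNP in turn; flags the most influential."""
    g, se_g, big, se_big, snps = _arrays(instrument_set)
    j = g.size
    if j < 3:
        raise ValueError("leave-one-out needs at least 3 SNPs")
    full, _ = ivw(instrument_set, effects_model)
    rows = []
    for i in range(j):
        keep = np.ones(j, dtype=bool)
        keep[i] = False
        sub = pd.DataFrame(
            {
                "snp": [s for k, s in enumerate(snps) if keep[k]],
                "beta_exposure": g[keep],
                "se_exposure": se_g[keep],
                "beta_outcome": big[keep],
                "se_outcome": se_big[keep],
            }
        )
        est, _ = ivw(sub, effects_model)
        rows.append(
            {
                "snp": snps[i],
                "beta": est.beta,
                "se": est.se,
                "or": est.or_point,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "delta": abs(est.beta - full.beta),
            }
        )
    table = pd.DataFrame(rows)
    table["max_influence"] = table["delta"] == table["delta"].max()
    # ensure a unique flag under exact ties (first in input order)
    first = table.index[table["max_influence"]][0]
    table["max_influence"] = table.index == first
    return LeaveOneOutResult(table=table.drop(columns="delta"))


def funnel_data(instrument_set) -> pd.DataFrame:
    """Per-SNP Wald ratios and precisions for funnel-plot rendering."""
    table = instrument_set.table if isinstance(instrument_set, HarmonizedSet) else instrument_set
    if len(table) == 0:
        return pd.DataFrame(columns=["snp", "ratio", "precision"])
    g, _, big, se_big, snps = _arrays(instrument_set)
    return pd.DataFrame(
        {"snp": snps, "ratio": big / g, "precision": np.abs(g) / se_big}
    )
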