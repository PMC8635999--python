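"""MR-PRESSO: pleiotropy residual sum and outlier detection.

The global test asks whether the instruments' weighted residuals about
leave-one-out IVW slopes are larger than expected under a homogeneous
causal model; the per-SNP outlier test localizes the excess; the
distortion test asks whether removing the flagged SNPs meaningfully
moves the causal estimate.

Observed statistic: for each SNP j, fit the IVW slope on the other J - 1
SNPs (theta_-j) and accumulate RSS_j = w_j (Gamma_j - theta_-j gamma_j)^2
with w_j = 1 / se_outcome_j^2 (the same weights as the IVW fit, for
internal consistency).  The null distribution redraws each SNP's
(gamma*, Gamma*) from normal distributions centred on
(gamma_j, theta_-j gamma_j) with the observed SEs and recomputes the
statistic the same way.  Empirical p-values use the add-one rule, so the
smallest attainable p is 1 / (n_sim + 1).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .uv import MrEstimate, HeterogeneityStats, ivw

logger = logging.getLogger(__name__)

__all__ = ["PressoConfig", "PressoResult", "presso", "rerun_after_outliers"]


@dataclasses.dataclass(frozen=True)
class PressoConfig:
    """Simulation settings for the MR-PRESSO null distribution."""

    n_sim: int = 1000
    outlier_alpha: float = 0.05
    n_distortion_subsets: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sim < 100:
            raise ValueError("n_sim must be >= 100")
        if not (0.0 < self.outlier_alpha < 1.0):
            raise ValueError("outlier_alpha must be in (0, 1)")
        if self.n_distortion_subsets < 100:
            raise ValueError("n_distortion_subsets must be >= 100")


@dataclasses.dataclass
class PressoResult:
    """Global, outlier, and distortion test results."""

    rss_obs: float
    global_p: float
    outlier_pvals: pd.Series  # Bonferroni-adjusted, indexed by SNP
    outliers: list[str]
    distortion_p: float | None
    estimate_raw: MrEstimate
    estimate_outlier_corrected: MrEstimate | None


def _loo_slopes(g: np.ndarray, big: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes for every SNP, O(J)."""
    sxx = np.sum(w * g * g)
    sxy = np.sum(w * g * big)
    return (sxy - w * g * big) / (sxx - w * g * g)


def _loo_slopes_batch(g: np.ndarray, big: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise leave-one-out slopes for a (B, J) batch of datasets."""
    wx2 = w * g * g
    wxy = w * g * big
    sxx = wx2.sum(axis=1, keepdims=True)
    sxy = wxy.sum(axis=1, keepdims=True)
    return (sxy - wxy) / (sxx - wx2)


def presso(instrument_set, config: PressoConfig = PressoConfig()) -> PressoResult:
    """Run the global, outlier, and distortion tests on a harmonized set."""
    table = getattr(instrument_set, "table", instrument_set)
    g = np.asarray(table["beta_exposure"], dtype=float)
    se_g = np.asarray(table["se_exposure"], dtype=float)
    big = np.asarray(table["beta_outcome"], dtype=float)
    se_big = np.asarray(table["se_outcome"], dtype=float)
    snps = list(table["snp"])
    j = g.size
    if j < 4:
        raise ValueError(f"MR-PRESSO needs at least 4 SNPs, got {j}")
    w = 1.0 / se_big**2

    theta_loo = _loo_slopes(g, big, w)
    resid = big - theta_loo * g
    rss_per_snp = w * resid**2
    rss_obs = float(rss_per_snp.sum())

    rng = np.random.default_rng(config.seed)
    b = config.n_sim
    g_star = g + se_g * rng.standard_normal((b, j))
    big_star = theta_loo * g + se_big * rng.standard_normal((b, j))
    theta_star = _loo_slopes_batch(g_star, big_star, np.broadcast_to(w, (b, j)))
    rss_star = w * (big_star - theta_star * g_star) ** 2  # (B, J)
    rss_star_total = rss_star.sum(axis=1)

    global_p = float((1 + np.sum(rss_star_total >= rss_obs)) / (b + 1))

    raw_p = (1 + np.sum(rss_star >= rss_per_snp, axis=0)) / (b + 1)
    adj_p = np.minimum(raw_p * j, 1.0)
    outlier_pvals = pd.Series(adj_p, index=pd.Index(snps, name="snp"), name="outlier_p")
    outliers = [s for s, p in outlier_pvals.items() if p <= config.outlier_alpha]

    estimate_raw, _ = ivw(table)

    distortion_p = None
    corrected = None
    if outliers:
        keep = ~np.isin(snps, outliers)
        reduced = pd.DataFrame(
            {
                "snp": np.asarray(snps, dtype=object)[keep],
                "beta_exposure": g[keep],
                "se_exposure": se_g[keep],
                "beta_outcome": big[keep],
                "se_outcome": se_big[keep],
            }
        )
        corrected, _ = ivw(reduced)
        n_out = len(outliers)
        if n_out < j:
            # reference distribution: estimates with random same-sized subsets removed
            obs_distortion = abs(estimate_raw.beta - corrected.beta)
            dist = np.empty(config.n_distortion_subsets)
            for i in range(config.n_distortion_subsets):
                drop = rng.choice(j, size=n_out, replace=False)
                mask = np.ones(j, dtype=bool)
                mask[drop] = False
                slope = np.sum(w[mask] * g[mask] * big[mask]) / np.sum(
                    w[mask] * g[mask] * g[mask]
                )
                dist[i] = abs(estimate_raw.beta - slope)
            distortion_p = float(
                (1 + np.sum(dist >= obs_distortion)) / (config.n_distortion_subsets + 1)
            )

    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        outlier_pvals=outlier_pvals,
        outliers=outliers,
        distortion_p=distortion_p,
        estimate_raw=estimate_raw,
        estimate_outlier_corrected=corrected,
    )


def rerun_after_outliers(instrument_set, result: PressoResult):
    """Drop flagged outliers and re-fit the univariable battery.

    Returns ``(reduced_set, battery)`` where ``battery`` maps method
    names to re-fitted results (IVW estimate plus heterogeneity, Egger
    slope plus intercept, weighted median).  With no outliers the input
    is returned unchanged with an informational notice.
    """
    from .harmonize import HarmonizedSet
    from .uv import egger, weighted_median

    if not result.outliers:
        logger.info("no outliers flagged: nothing to remove")
        return instrument_set, None

    table = getattr(instrument_set, "table", instrument_set)
    reduced_table = table.loc[~table["snp"].isin(result.outliers)].reset_index(drop=True)
    if isinstance(instrument_set, HarmonizedSet):
        reduced = dataclasses.replace(instrument_set, table=reduced_table)
    else:
        reduced = reduced_table

    est_ivw, het = ivw(reduced_table)
    battery: dict[str, object] = {"IVW": est_ivw, "heterogeneity": het}
    if len(reduced_table) >= 3:
        slope, pleio = egger(reduced_table)
        battery["MR-Egger"] = slope
        battery["egger_intercept"] = pleio
        battery["Weighted median"] = weighted_median(reduced_table)
    return reduced, battery
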