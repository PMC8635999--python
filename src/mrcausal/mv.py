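"""Multivariable MR: each exposure's direct effect conditional on the rest.

With J instruments and K exposures, the outcome betas are regressed on
the J x K matrix of exposure betas, weighted by the reciprocal outcome
variance.  mvIVW omits the intercept; mvMR-Egger adds one after
sign-flipping every SNP row so a chosen orientation exposure's betas are
non-negative (the outcome and the remaining exposures flip in tandem),
extending the univariable Egger intercept test to the multivariable
setting.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import MvInstrumentSet
from .uv import HeterogeneityStats, MrEstimate, PleiotropyStats

__all__ = ["MvMrResult", "mv_ivw", "mv_egger"]


@dataclasses.dataclass
class MvMrResult:
    """Per-exposure conditional estimates plus shared diagnostics."""

    method: str
    estimates: dict[str, MrEstimate]
    heterogeneity: HeterogeneityStats
    intercept: PleiotropyStats | None = None
    orientation: str | None = None


def _design(instrument_set: MvInstrumentSet):
    x = instrument_set.beta_exposure.to_numpy(dtype=float)
    y = instrument_set.beta_outcome.to_numpy(dtype=float)
    w = 1.0 / instrument_set.se_outcome.to_numpy(dtype=float) ** 2
    return x, y, w, list(instrument_set.exposure_names)


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        corr = np.corrcoef(x, rowvar=False)
        pairs = [
            f"{names[a]}~{names[b]}"
            for a in range(len(names))
            for b in range(a + 1, len(names))
            if abs(corr[a, b]) > 1 - 1e-10
        ]
        raise ValueError(
            "exposure beta matrix is rank deficient"
            + (f" (collinear: {', '.join(pairs)})" if pairs else "")
        )


def _wls(x, y, w):
    xtwx = x.T @ (w[:, None] * x)
    coef = np.linalg.solve(xtwx, x.T @ (w * y))
    resid = y - x @ coef
    q = float(np.sum(w * resid * resid))
    cov = np.linalg.inv(xtwx)
    return coef, cov, q


def mv_ivw(
    instrument_set: MvInstrumentSet, effects_model: str = "multiplicative_random"
) -> MvMrResult:
    """Multivariable IVW: weighted no-intercept regression on all exposures.

    Under the multiplicative random-effects model (the default) every
    SE is scaled by max(1, sqrt(Q / (J - K))).
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ValueError("effects_model must be 'fixed' or 'multiplicative_random'")
    x, y, w, names = _design(instrument_set)
    j, k = x.shape
    if j <= k:
        raise ValueError(f"need more SNPs ({j}) than exposures ({k})")
    _check_rank(x, names)
    coef, cov, q = _wls(x, y, w)
    df = j - k
    scale = max(1.0, np.sqrt(q / df)) if effects_model == "multiplicative_random" else 1.0
    ses = np.sqrt(np.diag(cov)) * scale
    estimates = {
        name: MrEstimate.from_beta(f"mvIVW[{name}]", coef[i], ses[i], j)
        for i, name in enumerate(names)
    }
    return MvMrResult(
        method="mvIVW",
        estimates=estimates,
        heterogeneity=HeterogeneityStats.from_q(q, df),
    )


def mv_egger(
    instrument_set: MvInstrumentSet, orientation: str | None = None
) -> MvMrResult:
    """Multivariable MR-Egger oriented to one exposure.

    Every SNP row is sign-flipped so the orientation exposure's betas are
    non-negative; the regression then gains a free intercept whose
    two-sided test indicates average directional pleiotropy.  Inference
    uses the t distribution with J - K - 1 df.
    """
    x, y, w, names = _design(instrument_set)
    j, k = x.shape
    if orientation is None:
        orientation = names[0]
    if orientation not in names:
        raise ValueError(f"unknown orientation exposure {orientation!r}; have {names}")
    if j <= k + 1:
        raise ValueError(f"need more SNPs ({j}) than exposures plus intercept ({k + 1})")
    _check_rank(x, names)

    ref = names.index(orientation)
    sign = np.where(x[:, ref] < 0, -1.0, 1.0)
    xs = x * sign[:, None]
    ys = y * sign

    design = np.column_stack([np.ones(j), xs])
    coef, cov, q = _wls(design, ys, w)
    df = j - k - 1
    scale = max(1.0, np.sqrt(q / df))
    ses = np.sqrt(np.diag(cov)) * scale

    estimates = {
        name: MrEstimate.from_beta(f"mvMR-Egger[{name}]", coef[i + 1], ses[i + 1], j, df=df)
        for i, name in enumerate(names)
    }
    p_int = float(2.0 * stats.t.sf(abs(coef[0]) / ses[0], df))
    intercept = PleiotropyStats(
        intercept=float(coef[0]), se=float(ses[0]), pval=max(p_int, np.nextafter(0.0, 1.0))
    )
    return MvMrResult(
        method="mvMR-Egger",
        estimates=estimates,
        heterogeneity=HeterogeneityStats.from_q(q, df),
        intercept=intercept,
        orientation=orientation,
    )
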