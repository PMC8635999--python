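"""Cross-trait LD score regression at desk scale.

Univariate heritability: weighted regression of z^2 on N * l_j / M with a
free intercept; the slope estimates SNP heritability and the intercept
absorbs confounding inflation.  Cross-trait genetic covariance: the same
regression of z1 * z2 on sqrt(N1 N2) * l_j / M, whose intercept absorbs
sample overlap.  Genetic correlation rg = gencov / sqrt(h2_1 * h2_2).

Weighting is a single heteroskedasticity iteration: a first pass with
crude stabilizing weights 1/(1 + x_j)^2 (x_j the regressor; under the
model the response variance grows like (1 + h2 x_j)^2, so these damp the
heavy right tail of the LD score distribution for any h2) supplies slope
and intercept estimates, from which per-SNP variance weights 1/a_i^2
(univariate, a_i = int_i + N_i h2_i l_j / M) and 1/(a_1 a_2 + c^2)
(bivariate, c = int_12 + sqrt(N1 N2) gencov l_j / M) are formed for the
second pass.  Standard errors come from a delete-one
block jackknife over contiguous SNP blocks, with rg pseudo-values
recomputing all three regressions per deleted block.

A genetic correlation is only meaningful on the scale of two positive
heritabilities.  When either heritability estimate is non-positive, or
not distinguishable from zero at the 95% level (point estimate below
1.96 jackknife SEs), the result is reported as undefined (NaN rg, SE,
and p with ``defined=False``) rather than as a number.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

__all__ = ["LdscInput", "LdscResult", "ldsc_h2", "ldsc_rg"]


@dataclasses.dataclass(frozen=True)
class LdscInput:
    """Per-SNP z-scores for two traits with their shared LD scores."""

    z1: np.ndarray
    z2: np.ndarray
    ld_scores: np.ndarray
    n1: int
    n2: int
    n_overlap: int = 0
    m: int | None = None  # total SNPs behind the LD scores; defaults to len(z1)

    def __post_init__(self) -> None:
        z1 = np.asarray(self.z1, dtype=float)
        z2 = np.asarray(self.z2, dtype=float)
        ell = np.asarray(self.ld_scores, dtype=float)
        if not (z1.shape == z2.shape == ell.shape):
            raise ValueError("z1, z2 and ld_scores must have equal length")
        if np.any(ell < 0):
            raise ValueError("LD scores must be non-negative")


def _default_blocks(m: int, n_blocks: int | None) -> int:
    if n_blocks is not None:
        return n_blocks
    return 200 if m >= 1000 else max(2, m // 5)


def _block_bounds(m: int, n_blocks: int) -> list[tuple[int, int]]:
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    return [(edges[i], edges[i + 1]) for i in range(n_blocks)]


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted straight-line fit; returns (intercept, slope)."""
    design = np.column_stack([np.ones_like(x), x])
    xtwx = design.T @ (w[:, None] * design)
    coef = np.linalg.solve(xtwx, design.T @ (w * y))
    return float(coef[0]), float(coef[1])


def _block_accumulators(x, y, w, bounds):
    """Per-block X'WX (2x2) and X'Wy for fast delete-one-block re-fits."""
    design = np.column_stack([np.ones_like(x), x])
    wx = w[:, None] * design
    a_blocks = np.empty((len(bounds), 2, 2))
    c_blocks = np.empty((len(bounds), 2))
    for i, (lo, hi) in enumerate(bounds):
        a_blocks[i] = design[lo:hi].T @ wx[lo:hi]
        c_blocks[i] = wx[lo:hi].T @ y[lo:hi]
    return a_blocks, c_blocks


def _jackknife_slopes(a_blocks, c_blocks):
    """Delete-one-block (intercept, slope) for every block."""
    a_tot = a_blocks.sum(axis=0)
    c_tot = c_blocks.sum(axis=0)
    out = np.empty((len(a_blocks), 2))
    for i in range(len(a_blocks)):
        out[i] = np.linalg.solve(a_tot - a_blocks[i], c_tot - c_blocks[i])
    return out  # columns: intercept, slope


def _jackknife_se(pseudo: np.ndarray) -> float:
    b = pseudo.size
    return float(np.sqrt((b - 1) / b * np.sum((pseudo - pseudo.mean()) ** 2)))


def _h2_weights(x: np.ndarray, intercept: float, slope: float) -> np.ndarray:
    a = np.maximum(intercept + slope * x, 0.05)
    return 1.0 / a**2


def _first_pass_weights(x: np.ndarray) -> np.ndarray:
    # response variance grows ~ (1 + h2 x)^2; 1/(1+x)^2 is a stable stand-in
    return 1.0 / (1.0 + x) ** 2


def ldsc_h2(
    z: np.ndarray,
    ld_scores: np.ndarray,
    n: int,
    m: int | None = None,
    n_blocks: int | None = None,
) -> tuple[float, float, float]:
    """Estimate SNP heritability from one trait's z-scores.

    Returns ``(h2, jackknife_se, intercept)``.
    """
    z = np.asarray(z, dtype=float)
    ell = np.asarray(ld_scores, dtype=float)
    m_total = m if m is not None else z.size
    n_blocks = _default_blocks(z.size, n_blocks)
    if z.size < n_blocks or n_blocks < 2:
        raise ValueError("need at least n_blocks >= 2 SNPs")
    if np.allclose(ell, ell[0]):
        raise ValueError("constant LD scores: heritability slope unidentifiable")

    x = n * ell / m_total
    y = z**2
    int0, slope0 = _wls_line(x, y, _first_pass_weights(x))
    w = _h2_weights(x, int0, slope0)
    intercept, slope = _wls_line(x, y, w)

    bounds = _block_bounds(z.size, n_blocks)
    a_blocks, c_blocks = _block_accumulators(x, y, w, bounds)
    pseudo = _jackknife_slopes(a_blocks, c_blocks)[:, 1]
    return slope, _jackknife_se(pseudo), intercept


@dataclasses.dataclass
class LdscResult:
    """Heritabilities, genetic covariance and correlation with jackknife SEs."""

    h2_1: float
    h2_1_se: float
    h2_2: float
    h2_2_se: float
    gencov: float
    gencov_se: float
    rg: float
    rg_se: float
    rg_pval: float
    intercept_1: float
    intercept_2: float
    intercept_cross: float
    defined: bool
    n_blocks: int


def ldsc_rg(input_data: LdscInput, n_blocks: int | None = None) -> LdscResult:
    """Cross-trait genetic correlation with block-jackknife uncertainty.

    ``defined`` is False (and rg, its SE and p are NaN) whenever either
    heritability estimate is non-positive or within 1.96 jackknife SEs of
    zero; |rg| > 1 in noisy but defined estimates is reported as-is.
    """
    z1 = np.asarray(input_data.z1, dtype=float)
    z2 = np.asarray(input_data.z2, dtype=float)
    ell = np.asarray(input_data.ld_scores, dtype=float)
    m_total = input_data.m if input_data.m is not None else z1.size
    m = z1.size
    n_blocks = _default_blocks(m, n_blocks)
    if m < n_blocks or n_blocks < 2:
        raise ValueError("need at least n_blocks >= 2 SNPs")
    if np.allclose(ell, ell[0]):
        raise ValueError("constant LD scores: slopes unidentifiable")

    n1, n2 = input_data.n1, input_data.n2
    x1 = n1 * ell / m_total
    x2 = n2 * ell / m_total
    xc = math.sqrt(n1 * n2) * ell / m_total
    y1 = z1**2
    y2 = z2**2
    yc = z1 * z2

    i1_0, s1_0 = _wls_line(x1, y1, _first_pass_weights(x1))
    i2_0, s2_0 = _wls_line(x2, y2, _first_pass_weights(x2))
    ic_0, sc_0 = _wls_line(xc, yc, _first_pass_weights(xc))

    a1 = np.maximum(i1_0 + s1_0 * x1, 0.05)
    a2 = np.maximum(i2_0 + s2_0 * x2, 0.05)
    c = ic_0 + sc_0 * xc
    w1 = 1.0 / a1**2
    w2 = 1.0 / a2**2
    wc = 1.0 / (a1 * a2 + c**2)

    int1, h2_1 = _wls_line(x1, y1, w1)
    int2, h2_2 = _wls_line(x2, y2, w2)
    intc, gencov = _wls_line(xc, yc, wc)

    bounds = _block_bounds(m, n_blocks)
    jk1 = _jackknife_slopes(*_block_accumulators(x1, y1, w1, bounds))[:, 1]
    jk2 = _jackknife_slopes(*_block_accumulators(x2, y2, w2, bounds))[:, 1]
    jkc = _jackknife_slopes(*_block_accumulators(xc, yc, wc, bounds))[:, 1]

    h2_1_se = _jackknife_se(jk1)
    h2_2_se = _jackknife_se(jk2)
    gencov_se = _jackknife_se(jkc)

    def usable(h2, se):
        return h2 > 0 and h2 > 1.96 * se

    defined = usable(h2_1, h2_1_se) and usable(h2_2, h2_2_se)
    if defined:
        rg = gencov / math.sqrt(h2_1 * h2_2)
        with np.errstate(invalid="ignore"):
            prod = jk1 * jk2
            rg_pseudo = np.where(prod > 0, jkc / np.sqrt(np.abs(prod)), np.nan)
        if np.any(~np.isfinite(rg_pseudo)):
            # fall back to delta-free pseudo-values only where defined
            rg_pseudo = rg_pseudo[np.isfinite(rg_pseudo)]
        rg_se = _jackknife_se(np.asarray(rg_pseudo))
        rg_pval = float(2.0 * stats.norm.sf(abs(rg) / rg_se)) if rg_se > 0 else 0.0
    else:
        rg = rg_se = rg_pval = float("nan")

    return LdscResult(
        h2_1=h2_1,
        h2_1_se=h2_1_se,
        h2_2=h2_2,
        h2_2_se=h2_2_se,
        gencov=gencov,
        gencov_se=gencov_se,
        rg=rg,
        rg_se=rg_se,
        rg_pval=rg_pval,
        intercept_1=int1,
        intercept_2=int2,
        intercept_cross=intc,
        defined=defined,
        n_blocks=n_blocks,
    )
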