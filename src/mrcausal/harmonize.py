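"""Instrument selection, allele harmonization, and instrument strength.

Selection follows the standard genome-wide pipeline: keep SNPs with
p < 5e-8 in the exposure GWAS, then greedily clump so retained instruments
are mutually independent below an r^2 threshold (default 1e-4).
Harmonization aligns exposure and outcome records to a common effect
allele, resolving swapped effect/other alleles and complementary-strand
codings, and removes palindromic (A/T or C/G) SNPs whose allele frequency
is too close to 0.5 for the strand to be inferred.

Instrument strength uses the summary-data approximations
r2_j = 2 * EAF_j * (1 - EAF_j) * beta_j^2, R^2 = sum_j r2_j and
F = R^2 * (N - 2) / (1 - R^2).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "HarmonizedSet",
    "MvInstrumentSet",
    "InstrumentStrength",
    "select_instruments",
    "harmonize",
    "build_mv_instruments",
    "instrument_strength",
    "f_statistic",
    "mr_power",
    "bonferroni_alpha",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: columns of the harmonized per-SNP table
HARMONIZED_COLUMNS = [
    "snp",
    "effect_allele",
    "other_allele",
    "beta_exposure",
    "se_exposure",
    "eaf_exposure",
    "beta_outcome",
    "se_outcome",
    "eaf_outcome",
    "allele_swapped",
    "strand_flipped",
]


@dataclasses.dataclass
class HarmonizedSet:
    """Exposure and outcome effects aligned to a common effect allele.

    ``table`` holds one row per retained SNP (columns
    :data:`HARMONIZED_COLUMNS`); ``dropped`` records every excluded SNP
    with a ``reason`` in {"palindromic", "unmatched"}.
    """

    table: pd.DataFrame
    dropped: pd.DataFrame
    n_input: int
    n_dropped_palindromic: int
    n_unmatched: int

    @property
    def n_retained(self) -> int:
        return len(self.table)

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @classmethod
    def from_arrays(
        cls,
        beta_exposure,
        se_exposure,
        beta_outcome,
        se_outcome,
        snp=None,
        eaf=None,
    ) -> "HarmonizedSet":
        """Build a set directly from aligned effect arrays (no allele work)."""
        beta_exposure = np.atleast_1d(np.asarray(beta_exposure, dtype=float))
        j = beta_exposure.size
        broadcast = lambda v: np.broadcast_to(np.asarray(v, dtype=float), j)
        table = pd.DataFrame(
            {
                "snp": snp if snp is not None else [f"rs{i + 1}" for i in range(j)],
                "effect_allele": "A",
                "other_allele": "G",
                "beta_exposure": beta_exposure,
                "se_exposure": broadcast(se_exposure),
                "eaf_exposure": eaf if eaf is not None else 0.5,
                "beta_outcome": broadcast(beta_outcome),
                "se_outcome": broadcast(se_outcome),
                "eaf_outcome": eaf if eaf is not None else 0.5,
                "allele_swapped": False,
                "strand_flipped": False,
            }
        )
        empty = pd.DataFrame(columns=["snp", "reason"])
        return cls(table, empty, n_input=j, n_dropped_palindromic=0, n_unmatched=0)


@dataclasses.dataclass
class MvInstrumentSet:
    """Joint instrument set for several exposures against one outcome.

    ``beta_exposure``/``se_exposure`` are J x K frames indexed by SNP with
    one column per exposure; ``significant`` flags which exposures each
    SNP reached genome-wide significance for.  ``source`` holds, per SNP,
    the exposure with the smallest p-value (its beta/EAF feed the
    variance-explained bookkeeping).
    """

    snps: list[str]
    exposure_names: list[str]
    beta_exposure: pd.DataFrame
    se_exposure: pd.DataFrame
    beta_outcome: pd.Series
    se_outcome: pd.Series
    eaf: pd.Series
    beta_source: pd.Series
    significant: pd.DataFrame
    source: pd.Series
    n_union: int
    n_duplicates_removed: int
    n_dropped_palindromic: int

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_retained(self) -> int:
        return len(self.snps)

    @classmethod
    def from_arrays(
        cls,
        beta_exposure,
        se_exposure,
        beta_outcome,
        se_outcome,
        exposure_names: Sequence[str] | None = None,
        snps: Sequence[str] | None = None,
        eaf=None,
    ) -> "MvInstrumentSet":
        """Build a set from aligned J x K effect arrays (no allele work)."""
        bx = np.atleast_2d(np.asarray(beta_exposure, dtype=float))
        if bx.shape[0] == 1 and np.asarray(beta_outcome).size != 1:
            bx = bx.T
        j, k = bx.shape
        sx = np.broadcast_to(np.asarray(se_exposure, dtype=float), bx.shape)
        names = list(exposure_names) if exposure_names is not None else [f"x{i+1}" for i in range(k)]
        ids = list(snps) if snps is not None else [f"rs{i+1}" for i in range(j)]
        index = pd.Index(ids, name="snp")
        eaf_s = pd.Series(
            np.broadcast_to(np.asarray(0.5 if eaf is None else eaf, dtype=float), j),
            index=index,
        )
        return cls(
            snps=ids,
            exposure_names=names,
            beta_exposure=pd.DataFrame(bx, index=index, columns=names),
            se_exposure=pd.DataFrame(np.array(sx), index=index, columns=names),
            beta_outcome=pd.Series(np.asarray(beta_outcome, dtype=float), index=index),
            se_outcome=pd.Series(
                np.broadcast_to(np.asarray(se_outcome, dtype=float), j), index=index
            ),
            eaf=eaf_s,
            beta_source=pd.Series(bx[:, 0], index=index),
            significant=pd.DataFrame(True, index=index, columns=names),
            source=pd.Series(names[0], index=index),
            n_union=j,
            n_duplicates_removed=0,
            n_dropped_palindromic=0,
        )


@dataclasses.dataclass(frozen=True)
class InstrumentStrength:
    """Summary-data variance explained and F statistics for an instrument set."""

    per_snp_r2: pd.Series
    r2: float
    f_stat: float
    per_snp_f: pd.Series
    n: int


def _check_unique(stats_table: pd.DataFrame, label: str) -> None:
    dup = stats_table["snp"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate SNP identifiers in {label} table: "
            f"{sorted(stats_table.loc[dup, 'snp'].unique())}"
        )


def select_instruments(
    stats_table: pd.DataFrame,
    p_threshold: float = 5e-8,
    ld: pd.DataFrame | None = None,
    r2_threshold: float = 1e-4,
) -> list[str]:
    """Significance filter plus greedy LD clumping.

    Significant SNPs are visited in order of ascending p-value (ties
    broken lexicographically by identifier); a SNP is kept iff its r^2
    with every already-kept SNP is below ``r2_threshold``.  When no LD
    matrix is supplied all significant SNPs are treated as independent.
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must be in (0, 1)")
    if not (0.0 <= r2_threshold <= 1.0):
        raise ValueError("r2_threshold must be in [0, 1]")
    _check_unique(stats_table, "association")

    sig = stats_table.loc[stats_table["pval"] < p_threshold, ["snp", "pval"]]
    if sig.empty:
        logger.warning("no SNP passed p < %.3g; returning empty instrument list", p_threshold)
        return []
    sig = sig.sort_values(["pval", "snp"], kind="mergesort")

    if ld is None:
        return sig["snp"].tolist()

    missing = [s for s in sig["snp"] if s not in ld.index or s not in ld.columns]
    if missing:
        raise KeyError(f"LD matrix does not cover significant SNP(s): {missing}")

    kept: list[str] = []
    for snp in sig["snp"]:
        if all(float(ld.loc[snp, k]) < r2_threshold for k in kept):
            kept.append(snp)
    return kept


def _classify_pair(ea_x, oa_x, ea_y, oa_y):
    """Return (action, strand_flipped) aligning one outcome record.

    action: 'same' | 'swap' | 'unmatched'; palindromic pairs are handled
    by the caller because allele letters cannot resolve their strand.
    """
    if (ea_y, oa_y) == (ea_x, oa_x):
        return "same", False
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "swap", False
    c_ea, c_oa = _COMPLEMENT[ea_y], _COMPLEMENT[oa_y]
    if (c_ea, c_oa) == (ea_x, oa_x):
        return "same", True
    if (c_ea, c_oa) == (oa_x, ea_x):
        return "swap", True
    return "unmatched", False


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_window: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedSet:
    """Align outcome records to the exposure's effect-allele coding.

    For each SNP present in both tables: identical allele pairs are kept
    as-is; swapped effect/other alleles negate the outcome beta and
    reflect its EAF; complementary-strand codings are mapped via A<->T,
    C<->G first.  Palindromic pairs with either trait's EAF inside
    ``palindrome_window`` are dropped (strand genuinely ambiguous);
    outside the window they are aligned by comparing which side of 0.5
    the frequencies fall on.  Irreconcilable allele pairs are dropped as
    unmatched.
    """
    lo, hi = palindrome_window
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("palindrome_window must be an interval within [0, 1]")
    _check_unique(exposure, "exposure")
    _check_unique(outcome, "outcome")

    merged = exposure.merge(outcome, on="snp", suffixes=("_x", "_y"), how="inner")

    rows = []
    dropped = []
    n_pal = 0
    n_unmatched = 0
    for rec in merged.itertuples(index=False):
        ea_x, oa_x = rec.effect_allele_x, rec.other_allele_x
        ea_y, oa_y = rec.effect_allele_y, rec.other_allele_y
        pal_x = _COMPLEMENT.get(ea_x) == oa_x
        pal_y = _COMPLEMENT.get(ea_y) == oa_y

        beta_y, eaf_y = rec.beta_y, rec.eaf_y
        swapped = False
        flipped = False
        if pal_x or pal_y:
            if not (pal_x and pal_y and {ea_x, oa_x} == {ea_y, oa_y}):
                dropped.append((rec.snp, "unmatched"))
                n_unmatched += 1
                continue
            in_window = (lo <= rec.eaf_x <= hi) or (lo <= eaf_y <= hi)
            if in_window:
                dropped.append((rec.snp, "palindromic"))
                n_pal += 1
                continue
            # align by frequency: same side of 0.5 means same effect allele
            if (rec.eaf_x - 0.5) * (eaf_y - 0.5) < 0:
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y
                swapped = True
        else:
            action, flipped = _classify_pair(ea_x, oa_x, ea_y, oa_y)
            if action == "unmatched":
                dropped.append((rec.snp, "unmatched"))
                n_unmatched += 1
                continue
            if action == "swap":
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y
                swapped = True

        rows.append(
            (
                rec.snp, ea_x, oa_x,
                rec.beta_x, rec.se_x, rec.eaf_x,
                beta_y, rec.se_y, eaf_y,
                swapped, flipped,
            )
        )

    table = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    dropped_df = pd.DataFrame(dropped, columns=["snp", "reason"])
    n_missing = len(exposure) - len(merged)
    if n_missing:
        logger.info("%d exposure SNP(s) absent from the outcome table", n_missing)
    return HarmonizedSet(
        table=table,
        dropped=dropped_df,
        n_input=len(merged),
        n_dropped_palindromic=n_pal,
        n_unmatched=n_unmatched,
    )


def build_mv_instruments(
    exposures: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
    outcome: pd.DataFrame,
    p_threshold: float = 5e-8,
    ld: pd.DataFrame | None = None,
    r2_threshold: float = 1e-4,
    palindrome_window: tuple[float, float] = (0.42, 0.58),
) -> MvInstrumentSet:
    """Union the exposures' clumped instruments and harmonize jointly.

    Per-exposure significant, clumped SNP lists are merged; duplicates
    (and SNPs in mutual LD at or above ``r2_threshold`` across lists) are
    resolved by keeping the occurrence with the smallest p-value.  Betas
    and SEs for every retained SNP are extracted from every exposure
    table (aligned to the best-p exposure's allele coding), and the set
    is harmonized once against the outcome.
    """
    if not isinstance(exposures, Mapping):
        exposures = {f"x{k + 1}": t for k, t in enumerate(exposures)}
    names = list(exposures)
    if len(names) < 2:
        raise ValueError("multivariable instrument construction needs >= 2 exposures")

    pooled = []
    for name, table in exposures.items():
        kept = select_instruments(table, p_threshold, ld, r2_threshold)
        sub = table.set_index("snp").loc[kept]
        for snp, p in sub["pval"].items():
            pooled.append((snp, name, p))
    pooled_df = pd.DataFrame(pooled, columns=["snp", "exposure", "pval"])
    n_union = len(pooled_df)
    pooled_df = pooled_df.sort_values(["pval", "snp"], kind="mergesort")

    # lowest-p occurrence wins; greedy cross-list LD pruning when ld given
    chosen: dict[str, str] = {}
    for rec in pooled_df.itertuples(index=False):
        if rec.snp in chosen:
            continue
        if ld is not None and any(
            float(ld.loc[rec.snp, k]) >= r2_threshold for k in chosen if k != rec.snp
        ):
            continue
        chosen[rec.snp] = rec.exposure
    n_dup = n_union - len(chosen)

    indexed = {name: t.set_index("snp") for name, t in exposures.items()}

    rows = []
    for snp, src in chosen.items():
        ref = indexed[src].loc[snp]
        entry = {
            "snp": snp,
            "effect_allele": ref["effect_allele"],
            "other_allele": ref["other_allele"],
            "eaf": ref["eaf"],
            "source": src,
            "beta_source": ref["beta"],
        }
        ok = True
        for name in names:
            tab = indexed[name]
            if snp not in tab.index:
                logger.warning("SNP %s missing from exposure %s; dropped", snp, name)
                ok = False
                break
            rec = tab.loc[snp]
            pal = _COMPLEMENT.get(entry["effect_allele"]) == entry["other_allele"]
            if pal:
                same_pair = {rec["effect_allele"], rec["other_allele"]} == {
                    entry["effect_allele"], entry["other_allele"]
                }
                if not same_pair:
                    ok = False
                else:
                    sign = 1.0 if (rec["eaf"] - 0.5) * (entry["eaf"] - 0.5) >= 0 else -1.0
                    entry[f"beta_{name}"] = sign * rec["beta"]
                    entry[f"se_{name}"] = rec["se"]
                    entry[f"sig_{name}"] = rec["pval"] < p_threshold
            else:
                action, _ = _classify_pair(
                    entry["effect_allele"], entry["other_allele"],
                    rec["effect_allele"], rec["other_allele"],
                )
                if action == "unmatched":
                    ok = False
                else:
                    sign = -1.0 if action == "swap" else 1.0
                    entry[f"beta_{name}"] = sign * rec["beta"]
                    entry[f"se_{name}"] = rec["se"]
                    entry[f"sig_{name}"] = rec["pval"] < p_threshold
            if not ok:
                logger.warning(
                    "SNP %s alleles irreconcilable across exposures; dropped", snp
                )
                break
        if ok:
            rows.append(entry)

    wide = pd.DataFrame(rows)

    # joint harmonization against the outcome, palindromic removal once
    pseudo_exposure = wide[["snp", "effect_allele", "other_allele", "eaf", "beta_source"]].copy()
    pseudo_exposure = pseudo_exposure.rename(columns={"beta_source": "beta"})
    pseudo_exposure["se"] = 1.0
    pseudo_exposure["pval"] = 0.5
    pseudo_exposure["n"] = 0
    hset = harmonize(pseudo_exposure, outcome, palindrome_window)
    retained = hset.table.set_index("snp")

    wide = wide.set_index("snp").loc[retained.index]
    beta_x = wide[[f"beta_{n}" for n in names]].astype(float)
    beta_x.columns = names
    se_x = wide[[f"se_{n}" for n in names]].astype(float)
    se_x.columns = names
    sig = wide[[f"sig_{n}" for n in names]].astype(bool)
    sig.columns = names

    return MvInstrumentSet(
        snps=list(retained.index),
        exposure_names=names,
        beta_exposure=beta_x,
        se_exposure=se_x,
        beta_outcome=retained["beta_outcome"].astype(float),
        se_outcome=retained["se_outcome"].astype(float),
        eaf=wide["eaf"].astype(float),
        beta_source=wide["beta_source"].astype(float),
        significant=sig,
        source=wide["source"],
        n_union=n_union,
        n_duplicates_removed=n_dup,
        n_dropped_palindromic=hset.n_dropped_palindromic,
    )


def f_statistic(r2: float, n: int) -> float:
    """Overall instrument F from total variance explained: R2*(N-2)/(1-R2)."""
    if not (0.0 <= r2 < 1.0):
        raise ValueError("R^2 must lie in [0, 1)")
    if n <= 2:
        raise ValueError("sample size must exceed 2")
    return r2 * (n - 2) / (1.0 - r2)


def instrument_strength(
    instrument_set: HarmonizedSet | MvInstrumentSet, n: int
) -> InstrumentStrength:
    """Per-SNP and total variance explained plus F statistics.

    r2_j = 2 EAF_j (1 - EAF_j) beta_j^2 summed over the instrument set;
    ``n`` is the exposure GWAS sample size.  For a multivariable set each
    SNP contributes through its best-p exposure's beta and EAF.
    """
    if isinstance(instrument_set, MvInstrumentSet):
        eaf = instrument_set.eaf
        beta = instrument_set.beta_source
        index = pd.Index(instrument_set.snps, name="snp")
    else:
        t = instrument_set.table
        eaf = t["eaf_exposure"]
        beta = t["beta_exposure"]
        index = pd.Index(t["snp"], name="snp")
    r2_per = pd.Series(
        2.0 * np.asarray(eaf, dtype=float) * (1.0 - np.asarray(eaf, dtype=float))
        * np.asarray(beta, dtype=float) ** 2,
        index=index,
        name="r2",
    )
    r2 = float(r2_per.sum())
    if r2 >= 1.0:
        raise ValueError("total R^2 >= 1: degenerate input")
    f_per = r2_per.apply(lambda r: f_statistic(r, n))
    return InstrumentStrength(
        per_snp_r2=r2_per, r2=r2, f_stat=f_statistic(r2, n), per_snp_f=f_per, n=n
    )


def mr_power(
    n: int,
    r2: float,
    effect: float,
    alpha: float = 0.05,
    binary: bool = False,
    case_fraction: float | None = None,
) -> float:
    """Asymptotic two-sided power of an MR test on the outcome sample.

    Follows the closed-form calculation of the mRnd online calculator:
    the Wald test non-centrality is N * R2 * b^2 for a continuous
    outcome, attenuated by K(1-K) for a binary (case-control) outcome
    analysed on the log-odds scale, where b is the hypothesized effect
    (log odds ratio when binary) and R2 the instrument variance explained
    on the exposure.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if not (0.0 <= r2 < 1.0):
        raise ValueError("r2 must be in [0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    if binary:
        if case_fraction is None:
            raise ValueError("case_fraction is required for a binary outcome")
        if not (0.0 < case_fraction < 1.0):
            raise ValueError("case_fraction must be in (0, 1)")
        b = math.log(effect) if effect > 0 else float("nan")
        if not math.isfinite(b):
            raise ValueError("binary effect must be a positive odds ratio")
        ncp = n * r2 * case_fraction * (1.0 - case_fraction) * b**2
    else:
        ncp = n * r2 * effect**2
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    drift = math.sqrt(ncp)
    return float(stats.norm.sf(z - drift) + stats.norm.cdf(-z - drift))


def bonferroni_alpha(family_alpha: float, n_tests: int) -> float:
    """Per-test significance level controlling the family-wise error rate."""
    if not (0.0 < family_alpha < 1.0):
        raise ValueError("family_alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests
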