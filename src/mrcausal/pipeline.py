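"""Orchestration of the full bidirectional MR design.

A single configuration drives: forward univariable MR of each exposure on
the outcome, reverse univariable MR of the outcome on each exposure,
multivariable MR of all exposures jointly, and (when z-scores with LD
scores are supplied) cross-trait LD score regression.  Each
exposure-outcome pair runs the whole battery - instrument selection,
harmonization, IVW, MR-Egger, weighted median, MR-PRESSO, Cochran Q/I^2,
leave-one-out, and funnel coordinates - with SNP attrition logged at
every stage (input -> significant -> clumped -> harmonized).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as mrio
from .harmonize import (
    HarmonizedSet,
    build_mv_instruments,
    harmonize,
    instrument_strength,
    mr_power,
    select_instruments,
)
from .ldsc import LdscInput, ldsc_rg
from .mv import mv_egger, mv_ivw
from .presso import PressoConfig, presso
from .uv import egger, funnel_data, ivw, leave_one_out, weighted_median

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "ReportBundle", "run_bidirectional", "write_report"]

EN_DASH = "–"


@dataclasses.dataclass
class AnalysisConfig:
    """Thresholds, directions, and input locations for a full run."""

    direction: str = "both"  # forward | reverse | both
    p_threshold: float = 5e-8
    clump_r2: float = 1e-4
    palindrome_window: tuple[float, float] = (0.42, 0.58)
    alpha: float = 0.017
    effects_model: str = "multiplicative_random"
    presso_n_sim: int = 1000
    wm_n_boot: int = 1000
    power_effect_or: float = 1.1
    seed: int = 0
    exposure_paths: dict[str, str] | None = None
    outcome_path: str | None = None
    outcome_name: str = "outcome"
    outcome_binary: bool = True
    case_fraction: float = 60_620 / 1_030_836
    ld_path: str | None = None
    ldsc_path: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse", "both"):
            raise ValueError("direction must be forward, reverse, or both")
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0, 1)")
        if not (0.0 <= self.clump_r2 <= 1.0):
            raise ValueError("clump_r2 must be in [0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a flat key-value (YAML mapping) configuration file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        exposures = raw.pop("exposures", None)
        window = raw.pop("palindrome_window", None)
        cfg = {k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}}
        unknown = set(raw) - set(cfg)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if exposures is not None:
            cfg["exposure_paths"] = dict(exposures)
        if window is not None:
            if isinstance(window, str):
                lo, hi = window.split(":")
                window = (float(lo), float(hi))
            cfg["palindrome_window"] = tuple(window)
        return cls(**cfg)


@dataclasses.dataclass
class ReportBundle:
    """Everything a run produced, ready for the report writer."""

    uv_results: pd.DataFrame
    mv_results: pd.DataFrame | None
    strength: pd.DataFrame
    attrition: pd.DataFrame
    leave_one_out: dict[str, pd.DataFrame]
    funnel: dict[str, pd.DataFrame]
    ldsc: pd.DataFrame | None
    log_lines: list[str]
    alpha: float
    seed: int


def _fmt_or(or_point: float, lo: float, hi: float) -> str:
    return f"{or_point:.3f} ({lo:.3f}{EN_DASH}{hi:.3f})"


def _uv_row(direction, exposure, outcome, est, het=None, pleio=None, global_p=None, alpha=0.017):
    return {
        "direction": direction,
        "exposure": exposure,
        "outcome": outcome,
        "method": est.method,
        "n_snps": est.n_snps,
        "beta": est.beta,
        "se": est.se,
        "or": est.or_point,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "or_ci": _fmt_or(est.or_point, est.ci_low, est.ci_high),
        "pval": est.pval,
        "q": het.q if het else np.nan,
        "q_pval": het.q_pval if het else np.nan,
        "i2": het.i2 if het else np.nan,
        "intercept": pleio.intercept if pleio else np.nan,
        "intercept_pval": pleio.pval if pleio else np.nan,
        "global_pval": global_p if global_p is not None else np.nan,
        "significant": est.pval < alpha,
    }


def _pair_battery(direction, exp_name, out_name, exp_table, out_table, cfg, ld, bundle_parts):
    """Run the full univariable battery for one exposure-outcome pair."""
    rows, attrition, loo_tables, funnel_tables, strength_rows, log = bundle_parts
    n_total = len(exp_table)
    kept = select_instruments(exp_table, cfg.p_threshold, ld, cfg.clump_r2)
    n_sig = int((exp_table["pval"] < cfg.p_threshold).sum())
    n_clumped_away = n_sig - len(kept)
    if not kept:
        log.append(
            f"[{direction}] {exp_name}->{out_name}: no instruments after filtering; skipped"
        )
        logger.warning("no instruments for %s -> %s; analysis skipped", exp_name, out_name)
        return
    sub = exp_table.loc[exp_table["snp"].isin(kept)]
    hset = harmonize(sub, out_table, cfg.palindrome_window)
    n_missing = len(kept) - hset.n_input
    attrition.append(
        {
            "direction": direction,
            "exposure": exp_name,
            "outcome": out_name,
            "n_input": n_total,
            "n_not_significant": n_total - n_sig,
            "n_clumped_away": n_clumped_away,
            "n_missing_outcome": n_missing,
            "n_dropped_palindromic": hset.n_dropped_palindromic,
            "n_unmatched": hset.n_unmatched,
            "n_retained": hset.n_retained,
        }
    )
    log.append(
        f"[{direction}] {exp_name}->{out_name}: {n_total} input, {n_sig} significant, "
        f"{len(kept)} after clumping, {hset.n_dropped_palindromic} palindromic dropped, "
        f"{hset.n_unmatched} unmatched, {hset.n_retained} retained"
    )
    if hset.n_retained == 0:
        log.append(f"[{direction}] {exp_name}->{out_name}: empty harmonized set; skipped")
        return

    key = f"{direction}_{exp_name}_vs_{out_name}"
    est_ivw, het = ivw(hset, cfg.effects_model)
    rows.append(_uv_row(direction, exp_name, out_name, est_ivw, het=het, alpha=cfg.alpha))
    if hset.n_retained >= 3:
        est_egger, pleio = egger(hset)
        rows.append(_uv_row(direction, exp_name, out_name, est_egger, pleio=pleio, alpha=cfg.alpha))
        est_wm = weighted_median(hset, cfg.wm_n_boot, seed=cfg.seed)
        rows.append(_uv_row(direction, exp_name, out_name, est_wm, alpha=cfg.alpha))
        loo_tables[key] = leave_one_out(hset, cfg.effects_model).table
    if hset.n_retained >= 4:
        pres = presso(hset, PressoConfig(n_sim=cfg.presso_n_sim, seed=cfg.seed))
        est = pres.estimate_outlier_corrected or pres.estimate_raw
        row = _uv_row(direction, exp_name, out_name, est, global_p=pres.global_p, alpha=cfg.alpha)
        row["method"] = "MR-PRESSO"
        row["n_outliers"] = len(pres.outliers)
        rows.append(row)
    funnel_tables[key] = funnel_data(hset)

    n_exp = int(exp_table["n"].iloc[0])
    n_out = int(out_table["n"].iloc[0])
    strength = instrument_strength(hset, n_exp)
    binary = cfg.outcome_binary and direction == "forward"
    power = mr_power(
        n_out,
        strength.r2,
        cfg.power_effect_or if binary else np.log(cfg.power_effect_or),
        alpha=cfg.alpha,
        binary=binary,
        case_fraction=cfg.case_fraction if binary else None,
    )
    strength_rows.append(
        {
            "direction": direction,
            "exposure": exp_name,
            "outcome": out_name,
            "n_ivs": hset.n_retained,
            "r2": strength.r2,
            "f_stat": strength.f_stat,
            "power": power,
        }
    )


def run_bidirectional(
    config: AnalysisConfig,
    exposures: Mapping[str, pd.DataFrame] | None = None,
    outcome: pd.DataFrame | None = None,
    ld: pd.DataFrame | None = None,
    ldsc_input: LdscInput | None = None,
) -> ReportBundle:
    """Execute every enabled analysis direction and assemble the report.

    Tables may be passed in memory; otherwise they are read from the
    paths in ``config``.  Using the same file as exposure and outcome is
    refused: a two-sample design requires non-overlapping samples.
    """
    if exposures is None:
        if not config.exposure_paths:
            raise ValueError("no exposure tables or paths supplied")
        if config.outcome_path and config.outcome_path in config.exposure_paths.values():
            raise ValueError(
                "exposure and outcome point at the same file: the two-sample design "
                "requires independent, non-overlapping samples"
            )
        exposures = {name: mrio.read_gwas(p) for name, p in config.exposure_paths.items()}
    if outcome is None:
        if not config.outcome_path:
            raise ValueError("no outcome table or path supplied")
        outcome = mrio.read_gwas(config.outcome_path)
    if ld is None and config.ld_path:
        ld = mrio.read_ld_matrix(config.ld_path)
    if ldsc_input is None and config.ldsc_path:
        ldsc_input = mrio.read_ldsc_input(config.ldsc_path)

    rows: list[dict] = []
    attrition: list[dict] = []
    loo_tables: dict[str, pd.DataFrame] = {}
    funnel_tables: dict[str, pd.DataFrame] = {}
    strength_rows: list[dict] = []
    log: list[str] = [f"seed={config.seed} direction={config.direction}"]
    parts = (rows, attrition, loo_tables, funnel_tables, strength_rows, log)

    if config.direction in ("forward", "both"):
        for name, table in exposures.items():
            _pair_battery("forward", name, config.outcome_name, table, outcome, config, ld, parts)
    if config.direction in ("reverse", "both"):
        for name, table in exposures.items():
            _pair_battery("reverse", config.outcome_name, name, outcome, table, config, ld, parts)

    mv_results = None
    if config.direction in ("forward", "both") and len(exposures) >= 2:
        mv_results = _mv_battery(exposures, outcome, config, ld, strength_rows, log)

    ldsc_table = None
    if ldsc_input is not None:
        res = ldsc_rg(ldsc_input)
        ldsc_table = pd.DataFrame(
            [
                {
                    "phenotype_1": "trait1",
                    "phenotype_2": "trait2",
                    "rg": res.rg,
                    "se": res.rg_se,
                    "pval": res.rg_pval,
                    "h2_1": res.h2_1,
                    "h2_2": res.h2_2,
                    "defined": res.defined,
                }
            ]
        )
        log.append(f"[ldsc] defined={res.defined} rg={res.rg}")

    return ReportBundle(
        uv_results=pd.DataFrame(rows),
        mv_results=mv_results,
        strength=pd.DataFrame(strength_rows),
        attrition=pd.DataFrame(attrition),
        leave_one_out=loo_tables,
        funnel=funnel_tables,
        ldsc=ldsc_table,
        log_lines=log,
        alpha=config.alpha,
        seed=config.seed,
    )


def _mv_battery(exposures, outcome, cfg, ld, strength_rows, log):
    mv_set = build_mv_instruments(
        exposures, outcome, cfg.p_threshold, ld, cfg.clump_r2, cfg.palindrome_window
    )
    log.append(
        f"[mv] union={mv_set.n_union} duplicates_removed={mv_set.n_duplicates_removed} "
        f"palindromic_dropped={mv_set.n_dropped_palindromic} retained={mv_set.n_retained}"
    )
    if mv_set.n_retained <= len(exposures) + 1:
        log.append("[mv] too few instruments; multivariable analysis skipped")
        return None
    res_ivw = mv_ivw(mv_set, cfg.effects_model)
    res_egger = mv_egger(mv_set)
    rows = []
    for name in mv_set.exposure_names:
        est = res_ivw.estimates[name]
        # per-exposure PRESSO global p on the exposure's own column vs the outcome
        per = pd.DataFrame(
            {
                "snp": mv_set.snps,
                "beta_exposure": mv_set.beta_exposure[name].to_numpy(),
                "se_exposure": mv_set.se_exposure[name].to_numpy(),
                "beta_outcome": mv_set.beta_outcome.to_numpy(),
                "se_outcome": mv_set.se_outcome.to_numpy(),
            }
        )
        presso_p = (
            presso(per, PressoConfig(n_sim=cfg.presso_n_sim, seed=cfg.seed)).global_p
            if len(per) >= 4
            else np.nan
        )
        rows.append(
            {
                "exposure": name,
                "method": "mvIVW",
                "n_snps": est.n_snps,
                "or_ci": _fmt_or(est.or_point, est.ci_low, est.ci_high),
                "or": est.or_point,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "intercept_pval": np.nan,
                "q_pval": res_ivw.heterogeneity.q_pval,
                "i2": res_ivw.heterogeneity.i2,
                "presso_pval": presso_p,
            }
        )
        est_e = res_egger.estimates[name]
        rows.append(
            {
                "exposure": name,
                "method": f"mvMR-Egger (orientated to {res_egger.orientation})",
                "n_snps": est_e.n_snps,
                "or_ci": _fmt_or(est_e.or_point, est_e.ci_low, est_e.ci_high),
                "or": est_e.or_point,
                "ci_low": est_e.ci_low,
                "ci_high": est_e.ci_high,
                "pval": est_e.pval,
                "intercept_pval": res_egger.intercept.pval,
                "q_pval": res_egger.heterogeneity.q_pval,
                "i2": res_egger.heterogeneity.i2,
                "presso_pval": np.nan,
            }
        )
    n_exp = int(next(iter(exposures.values()))["n"].iloc[0])
    n_out = int(outcome["n"].iloc[0])
    strength = instrument_strength(mv_set, n_exp)
    power = mr_power(
        n_out,
        strength.r2,
        cfg.power_effect_or,
        alpha=cfg.alpha,
        binary=cfg.outcome_binary,
        case_fraction=cfg.case_fraction if cfg.outcome_binary else None,
    )
    strength_rows.append(
        {
            "direction": "mv",
            "exposure": "+".join(mv_set.exposure_names),
            "outcome": cfg.outcome_name,
            "n_ivs": mv_set.n_retained,
            "r2": strength.r2,
            "f_stat": strength.f_stat,
            "power": power,
        }
    )
    return pd.DataFrame(rows)


def _round_frame(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(6)
    return out


def write_report(bundle: ReportBundle, out_dir: str | Path) -> list[Path]:
    """Write the deterministic report file set; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(frame: pd.DataFrame, name: str):
        path = out / name
        _round_frame(frame).to_csv(path, sep="\t", index=False)
        written.append(path)

    _write(bundle.uv_results, "uv_results.tsv")
    if bundle.mv_results is not None:
        _write(bundle.mv_results, "mv_results.tsv")
    _write(bundle.strength, "instrument_strength.tsv")
    _write(bundle.attrition, "attrition.tsv")
    if bundle.ldsc is not None:
        _write(bundle.ldsc, "ldsc.tsv")
    for key, table in sorted(bundle.leave_one_out.items()):
        _write(table, f"loo_{key}.tsv")
    for key, table in sorted(bundle.funnel.items()):
        _write(table, f"funnel_{key}.tsv")

    summary = out / "summary.txt"
    with open(summary, "w") as fh:
        fh.write(f"Bidirectional MR report (seed={bundle.seed}, alpha={bundle.alpha})\n\n")
        if not bundle.uv_results.empty:
            for _, r in bundle.uv_results.iterrows():
                star = " *" if r.get("significant") else ""
                fh.write(
                    f"{r['direction']:>8} {r['exposure']} vs {r['outcome']} "
                    f"{r['method']:<16} nSNPs={r['n_snps']:>3} "
                    f"OR={r['or_ci']} P={r['pval']:.3f}{star}\n"
                )
        fh.write("\n")
        for line in bundle.log_lines:
            fh.write(line + "\n")
    written.append(summary)

    machine = out / "results.json"
    payload = {
        "seed": bundle.seed,
        "alpha": bundle.alpha,
        "uv_results": json.loads(_round_frame(bundle.uv_results).to_json(orient="records")),
        "mv_results": (
            json.loads(_round_frame(bundle.mv_results).to_json(orient="records"))
            if bundle.mv_results is not None
            else None
        ),
        "strength": json.loads(_round_frame(bundle.strength).to_json(orient="records")),
        "attrition": json.loads(bundle.attrition.to_json(orient="records")),
        "log": bundle.log_lines,
    }
    with open(machine, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    written.append(machine)

    log_path = out / "run.log"
    with open(log_path, "w") as fh:
        fh.write("\n".join(bundle.log_lines) + "\n")
    written.append(log_path)
    return written
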