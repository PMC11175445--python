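"""End-to-end orchestration: select → harmonize → UVMR → sensitivity →
MVMR → mediation, with study-style result tables and a structured run log.

Outputs are plain TSV files shaped like the conventional reporting tables of
a two-sample MR study: one univariable row per (exposure, outcome, method),
one multivariable row per (exposure, method) with instrument-strength F, and
one mediation table carrying the stage estimates and the mediated effect.
Every dropped SNP and every estimator call is recorded in ``run_log.txt``;
outputs are byte-deterministic for a fixed configuration and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .harmonize import DEFAULT_PALINDROME_WINDOW, harmonize, harmonize_multi
from .mediation import MediationResult, two_step_mediation
from .mvmr import mvmr_egger, mvmr_ivw
from .sensitivity import cochran_q, egger_intercept_test, funnel_data, leave_one_out
from .sumstats import (
    ConfigurationError,
    SummaryStatTable,
    read_sumstats,
    select_instruments,
)
from .uvmr import MREstimate, ivw, mr_egger, weighted_median

logger = logging.getLogger("mrmediate")

_FLOAT_FMT = "%.10g"


@dataclass
class AnalysisConfig:
    """Configuration for a full mediation-MR run over three tables."""

    exposure_path: str | Path
    mediator_path: str | Path
    outcome_path: str | Path
    output_dir: str | Path
    seed: int
    p_threshold: float = 5.0e-8
    palindrome_eaf_window: tuple[float, float] = DEFAULT_PALINDROME_WINDOW
    one_per_block: bool = True
    n_boot: int = 1000
    total_effect_convention: str = "estimated_total"
    beta2_source: str = "univariable"
    exposure_name: str = "exposure"
    mediator_name: str = "mediator"
    outcome_name: str = "outcome"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ConfigurationError("p_threshold must be in (0,1)")
        lo, hi = self.palindrome_eaf_window
        if not (0 <= lo <= hi <= 1):
            raise ConfigurationError("palindrome window must satisfy 0 ≤ low ≤ high ≤ 1")
        if self.n_boot < 1:
            raise ConfigurationError("n_boot must be ≥ 1")


@dataclass
class ResultBundle:
    """In-memory results of one pipeline run plus their file paths."""

    univariable: pd.DataFrame
    multivariable: pd.DataFrame
    mediation: pd.DataFrame
    heterogeneity: pd.DataFrame
    mediation_result: MediationResult
    paths: dict[str, Path] = field(default_factory=dict)


def format_estimate(est: MREstimate, style: str = "both", digits: int = 2) -> str:
    """Study-style text row for an estimate.

    ``log`` prints beta with its beta-scale CI; ``exp`` prints beta alongside
    the exponentiated CI (the mixed convention common in MR reports);
    ``both`` prints the two.
    """
    d = digits
    log_part = (f"beta = {est.beta:.{d}f}, 95% CI {est.ci_low:.{d}f} to "
                f"{est.ci_high:.{d}f}, p = {est.pval:.3g}")
    exp_part = (f"beta = {est.beta:.{d}f}, 95% CI {est.or_low:.{d}f} to "
                f"{est.or_high:.{d}f}, p = {est.pval:.3g}")
    if style == "log":
        return log_part
    if style == "exp":
        return exp_part
    if style == "both":
        return f"{log_part} | exp-scale CI {est.or_low:.{d}f} to {est.or_high:.{d}f}"
    raise ValueError("style must be 'log', 'exp' or 'both'")


def _uv_row(exposure, outcome, est: MREstimate) -> dict:
    return {
        "exposure": exposure, "outcome": outcome, "method": est.method,
        "beta": est.beta, "se": est.se, "ci_low": est.ci_low, "ci_high": est.ci_high,
        "or_point": est.or_point, "or_low": est.or_low, "or_high": est.or_high,
        "pval": est.pval, "k": est.k,
    }


def _write_tsv(frame: pd.DataFrame, path: Path, scale_note: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {scale_note}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: AnalysisConfig) -> ResultBundle:
    """Execute the full univariable → MVMR → mediation workflow.

    Validates all inputs before computing anything; writes one TSV per
    report table plus sensitivity diagnostics and a run log under
    ``config.output_dir``.  Identical configuration and seed produce a
    byte-identical bundle.
    """
    for label, p in (("exposure", config.exposure_path),
                     ("mediator", config.mediator_path),
                     ("outcome", config.outcome_path)):
        if not Path(p).is_file():
            raise ConfigurationError(f"{label} table not found: {p}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        bundle = _run(config, outdir)
    except Exception:
        logger.exception("pipeline aborted")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    bundle.paths["run_log"] = log_path
    return bundle


def _run(config: AnalysisConfig, outdir: Path) -> ResultBundle:
    exposure = read_sumstats(config.exposure_path, trait_name=config.exposure_name)
    mediator = read_sumstats(config.mediator_path, trait_name=config.mediator_name)
    outcome = read_sumstats(config.outcome_path, trait_name=config.outcome_name)

    uv_rows, het_rows = [], []
    pairs = [(exposure, outcome), (mediator, outcome)]
    for exp_table, out_table in pairs:
        logger.info("univariable MR: %s -> %s", exp_table.trait_name, out_table.trait_name)
        inst = select_instruments(exp_table, config.p_threshold, config.one_per_block)
        hset = harmonize(inst, out_table, config.palindrome_eaf_window)
        est_ivw = ivw(hset, "random")
        est_wm = weighted_median(hset, n_boot=config.n_boot, seed=config.seed)
        est_egger = mr_egger(hset)
        for est in (est_ivw, est_wm, est_egger):
            logger.info("estimate %s->%s %s: %s", exp_table.trait_name,
                        out_table.trait_name, est.method, format_estimate(est))
            uv_rows.append(_uv_row(exp_table.trait_name, out_table.trait_name, est))
        for ref in ("ivw", "egger"):
            het = cochran_q(hset, ref)
            het_rows.append({"exposure": exp_table.trait_name, "outcome": out_table.trait_name,
                             "reference": ref, "q": het.q, "df": het.df, "pval": het.pval})
        pleio = egger_intercept_test(hset)
        het_rows.append({"exposure": exp_table.trait_name, "outcome": out_table.trait_name,
                         "reference": "egger_intercept", "q": pleio.intercept,
                         "df": 0, "pval": pleio.pval})
        loo = leave_one_out(hset)
        _write_tsv(loo.to_frame(), outdir / f"leave_one_out_{exp_table.trait_name}.tsv",
                   "beta-scale leave-one-out random-effects IVW estimates")
        _write_tsv(funnel_data(hset).to_frame(), outdir / f"funnel_{exp_table.trait_name}.tsv",
                   "per-SNP Wald ratios and precisions (funnel data)")

    # multivariable: joint exposure + mediator on the union of instruments
    logger.info("multivariable MR: %s + %s -> %s", config.exposure_name,
                config.mediator_name, config.outcome_name)
    inst_x = select_instruments(exposure, config.p_threshold, config.one_per_block)
    inst_m = select_instruments(mediator, config.p_threshold, config.one_per_block)
    union_ids = list(dict.fromkeys(inst_x.snp_ids + inst_m.snp_ids))
    hm = harmonize_multi([exposure, mediator], outcome, snp_ids=union_ids,
                         palindrome_eaf_window=config.palindrome_eaf_window)
    mv_rows = []
    for mv, label in ((mvmr_ivw(hm), "mvmr_ivw"), (mvmr_egger(hm), "mvmr_egger")):
        for name, est, f in zip(mv.exposure_names, mv.estimates, mv.f_stats):
            logger.info("estimate MVMR %s %s: %s", label, name, format_estimate(est))
            mv_rows.append({
                "exposure": name, "outcome": config.outcome_name, "method": label,
                "beta": est.beta, "se": est.se, "ci_low": est.ci_low, "ci_high": est.ci_high,
                "or_low": est.or_low, "or_high": est.or_high, "pval": est.pval,
                "f_statistic": f, "k": mv.k,
            })

    med = two_step_mediation(
        exposure, mediator, outcome,
        p_threshold=config.p_threshold,
        palindrome_eaf_window=config.palindrome_eaf_window,
        one_per_block=config.one_per_block,
        beta2_source=config.beta2_source,
        total_effect_convention=config.total_effect_convention,
    )
    med_rows = []
    for label, est in (
        (f"{config.exposure_name}->{config.mediator_name}", med.beta1),
        (f"{config.mediator_name}->{config.outcome_name}", med.beta2),
        (f"{config.exposure_name}->{config.outcome_name} (total)", med.beta3),
        (f"{config.exposure_name}->{config.outcome_name} (direct)", med.beta3_prime),
    ):
        med_rows.append({"path": label, "beta": est.beta, "se": est.se,
                         "ci_low": est.ci_low, "ci_high": est.ci_high, "pval": est.pval})
    med_rows.append({"path": "indirect (mediated)", "beta": med.indirect,
                     "se": med.indirect_se, "ci_low": med.indirect_ci[0],
                     "ci_high": med.indirect_ci[1], "pval": med.indirect_pval})
    if med.mediation_ratio is not None:
        med_rows.append({"path": f"mediation ratio ({med.total_effect_convention})",
                         "beta": med.mediation_ratio, "se": med.ratio_se,
                         "ci_low": med.ratio_ci[0], "ci_high": med.ratio_ci[1],
                         "pval": np.nan})
    logger.info("mediation conditions: %s (mediator %s)", med.conditions,
                "present" if med.mediator_present else "not established")

    uv = pd.DataFrame(uv_rows)
    mv_frame = pd.DataFrame(mv_rows)
    med_frame = pd.DataFrame(med_rows)
    het = pd.DataFrame(het_rows)

    paths = {
        "univariable": outdir / "univariable_mr.tsv",
        "multivariable": outdir / "multivariable_mr.tsv",
        "mediation": outdir / "mediation.tsv",
        "heterogeneity": outdir / "heterogeneity.tsv",
    }
    _write_tsv(uv, paths["univariable"],
               "beta on log/standardized scale; or_* columns exponentiated")
    _write_tsv(mv_frame, paths["multivariable"],
               "beta on log/standardized scale; or_* columns exponentiated")
    _write_tsv(med_frame, paths["mediation"],
               "all columns on the raw beta scale")
    _write_tsv(het, paths["heterogeneity"],
               "Cochran Q diagnostics; egger_intercept rows carry the intercept in the q column")
    return ResultBundle(univariable=uv, multivariable=mv_frame, mediation=med_frame,
                        heterogeneity=het, mediation_result=med, paths=paths)
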