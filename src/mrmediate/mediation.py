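"""Two-step mediation MR: decomposing an exposure→outcome effect.

The causal chain exposure → mediator → outcome is quantified by four
estimates (product-of-coefficients / two-step MR):

* β1 — exposure→mediator effect (univariable MR on exposure instruments);
* β2 — mediator→outcome effect (univariable MR on mediator instruments by
  default; optionally the mediator coefficient from MVMR);
* β3 — total exposure→outcome effect (univariable MR);
* β3′ — direct exposure→outcome effect adjusted for the mediator (the
  exposure coefficient from MVMR on exposure + mediator jointly).

The indirect (mediated) effect is β1·β2 with Sobel SE
√(β1²·se2² + β2²·se1²); the mediation ratio divides it by the total effect,
either the estimated total β3 (``estimated_total``) or the reconstructed
total β3′ + β1·β2 (``reconstructed_total``).  A mediator is declared present
when all three chain associations (β1, β3, β2) are significant at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .harmonize import harmonize, harmonize_multi
from .mvmr import MVMRResult, mvmr_ivw
from .sumstats import (
    AnalysisError,
    SummaryStatTable,
    logger,
    select_instruments,
)
from .uvmr import _Z, MREstimate, ivw

#: |β3| below this is treated as a vanishing total effect
_TOTAL_EFFECT_EPS = 1e-12

CONVENTIONS = ("estimated_total", "reconstructed_total")
SIGNIFICANCE = 0.05


@dataclass
class MediationResult:
    beta1: MREstimate            # exposure → mediator
    beta2: MREstimate            # mediator → outcome
    beta3: MREstimate            # total exposure → outcome
    beta3_prime: MREstimate      # direct exposure → outcome (MVMR-adjusted)
    indirect: float
    indirect_se: float
    indirect_ci: tuple[float, float]
    indirect_pval: float
    mediation_ratio: float | None
    ratio_se: float | None
    ratio_ci: tuple[float, float] | None
    total_effect_convention: str
    conditions: dict[str, bool] = field(default_factory=dict)
    mvmr: MVMRResult | None = None

    @property
    def mediator_present(self) -> bool:
        return all(self.conditions.values())


def sobel_se(beta1: float, se1: float, beta2: float, se2: float) -> float:
    """First-order delta-method SE of the product β1·β2."""
    return float(np.sqrt(beta1**2 * se2**2 + beta2**2 * se1**2))


def two_step_mediation(
    exposure: SummaryStatTable,
    mediator: SummaryStatTable,
    outcome: SummaryStatTable,
    p_threshold: float = 5e-8,
    palindrome_eaf_window: tuple[float, float] = (0.42, 0.58),
    one_per_block: bool = True,
    beta2_source: str = "univariable",
    total_effect_convention: str = "estimated_total",
) -> MediationResult:
    """Run the full two-step mediation analysis on three summary tables.

    Instruments are selected independently for the exposure and the mediator
    at ``p_threshold``; β3′ always comes from MVMR on the union of both
    instrument sets harmonized across all three tables.  All stage fits are
    random-effects IVW.
    """
    if total_effect_convention not in CONVENTIONS:
        raise ValueError(f"total_effect_convention must be one of {CONVENTIONS}")
    if beta2_source not in ("univariable", "mvmr"):
        raise ValueError("beta2_source must be 'univariable' or 'mvmr'")

    def stage(label, fn):
        try:
            return fn()
        except AnalysisError as err:
            raise AnalysisError(f"mediation stage '{label}': {err}") from err

    exp_inst = stage("select exposure instruments",
                     lambda: select_instruments(exposure, p_threshold, one_per_block))
    med_inst = stage("select mediator instruments",
                     lambda: select_instruments(mediator, p_threshold, one_per_block))

    h1 = stage("harmonize exposure→mediator",
               lambda: harmonize(exp_inst, mediator, palindrome_eaf_window))
    beta1 = stage("fit exposure→mediator", lambda: ivw(h1, "random"))

    h3 = stage("harmonize exposure→outcome",
               lambda: harmonize(exp_inst, outcome, palindrome_eaf_window))
    beta3 = stage("fit exposure→outcome", lambda: ivw(h3, "random"))

    h2 = stage("harmonize mediator→outcome",
               lambda: harmonize(med_inst, outcome, palindrome_eaf_window))
    beta2_uv = stage("fit mediator→outcome", lambda: ivw(h2, "random"))

    union_ids = list(dict.fromkeys(exp_inst.snp_ids + med_inst.snp_ids))
    hm = stage("harmonize joint exposure+mediator→outcome",
               lambda: harmonize_multi([exposure, mediator], outcome,
                                       snp_ids=union_ids,
                                       palindrome_eaf_window=palindrome_eaf_window))
    mv = stage("fit MVMR exposure+mediator→outcome", lambda: mvmr_ivw(hm))
    beta3_prime = mv.estimates[0]
    beta2 = beta2_uv if beta2_source == "univariable" else mv.estimates[1]

    indirect = beta1.beta * beta2.beta
    ind_se = sobel_se(beta1.beta, beta1.se, beta2.beta, beta2.se)
    if ind_se > 0:
        ind_p = 2 * stats.norm.sf(abs(indirect / ind_se))
    else:
        ind_p = 1.0 if indirect == 0 else 0.0
    ind_ci = (indirect - _Z * ind_se, indirect + _Z * ind_se)

    if total_effect_convention == "estimated_total":
        total, total_se = beta3.beta, beta3.se
    else:
        total = beta3_prime.beta + indirect
        total_se = float(np.sqrt(beta3_prime.se**2 + ind_se**2))  # cross-term ignored

    if abs(total) < _TOTAL_EFFECT_EPS:
        logger.warning("two_step_mediation: total effect ≈ 0; mediation ratio undefined")
        ratio = ratio_se = ratio_ci = None
    else:
        ratio = indirect / total
        # delta method on a ratio of (approximately) independent estimates
        rel = (ind_se / indirect) ** 2 if indirect != 0 else np.inf
        rel += (total_se / total) ** 2
        ratio_se = abs(ratio) * float(np.sqrt(rel)) if np.isfinite(rel) else float(ind_se / abs(total))
        ratio_ci = (ratio - _Z * ratio_se, ratio + _Z * ratio_se)

    conditions = {
        "exposure_mediator_associated": beta1.pval < SIGNIFICANCE,
        "exposure_outcome_associated": beta3.pval < SIGNIFICANCE,
        "mediator_outcome_associated": beta2.pval < SIGNIFICANCE,
    }
    if indirect == 0:
        conditions["exposure_mediator_associated"] = conditions["exposure_mediator_associated"] and beta1.beta != 0

    return MediationResult(
        beta1=beta1, beta2=beta2, beta3=beta3, beta3_prime=beta3_prime,
        indirect=float(indirect), indirect_se=ind_se,
        indirect_ci=ind_ci, indirect_pval=float(ind_p),
        mediation_ratio=ratio, ratio_se=ratio_se, ratio_ci=ratio_ci,
        total_effect_convention=total_effect_convention,
        conditions=conditions, mvmr=mv,
    )
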