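"""Heterogeneity, pleiotropy, influence, and funnel diagnostics for MR fits.

All diagnostics operate on the ratio scale with first-order inverse-variance
weights, consistent with the IVW definition in :mod:`mrmediate.uvmr`:
Cochran's Q measures dispersion of the per-SNP Wald ratios around the
reference fit, the Egger intercept test probes average directional
pleiotropy, leave-one-out refits flag single influential SNPs, and the
funnel data pair each ratio with its precision for asymmetry inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import HarmonizedInstrumentSet
from .sumstats import AnalysisError
from .uvmr import MREstimate, _ratios_and_weights, ivw, mr_egger


@dataclass(frozen=True)
class HeterogeneityResult:
    q: float
    df: int
    pval: float


@dataclass(frozen=True)
class PleiotropyResult:
    intercept: float
    se: float
    pval: float


@dataclass
class LeaveOneOutTable:
    """One random-effects IVW refit per dropped SNP, plus the full-set fit."""

    full_estimate: MREstimate
    rows: list[tuple[str, MREstimate, bool]]  # (dropped snp, estimate, driver flag)

    def to_frame(self) -> pd.DataFrame:
        recs = [
            (snp, est.beta, est.se, est.ci_low, est.ci_high, est.pval, driver)
            for snp, est, driver in self.rows
        ]
        return pd.DataFrame(
            recs, columns=["dropped_snp", "beta", "se", "ci_low", "ci_high", "pval", "driver"]
        )


@dataclass
class FunnelData:
    """Per-SNP Wald ratio against its precision (1/SE of the ratio)."""

    frame: pd.DataFrame  # columns: snp_id, wald_ratio, precision

    def to_frame(self) -> pd.DataFrame:
        return self.frame


def cochran_q(hset: HarmonizedInstrumentSet, reference: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q against the IVW mean or the Egger regression line.

    Q = Σ w_j (θ_j − θ̂_j)² with w_j = bx_j²/se_by_j²; θ̂_j is the fixed-effects
    IVW mean (df = k−1) or the Egger prediction (α + θ·bx_j)/bx_j on the
    ratio scale (df = k−2).
    """
    theta, w = _ratios_and_weights(hset)
    k = hset.k
    if reference == "ivw":
        if k < 2:
            raise AnalysisError("Q (IVW) needs k ≥ 2")
        beta = float(np.sum(w * theta) / np.sum(w))
        fitted = np.full(k, beta)
        df = k - 1
    elif reference == "egger":
        if k < 3:
            raise AnalysisError("Q (Egger) needs k ≥ 3")
        est = mr_egger(hset)
        bx = np.abs(hset.bx)  # Egger fit is in the bx>0 orientation
        fitted = (est.intercept + est.beta * bx) / bx
        # ratios are orientation-invariant, so compare in oriented space
        theta = (hset.beta_outcome * np.sign(hset.bx)) / bx
        df = k - 2
    else:
        raise ValueError("reference must be 'ivw' or 'egger'")
    q = float(np.sum(w * (theta - fitted) ** 2))
    pval = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(q=q, df=df, pval=max(pval, 5e-324))


def egger_intercept_test(hset: HarmonizedInstrumentSet) -> PleiotropyResult:
    """Directional-pleiotropy test: the MR-Egger intercept, SE, and t(k−2) p."""
    est = mr_egger(hset)
    return PleiotropyResult(intercept=est.intercept, se=est.intercept_se, pval=est.intercept_pval)


def leave_one_out(hset: HarmonizedInstrumentSet) -> LeaveOneOutTable:
    """Refit random-effects IVW leaving each SNP out in turn.

    A row is flagged as a *driver* when dropping its SNP changes the sign
    conclusion: the reduced fit's CI excludes zero on the opposite side, or
    no longer supports a full-fit conclusion that was significant.
    """
    if hset.k < 3:
        raise AnalysisError("leave-one-out needs k ≥ 3 so each refit has k ≥ 2")
    full = ivw(hset, effects_model="random")
    full_sig = full.ci_low > 0 or full.ci_high < 0
    rows = []
    for i, snp in enumerate(hset.snp_ids):
        est = ivw(hset.drop_index(i), effects_model="random")
        sig = est.ci_low > 0 or est.ci_high < 0
        if full_sig:
            driver = (not sig) or (np.sign(est.beta) != np.sign(full.beta))
        else:
            driver = sig
        rows.append((snp, est, bool(driver)))
    return LeaveOneOutTable(full_estimate=full, rows=rows)


def funnel_data(hset: HarmonizedInstrumentSet) -> FunnelData:
    """Wald ratio and precision per SNP; rendering is left to the caller."""
    theta = hset.beta_outcome / hset.bx
    precision = np.abs(hset.bx) / hset.se_outcome
    frame = pd.DataFrame(
        {"snp_id": hset.snp_ids, "wald_ratio": theta, "precision": precision}
    )
    return FunnelData(frame=frame)
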