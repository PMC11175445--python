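"""Multivariable MR: joint regression of outcome effects on several exposures.

With p exposures, the outcome effect vector is regressed on the (k × p)
exposure effect matrix by weighted least squares with weights 1/se_by²
(no intercept for the IVW variant; with an intercept after orientation for
the Egger variant).  Each coefficient is the direct effect of that exposure
on the outcome holding the others fixed.  Per-exposure instrument strength
uses the same R²/F formulas as the univariable pipeline, summed over the
shared instrument set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstrumentSet
from .sumstats import AnalysisError, f_statistic, logger
from .uvmr import MREstimate, _normal_estimate

_RANK_TOL = 1e-10


@dataclass
class MVMRResult:
    exposure_names: list[str]
    estimates: list[MREstimate]  # one per exposure, shared k
    f_stats: list[float]
    k: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None

    def estimate_for(self, name: str) -> MREstimate:
        return self.estimates[self.exposure_names.index(name)]


def _wls_fit(X: np.ndarray, y: np.ndarray, w: np.ndarray, df_resid: int):
    """Weighted least squares with multiplicative residual scale floored at 1."""
    XtW = X.T * w
    gram = XtW @ X
    if np.linalg.matrix_rank(gram, tol=_RANK_TOL * np.abs(gram).max()) < X.shape[1]:
        raise AnalysisError("collinear exposures: design matrix is rank deficient")
    gram_inv = np.linalg.inv(gram)
    coef = gram_inv @ (XtW @ y)
    resid = y - X @ coef
    rss_w = float(np.sum(w * resid**2))
    scale = rss_w / df_resid if df_resid > 0 else 0.0
    cov = max(scale, 1.0) * gram_inv
    return coef, np.sqrt(np.diag(cov)), rss_w


def _f_stats(hset: HarmonizedInstrumentSet) -> list[float]:
    """Per-exposure F as a diagnostic: NaN (with a warning) when undefined."""
    out = []
    for i in range(hset.n_exposures):
        try:
            out.append(mvmr_f(hset, i))
        except AnalysisError as err:
            logger.warning("mvmr F-statistic unavailable for exposure %d: %s", i, err)
            out.append(float("nan"))
    return out


def mvmr_ivw(hset: HarmonizedInstrumentSet) -> MVMRResult:
    """Multivariable IVW: WLS of by on the exposure matrix, no intercept.

    Residual heterogeneity inflates the SEs multiplicatively (the
    multivariable Q analogue with df = k − p, floored at 1); per-exposure
    CIs and p-values use normal quantiles.
    """
    p = hset.n_exposures
    if p < 1:
        raise AnalysisError("at least one exposure required")
    if hset.k < p + 1:
        raise AnalysisError(f"MVMR-IVW needs k ≥ {p + 1} SNPs for {p} exposures")
    X = hset.beta_exposure
    if np.any(np.all(X == 0, axis=0)):
        raise AnalysisError("collinear exposures: an exposure column is all zeros")
    w = hset.weights
    coef, se, _ = _wls_fit(X, hset.beta_outcome, w, df_resid=hset.k - p)
    estimates = [
        _normal_estimate("mvmr_ivw", float(coef[i]), float(se[i]), k=hset.k)
        for i in range(p)
    ]
    return MVMRResult(
        exposure_names=list(hset.exposure_names),
        estimates=estimates,
        f_stats=_f_stats(hset),
        k=hset.k,
    )


def mvmr_egger(hset: HarmonizedInstrumentSet) -> MVMRResult:
    """Multivariable MR-Egger: adds an intercept after orienting each SNP so
    the first exposure's effect is positive (whole rows flip jointly)."""
    p = hset.n_exposures
    if hset.k < p + 2:
        raise AnalysisError(f"MVMR-Egger needs k ≥ {p + 2} SNPs for {p} exposures")
    s = np.where(hset.beta_exposure[:, 0] < 0, -1.0, 1.0)
    X = np.column_stack([np.ones(hset.k), hset.beta_exposure * s[:, None]])
    y = hset.beta_outcome * s
    w = hset.weights
    coef, se, _ = _wls_fit(X, y, w, df_resid=hset.k - p - 1)
    estimates = [
        _normal_estimate("mvmr_egger", float(coef[i + 1]), float(se[i + 1]), k=hset.k)
        for i in range(p)
    ]
    z0 = coef[0] / se[0] if se[0] > 0 else 0.0
    return MVMRResult(
        exposure_names=list(hset.exposure_names),
        estimates=estimates,
        f_stats=_f_stats(hset),
        k=hset.k,
        intercept=float(coef[0]),
        intercept_se=float(se[0]),
        intercept_pval=float(2 * stats.norm.sf(abs(z0))),
    )


def mvmr_f(hset: HarmonizedInstrumentSet, exposure_index: int) -> float:
    """Per-exposure instrument-strength F over the shared instrument set.

    Sums the per-SNP variance explained R²_j = 2β²pq / (2β²pq + SE²·2N·pq)
    for that exposure column, then applies F = [(N−k−1)/k]·[R²/(1−R²)] with
    N the (median) exposure sample size and k the shared instrument count.
    SNPs with missing EAF are excluded from the sum with a warning.
    """
    beta = hset.beta_exposure[:, exposure_index]
    se = hset.se_exposure[:, exposure_index]
    eaf = hset.eaf_exposure[:, exposure_index]
    n = hset.n_exposure[:, exposure_index]
    ok = np.isfinite(eaf) & (eaf > 0) & (eaf < 1)
    if not ok.any():
        raise AnalysisError("F-statistic: EAF missing for every SNP of this exposure")
    if not ok.all():
        logger.warning("mvmr_f: %d SNP(s) excluded from R² (missing EAF)", int((~ok).sum()))
    pq = eaf[ok] * (1 - eaf[ok])
    num = 2 * beta[ok] ** 2 * pq
    r2 = float(np.sum(num / (num + se[ok] ** 2 * 2 * n[ok] * pq)))
    return f_statistic(r2, int(np.median(n[ok])), hset.k)
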