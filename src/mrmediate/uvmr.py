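"""Univariable two-sample MR estimators.

Each SNP j contributes a Wald ratio θ_j = by_j / bx_j — the outcome effect
divided by the exposure effect.  The estimators differ in how they pool the
ratios:

* **IVW** — inverse-variance-weighted mean of the ratios with first-order
  weights w_j = bx_j²/se_by_j², algebraically the weighted least-squares
  slope of by on bx through the origin.  The fixed-effects SE is
  (Σw_j)^(-1/2); the random-effects variant multiplies it by
  max(1, √(Q/(k−1))) with Q Cochran's heterogeneity statistic.
* **MR-Egger** — the same regression with a free intercept after orienting
  every SNP so bx_j > 0; the intercept estimates average directional
  pleiotropy, the slope remains consistent under the InSIDE assumption.
  Inference uses a t reference with k−2 degrees of freedom.
* **Weighted median** — the 50% quantile of the weighted empirical
  distribution of ratios; consistent when at least half the weight comes
  from valid instruments.  Its SE comes from a seeded parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstrumentSet
from .sumstats import AnalysisError

CI_LEVEL = 0.95
_Z = stats.norm.ppf(0.5 + CI_LEVEL / 2)  # 1.959964...


@dataclass
class MREstimate:
    """A causal-effect estimate on the log/standardized scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    k: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None

    @property
    def or_point(self) -> float:
        """Point estimate on the exponentiated (odds/multiplicative) scale."""
        return float(np.exp(self.beta))

    @property
    def or_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_high(self) -> float:
        return float(np.exp(self.ci_high))


def _normal_estimate(method: str, beta: float, se: float, k: int, **extra) -> MREstimate:
    z = beta / se if se > 0 else np.inf * np.sign(beta)
    pval = 2 * stats.norm.sf(abs(z)) if se > 0 else (1.0 if beta == 0 else 0.0)
    if se == 0 and beta == 0:
        pval = 1.0
    return MREstimate(method=method, beta=beta, se=se,
                      ci_low=beta - _Z * se, ci_high=beta + _Z * se,
                      pval=float(pval), k=k, **extra)


def wald_ratio(bx: float, by: float, se_by: float) -> MREstimate:
    """Single-SNP causal estimate by/bx with first-order delta-method SE.

    The SE ignores uncertainty in bx (se_by/|bx|); adequate for strong
    instruments, anticonservative otherwise.
    """
    if bx == 0:
        raise AnalysisError("null instrument: exposure effect is zero")
    return _normal_estimate("wald", by / bx, se_by / abs(bx), k=1)


def _ratios_and_weights(hset: HarmonizedInstrumentSet) -> tuple[np.ndarray, np.ndarray]:
    bx, by = hset.bx, hset.beta_outcome
    if np.any(bx == 0):
        raise AnalysisError("null instrument in set: exposure effect is zero")
    theta = by / bx
    w = bx**2 / hset.se_outcome**2
    return theta, w


def cochran_q_value(hset: HarmonizedInstrumentSet) -> float:
    """Q = Σ w_j (θ_j − θ̂_IVW)² — shared with the sensitivity module."""
    theta, w = _ratios_and_weights(hset)
    beta = float(np.sum(w * theta) / np.sum(w))
    return float(np.sum(w * (theta - beta) ** 2))


def ivw(hset: HarmonizedInstrumentSet, effects_model: str = "random") -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``effects_model='fixed'`` returns the plain weighted-mean SE;
    ``'random'`` (the headline convention) applies multiplicative
    heterogeneity inflation max(1, √(Q/(k−1))).
    """
    if effects_model not in ("fixed", "random"):
        raise ValueError("effects_model must be 'fixed' or 'random'")
    if hset.k < 2:
        raise AnalysisError("IVW needs k ≥ 2 SNPs; use wald_ratio for a single instrument")
    theta, w = _ratios_and_weights(hset)
    sw = float(np.sum(w))
    beta = float(np.sum(w * theta) / sw)
    se = sw ** -0.5
    method = "ivw_fe"
    if effects_model == "random":
        q = float(np.sum(w * (theta - beta) ** 2))
        se *= max(1.0, np.sqrt(q / (hset.k - 1)))
        method = "ivw_re"
    return _normal_estimate(method, beta, se, k=hset.k)


def _orient(bx: np.ndarray, by: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip SNPs jointly so every exposure effect is positive."""
    s = np.where(bx < 0, -1.0, 1.0)
    return bx * s, by * s


def mr_egger(hset: HarmonizedInstrumentSet) -> MREstimate:
    """MR-Egger regression: weighted fit of by = α + θ·bx with free intercept.

    SNPs are oriented to bx > 0 first.  The residual scale is floored at 1
    (multiplicative random effects), and inference uses t with k−2 df.
    """
    k = hset.k
    if k < 3:
        raise AnalysisError("MR-Egger needs k ≥ 3 SNPs")
    bx, by = _orient(hset.bx, hset.beta_outcome)
    if np.allclose(bx, bx[0]):
        raise AnalysisError("slope unidentifiable: zero exposure-beta variance")
    w = 1.0 / hset.se_outcome**2
    X = np.column_stack([np.ones(k), bx])
    XtW = X.T * w
    xtwx_inv = np.linalg.inv(XtW @ X)
    coef = xtwx_inv @ (XtW @ by)
    resid = by - X @ coef
    scale = float(np.sum(w * resid**2) / (k - 2))
    cov = max(scale, 1.0) * xtwx_inv
    alpha, slope = float(coef[0]), float(coef[1])
    se_alpha, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    tq = stats.t.ppf(0.5 + CI_LEVEL / 2, df=k - 2)
    p_slope = 2 * stats.t.sf(abs(slope / se_slope), df=k - 2)
    p_alpha = 2 * stats.t.sf(abs(alpha / se_alpha), df=k - 2)
    return MREstimate(
        method="egger", beta=slope, se=se_slope,
        ci_low=slope - tq * se_slope, ci_high=slope + tq * se_slope,
        pval=float(p_slope), k=k,
        intercept=alpha, intercept_se=se_alpha, intercept_pval=float(p_alpha),
    )


def weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    """Median of the weighted empirical CDF of ratio estimates.

    With ratios sorted and weights normalized to 1, the cumulative midpoint
    position of the j-th ratio is p_j = Σ_{i<j} w_(i) + w_(j)/2; the estimate
    interpolates θ over p at p = 0.5.
    """
    order = np.argsort(theta, kind="stable")
    th = np.asarray(theta, float)[order]
    ww = np.asarray(w, float)[order]
    ww = ww / ww.sum()
    p = np.cumsum(ww) - ww / 2
    if 0.5 <= p[0]:
        return float(th[0])
    if 0.5 >= p[-1]:
        return float(th[-1])
    return float(np.interp(0.5, p, th))


def weighted_median(hset: HarmonizedInstrumentSet, n_boot: int = 1000, seed: int | None = None) -> MREstimate:
    """Weighted median estimator with parametric-bootstrap SE.

    The bootstrap redraws bx and by from normals centred at the observed
    effects with their reported SEs (``n_boot`` replicates, explicit
    ``seed``); the SE is the standard deviation of the replicate estimates.
    """
    if hset.k < 3:
        raise AnalysisError("weighted median needs k ≥ 3 SNPs")
    if n_boot < 1:
        raise ValueError("n_boot must be ≥ 1")
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    theta, w = _ratios_and_weights(hset)
    beta = weighted_median_point(theta, w)

    rng = np.random.default_rng(seed)
    bx, by = hset.bx, hset.beta_outcome
    se_bx, se_by = hset.se_bx, hset.se_outcome
    reps = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, se_bx)
        by_b = rng.normal(by, se_by)
        bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
        th_b = by_b / bx_b
        w_b = bx_b**2 / se_by**2
        reps[b] = weighted_median_point(th_b, w_b)
    se = float(np.std(reps, ddof=1)) if n_boot > 1 else 0.0
    if se == 0:
        est = MREstimate("weighted_median", beta, 0.0, beta, beta,
                         1.0 if beta == 0 else 0.0, hset.k)
        return est
    return _normal_estimate("weighted_median", beta, se, k=hset.k)
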