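"""Allele harmonization across summary-statistics tables.

Two-sample MR requires that, for every shared SNP, the exposure and outcome
effect sizes refer to the same effect allele.  GWAS tables disagree in two
independent ways: the effect/other alleles may be swapped (the outcome GWAS
coded the opposite allele), and the alleles may be reported on the opposite
DNA strand (A/G vs T/C).  Both are resolvable from the allele labels except
for palindromic SNPs (A/T or C/G), where a strand flip is indistinguishable
from an allele swap; those are kept only when the exposure effect-allele
frequency is far enough from 0.5 to make the orientation unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sumstats import AnalysisError, SummaryStatTable

logger = logging.getLogger("mrmediate")

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: exposure-EAF interval inside which palindromic SNPs are ambiguous
DEFAULT_PALINDROME_WINDOW = (0.42, 0.58)

# resolver actions
KEEP = "keep"
FLIP = "flip"          # swap orientation: negate beta, complement EAF
DROP_PALINDROMIC = "drop_palindromic"
DROP_MISMATCH = "drop_mismatch"


def complement(allele: str) -> str:
    return _COMP[allele]


def is_palindromic(ea: str, oa: str) -> bool:
    """A/T or C/G pair: strand cannot be resolved from labels alone."""
    return _COMP[ea] == oa


def resolve_alleles(ea_x: str, oa_x: str, ea_y: str, oa_y: str) -> str:
    """Action aligning a second table's row to the reference allele pair.

    Returns ``keep`` (same orientation, possibly after strand
    complementation), ``flip`` (opposite orientation: the second table's
    effect allele is the reference other allele), ``drop_palindromic``
    (orientation unresolvable from labels) or ``drop_mismatch``
    (irreconcilable allele sets).  The palindromic verdict is refined by the
    caller using allele frequency.
    """
    if is_palindromic(ea_x, oa_x):
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return DROP_MISMATCH
        return DROP_PALINDROMIC
    if (ea_y, oa_y) == (ea_x, oa_x):
        return KEEP
    if (ea_y, oa_y) == (oa_x, ea_x):
        return FLIP
    cea, coa = _COMP[ea_y], _COMP[oa_y]
    if (cea, coa) == (ea_x, oa_x):
        return KEEP
    if (cea, coa) == (oa_x, ea_x):
        return FLIP
    return DROP_MISMATCH


@dataclass
class HarmonizedInstrumentSet:
    """Aligned effect vectors for a common instrument set.

    ``beta_exposure`` and friends are (k, p) matrices — one column per
    exposure — so the same container feeds univariable MR (p = 1) and
    multivariable MR (p ≥ 2).  ``weights`` is the outcome inverse-variance
    vector w_j = 1/se_outcome_j².
    """

    snp_ids: list[str]
    exposure_names: list[str]
    outcome_name: str
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    eaf_exposure: np.ndarray
    n_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    n_outcome: np.ndarray
    drop_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta_exposure = np.atleast_2d(np.asarray(self.beta_exposure, float))
        if self.beta_exposure.shape[0] == 1 and len(self.snp_ids) != 1:
            self.beta_exposure = self.beta_exposure.T
        for name in ("se_exposure", "eaf_exposure", "n_exposure"):
            arr = np.atleast_2d(np.asarray(getattr(self, name), float))
            if arr.shape != self.beta_exposure.shape:
                arr = arr.T
            setattr(self, name, arr)
        self.beta_outcome = np.asarray(self.beta_outcome, float).ravel()
        self.se_outcome = np.asarray(self.se_outcome, float).ravel()
        self.n_outcome = np.asarray(self.n_outcome, float).ravel()
        k = len(self.snp_ids)
        if k < 1:
            raise AnalysisError("harmonized set must contain at least one SNP")
        if self.beta_exposure.shape[0] != k or self.beta_outcome.shape[0] != k:
            raise AnalysisError("harmonized vectors must share length k")
        if self.se_exposure.shape != self.beta_exposure.shape:
            raise AnalysisError("se_exposure shape mismatch")
        if not (self.se_outcome > 0).all() or not (self.se_exposure > 0).all():
            raise AnalysisError("all standard errors must be positive")

    # -- derived views -----------------------------------------------------
    @property
    def k(self) -> int:
        return len(self.snp_ids)

    @property
    def n_exposures(self) -> int:
        return self.beta_exposure.shape[1]

    @property
    def weights(self) -> np.ndarray:
        return 1.0 / self.se_outcome**2

    @property
    def bx(self) -> np.ndarray:
        """Exposure effect vector (univariable sets only)."""
        if self.n_exposures != 1:
            raise AnalysisError("bx is defined for a single exposure; use beta_exposure")
        return self.beta_exposure[:, 0]

    @property
    def se_bx(self) -> np.ndarray:
        if self.n_exposures != 1:
            raise AnalysisError("se_bx is defined for a single exposure")
        return self.se_exposure[:, 0]

    def exposure_column(self, index: int) -> "HarmonizedInstrumentSet":
        """Univariable view of one exposure (same SNPs and outcome)."""
        return HarmonizedInstrumentSet(
            snp_ids=list(self.snp_ids),
            exposure_names=[self.exposure_names[index]],
            outcome_name=self.outcome_name,
            beta_exposure=self.beta_exposure[:, [index]],
            se_exposure=self.se_exposure[:, [index]],
            eaf_exposure=self.eaf_exposure[:, [index]],
            n_exposure=self.n_exposure[:, [index]],
            beta_outcome=self.beta_outcome,
            se_outcome=self.se_outcome,
            n_outcome=self.n_outcome,
        )

    def drop_index(self, i: int) -> "HarmonizedInstrumentSet":
        keep = [j for j in range(self.k) if j != i]
        return self.subset(keep)

    def subset(self, idx: Sequence[int]) -> "HarmonizedInstrumentSet":
        idx = list(idx)
        return HarmonizedInstrumentSet(
            snp_ids=[self.snp_ids[j] for j in idx],
            exposure_names=list(self.exposure_names),
            outcome_name=self.outcome_name,
            beta_exposure=self.beta_exposure[idx],
            se_exposure=self.se_exposure[idx],
            eaf_exposure=self.eaf_exposure[idx],
            n_exposure=self.n_exposure[idx],
            beta_outcome=self.beta_outcome[idx],
            se_outcome=self.se_outcome[idx],
            n_outcome=self.n_outcome[idx],
        )


def _align_row(ref, row, window) -> tuple[str, float, float]:
    """Resolve one matched row against the reference alleles.

    Returns (action, beta, eaf) with beta/eaf already oriented when kept.
    """
    action = resolve_alleles(ref.effect_allele, ref.other_allele,
                             row.effect_allele, row.other_allele)
    if action == DROP_PALINDROMIC:
        eaf_ref = ref.eaf
        lo, hi = window
        if eaf_ref is None or pd.isna(eaf_ref) or lo <= eaf_ref <= hi:
            return DROP_PALINDROMIC, np.nan, np.nan
        # orientation inferable from frequency: the minor allele is the same
        # allele in both studies, so matching sides of 0.5 means same strand
        eaf_row = row.eaf
        if eaf_row is None or pd.isna(eaf_row):
            # fall back to the labels (same labels → same orientation)
            action = KEEP if row.effect_allele == ref.effect_allele else FLIP
        elif (eaf_ref < 0.5) == (eaf_row < 0.5):
            action = KEEP
        else:
            action = FLIP
    if action == KEEP:
        return KEEP, row.beta, row.eaf if row.eaf is not None else np.nan
    if action == FLIP:
        eaf = np.nan if row.eaf is None or pd.isna(row.eaf) else 1.0 - row.eaf
        return FLIP, -row.beta, eaf
    return action, np.nan, np.nan


def harmonize(
    exposure: SummaryStatTable,
    outcome: SummaryStatTable,
    palindrome_eaf_window: tuple[float, float] = DEFAULT_PALINDROME_WINDOW,
) -> HarmonizedInstrumentSet:
    """Align outcome effects to the exposure's effect alleles.

    For every SNP shared by the two tables: identical alleles are kept;
    swapped alleles negate the outcome beta (EAF → 1−EAF); strand complements
    are mapped back first; palindromic SNPs are kept only when the exposure
    EAF lies outside ``palindrome_eaf_window``; irreconcilable allele sets
    are dropped.  Every drop is logged with its reason.
    """
    hset = harmonize_multi([exposure], outcome, palindrome_eaf_window=palindrome_eaf_window)
    return hset


def harmonize_multi(
    exposures: Sequence[SummaryStatTable],
    outcome: SummaryStatTable,
    snp_ids: Sequence[str] | None = None,
    palindrome_eaf_window: tuple[float, float] = DEFAULT_PALINDROME_WINDOW,
) -> HarmonizedInstrumentSet:
    """Align several exposure tables and one outcome to shared effect alleles.

    The first exposure's allele coding is the reference.  ``snp_ids``
    restricts (and orders) the instrument set; by default the intersection of
    all tables in first-exposure order is used.
    """
    tables = list(exposures) + [outcome]
    by_id = []
    for t in tables:
        by_id.append({r.snp_id: r for r in t.records()})
    shared = [s for s in exposures[0].snp_ids if all(s in m for m in by_id)]
    if snp_ids is not None:
        wanted = [s for s in snp_ids]
        shared_set = {s for s in wanted if all(s in m for m in by_id)}
        for s in wanted:
            if s not in shared_set:
                logger.info("harmonize: %s dropped (absent from at least one table)", s)
        shared = [s for s in wanted if s in shared_set]
    if not shared:
        raise AnalysisError("no shared instruments between exposure and outcome tables")

    drop_log: list[tuple[str, str]] = []
    kept_ids: list[str] = []
    bx_rows, sex_rows, eafx_rows, nx_rows = [], [], [], []
    by_vals, sey_vals, ny_vals = [], [], []

    p = len(exposures)
    for snp in shared:
        ref = by_id[0][snp]
        betas = [ref.beta]
        ses = [ref.se]
        eafs = [np.nan if ref.eaf is None else ref.eaf]
        ns = [ref.n]
        ok = True
        for m in range(1, p + 1):
            row = by_id[m][snp]
            action, beta, eaf = _align_row(ref, row, palindrome_eaf_window)
            if action == DROP_PALINDROMIC:
                drop_log.append((snp, "palindromic with ambiguous EAF"))
                logger.info("harmonize: %s dropped (palindromic, exposure EAF inside window)", snp)
                ok = False
                break
            if action == DROP_MISMATCH:
                drop_log.append((snp, "irreconcilable alleles"))
                logger.info("harmonize: %s dropped (irreconcilable allele sets)", snp)
                ok = False
                break
            betas.append(beta)
            ses.append(row.se)
            eafs.append(eaf)
            ns.append(row.n)
        if not ok:
            continue
        kept_ids.append(snp)
        bx_rows.append(betas[:p])
        sex_rows.append(ses[:p])
        eafx_rows.append(eafs[:p])
        nx_rows.append(ns[:p])
        by_vals.append(betas[p])
        sey_vals.append(ses[p])
        ny_vals.append(ns[p])

    if not kept_ids:
        raise AnalysisError("no shared instruments survive harmonization")
    return HarmonizedInstrumentSet(
        snp_ids=kept_ids,
        exposure_names=[t.trait_name for t in exposures],
        outcome_name=outcome.trait_name,
        beta_exposure=np.array(bx_rows, float),
        se_exposure=np.array(sex_rows, float),
        eaf_exposure=np.array(eafx_rows, float),
        n_exposure=np.array(nx_rows, float),
        beta_outcome=np.array(by_vals, float),
        se_outcome=np.array(sey_vals, float),
        n_outcome=np.array(ny_vals, float),
        drop_log=drop_log,
    )
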