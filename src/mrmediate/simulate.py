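"""Synthetic two-sample GWAS summary statistics under a known mediation DAG.

The generator emulates the inputs of a two-step MR study: three GWAS
summary-statistics tables (exposure, mediator, outcome) measured in three
non-overlapping samples, produced by a known causal diagram

    SNPs (exposure block)  →  exposure  →  mediator  →  outcome
                                   └────────── direct path ─────────┘
    SNPs (mediator block)  →  mediator

Per SNP j with minor-allele frequency p_j, the true per-allele effects on
the standardized traits are

* exposure:  γ_j            (half-normal, exposure block only)
* mediator:  θ_xm·γ_j + δ_j (δ_j half-normal, mediator block only)
* outcome:   θ_my·(θ_xm·γ_j + δ_j) + θ_xy·γ_j + α_j·1[j invalid]

so the path-traced totals are β1 = θ_xm, β2 = θ_my, β3 = θ_xm·θ_my + θ_xy,
β3′ = θ_xy for the exposure, and the pleiotropy offsets α_j (drawn
independently of effect sizes — the InSIDE regime) corrupt a chosen share of
exposure instruments.  Each study observes ``true effect + N(0, se_j²)``
independently (two-sample structure) with the analytic standard error
se_j = 1/√(2·N·p_j(1−p_j)) of a standardized-trait additive model; in
``noise_free`` mode the true effects are reported exactly.

Effect magnitudes are drawn as |N(0, sd²)| — the effect allele is, by
convention, the trait-raising allele — which keeps directional pleiotropy
directional after MR-Egger's bx > 0 orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import COLUMNS, ConfigurationError, SummaryStatTable

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic mediation-MR study.

    Defaults: 50 exposure instruments and 50 mediator instruments, GWAS
    sample sizes of 100,000 per study, per-SNP effect scale 0.1 SD, and the
    study DAG β1 = −0.08, β2 = −0.07, direct effect 0.045 — so the total
    exposure→outcome effect is 0.0506 and the indirect effect 0.0056.
    """

    j_snps: int = 50                    # SNPs acting on the exposure
    j_snps_mediator: int = 50           # SNPs acting directly on the mediator
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exposure: int = 100_000
    n_mediator: int = 100_000
    n_outcome: int = 100_000
    gamma_sd: float = 0.1               # scale of SNP→exposure effects (SD units)
    delta_sd: float | None = None       # scale of SNP→mediator effects; default gamma_sd
    theta_xm: float = -0.08             # exposure→mediator (β1)
    theta_my: float = -0.07             # mediator→outcome (β2)
    theta_xy_direct: float = 0.045      # direct exposure→outcome (β3′)
    pleio_mean: float = 0.0             # mean pleiotropic outcome offset α_j
    pleio_sd: float = 0.0
    invalid_fraction: float = 0.0       # share of exposure instruments receiving α_j
    palindromic_fraction: float = 0.0   # share of SNPs given A/T or C/G alleles
    noise_free: bool = False
    corrupt_alleles_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < low < high ≤ 0.5")
        if not (0 <= self.invalid_fraction <= 1):
            raise ConfigurationError("invalid_fraction must lie in [0,1]")
        if min(self.n_exposure, self.n_mediator, self.n_outcome) < 2:
            raise ConfigurationError("sample sizes must be ≥ 2")
        if self.gamma_sd <= 0:
            raise ConfigurationError("gamma_sd must be positive")
        if self.delta_sd is None:
            self.delta_sd = self.gamma_sd

    @property
    def total_effect(self) -> float:
        """Path-traced exposure→outcome total: θ_xm·θ_my + θ_xy."""
        return self.theta_xm * self.theta_my + self.theta_xy_direct

    @property
    def indirect_effect(self) -> float:
        return self.theta_xm * self.theta_my


@dataclass
class SimulationTruth:
    """Ground-truth per-SNP parameters emitted alongside the tables."""

    snp_ids: list[str]
    gamma: np.ndarray           # SNP→exposure effects
    delta: np.ndarray           # direct SNP→mediator effects
    alpha: np.ndarray           # pleiotropic outcome offsets
    invalid: np.ndarray         # bool mask of pleiotropic SNPs
    maf: np.ndarray
    config: SimulationConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.snp_ids, "maf": self.maf, "gamma": self.gamma,
            "delta": self.delta, "alpha": self.alpha, "invalid": self.invalid,
        })


class Triplet(NamedTuple):
    exposure: SummaryStatTable
    mediator: SummaryStatTable
    outcome: SummaryStatTable
    truth: SimulationTruth


def _p_from_z(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, 5e-324)


def _make_table(trait, snp_ids, ea, oa, eaf, beta, se, n, blocks) -> SummaryStatTable:
    frame = pd.DataFrame({
        "snp_id": snp_ids, "effect_allele": ea, "other_allele": oa,
        "eaf": eaf, "beta": beta, "se": se, "pval": _p_from_z(beta, se),
        "n": n, "ld_block": blocks,
    })[COLUMNS]
    return SummaryStatTable(trait, frame)


def simulate_triplet(config: SimulationConfig) -> Triplet:
    """Generate (exposure, mediator, outcome) tables plus the ground truth.

    Identical seeds yield byte-identical tables.  All SNPs appear in all
    three tables; ``ld_block`` is the SNP index (every instrument
    independent).
    """
    rng = np.random.default_rng(config.seed)
    j_x, j_m = config.j_snps, config.j_snps_mediator
    j = j_x + j_m
    snp_ids = [f"rs{100 + i}" for i in range(j)]
    maf = rng.uniform(*config.maf_range, size=j)

    gamma = np.zeros(j)
    gamma[:j_x] = np.abs(rng.normal(0.0, config.gamma_sd, size=j_x))
    delta = np.zeros(j)
    delta[j_x:] = np.abs(rng.normal(0.0, config.delta_sd, size=j_m))

    invalid = np.zeros(j, dtype=bool)
    n_invalid = int(round(config.invalid_fraction * j_x))
    if n_invalid:
        invalid[rng.choice(j_x, size=n_invalid, replace=False)] = True
    alpha = np.zeros(j)
    if n_invalid:
        alpha[invalid] = rng.normal(config.pleio_mean, config.pleio_sd, size=n_invalid)

    true_x = gamma
    true_m = config.theta_xm * gamma + delta
    true_y = config.theta_my * true_m + config.theta_xy_direct * gamma + alpha

    # allele pairs: non-palindromic by default, a configurable share palindromic
    n_pal = int(round(config.palindromic_fraction * j))
    pal_idx = set(rng.choice(j, size=n_pal, replace=False).tolist()) if n_pal else set()
    ea, oa = [], []
    for i in range(j):
        pool = _PALINDROMIC_PAIRS if i in pal_idx else _NONPALINDROMIC_PAIRS
        a, b = pool[rng.integers(len(pool))]
        ea.append(a)
        oa.append(b)

    blocks = np.arange(1, j + 1)
    tables = []
    for trait, true_beta, n in (
        ("exposure", true_x, config.n_exposure),
        ("mediator", true_m, config.n_mediator),
        ("outcome", true_y, config.n_outcome),
    ):
        se = 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))
        if config.noise_free:
            beta = true_beta.copy()
        else:
            beta = true_beta + rng.normal(0.0, se)
        tables.append(_make_table(trait, snp_ids, ea, oa, maf, beta, se,
                                  np.full(j, n, dtype=int), blocks))

    exposure, mediator, outcome = tables
    if config.corrupt_alleles_fraction > 0:
        outcome, _ = corrupt_alleles(outcome, config.corrupt_alleles_fraction,
                                     seed=int(rng.integers(2**31)))

    truth = SimulationTruth(snp_ids=snp_ids, gamma=gamma, delta=delta,
                            alpha=alpha, invalid=invalid, maf=maf, config=config)
    return Triplet(exposure, mediator, outcome, truth)


def corrupt_alleles(
    table: SummaryStatTable,
    fraction: float,
    seed: int,
    mode: str = "both",
) -> tuple[SummaryStatTable, list[tuple[str, str]]]:
    """Re-code a random share of rows without changing their meaning.

    ``swap`` exchanges effect/other allele (negating beta, complementing
    EAF); ``complement`` re-reports both alleles on the opposite strand;
    ``both`` picks per row.  Harmonization against the original table must
    undo every alteration.  Returns the altered table and a ground-truth log
    of ``(snp_id, action)``.
    """
    if not (0 <= fraction <= 1):
        raise ConfigurationError("fraction must lie in [0,1]")
    if mode not in ("swap", "complement", "both"):
        raise ValueError("mode must be 'swap', 'complement' or 'both'")
    rng = np.random.default_rng(seed)
    frame = table.frame.copy()
    n = len(frame)
    n_alter = int(round(fraction * n))
    idx = rng.choice(n, size=n_alter, replace=False) if n_alter else np.array([], int)
    log: list[tuple[str, str]] = []
    for i in sorted(idx):
        if mode == "both":
            action = ("swap", "complement", "swap_complement")[rng.integers(3)]
        else:
            action = mode
        ea, oa = frame.at[i, "effect_allele"], frame.at[i, "other_allele"]
        if "swap" in action:
            ea, oa = oa, ea
            frame.at[i, "beta"] = -frame.at[i, "beta"]
            if pd.notna(frame.at[i, "eaf"]):
                frame.at[i, "eaf"] = 1.0 - frame.at[i, "eaf"]
        if "complement" in action:
            ea, oa = _COMP[ea], _COMP[oa]
        frame.at[i, "effect_allele"] = ea
        frame.at[i, "other_allele"] = oa
        log.append((frame.at[i, "snp_id"], action))
    return SummaryStatTable(table.trait_name, frame), log
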