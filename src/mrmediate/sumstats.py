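"""GWAS summary-statistics tables: data model, I/O, and instrument selection.

A summary-statistics table carries one row per SNP with its marginal
association to a single trait: effect/other allele, effect-allele frequency
(EAF), per-allele effect size ``beta`` on the standardized-trait scale, its
standard error, p-value and GWAS sample size.  An optional integer
``ld_block`` label encodes linkage-disequilibrium structure: SNPs sharing a
label are treated as correlated, and independence filtering keeps one SNP
per block (the stand-in for reference-panel clumping at r²=0.001 within
10,000 kb).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mrmediate")

VALID_ALLELES = frozenset("ACGT")

COLUMNS = ["snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n", "ld_block"]

#: default genome-wide significance threshold for instrument selection
GENOME_WIDE_P = 5.0e-8

#: F-statistic at or below this flags weak instruments
WEAK_F_THRESHOLD = 10.0


class SumstatsError(ValueError):
    """Invalid summary-statistics input."""


class ConfigurationError(ValueError):
    """Caller-side configuration problem (bad column map, missing labels)."""


class AnalysisError(RuntimeError):
    """A statistical step cannot proceed (too few SNPs, empty intersection...)."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one trait."""

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int
    ld_block: int | None = None

    def __post_init__(self) -> None:
        reason = _row_problem(
            self.effect_allele, self.other_allele, self.eaf, self.beta, self.se, self.pval, self.n
        )
        if reason:
            raise SumstatsError(f"{self.snp_id}: {reason}")


def _two_sided_p(beta: float, se: float) -> float:
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    # keep p in (0, 1] — huge z-scores underflow to exactly 0
    return max(p, 5e-324)


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def _row_problem(effect_allele, other_allele, eaf, beta, se, pval, n) -> str | None:
    """Reason a row violates the record invariants, or None if valid."""
    if effect_allele not in VALID_ALLELES or other_allele not in VALID_ALLELES:
        return "alleles must be single bases A/C/G/T (indels and multi-allelic rejected)"
    if effect_allele == other_allele:
        return "effect and other allele identical"
    if not (np.isfinite(se) and se > 0):
        return "non-positive SE"
    if not np.isfinite(beta):
        return "non-finite beta"
    if eaf is not None and not (np.isnan(eaf) or 0.0 <= eaf <= 1.0):
        return "EAF outside [0,1]"
    if not (0 < pval <= 1):
        return "p-value outside (0,1]"
    if not (np.isfinite(n) and n > 0 and float(n) == int(n)):
        return "sample size must be a positive integer"
    # p must be consistent with beta/se (to 2 significant figures, where
    # representable; far-tail p-values lose precision and are not compared)
    p_z = _two_sided_p(beta, se)
    if pval > 1e-290 and p_z > 1e-290:
        if _round_sig(pval) != _round_sig(p_z) and abs(pval - p_z) > 0.06 * max(pval, p_z):
            return f"p-value {pval:.3g} inconsistent with beta/se (implies {p_z:.3g})"
    return None


class SummaryStatTable:
    """Ordered collection of :class:`SummaryStatRecord`, unique by ``snp_id``.

    Backed by a pandas DataFrame in canonical column order; ``eaf`` and
    ``ld_block`` may be missing (NaN).
    """

    def __init__(self, trait_name: str, frame: pd.DataFrame):
        frame = frame.reset_index(drop=True)
        for col in COLUMNS:
            if col not in frame.columns:
                raise ConfigurationError(f"missing mandatory column '{col}'")
        dup = frame["snp_id"][frame["snp_id"].duplicated()]
        if len(dup):
            raise SumstatsError(f"duplicate snp_id: {sorted(set(dup))}")
        self.trait_name = trait_name
        self.frame = frame[COLUMNS].copy()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(cls, trait_name: str, records: Iterable[SummaryStatRecord]) -> "SummaryStatTable":
        rows = [
            (r.snp_id, r.effect_allele, r.other_allele,
             np.nan if r.eaf is None else r.eaf, r.beta, r.se, r.pval, r.n,
             np.nan if r.ld_block is None else r.ld_block)
            for r in records
        ]
        frame = pd.DataFrame(rows, columns=COLUMNS)
        return cls(trait_name, frame)

    # -- container protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.frame["snp_id"])

    def records(self) -> list[SummaryStatRecord]:
        out = []
        for row in self.frame.itertuples(index=False):
            out.append(SummaryStatRecord(
                snp_id=row.snp_id,
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                eaf=None if pd.isna(row.eaf) else float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                n=int(row.n),
                ld_block=None if pd.isna(row.ld_block) else int(row.ld_block),
            ))
        return out

    def subset(self, snp_ids: Sequence[str]) -> "SummaryStatTable":
        """Rows for the given SNPs, preserving this table's order."""
        keep = self.frame["snp_id"].isin(set(snp_ids))
        return SummaryStatTable(self.trait_name, self.frame[keep])

    def equals(self, other: "SummaryStatTable") -> bool:
        a, b = self.frame, other.frame
        if list(a["snp_id"]) != list(b["snp_id"]):
            return False
        for col in COLUMNS:
            x, y = a[col].to_numpy(), b[col].to_numpy()
            if col in ("snp_id", "effect_allele", "other_allele"):
                if not (x == y).all():
                    return False
            else:
                x = x.astype(float)
                y = y.astype(float)
                ok = (x == y) | (np.isnan(x) & np.isnan(y))
                if not ok.all():
                    return False
        return True


# ---------------------------------------------------------------------------
# I/O — tab-separated, GWAS-SSF-like dialect, blank cell = missing
# ---------------------------------------------------------------------------

def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str | None = None,
) -> SummaryStatTable:
    """Read a TSV of summary statistics, validating every row.

    ``column_map`` maps file header names to canonical field names, e.g.
    ``{"A1": "effect_allele"}``.  Rows violating the record invariants are
    rejected with a logged per-row reason; a missing p-value is recomputed
    from ``beta/se`` (two-sided normal).  Alleles are upper-cased.
    """
    raw = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=[""],
                      keep_default_na=True, float_precision="round_trip")
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    for col in COLUMNS:
        if col == "ld_block":
            if col not in raw.columns:
                raw[col] = np.nan
        elif col not in raw.columns:
            raise ConfigurationError(
                f"missing mandatory column '{col}' (have {list(raw.columns)}); "
                "supply a column_map"
            )
    raw = raw[COLUMNS].copy()
    raw["snp_id"] = raw["snp_id"].astype(str)
    raw["effect_allele"] = raw["effect_allele"].astype(str).str.upper()
    raw["other_allele"] = raw["other_allele"].astype(str).str.upper()

    keep_rows = []
    for idx, row in raw.iterrows():
        pval = row["pval"]
        if pd.isna(pval):
            if pd.notna(row["beta"]) and pd.notna(row["se"]) and row["se"] > 0:
                pval = _two_sided_p(float(row["beta"]), float(row["se"]))
                raw.at[idx, "pval"] = pval
            else:
                logger.warning("read_sumstats: row %s rejected: missing p-value and beta/se", row["snp_id"])
                continue
        reason = _row_problem(
            row["effect_allele"], row["other_allele"],
            None if pd.isna(row["eaf"]) else float(row["eaf"]),
            float(row["beta"]) if pd.notna(row["beta"]) else np.nan,
            float(row["se"]) if pd.notna(row["se"]) else np.nan,
            float(pval), row["n"] if pd.notna(row["n"]) else np.nan,
        )
        if reason:
            logger.warning("read_sumstats: row %s rejected: %s", row["snp_id"], reason)
        else:
            keep_rows.append(idx)
    frame = raw.loc[keep_rows]
    frame = frame.astype({"n": int})
    name = trait_name if trait_name is not None else str(path)
    return SummaryStatTable(name, frame)


def write_sumstats(table: SummaryStatTable, path) -> None:
    """Write the canonical TSV dialect; missing values as blank cells."""
    out = table.frame.copy()
    out["ld_block"] = out["ld_block"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False, na_rep="")  # str() floats round-trip


# ---------------------------------------------------------------------------
# instrument selection
# ---------------------------------------------------------------------------

def select_instruments(
    table: SummaryStatTable,
    p_threshold: float = GENOME_WIDE_P,
    one_per_block: bool = False,
) -> SummaryStatTable:
    """Genome-wide-significant, LD-independent instruments.

    Retains rows with ``pval < p_threshold``; with ``one_per_block``, keeps
    only the lowest-p SNP per ``ld_block`` (ties broken by lexicographically
    smallest snp_id).  Input order is preserved.
    """
    if not (0 < p_threshold < 1):
        raise ConfigurationError("p_threshold must be in (0,1)")
    frame = table.frame[table.frame["pval"] < p_threshold]
    if one_per_block and len(frame):
        if frame["ld_block"].isna().all():
            raise ConfigurationError(
                "one_per_block requested but no ld_block labels present; "
                "supply labels or disable the flag"
            )
        ranked = frame.sort_values(["pval", "snp_id"], kind="mergesort")
        keep_ids = set()
        seen_blocks = set()
        for row in ranked.itertuples(index=False):
            block = row.ld_block
            if pd.isna(block):
                keep_ids.add(row.snp_id)  # unlabeled SNPs treated as their own block
            elif block not in seen_blocks:
                seen_blocks.add(block)
                keep_ids.add(row.snp_id)
        dropped = [s for s in frame["snp_id"] if s not in keep_ids]
        for snp in dropped:
            logger.info("select_instruments: %s dropped (not best in ld_block)", snp)
        frame = frame[frame["snp_id"].isin(keep_ids)]
    return SummaryStatTable(table.trait_name, frame)


def substitute_proxies(
    instruments: SummaryStatTable,
    outcome: SummaryStatTable,
    proxy_map: pd.DataFrame | Sequence[tuple[str, str, float]],
    r2_threshold: float = 0.8,
) -> SummaryStatTable:
    """Replace instruments absent from the outcome table by LD proxies.

    ``proxy_map`` rows are ``(snp_id, proxy_id, r2)``.  An instrument missing
    from the outcome table is replaced by its highest-r² proxy with
    ``r² > r2_threshold`` that is present in both the instrument-source and
    outcome tables; instruments with no admissible proxy are dropped and
    logged.  The result contains only SNPs resolvable in the outcome table.
    """
    if not isinstance(proxy_map, pd.DataFrame):
        proxy_map = pd.DataFrame(list(proxy_map), columns=["snp_id", "proxy_id", "r2"])
    else:
        proxy_map = proxy_map.rename(
            columns=dict(zip(proxy_map.columns[:3], ["snp_id", "proxy_id", "r2"]))
        )
    if len(proxy_map) and not proxy_map["r2"].between(0, 1, inclusive="right").all():
        raise SumstatsError("proxy r2 values must lie in (0,1]")
    known = set(instruments.snp_ids) | set(outcome.snp_ids)
    unknown = set(proxy_map["snp_id"]) - set(instruments.snp_ids)
    unknown |= set(proxy_map["proxy_id"]) - known
    if unknown:
        raise SumstatsError(f"proxy_map references unknown SNPs: {sorted(unknown)}")

    outcome_ids = set(outcome.snp_ids)
    rows = []
    for row in instruments.frame.itertuples(index=False):
        if row.snp_id in outcome_ids:
            rows.append(pd.DataFrame([row], columns=COLUMNS))
            continue
        cand = proxy_map[(proxy_map["snp_id"] == row.snp_id) & (proxy_map["r2"] > r2_threshold)]
        cand = cand[cand["proxy_id"].isin(outcome_ids)]
        cand = cand.sort_values(["r2", "proxy_id"], ascending=[False, True], kind="mergesort")
        replaced = False
        for proxy in cand.itertuples(index=False):
            hit = instruments.frame[instruments.frame["snp_id"] == proxy.proxy_id]
            if len(hit):
                logger.info("substitute_proxies: %s replaced by proxy %s (r2=%.3g)",
                            row.snp_id, proxy.proxy_id, proxy.r2)
                rows.append(hit)
                replaced = True
                break
        if not replaced:
            logger.info("substitute_proxies: %s dropped (absent from outcome, no admissible proxy)",
                        row.snp_id)
    if rows:
        frame = pd.concat(rows, ignore_index=True).drop_duplicates(subset="snp_id")
    else:
        frame = instruments.frame.iloc[:0]
    return SummaryStatTable(instruments.trait_name, frame)


# ---------------------------------------------------------------------------
# instrument strength
# ---------------------------------------------------------------------------

def snp_r2(record: SummaryStatRecord | pd.Series) -> float:
    """Proportion of trait variance explained by one SNP.

    R² = 2β²·EAF·(1−EAF) / [2β²·EAF·(1−EAF) + SE²·2N·EAF·(1−EAF)].
    Returns NaN (with a logged warning) when EAF is missing; the total
    instrument R² is the sum of per-SNP values.
    """
    eaf = record.eaf if not isinstance(record, pd.Series) else record["eaf"]
    if eaf is None or (isinstance(eaf, float) and np.isnan(eaf)):
        snp = record.snp_id if not isinstance(record, pd.Series) else record["snp_id"]
        logger.warning("snp_r2: %s has no EAF; excluded from R²/F computation", snp)
        return float("nan")
    beta, se, n = (record.beta, record.se, record.n)
    if not (0 < eaf < 1):
        raise SumstatsError("snp_r2 requires EAF in (0,1)")
    num = 2.0 * beta**2 * eaf * (1.0 - eaf)
    den = num + se**2 * 2.0 * n * eaf * (1.0 - eaf)
    return num / den


def f_statistic(r2_total: float, n: int, k: int) -> float:
    """Instrument-strength F = [(N−k−1)/k] · [R²/(1−R²)]; F ≤ 10 is weak."""
    if not (0 <= r2_total < 1):
        raise AnalysisError("total R² must lie in [0,1)")
    if n <= k + 1:
        raise AnalysisError("insufficient sample size for F (need N > k+1)")
    f = ((n - k - 1) / k) * (r2_total / (1.0 - r2_total))
    if f <= WEAK_F_THRESHOLD:
        logger.warning("f_statistic: F = %.3g ≤ 10 — weak instruments", f)
    return f


def table_r2_total(table: SummaryStatTable) -> tuple[float, int]:
    """Summed per-SNP R² over SNPs with EAF, and the count contributing."""
    vals = [snp_r2(r) for r in table.records()]
    arr = np.asarray(vals, dtype=float)
    ok = ~np.isnan(arr)
    return float(arr[ok].sum()), int(ok.sum())
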