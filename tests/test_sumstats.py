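"""Summary-statistics I/O, instrument selection, and strength statistics."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrmediate import (
    ConfigurationError,
    SummaryStatRecord,
    SummaryStatTable,
    SumstatsError,
    f_statistic,
    read_sumstats,
    select_instruments,
    snp_r2,
    substitute_proxies,
    write_sumstats,
)
from mrmediate.sumstats import AnalysisError, _two_sided_p


def rec(snp, beta=0.1, se=0.01, eaf=0.3, n=10_000, ea="A", oa="G", block=None, pval=None):
    return SummaryStatRecord(
        snp_id=snp, effect_allele=ea, other_allele=oa, eaf=eaf, beta=beta, se=se,
        pval=pval if pval is not None else _two_sided_p(beta, se), n=n, ld_block=block,
    )


def rec_p(snp, pval, se=0.01, block=None, **kw):
    """Record whose beta is exactly consistent with the requested p-value."""
    beta = float(stats.norm.isf(pval / 2) * se)
    return rec(snp, beta=beta, se=se, pval=pval, block=block, **kw)


def table(records, name="trait"):
    return SummaryStatTable.from_records(name, records)


class TestRecordValidation:
    def test_rejects_identical_alleles(self):
        with pytest.raises(SumstatsError, match="identical"):
            rec("rs1", ea="A", oa="A")

    def test_rejects_nonpositive_se(self):
        with pytest.raises(SumstatsError, match="SE"):
            rec("rs1", se=0.0, pval=0.5)

    def test_rejects_indel_alleles(self):
        with pytest.raises(SumstatsError, match="single bases"):
            SummaryStatRecord("rs1", "AT", "G", 0.3, 0.1, 0.01, 0.5, 100)

    def test_rejects_inconsistent_pval(self):
        # z = 10 implies p ~ 1.5e-23; p = 0.5 is inconsistent
        with pytest.raises(SumstatsError, match="inconsistent"):
            rec("rs1", beta=0.1, se=0.01, pval=0.5)

    def test_duplicate_snp_id_rejected(self):
        with pytest.raises(SumstatsError, match="duplicate"):
            table([rec("rs1"), rec("rs1")])


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path):
        t = table([rec("rs1", eaf=0.25, block=3), rec("rs2", beta=-0.05, eaf=None),
                   rec("rs3", ea="T", oa="C", n=555)])
        path = tmp_path / "t.tsv"
        write_sumstats(t, path)
        back = read_sumstats(path, trait_name="trait")
        assert back.equals(t)

    def test_empty_table_round_trips(self, tmp_path):
        t = SummaryStatTable("x", pd.DataFrame(columns=pd.Index(
            ["snp_id", "effect_allele", "other_allele", "eaf", "beta", "se",
             "pval", "n", "ld_block"])))
        path = tmp_path / "e.tsv"
        write_sumstats(t, path)
        assert len(read_sumstats(path)) == 0

    def test_missing_eaf_round_trips_as_missing(self, tmp_path):
        t = table([rec("rs1", eaf=None)])
        path = tmp_path / "m.tsv"
        write_sumstats(t, path)
        back = read_sumstats(path)
        assert back.records()[0].eaf is None


class TestRead:
    def test_column_map_alias(self, tmp_path):
        t = table([rec("rs1"), rec("rs2", beta=-0.02)])
        canonical = tmp_path / "canonical.tsv"
        write_sumstats(t, canonical)
        aliased = tmp_path / "aliased.tsv"
        txt = canonical.read_text().replace("effect_allele", "A1").replace("pval", "P")
        aliased.write_text(txt)
        back = read_sumstats(aliased, column_map={"A1": "effect_allele", "P": "pval"},
                             trait_name="trait")
        assert back.equals(t)

    def test_missing_mandatory_column_is_config_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("snp_id\tbeta\nrs1\t0.1\n")
        with pytest.raises(ConfigurationError, match="mandatory column"):
            read_sumstats(path)

    def test_bad_rows_rejected_and_logged(self, tmp_path, caplog):
        path = tmp_path / "rows.tsv"
        good = rec("rs1")
        path.write_text(
            "snp_id\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n"
            f"rs1\tA\tG\t0.3\t0.1\t0.01\t{good.pval:.17g}\t10000\n"
            "rs2\tA\tG\t0.3\t0.1\t0\t0.5\t10000\n"  # se = 0
        )
        with caplog.at_level(logging.WARNING, logger="mrmediate"):
            t = read_sumstats(path)
        assert t.snp_ids == ["rs1"]
        assert any("non-positive SE" in m for m in caplog.messages)

    def test_missing_pval_recomputed(self, tmp_path):
        path = tmp_path / "nop.tsv"
        path.write_text(
            "snp_id\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n"
            "rs1\tA\tG\t0.3\t0.1\t0.01\t\t10000\n"
        )
        t = read_sumstats(path)
        assert t.records()[0].pval == pytest.approx(2 * stats.norm.sf(10))


class TestSelectInstruments:
    def test_genome_wide_threshold(self):
        t = table([rec_p("rs1", 1e-9), rec_p("rs2", 1e-7), rec_p("rs3", 1e-10)])
        out = select_instruments(t, 5e-8)
        assert out.snp_ids == ["rs1", "rs3"]

    def test_one_per_block_keeps_lowest_p(self):
        t = table([rec_p("rs1", 1e-12, block=7), rec_p("rs2", 1e-9, block=7)])
        out = select_instruments(t, 5e-8, one_per_block=True)
        assert out.snp_ids == ["rs1"]

    def test_block_tie_breaks_lexicographically(self):
        t = table([rec_p("rsB", 1e-9, block=1), rec_p("rsA", 1e-9, block=1)])
        out = select_instruments(t, 5e-8, one_per_block=True)
        assert out.snp_ids == ["rsA"]

    def test_empty_in_empty_out(self):
        t = table([rec_p("rs1", 0.5)])
        assert len(select_instruments(t, 5e-8)) == 0

    def test_one_per_block_without_labels_errors(self):
        t = table([rec_p("rs1", 1e-9)])
        with pytest.raises(ConfigurationError, match="ld_block"):
            select_instruments(t, 5e-8, one_per_block=True)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_subset_and_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(12):
            beta = rng.normal(0, 0.05)
            recs.append(rec(f"rs{i}", beta=beta, se=0.01,
                            block=int(rng.integers(1, 5))))
        t = table(recs)
        once = select_instruments(t, 5e-8, one_per_block=True)
        twice = select_instruments(once, 5e-8, one_per_block=True)
        assert set(once.snp_ids) <= set(t.snp_ids)
        assert once.snp_ids == twice.snp_ids


class TestProxies:
    def _tables(self):
        inst = table([rec("rs1"), rec("rs2", beta=0.09)], name="exp")
        outcome = table([rec("rs2", beta=0.01), rec("rs3", beta=0.02)], name="out")
        return inst, outcome

    def test_high_r2_proxy_substituted(self):
        inst = table([rec("rs1"), rec("rs2", beta=0.09)], name="exp")
        outcome = table([rec("rs2", beta=0.01)], name="out")
        out = substitute_proxies(inst, outcome, [("rs1", "rs2", 0.95)])
        assert out.snp_ids == ["rs2"]

    def test_low_r2_proxy_not_used(self):
        inst, outcome = self._tables()
        out = substitute_proxies(inst, outcome, [("rs1", "rs2", 0.7)])
        assert out.snp_ids == ["rs2"]  # rs1 dropped

    def test_all_present_is_noop(self):
        inst = table([rec("rs2"), rec("rs3")], name="exp")
        outcome = table([rec("rs2"), rec("rs3")], name="out")
        out = substitute_proxies(inst, outcome, [])
        assert out.snp_ids == inst.snp_ids

    def test_unknown_proxy_snp_errors(self):
        inst, outcome = self._tables()
        with pytest.raises(SumstatsError, match="unknown"):
            substitute_proxies(inst, outcome, [("rsX", "rs2", 0.9)])


class TestStrength:
    def test_snp_r2_hand_value(self):
        # 2·0.01·0.25 / (2·0.01·0.25 + 0.0001·2·1000·0.25) = 0.005/0.055 = 1/11
        r = rec("rs1", beta=0.1, se=0.01, eaf=0.5, n=1000)
        assert snp_r2(r) == pytest.approx(1 / 11, rel=1e-12)

    def test_zero_beta_zero_r2(self):
        assert snp_r2(rec("rs1", beta=0.0, se=0.01, pval=1.0)) == 0.0

    def test_missing_eaf_propagates_nan(self, caplog):
        with caplog.at_level(logging.WARNING, logger="mrmediate"):
            out = snp_r2(rec("rs1", eaf=None))
        assert np.isnan(out)
        assert any("EAF" in m for m in caplog.messages)

    @given(st.floats(0.01, 0.99), st.floats(-0.5, 0.5), st.floats(0.001, 0.1),
           st.integers(100, 10**6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_r2_invariant_under_allele_recoding(self, eaf, beta, se, n):
        """R² is unchanged by flipping which allele is 'effect'."""
        a = rec("rs1", beta=beta, se=se, eaf=eaf, n=n)
        b = rec("rs1", beta=-beta, se=se, eaf=1 - eaf, n=n,
                pval=_two_sided_p(-beta, se))
        assert snp_r2(a) == pytest.approx(snp_r2(b), rel=1e-9, abs=1e-15)

    def test_f_statistic_hand_values(self):
        assert f_statistic(0.1, 901, 9) == pytest.approx(11.0, rel=1e-12)
        assert f_statistic(0.5, 21, 10) == pytest.approx(1.0, rel=1e-12)
        assert f_statistic(0.0, 100, 5) == 0.0

    def test_f_statistic_insufficient_n(self):
        with pytest.raises(AnalysisError, match="sample size"):
            f_statistic(0.1, 10, 9)
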