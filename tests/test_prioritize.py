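import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sccismr.cis_likelihood import CisMLResult
from sccismr.coloc import ColocResult
from sccismr.instruments import LDMatrix
from sccismr.mr_core import MRResult
from sccismr.prioritize import (
    AD_CELLTYPE_GENE_COUNTS,
    AD_SINGLE_CELLTYPE_GENES,
    AD_UNIQUE_GENES,
    assign_genes_to_loci,
    attach_fdr,
    bulk_concordance,
    conditional_odds_ratio,
    fisher_enrichment,
    gws_leads,
    single_context_share,
    three_step_filter,
)
from sccismr.sumstats import GeneRecord


def _mr(gene="G1", cell="c1", est=0.5, p=1e-5, fdr=0.01, methods=()):
    primary = MRResult(gene, cell, "ivw", est, 0.1, p, 3, fdr_q=fdr)
    out = [primary]
    for m, e, pp, int_p in methods:
        r = MRResult(gene, cell, m, e, 0.1, pp, 3)
        if m == "egger":
            r.egger_intercept = 0.0
            r.egger_intercept_p = int_p
        out.append(r)
    return out


def _gate(gene="G1", cell="c1", alpha_p=0.01, sigma_p=0.5):
    return CisMLResult(gene, cell, 0.4, alpha_p, 0.0, sigma_p, 20)


def _coloc(gene="G1", cell="c1", h3=0.1, h4=0.8):
    pp = np.array([1 - 0.05 - h3 - h4, 0.03, 0.02, h3, h4])
    return ColocResult(gene, cell, pp, h4 / (h3 + h4), h4 / (h3 + h4) >= 0.6,
                       25)


class TestThreeStepFilter:
    def test_all_steps_pass(self):
        key = ("G1", "c1")
        recs = three_step_filter(
            {key: _mr(methods=[("weighted_median", 0.45, 0.01, None),
                               ("egger", 0.52, 0.03, 0.4)])},
            {key: _gate()},
            {key: _coloc()},
        )
        assert recs[0].prioritized
        assert recs[0].step1_pass and recs[0].step2_pass and recs[0].step3_pass

    def test_significant_egger_intercept_fails_step1(self):
        key = ("G1", "c1")
        recs = three_step_filter(
            {key: _mr(fdr=0.04, methods=[("egger", 0.5, 0.02, 0.01)])},
            {key: _gate()}, {key: _coloc()},
        )
        assert not recs[0].step1_pass
        assert not recs[0].prioritized

    def test_discordant_sensitivity_sign_fails_step1(self):
        key = ("G1", "c1")
        recs = three_step_filter(
            {key: _mr(methods=[("weighted_median", -0.3, 0.01, None)])},
            {key: _gate()}, {key: _coloc()},
        )
        assert not recs[0].step1_pass

    def test_weak_coloc_ratio_fails_step3(self):
        key = ("G1", "c1")
        recs = three_step_filter(
            {key: _mr()}, {key: _gate()}, {key: _coloc(h3=0.45, h4=0.55)},
        )
        assert not recs[0].step3_pass
        assert not recs[0].prioritized

    def test_missing_gate_or_coloc_fails_that_step(self):
        key = ("G1", "c1")
        recs = three_step_filter({key: _mr()}, {}, {key: _coloc()})
        assert not recs[0].step2_pass
        recs = three_step_filter({key: _mr()}, {key: _gate()}, {})
        assert not recs[0].step3_pass

    def test_relaxing_thresholds_is_monotone(self):
        keys = [("G", f"c{i}") for i in range(6)]
        mr = {k: _mr(cell=k[1], fdr=0.01 + 0.01 * i)
              for i, k in enumerate(keys)}
        gate = {k: _gate(cell=k[1]) for k in keys}
        coloc = {k: _coloc(cell=k[1], h3=0.3, h4=0.45 + 0.05 * i)
                 for i, k in enumerate(keys)}
        strict = {r.cell_type for r in three_step_filter(
            mr, gate, coloc, fdr_threshold=0.03, coloc_threshold=0.7)
            if r.prioritized}
        relaxed = {r.cell_type for r in three_step_filter(
            mr, gate, coloc, fdr_threshold=0.06, coloc_threshold=0.55)
            if r.prioritized}
        assert strict <= relaxed

    def test_attach_fdr_pools_primary_pvalues(self):
        mr = {("G1", "c"): _mr(p=0.01), ("G2", "c"): _mr("G2", p=0.02),
              ("G3", "c"): _mr("G3", p=0.03), ("G4", "c"): _mr("G4", p=0.04)}
        for v in mr.values():
            v[0].fdr_q = None
        attach_fdr(mr)
        assert all(v[0].fdr_q == pytest.approx(0.04) for v in mr.values())


class TestGwsLeads:
    def _gwas(self, rows):
        return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "p"])

    def _ld(self, ids, r2_off):
        r = np.full((len(ids), len(ids)), np.sqrt(r2_off))
        np.fill_diagonal(r, 1.0)
        return {"1": LDMatrix(ids, r)}

    def test_close_pair_collapses_to_one_lead(self):
        gwas = self._gwas([["a", "1", 1_000_000, 1e-9],
                           ["b", "1", 1_100_000, 1e-8]])
        leads = gws_leads(gwas, self._ld(["a", "b"], 0.0005))
        assert list(leads["variant_id"]) == ["a"]

    def test_distant_pair_keeps_both(self):
        gwas = self._gwas([["a", "1", 1_000_000, 1e-9],
                           ["b", "1", 1_600_001, 1e-8]])
        leads = gws_leads(gwas, self._ld(["a", "b"], 0.0005))
        assert sorted(leads["variant_id"]) == ["a", "b"]

    def test_high_ld_distant_pair_collapses(self):
        gwas = self._gwas([["a", "1", 1_000_000, 1e-9],
                           ["b", "1", 2_000_000, 1e-8]])
        leads = gws_leads(gwas, self._ld(["a", "b"], 0.01))
        assert list(leads["variant_id"]) == ["a"]

    def test_no_gws_variants_gives_empty(self):
        gwas = self._gwas([["a", "1", 1_000_000, 1e-6]])
        assert gws_leads(gwas, self._ld(["a"], 0.0)).empty


class TestAssignGenes:
    LEADS = pd.DataFrame({"variant_id": ["a"], "chrom": ["1"],
                          "pos": [10_000_000], "p": [1e-9]})

    def test_gene_inside_window_assigned(self):
        genes = [GeneRecord("G1", "1", 10_400_000, 10_450_000)]
        assert assign_genes_to_loci(genes, self.LEADS)["G1"]

    def test_gene_just_beyond_window_not_assigned(self):
        genes = [GeneRecord("G1", "1", 11_000_001, 11_050_000)]
        assert not assign_genes_to_loci(genes, self.LEADS)["G1"]

    def test_other_chromosome_not_assigned(self):
        genes = [GeneRecord("G1", "2", 10_400_000, 10_450_000)]
        assert not assign_genes_to_loci(genes, self.LEADS)["G1"]

    def test_partial_overlap_counts(self):
        genes = [GeneRecord("G1", "1", 8_900_000, 9_100_000)]
        assert assign_genes_to_loci(genes, self.LEADS)["G1"]


class TestFisherEnrichment:
    COUNTS = [(ct, k, n) for ct, (k, n) in AD_CELLTYPE_GENE_COUNTS.items()]

    def test_reproduces_published_odds_ratios(self):
        rows = {r.cell_type: r for r in fisher_enrichment(self.COUNTS)}
        assert rows["CD4_SOX4"].odds_ratio == pytest.approx(2.895, abs=0.01)
        assert rows["NK"].odds_ratio == pytest.approx(0.686, abs=0.01)
        assert rows["DC"].odds_ratio == pytest.approx(1.552, abs=0.01)
        assert rows["CD8_S100B"].odds_ratio == pytest.approx(1.318, abs=0.01)
        assert rows["CD4_SOX4"].p == pytest.approx(0.009, abs=0.002)

    def test_counts_at_global_rate_give_unit_odds_ratio(self):
        counts = [("x", 10, 1000), ("y", 10, 1000), ("z", 10, 1000)]
        rows = fisher_enrichment(counts)
        for r in rows:
            assert r.odds_ratio == pytest.approx(1.0, abs=0.02)
            assert r.p == pytest.approx(1.0, abs=0.05)

    def test_tables_conserve_grand_totals(self):
        K = sum(k for _, k, _ in self.COUNTS)
        N = sum(n for _, _, n in self.COUNTS)
        # in the textbook layout the four cells always sum to N
        for ct, k, n in self.COUNTS:
            cells = [k, n - k, K - k, (N - n) - (K - k)]
            assert sum(cells) == N

    def test_sample_and_conditional_or_agree_within_15pct(self):
        K = sum(k for _, k, _ in self.COUNTS)
        N = sum(n for _, _, n in self.COUNTS)
        for ct, k, n in self.COUNTS:
            table = np.array([[k, n - k], [K - k, (N - n) - (K - k)]])
            sample = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
            cmle = conditional_odds_ratio(table)
            assert abs(cmle - sample) / sample < 0.15

    def test_fisher_p_matches_scipy_on_textbook_layout(self):
        rows = fisher_enrichment(self.COUNTS, margins="nonsig")
        K = sum(k for _, k, _ in self.COUNTS)
        N = sum(n for _, _, n in self.COUNTS)
        for r in rows:
            k, n = AD_CELLTYPE_GENE_COUNTS[r.cell_type]
            table = [[k, n - k], [K - k, (N - n) - (K - k)]]
            assert r.p == pytest.approx(
                stats.fisher_exact(table)[1], rel=1e-12)

    def test_requires_two_cell_types(self):
        with pytest.raises(ValueError):
            fisher_enrichment([("x", 1, 10)])


class TestSingleContextShare:
    def test_published_share_arithmetic(self):
        rows = [{"gene_id": f"g{i}", "cell_type": "c0"}
                for i in range(AD_SINGLE_CELLTYPE_GENES)]
        for i in range(AD_SINGLE_CELLTYPE_GENES, AD_UNIQUE_GENES):
            rows.append({"gene_id": f"g{i}", "cell_type": "c0"})
            rows.append({"gene_id": f"g{i}", "cell_type": "c1"})
        single, unique, pct = single_context_share(pd.DataFrame(rows))
        assert (single, unique) == (108, 162)
        assert pct == 66.67


class TestBulkConcordance:
    def _sc(self, estimates, cell="c1"):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(estimates))],
            "cell_type": cell,
            "estimate": estimates,
            "fdr_q": 0.01,
            "prioritized": True,
        })

    def test_identical_estimates_correlate_perfectly(self):
        sc = self._sc([0.1, 0.3, -0.2, 0.4])
        bulk = sc[["gene_id", "estimate"]].assign(fdr_q=0.01)
        inter, corr = bulk_concordance(sc, bulk)
        assert corr["pearson_r"].iloc[0] == pytest.approx(1.0)
        assert inter["fraction"].iloc[0] == pytest.approx(1.0)

    def test_flipped_estimates_anticorrelate(self):
        sc = self._sc([0.1, 0.3, -0.2, 0.4])
        bulk = sc[["gene_id"]].assign(estimate=-sc["estimate"], fdr_q=0.01)
        inter, corr = bulk_concordance(sc, bulk)
        assert corr["pearson_r"].iloc[0] == pytest.approx(-1.0)
        assert inter["fraction"].iloc[0] == 0.0  # sign-discordant

    def test_too_few_shared_genes_undefined(self):
        sc = self._sc([0.1, 0.3])
        bulk = sc[["gene_id", "estimate"]].assign(fdr_q=0.01)
        _, corr = bulk_concordance(sc, bulk)
        assert np.isnan(corr["pearson_r"].iloc[0])
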