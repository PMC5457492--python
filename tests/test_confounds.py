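"""Artifact analyses: multiplicity, amplicons, categories, bidirectional promoters."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from duoscreen import confounds as cf
from duoscreen import call_essential, score_genes, screen_lfc
from duoscreen.quant import FoldChangeVector
from duoscreen.screen_io import GenomeModel, SgRNARecord, TSSRecord, revcomp


def _tss(gene, pos, strand, chrom="chr1", height=10.0, rank=1):
    return TSSRecord(gene=gene, chrom=chrom, position=pos, strand=strand,
                     peak_height=height, rank_within_gene=rank)


class TestTargetMultiplicity:
    @pytest.fixture(scope="class")
    def planted(self):
        rng = np.random.default_rng(21)
        spacer = "".join(rng.choice(list("ACGT"), 20))
        # 1-mismatch neighbour of the spacer
        neighbour = ("T" if spacer[7] != "T" else "A").join([spacer[:7], spacer[8:]])
        backbone = "".join(rng.choice(list("AT"), 900))
        seq = (backbone[:100] + spacer + backbone[100:300] + spacer + backbone[300:500]
               + revcomp(spacer) + backbone[500:700] + neighbour + backbone[700:])
        return spacer, GenomeModel({"chr1": seq})

    def test_exact_counts_all_strand_hits(self, planted):
        spacer, genome = planted
        assert cf.target_multiplicity(spacer, genome, "exact") == 3

    def test_one_mismatch_adds_neighbour(self, planted):
        spacer, genome = planted
        assert cf.target_multiplicity(spacer, genome, "one_mismatch") == 4

    def test_partial_seed_matches(self, planted):
        spacer, genome = planted
        # the 3' 12-mer seed is shared by all four planted sites
        assert cf.target_multiplicity(spacer, genome, "partial") >= 3

    def test_absent_spacer_is_zero(self):
        genome = GenomeModel({"chr1": "AT" * 200})
        assert cf.target_multiplicity("G" * 20, genome, "exact") == 0

    def test_short_spacer_rejected_for_partial(self):
        genome = GenomeModel({"chr1": "AT" * 50})
        with pytest.raises(Exception):
            cf.target_multiplicity("ACGTACG", genome, "partial")

    def test_unknown_mode_rejected(self, planted):
        spacer, genome = planted
        with pytest.raises(Exception):
            cf.target_multiplicity(spacer, genome, "bowtie")


class TestMultiplicityEffect:
    def _inputs(self):
        rng = np.random.default_rng(2)
        lib, mult, lfc_c, lfc_k = [], {}, {}, {}
        for i, m in enumerate([1] * 10 + [3] * 10 + [8] * 10):
            sid = f"g{i}"
            lib.append(SgRNARecord(sid, "ACGT" * 5, "chr1", 100 + i, "+", "X", "exon"))
            mult[sid] = m
            # cutting toxicity proportional to extra target sites; none in CRISPRi
            lfc_c[sid] = -0.2 * (m - 1) + rng.normal(0, 0.05)
            lfc_k[sid] = rng.normal(0, 0.05)
        fc = lambda d: FoldChangeVector(lfc=pd.Series(d), condition_pair=("early", "late"))
        return lib, mult, {"cas9": fc(lfc_c), "krab_dcas9": fc(lfc_k)}

    def test_cas9_medians_decrease_with_multiplicity(self):
        lib, mult, fcs = self._inputs()
        summary = cf.multiplicity_effect(fcs, lib, mult)
        cas9 = summary[summary.modality == "cas9"].set_index("bin")["median_lfc"]
        assert cas9["1"] > cas9["2-5"] > cas9[">=6"]

    def test_krab_medians_flat(self):
        lib, mult, fcs = self._inputs()
        summary = cf.multiplicity_effect(fcs, lib, mult)
        krab = summary[summary.modality == "krab_dcas9"]["median_lfc"]
        assert krab.abs().max() < 0.1

    def test_summary_matches_percentile_oracle(self):
        lib, mult, fcs = self._inputs()
        summary = cf.multiplicity_effect(fcs, lib, mult)
        row = summary[(summary.modality == "cas9") & (summary["bin"] == "1")].iloc[0]
        vals = [fcs["cas9"].lfc[f"g{i}"] for i in range(10)]
        q25, med, q75 = np.percentile(vals, [25, 50, 75])
        assert row.median_lfc == pytest.approx(med)
        assert row.q25 == pytest.approx(q25) and row.q75 == pytest.approx(q75)
        assert row.n == 10

    def test_empty_bins_are_missing_not_rows(self):
        lib, mult, fcs = self._inputs()
        only_single = {k: 1 for k in mult}
        summary = cf.multiplicity_effect(fcs, lib, only_single)
        assert set(summary["bin"]) == {"1"}


class TestCategorize:
    def test_set_algebra_example(self):
        cats = cf.category_sets(
            cf.categorize_genes({"A", "B"}, {"B", "C"}, {"A", "B", "C", "D"})
        )
        assert cats == {"both": {"B"}, "cas9_only": {"A"}, "krab_only": {"C"}, "neither": {"D"}}

    def test_identical_calls_have_no_specific_categories(self):
        cats = cf.category_sets(cf.categorize_genes({"A"}, {"A"}, {"A", "B"}))
        assert cats["cas9_only"] == set() and cats["krab_only"] == set()

    def test_partition_covers_universe(self):
        universe = {f"g{i}" for i in range(30)}
        cats = cf.category_sets(
            cf.categorize_genes({"g1", "g2", "g3"}, {"g3", "g4"}, universe)
        )
        assert sum(len(v) for v in cats.values()) == len(universe)


def fisher_two_sided_oracle(a, b, c, d):
    """Exact hypergeometric enumeration with integer arithmetic."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    def weight(k):
        return math.comb(r1, k) * math.comb(n - r1, c1 - k)
    obs = weight(a)
    total = math.comb(n, c1)
    num = sum(weight(k) for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
              if weight(k) <= obs)
    return num / total


class TestFisher:
    def test_worked_example_34_over_70(self):
        _, p = cf.fisher_exact_2x2(3, 1, 1, 3)
        assert p == pytest.approx(34 / 70)

    def test_agrees_with_enumeration_on_sampled_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(80):
            a, b, c, d = rng.integers(0, 10, size=4)
            if a + b + c + d == 0:
                continue
            _, p = cf.fisher_exact_2x2(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), abs=1e-12)

    def test_extreme_table_gets_finite_corrected_odds_ratio(self):
        orat, p = cf.fisher_exact_2x2(5, 0, 0, 5)
        assert np.isfinite(orat) and orat > 1
        assert p == pytest.approx(1 / math.comb(10, 5) * 2, rel=1e-9)

    def test_null_simulation_p_roughly_uniform(self):
        rng = np.random.default_rng(23)
        universe = {f"g{i}" for i in range(60)}
        ps = []
        for _ in range(200):
            cat = set(rng.choice(sorted(universe), 15, replace=False))
            prop = set(rng.choice(sorted(universe), 15, replace=False))
            ps.append(cf.fisher_enrichment(cat, prop, universe)[1])
        ps = np.array(ps)
        # discrete conservative p-values: sub-uniform tail
        assert (ps < 0.05).mean() <= 0.08
        assert np.median(ps) > 0.3

    def test_empty_universe_rejected(self):
        with pytest.raises(Exception):
            cf.fisher_enrichment(set(), set(), set())


class TestBidirectional:
    def test_divergent_within_1kb_is_a_pair(self):
        tss = [_tss("A", 1000, "-"), _tss("B", 1800, "+")]
        pairs, frac = cf.detect_bidirectional(tss)
        assert len(pairs) == 1 and pairs[0].tss_distance == 800
        assert frac == 1.0

    def test_beyond_threshold_is_not(self):
        tss = [_tss("A", 1000, "-"), _tss("B", 2200, "+")]
        pairs, frac = cf.detect_bidirectional(tss)
        assert pairs == [] and frac == 0.0

    @pytest.mark.parametrize(
        "strands", [("+", "-"), ("+", "+"), ("-", "-")],
        ids=["convergent", "tandem_plus", "tandem_minus"],
    )
    def test_non_divergent_orientations_excluded(self, strands):
        sa, sb = strands
        tss = [_tss("A", 1000, sa), _tss("B", 1500, sb)]
        assert cf.detect_bidirectional(tss)[0] == []

    def test_row_order_and_gene_order_invariant(self):
        tss = [_tss("A", 1000, "-"), _tss("B", 1600, "+"), _tss("C", 9000, "+")]
        p1, f1 = cf.detect_bidirectional(tss)
        p2, f2 = cf.detect_bidirectional(list(reversed(tss)))
        assert {(p.gene_a, p.gene_b) for p in p1} == {(p.gene_a, p.gene_b) for p in p2}
        assert f1 == f2 == pytest.approx(2 / 3)

    def test_secondary_tss_ignored(self):
        tss = [
            _tss("A", 1000, "-"),
            _tss("B", 1800, "+", rank=2, height=5),
            _tss("B", 50_000, "+", rank=1, height=50),
        ]
        assert cf.detect_bidirectional(tss)[0] == []


class TestOnSimulatedConfoundScreen:
    """End-to-end artifact recovery on a small screen with both mechanisms on."""

    @pytest.fixture(scope="class")
    def calls(self, confound_exp):
        out = {}
        for modality, mode in (("cas9", "exon"), ("krab_dcas9", "primary_tss")):
            fc = screen_lfc(confound_exp.counts[modality], confound_exp.library)
            out[modality] = (fc, call_essential(score_genes(fc, confound_exp.library, mode)))
        return out

    def test_amplicon_scan_separates_driver_from_passengers(self, confound_exp, calls):
        exp = confound_exp
        amp = sorted(exp.truth.amplified_genes)
        fc_c, _ = calls["cas9"]
        fc_k, _ = calls["krab_dcas9"]
        cas9_scores = cf.amplicon_scan(fc_c, exp.library, amp, "cas9")
        krab_scores = cf.amplicon_scan(fc_k, exp.library, amp, "krab_dcas9")
        # cleavage toxicity drags every amplified gene down in the cutting screen
        assert np.mean(list(cas9_scores.values())) < -0.5
        # CRISPRi sees no amplicon-wide depletion (no essential drivers planted)
        assert abs(np.mean(list(krab_scores.values()))) < 0.5

    def test_gene_score_is_exact_guide_mean(self, confound_exp, calls):
        exp = confound_exp
        fc_c, _ = calls["cas9"]
        gene = sorted(exp.truth.amplified_genes)[0]
        ids = [r.spacer_id for r in exp.library
               if r.target_gene == gene and r.target_class == "exon"]
        score = cf.amplicon_scan(fc_c, exp.library, [gene], "cas9")[gene]
        assert score == pytest.approx(float(fc_c.lfc[ids].mean()))

    def test_double_dissociation(self, confound_exp, calls):
        exp = confound_exp
        universe = set(exp.truth.gene_effects)
        cats = cf.category_sets(
            cf.categorize_genes(calls["cas9"][1], calls["krab_dcas9"][1], universe)
        )
        amp = cf.amplified_genes(exp.tss_records, exp.genome)
        bid = cf.bidirectional_genes(exp.tss_records)
        assert amp == exp.truth.amplified_genes
        _, p_amp = cf.fisher_enrichment(cats["cas9_only"], amp, universe)
        _, p_bid = cf.fisher_enrichment(cats["krab_only"], bid, universe)
        assert p_amp < 0.01
        assert p_bid < 0.01

    def test_proximity_bias_concentrates_below_1kb(self, confound_exp, calls):
        exp = confound_exp
        prox = cf.proximity_to_essential(
            exp.tss_records, exp.truth.essential_genes, calls["krab_dcas9"][1]
        ).set_index("bin")
        near = prox.loc["[0,1000)", "fraction_called"]
        far = prox.loc["[10000,inf)", "fraction_called"]
        assert near > far + 0.5

    def test_no_essential_reference_gives_missing_bins(self, confound_exp):
        prox = cf.proximity_to_essential(confound_exp.tss_records, set(), set())
        assert prox["fraction_called"].isna().all()
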