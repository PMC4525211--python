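import pytest

from chriplex.annotation import Annotation, TranscriptModel
from chriplex.peaks import (
    GeneSet,
    Peak,
    associate_peaks,
    benjamini_hochberg,
    build_regulatory_domains,
    fisher_gene_set_enrichment,
    ga_content_enrichment,
    intersect_with_marks,
)
from conftest import random_dna
from oracles import (
    association_oracle,
    fisher_one_sided_oracle,
    quadratic_intersection_oracle,
)


def _single_gene(strand="+", tss_exon=(500_000, 501_000)):
    return Annotation(
        [
            TranscriptModel(
                transcript_id="tx1",
                gene_id="g1",
                chrom="chr1",
                strand=strand,
                exons=(tss_exon,),
            )
        ]
    )


class TestRegulatoryDomains:
    def test_single_gene_extends_to_max(self):
        domains = build_regulatory_domains(
            _single_gene(), chrom_sizes={"chr1": 2_000_000}
        )
        (dom,) = domains
        assert dom.basal == (495_000, 501_000)
        assert dom.extended == (0, 1_500_000)

    def test_two_genes_meet_at_neighbour_basal(self):
        # TSSs 10 kb apart on the plus strand; hand-computed from the rule:
        # gene1 basal [95_000, 101_000), gene2 basal [105_000, 111_000);
        # gene1 extends right to 105_000, gene2 extends left to 101_000
        ann = Annotation(
            [
                TranscriptModel("tx1", "g1", "chr1", "+", ((100_000, 100_500),)),
                TranscriptModel("tx2", "g2", "chr1", "+", ((110_000, 110_500),)),
            ]
        )
        domains = {
            d.gene_id: d
            for d in build_regulatory_domains(ann, chrom_sizes={"chr1": 1_000_000})
        }
        assert domains["g1"].basal == (95_000, 101_000)
        assert domains["g2"].basal == (105_000, 111_000)
        assert domains["g1"].extended[1] == 105_000
        assert domains["g2"].extended[0] == 101_000

    def test_strand_flip_mirrors_basal_asymmetry(self):
        plus = build_regulatory_domains(
            _single_gene("+"), chrom_sizes={"chr1": 2_000_000}
        )[0]
        minus = build_regulatory_domains(
            _single_gene("-"), chrom_sizes={"chr1": 2_000_000}
        )[0]
        # count positions strictly upstream / downstream-inclusive of the TSS
        plus_up = plus.tss - plus.basal[0]
        plus_down = plus.basal[1] - plus.tss
        minus_up = minus.basal[1] - minus.tss - 1
        minus_down = minus.tss - minus.basal[0] + 1
        assert (plus_up, plus_down) == (minus_up, minus_down) == (5000, 1000)
        assert plus.basal[1] - plus.basal[0] == minus.basal[1] - minus.basal[0]

    def test_basal_contains_tss_and_sits_in_extended(self, rng):
        txs = []
        cursor = 10_000
        for i in range(20):
            strand = "+" if rng.random() < 0.5 else "-"
            txs.append(
                TranscriptModel(f"tx{i}", f"g{i}", "chr1", strand, ((cursor, cursor + 500),))
            )
            cursor += int(rng.integers(2_000, 30_000))
        ann = Annotation(txs)
        for dom in build_regulatory_domains(ann, chrom_sizes={"chr1": cursor + 10_000}):
            assert dom.extended[0] <= dom.basal[0] <= dom.tss < dom.basal[1] <= dom.extended[1]


class TestAssociatePeaks:
    @pytest.fixture()
    def domains(self):
        ann = Annotation(
            [
                TranscriptModel("tx1", "g1", "chr1", "+", ((100_000, 100_500),)),
                TranscriptModel("tx2", "g2", "chr1", "+", ((300_000, 300_500),)),
            ]
        )
        return build_regulatory_domains(ann, chrom_sizes={"chr1": 1_000_000})

    def test_summit_in_basal_is_promoter(self, domains):
        peak = Peak("chr1", 99_000, 100_100, summit=100_000)
        assoc = associate_peaks([peak], domains)
        assert assoc.promoter_peaks == [0]
        assert assoc.peak_genes[0] == {"g1"}

    def test_distal_summit(self, domains):
        peak = Peak("chr1", 150_000, 151_000, summit=150_500)
        assoc = associate_peaks([peak], domains)
        assert assoc.distal_peaks == [0]

    def test_partition_identity(self, domains, rng):
        peaks = []
        for i in range(100):
            start = int(rng.integers(0, 999_000))
            peaks.append(Peak("chr1", start, start + 1000, summit=start + 500))
        assoc = associate_peaks(peaks, domains)
        # promoter + distal = associated, and associated + unassociated = all
        assert len(assoc.promoter_peaks) + len(assoc.distal_peaks) == len(assoc.peak_genes)
        assert len(assoc.peak_genes) + len(assoc.unassociated_peaks) == len(peaks)
        assert not (set(assoc.promoter_peaks) & set(assoc.distal_peaks))

    def test_matches_quadratic_oracle(self, domains, rng):
        peaks = []
        for _ in range(150):
            start = int(rng.integers(0, 999_000))
            peaks.append(Peak("chr1", start, start + 200, summit=start + 100))
        assoc = associate_peaks(peaks, domains)
        oracle = association_oracle(
            [(p.chrom, p.summit) for p in peaks],
            [(d.gene_id, d.chrom, d.extended) for d in domains],
        )
        assert assoc.peak_genes == oracle

    def test_translation_invariance(self, rng):
        shift = 123_456
        ann1 = Annotation(
            [TranscriptModel("tx1", "g1", "chr1", "+", ((50_000, 50_500),))]
        )
        ann2 = Annotation(
            [
                TranscriptModel(
                    "tx1", "g1", "chr1", "+", ((50_000 + shift, 50_500 + shift),)
                )
            ]
        )
        d1 = build_regulatory_domains(ann1, max_extension=20_000)
        d2 = build_regulatory_domains(ann2, max_extension=20_000)
        peaks1 = [Peak("chr1", 60_000, 60_500, 60_250)]
        peaks2 = [Peak("chr1", 60_000 + shift, 60_500 + shift, 60_250 + shift)]
        a1 = associate_peaks(peaks1, d1)
        a2 = associate_peaks(peaks2, d2)
        assert a1.peak_genes == a2.peak_genes
        assert a1.promoter_peaks == a2.promoter_peaks


class TestIntersect:
    def _peaks(self, intervals, sample="a"):
        return [
            Peak(c, s, e, summit=(s + e) // 2, sample=sample, name=f"{sample}{i}")
            for i, (c, s, e) in enumerate(intervals)
        ]

    def test_disjoint_sets(self):
        a = self._peaks([("chr1", 0, 100), ("chr1", 500, 600)])
        b = self._peaks([("chr1", 200, 300)], "b")
        hits, counts = intersect_with_marks(a, b)
        assert hits == []
        assert counts["a_overlapping_b"] == 0

    def test_identical_sets(self):
        a = self._peaks([("chr1", 0, 100), ("chr2", 50, 80)])
        hits, counts = intersect_with_marks(a, a)
        assert len(hits) == 2
        assert counts["a_overlapping_b"] == counts["b_overlapping_a"] == 2

    def test_malformed_interval_errors(self):
        a = [Peak("chr1", 0, 100, 50)]
        bad = Peak.__new__(Peak)  # bypass constructor validation deliberately
        object.__setattr__(bad, "chrom", "chr1")
        object.__setattr__(bad, "start", 100)
        object.__setattr__(bad, "end", 100)
        object.__setattr__(bad, "summit", 100)
        object.__setattr__(bad, "sample", "b")
        object.__setattr__(bad, "score", 0.0)
        object.__setattr__(bad, "name", "bad")
        with pytest.raises(ValueError, match="malformed"):
            intersect_with_marks(a, [bad])

    def test_min_overlap_threshold(self):
        a = self._peaks([("chr1", 0, 100)])
        b = self._peaks([("chr1", 95, 200)], "b")
        assert intersect_with_marks(a, b, min_overlap_bp=5)[0] == a
        assert intersect_with_marks(a, b, min_overlap_bp=6)[0] == []

    def test_matches_quadratic_oracle(self, rng):
        def random_set(n, sample):
            out = []
            for i in range(n):
                chrom = f"chr{int(rng.integers(1, 4))}"
                start = int(rng.integers(0, 10_000))
                out.append(
                    Peak(
                        chrom, start, start + int(rng.integers(1, 500)),
                        summit=start, sample=sample, name=f"{sample}{i}",
                    )
                )
            return out

        for trial in range(5):
            a = random_set(200, "a")
            b = random_set(200, "b")
            hits, _ = intersect_with_marks(a, b, min_overlap_bp=3)
            expected = quadratic_intersection_oracle(
                [(p.chrom, p.start, p.end) for p in a],
                [(p.chrom, p.start, p.end) for p in b],
                min_overlap_bp=3,
            )
            assert [a.index(h) for h in hits] == expected


class TestFisher:
    def test_query_equals_pathway_is_extreme(self):
        universe = [f"g{i}" for i in range(30)]
        query = GeneSet("q", frozenset(universe[:8]))
        table = fisher_gene_set_enrichment(query, [GeneSet("p", query.genes)], universe)
        p_extreme = table.p_value.iloc[0]
        # the fully-overlapping table is the most extreme at these margins
        assert p_extreme == pytest.approx(
            fisher_one_sided_oracle(8, 8, 8, 30), rel=1e-9
        )
        weaker = GeneSet("p2", frozenset(universe[:7] + [universe[10]]))
        table2 = fisher_gene_set_enrichment(query, [GeneSet("p2", weaker.genes)], universe)
        assert p_extreme < table2.p_value.iloc[0]

    def test_enumeration_oracle_small_table(self):
        # 2x2 table (3,1;1,5): query 4, pathway 4, universe 10, overlap 3
        universe = [f"g{i}" for i in range(10)]
        query = GeneSet("q", frozenset(universe[:4]))
        pathway = GeneSet("p", frozenset(universe[:3] + [universe[5]]))
        table = fisher_gene_set_enrichment(query, [pathway], universe)
        expected = fisher_one_sided_oracle(3, 4, 4, 10)
        assert table.p_value.iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_exhaustive_universes_up_to_12(self):
        for u in range(2, 13):
            universe = [f"g{i}" for i in range(u)]
            for q_size in range(1, u + 1):
                for p_size in range(1, u + 1):
                    k = min(q_size, p_size)
                    if q_size + p_size - k > u:
                        continue
                    query = GeneSet("q", frozenset(universe[:q_size]))
                    pathway = GeneSet(
                        "p",
                        frozenset(universe[:k] + universe[q_size : q_size + p_size - k]),
                    )
                    got = fisher_gene_set_enrichment(query, [pathway], universe)
                    expected = fisher_one_sided_oracle(k, q_size, p_size, u)
                    assert got.p_value.iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_disjoint_large_universe_p_near_one(self):
        universe = [f"g{i}" for i in range(1000)]
        query = GeneSet("q", frozenset(universe[:10]))
        pathway = GeneSet("p", frozenset(universe[500:510]))
        table = fisher_gene_set_enrichment(query, [pathway], universe)
        assert table.p_value.iloc[0] > 0.5

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            fisher_gene_set_enrichment(GeneSet("q", frozenset()), [], [])

    def test_gene_outside_universe_errors(self):
        with pytest.raises(ValueError):
            fisher_gene_set_enrichment(
                GeneSet("q", frozenset({"x"})), [], ["a", "b"]
            )

    def test_bh_matches_definition(self):
        ps = [0.01, 0.04, 0.03, 0.5]
        adj = benjamini_hochberg(ps)
        # classic step-up: sorted ps 0.01,0.03,0.04,0.5 -> q 0.04,0.053.,0.053.,0.5
        assert adj[0] == pytest.approx(0.04)
        assert adj[1] == pytest.approx(0.04 * 4 / 3)
        assert adj[2] == pytest.approx(0.04 * 4 / 3)
        assert adj[3] == pytest.approx(0.5)


class TestGaContent:
    def test_planted_tracts_significant(self, rng):
        seqs = []
        for _ in range(30):
            seqs.append(random_dna(rng, 80) + "GAGAGGAGAGGGAGAGGAGA" + random_dna(rng, 80))
        result = ga_content_enrichment(seqs, n_shuffles=999, seed=3)
        assert result["p_value"] <= 0.01

    def test_null_input_behaves_as_null(self, rng):
        seqs = [random_dna(rng, 180) for _ in range(30)]
        result = ga_content_enrichment(seqs, n_shuffles=199, seed=4)
        assert result["p_value"] > 0.05

    def test_add_one_lower_bound(self, rng):
        seqs = ["GA" * 50]
        result = ga_content_enrichment(seqs, n_shuffles=99, seed=5)
        assert result["p_value"] >= 1 / 100

    def test_shuffle_count_validation(self):
        with pytest.raises(ValueError):
            ga_content_enrichment(["ACGT"], n_shuffles=0, seed=1)
        with pytest.raises(ValueError):
            ga_content_enrichment([], n_shuffles=10, seed=1)
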