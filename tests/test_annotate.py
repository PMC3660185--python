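"""Gene-model indexing, position classification, and distance statistics.

The independent oracle throughout is a brute-force per-base membership
scan over the raw feature list — no interval structures involved.
"""

import io

import numpy as np
import pandas as pd
import pytest

import pooldiff as pdx
from pooldiff.pileup import BaseCounts, PooledPileupSite


def covered_site(chrom, pos, depth=4):
    return PooledPileupSite(chrom, pos, "A", (BaseCounts(a=depth), BaseCounts(a=depth)))


def brute_force_features(index):
    """Flatten the index trees back to (chrom, start, end, gene, kind)."""
    out = []
    for chrom, tree in index.trees.items():
        for iv in tree:
            out.append((chrom, iv.begin, iv.end, iv.data[0], iv.data[1]))
    return out


def brute_classify(features, chrom, pos):
    hits = [(g, k) for c, s, e, g, k in features if c == chrom and s <= pos < e]
    if not hits:
        return "intergenic"
    genes = {g for g, _ in hits}
    kinds = {k for _, k in hits}
    if len(genes) > 1 or len(kinds) > 1:
        return "genic_ambiguous"
    return kinds.pop()


def brute_distance(features, chrom, pos):
    best = None
    for c, s, e, _, _ in features:
        if c != chrom:
            continue
        d = s - pos if pos < s else (pos - e + 1 if pos >= e else 0)
        best = d if best is None else min(best, d)
    return best


class TestFeatureIndex:
    def test_toy_gtf_counts(self, toy_gtf):
        index = pdx.build_feature_index(toy_gtf)
        assert index.n_exons == 7
        assert index.n_introns == 4
        assert index.n_transcripts == 3
        assert index.genes == {"gene1", "gene2"}

    def test_intron_between_consecutive_exons(self, toy_gtf):
        index = pdx.build_feature_index(toy_gtf)
        introns = {
            (iv.begin, iv.end)
            for iv in index.trees["chr1"]
            if iv.data[1] == "intron"
        }
        assert introns == {(200, 300), (400, 500), (250, 500), (900, 1000)}

    def test_single_exon_transcript_has_no_intron(self, tmp_path):
        gtf = tmp_path / "single.gtf"
        gtf.write_text(
            'chr1\tt\texon\t11\t50\t.\t+\t.\tgene_id "g"; transcript_id "t1";\n'
        )
        assert pdx.build_feature_index(gtf).n_introns == 0

    def test_missing_identifiers_raise(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text('chr1\tt\texon\t11\t50\t.\t+\t.\tgene_id "g";\n')
        with pytest.raises(ValueError, match="transcript_id"):
            pdx.build_feature_index(gtf)

    def test_gene_span_covers_all_exons(self, toy_gtf):
        index = pdx.build_feature_index(toy_gtf)
        assert index.gene_spans["gene1"] == ("chr1", 100, 600)
        assert index.gene_spans["gene2"] == ("chr1", 800, 1100)


class TestClassification:
    @pytest.mark.parametrize(
        "pos, category",
        [
            (150, "exon"),               # exon of both gene1 transcripts
            (220, "genic_ambiguous"),    # tx1 intron + tx2 exon, same gene
            (260, "intron"),             # introns of both transcripts
            (850, "exon"),
            (950, "intron"),
            (700, "intergenic"),
        ],
    )
    def test_toy_positions(self, toy_gtf, pos, category):
        index = pdx.build_feature_index(toy_gtf)
        assert pdx.classify_position("chr1", pos, index).category == category

    def test_multi_gene_overlap_ambiguous_with_both_ids(self, overlap_gtf):
        index = pdx.build_feature_index(overlap_gtf)
        sc = pdx.classify_position("chr1", 250, index)
        assert sc.category == "genic_ambiguous"
        assert sc.gene_ids == {"geneA", "geneB"}

    def test_unknown_chromosome_is_feature_free(self, toy_gtf):
        index = pdx.build_feature_index(toy_gtf)
        sc = pdx.classify_position("chr99", 10, index)
        assert sc.category == "intergenic" and sc.distance is None

    def test_agrees_with_brute_force_on_simulated_genome(self, small_truth, tmp_path):
        gtf = tmp_path / "sim.gtf"
        pdx.write_gtf(small_truth, gtf)
        index = pdx.build_feature_index(gtf)
        features = brute_force_features(index)
        rng = np.random.default_rng(5)
        positions = rng.integers(0, small_truth.params.chromosome_length, size=400)
        for pos in positions:
            got = pdx.classify_position("chr1", int(pos), index)
            assert got.category == brute_classify(features, "chr1", int(pos))
            if got.category == "intergenic":
                assert got.distance == brute_distance(features, "chr1", int(pos))


class TestNearestDistance:
    @pytest.mark.parametrize(
        "pos, expected",
        [
            (600, 1),    # book-ended right of exon [500,600)
            (99, 1),     # book-ended left of exon [100,200)
            (700, 100),  # 100 bp to gene2's first exon at 800
            (1600, 501),
        ],
    )
    def test_adjacency_convention(self, toy_gtf, pos, expected):
        index = pdx.build_feature_index(toy_gtf)
        assert pdx.nearest_feature_distance("chr1", pos, index) == expected


class TestCategoryStatistics:
    def test_density_formula(self, toy_gtf):
        index = pdx.build_feature_index(toy_gtf)
        sites = [covered_site("chr1", p) for p in range(1200, 1400)]
        classified = pdx.classify_sites(sites, index)
        snps = [("chr1", 1210), ("chr1", 1220), ("chr1", 1230)]
        stats = pdx.category_statistics(classified, snps).set_index("feature")
        assert stats.loc["Intergenic", "n_bp"] == 200
        assert stats.loc["Intergenic", "snp_density"] == pytest.approx(15.0)

    def test_bp_partition_on_simulation(self, small_truth, tmp_path):
        gtf = tmp_path / "sim.gtf"
        pdx.write_gtf(small_truth, gtf)
        index = pdx.build_feature_index(gtf)
        buf = io.StringIO()
        pdx.synthesize_pileup(small_truth, buf)
        buf.seek(0)
        classified = pdx.classify_sites(pdx.parse_pileup(buf), index)
        stats = pdx.category_statistics(classified, []).set_index("feature")
        assert (
            stats.loc["Genic", "n_bp"] + stats.loc["Intergenic", "n_bp"]
            == stats.loc["All", "n_bp"]
        )
        assert (
            stats.loc["Exon", "n_bp"] + stats.loc["Intron", "n_bp"]
            <= stats.loc["Genic", "n_bp"]
        )

    def test_mean_depth_matches_generator_truth(self, tmp_path):
        params = pdx.SimParams(
            seed=3, n_chromosomes=1, chromosome_length=30_000, n_genes=4,
            error_rate=0.0, n_call_rate=0.0,
        )
        truth = pdx.simulate_truth(params)
        gtf = tmp_path / "g.gtf"
        pdx.write_gtf(truth, gtf)
        index = pdx.build_feature_index(gtf)
        buf = io.StringIO()
        real = pdx.synthesize_pileup(truth, buf)
        buf.seek(0)
        classified = pdx.classify_sites(pdx.parse_pileup(buf), index)
        stats = pdx.category_statistics(classified, []).set_index("feature")
        truth_depth = real.depth["depth_pool1"] + real.depth["depth_pool2"]
        assert stats.loc["All", "mean_depth"] == pytest.approx(truth_depth.mean())
        exon_truth = truth_depth[real.depth["category"] == "exon"]
        assert stats.loc["Exon", "mean_depth"] == pytest.approx(exon_truth.mean())


class TestGeneCounts:
    def test_empty_input(self, toy_gtf):
        index = pdx.build_feature_index(toy_gtf)
        classified = pdx.classify_sites([], index)
        assert pdx.unique_gene_counts(classified, "exclude_multi") == 0
        assert pdx.unique_gene_counts(classified, "include_multi") == 0

    def test_multi_gene_position_counts_only_in_include_mode(self, overlap_gtf):
        index = pdx.build_feature_index(overlap_gtf)
        classified = pdx.classify_sites([covered_site("chr1", 250)], index)
        assert pdx.unique_gene_counts(classified, "exclude_multi") == 0
        assert pdx.unique_gene_counts(classified, "include_multi") == 2

    def test_include_ge_exclude_on_random_positions(self, overlap_gtf, toy_gtf):
        rng = np.random.default_rng(11)
        for gtf in (overlap_gtf, toy_gtf):
            index = pdx.build_feature_index(gtf)
            sites = [
                covered_site("chr1", int(p))
                for p in rng.integers(0, 1300, size=300)
            ]
            classified = pdx.classify_sites(sites, index)
            assert pdx.unique_gene_counts(
                classified, "include_multi"
            ) >= pdx.unique_gene_counts(classified, "exclude_multi")


class TestFlankExpansion:
    def test_zero_flank_gains_nothing(self, toy_gtf):
        index = pdx.build_feature_index(toy_gtf)
        classified = pdx.classify_sites([covered_site("chr1", 700)], index)
        assert pdx.flank_expansion_gain(classified, index, 0) == 0

    def test_upstream_position_within_flank_counts(self, toy_gtf):
        index = pdx.build_feature_index(toy_gtf)
        # 1500 bp right of gene2's span end (1100): inside span+2000 only
        classified = pdx.classify_sites([covered_site("chr1", 2600)], index)
        assert pdx.flank_expansion_gain(classified, index, 2000) == 1
        assert pdx.flank_expansion_gain(classified, index, 1000) == 0

    def test_agrees_with_brute_force_reclassification(self, small_truth, tmp_path):
        gtf = tmp_path / "sim.gtf"
        pdx.write_gtf(small_truth, gtf)
        index = pdx.build_feature_index(gtf)
        rng = np.random.default_rng(7)
        sites = [
            covered_site("chr1", int(p))
            for p in sorted(rng.integers(0, small_truth.params.chromosome_length, 500))
        ]
        classified = pdx.classify_sites(sites, index)
        flank = 2000
        expected = 0
        positions = classified["pos"].to_numpy()
        for chrom, start, end in index.gene_spans.values():
            inside = ((positions >= start) & (positions < end)).any()
            near = ((positions >= start - flank) & (positions < end + flank)).any()
            expected += int(not inside and near)
        assert pdx.flank_expansion_gain(classified, index, flank) == expected


class TestDistanceDistribution:
    def test_summary_values(self, toy_gtf):
        index = pdx.build_feature_index(toy_gtf)
        classified = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "pos": [1, 2, 3],
                "total_depth": [1, 1, 1],
                "category": ["intergenic"] * 3,
                "gene_ids": [frozenset()] * 3,
                "distance": [1.0, 3.0, 5.0],
            }
        )
        summary, hist = pdx.distance_distribution(classified, index)
        assert summary["mean"] == pytest.approx(3.0)
        assert summary["median"] == pytest.approx(3.0)
        assert summary["min"] == 1 and summary["max"] == 5
        assert hist["count"].sum() == summary["n"] == 3

    def test_excluded_chromosomes_absent(self, tmp_path):
        gtf = tmp_path / "with_random.gtf"
        gtf.write_text(
            'chr1\tt\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1_random\tt\texon\t101\t200\t.\t+\t.\tgene_id "g2"; transcript_id "t2";\n'
        )
        index = pdx.build_feature_index(gtf)
        assert index.excluded_chroms == {"chr1_random"}
        sites = [covered_site("chr1", 500), covered_site("chr1_random", 500)]
        classified = pdx.classify_sites(sites, index)
        summary, _ = pdx.distance_distribution(classified, index)
        assert summary["n"] == 1

    def test_empty_input_returns_empty_summary(self, toy_gtf):
        index = pdx.build_feature_index(toy_gtf)
        summary, hist = pdx.distance_distribution(
            pdx.classify_sites([], index), index
        )
        assert summary["n"] == 0 and len(hist) == 0
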