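"""Gene models, region assignment, TS/NTS attribution, expression bins."""

import numpy as np
import pytest

from didymascan.annotate import (
    ExpressionBins,
    GeneIndex,
    GeneModel,
    RegionSizes,
    annotate_didyma,
    assign_region,
    didyma_by_expression,
    didyma_density_by_region,
    read_gene_models,
    transcribed_strand,
)
from didymascan.catalog import MutationRecord
from didymascan.clusters import DidymosPair

from _util import revcomp_dataset


def _rec(pos, ref="C", alt="T", chrom="chr1"):
    return MutationRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, vaf=0.4, sample="s")


def _pair(pos1, pos2, strand="+", chrom="chr1"):
    ref = "C" if strand == "+" else "G"
    alt = "T" if strand == "+" else "A"
    return DidymosPair(sample="s", chrom=chrom, first=_rec(pos1, ref, alt, chrom),
                       second=_rec(pos2, ref, alt, chrom), imd=pos2 - pos1,
                       strand=strand)


TOY_GTF = """chr1\ttoy\tgene\t100\t500\t.\t+\t.\tgene_id "g1";
chr1\ttoy\texon\t100\t250\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t";
chr1\ttoy\texon\t400\t500\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t";
chr1\ttoy\tgene\t700\t900\t.\t-\t.\tgene_id "g2";
chr1\ttoy\texon\t700\t900\t.\t-\t.\tgene_id "g2"; transcript_id "g2.t";
"""


class TestReadGeneModels:
    def test_spans_from_exons(self, tmp_path):
        gtf = tmp_path / "toy.gtf"
        gtf.write_text(TOY_GTF)
        models = read_gene_models(gtf)
        by_id = {m.gene_id: m for m in models}
        assert by_id["g1"].start == 100 and by_id["g1"].end == 500
        assert by_id["g1"].strand == "+"
        assert by_id["g2"].strand == "-"

    def test_expression_join_missing_gene_non_expressed(self, tmp_path):
        gtf = tmp_path / "toy.gtf"
        gtf.write_text(TOY_GTF)
        expr = tmp_path / "expr.tsv"
        expr.write_text("gene_id\texpression\ng1\t5.5\n")
        models = read_gene_models(gtf, expr)
        by_id = {m.gene_id: m for m in models}
        assert by_id["g1"].expression == pytest.approx(5.5)
        assert by_id["g2"].expression is None
        bins = ExpressionBins.from_models(models)
        assert bins.bin_of("g2") == "non_expressed"

    def test_overlapping_genes_both_retained(self, tmp_path):
        gtf = tmp_path / "ovl.gtf"
        gtf.write_text(
            'chr1\tt\tgene\t100\t300\t.\t+\t.\tgene_id "a";\n'
            'chr1\tt\tgene\t200\t400\t.\t-\t.\tgene_id "b";\n'
        )
        models = read_gene_models(gtf)
        assert {m.gene_id for m in models} == {"a", "b"}


class TestAssignRegion:
    def _index(self):
        return GeneIndex([
            GeneModel("g1", "chr1", 100, 500, "+", 5.0),
            GeneModel("g2", "chr1", 700, 900, "-", 0.0),
        ])

    def test_inside_gene_is_genic(self):
        region, genes = assign_region(_rec(250), self._index())
        assert region == "genic" and genes == ["g1"]

    def test_between_genes_is_intergenic(self):
        region, genes = assign_region(_rec(600), self._index())
        assert region == "intergenic" and genes == []

    @pytest.mark.parametrize("pos", [100, 500])  # both span ends inclusive
    def test_span_ends_are_genic(self, pos):
        region, _ = assign_region(_rec(pos), self._index())
        assert region == "genic"

    def test_partition(self):
        index = self._index()
        n_genic = sum(
            assign_region(_rec(p), index)[0] == "genic" for p in range(50, 1000, 7)
        )
        n_inter = sum(
            assign_region(_rec(p), index)[0] == "intergenic" for p in range(50, 1000, 7)
        )
        assert n_genic + n_inter == len(range(50, 1000, 7))


class TestTranscribedStrand:
    def _index(self):
        return GeneIndex([
            GeneModel("plus_gene", "chr1", 100, 500, "+", 1.0),
            GeneModel("minus_gene", "chr1", 700, 900, "-", 1.0),
            GeneModel("ovl_a", "chr1", 1000, 1200, "+", 1.0),
            GeneModel("ovl_b", "chr1", 1100, 1300, "-", 1.0),
        ])

    def test_pyrimidine_on_sense_strand_is_non_transcribed(self):
        assert transcribed_strand(_pair(200, 220, "+"), self._index()) == "non_transcribed"

    def test_pyrimidine_on_antisense_strand_is_transcribed(self):
        assert transcribed_strand(_pair(200, 220, "-"), self._index()) == "transcribed"

    def test_minus_gene_convention_mirrors(self):
        assert transcribed_strand(_pair(750, 770, "-"), self._index()) == "non_transcribed"
        assert transcribed_strand(_pair(750, 770, "+"), self._index()) == "transcribed"

    def test_opposite_strand_overlap_is_na(self):
        assert transcribed_strand(_pair(1150, 1160, "+"), self._index()) == "NA"

    def test_intergenic_is_na(self):
        assert transcribed_strand(_pair(600, 610, "+"), self._index()) == "NA"

    def test_ts_nts_swap_under_reverse_complement(self, default_dataset):
        """Reverse-complementing the dataset with gene strands flipped
        swaps the TS and NTS tallies exactly."""
        from didymascan.clusters import extract_didyma

        ds = default_dataset
        index = GeneIndex(ds.models)
        pairs = annotate_didyma(extract_didyma(ds.catalog, ds.genome), index)
        rc_genome, rc_catalog = revcomp_dataset(ds.genome, ds.catalog)
        L = {c: ds.genome.lengths[c] for c in ds.genome.lengths}
        rc_models = [
            GeneModel(m.gene_id, m.chrom, L[m.chrom] - m.end + 1,
                      L[m.chrom] - m.start + 1,
                      "+" if m.strand == "-" else "-", m.expression)
            for m in ds.models
        ]
        rc_pairs = annotate_didyma(
            extract_didyma(rc_catalog, rc_genome), GeneIndex(rc_models)
        )

        def tally(ps):
            return (
                sum(p.ts_nts == "transcribed" for p in ps),
                sum(p.ts_nts == "non_transcribed" for p in ps),
            )

        ts, nts = tally(pairs)
        rc_ts, rc_nts = tally(rc_pairs)
        assert (ts, nts) == (rc_ts, rc_nts)  # strand flip + coordinate flip cancel

        # keeping the gene strand annotations fixed while the mutations
        # flip swaps the tallies exactly
        keep_models = [
            GeneModel(m.gene_id, m.chrom, L[m.chrom] - m.end + 1,
                      L[m.chrom] - m.start + 1, m.strand, m.expression)
            for m in ds.models
        ]
        swap_pairs = annotate_didyma(
            extract_didyma(rc_catalog, rc_genome), GeneIndex(keep_models)
        )
        assert tally(swap_pairs) == (nts, ts)


class TestDensities:
    def test_default_sizes_arithmetic(self):
        pairs = [_pair(10 * i + 10, 10 * i + 15) for i in range(30)]
        for i, p in enumerate(pairs):
            p.region = "genic" if i < 20 else "intergenic"
        density = didyma_density_by_region(pairs, RegionSizes())
        assert density["genic"] == pytest.approx(20 / 1139.0)
        assert density["intergenic"] == pytest.approx(10 / 1584.0)

    def test_empty_is_zero(self):
        assert didyma_density_by_region([], RegionSizes()) == {
            "genic": 0.0, "intergenic": 0.0
        }

    def test_unannotated_pairs_rejected(self):
        with pytest.raises(ValueError):
            didyma_density_by_region([_pair(10, 15)])

    def test_sizes_from_models_merge_overlaps(self):
        models = [
            GeneModel("a", "chr1", 1, 1_000_000, "+", 1.0),
            GeneModel("b", "chr1", 500_000, 1_500_000, "-", 1.0),
        ]
        sizes = RegionSizes.from_models(models, genome_length=4_000_000)
        assert sizes.genic == pytest.approx(1.5)
        assert sizes.intergenic == pytest.approx(2.5)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            RegionSizes(genic=0.0, intergenic=10.0)


class TestExpressionBins:
    def _models(self, values):
        return [
            GeneModel(f"g{i}", "chr1", 10 * i + 1, 10 * i + 5, "+", v)
            for i, v in enumerate(values)
        ]

    @pytest.mark.parametrize("n", [8, 9, 10, 11, 40])
    def test_quartile_populations_balanced(self, n):
        rng = np.random.default_rng(n)
        values = list(rng.lognormal(1, 1, size=n))
        bins = ExpressionBins.from_models(self._models(values))
        counts = {f"Q{k}": 0 for k in range(1, 5)}
        for g, b in bins.assignments.items():
            counts[b] += 1
        sizes = sorted(counts.values())
        assert sizes[-1] - sizes[0] <= 1

    def test_zero_and_missing_are_non_expressed(self):
        bins = ExpressionBins.from_models(self._models([0.0, 1.0, 2.0, 3.0, 4.0]))
        assert bins.bin_of("g0") == "non_expressed"
        assert bins.bin_of("unknown_gene") == "non_expressed"

    def test_percentages_sum_to_hundred(self):
        models = self._models([0.0, 1.0, 2.0, 3.0, 4.0])
        bins = ExpressionBins.from_models(models)
        pairs = []
        for i, m in enumerate(models):
            p = _pair(m.start, m.start + 2)
            p.region = "genic"
            p.gene_id = m.gene_id
            pairs.append(p)
        pct = didyma_by_expression(pairs, bins)
        assert sum(pct.values()) == pytest.approx(100.0)
        assert pct["non_expressed"] == pytest.approx(20.0)

    def test_all_in_top_quartile(self):
        models = self._models([1.0, 2.0, 3.0, 4.0, 8.0, 9.0, 10.0, 11.0])
        bins = ExpressionBins.from_models(models)
        top = [g for g, b in bins.assignments.items() if b == "Q4"]
        pairs = []
        for g in top:
            m = next(mm for mm in models if mm.gene_id == g)
            p = _pair(m.start, m.start + 2)
            p.region = "genic"
            p.gene_id = g
            pairs.append(p)
        pct = didyma_by_expression(pairs, bins)
        assert pct["Q4"] == pytest.approx(100.0)

    def test_no_genic_pairs_all_zero(self):
        bins = ExpressionBins.from_models(self._models([1.0, 2.0]))
        assert all(v == 0.0 for v in didyma_by_expression([], bins).values())
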