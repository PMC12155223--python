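"""Genic/intergenic, transcriptional-strand, and expression attribution.

Gene models are whole-gene spans (exons plus introns, 1-based inclusive)
with the mRNA-sense strand and an optional normalized expression value.
A mutation is genic iff it falls within any gene span.  For a didymos in
an unambiguously stranded gene, a shared pyrimidine strand equal to the
gene's sense strand places the lesion on the non-transcribed (coding)
strand; the opposite places it on the transcribed (template) strand.
Genes are binned into expression quartiles over the positive-expression
distribution, with a fifth bin for non-expressed genes.

Default region territories follow the mouse genome annotation used for
tumor analyses: genic 1,139 Mb, intergenic 1,584 Mb; both can be
recomputed from supplied gene models (merged-interval union).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pyranges
from intervaltree import IntervalTree

from .catalog import MutationRecord
from .clusters import DidymosPair

logger = logging.getLogger(__name__)

EXPRESSION_BINS = ["non_expressed", "Q1", "Q2", "Q3", "Q4"]


@dataclass
class GeneModel:
    """Whole-gene span (1-based inclusive) with strand and expression."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    expression: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class RegionSizes:
    """Region territories in megabases (mouse WGS defaults)."""

    genic: float = 1139.0
    intergenic: float = 1584.0

    def __post_init__(self) -> None:
        if self.genic <= 0 or self.intergenic <= 0:
            raise ValueError("region sizes must be positive")

    @classmethod
    def from_models(cls, models: Sequence[GeneModel], genome_length: int) -> "RegionSizes":
        """Measure the merged union of gene spans against a genome length."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for m in models:
            by_chrom.setdefault(m.chrom, []).append((m.start, m.end))
        genic_bp = 0
        for ivs in by_chrom.values():
            ivs.sort()
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e + 1:
                    cur_e = max(cur_e, e)
                else:
                    genic_bp += cur_e - cur_s + 1
                    cur_s, cur_e = s, e
            genic_bp += cur_e - cur_s + 1
        return cls(genic=genic_bp / 1e6, intergenic=(genome_length - genic_bp) / 1e6)


def read_gene_models(
    gtf_path: str | Path,
    expression: Optional[str | Path | dict[str, float]] = None,
) -> list[GeneModel]:
    """Read gene models from GTF/GFF and join expression by gene_id.

    One model per gene spanning min(exon start)..max(exon end) (falling
    back to 'gene' features where no exons exist); genes missing from the
    expression table are treated as non-expressed (None).
    """
    gr = pyranges.read_gtf(str(gtf_path))
    df = gr.df
    if "gene_id" not in df.columns:
        raise ValueError(f"{gtf_path}: GTF lacks gene_id attributes")
    expr: dict[str, float] = {}
    if isinstance(expression, dict):
        expr = dict(expression)
    elif expression is not None:
        tbl = pd.read_csv(expression, sep="\t")
        expr = dict(zip(tbl.iloc[:, 0].astype(str), tbl.iloc[:, 1].astype(float)))

    exons = df[df["Feature"] == "exon"]
    source = exons if len(exons) else df[df["Feature"] == "gene"]
    models: list[GeneModel] = []
    skipped = 0
    for gene_id, sub in source.groupby("gene_id", sort=True):
        sub = sub.dropna(subset=["Start", "End"])
        if not len(sub):
            skipped += 1
            continue
        models.append(
            GeneModel(
                gene_id=str(gene_id),
                chrom=str(sub["Chromosome"].iloc[0]),
                start=int(sub["Start"].min()) + 1,  # pyranges is 0-based
                end=int(sub["End"].max()),
                strand=str(sub["Strand"].iloc[0]),
                expression=expr.get(str(gene_id)),
            )
        )
    if skipped:
        logger.info("read_gene_models: skipped %d genes without coordinates", skipped)
    return models


class GeneIndex:
    """Interval lookup over gene spans (1-based inclusive)."""

    def __init__(self, models: Sequence[GeneModel]) -> None:
        self.models = list(models)
        self.trees: dict[str, IntervalTree] = {}
        for m in self.models:
            # intervaltree is half-open; +1 makes the end inclusive.
            self.trees.setdefault(m.chrom, IntervalTree()).addi(m.start, m.end + 1, m)

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree[pos]), key=lambda m: m.gene_id)

    def genic_intervals(self) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for m in self.models:
            out.setdefault(m.chrom, []).append((m.start, m.end))
        return out


def assign_region(
    record: MutationRecord, index: GeneIndex
) -> tuple[str, list[str]]:
    """('genic'|'intergenic', overlapping gene ids); span ends are genic."""
    genes = index.overlapping(record.chrom, record.pos)
    return ("genic" if genes else "intergenic", [g.gene_id for g in genes])


def transcribed_strand(pair: DidymosPair, index: GeneIndex) -> str:
    """'transcribed' | 'non_transcribed' | 'NA' for a didymos.

    Uses the first member's position (a ≤32 nt pair virtually never
    straddles a boundary).  Intergenic pairs and pairs over genes that
    overlap on opposite strands are 'NA'.  With gene sense strand S: the
    pair's shared pyrimidine strand == S puts the deaminated cytosines on
    the non-transcribed (coding) strand; the opposite on the transcribed
    (template) strand.
    """
    genes = index.overlapping(pair.chrom, pair.first.pos)
    strands = {g.strand for g in genes}
    if not genes or len(strands) != 1:
        return "NA"
    return "non_transcribed" if pair.strand == strands.pop() else "transcribed"


def annotate_didyma(
    pairs: Iterable[DidymosPair],
    index: GeneIndex,
    bins: Optional["ExpressionBins"] = None,
) -> list[DidymosPair]:
    """Fill region, gene_id, ts_nts (and expression_bin) on each pair.

    A pair is assigned one region/gene by its first member's position.
    """
    out = []
    for p in pairs:
        region, gene_ids = assign_region(p.first, index)
        p.region = region
        p.gene_id = gene_ids[0] if gene_ids else None
        p.ts_nts = transcribed_strand(p, index)
        if bins is not None and p.gene_id is not None:
            p.expression_bin = bins.bin_of(p.gene_id)
        out.append(p)
    return out


def didyma_density_by_region(
    pairs: Iterable[DidymosPair], sizes: RegionSizes = RegionSizes()
) -> dict[str, float]:
    """Pairs per megabase of genic and intergenic territory."""
    counts = {"genic": 0, "intergenic": 0}
    for p in pairs:
        if p.region not in counts:
            raise ValueError("pairs must be region-annotated first")
        counts[p.region] += 1
    return {
        "genic": counts["genic"] / sizes.genic,
        "intergenic": counts["intergenic"] / sizes.intergenic,
    }


@dataclass
class ExpressionBins:
    """Quartile bins over positive expression, plus a non-expressed bin.

    Boundaries use the nearest-rank quartiles of the positive-expression
    gene distribution; genes with zero or missing expression fall in
    ``non_expressed``.  Ties share a bin by value.
    """

    assignments: dict[str, str]

    @classmethod
    def from_models(cls, models: Sequence[GeneModel]) -> "ExpressionBins":
        pos = sorted(
            (m.expression, m.gene_id) for m in models if m.expression and m.expression > 0
        )
        values = np.array([v for v, _ in pos])
        assignments: dict[str, str] = {}
        if len(values):
            qs = np.quantile(values, [0.25, 0.5, 0.75], method="inverted_cdf")
        for m in models:
            if not m.expression or m.expression <= 0:
                assignments[m.gene_id] = "non_expressed"
            else:
                k = int(np.searchsorted(qs, m.expression, side="left"))
                assignments[m.gene_id] = f"Q{k + 1}"
        return cls(assignments)

    def bin_of(self, gene_id: str) -> str:
        return self.assignments.get(gene_id, "non_expressed")


def didyma_by_expression(
    pairs: Iterable[DidymosPair], bins: ExpressionBins
) -> dict[str, float]:
    """Percentage of genic didyma per expression bin (sums to 100)."""
    counts = {b: 0 for b in EXPRESSION_BINS}
    total = 0
    for p in pairs:
        if p.region != "genic" or p.gene_id is None:
            continue
        counts[bins.bin_of(p.gene_id)] += 1
        total += 1
    if total == 0:
        logger.warning("didyma_by_expression: no genic pairs")
        return {b: 0.0 for b in EXPRESSION_BINS}
    return {b: 100.0 * n / total for b, n in counts.items()}
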