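"""Synthetic genomes, gene models, and mutation catalogs with truth labels.

The generator emulates the mutational landscape of carcinogen-exposed,
APOBEC3B-expressing tumors at desk scale:

* dispersed APOBEC mutations — C>T/C>G uniformly over TCW motif sites on
  either strand (SBS2/13-like);
* dispersed carcinogen (NQO-like) mutations — G>T (majority) and G>C over
  guanine sites, weighted toward guanines with a 3' guanine (the GG
  dinucleotide adduct preference), never planting G>C in a GA context;
* didyma — for each pair, a 24–32 nt single-strand tract (the gap exposed
  by nucleotide excision repair) is placed on one strand, two TCW
  cytosines inside it are deaminated (C>T or C>G, each with probability
  0.5), and both members share one clone VAF ± small noise so the 0.1
  ΔVAF pairing filter holds for true pairs;
* per-mutation read support consistent with the default somatic filters.

Tract placement is transcription-biased when gene models are supplied
(most pairs land in genes sampled proportionally to expression),
mirroring transcription-coupled repair.  Background mutations keep a
33 nt distance from planted pair members so truth labels stay
unambiguous without carving structure out of longer-range pair spacing.

Every emitted mutation carries a row in the truth table (class, pair id,
planted IMD, strand, region) for recovery scoring.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .annotate import GeneModel
from .catalog import Genome, MutationCatalog, MutationRecord, write_catalog, write_genome

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic co-mutagenesis dataset.

    Defaults give a 1 Mb single-chromosome genome at mouse-like GC with
    200 dispersed APOBEC mutations, 400 dispersed carcinogen mutations,
    and 50 planted didyma pairs in 24–32 nt tracts.
    """

    chrom_length: int = 1_000_000
    n_chromosomes: int = 1
    gc_fraction: float = 0.42
    n_genes: int = 40
    gene_length: tuple[int, int] = (5_000, 15_000)
    expr_log_mean: float = 1.0
    expr_log_sigma: float = 1.0
    expr_zero_fraction: float = 0.2
    n_dispersed_apobec: int = 200
    n_dispersed_nqo: int = 400
    n_didyma_pairs: int = 50
    ner_tract_range: tuple[int, int] = (24, 32)
    nqo_gg_bias: float = 3.0
    apobec_ct_fraction: float = 0.7
    nqo_gt_fraction: float = 0.75
    didyma_genic_fraction: float = 0.8
    clone_vaf_mean: float = 0.35
    clone_vaf_sd: float = 0.10
    member_vaf_sd: float = 0.02
    exclusion_radius: int = 32
    mutations_per_tract: int = 2
    sample: str = "synthetic_1"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ner_tract_range
        if not (1 <= lo <= hi <= self.chrom_length):
            raise ValueError("ner_tract_range must lie within [1, chrom_length]")
        if min(self.n_dispersed_apobec, self.n_dispersed_nqo, self.n_didyma_pairs) < 0:
            raise ValueError("mutation counts must be non-negative")


@dataclass
class SyntheticDataset:
    """In-memory bundle: genome, gene models, catalog, and truth table."""

    genome: Genome
    models: list[GeneModel]
    catalog: MutationCatalog
    truth: pd.DataFrame
    config: SyntheticConfig


def make_genome(cfg: SyntheticConfig, rng: Optional[np.random.Generator] = None) -> Genome:
    """I.i.d.-base genome at the target GC fraction; seed-deterministic."""
    rng = rng or np.random.default_rng(cfg.seed)
    gc = cfg.gc_fraction
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    sequences = {}
    for i in range(cfg.n_chromosomes):
        draws = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=cfg.chrom_length, p=p)
        sequences[f"chr{i + 1}"] = draws.tobytes().decode("ascii")
    return Genome(sequences=sequences)


def make_gene_models(
    genome: Genome, cfg: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> list[GeneModel]:
    """Non-overlapping gene spans on random strands with zero-inflated
    log-normal expression."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    chroms = list(genome.sequences)
    models: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    lo, hi = cfg.gene_length
    for g in range(cfg.n_genes):
        length = int(rng.integers(lo, hi + 1))
        placed = False
        for attempt in range(200):
            chrom = chroms[int(rng.integers(len(chroms)))]
            L = genome.lengths[chrom]
            if length + 10 >= L:
                length = max(100, length // 2)
                continue
            start = int(rng.integers(3, L - length - 2))
            end = start + length - 1
            if all(e < start - 1 or s > end + 1 for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                placed = True
                break
            if attempt and attempt % 50 == 0:
                length = max(100, int(length * 0.7))
        if not placed:
            raise RuntimeError(f"could not place gene {g} after bounded retries")
        expressed = rng.random() >= cfg.expr_zero_fraction
        expression = (
            float(rng.lognormal(cfg.expr_log_mean, cfg.expr_log_sigma)) if expressed else 0.0
        )
        models.append(
            GeneModel(
                gene_id=f"gene{g + 1:04d}",
                chrom=chrom,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                expression=expression,
            )
        )
    return models


# ---------------------------------------------------------------------------
# Motif site enumeration (vectorized over the forward-strand sequence)


def _site_positions(seq: str) -> dict[str, np.ndarray]:
    """1-based positions of motif sites on a chromosome.

    ``tcw_plus``: C of a TCW on the forward strand; ``tcw_minus``: the
    forward-strand G whose reverse-strand pyrimidine sits in a TCW (i.e.
    forward context W'GA); ``g_plus``/``g_minus``: guanine sites per
    strand (forward G, and forward C = reverse-strand G); ``gg_plus``/
    ``gg_minus``: guanines with a 3' guanine on the guanine strand.
    """
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    A, C, G, T = (ord(x) for x in "ACGT")
    n = len(a)
    up = a[:-2]
    mid = a[1:-1]
    dn = a[2:]
    idx = np.arange(2, n)  # 1-based position of `mid`
    is_w_up = (up == A) | (up == T)
    is_w_dn = (dn == A) | (dn == T)
    sel_g_plus = mid == G
    sel_g_minus = mid == C
    return {
        "tcw_plus": idx[(up == T) & (mid == C) & is_w_dn],
        "tcw_minus": idx[is_w_up & (mid == G) & (dn == A)],
        "g_plus": idx[sel_g_plus],
        "g_minus": idx[sel_g_minus],
        # 3' neighbour of the guanine, on the guanine strand
        "gg_mask_plus": (dn == G)[sel_g_plus],
        "gg_mask_minus": (up == C)[sel_g_minus],
    }


class _Occupancy:
    """Used positions and keep-out zones around planted pair members."""

    def __init__(self) -> None:
        self.used: dict[str, set[int]] = {}
        self.zones: dict[str, list[tuple[int, int]]] = {}

    def in_zone(self, chrom: str, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.zones.get(chrom, []))

    def is_free(self, chrom: str, pos: int) -> bool:
        return pos not in self.used.get(chrom, set()) and not self.in_zone(chrom, pos)

    def take(self, chrom: str, pos: int) -> None:
        self.used.setdefault(chrom, set()).add(pos)

    def add_zone(self, chrom: str, start: int, end: int) -> None:
        self.zones.setdefault(chrom, []).append((start, end))

    def free_mask(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Vectorized is_free over an array of positions."""
        mask = np.ones(len(pos), dtype=bool)
        used = self.used.get(chrom)
        if used:
            mask &= ~np.isin(pos, np.fromiter(used, dtype=np.int64))
        zones = sorted(self.zones.get(chrom, []))
        if zones:
            starts = np.array([s for s, _ in zones])
            ends = np.array([e for _, e in zones])
            k = np.searchsorted(starts, pos, side="right") - 1
            inside = (k >= 0) & (pos <= ends[np.clip(k, 0, None)])
            mask &= ~inside
        return mask


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def _read_support(rng: np.random.Generator, vaf: float) -> tuple[int, int, int]:
    depth = int(rng.integers(30, 81))
    alt = int(np.clip(round(vaf * depth), 3, depth))
    callers = int(rng.integers(2, 5))
    return alt, depth, callers


def _apobec_record(
    chrom: str, pos: int, strand: str, seq: str, to_t: bool, vaf: float,
    rng: np.random.Generator, sample: str,
) -> MutationRecord:
    """Record for a deaminated cytosine at a TCW site on the given strand."""
    if strand == "+":
        ref, alt = "C", ("T" if to_t else "G")
    else:
        ref, alt = "G", ("A" if to_t else "C")
    assert seq[pos - 1] == ref
    ar, dp, ca = _read_support(rng, vaf)
    return MutationRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, vaf=vaf,
        alt_reads=ar, depth=dp, caller_support=ca, sample=sample,
    )


def plant_didyma_ner(
    genome: Genome,
    models: Optional[list[GeneModel]],
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    occupancy: _Occupancy,
    sites: dict[str, dict[str, np.ndarray]],
) -> tuple[list[MutationRecord], list[dict]]:
    """Plant didyma pairs inside NER-sized single-strand tracts.

    For each pair: pick a strand and a 24–32 nt tract (expression-weighted
    genic placement when models are given), locate TCW cytosines on that
    strand inside the tract, deaminate two of them (C>T or C>G, p=0.5
    each), and give both members one clone VAF ± σ=0.02.  Tracts without
    two usable sites, or colliding with earlier placements, are resampled
    with bounded retries.
    """
    records: list[MutationRecord] = []
    truth_rows: list[dict] = []
    chroms = list(genome.sequences)
    spans: dict[str, list[tuple[int, int]]] = {}
    for m in models or []:
        spans.setdefault(m.chrom, []).append((m.start, m.end))

    def region_of(chrom: str, pos: int) -> str:
        return (
            "genic"
            if any(s <= pos <= e for s, e in spans.get(chrom, []))
            else "intergenic"
        )

    genic = [m for m in (models or []) if m.end - m.start + 1 > cfg.ner_tract_range[1] + 4]
    weights = None
    if genic:
        w = np.array([max(m.expression or 0.0, 0.0) + 1e-3 for m in genic])
        weights = w / w.sum()
    tract_lo, tract_hi = cfg.ner_tract_range

    for pair_id in range(cfg.n_didyma_pairs):
        planted = False
        for _ in range(500):
            strand = "+" if rng.random() < 0.5 else "-"
            tract_len = int(rng.integers(tract_lo, tract_hi + 1))
            in_gene = genic and rng.random() < cfg.didyma_genic_fraction
            if in_gene:
                gene = genic[int(rng.choice(len(genic), p=weights))]
                chrom = gene.chrom
                start = int(rng.integers(gene.start, gene.end - tract_len + 1))
            else:
                chrom = chroms[int(rng.integers(len(chroms)))]
                start = int(rng.integers(3, genome.lengths[chrom] - tract_len - 2))
                if region_of(chrom, start) == "genic":
                    continue  # intergenic draw landed in a gene; resample
            key = "tcw_plus" if strand == "+" else "tcw_minus"
            pool = sites[chrom][key]
            lo_i = np.searchsorted(pool, start)
            hi_i = np.searchsorted(pool, start + tract_len - 1, side="right")
            cand = [
                int(p) for p in pool[lo_i:hi_i] if occupancy.is_free(chrom, int(p))
            ]
            if len(cand) < cfg.mutations_per_tract:
                continue
            chosen = sorted(
                int(x) for x in rng.choice(cand, size=cfg.mutations_per_tract, replace=False)
            )
            clone_vaf = _truncnorm(rng, cfg.clone_vaf_mean, cfg.clone_vaf_sd, 0.10, 0.90)
            seq = genome.sequences[chrom]
            for pos in chosen:
                vaf = float(np.clip(rng.normal(clone_vaf, cfg.member_vaf_sd), 0.06, 0.98))
                rec = _apobec_record(
                    chrom, pos, strand, seq, to_t=rng.random() < 0.5,
                    vaf=vaf, rng=rng, sample=cfg.sample,
                )
                records.append(rec)
                truth_rows.append(
                    {
                        "sample": cfg.sample, "chrom": chrom, "pos": pos,
                        "ref": rec.ref, "alt": rec.alt, "class": "didyma_member",
                        "pair_id": pair_id, "imd": chosen[-1] - chosen[0],
                        "strand": strand, "region": region_of(chrom, pos),
                    }
                )
                occupancy.take(chrom, pos)
            for pos in chosen:
                occupancy.add_zone(
                    chrom, pos - cfg.exclusion_radius, pos + cfg.exclusion_radius
                )
            planted = True
            break
        if not planted:
            raise RuntimeError(
                f"could not place didyma pair {pair_id} after bounded retries"
            )
    return records, truth_rows


def plant_dispersed(
    genome: Genome,
    cfg: SyntheticConfig,
    mutation_class: str,
    rng: np.random.Generator,
    occupancy: _Occupancy,
    sites: dict[str, dict[str, np.ndarray]],
    models: Optional[list[GeneModel]] = None,
) -> tuple[list[MutationRecord], list[dict]]:
    """Plant dispersed APOBEC or carcinogen mutations, collision-free.

    ``apobec``: uniform over TCW sites on both strands, C>T with
    probability ``apobec_ct_fraction`` else C>G.  ``nqo``: over guanine
    sites with GG-context sites weighted ``nqo_gg_bias``-fold, G>T with
    probability ``nqo_gt_fraction`` else G>C, where a would-be G>C at a
    GA-context guanine is planted as G>T instead (exclusion honored).
    """
    if mutation_class == "apobec":
        n_target = cfg.n_dispersed_apobec
    elif mutation_class == "nqo":
        n_target = cfg.n_dispersed_nqo
    else:
        raise ValueError(f"unknown class {mutation_class!r}")
    records: list[MutationRecord] = []
    truth_rows: list[dict] = []
    if n_target == 0:
        return records, truth_rows

    chroms = list(sites)
    pos_parts: list[np.ndarray] = []
    chrom_parts: list[np.ndarray] = []
    strand_parts: list[np.ndarray] = []
    w_parts: list[np.ndarray] = []
    for ci, chrom in enumerate(chroms):
        s = sites[chrom]
        if mutation_class == "apobec":
            entries = [(0, s["tcw_plus"], None), (1, s["tcw_minus"], None)]
        else:
            entries = [
                (0, s["g_plus"], s["gg_mask_plus"]),
                (1, s["g_minus"], s["gg_mask_minus"]),
            ]
        for strand_code, arr, gg_mask in entries:
            ok = occupancy.free_mask(chrom, arr)
            ok &= (arr >= 3) & (arr <= genome.lengths[chrom] - 2)
            pos_parts.append(arr[ok])
            chrom_parts.append(np.full(ok.sum(), ci, dtype=np.int32))
            strand_parts.append(np.full(ok.sum(), strand_code, dtype=np.int8))
            w = np.ones(len(arr))
            if gg_mask is not None:
                w[gg_mask] = cfg.nqo_gg_bias
            w_parts.append(w[ok])
    pool_pos = np.concatenate(pos_parts)
    pool_chrom = np.concatenate(chrom_parts)
    pool_strand = np.concatenate(strand_parts)
    w = np.concatenate(w_parts)
    if len(pool_pos) < n_target:
        raise RuntimeError(
            f"only {len(pool_pos)} candidate sites for {n_target} {mutation_class} mutations"
        )
    # Weighted sampling without replacement via Gumbel top-k keys.
    keys = np.log(w) + rng.gumbel(size=len(w))
    order = np.argsort(-keys)[:n_target]

    planted = 0
    for i in order:
        chrom = chroms[int(pool_chrom[i])]
        pos = int(pool_pos[i])
        strand = "+" if pool_strand[i] == 0 else "-"
        seq = genome.sequences[chrom]
        vaf = _truncnorm(rng, cfg.clone_vaf_mean, cfg.clone_vaf_sd, 0.06, 0.95)
        if mutation_class == "apobec":
            rec = _apobec_record(
                chrom, pos, strand, seq, to_t=rng.random() < cfg.apobec_ct_fraction,
                vaf=vaf, rng=rng, sample=cfg.sample,
            )
        else:
            to_t = rng.random() < cfg.nqo_gt_fraction
            if strand == "+":
                down = seq[pos]  # base 3' of the + strand guanine
                if not to_t and down == "A":
                    to_t = True  # GA-context G>C never planted
                ref, alt = "G", ("T" if to_t else "C")
            else:
                down = _COMP[seq[pos - 2]]  # 3' neighbour on the - strand
                if not to_t and down == "A":
                    to_t = True
                ref, alt = "C", ("A" if to_t else "G")
            ar, dp, ca = _read_support(rng, vaf)
            rec = MutationRecord(
                chrom=chrom, pos=pos, ref=ref, alt=alt, vaf=vaf,
                alt_reads=ar, depth=dp, caller_support=ca, sample=cfg.sample,
            )
        records.append(rec)
        truth_rows.append(
            {
                "sample": cfg.sample, "chrom": chrom, "pos": pos,
                "ref": rec.ref, "alt": rec.alt,
                "class": f"dispersed_{mutation_class}",
                "pair_id": -1, "imd": -1, "strand": strand, "region": "",
            }
        )
        occupancy.take(chrom, pos)
        planted += 1
    if planted < n_target:
        raise RuntimeError(
            f"placed only {planted}/{n_target} dispersed {mutation_class} mutations"
        )
    return records, truth_rows


def generate_dataset(cfg: SyntheticConfig = SyntheticConfig()) -> SyntheticDataset:
    """Generate the full dataset: genome, genes, planted catalog, truth."""
    rng = np.random.default_rng(cfg.seed)
    genome = make_genome(cfg, rng)
    models = make_gene_models(genome, cfg, rng) if cfg.n_genes > 0 else []
    sites = {c: _site_positions(s) for c, s in genome.sequences.items()}
    occupancy = _Occupancy()
    records: list[MutationRecord] = []
    truth_rows: list[dict] = []
    recs, rows = plant_didyma_ner(genome, models, cfg, rng, occupancy, sites)
    records += recs
    truth_rows += rows
    for mutation_class in ("apobec", "nqo"):
        recs, rows = plant_dispersed(
            genome, cfg, mutation_class, rng, occupancy, sites, models
        )
        records += recs
        truth_rows += rows
    catalog = MutationCatalog(records, genome_build="synthetic")
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample", "chrom", "pos", "ref", "alt", "class", "pair_id",
                 "imd", "strand", "region"],
    ).sort_values(["sample", "chrom", "pos"], ignore_index=True)
    return SyntheticDataset(genome=genome, models=models, catalog=catalog,
                            truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# File emission


def write_gtf(models: list[GeneModel], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}";'
            fh.write(
                f"{m.chrom}\tdidymascan\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{m.chrom}\tdidymascan\texon\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f'{attrs} transcript_id "{m.gene_id}.t1";\n'
            )
    return path


def write_vcf(catalog: MutationCatalog, genome: Genome, path: str | Path) -> Path:
    """Minimal VCF 4.2 with per-sample AF/AD/DP and a CALLERS info tag."""
    path = Path(path)
    samples = catalog.samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in genome.lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=CALLERS,Number=1,Type=Integer,Description="Supporting callers">\n')
        fh.write('##FORMAT=<ID=AF,Number=1,Type=Float,Description="Allele fraction">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for rec in catalog:
            info = f"CALLERS={rec.caller_support}" if rec.caller_support is not None else "."
            ref_reads = (rec.depth or 0) - (rec.alt_reads or 0)
            cols = []
            for s in samples:
                if s == rec.sample:
                    cols.append(f"{rec.vaf if rec.vaf is not None else 0}:{ref_reads},{rec.alt_reads or 0}:{rec.depth or 0}")
                else:
                    cols.append(".:.:.")
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t{info}\tAF:AD:DP\t"
                + "\t".join(cols) + "\n"
            )
    return path


def emit_dataset(
    dataset: SyntheticDataset, out_dir: str | Path, force: bool = False,
    vcf: bool = True,
) -> dict[str, Path]:
    """Write FASTA, GTF, expression TSV, catalog TSV (+ VCF), truth TSV,
    and a JSON manifest with the config and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True)")
    paths = {
        "fasta": out / "genome.fa",
        "gtf": out / "genes.gtf",
        "expression": out / "expression.tsv",
        "catalog": out / "catalog.tsv",
        "truth": out / "truth.tsv",
        "manifest": out / "manifest.json",
    }
    write_genome(dataset.genome, paths["fasta"])
    write_gtf(dataset.models, paths["gtf"])
    pd.DataFrame(
        {
            "gene_id": [m.gene_id for m in dataset.models],
            "expression": [m.expression for m in dataset.models],
        }
    ).to_csv(paths["expression"], sep="\t", index=False)
    write_catalog(dataset.catalog, paths["catalog"])
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)
    if vcf:
        paths["vcf"] = out / "catalog.vcf"
        write_vcf(dataset.catalog, dataset.genome, paths["vcf"])
    cfg = asdict(dataset.config)
    cfg["gene_length"] = list(cfg["gene_length"])
    cfg["ner_tract_range"] = list(cfg["ner_tract_range"])
    with open(paths["manifest"], "w") as fh:
        json.dump({"config": cfg, "n_records": len(dataset.catalog)}, fh, indent=2)
    return paths
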