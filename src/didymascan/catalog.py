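"""Mutation catalogs, reference genomes, and somatic-confidence filtering.

A :class:`MutationCatalog` is a flat, sorted collection of single-base
substitutions (SNVs) from one or more tumor samples.  Coordinates are
1-based inclusive throughout (VCF convention).  Catalogs can be read from
VCF 4.x or from a simple TSV dialect and written back losslessly.

Somatic-confidence filtering follows the standard multi-caller consensus
recipe for murine/human WGS: a mutation is retained when it is supported
by at least ``min_alt_reads`` reads, covered by at least ``min_depth``
reads, carries a variant allele frequency strictly above ``min_vaf``, and
was reported by at least ``min_callers`` independent callers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

BASES = frozenset("ACGT")

TSV_COLUMNS = [
    "chrom", "pos", "ref", "alt", "vaf", "alt_reads", "depth", "callers", "sample",
]


class CatalogError(ValueError):
    """Raised for malformed catalog inputs."""


@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-base substitution.

    ``pos`` is 1-based.  ``vaf`` is the variant allele frequency in [0, 1];
    ``alt_reads``/``depth`` are the supporting/total read counts and
    ``caller_support`` the number of callers that reported the variant
    (``None`` where unknown).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: Optional[float] = None
    alt_reads: Optional[int] = None
    depth: Optional[int] = None
    caller_support: Optional[int] = None
    sample: str = "sample"

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise CatalogError(
                f"ref/alt must be single bases in ACGT, got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise CatalogError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise CatalogError(f"pos must be >= 1, got {self.pos}")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise CatalogError(f"vaf {self.vaf} outside [0, 1]")
        if (
            self.alt_reads is not None
            and self.depth is not None
            and self.alt_reads > self.depth
        ):
            raise CatalogError(
                f"alt_reads {self.alt_reads} exceeds depth {self.depth} "
                f"at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.sample, self.chrom, self.pos)


@dataclass
class MutationCatalog:
    """A sorted, de-duplicated collection of :class:`MutationRecord`."""

    records: list[MutationRecord] = field(default_factory=list)
    genome_build: str = "unknown"

    def __post_init__(self) -> None:
        # Uniqueness includes the alt allele so split multi-allelic VCF rows
        # (same position, different alt) can coexist.
        self.records = sorted(self.records, key=lambda r: (r.key, r.alt))
        seen: set[tuple] = set()
        for rec in self.records:
            full = (*rec.key, rec.alt)
            if full in seen:
                raise CatalogError(
                    f"duplicate record at {rec.sample}:{rec.chrom}:{rec.pos} {rec.ref}>{rec.alt}"
                )
            seen.add(full)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MutationRecord]:
        return iter(self.records)

    @property
    def samples(self) -> list[str]:
        return sorted({r.sample for r in self.records})

    def subset(self, predicate) -> "MutationCatalog":
        return MutationCatalog(
            [r for r in self.records if predicate(r)], genome_build=self.genome_build
        )

    def by_sample_chrom(self) -> Iterator[tuple[tuple[str, str], list[MutationRecord]]]:
        """Yield ((sample, chrom), records) groups in sorted order."""
        group: list[MutationRecord] = []
        key: Optional[tuple[str, str]] = None
        for rec in self.records:
            k = (rec.sample, rec.chrom)
            if k != key and group:
                yield key, group  # type: ignore[misc]
                group = []
            key = k
            group.append(rec)
        if group:
            yield key, group  # type: ignore[misc]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.records],
                "pos": [r.pos for r in self.records],
                "ref": [r.ref for r in self.records],
                "alt": [r.alt for r in self.records],
                "vaf": [r.vaf for r in self.records],
                "alt_reads": [r.alt_reads for r in self.records],
                "depth": [r.depth for r in self.records],
                "callers": [r.caller_support for r in self.records],
                "sample": [r.sample for r in self.records],
            }
        )


@dataclass
class Genome:
    """Uppercase reference sequences keyed by chromosome name."""

    sequences: dict[str, str]
    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lengths:
            self.lengths = {c: len(s) for c, s in self.sequences.items()}

    def base(self, chrom: str, pos: int) -> str:
        """Forward-strand base at a 1-based position."""
        return self.sequences[chrom][pos - 1]

    def context(self, chrom: str, pos: int, flank: int) -> str:
        """Forward-strand window of ``2*flank + 1`` bases centred on ``pos``.

        Raises IndexError when the window overruns a contig edge.
        """
        seq = self.sequences[chrom]
        lo = pos - 1 - flank
        hi = pos + flank
        if lo < 0 or hi > len(seq):
            raise IndexError(
                f"context window {chrom}:{pos}±{flank} overruns contig edge"
            )
        return seq[lo:hi]


@dataclass(frozen=True)
class SomaticFilterConfig:
    """Multi-caller consensus confidence thresholds.

    ``min_vaf`` is a strict bound (a record at exactly the threshold is
    removed).  Setting a threshold to 0 disables its criterion, including
    the missing-field check for that criterion.
    """

    min_alt_reads: int = 3
    min_depth: int = 10
    min_vaf: float = 0.05
    min_callers: int = 2

    def __post_init__(self) -> None:
        if min(self.min_alt_reads, self.min_depth, self.min_callers) < 0 or self.min_vaf < 0:
            raise ValueError("filter thresholds must be >= 0")


def apply_somatic_filters(
    catalog: MutationCatalog, cfg: SomaticFilterConfig = SomaticFilterConfig()
) -> MutationCatalog:
    """Retain records meeting every enabled confidence criterion.

    Records lacking a field fail the corresponding criterion unless that
    criterion is disabled (threshold 0).  Never raises on values; order is
    preserved.  Idempotent.
    """

    def keep(r: MutationRecord) -> bool:
        if cfg.min_alt_reads > 0 and (r.alt_reads is None or r.alt_reads < cfg.min_alt_reads):
            return False
        if cfg.min_depth > 0 and (r.depth is None or r.depth < cfg.min_depth):
            return False
        if cfg.min_vaf > 0 and (r.vaf is None or r.vaf <= cfg.min_vaf):
            return False
        if cfg.min_callers > 0 and (r.caller_support is None or r.caller_support < cfg.min_callers):
            return False
        return True

    return catalog.subset(keep)


# ---------------------------------------------------------------------------
# I/O


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, str) and v in {".", ""}) or pd.isna(v):
        return None
    return float(v)


def _opt_int(v) -> Optional[int]:
    f = _opt_float(v)
    return None if f is None else int(f)


def read_catalog(path: str | Path, sample: Optional[str] = None) -> MutationCatalog:
    """Read a mutation catalog from VCF (by extension .vcf/.vcf.gz) or TSV.

    Non-SNV rows (indels, MNVs, symbolic alleles) are skipped with a logged
    tally; multi-allelic VCF rows are split into per-ALT records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        return _read_vcf(path, sample)
    return _read_tsv(path, sample)


def _read_vcf(path: Path, sample: Optional[str]) -> MutationCatalog:
    records: list[MutationRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        vcf_samples = list(vf.header.samples)
        tumor = None
        if vcf_samples:
            if sample is not None and sample in vcf_samples:
                tumor = sample
            else:
                tumor = vcf_samples[0]
        label = sample or tumor or path.stem
        for row in vf:
            if row.ref is None or row.alts is None:
                skipped += 1
                continue
            ref = row.ref.upper()
            for alt in row.alts:
                alt = (alt or "").upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                    skipped += 1
                    continue
                vaf = alt_reads = depth = callers = None
                if tumor is not None:
                    fmt = row.samples[tumor]
                    if "AF" in fmt and fmt["AF"] is not None:
                        af = fmt["AF"]
                        vaf = float(af[0] if isinstance(af, tuple) else af)
                    if "AD" in fmt and fmt["AD"] is not None:
                        ad = fmt["AD"]
                        if isinstance(ad, tuple) and len(ad) >= 2 and ad[0] is not None:
                            alt_reads = int(ad[1])
                            depth = int(sum(x for x in ad if x is not None))
                            if vaf is None and depth > 0:
                                vaf = alt_reads / depth
                    if "DP" in fmt and fmt["DP"] is not None:
                        depth = int(fmt["DP"])
                if "CALLERS" in row.info:
                    callers = int(row.info["CALLERS"])
                records.append(
                    MutationRecord(
                        chrom=row.chrom,
                        pos=row.pos,
                        ref=ref,
                        alt=alt,
                        vaf=vaf,
                        alt_reads=alt_reads,
                        depth=depth,
                        caller_support=callers,
                        sample=label,
                    )
                )
    if skipped:
        logger.info("read_catalog(%s): skipped %d non-SNV allele rows", path, skipped)
    return MutationCatalog(records)


def _read_tsv(path: Path, sample: Optional[str]) -> MutationCatalog:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["."],
                         float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CatalogError(f"cannot parse {path}: {exc}") from exc
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise CatalogError(
            f"{path}: TSV catalog requires columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    records: list[MutationRecord] = []
    skipped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        ref = str(d["ref"]).upper()
        alt = str(d["alt"]).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
            skipped += 1
            continue
        try:
            records.append(
                MutationRecord(
                    chrom=str(d["chrom"]),
                    pos=int(d["pos"]),
                    ref=ref,
                    alt=alt,
                    vaf=_opt_float(d.get("vaf")),
                    alt_reads=_opt_int(d.get("alt_reads")),
                    depth=_opt_int(d.get("depth")),
                    caller_support=_opt_int(d.get("callers")),
                    sample=sample or str(d.get("sample") or path.stem),
                )
            )
        except (CatalogError, ValueError) as exc:
            raise CatalogError(f"{path}: malformed row at line {i}: {exc}") from exc
    if skipped:
        logger.info("read_catalog(%s): skipped %d non-SNV rows", path, skipped)
    return MutationCatalog(records)


def write_catalog(catalog: MutationCatalog, path: str | Path) -> Path:
    """Write a catalog in the TSV dialect; round-trips with read_catalog."""
    path = Path(path)
    df = catalog.to_frame()
    df = df.rename(columns={"caller_support": "callers"})
    out = df[TSV_COLUMNS] if len(df) else pd.DataFrame(columns=TSV_COLUMNS)
    out.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.17g")
    return path


def read_genome(path: str | Path) -> Genome:
    """Read a FASTA reference; sequences uppercased, names = header token."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in sequences:
            raise CatalogError(f"duplicate chromosome name {name!r} in {path}")
        sequences[name] = str(rec.seq).upper()
    return Genome(sequences=sequences)


def write_genome(genome: Genome, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    return path
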