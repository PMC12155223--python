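"""Sequence-context classification of single-base substitutions.

Implements strand normalization to the pyrimidine (or purine) carrying
strand, SBS96 trinucleotide channels, the APOBEC deamination motif
T[C>T/G]W (W = A or T), the carcinogen guanine-adduct classes G>T / G>C
with the GA-dinucleotide exclusion, and pentanucleotide spectra adjusted
by genome-wide 5-mer abundance.

Conventions
-----------
* A substitution is always reported on the strand whose reference base is
  a pyrimidine (C/T); purine-reference records are reverse-complemented
  (alleles and flanks) before channel assignment.
* The guanine-adduct (NQO-like) classes are evaluated on the strand
  carrying the reference guanine; a forward-strand C>A is a minus-strand
  G>T.
* The GA exclusion removes G>C mutations whose guanine is followed by A
  on the guanine strand — exactly the reverse complement of the APOBEC
  T/N C>G case in a TC dinucleotide — so the APOBEC and guanine-adduct
  pair classes never overlap.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .catalog import Genome, MutationCatalog, MutationRecord

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGT", "TGCA")

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")

#: Canonical SBS96 channel order (COSMIC convention): substitutions grouped
#: C>A, C>G, C>T, T>A, T>C, T>G; within each, flanks vary A,C,G,T upstream-major.
SUBSTITUTIONS = [("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G")]
CHANNELS: list[str] = [
    f"{up}[{ref}>{alt}]{dn}"
    for (ref, alt) in SUBSTITUTIONS
    for up in "ACGT"
    for dn in "ACGT"
]
CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNELS)}


class ContextError(ValueError):
    """Raised when a record is inconsistent with the reference genome."""


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def pyrimidine_strand(record: MutationRecord) -> str:
    """Strand ('+'/'-') carrying the pyrimidine of the reference base pair.

    '+' when ref is C/T; '-' when ref is A/G (the paired pyrimidine then
    lies on the reverse strand).
    """
    return "+" if record.ref in PYRIMIDINES else "-"


def _oriented_context(record: MutationRecord, genome: Genome, flank: int) -> tuple[str, str]:
    """(context, alt) normalized to the pyrimidine strand.

    ``context`` is the ``2*flank+1`` window with the mutated pyrimidine at
    its centre.  Raises :class:`ContextError` on a ref mismatch or a contig
    edge; returns ('', alt) sentinel never — N flanks raise KeyError-free
    via the caller's tally.
    """
    actual = genome.base(record.chrom, record.pos)
    if actual != record.ref:
        raise ContextError(
            f"ref mismatch at {record.chrom}:{record.pos}: "
            f"catalog {record.ref}, genome {actual}"
        )
    try:
        window = genome.context(record.chrom, record.pos, flank)
    except IndexError as exc:
        raise ContextError(str(exc)) from exc
    alt = record.alt
    if record.ref in PURINES:
        window = revcomp(window)
        alt = alt.translate(COMPLEMENT)
    return window, alt


def sbs96_channel(record: MutationRecord, genome: Genome) -> str:
    """COSMIC-style channel name, e.g. ``'A[C>T]A'``.

    Raises :class:`ContextError` on ref mismatch or missing flank; returns
    None when a flank contains N (caller should tally the exclusion).
    """
    window, alt = _oriented_context(record, genome, flank=1)
    if any(b not in "ACGT" for b in window):
        return None
    name = f"{window[0]}[{window[1]}>{alt}]{window[2]}"
    if name not in CHANNEL_INDEX:  # pragma: no cover - defensive
        raise ContextError(f"unmappable channel {name}")
    return name


def is_apobec_context(record: MutationRecord, genome: Genome) -> bool:
    """True iff the record is T[C>T/G]W on the pyrimidine strand (W = A/T)."""
    window, alt = _oriented_context(record, genome, flank=1)
    if any(b not in "ACGT" for b in window):
        return False
    return (
        window[1] == "C"
        and window[0] == "T"
        and alt in "TG"
        and window[2] in "AT"
    )


def is_nqo_context(record: MutationRecord, genome: Genome) -> bool:
    """True iff a guanine-adduct class substitution: G>T, or G>C not in GA.

    Evaluated on the strand carrying the reference guanine.  G>C with a
    downstream A (GA dinucleotide) is excluded regardless of the upstream
    base; that excluded class is the exact opposite-strand complement of
    the APOBEC C>G-in-TC case, keeping the two pair classes disjoint.
    """
    window, alt = _oriented_context(record, genome, flank=1)
    if any(b not in "ACGT" for b in window):
        return False
    # _oriented_context normalizes to the pyrimidine strand; re-orient to
    # the guanine strand (reverse complement of the pyrimidine view).
    if window[1] != "C":
        return False
    g_alt = alt.translate(COMPLEMENT)
    g_down = window[0].translate(COMPLEMENT)  # base 3' of G on the G strand
    if g_alt == "T":
        return True
    if g_alt == "C":
        return g_down != "A"
    return False


def guanine_strand(record: MutationRecord) -> Optional[str]:
    """Strand carrying the reference guanine ('+' if ref G, '-' if ref C)."""
    if record.ref == "G":
        return "+"
    if record.ref == "C":
        return "-"
    return None


# ---------------------------------------------------------------------------
# Spectra


def build_sbs96(catalog: MutationCatalog, genome: Genome) -> np.ndarray:
    """96-vector of channel counts; N-flank/edge records excluded with a tally."""
    counts = np.zeros(96, dtype=np.int64)
    excluded = 0
    for rec in catalog:
        try:
            name = sbs96_channel(rec, genome)
        except ContextError:
            raise
        if name is None:
            excluded += 1
            continue
        counts[CHANNEL_INDEX[name]] += 1
    if excluded:
        logger.info("build_sbs96: excluded %d records with N/edge contexts", excluded)
    return counts


@dataclass
class PentanucleotideSpectrum:
    """Counts of (5-mer context, alt) pairs with genome-abundance adjustment.

    ``counts`` maps (pentamer, alt) — the pentamer oriented to the strand
    on which the record matches the requested substitution class — to the
    number of catalog records.  ``genome_counts`` holds strand-symmetric
    genome-wide occurrences of each pentamer, and ``adjusted`` the ratio
    count / genome occurrences.
    """

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    genome_counts: dict[str, int] = field(default_factory=dict)
    adjusted: dict[tuple[str, str], float] = field(default_factory=dict)
    excluded: int = 0


def count_kmers(genome: Genome, k: int, strand_symmetric: bool = True) -> dict[str, int]:
    """Genome-wide k-mer occurrence counts (forward + reverse complement)."""
    counts: dict[str, int] = {}
    for seq in genome.sequences.values():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            counts[kmer] = counts.get(kmer, 0) + 1
    if strand_symmetric:
        sym: dict[str, int] = {}
        for kmer, n in counts.items():
            sym[kmer] = sym.get(kmer, 0) + n
            rc = revcomp(kmer)
            sym[rc] = sym.get(rc, 0) + n
        counts = sym
    return counts


def pentanucleotide_spectrum(
    catalog: MutationCatalog,
    genome: Genome,
    subset: Optional[tuple[str, str]] = None,
) -> PentanucleotideSpectrum:
    """Pentanucleotide spectrum for a substitution class.

    ``subset`` is a (ref, alt) class such as ('G', 'T'); records matching
    the class on either strand are oriented to the class's reference
    strand before the 5-mer is extracted.  ``None`` uses the pyrimidine
    strand for every record.  Adjusted frequencies divide each raw count
    by the strand-symmetric genome-wide occurrences of the 5-mer.
    """
    spec = PentanucleotideSpectrum()
    for rec in catalog:
        actual = genome.base(rec.chrom, rec.pos)
        if actual != rec.ref:
            raise ContextError(
                f"ref mismatch at {rec.chrom}:{rec.pos}: catalog {rec.ref}, genome {actual}"
            )
        try:
            window = genome.context(rec.chrom, rec.pos, 2)
        except IndexError:
            spec.excluded += 1
            continue
        if any(b not in "ACGT" for b in window):
            spec.excluded += 1
            continue
        ref, alt = rec.ref, rec.alt
        if subset is not None:
            want_ref, want_alt = subset
            if (ref, alt) == (want_ref, want_alt):
                pass
            elif (ref.translate(COMPLEMENT), alt.translate(COMPLEMENT)) == (want_ref, want_alt):
                window = revcomp(window)
                ref, alt = want_ref, want_alt
            else:
                continue
        elif ref in PURINES:
            window = revcomp(window)
            alt = alt.translate(COMPLEMENT)
        key = (window, alt)
        spec.counts[key] = spec.counts.get(key, 0) + 1
    if spec.counts:
        genome_counts = count_kmers(genome, 5, strand_symmetric=True)
        for (window, alt), n in spec.counts.items():
            occ = genome_counts.get(window, 0)
            spec.genome_counts[window] = occ
            spec.adjusted[(window, alt)] = n / occ if occ else float("nan")
    return spec
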