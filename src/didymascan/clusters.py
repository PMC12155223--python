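"""Intermutation distances, clustered-event detection, and taxonomy.

The intermutation distance (IMD) between two mutations on the same
chromosome of the same sample is ``pos2 - pos1``: the two cytosines of a
TCC motif are 1 IMD apart, the two cytosines of TCTC are 2 IMD apart.

Clustered APOBEC events are labelled by size and spacing:

* **didyma** — a pair of strand-coordinated APOBEC-context mutations
  (T[C>T/G]W) within 32 nt of each other and with a variant-allele-
  frequency difference of at most 0.1 (same cell lineage);
* **omikli** — events of 2–3 mutations with at least one IMD > 1;
* **kataegis** — events of ≥4 mutations with at least one IMD > 1;
* **omikli − didyma** — omikli whose IMDs are all > 32 nt.

A size-2 event with IMD exactly 1 fails the omikli "at least one IMD > 1"
clause but sits on the didyma ladder; it is tallied as didyma only.

Guanine-adduct (NQO-like) mutation pairs are extracted separately, on the
same or opposite reference-guanine strands, with the GA-context exclusion
applied through :func:`didymascan.context.is_nqo_context`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np

from .catalog import Genome, MutationCatalog, MutationRecord
from .context import guanine_strand, is_apobec_context, is_nqo_context, pyrimidine_strand


@dataclass(frozen=True)
class ClusterDetectionConfig:
    """Thresholds of the clustered-mutation scan.

    ``capture_fraction``/``q_max`` govern the sample-dependent IMD
    threshold (at most ``1 - capture_fraction`` of sub-threshold mutations
    expected by chance, at BH-adjusted q < ``q_max``); ``window`` is the
    regional-correction window size in nt; ``vaf_max_diff`` the maximum
    within-event VAF difference; ``didyma_imd_max`` the fixed didyma
    pairing window in nt.
    """

    capture_fraction: float = 0.90
    q_max: float = 0.01
    window: int = 1_000_000
    vaf_max_diff: float = 0.1
    didyma_imd_max: int = 32

    def __post_init__(self) -> None:
        if not (0.0 < self.capture_fraction < 1.0):
            raise ValueError("capture_fraction must be in (0, 1)")
        if not (0.0 < self.q_max < 1.0):
            raise ValueError("q_max must be in (0, 1)")


@dataclass
class ClusterEvent:
    """A maximal run of clustered mutations on one chromosome of one sample."""

    sample: str
    chrom: str
    members: list[MutationRecord]
    imds: list[int]
    strand_coordinated: bool
    all_apobec: bool
    label: str = "other"  # didyma | omikli | kataegis | other
    didyma_mark: bool = False
    max_vaf_diff: float = 0.0

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def start(self) -> int:
        return self.members[0].pos

    @property
    def end(self) -> int:
        return self.members[-1].pos


@dataclass
class DidymosPair:
    """One didymos: two strand-coordinated APOBEC mutations within 32 nt."""

    sample: str
    chrom: str
    first: MutationRecord
    second: MutationRecord
    imd: int
    strand: str
    region: Optional[str] = None  # genic | intergenic
    gene_id: Optional[str] = None
    ts_nts: Optional[str] = None  # transcribed | non_transcribed | NA
    expression_bin: Optional[str] = None


def compute_imds(catalog: MutationCatalog) -> dict[tuple[str, str], list[int]]:
    """Per-(sample, chromosome) IMDs between consecutive mutations.

    Adjacent genomic positions have IMD 1; no IMD spans a chromosome or
    sample boundary; groups with a single mutation yield an empty list.
    """
    out: dict[tuple[str, str], list[int]] = {}
    for key, group in catalog.by_sample_chrom():
        out[key] = [b.pos - a.pos for a, b in zip(group, group[1:])]
    return out


def detect_clusters(
    catalog: MutationCatalog,
    flags: Optional[dict[tuple[str, str, int], bool]],
    threshold: int,
    cfg: ClusterDetectionConfig = ClusterDetectionConfig(),
    genome: Optional[Genome] = None,
) -> list[ClusterEvent]:
    """Group clustered-flagged mutations into events.

    Candidate events are maximal runs of consecutive flagged mutations
    whose successive IMDs are all ≤ ``threshold``; runs are split wherever
    a successive pair differs in VAF by more than ``cfg.vaf_max_diff``;
    runs of ≥2 members are emitted.  ``flags`` maps (sample, chrom, pos)
    to the clustered/dispersed flag from the background simulation; pass
    ``None`` to treat every mutation as flagged (fixed-threshold runs).
    When ``genome`` is given, events are annotated with strand
    coordination and APOBEC-context composition and labelled via
    :func:`classify_event`.
    """
    events: list[ClusterEvent] = []
    for (sample, chrom), group in catalog.by_sample_chrom():
        run: list[MutationRecord] = []

        def push(run: list[MutationRecord]) -> None:
            if len(run) < 2:
                return
            imds = [b.pos - a.pos for a, b in zip(run, run[1:])]
            vafs = [r.vaf for r in run if r.vaf is not None]
            max_diff = (max(vafs) - min(vafs)) if len(vafs) == len(run) else 0.0
            if genome is not None:
                strands = {pyrimidine_strand(r) for r in run}
                coordinated = len(strands) == 1
                apobec = all(is_apobec_context(r, genome) for r in run)
            else:
                coordinated = False
                apobec = False
            ev = ClusterEvent(
                sample=sample,
                chrom=chrom,
                members=list(run),
                imds=imds,
                strand_coordinated=coordinated,
                all_apobec=apobec,
                max_vaf_diff=max_diff,
            )
            if genome is not None:
                classify_event(ev, cfg)
            events.append(ev)

        for rec in group:
            flagged = True if flags is None else flags.get((sample, chrom, rec.pos), False)
            if not flagged:
                push(run)
                run = []
                continue
            if run:
                imd = rec.pos - run[-1].pos
                vaf_break = (
                    rec.vaf is not None
                    and run[-1].vaf is not None
                    and abs(rec.vaf - run[-1].vaf) > cfg.vaf_max_diff
                )
                if imd > threshold or vaf_break:
                    push(run)
                    run = []
            run.append(rec)
        push(run)
    return events


def classify_event(
    event: ClusterEvent, cfg: ClusterDetectionConfig = ClusterDetectionConfig()
) -> str:
    """Assign the APOBEC taxonomy label in place and return it.

    Events that are not strand-coordinated or not entirely APOBEC-context
    are ``other``.  Among qualifying events: size ≥4 with ≥1 IMD > 1 is
    kataegis; size 2–3 with ≥1 IMD > 1 is omikli (a size-2 omikli with
    IMD ≤ 32 additionally carries the didyma mark); a size-2 event with
    IMD 1 is didyma only; anything else (all-IMD-1 runs of ≥3) is other.
    """
    label = "other"
    didyma_mark = False
    if event.strand_coordinated and event.all_apobec:
        any_gt1 = any(d > 1 for d in event.imds)
        if event.size >= 4 and any_gt1:
            label = "kataegis"
        elif 2 <= event.size <= 3 and any_gt1:
            label = "omikli"
            if event.size == 2 and event.imds[0] <= cfg.didyma_imd_max:
                didyma_mark = True
        elif event.size == 2 and event.imds[0] == 1:
            label = "didyma"
            didyma_mark = True
    event.label = label
    event.didyma_mark = didyma_mark
    return label


def _qualifying_edge(
    a: MutationRecord, b: MutationRecord, cfg: ClusterDetectionConfig
) -> bool:
    """Didyma pairing predicate for two APOBEC-context records (a before b)."""
    if b.pos - a.pos > cfg.didyma_imd_max:
        return False
    if pyrimidine_strand(a) != pyrimidine_strand(b):
        return False
    if a.vaf is not None and b.vaf is not None and abs(a.vaf - b.vaf) > cfg.vaf_max_diff:
        return False
    return True


def extract_didyma(
    catalog: MutationCatalog,
    genome: Genome,
    cfg: ClusterDetectionConfig = ClusterDetectionConfig(),
    clustered_flags: Optional[dict[tuple[str, str, int], bool]] = None,
) -> list[DidymosPair]:
    """Extract didyma: isolated qualifying pairs of APOBEC mutations.

    All same-sample, same-chromosome pairs of APOBEC-context mutations
    within ``didyma_imd_max`` nt, sharing a pyrimidine strand, and within
    the VAF-difference bound form edges of a pairing graph; connected
    components of exactly two mutations are emitted as didyma.  Larger
    components (runs of ≥3 mutually clustered mutations) are left to the
    omikli/kataegis taxonomy and emit no pair, keeping the three classes
    disjoint.  When ``clustered_flags`` is given, only flagged mutations
    participate; the default scans all mutations.
    """
    pairs: list[DidymosPair] = []
    for (sample, chrom), group in catalog.by_sample_chrom():
        apo = [
            r
            for r in group
            if (clustered_flags is None or clustered_flags.get((sample, chrom, r.pos), False))
            and is_apobec_context(r, genome)
        ]
        n = len(apo)
        if n < 2:
            continue
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        edges: list[tuple[int, int]] = []
        j0 = 0
        for j in range(n):
            for i in range(j - 1, -1, -1):
                if apo[j].pos - apo[i].pos > cfg.didyma_imd_max:
                    break
                if _qualifying_edge(apo[i], apo[j], cfg):
                    edges.append((i, j))
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[ri] = rj
        comp_size: dict[int, int] = {}
        for i in range(n):
            r = find(i)
            comp_size[r] = comp_size.get(r, 0) + 1
        for i, j in edges:
            if comp_size[find(i)] == 2:
                pairs.append(
                    DidymosPair(
                        sample=sample,
                        chrom=chrom,
                        first=apo[i],
                        second=apo[j],
                        imd=apo[j].pos - apo[i].pos,
                        strand=pyrimidine_strand(apo[i]),
                    )
                )
    return pairs


def extract_nqo_pairs(
    catalog: MutationCatalog,
    genome: Genome,
    max_imd: int = 32,
    strand_mode: Literal["same", "opposite"] = "same",
) -> list[tuple[MutationRecord, MutationRecord]]:
    """Pairs of guanine-adduct-context mutations within ``max_imd`` nt.

    ``same`` keeps pairs whose reference guanines lie on one strand;
    ``opposite`` keeps pairs with guanines on opposite strands.  All
    in-range pairs are reported (not only consecutive ones); G>C
    mutations in a GA context never participate.
    """
    out: list[tuple[MutationRecord, MutationRecord]] = []
    for (sample, chrom), group in catalog.by_sample_chrom():
        nqo = [r for r in group if is_nqo_context(r, genome)]
        n = len(nqo)
        for j in range(n):
            for i in range(j - 1, -1, -1):
                if nqo[j].pos - nqo[i].pos > max_imd:
                    break
                same = guanine_strand(nqo[i]) == guanine_strand(nqo[j])
                if (strand_mode == "same") == same:
                    out.append((nqo[i], nqo[j]))
    return out


def taxonomy_counts(events: Iterable[ClusterEvent]) -> dict[str, int]:
    """Tally events by label plus the didyma-mark and omikli−didyma splits.

    ``didyma_fixed_window`` counts every event carrying the didyma mark
    (including IMD-1 pairs); ``didyma_omikli_eligible`` counts only marked
    events that are also omikli; both tallies are reported side by side.
    """
    counts = {
        "didyma": 0,
        "omikli": 0,
        "kataegis": 0,
        "other": 0,
        "didyma_fixed_window": 0,
        "didyma_omikli_eligible": 0,
        "omikli_minus_didyma": 0,
    }
    for ev in events:
        counts[ev.label] += 1
        if ev.didyma_mark:
            counts["didyma_fixed_window"] += 1
            if ev.label == "omikli":
                counts["didyma_omikli_eligible"] += 1
        if ev.label == "omikli" and not ev.didyma_mark:
            counts["omikli_minus_didyma"] += 1
    return counts
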