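"""Shared test helpers: independent oracles and dataset transforms.

Oracles here are deliberately naive (string scans, O(n^2) enumeration)
and independent of the package's implementation paths.
"""

from __future__ import annotations

import numpy as np

from didymascan.catalog import Genome, MutationCatalog, MutationRecord

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def oracle_channel(up: str, ref: str, alt: str, dn: str) -> str:
    """SBS96 channel by direct case analysis (independent of the package)."""
    if ref in "AG":
        up, ref, alt, dn = _COMP[dn], _COMP[ref], _COMP[alt], _COMP[up]
    return f"{up}[{ref}>{alt}]{dn}"


def oracle_is_apobec(up: str, ref: str, alt: str, dn: str) -> bool:
    if ref in "AG":
        up, ref, alt, dn = _COMP[dn], _COMP[ref], _COMP[alt], _COMP[up]
    return up == "T" and ref == "C" and alt in "TG" and dn in "AT"


def oracle_is_nqo(up: str, ref: str, alt: str, dn: str) -> bool:
    if ref in "CT":
        up, ref, alt, dn = _COMP[dn], _COMP[ref], _COMP[alt], _COMP[up]
    if ref != "G":
        return False
    if alt == "T":
        return True
    return alt == "C" and dn != "A"


def flanks(genome: Genome, chrom: str, pos: int) -> tuple[str, str]:
    seq = genome.sequences[chrom]
    return seq[pos - 2], seq[pos]


def brute_force_didyma(catalog: MutationCatalog, genome: Genome,
                       max_imd: int = 32, vaf_max_diff: float = 0.1) -> list[tuple]:
    """O(n^2) didyma enumeration: qualifying-pair graph, components of size 2."""
    out = []
    groups: dict[tuple[str, str], list[MutationRecord]] = {}
    for r in catalog:
        groups.setdefault((r.sample, r.chrom), []).append(r)
    for (sample, chrom), recs in groups.items():
        apo = []
        for r in recs:
            up, dn = flanks(genome, chrom, r.pos)
            if oracle_is_apobec(up, r.ref, r.alt, dn):
                apo.append(r)
        n = len(apo)
        adj = [set() for _ in range(n)]
        for i in range(n):
            for j in range(n):
                if i >= j:
                    continue
                a, b = apo[i], apo[j]
                if abs(b.pos - a.pos) > max_imd:
                    continue
                sa = "+" if a.ref in "CT" else "-"
                sb = "+" if b.ref in "CT" else "-"
                if sa != sb:
                    continue
                if a.vaf is not None and b.vaf is not None and abs(a.vaf - b.vaf) > vaf_max_diff:
                    continue
                adj[i].add(j)
                adj[j].add(i)
        seen = set()
        for i in range(n):
            if i in seen:
                continue
            comp = {i}
            stack = [i]
            while stack:
                k = stack.pop()
                for m in adj[k]:
                    if m not in comp:
                        comp.add(m)
                        stack.append(m)
            seen |= comp
            if len(comp) == 2:
                a, b = sorted(comp)
                out.append((sample, chrom, apo[a].pos, apo[b].pos))
    return sorted(out)


def brute_force_pair_counts(catalog: MutationCatalog, genome: Genome,
                            pair_class: str, max_imd: int) -> np.ndarray:
    """O(n^2) per-IMD pair counting for a pair class."""
    counts = np.zeros(max_imd, dtype=np.int64)
    groups: dict[tuple[str, str], list[MutationRecord]] = {}
    for r in catalog:
        groups.setdefault((r.sample, r.chrom), []).append(r)
    apobec = pair_class.startswith("apobec")
    same = pair_class.endswith("same_strand")
    for (_, chrom), recs in groups.items():
        members = []
        for r in recs:
            up, dn = flanks(genome, chrom, r.pos)
            if apobec:
                if not oracle_is_apobec(up, r.ref, r.alt, dn):
                    continue
                strand = "+" if r.ref in "CT" else "-"
            else:
                if not oracle_is_nqo(up, r.ref, r.alt, dn):
                    continue
                strand = "+" if r.ref == "G" else "-"
            members.append((r.pos, strand))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                d = abs(members[j][0] - members[i][0])
                if 1 <= d <= max_imd:
                    if (members[i][1] == members[j][1]) == same:
                        counts[d - 1] += 1
    return counts


def brute_force_cluster_runs(catalog: MutationCatalog, threshold: int,
                             vaf_max_diff: float = 0.1) -> list[tuple]:
    """Direct enumeration of clustered runs: consecutive same-sample,
    same-chromosome mutations chained while gap <= threshold and
    successive VAF difference <= vaf_max_diff; runs of >= 2 reported as
    (sample, chrom, member position tuple)."""
    groups: dict[tuple[str, str], list[MutationRecord]] = {}
    for r in catalog:
        groups.setdefault((r.sample, r.chrom), []).append(r)
    out = []
    for (sample, chrom), recs in groups.items():
        recs = sorted(recs, key=lambda r: r.pos)
        run = [recs[0]]
        for prev, cur in zip(recs, recs[1:]):
            ok = cur.pos - prev.pos <= threshold
            if ok and prev.vaf is not None and cur.vaf is not None:
                ok = abs(cur.vaf - prev.vaf) <= vaf_max_diff
            if ok:
                run.append(cur)
            else:
                if len(run) >= 2:
                    out.append((sample, chrom, tuple(r.pos for r in run)))
                run = [cur]
        if len(run) >= 2:
            out.append((sample, chrom, tuple(r.pos for r in run)))
    return sorted(out)


def revcomp_dataset(genome: Genome, catalog: MutationCatalog):
    """Reverse-complement the genome and every record (alleles + coordinates)."""
    new_seqs = {c: rc(s) for c, s in genome.sequences.items()}
    new_genome = Genome(sequences=new_seqs)
    new_records = []
    for r in catalog:
        L = genome.lengths[r.chrom]
        new_records.append(
            MutationRecord(
                chrom=r.chrom,
                pos=L - r.pos + 1,
                ref=_COMP[r.ref],
                alt=_COMP[r.alt],
                vaf=r.vaf,
                alt_reads=r.alt_reads,
                depth=r.depth,
                caller_support=r.caller_support,
                sample=r.sample,
            )
        )
    return new_genome, MutationCatalog(new_records, genome_build=catalog.genome_build)


def random_catalog(genome: Genome, n: int, rng: np.random.Generator,
                   sample: str = "rand") -> MutationCatalog:
    """Random SNVs at distinct interior positions; ref matches the genome."""
    records = []
    chroms = list(genome.sequences)
    used = set()
    while len(records) < n:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(3, genome.lengths[chrom] - 1))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref = genome.base(chrom, pos)
        alt = rng.choice([b for b in "ACGT" if b != ref])
        records.append(
            MutationRecord(chrom=chrom, pos=pos, ref=ref, alt=str(alt),
                           vaf=float(rng.uniform(0.1, 0.6)), alt_reads=20,
                           depth=60, caller_support=3, sample=sample)
        )
    return MutationCatalog(records)
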