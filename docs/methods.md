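# Methods

## Model and procedure

`didymascan` analyzes somatic single-base-substitution (SBS) catalogs
for the footprint of cooperative mutagenesis between a bulky-adduct
carcinogen and the single-strand DNA deaminase APOBEC3B. The mechanistic
model is: nucleotide excision repair (NER) removes a guanine adduct and
exposes a 24–32 nt single-stranded tract; APOBEC3B deaminates cytosines
in that tract (preferring TCW, W ∈ {A, T}); gap-filling synthesis fixes
the uracils as mutations. Two deaminations in one tract leave a
*didymos*: a pair of T[C>T/G]W mutations on the same strand within
32 nt, with near-equal variant allele frequencies (VAFs) because both
arise in one cell.

The pipeline stages are:

1. **Ingest and filter.** VCF/TSV catalogs; somatic confidence requires
   ≥ 3 supporting reads, ≥ 10 reads of coverage, VAF strictly over 0.05,
   and support from ≥ 2 callers (each criterion can be disabled by
   setting its threshold to 0). Coordinates are 1-based inclusive.
2. **Context classification.** Substitutions are strand-normalized to
   the pyrimidine (APOBEC classes) or guanine (carcinogen classes)
   strand. APOBEC context = T[C>T/G]W. Carcinogen (NQO-like) context =
   G>T, or G>C with a 3' base other than A; the GA exclusion is applied
   for every downstream-A guanine regardless of the upstream base, and
   makes the APOBEC and carcinogen pair classes provably disjoint (the
   excluded class is exactly the opposite-strand image of C>G in a TC
   dinucleotide).
3. **Background simulation.** Each of 100 iterations reassigns every
   mutation to a uniformly random position on the same chromosome with
   the same forward-strand trinucleotide (hence the same context *and*
   reference strand) and the same genic/intergenic class, drawn without
   replacement within each stratum; alleles and VAFs travel with the
   record, so per-stratum counts are conserved exactly. Strata with too
   few candidate positions relax the region constraint with a logged
   tally. This simulator reproduces the behavior of trinucleotide-
   preserving background generators; it does not reproduce any
   particular tool's output streams.
4. **Sample-dependent IMD threshold.** Integer cutoffs 1..10,000 are
   scanned. A cutoff qualifies when (a) the Poisson upper-tail
   probability of the observed count of consecutive IMDs ≤ c, with mean
   equal to the simulated count (a +1/(n_iter+1) continuity prior
   avoids p = 0 from empty simulated strata), is below 0.01 after
   Benjamini-Hochberg adjustment across the scanned grid, and (b) at
   most 10% of those sub-cutoff mutations are expected under the null
   (the 90%-capture condition, mean_sim/observed ≤ 0.1). The largest
   qualifying cutoff is the sample threshold; `None` when no cutoff
   qualifies. The published threshold procedure is not fully specified;
   this is an operational reconstruction built from its stated capture
   fraction and q bound. An empirical tail probability was considered
   and rejected: with 100 iterations its floor (1/101) exceeds what BH
   across a 10,000-point grid can leave under q < 0.01, so it can never
   qualify any cutoff.
5. **Regional correction.** 1 Mb windows slide in 0.5 Mb steps; each
   mutation is evaluated in the window centred nearest to it. Where the
   window's observed mutation count exceeds the simulated mean, the
   sample cutoff is divided by that ratio (never loosened in sparse
   windows — the ratio is clamped at 1 from below); a mutation stays
   clustered only if its nearest-neighbour distance fits the rescaled
   cutoff. An alternative formulation — re-testing counts per window —
   would be equally defensible; the rescaling form is the package's
   choice. Note its limit: a hotspot packed at IMD 1–2 cannot
   be demoted below a cutoff of 1.
6. **Clustering and taxonomy.** Maximal runs of clustered-flagged
   mutations with successive IMDs ≤ the threshold, split where the VAF
   difference of a successive pair exceeds 0.1. Strand-coordinated,
   all-APOBEC events are labelled: ≥ 4 members with ≥ 1 IMD > 1 →
   kataegis; 2–3 members with ≥ 1 IMD > 1 → omikli (size-2 omikli with
   IMD ≤ 32 carry the didyma mark); a size-2 event at IMD 1 is didyma
   only. Both didyma tallies — fixed-window (including IMD-1 pairs) and
   omikli-eligible — are reported side by side because the source
   definitions differ only on IMD-1 pairs and downstream consumers may
   prefer either. Note
   that two reference-context TCW motifs cannot sit 1 nt apart (the
   second cytosine's upstream base is the first cytosine); IMD-1 didyma
   arise in real data through processive deamination of the
   post-lesion context, so the taxonomy branch exists even though the
   reference-context generator cannot produce it.
7. **Didyma extraction** scans *all* same-sample, same-chromosome pairs
   of APOBEC-context mutations within 32 nt that share a pyrimidine
   strand and satisfy the 0.1 ΔVAF bound (a flag restricts the scan to
   clustered-flagged mutations instead). Qualifying pairs form graph
   edges; only connected components of exactly two mutations emit a
   didymos — larger runs are left to the omikli/kataegis taxonomy so
   the three classes stay disjoint and the omikli − didyma subtraction
   is well defined. The fixed 32 nt window applies even when the sample
   threshold is smaller.
8. **Enrichment.** For each pair class (APOBEC or carcinogen context,
   same or opposite reference strands), counts of all in-range pairs at
   each exact IMD 1..100 are divided by the mean simulated counts.
   Bins with zero simulated mean are undefined (NaN), never 0 or ∞.
   Cohort curves average per-sample enrichment values per IMD, skipping
   undefined entries and recording the per-IMD n; band summaries use
   the ratio of summed observed to summed simulated counts
   (count-weighted). Pooled-count curves are computable from the same
   profiles. "Observed divided by simulated" is read as *pair* counts
   per IMD — mutation-level division has no per-IMD meaning.
9. **Signature refit.** Two-pass NNLS over a known-signature matrix:
   full pass, pruning of signatures whose exposure share is strictly
   below 0.015 (ties at the cutoff retained, with a 1e-9 tolerance for
   solver round-off), second pass over the survivors. The pruning
   criterion is exposure share, not variance explained. If everything
   falls below the cutoff the single best pass-1 signature is kept and
   flagged. Counts (not frequency-normalized vectors) are fit; NNLS is
   scale-equivariant so this only fixes the exposure units. Burdens per
   Mb use mouse WGS 2,723 Mb, human WGS 2,800 Mb, human WES 30 Mb.
   A compact fixture matrix (six schematic profiles echoing
   SBS1/2/4/5/13/29 shapes) ships for tests and examples; the loader
   accepts COSMIC-format TSVs.
10. **Genomic attribution.** Genes are whole spans (exons + introns,
    1-based inclusive); a didymos is assigned one region/gene by its
    first member (≤ 32 nt pairs virtually never straddle a boundary;
    straddlers are flagged rather than double-counted). With gene sense
    strand S, a pair's pyrimidine strand = S puts the lesions on the
    non-transcribed (coding) strand; opposite = transcribed (template)
    strand; genes overlapping on opposite strands give NA. Densities
    normalize by genic 1,139 Mb / intergenic 1,584 Mb (mouse defaults)
    or by the merged-interval union of supplied models. Expression
    quartiles are nearest-rank cuts over positive-expression genes
    (computed per gene, not per transcript; ties share a bin), with a
    fifth bin for zero/missing expression.

## Synthetic data: what it emulates and what it does not

The generator produces an i.i.d.-base genome at a target GC fraction
(default 0.42, mouse-like), non-overlapping genes with zero-inflated
log-normal expression, and three mutation classes with truth labels:

* **didyma** — per pair, a strand is chosen (50/50), a tract length
  uniform in 24–32 nt, and a tract start; with gene models present 80%
  of tracts land in genes sampled proportionally to expression (the
  transcription-coupled-repair bias), the rest intergenic. Two TCW
  cytosines inside the tract are deaminated, C>T or C>G each with
  probability 0.5; members share a clone VAF (truncated normal,
  mean 0.35, sd 0.10) ± noise (sd 0.02), so true pairs pass the 0.1
  ΔVAF bound essentially always.
* **dispersed APOBEC** — uniform over genome-wide TCW sites, 70% C>T /
  30% C>G.
* **dispersed carcinogen** — over guanine sites with GG-context sites
  (3' guanine) weighted 3-fold, 75% G>T / 25% G>C, with would-be G>C at
  GA-context guanines planted as G>T so the exclusion class is never
  generated.

Read support is drawn to satisfy the default somatic filters (depth
30–80, alt reads ≥ 3, VAF > 0.05, 2–4 callers). Background mutations
keep ≥ 33 nt from planted pair members: exactly wide enough that no
background mutation can join a planted pair's 32 nt pairing graph
(keeping truth labels unambiguous) while leaving the 33–100 nt IMD band
of dispersed–didyma cross pairs intact — a wider dead zone would carve
observed pairs out of that band and bias its null enrichment below 1,
since the simulation redistributes the same mutations uniformly.

Not emulated: sequencing noise and mapping artifacts, copy number and
subclonal structure beyond the one-clone VAF model, replication timing,
realistic k-mer composition (i.i.d. bases), full 96-channel COSMIC
spectra for the dispersed classes (motif-level models only), and
processive-deamination IMD-1 pairs. Passing tests therefore demonstrate
correctness of the detection and attribution machinery under the
mechanistic model, not robustness to real-data artifacts.

## Study conditions used by the acceptance suite

Problem sizes were set by power calculation, not tuned on outcomes:

* **Planted recovery** — the default dataset (1 Mb, 200 dispersed
  APOBEC + 400 dispersed carcinogen, 50 didyma pairs), 10 seeded
  replicates; ≥ 95% of planted pairs recovered, ≤ 5% spurious.
* **Null enrichment** — 50,000 dispersed APOBEC mutations on a 2 Mb
  genome (expected same-strand pairs per exact IMD ≈ n²/2L ≈ 625, so
  the ≥ 500-expected-pairs clause is non-vacuous), 100 iterations;
  every such bin within [0.8, 1.2].
* **Enrichment shape** — a cohort of 8 samples (matching the 8-tumor
  cohort the enrichment curves average over) on 3 Mb genomes with
  3,000 dispersed APOBEC, 2,000 dispersed carcinogen, and 250 didyma
  pairs each — didyma members ≈ 14% of APOBEC mutations, near the
  ~15%-of-SBS2 proportion reported for carcinogen-exposed
  deaminase-active tumors; count-weighted band enrichment > 2 at
  IMD ≤ 32 and within [0.8, 1.2] at IMD 33–100.
* **Refit recovery** — multinomial draws of 10,000 mutations from a
  0.60/0.30/0.10 fixture mixture; shares recovered within ±0.03; a 1%
  contributor is pruned by the 0.015 cutoff.
* **Brute-force equivalence** — 50 random catalogs of n ∈ [50, 2000]
  against direct O(n²)/linear enumeration oracles.

## Numerical choices and degenerate inputs

* All randomness flows from explicit `numpy.random.default_rng` seeds;
  reruns are bit-identical.
* Records whose context window overruns a contig edge or contains N are
  excluded from context-dependent operations with a logged tally but
  retained in the catalog.
* A reference-allele mismatch against the genome raises at
  classification time, not at read time, so catalogs can be read
  without a genome.
* Catalog uniqueness is keyed on (sample, chromosome, position, alt) so
  split multi-allelic rows coexist.
* Fewer than two mutations, or fewer than two simulation iterations,
  make the threshold estimate `None` (with a warning) rather than an
  error; a `None` threshold flags every mutation dispersed.
* Pentanucleotide spectra adjust raw counts by strand-symmetric
  (collapsed) genome-wide 5-mer occurrences; per-strand normalization
  is a known alternative and the collapsed choice is flagged for
  sensitivity analysis.

## Known limitations

* The sample-threshold and regional-correction procedures are
  reconstructions of an under-specified published method; absolute
  thresholds may differ from other implementations even where the
  downstream didyma counts (fixed 32 nt window, scan over all
  mutations) do not.
* Sparse catalogs (a few hundred mutations per Mb) rarely support a
  sample-dependent threshold at q < 0.01 with 90% capture; didyma
  extraction is deliberately independent of that threshold.
* The regional rescaling cannot demote hotspots packed at IMD ≤ 2.
* Cohort enrichment averages per-sample ratios; with near-zero
  simulated means per bin those ratios are unstable, which is why band
  summaries are count-weighted.
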