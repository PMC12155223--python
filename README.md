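# didymascan

Analysis of synergistic APOBEC/carcinogen co-mutagenesis in somatic
mutation catalogs: detection and taxonomy of clustered mutations —
including **didyma**, pairs of strand-coordinated APOBEC-signature
mutations with an intermutation distance (IMD) ≤ 32 nt — plus
context-preserving background simulation, per-IMD enrichment profiling,
two-pass signature refitting, and genic/strand/expression attribution.

## The problem

Bulky-adduct carcinogens (tobacco-smoke mutagens and their laboratory
surrogate 4-nitroquinoline 1-oxide, NQO) damage guanines and yield
G→T/G→C mutations (an SBS4-like spectrum). The endogenous deaminase
APOBEC3B attacks cytosines in single-stranded DNA, preferring TC
dinucleotides with a downstream A/T (TCW), and produces the SBS2/SBS13
signatures. These processes are not independent: excision of a bulky
adduct by nucleotide excision repair (NER) transiently exposes a
24–32 nt single-stranded tract, and deamination of two cytosines inside
one tract — immortalized by gap-filling synthesis — leaves a hallmark
pair of strand-coordinated T[C>T/G]W mutations a few tens of
nucleotides apart. `didymascan` detects that footprint and separates it
from the other clustered-mutation classes:

| class | definition |
| --- | --- |
| didyma | pair of strand-coordinated APOBEC-context (T[C>T/G]W) mutations, IMD ≤ 32 nt, ΔVAF ≤ 0.1 |
| omikli | clustered event of 2–3 mutations with ≥ 1 IMD > 1 |
| kataegis | clustered event of ≥ 4 mutations with ≥ 1 IMD > 1 |
| omikli − didyma | omikli whose IMDs are all > 32 nt |

IMD is the positional difference of two mutations on one chromosome of
one sample: the two cytosines of a mutated TCC motif are 1 IMD apart,
those of TCTC are 2 IMD apart.

Enrichment of a pair class at a given IMD is `observed / simulated`,
where the simulated counts come from catalogs in which every mutation is
reassigned uniformly at random among positions on the same chromosome
with the same trinucleotide context, reference strand, and
genic/intergenic class (100 iterations by default). Signature burdens
are refit by two-pass non-negative least squares: a full NNLS pass, then
removal of signatures contributing < 1.5% of exposures, then a second
pass over the survivors; burdens normalize per megabase (mouse WGS
2,723 Mb, human WGS 2,800 Mb, human WES 30 Mb).

## Worked example

The package ships a synthetic-data generator that emulates the
co-mutagenesis model: dispersed APOBEC (TCW C>T/G) and carcinogen
(GG-biased G>T/G>C) mutations plus didyma planted inside 24–32 nt NER
tracts, with truth labels for every mutation.

```python
import didymascan as d
from didymascan.clusters import taxonomy_counts
from didymascan.annotate import (GeneIndex, ExpressionBins, annotate_didyma,
                                 RegionSizes, didyma_density_by_region,
                                 didyma_by_expression)

ds = d.generate_dataset(d.SyntheticConfig(seed=7))        # 1 Mb, 700 mutations
pairs = d.extract_didyma(ds.catalog, ds.genome)
events = d.detect_clusters(ds.catalog, None, threshold=100, genome=ds.genome)
print(len(pairs), taxonomy_counts(events))

index = GeneIndex(ds.models)
bins = ExpressionBins.from_models(ds.models)
pairs = annotate_didyma(pairs, index, bins)
sizes = RegionSizes.from_models(ds.models, sum(ds.genome.lengths.values()))
print(didyma_density_by_region(pairs, sizes))
print(didyma_by_expression(pairs, bins))
```

Output (seed 7):

```
50 {'didyma': 0, 'omikli': 50, 'kataegis': 0, 'other': 10,
    'didyma_fixed_window': 50, 'didyma_omikli_eligible': 50,
    'omikli_minus_didyma': 0}
{'genic': 107.0, 'intergenic': 13.2}          # didyma per Mb of territory
{'non_expressed': 0.0, 'Q1': 7.1, 'Q2': 14.3, 'Q3': 26.2, 'Q4': 52.4}
```

All 50 planted pairs are recovered (the 10 `other` events are chance
adjacencies of background mutations); didyma concentrate in genic
territory (107 vs 13 per Mb) and climb with expression quartile —
the transcription-coupled-repair bias the generator plants. Refitting
the bundled signature fixtures to the same catalog attributes the
APOBEC share to SBS2/SBS13 and the carcinogen share to the C>A-type
profiles:

```python
counts = d.build_sbs96(ds.catalog, ds.genome)
print(d.fit_two_pass_nnls(counts, d.fixture_signatures()).summary("mouse_wgs"))
# SBS2 217.3 + SBS13 148.2 (APOBEC) vs SBS4 274.3 + SBS29 40.2; SBS1/SBS5 pruned
```

A command-line surface wraps the same stages:

```sh
didymascan synth --out data/ --seed 7
didymascan clusters --catalog data/catalog.tsv --genome data/genome.fa \
    --fixed-threshold 100 --out-prefix results/run
didymascan run-all --config pipeline.json
```

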