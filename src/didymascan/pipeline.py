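"""End-to-end orchestration and cohort-level summary statistics.

``run_pipeline`` wires the stages together — ingest, somatic filtering,
background simulation, sample-dependent IMD threshold, regional
correction, cluster detection and taxonomy, didyma and carcinogen-pair
extraction, per-IMD enrichment, signature refitting, and genomic
attribution — writing each stage's outputs before the next begins.  All
randomness flows from the single configured seed, so a rerun reproduces
the run bit for bit.

``cohort_summary`` compares per-sample metrics between groups with
two-tailed Mann-Whitney U tests, Spearman correlations for designated
metric pairs, and Benjamini-Hochberg adjustment applied when four or
more tests are reported together.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import annotate, clusters, context, enrichment, signatures, simulate
from .catalog import (
    Genome,
    MutationCatalog,
    SomaticFilterConfig,
    apply_somatic_filters,
    read_catalog,
    read_genome,
    write_catalog,
)
from .clusters import ClusterDetectionConfig
from .signatures import FitConfig, SignatureMatrix, fixture_signatures
from .simulate import PositionIndex, SimulationConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and stage settings for a full run."""

    genome: Path
    catalogs: list[Path]
    out_dir: Path
    gene_models: Optional[Path] = None
    expression: Optional[Path] = None
    signature_matrix: Optional[Path] = None  # COSMIC-style TSV; fixture if None
    platform: str = "mouse_wgs"
    detection: ClusterDetectionConfig = field(default_factory=ClusterDetectionConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    filters: SomaticFilterConfig = field(default_factory=SomaticFilterConfig)
    max_imd: int = 100
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        kwargs = dict(raw)
        for key in ("genome", "gene_models", "expression", "signature_matrix", "out_dir"):
            if kwargs.get(key):
                kwargs[key] = Path(kwargs[key])
        kwargs["catalogs"] = [Path(p) for p in raw["catalogs"]]
        for key, klass in [
            ("detection", ClusterDetectionConfig),
            ("simulation", SimulationConfig),
            ("fit", FitConfig),
            ("filters", SomaticFilterConfig),
        ]:
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        return cls(**kwargs)

    def validate(self) -> None:
        missing = [
            p
            for p in [self.genome, *self.catalogs, self.gene_models, self.expression,
                      self.signature_matrix]
            if p is not None and not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage in order; returns the result directory.

    Stage outputs land under ``cfg.out_dir``; a failure aborts with the
    stage name while preserving whatever was already written.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log = {"seed": cfg.seed, "stages": [], "tallies": {}}
    stage = "ingest"
    try:
        genome = read_genome(cfg.genome)
        catalog = MutationCatalog(
            [r for p in cfg.catalogs for r in read_catalog(p).records]
        )
        run_log["stages"].append(stage)

        stage = "filter"
        catalog = apply_somatic_filters(catalog, cfg.filters)
        write_catalog(catalog, out / "filtered_catalog.tsv")
        run_log["stages"].append(stage)

        stage = "gene_models"
        models: list[annotate.GeneModel] = []
        index = None
        genic_intervals = None
        if cfg.gene_models is not None:
            models = annotate.read_gene_models(cfg.gene_models, cfg.expression)
            index = annotate.GeneIndex(models)
            genic_intervals = index.genic_intervals()
        run_log["stages"].append(stage)

        stage = "simulate"
        pos_index = PositionIndex(genome, genic_intervals)
        sim_cfg = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        sims = simulate.simulate_catalog(catalog, genome, pos_index, sim_cfg)
        run_log["tallies"]["relaxed_draws"] = sims.relaxed
        run_log["stages"].append(stage)

        stage = "clusters"
        threshold = simulate.estimate_sample_imd_threshold(catalog, sims, cfg.detection)
        flags = simulate.regional_imd_correction(catalog, sims, threshold, cfg.detection)
        events = clusters.detect_clusters(
            catalog, flags, threshold or 0, cfg.detection, genome=genome
        )
        tax = clusters.taxonomy_counts(events)
        run_log["tallies"]["imd_threshold"] = threshold
        run_log["tallies"].update(tax)
        _write_events(events, out / "cluster_events.tsv")
        run_log["stages"].append(stage)

        stage = "didyma"
        pairs = clusters.extract_didyma(catalog, genome, cfg.detection)
        if index is not None:
            bins = annotate.ExpressionBins.from_models(models)
            pairs = annotate.annotate_didyma(pairs, index, bins)
        _write_pairs(pairs, out / "didyma.tsv")
        run_log["tallies"]["didyma_pairs"] = len(pairs)
        run_log["stages"].append(stage)

        stage = "enrichment"
        rows = []
        for pair_class in enrichment.PAIR_CLASSES:
            observed = enrichment.pair_counts_by_imd(catalog, genome, pair_class, cfg.max_imd)
            profile = enrichment.enrichment_vs_simulation(
                observed, sims, genome, pair_class, cfg.max_imd
            )
            for i in range(cfg.max_imd):
                rows.append(
                    {
                        "pair_class": pair_class,
                        "imd": int(profile.imd_axis[i]),
                        "observed": profile.observed[i],
                        "simulated_mean": profile.simulated_mean[i],
                        "enrichment": profile.enrichment[i],
                    }
                )
        pd.DataFrame(rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        run_log["stages"].append(stage)

        stage = "signatures"
        sig_matrix = (
            SignatureMatrix.from_cosmic_tsv(cfg.signature_matrix)
            if cfg.signature_matrix is not None
            else fixture_signatures()
        )
        sig_rows = []
        for sample in catalog.samples:
            sub = catalog.subset(lambda r: r.sample == sample)
            counts = signatures.build_sbs96(sub, genome)
            res = signatures.fit_two_pass_nnls(counts, sig_matrix, cfg.fit)
            df = res.summary(platform=cfg.platform)
            df.insert(0, "sample", sample)
            sig_rows.append(df)
        pd.concat(sig_rows).to_csv(out / "signature_exposures.tsv", sep="\t", index=False)
        run_log["stages"].append(stage)

        stage = "genomic_context"
        if index is not None and pairs:
            density = annotate.didyma_density_by_region(
                pairs,
                annotate.RegionSizes.from_models(models, sum(genome.lengths.values())),
            )
            bins = annotate.ExpressionBins.from_models(models)
            expr_pct = annotate.didyma_by_expression(pairs, bins)
            ts = sum(1 for p in pairs if p.ts_nts == "transcribed")
            nts = sum(1 for p in pairs if p.ts_nts == "non_transcribed")
            summary = {"density_per_mb": density, "expression_pct": expr_pct,
                       "ts": ts, "nts": nts}
            with open(out / "genomic_context.json", "w") as fh:
                json.dump(summary, fh, indent=2)
        run_log["stages"].append(stage)
    except Exception as exc:
        if isinstance(exc, StageFailure):
            raise
        raise StageFailure(stage, exc) from exc

    with open(out / "run.log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, default=str)
    return out


def _write_events(events: Sequence[clusters.ClusterEvent], path: Path) -> None:
    rows = []
    for ev in events:
        vafs = [r.vaf for r in ev.members if r.vaf is not None]
        rows.append(
            {
                "sample": ev.sample,
                "chrom": ev.chrom,
                "start": ev.start,
                "end": ev.end,
                "size": ev.size,
                "label": ev.label,
                "didyma_flag": ev.didyma_mark,
                "imds": ",".join(str(d) for d in ev.imds),
                "mean_vaf": float(np.mean(vafs)) if vafs else np.nan,
            }
        )
    pd.DataFrame(
        rows,
        columns=["sample", "chrom", "start", "end", "size", "label", "didyma_flag",
                 "imds", "mean_vaf"],
    ).to_csv(path, sep="\t", index=False)
    bed = path.with_suffix(".bed")
    with open(bed, "w") as fh:
        for ev in events:
            # BED is 0-based half-open
            fh.write(f"{ev.chrom}\t{ev.start - 1}\t{ev.end}\t{ev.label}\t{ev.size}\t.\n")


def _write_pairs(pairs: Sequence[clusters.DidymosPair], path: Path) -> None:
    pd.DataFrame(
        [
            {
                "sample": p.sample,
                "chrom": p.chrom,
                "pos1": p.first.pos,
                "pos2": p.second.pos,
                "imd": p.imd,
                "strand": p.strand,
                "region": p.region,
                "gene_id": p.gene_id,
                "ts_nts": p.ts_nts,
                "expression_bin": p.expression_bin,
            }
            for p in pairs
        ],
        columns=["sample", "chrom", "pos1", "pos2", "imd", "strand", "region",
                 "gene_id", "ts_nts", "expression_bin"],
    ).to_csv(path, sep="\t", index=False)


def cohort_summary(
    metrics: pd.DataFrame,
    group_col: str = "group",
    correlate: Sequence[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Group comparisons of per-sample metrics.

    ``metrics`` holds one row per sample with a ``group_col`` label and
    numeric metric columns.  For each metric and each group pair, reports
    group medians and a two-tailed Mann-Whitney U p-value; for each
    designated metric pair, a Spearman correlation over all samples.
    BH-adjusted q-values are added when the table carries at least four
    tests; groups with no observations are skipped with a note.
    """
    value_cols = [c for c in metrics.columns if c != group_col
                  and pd.api.types.is_numeric_dtype(metrics[c])]
    groups = sorted(metrics[group_col].dropna().unique())
    rows = []
    for col in value_cols:
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                a = metrics.loc[metrics[group_col] == ga, col].dropna()
                b = metrics.loc[metrics[group_col] == gb, col].dropna()
                if len(a) < 1 or len(b) < 1:
                    rows.append({"test": "mann_whitney", "metric": col,
                                 "group_a": ga, "group_b": gb, "p": np.nan,
                                 "note": "empty group"})
                    continue
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                rows.append(
                    {
                        "test": "mann_whitney", "metric": col,
                        "group_a": ga, "group_b": gb,
                        "median_a": float(a.median()), "median_b": float(b.median()),
                        "U": float(stat), "p": float(p), "note": "",
                    }
                )
    for x, y in correlate:
        sub = metrics[[x, y]].dropna()
        if len(sub) >= 3:
            rho, p = stats.spearmanr(sub[x], sub[y])
            rows.append({"test": "spearman", "metric": f"{x}~{y}",
                         "rho": float(rho), "p": float(p), "note": ""})
    df = pd.DataFrame(rows)
    tested = df["p"].notna() if len(df) else pd.Series(dtype=bool)
    # BH only when the table presents four or more tests.
    if len(df) and tested.sum() >= 4:
        df.loc[tested, "q"] = enrichment.bh_adjust(df.loc[tested, "p"])
    return df
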