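"""Per-IMD pair-count enrichment against simulated backgrounds.

For a pair class (APOBEC- or guanine-adduct-context mutations, on the
same or opposite reference strands), counts of qualifying pairs at each
exact intermutation distance 1..max_imd are compared between the
observed catalog and context-preserving simulated catalogs: enrichment
at an IMD is the observed pair count divided by the mean simulated pair
count over iterations.  Bins with zero simulated mean are undefined
(NaN), never 0 or infinity.  Cohort curves are per-IMD arithmetic means
of per-sample enrichment values, skipping undefined entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .catalog import Genome, MutationCatalog
from .context import guanine_strand, is_apobec_context, is_nqo_context, pyrimidine_strand

PAIR_CLASSES = (
    "apobec_same_strand",
    "apobec_opposite_strand",
    "nqo_same_strand",
    "nqo_opposite_strand",
)


@dataclass
class EnrichmentProfile:
    """Observed/simulated pair counts and their ratio per exact IMD."""

    imd_axis: np.ndarray  # 1..max_imd
    observed: np.ndarray
    simulated_mean: np.ndarray
    enrichment: np.ndarray  # NaN where simulated_mean == 0
    pair_class: str
    n_samples: Optional[np.ndarray] = None  # per-IMD sample count for cohorts

    def __post_init__(self) -> None:
        lens = {len(self.imd_axis), len(self.observed), len(self.simulated_mean),
                len(self.enrichment)}
        if len(lens) != 1:
            raise ValueError("profile arrays must share a length")

    def band_enrichment(self, lo: int, hi: int) -> float:
        """Ratio of summed observed to summed simulated counts over an
        inclusive IMD band — a count-weighted mean enrichment."""
        sel = (self.imd_axis >= lo) & (self.imd_axis <= hi)
        sim = self.simulated_mean[sel].sum()
        return float(self.observed[sel].sum() / sim) if sim > 0 else float("nan")


def _class_members(
    catalog: MutationCatalog, genome: Genome, pair_class: str
) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
    """Per (sample, chrom): sorted positions and strand codes of class members."""
    if pair_class not in PAIR_CLASSES:
        raise ValueError(f"unknown pair class {pair_class!r}")
    apobec = pair_class.startswith("apobec")
    out: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for key, group in catalog.by_sample_chrom():
        pos: list[int] = []
        strand: list[int] = []
        for r in group:
            if apobec:
                if not is_apobec_context(r, genome):
                    continue
                s = pyrimidine_strand(r)
            else:
                if not is_nqo_context(r, genome):
                    continue
                s = guanine_strand(r)
            pos.append(r.pos)
            strand.append(0 if s == "+" else 1)
        if pos:
            out[key] = (np.asarray(pos), np.asarray(strand))
    return out


def pair_counts_by_imd(
    catalog: MutationCatalog,
    genome: Genome,
    pair_class: str,
    max_imd: int = 100,
) -> np.ndarray:
    """Counts of qualifying pairs at each exact IMD 1..max_imd.

    All in-range pairs count, not only consecutive ones.  Returned vector
    has length ``max_imd``; index ``d - 1`` holds the count at IMD ``d``.
    """
    same = pair_class.endswith("same_strand")
    counts = np.zeros(max_imd, dtype=np.int64)
    for pos, strand in _class_members(catalog, genome, pair_class).values():
        n = len(pos)
        for k in range(1, n):
            d = pos[k:] - pos[:-k]
            within = d <= max_imd
            if not within.any():
                break
            pair_same = strand[k:] == strand[:-k]
            sel = within & (pair_same if same else ~pair_same)
            if sel.any():
                counts += np.bincount(d[sel] - 1, minlength=max_imd)[:max_imd]
    return counts


def enrichment_vs_simulation(
    observed: np.ndarray,
    sims: "SimulatedCatalogSet",
    genome: Genome,
    pair_class: str,
    max_imd: int = 100,
) -> EnrichmentProfile:
    """Enrichment profile of observed pair counts against simulations."""
    if sims.iterations < 1:
        raise ValueError("need at least one simulation iteration")
    sim_counts = np.vstack(
        [pair_counts_by_imd(c, genome, pair_class, max_imd) for c in sims.catalogs]
    )
    sim_mean = sim_counts.mean(axis=0)
    enrichment = np.full(max_imd, np.nan)
    nz = sim_mean > 0
    enrichment[nz] = observed[nz] / sim_mean[nz]
    return EnrichmentProfile(
        imd_axis=np.arange(1, max_imd + 1),
        observed=np.asarray(observed, dtype=float),
        simulated_mean=sim_mean,
        enrichment=enrichment,
        pair_class=pair_class,
    )


def cohort_average(profiles: Sequence[EnrichmentProfile]) -> EnrichmentProfile:
    """Per-IMD mean of per-sample enrichment values, skipping undefined bins.

    Observed and simulated counts are summed across samples (so the
    cohort profile's band ratios are count-weighted); the ``enrichment``
    track is the unweighted mean of per-sample ratios with per-IMD n
    recorded, matching sample-level ratio averaging.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    classes = {p.pair_class for p in profiles}
    if len(classes) != 1:
        raise ValueError(f"mixed pair classes: {sorted(classes)}")
    axis = profiles[0].imd_axis
    for p in profiles:
        if not np.array_equal(p.imd_axis, axis):
            raise ValueError("profiles must share an IMD axis")
    stack = np.vstack([p.enrichment for p in profiles])
    defined = ~np.isnan(stack)
    n = defined.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nansum(stack, axis=0) / np.maximum(n, 1), np.nan)
    return EnrichmentProfile(
        imd_axis=axis.copy(),
        observed=np.sum([p.observed for p in profiles], axis=0),
        simulated_mean=np.sum([p.simulated_mean for p in profiles], axis=0),
        enrichment=mean,
        pair_class=profiles[0].pair_class,
        n_samples=n,
    )


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
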