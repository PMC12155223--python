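"""Signature refitting by two-pass non-negative least squares.

A known-signature matrix (COSMIC-style, 96 trinucleotide channels per
column) is refit to an observed SBS96 count vector in two passes: pass 1
solves the full NNLS problem, signatures whose share of the total
exposure falls strictly below a cutoff (default 0.015) are pruned, and
pass 2 re-solves over the retained set.  Exposures are reported in
mutation counts; burdens are normalized per megabase using fixed
platform territory sizes (mouse WGS 2,723 Mb, human WGS 2,800 Mb, human
WES 30 Mb).

The refit is exposed both as a small Model/Results pair
(:class:`SignatureRefit` / :class:`SignatureRefitResults`) and as the
functional wrapper :func:`fit_two_pass_nnls`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .context import CHANNELS, build_sbs96  # noqa: F401  (re-exported: catalog -> counts -> refit)

#: Sequenced territory per platform, in megabases.
GENOME_MB = {"mouse_wgs": 2723.0, "human_wgs": 2800.0, "human_wes": 30.0}


def mutations_per_mb(count: float, platform: str) -> float:
    """Mutation burden normalized by the platform's sequenced megabases."""
    if platform not in GENOME_MB:
        raise KeyError(
            f"unknown platform {platform!r}; expected one of {sorted(GENOME_MB)}"
        )
    if count < 0:
        raise ValueError("count must be >= 0")
    return count / GENOME_MB[platform]


@dataclass
class SignatureMatrix:
    """Named SBS96 signature profiles; each column is non-negative, sums to 1."""

    names: list[str]
    profiles: np.ndarray  # shape (96, n_signatures)

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (96, len(self.names)):
            raise ValueError(
                f"profiles shape {self.profiles.shape} != (96, {len(self.names)})"
            )
        if (self.profiles < 0).any():
            raise ValueError("signature profiles must be non-negative")
        sums = self.profiles.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"signature columns must sum to 1; got {sums}")

    def subset(self, names: Sequence[str]) -> "SignatureMatrix":
        idx = [self.names.index(n) for n in names]
        return SignatureMatrix(list(names), self.profiles[:, idx])

    @classmethod
    def from_cosmic_tsv(cls, path: str | Path) -> "SignatureMatrix":
        """Load a COSMIC-format TSV: first column ``Type`` with rows like
        ``A[C>A]A``, one column per signature."""
        df = pd.read_csv(path, sep="\t")
        type_col = df.columns[0]
        df = df.set_index(type_col)
        missing = set(CHANNELS) - set(df.index)
        if missing:
            raise ValueError(f"signature TSV missing channels: {sorted(missing)[:5]}...")
        df = df.loc[CHANNELS]
        profiles = df.to_numpy(dtype=float)
        profiles = profiles / profiles.sum(axis=0, keepdims=True)
        return cls(list(df.columns), profiles)

    def to_cosmic_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(self.profiles, index=pd.Index(CHANNELS, name="Type"),
                     columns=self.names).to_csv(path, sep="\t")
        return path


@dataclass(frozen=True)
class FitConfig:
    """Two-pass refit settings; ``cutoff`` is the minimum exposure share."""

    cutoff: float = 0.015

    def __post_init__(self) -> None:
        if not (0.0 <= self.cutoff < 1.0):
            raise ValueError("cutoff must be in [0, 1)")


@dataclass
class SignatureRefitResults:
    """Exposures from a two-pass NNLS refit.

    ``exposures`` maps every input signature to a mutation count (exactly 0
    for signatures pruned after pass 1); ``retained`` lists the survivors;
    ``residual`` is the L2 reconstruction error of the pass-2 solution.
    ``fallback`` flags the degenerate case where every signature fell below
    the cutoff and the single best pass-1 signature was kept.
    """

    exposures: dict[str, float]
    residual: float
    retained: list[str]
    pass1_exposures: dict[str, float]
    fallback: bool = False

    @property
    def total(self) -> float:
        return float(sum(self.exposures.values()))

    def relative(self) -> dict[str, float]:
        t = self.total
        return {k: (v / t if t > 0 else 0.0) for k, v in self.exposures.items()}

    def summary(self, platform: Optional[str] = None) -> pd.DataFrame:
        rel = self.relative()
        df = pd.DataFrame(
            {
                "signature": list(self.exposures),
                "exposure_count": list(self.exposures.values()),
                "relative_contribution": [rel[k] for k in self.exposures],
                "retained": [k in self.retained for k in self.exposures],
            }
        )
        if platform is not None:
            df["exposure_per_mb"] = [
                mutations_per_mb(v, platform) for v in df["exposure_count"]
            ]
        return df


class SignatureRefit:
    """Two-pass NNLS refit of known signatures to an SBS96 count vector."""

    def __init__(
        self,
        counts: np.ndarray,
        signatures: SignatureMatrix,
        config: FitConfig = FitConfig(),
    ) -> None:
        counts = np.asarray(counts, dtype=float)
        if counts.shape != (96,):
            raise ValueError(f"counts must be a 96-vector, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not signatures.names:
            raise ValueError("at least one signature required")
        self.counts = counts
        self.signatures = signatures
        self.config = config

    def fit(self) -> SignatureRefitResults:
        S = self.signatures.profiles
        names = self.signatures.names
        x1, _ = nnls(S, self.counts)
        total1 = x1.sum()
        shares = x1 / total1 if total1 > 0 else np.zeros_like(x1)
        # Prune strictly below the cutoff; ties at the cutoff are retained
        # (tolerance absorbs solver round-off in the shares).
        keep = (
            shares >= self.config.cutoff - 1e-9
            if total1 > 0
            else np.zeros(len(names), bool)
        )
        fallback = False
        if not keep.any():
            keep[int(np.argmax(x1))] = True
            fallback = True
        retained = [n for n, k in zip(names, keep) if k]
        x2, res2 = nnls(S[:, keep], self.counts)
        exposures = {n: 0.0 for n in names}
        for n, v in zip(retained, x2):
            exposures[n] = float(v)
        return SignatureRefitResults(
            exposures=exposures,
            residual=float(res2),
            retained=retained,
            pass1_exposures={n: float(v) for n, v in zip(names, x1)},
            fallback=fallback,
        )


def fit_two_pass_nnls(
    counts: np.ndarray,
    signatures: SignatureMatrix,
    config: FitConfig = FitConfig(),
) -> SignatureRefitResults:
    """Functional wrapper over :class:`SignatureRefit`."""
    return SignatureRefit(counts, signatures, config).fit()


# ---------------------------------------------------------------------------
# Fixture signature matrix


def _peaked_profile(weights: dict[str, float], floor: float = 1e-4) -> np.ndarray:
    v = np.full(96, floor)
    for name, w in weights.items():
        v[CHANNELS.index(name)] += w
    return v / v.sum()


def fixture_signatures() -> SignatureMatrix:
    """A compact deterministic signature matrix for refit work and tests.

    Six profiles echo the shapes of the familiar COSMIC signatures: a
    CpG-deamination clock (SBS1-like), the two APOBEC signatures peaked at
    T[C>T]W and T[C>G/A]W (SBS2/SBS13-like), a tobacco-carcinogen C>A
    profile with a CC-dinucleotide emphasis (SBS4-like), a flat clock-like
    background (SBS5-like), and a second, differently shaped C>A profile
    (SBS29-like).  Shapes are schematic, not the COSMIC vectors.
    """
    sigs = {
        "SBS1": _peaked_profile(
            {f"{u}[C>T]G": 0.22 for u in "ACGT"} | {f"{u}[C>T]A": 0.02 for u in "ACGT"}
        ),
        "SBS2": _peaked_profile(
            {"T[C>T]A": 0.38, "T[C>T]T": 0.38, "T[C>T]C": 0.10, "T[C>T]G": 0.08}
        ),
        "SBS4": _peaked_profile(
            {f"C[C>A]{d}": 0.13 for d in "ACGT"}
            | {f"A[C>A]{d}": 0.06 for d in "ACGT"}
            | {f"G[C>A]{d}": 0.04 for d in "ACGT"}
            | {"T[C>A]C": 0.04, "C[C>T]C": 0.04}
        ),
        "SBS5": _peaked_profile(
            {f"{u}[{r}>{a}]{d}": 0.008
             for (r, a) in [("C", "T"), ("T", "C"), ("C", "A")]
             for u in "ACGT" for d in "ACGT"}
            | {f"{u}[T>A]{d}": 0.004 for u in "ACGT" for d in "ACGT"}
        ),
        "SBS13": _peaked_profile(
            {"T[C>G]A": 0.34, "T[C>G]T": 0.34, "T[C>A]A": 0.10, "T[C>A]T": 0.10}
        ),
        "SBS29": _peaked_profile(
            {f"T[C>A]{d}": 0.14 for d in "ACGT"}
            | {f"{u}[C>A]A": 0.06 for u in "ACG"}
            | {f"{u}[T>A]A": 0.04 for u in "ACGT"}
        ),
    }
    names = list(sigs)
    return SignatureMatrix(names, np.column_stack([sigs[n] for n in names]))
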