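"""Mutation-spectrum statistics: 12-class substitution table with Ts/Tv, per-plant
mutation rates, per-chromosome window densities, and InDel size distributions."""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .curation import CuratedVariant
from .io import GenomeSequence

__all__ = [
    "SUBSTITUTION_CLASSES",
    "SubstitutionSpectrum",
    "WindowDensity",
    "RateSummary",
    "classify_substitution",
    "compute_spectrum",
    "per_plant_rates",
    "indel_fraction_pct",
    "window_density",
    "indel_size_histogram",
]

#: The 12 REF->ALT substitution classes in canonical report order.
SUBSTITUTION_CLASSES = (
    "AC", "AG", "AT",
    "CA", "CG", "CT",
    "GA", "GC", "GT",
    "TA", "TC", "TG",
)

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
#: Transitions: purine<->purine or pyrimidine<->pyrimidine.
TRANSITION_CLASSES = ("AG", "GA", "CT", "TC")


def classify_substitution(ref: str, alt: str) -> tuple[str, bool]:
    """Return the REF->ALT class label and whether it is a transition."""
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"not a single-base substitution: {ref}->{alt}")
    ref, alt = ref.upper(), alt.upper()
    if ref == alt or {ref, alt} - (_PURINES | _PYRIMIDINES):
        raise ValueError(f"invalid substitution {ref}->{alt}")
    label = ref + alt
    is_ts = (ref in _PURINES) == (alt in _PURINES)
    return label, is_ts


@dataclass
class SubstitutionSpectrum:
    """Counts and summary ratios over the 12 substitution classes."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(SUBSTITUTION_CLASSES)
        if unknown:
            raise ValueError(f"unknown substitution classes {unknown}")
        self.counts = {c: int(self.counts.get(c, 0)) for c in SUBSTITUTION_CLASSES}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[str, float]:
        t = self.total
        return {c: (100.0 * n / t if t else 0.0) for c, n in self.counts.items()}

    @property
    def ts_count(self) -> int:
        return sum(self.counts[c] for c in TRANSITION_CLASSES)

    @property
    def tv_count(self) -> int:
        return self.total - self.ts_count

    @property
    def ts_tv_ratio(self) -> float:
        """Transition/transversion count ratio; ``inf`` when there are no transversions."""
        if self.tv_count == 0:
            return math.inf
        return self.ts_count / self.tv_count

    @property
    def gc_to_at_fraction(self) -> float:
        """Fraction of SNVs that are G/C -> A/T transitions (the alkylation signature)."""
        t = self.total
        return (self.counts["GA"] + self.counts["CT"]) / t if t else 0.0

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {
                "ref": [c[0] for c in SUBSTITUTION_CLASSES],
                "alt": [c[1] for c in SUBSTITUTION_CLASSES],
                "n_sites": [self.counts[c] for c in SUBSTITUTION_CLASSES],
                "pct": [round(pct[c], 2) for c in SUBSTITUTION_CLASSES],
            }
        )


def compute_spectrum(snvs: Iterable[CuratedVariant | tuple[str, str]]) -> SubstitutionSpectrum:
    """Tally the 12-class spectrum from curated SNVs (or bare (ref, alt) pairs)."""
    counts: Counter[str] = Counter()
    for v in snvs:
        ref, alt = (v.ref, v.alt) if isinstance(v, CuratedVariant) else v
        label, _ = classify_substitution(ref, alt)
        counts[label] += 1
    return SubstitutionSpectrum(dict(counts))


@dataclass
class RateSummary:
    n_plants: int
    total_snvs: int
    mean_per_plant: float
    min_per_plant: int
    max_per_plant: int
    rate_per_mb: float
    genome_size_bases: int

    @classmethod
    def from_total(cls, total_snvs: int, n_plants: int, genome_size_bases: int) -> "RateSummary":
        """Summary from the cohort total alone (per-plant extremes unknown, set 0)."""
        if n_plants <= 0:
            raise ValueError("n_plants must be positive")
        mean = total_snvs / n_plants
        return cls(
            n_plants=n_plants,
            total_snvs=int(total_snvs),
            mean_per_plant=mean,
            min_per_plant=0,
            max_per_plant=0,
            rate_per_mb=mean / (genome_size_bases / 1e6),
            genome_size_bases=genome_size_bases,
        )


def indel_fraction_pct(n_indels: int, n_snvs: int) -> float:
    """InDels as a percentage of all curated variants (SNVs + InDels)."""
    total = n_indels + n_snvs
    if total == 0:
        return 0.0
    return 100.0 * n_indels / total


def per_plant_rates(
    per_plant_counts: Mapping[str, int] | Sequence[int],
    genome_size_bases: int,
) -> RateSummary:
    """Per-plant SNV count summary and the cohort-mean mutation rate per megabase.

    The per-Mb denominator (total reference length) is explicit because reported
    rates depend on which assembly span is counted.
    """
    counts = (
        list(per_plant_counts.values())
        if isinstance(per_plant_counts, Mapping)
        else list(per_plant_counts)
    )
    if not counts:
        return RateSummary(0, 0, 0.0, 0, 0, 0.0, genome_size_bases)
    total = int(sum(counts))
    mean = total / len(counts)
    return RateSummary(
        n_plants=len(counts),
        total_snvs=total,
        mean_per_plant=mean,
        min_per_plant=int(min(counts)),
        max_per_plant=int(max(counts)),
        rate_per_mb=mean / (genome_size_bases / 1e6),
        genome_size_bases=genome_size_bases,
    )


@dataclass(frozen=True)
class WindowDensity:
    chrom: str
    window_start: int  # 1-based
    window_size: int
    n_snvs: int


def window_density(
    snvs: Iterable[CuratedVariant],
    genome: GenomeSequence,
    window_size: int = 100_000,
    step: int | None = None,
) -> list[WindowDensity]:
    """SNV counts in windows tiled along each chromosome (last window truncated).

    By default windows are non-overlapping tiles (step = window size); pass a
    smaller ``step`` for genuinely sliding windows.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    step = window_size if step is None else step
    if step <= 0:
        raise ValueError("step must be positive")
    positions: dict[str, list[int]] = {c: [] for c in genome.chrom_names}
    for v in snvs:
        if v.is_snv:
            positions[v.chrom].append(v.pos)
    out: list[WindowDensity] = []
    for chrom in genome.chrom_names:
        pos = np.sort(np.asarray(positions[chrom], dtype=np.int64))
        length = genome.length(chrom)
        for start in range(1, length + 1, step):
            end = min(start + window_size - 1, length)
            n = int(np.searchsorted(pos, end, "right") - np.searchsorted(pos, start, "left"))
            out.append(WindowDensity(chrom, start, window_size, n))
    return out


@dataclass
class IndelSizeSummary:
    histogram: dict[int, int]  # signed length -> count
    n_insertions: int
    n_deletions: int
    short_fraction: float  # fraction with |length| < 3

    @property
    def n_total(self) -> int:
        return self.n_insertions + self.n_deletions


def indel_size_histogram(indels: Iterable[CuratedVariant]) -> IndelSizeSummary:
    """Signed-length histogram of InDels with the short (<3 bp) fraction."""
    hist: Counter[int] = Counter()
    for v in indels:
        if v.is_snv:
            raise ValueError(f"SNV passed to indel_size_histogram: {v}")
        hist[v.indel_length] += 1
    n_ins = sum(n for length, n in hist.items() if length > 0)
    n_del = sum(n for length, n in hist.items() if length < 0)
    total = n_ins + n_del
    short = sum(n for length, n in hist.items() if abs(length) < 3)
    return IndelSizeSummary(
        histogram=dict(sorted(hist.items())),
        n_insertions=n_ins,
        n_deletions=n_del,
        short_fraction=short / total if total else 0.0,
    )
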