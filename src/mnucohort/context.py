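"""Flanking-nucleotide context bias around mutated guanines.

MNU alkylates guanine, and its local sequence preference shows up as skewed base
frequencies in the +/-20 bp neighborhoods of mutated G sites relative to a null of
randomly chosen genomic G positions. Sites enter in plus-strand reference
orientation (REF = G only; C>N complements are not folded in), so the profile is
directly comparable to a randomly-sampled-G null from the same strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .curation import CuratedVariant
from .io import GenomeSequence

__all__ = [
    "ContextProfile",
    "select_mutated_g",
    "profile_context",
    "sample_null_g",
    "bias_report",
]

BASES = ("A", "C", "G", "T")


@dataclass
class ContextProfile:
    """Per-offset base frequencies around a set of genomic sites.

    ``frequencies[offset + halfwidth, base_index]`` is the frequency of ``BASES[base_index]``
    at that offset; per-offset denominators exclude neighbors that fall off a
    chromosome end or are N.
    """

    halfwidth: int
    frequencies: np.ndarray  # (2*halfwidth+1, 4)
    n_valid: np.ndarray  # per-offset denominator
    n_sites: int
    label: str  # "observed" | "null"

    @property
    def offsets(self) -> list[int]:
        return list(range(-self.halfwidth, self.halfwidth + 1))

    def frequency(self, offset: int, base: str) -> float:
        return float(self.frequencies[offset + self.halfwidth, BASES.index(base)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, off in enumerate(self.offsets):
            for j, b in enumerate(BASES):
                rows.append(
                    {
                        "offset": off,
                        "base": b,
                        "frequency": float(self.frequencies[i, j]),
                        "n_valid": int(self.n_valid[i]),
                    }
                )
        return pd.DataFrame(rows)


def select_mutated_g(curated_snvs: Iterable[CuratedVariant]) -> list[tuple[str, int]]:
    """Sites of all curated SNVs whose reference base is G (any ALT)."""
    return [(v.chrom, v.pos) for v in curated_snvs if v.is_snv and v.ref == "G"]


def profile_context(
    sites: Sequence[tuple[str, int]],
    genome: GenomeSequence,
    halfwidth: int = 20,
    label: str = "observed",
) -> ContextProfile:
    """Base-frequency matrix over the +/-``halfwidth`` bp neighborhoods of ``sites``.

    Sites near chromosome ends contribute only their in-range offsets.
    """
    n_offsets = 2 * halfwidth + 1
    counts = np.zeros((n_offsets, 4), dtype=np.int64)
    base_index = {b: j for j, b in enumerate(BASES)}
    for chrom, pos in sites:
        seq = genome.sequences[chrom]
        if not 1 <= pos <= len(seq):
            raise IndexError(f"site {chrom}:{pos} outside genome")
        lo = max(1, pos - halfwidth)
        hi = min(len(seq), pos + halfwidth)
        window = seq[lo - 1 : hi]
        row0 = lo - pos + halfwidth
        for i, base in enumerate(window):
            j = base_index.get(base)
            if j is not None:  # N neighbors excluded from that offset's denominator
                counts[row0 + i, j] += 1
    n_valid = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        freqs = np.where(n_valid[:, None] > 0, counts / np.maximum(n_valid, 1)[:, None], 0.0)
    return ContextProfile(
        halfwidth=halfwidth,
        frequencies=freqs,
        n_valid=n_valid,
        n_sites=len(sites),
        label=label,
    )


def sample_null_g(
    genome: GenomeSequence, n: int, rng: np.random.Generator | int
) -> list[tuple[str, int]]:
    """Uniform without-replacement sample of ``n`` genomic G positions."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    chroms: list[str] = []
    offsets: list[np.ndarray] = []
    for chrom, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        pos = np.nonzero(arr == ord("G"))[0] + 1
        chroms.append(chrom)
        offsets.append(pos)
    totals = np.array([len(p) for p in offsets])
    total_g = int(totals.sum())
    if n > total_g:
        raise ValueError(f"requested {n} null G sites but genome has only {total_g}")
    pick = np.sort(rng.choice(total_g, size=n, replace=False))
    bounds = np.cumsum(totals)
    sites: list[tuple[str, int]] = []
    for idx in pick:
        c = int(np.searchsorted(bounds, idx, "right"))
        local = idx - (bounds[c - 1] if c else 0)
        sites.append((chroms[c], int(offsets[c][local])))
    return sites


def bias_report(
    observed: ContextProfile,
    null: ContextProfile,
    flag_threshold_pp: float = 5.0,
) -> pd.DataFrame:
    """Observed-minus-null frequency differences in percentage points, per offset/base.

    Rows where |difference| exceeds ``flag_threshold_pp`` are flagged.
    """
    if observed.halfwidth != null.halfwidth:
        raise ValueError("profiles have different halfwidths")
    diff_pp = 100.0 * (observed.frequencies - null.frequencies)
    rows = []
    for i, off in enumerate(observed.offsets):
        for j, b in enumerate(BASES):
            d = float(diff_pp[i, j])
            rows.append(
                {
                    "offset": off,
                    "base": b,
                    "observed_freq": float(observed.frequencies[i, j]),
                    "null_freq": float(null.frequencies[i, j]),
                    "difference_pp": d,
                    "flagged": abs(d) > flag_threshold_pp,
                }
            )
    return pd.DataFrame(rows)
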