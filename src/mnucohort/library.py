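"""Library-level reports: in silico TILLING queries, M1->M2 transmission summaries,
seed-setting correlation, and cohort-size saturation extrapolation."""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .effects import _IMPACT_RANK, EffectAnnotation

__all__ = [
    "TillingIndex",
    "TransmissionSummary",
    "SaturationEstimate",
    "transmission_summary",
    "correlate_seed_setting",
    "saturation_estimate",
]


class TillingIndex:
    """Gene-keyed index of annotated mutations for in silico TILLING queries.

    A reverse-genetics user asks: which plants in the library carry a mutation of
    at least a given impact in my gene of interest?
    """

    def __init__(self, annotations: Iterable[EffectAnnotation]):
        self._by_gene: dict[str, list[EffectAnnotation]] = defaultdict(list)
        for a in annotations:
            if a.gene_id is not None:
                self._by_gene[a.gene_id].append(a)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self._by_gene)

    def query(self, gene_id: str, min_impact: str = "MODIFIER") -> list[EffectAnnotation]:
        """Entries for ``gene_id`` with impact at least ``min_impact``; empty list for
        unknown genes."""
        if min_impact not in _IMPACT_RANK:
            raise ValueError(f"unknown impact tier {min_impact!r}")
        floor = _IMPACT_RANK[min_impact]
        return [a for a in self._by_gene.get(gene_id, []) if _IMPACT_RANK[a.impact] >= floor]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g,
                "plant_id": a.plant_id,
                "chrom": a.chrom,
                "pos": a.pos,
                "ref": a.ref,
                "alt": a.alt,
                "category": a.category,
                "impact": a.impact,
            }
            for g in self.gene_ids
            for a in self._by_gene[g]
        ]
        return pd.DataFrame(rows)


@dataclass
class TransmissionSummary:
    n_tested_snv: int
    n_transmitted_snv: int
    pct_snv: float | None
    n_tested_indel: int
    n_transmitted_indel: int
    pct_indel: float | None


def _pct(transmitted: int, tested: int) -> float | None:
    return round(100.0 * transmitted / tested, 1) if tested else None


def transmission_summary(validation: pd.DataFrame) -> TransmissionSummary:
    """M1->M2 transmission rates among Sanger-confirmed true variants.

    ``validation`` needs ``variant_class`` (SNV/insertion/deletion), ``confirmed``
    and ``transmitted`` boolean-like columns; only confirmed (true-positive) calls
    enter the denominators.
    """
    from .curation import _as_bool

    confirmed = _as_bool(validation["confirmed"])
    transmitted = _as_bool(validation["transmitted"])
    is_snv = validation["variant_class"].astype(str).str.upper() == "SNV"
    snv_tested = int((confirmed & is_snv).sum())
    snv_trans = int((confirmed & is_snv & transmitted).sum())
    indel_tested = int((confirmed & ~is_snv).sum())
    indel_trans = int((confirmed & ~is_snv & transmitted).sum())
    return TransmissionSummary(
        n_tested_snv=snv_tested,
        n_transmitted_snv=snv_trans,
        pct_snv=_pct(snv_trans, snv_tested),
        n_tested_indel=indel_tested,
        n_transmitted_indel=indel_trans,
        pct_indel=_pct(indel_trans, indel_tested),
    )


def correlate_seed_setting(
    per_plant_counts: Mapping[str, int],
    phenotypes: Mapping[str, float],
) -> tuple[float | None, float | None, int]:
    """Pearson correlation between per-plant mutation counts and seed-setting %.

    Returns (r, two-sided p from the t transform with n-2 df, n). Plants missing
    from either table are dropped; a constant series yields (None, None, n).
    """
    shared = sorted(set(per_plant_counts) & set(phenotypes))
    if len(shared) < 3:
        raise ValueError("need at least 3 paired observations")
    x = np.array([per_plant_counts[p] for p in shared], dtype=float)
    y = np.array([phenotypes[p] for p in shared], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None, len(shared)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(shared)


@dataclass
class SaturationEstimate:
    model: str  # "linear" | "poisson"
    observed_coverage_fraction: float
    observed_n: int
    target_fraction: float
    estimated_n: float


def saturation_estimate(
    observed_fraction: float,
    observed_n: int,
    target_fraction: float,
    model: str = "linear",
) -> SaturationEstimate:
    """Cohort size needed to cover ``target_fraction`` of genes, extrapolated from
    an observed coverage fraction at ``observed_n`` plants.

    linear:   n = observed_n * target / observed (cannot saturate; overshoots are
              possible for targets near 1).
    poisson:  assumes independent per-gene hit rate lambda per plant, so coverage
              after n plants is 1 - exp(-lambda * n); requires target < 1.
    """
    if not 0 < observed_fraction <= 1:
        raise ValueError("observed_fraction must be in (0, 1]")
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    if observed_n <= 0:
        raise ValueError("observed_n must be positive")
    if model == "linear":
        n = observed_n * target_fraction / observed_fraction
    elif model == "poisson":
        if target_fraction >= 1 or observed_fraction >= 1:
            raise ValueError("poisson model requires fractions < 1")
        lam = -math.log(1 - observed_fraction) / observed_n
        n = -math.log(1 - target_fraction) / lam
    else:
        raise ValueError(f"unknown model {model!r}")
    return SaturationEstimate(
        model=model,
        observed_coverage_fraction=observed_fraction,
        observed_n=observed_n,
        target_fraction=target_fraction,
        estimated_n=n,
    )
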