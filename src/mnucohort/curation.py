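"""Joint-VCF curation: cohort-unique heterozygous filtering, QV thresholding,
masked-InDel removal, and calibration of the QV threshold against Sanger validation.

An M1 plant from a chemically mutagenized fertilized egg cell carries its induced
mutations in the heterozygous state, and independent plants essentially never share
a mutation site. A call that is non-reference in more than one plant, or homozygous,
is therefore treated as a shared artifact (pre-existing polymorphism against the
reference, or a systematic mis-call) rather than an induced mutation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io import IntervalSet, VariantRecord, Zygosity

log = logging.getLogger(__name__)

__all__ = [
    "CuratedVariant",
    "CalibrationRow",
    "filter_unique_heterozygous",
    "apply_qv_threshold",
    "remove_masked_indels",
    "calibrate_qv_threshold",
    "curate",
]

DEFAULT_QV_THRESHOLD = 80.0


@dataclass(frozen=True)
class CuratedVariant:
    """A plant-assigned unique heterozygous mutation that survived all filters."""

    plant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    qv: float
    variant_class: str  # "SNV" | "insertion" | "deletion"
    indel_length: int  # signed; 0 for SNVs

    @property
    def is_snv(self) -> bool:
        return self.variant_class == "SNV"


@dataclass(frozen=True)
class CalibrationRow:
    qv_threshold: float
    n_tested: int
    n_true: int
    true_positive_pct: float | None  # None when n_tested == 0


def _variant_class(rec: VariantRecord) -> tuple[str, int]:
    if rec.is_snv:
        return "SNV", 0
    length = rec.indel_length
    return ("insertion" if length > 0 else "deletion"), length


def filter_unique_heterozygous(
    records: Iterable[VariantRecord], plant_ids: Sequence[str]
) -> list[CuratedVariant]:
    """Keep records where exactly one plant is non-reference and that call is heterozygous.

    Missing genotypes in other plants do not disqualify a site: at the modest
    sequencing depth of a cohort survey, missingness is common and carries no
    evidence that the plant shares the allele.
    """
    if len(plant_ids) < 2:
        log.warning("uniqueness filter run with <2 plants; cohort-uniqueness is undefined")
    kept: list[CuratedVariant] = []
    for rec in records:
        carriers = [
            i
            for i, z in enumerate(rec.genotypes)
            if z in (Zygosity.HET, Zygosity.HOM_ALT)
        ]
        if len(carriers) != 1 or rec.genotypes[carriers[0]] is not Zygosity.HET:
            continue
        vclass, length = _variant_class(rec)
        kept.append(
            CuratedVariant(
                plant_id=plant_ids[carriers[0]],
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alt,
                qv=rec.qv,
                variant_class=vclass,
                indel_length=length,
            )
        )
    return kept


def apply_qv_threshold(
    variants: Iterable[CuratedVariant], threshold: float = DEFAULT_QV_THRESHOLD
) -> list[CuratedVariant]:
    """Keep variants with QV strictly greater than ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return [v for v in variants if v.qv > threshold]


def remove_masked_indels(
    variants: Iterable[CuratedVariant], mask: IntervalSet
) -> list[CuratedVariant]:
    """Drop InDels whose leftmost base lies in a repeat-masked interval.

    SNVs are untouched regardless of the mask: only InDel calls in repeats are
    considered unreliable.
    """
    return [
        v for v in variants if v.is_snv or not mask.contains(v.chrom, v.pos)
    ]


def calibrate_qv_threshold(
    validation: pd.DataFrame, thresholds: Sequence[float]
) -> list[CalibrationRow]:
    """True-positive percentage among Sanger-validated calls above each QV threshold.

    ``validation`` needs ``qv`` (numeric) and ``confirmed`` (boolean-like) columns.
    """
    qv = validation["qv"].astype(float).to_numpy()
    confirmed = _as_bool(validation["confirmed"]).to_numpy()
    rows = []
    for t in thresholds:
        above = qv > t
        n_tested = int(above.sum())
        n_true = int((above & confirmed).sum())
        pct = 100.0 * n_true / n_tested if n_tested else None
        rows.append(CalibrationRow(float(t), n_tested, n_true, pct))
    return rows


def _as_bool(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col
    return col.astype(str).str.strip().str.lower().isin({"true", "yes", "y", "1", "t"})


def curate(
    records: Iterable[VariantRecord],
    plant_ids: Sequence[str],
    mask: IntervalSet | None = None,
    qv_threshold: float = DEFAULT_QV_THRESHOLD,
) -> tuple[list[CuratedVariant], dict]:
    """Full curation pipeline: unique-het -> QV threshold -> masked-InDel removal.

    Returns the curated variants and a summary with SNV/insertion/deletion totals
    and per-plant SNV counts.
    """
    variants = filter_unique_heterozygous(records, plant_ids)
    variants = apply_qv_threshold(variants, qv_threshold)
    if mask is not None:
        variants = remove_masked_indels(variants, mask)
    per_plant = Counter(v.plant_id for v in variants if v.is_snv)
    summary = {
        "n_total": len(variants),
        "n_snv": sum(v.is_snv for v in variants),
        "n_insertion": sum(v.variant_class == "insertion" for v in variants),
        "n_deletion": sum(v.variant_class == "deletion" for v in variants),
        "per_plant_snv": {p: per_plant.get(p, 0) for p in plant_ids},
    }
    return variants, summary


def curated_to_frame(variants: Iterable[CuratedVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plant_id": v.plant_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "qv": v.qv,
                "variant_class": v.variant_class,
                "indel_length": v.indel_length,
            }
            for v in variants
        ],
        columns=[
            "plant_id",
            "chrom",
            "pos",
            "ref",
            "alt",
            "qv",
            "variant_class",
            "indel_length",
        ],
    )


def frame_to_curated(df: pd.DataFrame) -> list[CuratedVariant]:
    return [
        CuratedVariant(
            plant_id=str(r.plant_id),
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            qv=float(r.qv),
            variant_class=str(r.variant_class),
            indel_length=int(r.indel_length),
        )
        for r in df.itertuples()
    ]
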