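"""Readers/writers for the external formats the pipeline touches, plus shared genomic types.

All coordinates are 1-based and closed internally (the native VCF/GFF3 convention);
BED input is converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

__all__ = [
    "GenomeSequence",
    "Zygosity",
    "VariantRecord",
    "GeneModel",
    "IntervalSet",
    "read_fasta",
    "write_fasta",
    "read_joint_vcf",
    "write_vcf",
    "read_gff3_longest_isoforms",
    "read_mask_bed",
    "read_table",
    "write_tsv",
    "validate_refs",
]


class Zygosity(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


@dataclass
class GenomeSequence:
    """An in-memory reference genome: ordered chromosomes of uppercase A/C/G/T/N."""

    sequences: dict[str, str]

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def base(self, chrom: str, pos: int) -> str:
        """Base at a 1-based position; raises on out-of-range lookups."""
        seq = self.sequences[chrom]
        if not 1 <= pos <= len(seq):
            raise IndexError(f"position {chrom}:{pos} outside [1, {len(seq)}]")
        return seq[pos - 1]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence for the 1-based closed interval [start, end]."""
        seq = self.sequences[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise IndexError(f"interval {chrom}:{start}-{end} outside [1, {len(seq)}]")
        return seq[start - 1 : end]


@dataclass
class VariantRecord:
    """One biallelic VCF site with per-plant genotype calls and a site quality value."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qv: float
    genotypes: list[Zygosity]

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"non-positive position {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"REF equals ALT ({self.ref}) at {self.chrom}:{self.pos}")
        if self.qv < 0:
            raise ValueError(f"negative QV at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def indel_length(self) -> int:
        """Signed length change: positive for insertions, negative for deletions, 0 for SNVs."""
        return 0 if self.is_snv else len(self.alt) - len(self.ref)


@dataclass
class GeneModel:
    """A single representative (longest-CDS) transcript of a protein-coding gene.

    ``cds`` and ``exons`` are 1-based closed intervals ordered 5'->3' on the genome
    (i.e. by ascending coordinate regardless of strand).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    cds: list[tuple[int, int]]
    exons: list[tuple[int, int]]
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        for name, ivs in (("cds", self.cds), ("exons", self.exons)):
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping/unsorted {name} intervals in {self.gene_id}")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def is_complete(self) -> bool:
        """True when the concatenated CDS length is an exact number of codons."""
        return self.cds_length % 3 == 0


class IntervalSet:
    """Per-chromosome sets of 1-based closed intervals with point membership queries."""

    def __init__(self, intervals: dict[str, Iterable[tuple[int, int]]] | None = None):
        self._trees: dict[str, IntervalTree] = {}
        if intervals:
            for chrom, ivs in intervals.items():
                for s, e in ivs:
                    self.add(chrom, s, e)

    def add(self, chrom: str, start: int, end: int) -> None:
        if start > end:
            raise ValueError(f"inverted interval [{start}, {end}]")
        # IntervalTree is half-open; store [start, end] as [start, end + 1)
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)

    def contains(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree.overlaps_point(pos)) if tree is not None else False

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end - 1) for iv in tree)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._trees)

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence` (uppercased, order preserved)."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate chromosome name {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty record {rec.id!r} in {path}")
        sequences[rec.id] = seq
    return GenomeSequence(sequences)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF


def _zygosity_for_allele(gt: tuple[int | None, ...], allele_index: int) -> Zygosity:
    if any(a is None for a in gt) or len(gt) == 0:
        return Zygosity.MISSING
    n = sum(a == allele_index for a in gt)
    if n == 0:
        return Zygosity.HOM_REF
    if n == len(gt):
        return Zygosity.HOM_ALT
    return Zygosity.HET


def read_joint_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Read a multi-sample VCF, splitting multi-allelic sites into one record per ALT.

    Each split record keeps the site QUAL; genotypes are reinterpreted against the
    split allele (``./.`` becomes missing). Returns the records and the sample ids.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"no sample columns in {path}")
        for site in vcf:
            qv = float(site.qual) if site.qual is not None else 0.0
            gts = [site.samples[s].get("GT", (None,)) for s in samples]
            for k, alt in enumerate(site.alts or (), start=1):
                if alt is None or alt in {".", "*", "<NON_REF>"}:
                    continue
                records.append(
                    VariantRecord(
                        chrom=site.chrom,
                        pos=site.pos,
                        ref=site.ref,
                        alt=alt,
                        qv=qv,
                        genotypes=[_zygosity_for_allele(gt, k) for gt in gts],
                    )
                )
    return records, samples


_GT_FIELD = {
    Zygosity.HOM_REF: (0, 0),
    Zygosity.HET: (0, 1),
    Zygosity.HOM_ALT: (1, 1),
    Zygosity.MISSING: (None, None),
}


def write_vcf(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    path: str | Path,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write biallelic records as a multi-sample VCF v4.2 text file."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if contigs is None:
        contigs = {}
        for rec in records:
            end = rec.pos + len(rec.ref) - 1
            contigs[rec.chrom] = max(contigs.get(rec.chrom, 0), end)
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            site = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                stop=rec.pos + len(rec.ref) - 1,
                alleles=(rec.ref, rec.alt),
                qual=rec.qv,
            )
            for s, z in zip(samples, rec.genotypes):
                site.samples[s]["GT"] = _GT_FIELD[z]
            out.write(site)


# ---------------------------------------------------------------------------
# GFF3


def read_gff3_longest_isoforms(path: str | Path) -> list[GeneModel]:
    """Load gene models from GFF3, keeping one transcript per gene: the one with the
    greatest total CDS length (ties broken by lexicographically smallest transcript id).

    Genes without any CDS-bearing transcript are excluded with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best: tuple[int, str] | None = None  # (-cds_len, transcript_id) for min()
        candidates: dict[str, gffutils.Feature] = {}
        for tx in db.children(gene, featuretype=("mRNA", "transcript"), level=1):
            cds_len = sum(c.end - c.start + 1 for c in db.children(tx, featuretype="CDS"))
            if cds_len == 0:
                continue
            candidates[tx.id] = tx
            key = (-cds_len, tx.id)
            if best is None or key < best:
                best = key
        if best is None:
            log.warning("gene %s has no CDS-bearing transcript; excluded", gene.id)
            continue
        tx = candidates[best[1]]
        cds = sorted((c.start, c.end) for c in db.children(tx, featuretype="CDS"))
        exons = sorted((e.start, e.end) for e in db.children(tx, featuretype="exon"))
        if not exons:
            exons = list(cds)
        models.append(
            GeneModel(
                gene_id=gene.id,
                transcript_id=tx.id,
                chrom=gene.seqid,
                strand=gene.strand,
                cds=cds,
                exons=exons,
                span=(gene.start, gene.end),
            )
        )
    return models


# ---------------------------------------------------------------------------
# BED / TSV


def read_mask_bed(path: str | Path) -> IntervalSet:
    """Read a (≥3-column) BED file; half-open 0-based records become 1-based closed."""
    mask = IntervalSet()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"empty/inverted BED interval {chrom}:{start}-{end}")
            mask.add(chrom, start + 1, end)
    return mask


def read_table(path: str | Path, required: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a header-rowed TSV; raises if any required column is absent."""
    df = pd.read_csv(path, sep="\t")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Consistency guards


def validate_refs(records: Iterable[VariantRecord], genome: GenomeSequence) -> None:
    """Raise if any record's REF allele disagrees with the reference genome.

    Cheap insurance against off-by-one coordinate bugs between inputs.
    """
    for rec in records:
        expected = genome.fetch(rec.chrom, rec.pos, rec.pos + len(rec.ref) - 1)
        if expected != rec.ref:
            raise ValueError(
                f"REF mismatch at {rec.chrom}:{rec.pos}: VCF says {rec.ref!r}, "
                f"genome says {expected!r}"
            )
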