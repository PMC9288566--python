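"""From-scratch variant-effect classification against longest-isoform gene models.

Each SNV is classified per overlapping gene by a fixed decision tree: coding
(translate the reference and alternate codon, strand-aware), splice site (the two
canonical intronic bases at each exon junction), UTR, intron, upstream/downstream
(5 kb windows by default), or intergenic when no gene is near. Impact tiers follow
the usual convention: stop/start disruptions and splice sites are HIGH, missense
MODERATE, synonymous LOW, everything positional MODIFIER.

Short InDels are deliberately given positional annotation only (gene vs
intergenic); frameshift calling is out of scope.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .curation import CuratedVariant
from .io import GeneModel, GenomeSequence

__all__ = [
    "CATEGORIES",
    "IMPACT_OF",
    "EffectAnnotation",
    "GeneIndex",
    "annotate_variant",
    "annotate_variants",
    "summarize_gene_coverage",
    "coverage_pct",
    "category_distribution",
]

CATEGORIES = (
    "intergenic",
    "upstream",
    "downstream",
    "intron",
    "five_prime_utr",
    "three_prime_utr",
    "splice_acceptor",
    "splice_donor",
    "synonymous",
    "missense",
    "stop_gained",
    "stop_lost",
    "start_lost",
)

IMPACT_OF = {
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "splice_acceptor": "HIGH",
    "splice_donor": "HIGH",
    "missense": "MODERATE",
    "synonymous": "LOW",
}
for _c in CATEGORIES:
    IMPACT_OF.setdefault(_c, "MODIFIER")

_IMPACT_RANK = {"HIGH": 3, "MODERATE": 2, "LOW": 1, "MODIFIER": 0}

DEFAULT_FLANK_WINDOW = 5_000  # upstream/downstream reach in bp

# Standard genetic code over codons in TCAG x TCAG x TCAG order.
_B = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    _B[i] + _B[j] + _B[k]: _AA[16 * i + 4 * j + k]
    for i in range(4)
    for j in range(4)
    for k in range(4)
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _translate_codon(codon: str) -> str:
    return CODON_TABLE.get(codon, "X")  # X for N-containing or truncated codons


@dataclass(frozen=True)
class EffectAnnotation:
    chrom: str
    pos: int
    ref: str
    alt: str
    plant_id: str | None
    gene_id: str | None
    category: str
    impact: str
    ref_aa: str | None = None
    aa_pos: int | None = None  # 1-based residue number
    alt_aa: str | None = None
    incomplete_model: bool = False

    @property
    def variant_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def severity(self) -> tuple[int, int]:
        return (_IMPACT_RANK[self.impact], CATEGORIES.index(self.category))


class GeneIndex:
    """Interval index over gene spans extended by the flanking window."""

    def __init__(self, genes: Sequence[GeneModel], window: int = DEFAULT_FLANK_WINDOW):
        self.window = window
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for g in self.genes:
            s, e = g.span
            self._trees[g.chrom].addi(max(1, s - window), e + window + 1, g)

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(pos)]
        return sorted(hits, key=lambda g: g.gene_id)


def _cds_positions(gene: GeneModel) -> list[int]:
    """Genomic positions of the CDS in transcript (5'->3' of the mRNA) order."""
    pos = [p for s, e in gene.cds for p in range(s, e + 1)]
    return pos if gene.strand == "+" else pos[::-1]


def _classify_coding(
    gene: GeneModel, genome: GenomeSequence, pos: int, ref: str, alt: str
) -> tuple[str, str, int, str, bool]:
    """Category + amino-acid change for an SNV inside the CDS."""
    tx_pos = _cds_positions(gene)
    cds_index = tx_pos.index(pos)
    codon_idx, within = divmod(cds_index, 3)
    codon_genomic = tx_pos[codon_idx * 3 : codon_idx * 3 + 3]
    incomplete = not gene.is_complete
    ref_codon = "".join(genome.base(gene.chrom, p) for p in codon_genomic)
    ref_base_tx, alt_base_tx = ref, alt
    if gene.strand == "-":
        ref_codon = ref_codon.translate(_COMPLEMENT)
        ref_base_tx = ref.translate(_COMPLEMENT)
        alt_base_tx = alt.translate(_COMPLEMENT)
    if len(ref_codon) == 3 and ref_codon[within] != ref_base_tx:
        raise ValueError(
            f"REF {ref!r} at {gene.chrom}:{pos} disagrees with genome codon "
            f"{ref_codon!r} of {gene.transcript_id}"
        )
    alt_codon = ref_codon[:within] + alt_base_tx + ref_codon[within + 1 :]
    ref_aa = _translate_codon(ref_codon)
    alt_aa = _translate_codon(alt_codon)
    if codon_idx == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        category = "start_lost"
    elif ref_aa == "*" and alt_aa != "*":
        category = "stop_lost"
    elif alt_aa == "*" and ref_aa != "*":
        category = "stop_gained"
    elif ref_aa != alt_aa:
        category = "missense"
    else:
        category = "synonymous"
    return category, ref_aa, codon_idx + 1, alt_aa, incomplete


def _classify_splice(gene: GeneModel, pos: int) -> str | None:
    """splice_donor/splice_acceptor when ``pos`` is one of the 2 canonical intronic
    bases at an exon junction; None otherwise. Donor takes precedence in the
    (degenerate) case of an intron shorter than 4 bp."""
    for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
        i_start, i_end = e1 + 1, s2 - 1
        if not i_start <= pos <= i_end:
            continue
        in_left = pos <= min(e1 + 2, i_end)  # intron bases abutting the left exon
        in_right = pos >= max(s2 - 2, i_start)  # abutting the right exon
        if gene.strand == "+":
            if in_left:
                return "splice_donor"
            if in_right:
                return "splice_acceptor"
        else:
            if in_right:
                return "splice_donor"
            if in_left:
                return "splice_acceptor"
        return None
    return None


def _classify_in_gene(
    gene: GeneModel, genome: GenomeSequence, pos: int, ref: str, alt: str
) -> tuple[str, str | None, int | None, str | None, bool]:
    for s, e in gene.cds:
        if s <= pos <= e:
            return _classify_coding(gene, genome, pos, ref, alt)
    splice = _classify_splice(gene, pos)
    if splice:
        return splice, None, None, None, False
    in_exon = any(s <= pos <= e for s, e in gene.exons)
    if in_exon and gene.cds:
        cds_start, cds_end = gene.cds[0][0], gene.cds[-1][1]
        before = pos < cds_start
        five = before if gene.strand == "+" else not before
        return ("five_prime_utr" if five else "three_prime_utr"), None, None, None, False
    return "intron", None, None, None, False


def annotate_variant(
    variant: CuratedVariant,
    index: GeneIndex,
    genome: GenomeSequence,
) -> list[EffectAnnotation]:
    """Annotate one SNV against every nearby gene; a single intergenic record when
    no gene span or flanking window covers it."""
    if not variant.is_snv:
        raise ValueError("annotate_variant classifies SNVs only; see indel_gene_overlap")
    chrom, pos, ref, alt = variant.chrom, variant.pos, variant.ref, variant.alt
    if genome.base(chrom, pos) != ref:
        raise ValueError(f"REF mismatch at {chrom}:{pos}: {ref!r} vs genome")
    out: list[EffectAnnotation] = []
    for gene in index.overlapping(chrom, pos):
        s, e = gene.span
        if s <= pos <= e:
            category, ref_aa, aa_pos, alt_aa, incomplete = _classify_in_gene(
                gene, genome, pos, ref, alt
            )
        else:
            before = pos < s
            upstream = before if gene.strand == "+" else not before
            category = "upstream" if upstream else "downstream"
            ref_aa = alt_aa = None
            aa_pos = None
            incomplete = False
        out.append(
            EffectAnnotation(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                plant_id=variant.plant_id,
                gene_id=gene.gene_id,
                category=category,
                impact=IMPACT_OF[category],
                ref_aa=ref_aa,
                aa_pos=aa_pos,
                alt_aa=alt_aa,
                incomplete_model=incomplete,
            )
        )
    if not out:
        out.append(
            EffectAnnotation(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                plant_id=variant.plant_id,
                gene_id=None,
                category="intergenic",
                impact="MODIFIER",
            )
        )
    return out


def annotate_variants(
    variants: Iterable[CuratedVariant],
    genes: Sequence[GeneModel],
    genome: GenomeSequence,
    window: int = DEFAULT_FLANK_WINDOW,
) -> list[EffectAnnotation]:
    """Annotate all SNVs in ``variants`` (InDels are skipped)."""
    index = GeneIndex(genes, window)
    out: list[EffectAnnotation] = []
    for v in variants:
        if v.is_snv:
            out.extend(annotate_variant(v, index, genome))
    return out


def indel_gene_overlap(
    indels: Iterable[CuratedVariant], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Positional annotation of InDels: the overlapping gene id or intergenic."""
    index = GeneIndex(genes, window=0)
    rows = []
    for v in indels:
        hits = [g for g in index.overlapping(v.chrom, v.pos) if g.span[0] <= v.pos <= g.span[1]]
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "plant_id": v.plant_id,
                "gene_id": hits[0].gene_id if hits else None,
                "category": "gene" if hits else "intergenic",
            }
        )
    return pd.DataFrame(rows)


def coverage_pct(n_genes_hit: int, n_annotated_genes: int) -> float:
    """Percentage of annotated genes carrying at least one SNV of some class."""
    if n_annotated_genes <= 0:
        raise ValueError("n_annotated_genes must be positive")
    if n_genes_hit > n_annotated_genes:
        raise ValueError("more genes hit than annotated")
    return 100.0 * n_genes_hit / n_annotated_genes


def summarize_gene_coverage(
    annotations: Iterable[EffectAnnotation], n_annotated_genes: int
) -> pd.DataFrame:
    """Per-category SNV counts, genes with >=1 hit, and percentage of annotated genes."""
    n_snvs: defaultdict[str, int] = defaultdict(int)
    genes: defaultdict[str, set] = defaultdict(set)
    for a in annotations:
        n_snvs[a.category] += 1
        if a.gene_id is not None:
            genes[a.category].add(a.gene_id)
    rows = []
    for cat in CATEGORIES:
        if n_snvs[cat] == 0 and not genes[cat]:
            continue
        rows.append(
            {
                "category": cat,
                "n_snvs": n_snvs[cat],
                "n_genes": len(genes[cat]),
                "pct_of_annotated_genes": round(
                    coverage_pct(len(genes[cat]), n_annotated_genes), 1
                ),
            }
        )
    return pd.DataFrame(rows, columns=["category", "n_snvs", "n_genes", "pct_of_annotated_genes"])


def most_severe_per_variant(
    annotations: Iterable[EffectAnnotation],
) -> list[EffectAnnotation]:
    best: dict[tuple, EffectAnnotation] = {}
    for a in annotations:
        k = a.variant_key
        if k not in best or a.severity() > best[k].severity():
            best[k] = a
    return list(best.values())


def category_distribution(annotations: Iterable[EffectAnnotation]) -> pd.DataFrame:
    """Percentage of SNVs per category, counting each variant once at its most
    severe annotation."""
    reduced = most_severe_per_variant(annotations)
    total = len(reduced)
    counts = defaultdict(int)
    for a in reduced:
        counts[a.category] += 1
    rows = [
        {"category": c, "n_snvs": counts[c], "pct": 100.0 * counts[c] / total}
        for c in CATEGORIES
        if counts[c]
    ]
    return pd.DataFrame(rows, columns=["category", "n_snvs", "pct"])
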