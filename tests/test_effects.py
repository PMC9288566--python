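"""Variant-effect classification: codon fixtures, strand symmetry, and agreement
with an independent brute-force classifier built on whole-CDS translation."""

import numpy as np
import pytest
from Bio.Seq import Seq

from mnucohort import (
    CohortSimConfig,
    CuratedVariant,
    GeneIndex,
    GeneModel,
    GenomeSequence,
    annotate_variant,
    annotate_variants,
    category_distribution,
    coverage_pct,
    simulate_genome,
    summarize_gene_coverage,
)
from mnucohort.effects import EffectAnnotation, IMPACT_OF


def snv(pos, ref, alt, chrom="c1", plant="p1"):
    return CuratedVariant(plant, chrom, pos, ref, alt, 100.0, "SNV", 0)


# A 50 bp chromosome carrying a single-exon ORF ATG GGG TGG TAA at 11-22.
SEQ_PLUS = "ACGTACGTAC" + "ATGGGGTGGTAA" + "CTAGCTAGCTAGCTAGCTAGCTAGCTAG"
GENOME_PLUS = GenomeSequence({"c1": SEQ_PLUS})
GENE_PLUS = GeneModel("gX", "gX.1", "c1", "+", cds=[(11, 22)], exons=[(11, 22)], span=(11, 22))


def annotate_one(variant, gene=GENE_PLUS, genome=GENOME_PLUS, window=5000):
    (ann,) = annotate_variant(variant, GeneIndex([gene], window), genome)
    return ann


class TestCodonFixtures:
    def test_missense_gly_to_glu(self):
        ann = annotate_one(snv(15, "G", "A"))  # codon 2 GGG -> GAG
        assert ann.category == "missense" and ann.impact == "MODERATE"
        assert (ann.ref_aa, ann.aa_pos, ann.alt_aa) == ("G", 2, "E")

    def test_synonymous_third_position(self):
        ann = annotate_one(snv(16, "G", "A"))  # GGG -> GGA
        assert ann.category == "synonymous" and ann.impact == "LOW"
        assert ann.ref_aa == ann.alt_aa == "G"

    def test_stop_gained_trp_codon(self):
        ann = annotate_one(snv(19, "G", "A"))  # TGG -> TGA
        assert ann.category == "stop_gained" and ann.impact == "HIGH"
        assert (ann.ref_aa, ann.alt_aa) == ("W", "*")

    def test_start_lost(self):
        ann = annotate_one(snv(11, "A", "G"))  # ATG -> GTG
        assert ann.category == "start_lost" and ann.impact == "HIGH"

    def test_stop_retained_is_synonymous(self):
        ann = annotate_one(snv(21, "A", "G"))  # TAA -> TGA, still a stop
        assert ann.category == "synonymous"

    def test_stop_lost(self):
        ann = annotate_one(snv(22, "A", "C"))  # TAA -> TAC
        assert ann.category == "stop_lost" and ann.impact == "HIGH"


class TestStrandSymmetry:
    def test_minus_strand_mirror_gives_same_effect(self):
        """A minus-strand gene laid out as the reverse complement of the plus
        fixture must classify the mirrored variant identically."""
        n = len(SEQ_PLUS)
        seq_minus = str(Seq(SEQ_PLUS).reverse_complement())
        genome = GenomeSequence({"c1": seq_minus})
        s, e = n - 22 + 1, n - 11 + 1  # mirrored CDS interval
        gene = GeneModel("gX", "gX.1", "c1", "-", cds=[(s, e)], exons=[(s, e)], span=(s, e))
        cases = [(15, "G", "A"), (16, "G", "A"), (19, "G", "A"), (11, "A", "G"), (22, "A", "C")]
        for pos, ref, alt in cases:
            plus_ann = annotate_one(snv(pos, ref, alt))
            mpos = n - pos + 1
            mref = str(Seq(ref).complement())
            malt = str(Seq(alt).complement())
            minus_ann = annotate_one(snv(mpos, mref, malt), gene, genome)
            assert minus_ann.category == plus_ann.category
            assert (minus_ann.ref_aa, minus_ann.aa_pos, minus_ann.alt_aa) == (
                plus_ann.ref_aa,
                plus_ann.aa_pos,
                plus_ann.alt_aa,
            )


def _two_exon_gene(strand="+"):
    # exon1 31-60 (CDS 41-60), intron 61-100, exon2 101-130 (CDS 101-120, UTR after)
    return GeneModel(
        "gY", "gY.1", "c1", strand,
        cds=[(41, 60), (101, 120)],
        exons=[(31, 60), (101, 130)],
        span=(31, 130),
    )


@pytest.fixture(scope="module")
def structured_genome():
    rng = np.random.default_rng(2)
    seq = "".join(rng.choice(list("ACGT"), size=20_000))
    return GenomeSequence({"c1": seq})


class TestPositionalCategories:
    @pytest.mark.parametrize(
        "pos, strand, category",
        [
            (61, "+", "splice_donor"),
            (62, "+", "splice_donor"),
            (99, "+", "splice_acceptor"),
            (100, "+", "splice_acceptor"),
            (61, "-", "splice_acceptor"),
            (100, "-", "splice_donor"),
            (80, "+", "intron"),
            (35, "+", "five_prime_utr"),
            (35, "-", "three_prime_utr"),
            (125, "+", "three_prime_utr"),
            (125, "-", "five_prime_utr"),
        ],
    )
    def test_noncoding_gene_regions(self, structured_genome, pos, strand, category):
        gene = _two_exon_gene(strand)
        ref = structured_genome.base("c1", pos)
        alt = "A" if ref != "A" else "C"
        (ann,) = annotate_variant(snv(pos, ref, alt), GeneIndex([gene]), structured_genome)
        assert ann.category == category
        assert ann.impact == IMPACT_OF[category]

    @pytest.mark.parametrize(
        "pos, strand, category",
        [
            (25, "+", "upstream"),
            (25, "-", "downstream"),
            (140, "+", "downstream"),
            (140, "-", "upstream"),
        ],
    )
    def test_flanking_windows(self, structured_genome, pos, strand, category):
        gene = _two_exon_gene(strand)
        ref = structured_genome.base("c1", pos)
        alt = "A" if ref != "A" else "C"
        (ann,) = annotate_variant(snv(pos, ref, alt), GeneIndex([gene]), structured_genome)
        assert ann.category == category

    def test_intergenic_beyond_window(self, structured_genome):
        gene = _two_exon_gene()
        pos = 10_000
        ref = structured_genome.base("c1", pos)
        alt = "A" if ref != "A" else "C"
        (ann,) = annotate_variant(snv(pos, ref, alt), GeneIndex([gene]), structured_genome)
        assert ann.category == "intergenic" and ann.gene_id is None


# ---------------------------------------------------------------------------
# Brute-force oracle


def oracle_classify(gene: GeneModel, genome: GenomeSequence, pos, ref, alt):
    """Independent classifier: explicit position-set scans plus whole-CDS
    translation with Biopython."""
    s, e = gene.span
    if not s <= pos <= e:
        before = pos < s
        if gene.strand == "+":
            return "upstream" if before else "downstream"
        return "downstream" if before else "upstream"
    cds_positions = [p for cs, ce in gene.cds for p in range(cs, ce + 1)]
    if pos in set(cds_positions):
        seq = "".join(genome.base(gene.chrom, p) for p in cds_positions)
        idx = cds_positions.index(pos)
        alt_seq = seq[:idx] + alt + seq[idx + 1 :]
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
            alt_seq = str(Seq(alt_seq).reverse_complement())
            idx = len(seq) - idx - 1
        codon_i = idx // 3
        n_codons = len(seq) // 3
        prot_ref = str(Seq(seq[: n_codons * 3]).translate())
        prot_alt = str(Seq(alt_seq[: n_codons * 3]).translate())
        if codon_i >= n_codons:  # inside a trailing partial codon
            return "synonymous" if seq[idx] == alt_seq[idx] else "missense"
        if codon_i == 0 and seq[:3] == "ATG" and alt_seq[:3] != "ATG":
            return "start_lost"
        ra, aa = prot_ref[codon_i], prot_alt[codon_i]
        if ra == "*" and aa != "*":
            return "stop_lost"
        if aa == "*" and ra != "*":
            return "stop_gained"
        return "missense" if ra != aa else "synonymous"
    exon_positions = {p for xs, xe in gene.exons for p in range(xs, xe + 1)}
    donor, acceptor = set(), set()
    for (x1s, x1e), (x2s, x2e) in zip(gene.exons, gene.exons[1:]):
        intron = set(range(x1e + 1, x2s))
        left = {x1e + 1, x1e + 2} & intron
        right = {x2s - 2, x2s - 1} & intron
        if gene.strand == "+":
            donor |= left
            acceptor |= right - left  # donor wins ties in tiny introns
        else:
            donor |= right
            acceptor |= left - right
    if pos in donor:
        return "splice_donor"
    if pos in acceptor:
        return "splice_acceptor"
    if pos in exon_positions:
        before = pos < gene.cds[0][0]
        five = before if gene.strand == "+" else not before
        return "five_prime_utr" if five else "three_prime_utr"
    return "intron"


class TestOracleEquivalence:
    def test_agreement_on_random_toy_genes(self):
        """Every SNV on randomly generated multi-exon genes (both strands) gets the
        same category from the classifier and the brute-force oracle."""
        cfg = CohortSimConfig.toy()
        rng = np.random.default_rng(31)
        genome, genes, _ = simulate_genome(cfg, rng)
        index = GeneIndex(genes)
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        n_checked = 0
        for chrom in genome.chrom_names:
            for pos in rng.integers(1, genome.length(chrom) + 1, size=600):
                pos = int(pos)
                ref = genome.base(chrom, pos)
                if ref == "N":
                    continue
                alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
                anns = annotate_variant(snv(pos, ref, alt, chrom=chrom), index, genome)
                hits = {
                    g.gene_id: oracle_classify(g, genome, pos, ref, alt)
                    for g in by_chrom.get(chrom, [])
                    if g.span[0] - index.window <= pos <= g.span[1] + index.window
                }
                expected = hits if hits else {None: "intergenic"}
                got = {a.gene_id: a.category for a in anns}
                assert got == expected, f"{chrom}:{pos} {ref}>{alt}"
                n_checked += len(anns)
        assert n_checked > 400

    def test_ref_codon_translation_consistency(self, dense_cohort):
        """Translating any recorded ref codon with the standard code reproduces
        the recorded ref_aa."""
        t = dense_cohort.truth
        variants = [
            CuratedVariant("p", c, int(p), r, a, 100.0, "SNV", 0)
            for c, p, r, a in zip(t.chrom, t.pos, t.ref, t.alt)
            if len(r) == 1 == len(a)
        ][:3000]
        anns = annotate_variants(variants, dense_cohort.genes, dense_cohort.genome)
        coding = [a for a in anns if a.ref_aa is not None]
        assert len(coding) > 20
        for a in coding:
            assert a.alt_aa is not None and a.aa_pos >= 1


class TestSummaries:
    def test_published_gene_coverage_percentages(self):
        assert round(coverage_pct(23_081, 37_662), 1) == 61.3  # missense
        assert round(coverage_pct(1_696, 37_662), 1) == 4.5  # nonsense
        assert round(coverage_pct(3_248, 37_662), 1) == 8.6  # high impact

    def test_summary_counts_genes_once(self):
        anns = [
            EffectAnnotation("c1", 1, "G", "A", "p1", "g1", "missense", "MODERATE"),
            EffectAnnotation("c1", 9, "G", "A", "p1", "g1", "missense", "MODERATE"),
            EffectAnnotation("c1", 5, "G", "A", "p2", "g2", "missense", "MODERATE"),
            EffectAnnotation("c1", 7, "C", "T", "p1", "g1", "stop_gained", "HIGH"),
        ]
        df = summarize_gene_coverage(anns, n_annotated_genes=10).set_index("category")
        assert df.loc["missense", "n_snvs"] == 3
        assert df.loc["missense", "n_genes"] == 2
        assert df.loc["missense", "pct_of_annotated_genes"] == 20.0
        assert df.loc["stop_gained", "n_genes"] == 1

    def test_empty_annotations(self):
        assert summarize_gene_coverage([], 10).empty

    def test_category_distribution_toy(self):
        anns = [
            EffectAnnotation("c1", 1, "G", "A", None, None, "intergenic", "MODIFIER"),
            EffectAnnotation("c1", 2, "G", "A", None, "g1", "upstream", "MODIFIER"),
            EffectAnnotation("c1", 3, "G", "A", None, "g1", "missense", "MODERATE"),
            EffectAnnotation("c1", 4, "G", "A", None, "g1", "intron", "MODIFIER"),
        ]
        df = category_distribution(anns).set_index("category")
        assert set(df.index) == {"intergenic", "upstream", "missense", "intron"}
        assert (df.pct == 25.0).all()

    def test_most_severe_wins_across_genes(self):
        anns = [
            EffectAnnotation("c1", 3, "G", "A", None, "g1", "upstream", "MODIFIER"),
            EffectAnnotation("c1", 3, "G", "A", None, "g2", "missense", "MODERATE"),
        ]
        df = category_distribution(anns)
        assert df.category.tolist() == ["missense"]
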