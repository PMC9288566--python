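"""Synthetic MNU-mutagenized M1 cohort generator.

Emulates, at the data level, a cohort of rice M1 plants grown from mutagenized
fertilized egg cells and joint-genotyped against their reference: an i.i.d.
random genome with toy multi-exon gene models and a repeat mask, per-plant
heterozygous mutations drawn from the observed 12-class substitution spectrum,
a -1/+1 sequence-context bias around mutated guanines, short InDels, false-
positive calls with depressed quality values, seed-setting phenotypes negatively
correlated with mutational load, and incomplete M1->M2 transmission. The output
is a joint VCF plus truth/phenotype/validation tables, so every downstream
analysis stage can be exercised against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import (
    GeneModel,
    GenomeSequence,
    IntervalSet,
    VariantRecord,
    Zygosity,
    write_fasta,
    write_tsv,
    write_vcf,
)

__all__ = [
    "TABLE1_CLASS_COUNTS",
    "CohortSimConfig",
    "CapacityError",
    "SimulatedCohort",
    "simulate_genome",
    "simulate_cohort",
    "phenotype_model",
]

#: Substitution-class site counts of the 266-plant rice MNU library (656,669 SNVs;
#: Ts/Tv = 615,144/41,525 = 14.81). Used both as printed-table input for spectrum
#: checks and, normalized, as the simulator's default class probabilities.
TABLE1_CLASS_COUNTS = {
    "AC": 1_060,
    "AG": 8_000,
    "AT": 11_768,
    "CA": 7_288,
    "CG": 623,
    "CT": 301_984,
    "GA": 297_005,
    "GC": 708,
    "GT": 7_336,
    "TA": 11_776,
    "TC": 8_155,
    "TG": 966,
}

_BASES = ("A", "C", "G", "T")


def _default_class_probs() -> dict[str, float]:
    total = sum(TABLE1_CLASS_COUNTS.values())
    return {k: v / total for k, v in TABLE1_CLASS_COUNTS.items()}


class CapacityError(ValueError):
    """Genome too small to place the requested mutations."""


@dataclass
class CohortSimConfig:
    """Parameters of the synthetic cohort; defaults reproduce the study conditions
    (cohort size, spectrum, per-plant load, context bias, InDel makeup, phenotype
    coupling) on a 3 Mb, 12-chromosome toy genome."""

    n_plants: int = 266
    # genome
    n_chroms: int = 12
    chrom_length: int = 250_000
    base_composition: tuple[float, float, float, float] = (0.282, 0.218, 0.218, 0.282)
    gene_fraction: float = 0.25
    mask_fraction: float = 0.10
    force_start_stop: bool = True
    # per-plant SNV load: lognormal matched to mean 2468.7 and observed range 134-13,222
    snv_count_log_mean: float = 7.458
    snv_count_log_sd: float = 0.84
    fixed_snvs_per_plant: int | None = None  # overrides the lognormal when set
    # substitution spectrum
    class_probs: dict[str, float] = field(default_factory=_default_class_probs)
    # -1/+1 context bias around mutated G sites, in added probability mass
    context_delta_minus1: dict[str, float] = field(
        default_factory=lambda: {"A": 0.158, "G": 0.187}
    )
    context_delta_plus1: dict[str, float] = field(default_factory=lambda: {"T": 0.064})
    # InDels: 3,118 of 659,787 variants; 2,486 deletions vs 632 insertions; ~80% < 3 bp
    indel_fraction: float = 3_118 / 659_787
    deletion_fraction: float = 2_486 / 3_118
    indel_size_probs: dict[int, float] = field(
        default_factory=lambda: {
            1: 0.552, 2: 0.25, 3: 0.07, 4: 0.045, 5: 0.03,
            6: 0.02, 7: 0.013, 8: 0.009, 9: 0.006, 10: 0.005,
        }
    )
    # call noise
    fp_rate: float = 0.10  # fraction of emitted calls that are false positives
    fp_indel_fraction: float = 0.02  # of false positives, fraction that are InDels
    fp_qv_range: tuple[float, float] = (30.0, 100.0)
    tp_qv_range: tuple[float, float] = (60.0, 500.0)
    # phenotype: seed-setting % = clamp(a + b * n_snv + N(0, sd), 0, 100)
    seed_setting_intercept: float = 49.5
    seed_setting_slope: float = -0.006
    seed_setting_noise_sd: float = 21.8  # Monte-Carlo calibrated for r ~ -0.43 at n=266 after clamping
    target_pearson_r: float = -0.43
    # transmission / validation
    transmission_loss: float = 0.152
    n_validation_snv: int = 101
    n_validation_indel: int = 16

    def validate(self) -> None:
        if self.n_plants < 1:
            raise ValueError("n_plants must be >= 1")
        if self.chrom_length < 10_000:
            raise ValueError("chromosomes must be at least 10 kb")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")
        if abs(sum(self.class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        if abs(sum(self.indel_size_probs.values()) - 1.0) > 1e-9:
            raise ValueError("indel size probabilities must sum to 1")
        for name in ("gene_fraction", "mask_fraction", "indel_fraction",
                     "deletion_fraction", "fp_rate", "fp_indel_fraction",
                     "transmission_loss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def toy(cls, n_plants: int = 5, mean_snvs: int = 400, **overrides) -> "CohortSimConfig":
        """A deliberately small cohort (2 x 500 kb chromosomes) for fixtures and
        examples; everything else keeps the study-condition defaults."""
        cfg = cls(
            n_plants=n_plants,
            n_chroms=2,
            chrom_length=500_000,
            snv_count_log_mean=math.log(mean_snvs) - 0.5 * 0.35**2,
            snv_count_log_sd=0.35,
            **overrides,
        )
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["base_composition"] = list(self.base_composition)
        data["fp_qv_range"] = list(self.fp_qv_range)
        data["tp_qv_range"] = list(self.tp_qv_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("base_composition", "fp_qv_range", "tp_qv_range"):
            if key in data:
                data[key] = tuple(data[key])
        if "indel_size_probs" in data:
            data["indel_size_probs"] = {int(k): v for k, v in data["indel_size_probs"].items()}
        cfg = cls(**data)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# Genome + gene models + mask


def _random_sequence(length: int, composition: Sequence[float], rng: np.random.Generator) -> str:
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=list(composition))
    return arr.tobytes().decode("ascii")


def _make_gene(
    chrom: str,
    start: int,
    strand: str,
    rng: np.random.Generator,
    idx: int,
) -> GeneModel:
    """One toy multi-exon gene laid out left-to-right; the strand decides which end
    is the 5' UTR at annotation time, so layout is strand-agnostic."""
    n_exons = int(rng.integers(2, 6))
    utr_left = int(rng.integers(100, 300))
    utr_right = int(rng.integers(100, 400))
    cds_chunks = [int(rng.integers(120, 500)) for _ in range(n_exons)]
    excess = sum(cds_chunks) % 3
    cds_chunks[-1] -= excess  # keep a whole number of codons
    introns = [int(rng.integers(80, 400)) for _ in range(n_exons - 1)]
    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    cursor = start
    for i, chunk in enumerate(cds_chunks):
        exon_start = cursor
        if i == 0:
            cds_start = exon_start + utr_left
        else:
            cds_start = exon_start
        cds_end = cds_start + chunk - 1
        exon_end = cds_end + (utr_right if i == n_exons - 1 else 0)
        exons.append((exon_start, exon_end))
        cds.append((cds_start, cds_end))
        cursor = exon_end + 1
        if i < n_exons - 1:
            cursor += introns[i]
    gid = f"gene{idx:05d}"
    return GeneModel(
        gene_id=gid,
        transcript_id=f"{gid}.1",
        chrom=chrom,
        strand=strand,
        cds=cds,
        exons=exons,
        span=(exons[0][0], exons[-1][1]),
    )


def _force_orf(genome_arrays: dict[str, bytearray], gene: GeneModel, rng: np.random.Generator) -> None:
    """Write ATG at the first codon and a stop at the last (strand-aware)."""
    pos = [p for s, e in gene.cds for p in range(s, e + 1)]
    if gene.strand == "-":
        pos = pos[::-1]
    comp = {65: 84, 67: 71, 71: 67, 84: 65}  # A<->T, C<->G on byte values
    stop = ["TAA", "TAG", "TGA"][int(rng.integers(0, 3))]
    for codon, where in (("ATG", pos[:3]), (stop, pos[-3:])):
        for base, p in zip(codon, where):
            b = ord(base)
            if gene.strand == "-":
                b = comp[b]
            genome_arrays[gene.chrom][p - 1] = b


def simulate_genome(
    config: CohortSimConfig, rng: np.random.Generator | int
) -> tuple[GenomeSequence, list[GeneModel], IntervalSet]:
    """Generate the reference: i.i.d. chromosomes at the configured composition,
    non-overlapping toy genes on both strands, and a repeat mask covering roughly
    ``mask_fraction`` of each chromosome."""
    config.validate()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    chrom_names = [f"chr{i + 1:02d}" for i in range(config.n_chroms)]
    arrays = {
        c: bytearray(_random_sequence(config.chrom_length, config.base_composition, rng), "ascii")
        for c in chrom_names
    }
    genes: list[GeneModel] = []
    idx = 1
    for chrom in chrom_names:
        if config.gene_fraction <= 0:
            break
        cursor = int(rng.integers(500, 3000))
        while True:
            strand = "+" if rng.random() < 0.5 else "-"
            gene = _make_gene(chrom, cursor, strand, rng, idx)
            if gene.span[1] + 10 > config.chrom_length:
                break
            genes.append(gene)
            idx += 1
            glen = gene.span[1] - gene.span[0] + 1
            gap = glen * (1.0 - config.gene_fraction) / config.gene_fraction
            cursor = gene.span[1] + 1 + int(gap * rng.uniform(0.5, 1.5))
    mask = IntervalSet()
    if config.mask_fraction > 0:
        for chrom in chrom_names:
            covered = 0
            target = config.mask_fraction * config.chrom_length
            while covered < target:
                length = int(rng.integers(2_000, 10_000))
                start = int(rng.integers(1, config.chrom_length - length))
                mask.add(chrom, start, start + length - 1)
                covered += length
    genome = GenomeSequence({c: a.decode("ascii") for c, a in arrays.items()})
    if config.force_start_stop:
        for gene in genes:
            _force_orf(arrays, gene, rng)
        genome = GenomeSequence({c: a.decode("ascii") for c, a in arrays.items()})
    return genome, genes, mask


# ---------------------------------------------------------------------------
# Cohort


@dataclass
class SimulatedCohort:
    """Joint-call records plus ground truth for a simulated M1 cohort.

    ``genome`` is the emitted reference (it differs from the pre-cohort genome at
    the rewritten -1/+1 neighbors of mutated G sites)."""

    config: CohortSimConfig
    genome: GenomeSequence
    genes: list[GeneModel]
    mask: IntervalSet
    plant_ids: list[str]
    records: list[VariantRecord]
    truth: pd.DataFrame
    phenotypes: pd.DataFrame
    validation: pd.DataFrame

    @property
    def true_snv_counts(self) -> dict[str, int]:
        t = self.truth
        sub = t[t.is_true & (t.variant_class == "SNV")]
        counts = sub.groupby("plant_id").size().to_dict()
        return {p: int(counts.get(p, 0)) for p in self.plant_ids}

    def write_outputs(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        _write_gff3(self.genes, outdir / "genes.gff3")
        _write_bed(self.mask, outdir / "mask.bed")
        contigs = {c: self.genome.length(c) for c in self.genome.chrom_names}
        write_vcf(self.records, self.plant_ids, outdir / "cohort.vcf", contigs)
        write_tsv(self.truth, outdir / "truth.tsv")
        write_tsv(self.phenotypes, outdir / "phenotype.tsv")
        write_tsv(self.validation, outdir / "validation.tsv")


def _write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write(
                f"{g.chrom}\tsim\tgene\t{s}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tsim\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.transcript_id};Parent={g.gene_id}\n"
            )
            for xs, xe in g.exons:
                fh.write(
                    f"{g.chrom}\tsim\texon\t{xs}\t{xe}\t.\t{g.strand}\t.\t"
                    f"Parent={g.transcript_id}\n"
                )
            for cs, ce in g.cds:
                fh.write(
                    f"{g.chrom}\tsim\tCDS\t{cs}\t{ce}\t.\t{g.strand}\t0\t"
                    f"Parent={g.transcript_id}\n"
                )


def _write_bed(mask: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in mask.chroms:
            for s, e in mask.intervals(chrom):
                fh.write(f"{chrom}\t{s - 1}\t{e}\n")


def phenotype_model(
    snv_counts: np.ndarray | Sequence[int],
    config: CohortSimConfig,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Seed-setting percentages from mutational load: a linear decline plus
    Gaussian noise, clamped to [0, 100]."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    counts = np.asarray(snv_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("SNV counts must be non-negative")
    raw = (
        config.seed_setting_intercept
        + config.seed_setting_slope * counts
        + rng.normal(0.0, config.seed_setting_noise_sd, size=counts.shape)
    )
    return np.clip(raw, 0.0, 100.0)


def _biased_distribution(
    composition: Sequence[float], deltas: dict[str, float]
) -> np.ndarray:
    """Add probability mass to the favored bases; shrink the others proportionally."""
    p = np.asarray(composition, dtype=float).copy()
    added = sum(deltas.values())
    favored = [_BASES.index(b) for b in deltas]
    others = [i for i in range(4) if i not in favored]
    p[others] *= (p[others].sum() - added) / p[others].sum()
    for b, d in deltas.items():
        p[_BASES.index(b)] += d
    if (p < 0).any():
        raise ValueError("context deltas exceed available probability mass")
    return p / p.sum()


def simulate_cohort(
    config: CohortSimConfig,
    genome: GenomeSequence,
    genes: Sequence[GeneModel],
    mask: IntervalSet,
    rng: np.random.Generator | int,
) -> SimulatedCohort:
    """Draw the cohort's mutations, call noise, phenotypes and validation subsample.

    Every true mutation is heterozygous in exactly one plant and placed at a
    genome position whose base matches its REF class; mutated-G sites have their
    -1/+1 neighbors resampled under the configured context bias (reflected in the
    emitted reference). True InDels avoid the repeat mask, so nothing recoverable
    is discarded by the masked-InDel filter.
    """
    config.validate()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    plant_ids = [f"P{i + 1:04d}" for i in range(config.n_plants)]
    chrom_names = genome.chrom_names
    lengths = np.array([genome.length(c) for c in chrom_names], dtype=np.int64)
    bounds = np.cumsum(lengths)
    total_len = int(bounds[-1])
    arrays = {c: bytearray(genome.sequences[c], "ascii") for c in chrom_names}
    flat = np.frombuffer(b"".join(arrays.values()), dtype=np.uint8).copy()

    def to_local(gidx: int) -> tuple[str, int]:
        c = int(np.searchsorted(bounds, gidx, "right"))
        return chrom_names[c], int(gidx - (bounds[c - 1] if c else 0) + 1)

    # --- per-plant true SNV loads
    if config.fixed_snvs_per_plant is not None:
        counts = np.full(config.n_plants, config.fixed_snvs_per_plant, dtype=np.int64)
    else:
        counts = np.maximum(
            1,
            np.round(
                rng.lognormal(config.snv_count_log_mean, config.snv_count_log_sd, config.n_plants)
            ).astype(np.int64),
        )
    n_snv = int(counts.sum())
    n_indel = int(round(n_snv * config.indel_fraction / (1.0 - config.indel_fraction)))

    # --- substitution classes, then REF-conditional placement
    classes = list(config.class_probs)
    class_n = rng.multinomial(n_snv, [config.class_probs[c] for c in classes])
    used = np.zeros(total_len, dtype=bool)
    snv_gidx: list[np.ndarray] = []
    snv_class: list[str] = []
    for ref_base in _BASES:
        members = [i for i, c in enumerate(classes) if c[0] == ref_base]
        need = int(sum(class_n[i] for i in members))
        if need == 0:
            continue
        pool = np.nonzero(flat == ord(ref_base))[0]
        if need > len(pool):
            raise CapacityError(
                f"need {need} {ref_base} sites but genome has only {len(pool)}"
            )
        chosen = rng.choice(pool, size=need, replace=False)
        used[chosen] = True
        off = 0
        for i in members:
            k = int(class_n[i])
            snv_gidx.append(chosen[off : off + k])
            snv_class.extend([classes[i]] * k)
            off += k
    snv_gidx = np.concatenate(snv_gidx) if snv_gidx else np.empty(0, dtype=np.int64)
    snv_class = np.array(snv_class)

    # --- context bias: rewrite -1/+1 neighbors of mutated G sites
    p_m1 = _biased_distribution(config.base_composition, config.context_delta_minus1)
    p_p1 = _biased_distribution(config.base_composition, config.context_delta_plus1)
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    g_sites = snv_gidx[np.char.startswith(snv_class.astype(str), "G")]
    chrom_starts = {c: (int(bounds[i - 1]) if i else 0) for i, c in enumerate(chrom_names)}
    for offset, dist in ((-1, p_m1), (1, p_p1)):
        neighbors = g_sites + offset
        ok = (neighbors >= 0) & (neighbors < total_len) & ~used[np.clip(neighbors, 0, total_len - 1)]
        # keep neighbors on the same chromosome as their site
        same_chrom = np.searchsorted(bounds, neighbors, "right") == np.searchsorted(
            bounds, g_sites, "right"
        )
        neighbors = neighbors[ok & same_chrom]
        flat[neighbors] = rng.choice(base_bytes, size=len(neighbors), p=dist)
    # push rewritten bases back into per-chromosome arrays
    for i, c in enumerate(chrom_names):
        start = chrom_starts[c]
        arrays[c][:] = flat[start : start + lengths[i]].tobytes()
    out_genome = GenomeSequence({c: arrays[c].decode("ascii") for c in chrom_names})

    rows: list[dict] = []
    # --- true SNVs
    owner = rng.permutation(np.repeat(np.arange(config.n_plants), counts))
    qv_lo, qv_hi = config.tp_qv_range
    snv_qv = rng.uniform(qv_lo, qv_hi, size=n_snv)
    for j in range(n_snv):
        chrom, pos = to_local(int(snv_gidx[j]))
        cls = str(snv_class[j])
        rows.append(
            {
                "plant_id": plant_ids[int(owner[j])],
                "chrom": chrom,
                "pos": pos,
                "ref": cls[0],
                "alt": cls[1],
                "qv": round(float(snv_qv[j]), 2),
                "variant_class": "SNV",
                "indel_length": 0,
                "is_true": True,
            }
        )

    # --- true InDels (outside the repeat mask, off used positions)
    sizes = np.array(sorted(config.indel_size_probs))
    size_p = np.array([config.indel_size_probs[s] for s in sizes])
    indel_owner = rng.integers(0, config.n_plants, size=n_indel)
    placed = 0
    attempts = 0
    while placed < n_indel:
        attempts += 1
        if attempts > 50 * max(n_indel, 1):
            raise CapacityError("could not place InDels outside mask/used positions")
        gidx = int(rng.integers(0, total_len))
        length = int(rng.choice(sizes, p=size_p))
        is_del = rng.random() < config.deletion_fraction
        span = range(gidx, gidx + length + 1) if is_del else (gidx,)
        chrom, pos = to_local(gidx)
        if is_del and gidx + length >= total_len:
            continue
        if is_del and to_local(gidx + length)[0] != chrom:
            continue
        if any(used[k] for k in span) or mask.contains(chrom, pos):
            continue
        for k in span:
            used[k] = True
        anchor = out_genome.base(chrom, pos)
        if is_del:
            ref = out_genome.fetch(chrom, pos, pos + length)
            alt = anchor
            signed = -length
        else:
            ref = anchor
            alt = anchor + "".join(
                rng.choice(list(_BASES), size=length, p=list(config.base_composition))
            )
            signed = length
        rows.append(
            {
                "plant_id": plant_ids[int(indel_owner[placed])],
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "qv": round(float(rng.uniform(qv_lo, qv_hi)), 2),
                "variant_class": "deletion" if is_del else "insertion",
                "indel_length": signed,
                "is_true": True,
            }
        )
        placed += 1

    # --- false positives (low-QV noise calls; may fall anywhere, including the mask)
    n_true = len(rows)
    n_fp = int(round(config.fp_rate / (1.0 - config.fp_rate) * n_true))
    fp_lo, fp_hi = config.fp_qv_range
    placed = 0
    attempts = 0
    while placed < n_fp:
        attempts += 1
        if attempts > 50 * max(n_fp, 1):
            raise CapacityError("could not place false-positive calls")
        gidx = int(rng.integers(0, total_len))
        if used[gidx]:
            continue
        chrom, pos = to_local(gidx)
        anchor = out_genome.base(chrom, pos)
        if anchor == "N":
            continue
        make_indel = rng.random() < config.fp_indel_fraction
        if make_indel:
            length = int(rng.choice(sizes, p=size_p))
            if rng.random() < config.deletion_fraction and pos + length <= out_genome.length(chrom):
                ref, alt, vclass, signed = (
                    out_genome.fetch(chrom, pos, pos + length),
                    anchor,
                    "deletion",
                    -length,
                )
            else:
                ins = "".join(rng.choice(list(_BASES), size=length, p=list(config.base_composition)))
                ref, alt, vclass, signed = anchor, anchor + ins, "insertion", length
        else:
            alts = [b for b in _BASES if b != anchor]
            ref, alt, vclass, signed = anchor, alts[int(rng.integers(0, 3))], "SNV", 0
        used[gidx] = True
        rows.append(
            {
                "plant_id": plant_ids[int(rng.integers(0, config.n_plants))],
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "qv": round(float(rng.uniform(fp_lo, fp_hi)), 2),
                "variant_class": vclass,
                "indel_length": signed,
                "is_true": False,
            }
        )
        placed += 1

    truth = pd.DataFrame(rows)
    transmitted = np.where(
        truth["is_true"].to_numpy(),
        rng.random(len(truth)) >= config.transmission_loss,
        False,
    )
    truth["was_transmitted"] = transmitted
    chrom_rank = {c: i for i, c in enumerate(chrom_names)}
    truth = truth.sort_values(
        by=["chrom", "pos"], key=lambda s: s.map(chrom_rank) if s.name == "chrom" else s
    ).reset_index(drop=True)

    plant_index = {p: i for i, p in enumerate(plant_ids)}
    records = []
    for r in truth.itertuples():
        genotypes = [Zygosity.HOM_REF] * config.n_plants
        genotypes[plant_index[r.plant_id]] = Zygosity.HET
        records.append(
            VariantRecord(
                chrom=r.chrom, pos=r.pos, ref=r.ref, alt=r.alt, qv=r.qv, genotypes=genotypes
            )
        )

    # --- phenotypes from true per-plant SNV load
    per_plant = truth[truth.is_true & (truth.variant_class == "SNV")].groupby("plant_id").size()
    load = np.array([int(per_plant.get(p, 0)) for p in plant_ids])
    seed = phenotype_model(load, config, rng)
    phenotypes = pd.DataFrame(
        {"plant_id": plant_ids, "seed_setting_pct": np.round(seed, 1), "n_true_snv": load}
    )

    # --- Sanger-style validation subsample
    validation = _sample_validation(truth, config, rng)

    return SimulatedCohort(
        config=config,
        genome=out_genome,
        genes=list(genes),
        mask=mask,
        plant_ids=plant_ids,
        records=records,
        truth=truth,
        phenotypes=phenotypes,
        validation=validation,
    )


def _sample_validation(
    truth: pd.DataFrame, config: CohortSimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    parts = []
    for is_snv, n_want in (
        (True, config.n_validation_snv),
        (False, config.n_validation_indel),
    ):
        pool = truth[(truth.variant_class == "SNV") == is_snv]
        n = min(n_want, len(pool))
        if n:
            pick = pool.iloc[np.sort(rng.choice(len(pool), size=n, replace=False))]
            parts.append(pick)
    if not parts:
        return pd.DataFrame(
            columns=["plant_id", "chrom", "pos", "ref", "alt", "variant_class", "qv",
                     "confirmed", "transmitted"]
        )
    val = pd.concat(parts, ignore_index=True)
    out = val[["plant_id", "chrom", "pos", "ref", "alt", "variant_class", "qv"]].copy()
    out["confirmed"] = np.where(val["is_true"], "yes", "no")
    out["transmitted"] = np.where(val["was_transmitted"], "yes", "no")
    return out
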