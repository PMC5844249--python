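"""Synthetic study generator: toy genome, cohort, reads and truth set.

Everything downstream of an aligner is emulated at desk scale: a
multi-chromosome toy genome with genes (UTRs, multi-exon CDS, introns),
Alu J/S/Y and LINE repeats, simple repeats, homopolymer runs and
excluded regions; a patient cohort with genotype dosages, covariates,
traits and gene expression; and per-sample single-end alignments that
carry planted editing events at known per-sample ratios, planted SNPs,
uniform sequencing errors and PCR duplicates, under strand-specific or
non-strand-specific protocols. A machine-readable truth set makes every
emitted read base attributable to an edit, a SNP or an error, so the
detection cascade and the QTL machinery can be scored exactly.

All randomness flows from one seeded numpy Generator passed explicitly;
a fixed seed yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from . import io as eio
from .catalog import EditingMatrix
from .filters import homopolymer_mask
from .io import GenomicInterval, RepeatElement, TranscriptModel

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: planted sites per genomic context (the toy-cohort study conditions)
DEFAULT_SITE_COUNTS = {
    "Alu_J": 6,
    "Alu_S": 8,
    "Alu_Y": 6,
    "LINE": 5,
    "nonrepeat": 5,
    "CDS": 8,
    "UTR3": 6,
    "intron": 5,
    "intergenic": 5,
    "homopolymer": 3,
    "near_splice": 3,
}

DECOY_CONTEXTS = {"homopolymer", "near_splice"}

TISSUES = ("LIV", "AOR", "BLO")


@dataclass
class SimConfig:
    """Study conditions of the toy cohort.

    The defaults define a desk-scale analog of a multi-tissue bulk
    RNA-seq cohort: a ~190 kb genome with 8 genes, 60 planted editing
    sites, 100 samples at ~30x site coverage with 50 bp single-end
    strand-specific reads, 0.1% per-base error, 10% PCR duplicates and a
    5% discordant secondary-alignment fraction.
    """

    seed: int = 0
    n_samples: int = 100
    depth_mean: float = 30.0
    read_length: int = 50
    stranded: bool = True
    error_rate: float = 0.001
    duplicate_rate: float = 0.10
    discordant_fraction: float = 0.05
    base_quality: int = 35
    site_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SITE_COUNTS)
    )
    base_ratio_range: tuple[float, float] = (0.05, 1.0)
    ratio_noise_sd: float = 0.08
    n_decoy_snps: int = 10
    decoy_snp_maf: float = 0.5
    n_qtl_snps: int = 12
    n_background_snps: int = 8
    qtl_maf: float = 0.3
    n_edqtl_sites: int = 10
    genetic_beta: float = 0.15
    n_trait_sites: int = 3
    trait_beta: float = 8.0
    trait_site_ratio_sd: float = 0.15
    trait_noise_sd: float = 0.5
    n_traits: int = 4
    n_eqtl_effects: int = 2
    background_reads_per_gene: int = 40
    min_site_separation: int = 120

    def __post_init__(self):
        for name in ("error_rate", "duplicate_rate", "discordant_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.read_length not in (50, 100):
            raise ValueError("read_length must be 50 or 100")


@dataclass
class TruthSite:
    """One planted editing site with its generative parameters."""

    site_id: str
    chrom: str
    pos: int  # internal 0-based
    ref_base: str  # genomic reference base
    edited_base: str  # genomic alternate base
    strand: str  # transcribed strand ('+'/'-'; '.' randomized per read)
    context: str
    gene_id: str | None
    base_ratio: float
    ratio_sd: float
    genetic_beta: float = 0.0
    causal_snp: str | None = None
    trait: str | None = None
    trait_beta: float = 0.0
    per_sample_ratio: np.ndarray | None = None

    @property
    def is_decoy(self) -> bool:
        return self.context in DECOY_CONTEXTS


@dataclass
class PlantedSnp:
    snp_id: str
    chrom: str
    pos: int  # internal 0-based
    ref_base: str
    alt_base: str
    maf: float
    strand: str = "."  # transcribed strand of the host gene, if any
    dosages: np.ndarray | None = None  # per sample, 0/1/2


@dataclass
class ToyGene:
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]  # without frames; frames derived

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def cds_frames(self) -> list[tuple[int, int, int]]:
        segs = sorted(self.cds)
        order = segs if self.strand == "+" else segs[::-1]
        out, cum = {}, 0
        for s, e in order:
            out[(s, e)] = (3 - cum % 3) % 3
            cum += e - s
        return [(s, e, out[(s, e)]) for s, e in segs]

    def to_transcript_model(self) -> TranscriptModel:
        return TranscriptModel(
            transcript_id=self.gene_id + ".t1",
            gene_id=self.gene_id,
            gene_symbol=self.symbol,
            biotype="protein_coding",
            chrom=self.chrom,
            strand=self.strand,
            exons=list(self.exons),
            cds=self.cds_frames(),
        )


@dataclass
class ToyGenome:
    sequences: dict[str, str]
    genes: list[ToyGene]
    repeats: list[RepeatElement]
    simple_repeats: list[GenomicInterval]
    excluded: list[GenomicInterval]

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


# ---------------------------------------------------------------------------
# Genome construction

_GENE_SPAN = 2600
# plus-strand offsets within a gene: 3 exons, CDS split over all three
_EXONS = [(0, 400), (1000, 1400), (2000, 2600)]
_CDS = [(200, 400), (1000, 1400), (2000, 2153)]  # 753 bp, divisible by 3

_CODONS_NO_STOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in {"TAA", "TAG", "TGA"}
]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _mirror(ivs, span):
    return sorted((span - e, span - s) for s, e in ivs)


def _make_cds_sequence(rng: np.random.Generator, n_codons: int) -> str:
    body = [
        _CODONS_NO_STOP[i]
        for i in rng.integers(0, len(_CODONS_NO_STOP), n_codons - 2)
    ]
    return "ATG" + "".join(body) + "TAG"


def build_genome(config: SimConfig, rng: np.random.Generator) -> ToyGenome:
    """Build the toy genome with genes, repeats and excluded regions.

    chr1 (120 kb, 5 genes) and chr2 (60 kb, 3 genes) carry all planted
    features; chrM and an unplaced contig exist solely to be excluded,
    together with a small MHC-like excluded block on chr1. Each gene has
    three exons with a complete ORF (ATG ... TAG) split across them.
    """
    sizes = {"chr1": 120_000, "chr2": 60_000, "chrM": 3_000, "chrUn_1": 3_000}
    seqs = {name: bytearray(_random_seq(rng, n), "ascii") for name, n in sizes.items()}

    genes: list[ToyGene] = []
    gene_starts = {"chr1": [5_000, 20_000, 35_000, 50_000, 65_000],
                   "chr2": [5_000, 20_000, 35_000]}
    gi = 0
    for chrom, starts in gene_starts.items():
        for gs in starts:
            gi += 1
            strand = "+" if gi % 2 else "-"
            if strand == "+":
                exons = [(gs + s, gs + e) for s, e in _EXONS]
                cds = [(gs + s, gs + e) for s, e in _CDS]
            else:
                exons = [(gs + s, gs + e) for s, e in _mirror(_EXONS, _GENE_SPAN)]
                cds = [(gs + s, gs + e) for s, e in _mirror(_CDS, _GENE_SPAN)]
            gene = ToyGene(
                gene_id=f"g{gi}", symbol=f"GENE{gi}", chrom=chrom,
                strand=strand, exons=exons, cds=cds,
            )
            # write a valid ORF into the CDS positions (transcript order)
            cds_seq = _make_cds_sequence(rng, 753 // 3)
            positions = [p for s, e in sorted(cds) for p in range(s, e)]
            if strand == "-":
                cds_seq = cds_seq.translate(_COMPLEMENT)[::-1]
            for p, b in zip(positions, cds_seq):
                seqs[chrom][p] = ord(b)
            genes.append(gene)

    repeats: list[RepeatElement] = []
    names = {"J": "AluJb", "S": "AluSx", "Y": "AluYa5"}
    # Alus in the intergenic gaps (8 per subfamily is ample for the sites)
    alu_spots = [("chr1", 9_000 + 1_200 * k) for k in range(8)] + [
        ("chr1", 39_000 + 1_200 * k) for k in range(8)
    ] + [("chr2", 9_000 + 1_200 * k) for k in range(8)]
    subfams = ["J", "S", "Y"] * 8
    for (chrom, start), sub in zip(alu_spots, subfams):
        repeats.append(
            RepeatElement(
                interval=GenomicInterval(chrom, start, start + 300),
                family="Alu", alu_subfamily=sub, name=names[sub],
            )
        )
    for k in range(4):  # LINEs
        start = 70_000 + 1_500 * k
        repeats.append(
            RepeatElement(
                interval=GenomicInterval("chr1", start, start + 900),
                family="LINE", alu_subfamily=None, name="L1MA4",
            )
        )
    simple: list[GenomicInterval] = []
    for k in range(6):
        start = 80_000 + 400 * k
        seqs["chr1"][start : start + 40] = b"AC" * 20
        simple.append(GenomicInterval("chr1", start, start + 40))
        repeats.append(
            RepeatElement(
                interval=GenomicInterval("chr1", start, start + 40),
                family="simple", alu_subfamily=None, name="(AC)n",
            )
        )
    excluded = [
        GenomicInterval("chrM", 0, sizes["chrM"]),
        GenomicInterval("chrUn_1", 0, sizes["chrUn_1"]),
        GenomicInterval("chr1", 100_000, 110_000),  # MHC-like block
    ]
    return ToyGenome(
        sequences={k: v.decode() for k, v in seqs.items()},
        genes=genes,
        repeats=repeats,
        simple_repeats=simple,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Truth-site placement


def _region_pool(genome: ToyGenome, context: str) -> list[tuple[str, int, int, str, str | None]]:
    """Candidate (chrom, start, end, strand, gene_id) regions per context."""
    pool = []
    gene_introns = [
        (g.chrom, s + 10, e - 10, g.strand, g.gene_id)
        for g in genome.genes
        for s, e in g.introns()
    ]
    if context in {"Alu_J", "Alu_S", "Alu_Y"}:
        sub = context[-1]
        for r in genome.repeats:
            if r.family == "Alu" and r.alu_subfamily == sub:
                iv = r.interval
                pool.append((iv.chrom, iv.start + 10, iv.end - 10, ".", None))
    elif context == "LINE":
        for r in genome.repeats:
            if r.family == "LINE":
                iv = r.interval
                pool.append((iv.chrom, iv.start + 10, iv.end - 10, ".", None))
    elif context in {"intron", "nonrepeat"}:
        pool = gene_introns
    elif context == "CDS":
        for g in genome.genes:
            for s, e in g.cds:
                pool.append((g.chrom, s + 3, e - 3, g.strand, g.gene_id))
    elif context == "UTR3":
        for g in genome.genes:
            tx = g.to_transcript_model()
            _, utr3 = tx.utr_intervals()
            for s, e in utr3:
                pool.append((g.chrom, s + 2, e - 10, g.strand, g.gene_id))
    elif context == "intergenic":
        pool = [("chr1", 55_000, 64_000, ".", None), ("chr2", 45_000, 58_000, ".", None)]
    else:
        raise ValueError(f"no placement pool for context {context!r}")
    return pool


def plant_truth_sites(
    genome: ToyGenome, config: SimConfig, rng: np.random.Generator
) -> tuple[list[TruthSite], list[PlantedSnp]]:
    """Plant editing sites per context plus decoy SNP positions.

    The reference base at each site is forced to the transcribed-strand
    adenosine (genomic A on '+', T on '-'); placements keep a minimum
    separation so no read covers two planted positions, and non-decoy
    sites are re-drawn until they sit clear of homopolymer runs, splice
    windows and simple repeats. Decoys are placed to violate exactly the
    region rule they probe: inside a planted >=5 bp A-run, or within 5
    bp of an exon-intron boundary.
    """
    seqs = {c: bytearray(s, "ascii") for c, s in genome.sequences.items()}
    occupied: dict[str, list[int]] = {c: [] for c in seqs}
    boundaries: dict[str, set[int]] = {}
    for g in genome.genes:
        bset = boundaries.setdefault(g.chrom, set())
        for istart, iend in g.introns():
            bset.update((istart, iend))
    simple_pos = {
        (iv.chrom, p) for iv in genome.simple_repeats for p in range(iv.start, iv.end)
    }

    def far_enough(chrom, pos):
        return all(abs(pos - q) >= config.min_site_separation for q in occupied[chrom])

    def near_junction(chrom, pos, window=5):
        for b in boundaries.get(chrom, ()):
            d = pos - b + 1 if pos >= b else b - pos
            if d <= window:
                return True
        return False

    def clean_after_plant(chrom, pos, base):
        lo, hi = max(0, pos - 7), min(len(seqs[chrom]), pos + 8)
        window = seqs[chrom][lo:hi].decode()
        window = window[: pos - lo] + base + window[pos - lo + 1 :]
        return (pos - lo) not in homopolymer_mask(window)

    sites: list[TruthSite] = []
    sid = 0
    for context, count in config.site_counts.items():
        placed = 0
        if context == "homopolymer":
            spots = [("chr1", 90_000 + 500 * k) for k in range(count)]
            for chrom, start in spots:
                seqs[chrom][start : start + 7] = b"A" * 7
                pos = start + 3
                sid += 1
                sites.append(
                    TruthSite(
                        site_id=f"site{sid:03d}", chrom=chrom, pos=pos,
                        ref_base="A", edited_base="G", strand=".",
                        context=context, gene_id=None,
                        base_ratio=float(rng.uniform(0.4, 0.9)),
                        ratio_sd=config.ratio_noise_sd,
                    )
                )
                occupied[chrom].append(pos)
            continue
        if context == "near_splice":
            candidates = []
            for g in genome.genes:
                for istart, iend in g.introns():
                    candidates.append((g, istart - 3))  # 3 bp inside the exon
            for g, pos in candidates:
                if placed >= count:
                    break
                if not far_enough(g.chrom, pos):
                    continue
                base = "A" if g.strand == "+" else "T"
                seqs[g.chrom][pos] = ord(base)
                sid += 1
                sites.append(
                    TruthSite(
                        site_id=f"site{sid:03d}", chrom=g.chrom, pos=pos,
                        ref_base=base,
                        edited_base="G" if base == "A" else "C",
                        strand=g.strand, context=context, gene_id=g.gene_id,
                        base_ratio=float(rng.uniform(0.4, 0.9)),
                        ratio_sd=config.ratio_noise_sd,
                    )
                )
                occupied[g.chrom].append(pos)
                placed += 1
            if placed < count:
                raise ValueError(f"cannot place {count} {context} sites")
            continue
        pool = _region_pool(genome, context)
        attempts = 0
        while placed < count:
            attempts += 1
            if attempts > 5000:
                raise ValueError(f"cannot place {count} sites in context {context}")
            chrom, lo, hi, strand, gene_id = pool[int(rng.integers(len(pool)))]
            pos = int(rng.integers(lo, hi))
            if strand == ".":
                strand_eff = "+" if rng.random() < 0.5 else "-"
            else:
                strand_eff = strand
            base = "A" if strand_eff == "+" else "T"
            if not far_enough(chrom, pos):
                continue
            if near_junction(chrom, pos):
                continue
            if (chrom, pos) in simple_pos:
                continue
            if not clean_after_plant(chrom, pos, base):
                continue
            seqs[chrom][pos] = ord(base)
            sid += 1
            sites.append(
                TruthSite(
                    site_id=f"site{sid:03d}", chrom=chrom, pos=pos,
                    ref_base=base,
                    edited_base="G" if base == "A" else "C",
                    strand=strand_eff, context=context, gene_id=gene_id,
                    base_ratio=float(
                        rng.uniform(*config.base_ratio_range)
                    ),
                    ratio_sd=config.ratio_noise_sd,
                )
            )
            occupied[chrom].append(pos)
            placed += 1

    # decoy SNPs in introns: survive region rules, die at the database stage
    snps: list[PlantedSnp] = []
    pool = _region_pool(genome, "intron")
    placed = 0
    attempts = 0
    while placed < config.n_decoy_snps:
        attempts += 1
        if attempts > 5000:
            raise ValueError("cannot place decoy SNPs")
        chrom, lo, hi, strand, gene_id = pool[int(rng.integers(len(pool)))]
        pos = int(rng.integers(lo, hi))
        if not far_enough(chrom, pos) or near_junction(chrom, pos):
            continue
        ref = seqs[chrom][pos : pos + 1].decode()
        if not clean_after_plant(chrom, pos, ref):
            continue
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
        placed += 1
        snps.append(
            PlantedSnp(
                snp_id=f"rsT{placed:03d}", chrom=chrom, pos=pos,
                ref_base=ref, alt_base=alt, maf=config.decoy_snp_maf,
                strand=strand,
            )
        )
        occupied[chrom].append(pos)

    genome.sequences = {c: b.decode() for c, b in seqs.items()}
    return sites, snps


# ---------------------------------------------------------------------------
# Cohort


@dataclass
class Cohort:
    samples: list[str]
    tissue: pd.Series  # sample -> tissue label
    genotypes: pd.DataFrame  # samples x SNPs, dosages
    snp_meta: pd.DataFrame  # snp -> chrom, pos (1-based), effect_allele
    covariates: pd.DataFrame
    traits: pd.DataFrame
    expression: pd.DataFrame  # samples x genes
    eqtl_pairs: list[tuple[str, str]]  # (snp, gene) with planted expression effect


def _clamp_ratio(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.02, 1.0)


def simulate_cohort(
    genome: ToyGenome,
    truth: list[TruthSite],
    decoy_snps: list[PlantedSnp],
    config: SimConfig,
    rng: np.random.Generator,
) -> Cohort:
    """Draw the cohort: genotypes under Hardy-Weinberg, per-sample true
    editing ratios (additively shifted by dosage for effect sites, then
    clamped into (0,1]), traits linked to designated site ratios, and
    gene expression with planted eQTL effects.
    """
    import warnings

    n = config.n_samples
    samples = [f"S{i:03d}" for i in range(n)]
    tissue = pd.Series(
        [TISSUES[i % len(TISSUES)] for i in range(n)], index=samples, name="tissue"
    )

    # marker panel: QTL SNPs (half cis on chr1, half on chr2) + background
    snp_rows, dosage_cols = [], {}
    for k in range(config.n_qtl_snps):
        snp_id = f"rsQ{k:03d}"
        chrom = "chr1" if k % 2 == 0 else "chr2"
        snp_rows.append((snp_id, chrom, 1_000 + 700 * k + 1, "G"))
        dosage_cols[snp_id] = rng.binomial(2, config.qtl_maf, n)
    for k in range(config.n_background_snps):
        snp_id = f"rsB{k:03d}"
        snp_rows.append((snp_id, "chr2", 50_000 + 97 * k + 1, "A"))
        dosage_cols[snp_id] = rng.binomial(2, config.qtl_maf, n)
    for s in decoy_snps:
        s.dosages = rng.binomial(2, s.maf, n)
        snp_rows.append((s.snp_id, s.chrom, s.pos + 1, s.alt_base))
        dosage_cols[s.snp_id] = s.dosages
    genotypes = pd.DataFrame(dosage_cols, index=samples)
    snp_meta = pd.DataFrame(
        snp_rows, columns=["snp", "chrom", "pos", "effect_allele"]
    ).set_index("snp")

    # assign genetic effects to eligible (non-decoy, mid-ratio) sites
    eligible = [s for s in truth if not s.is_decoy]
    effect_sites = eligible[: config.n_edqtl_sites]
    for k, site in enumerate(effect_sites):
        site.genetic_beta = config.genetic_beta
        site.causal_snp = f"rsQ{k % config.n_qtl_snps:03d}"
        site.base_ratio = float(rng.uniform(0.3, 0.5))
    trait_sites = [s for s in eligible if s.genetic_beta == 0][: config.n_trait_sites]
    for k, site in enumerate(trait_sites):
        site.trait = f"trait{k % config.n_traits + 1}"
        site.trait_beta = config.trait_beta
        site.ratio_sd = config.trait_site_ratio_sd
        site.base_ratio = float(rng.uniform(0.35, 0.6))

    for site in truth:
        shift = np.zeros(n)
        if site.genetic_beta:
            shift = site.genetic_beta * genotypes[site.causal_snp].to_numpy()
        raw = site.base_ratio + shift + rng.normal(0, site.ratio_sd, n)
        clamped = _clamp_ratio(raw)
        if (clamped != raw).any() and site.genetic_beta:
            warnings.warn(
                f"{site.site_id}: dosage shift clamped into (0,1]", stacklevel=2
            )
        site.per_sample_ratio = clamped

    age = rng.integers(40, 76, n).astype(float)
    sex = rng.integers(0, 2, n).astype(float)
    batch = np.array([f"b{1 + i % 3}" for i in range(n)])
    lab = np.array([f"L{1 + i % 2}" for i in range(n)])
    covariates = pd.DataFrame(
        {"age": age, "sex": sex, "batch": batch, "laboratory": lab}, index=samples
    )
    batch_effect = np.where(batch == "b2", 0.3, np.where(batch == "b3", -0.2, 0.0))

    traits = {}
    for t in range(1, config.n_traits + 1):
        name = f"trait{t}"
        y = 0.02 * age + 0.3 * sex + batch_effect + rng.normal(
            0, config.trait_noise_sd, n
        )
        for site in trait_sites:
            if site.trait == name:
                y = y + site.trait_beta * site.per_sample_ratio
        traits[name] = y
    traits = pd.DataFrame(traits, index=samples)

    gene_ids = [g.gene_id for g in genome.genes]
    base_expr = rng.uniform(5, 50, len(gene_ids))
    expr = base_expr[None, :] * (1 + rng.normal(0, 0.1, (n, len(gene_ids))))
    eqtl_pairs: list[tuple[str, str]] = []
    genic_effect_sites = [s for s in effect_sites if s.gene_id is not None]
    for site in genic_effect_sites[: config.n_eqtl_effects]:
        gi = gene_ids.index(site.gene_id)
        expr[:, gi] += 0.4 * base_expr[gi] * genotypes[site.causal_snp].to_numpy()
        eqtl_pairs.append((site.causal_snp, site.gene_id))
    expression = pd.DataFrame(expr, index=samples, columns=gene_ids)

    return Cohort(
        samples=samples, tissue=tissue, genotypes=genotypes, snp_meta=snp_meta,
        covariates=covariates, traits=traits, expression=expression,
        eqtl_pairs=eqtl_pairs,
    )


# ---------------------------------------------------------------------------
# Read simulation


@dataclass
class SimRead:
    read_id: str
    chrom: str
    start: int
    strand: str
    cigar: list[tuple[int, int]]  # pysam op codes
    seq: str

    @property
    def end(self) -> int:
        return self.start + sum(
            l for op, l in self.cigar if op in (0, 2, 3)
        )


def _apply_errors(
    seq: list[str], err_row: np.ndarray, rng: np.random.Generator
) -> None:
    for j in np.flatnonzero(err_row):
        cur = seq[j]
        choices = [b for b in "ACGT" if b != cur]
        seq[j] = choices[int(rng.integers(3))]


def _targeted_reads(
    label: str,
    chrom: str,
    pos: int,
    ref: str,
    alt_base: str,
    p_alt: float,
    strand: str,
    sample_idx: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[SimRead]:
    L = config.read_length
    seq = ref
    d = int(rng.poisson(config.depth_mean))
    if d == 0:
        return []
    offsets = rng.integers(0, L, d)
    alt_draw = rng.random(d) < p_alt
    errs = rng.random((d, L)) < config.error_rate
    if config.stranded:
        strands = (
            np.full(d, strand)
            if strand in "+-"
            else np.where(rng.random(d) < 0.5, "+", "-")
        )
    else:
        strands = np.where(rng.random(d) < 0.5, "+", "-")
    reads = []
    for r in range(d):
        start = pos - int(offsets[r])
        bases = list(seq[start : start + L])
        if alt_draw[r]:
            bases[int(offsets[r])] = alt_base
        if errs[r].any():
            _apply_errors(bases, errs[r], rng)
        reads.append(
            SimRead(
                read_id=f"s{sample_idx}_{label}_{r}",
                chrom=chrom, start=start, strand=str(strands[r]),
                cigar=[(0, L)], seq="".join(bases),
            )
        )
    return reads


def _background_reads(
    gene: ToyGene,
    genome: ToyGenome,
    exonic_sites: list[TruthSite],
    sample_idx: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[SimRead]:
    """Spliced reads drawn from the mature transcript (exercise N CIGARs)."""
    L = config.read_length
    seq = genome.sequences[gene.chrom]
    exons = gene.exons
    tx_len = sum(e - s for s, e in exons)
    # transcript coordinate -> genomic position map (genomic order)
    tx2g = [p for s, e in exons for p in range(s, e)]
    nb = config.background_reads_per_gene
    starts = rng.integers(0, tx_len - L, nb)
    errs = rng.random((nb, L)) < config.error_rate
    if config.stranded:
        strands = np.full(nb, gene.strand)
    else:
        strands = np.where(rng.random(nb) < 0.5, "+", "-")
    site_at = {s.pos: s for s in exonic_sites}
    reads = []
    for r in range(nb):
        t0 = int(starts[r])
        gpos = tx2g[t0 : t0 + L]
        bases = [seq[p] for p in gpos]
        for j, p in enumerate(gpos):
            site = site_at.get(p)
            if site is not None and rng.random() < site.per_sample_ratio[sample_idx]:
                bases[j] = site.edited_base
        if errs[r].any():
            _apply_errors(bases, errs[r], rng)
        # build CIGAR from the genomic positions (M runs split by N gaps)
        cigar: list[tuple[int, int]] = []
        run_start = gpos[0]
        prev = gpos[0]
        for p in gpos[1:]:
            if p != prev + 1:
                cigar.append((0, prev - run_start + 1))
                cigar.append((3, p - prev - 1))
                run_start = p
            prev = p
        cigar.append((0, prev - run_start + 1))
        reads.append(
            SimRead(
                read_id=f"s{sample_idx}_{gene.gene_id}_bg{r}",
                chrom=gene.chrom, start=gpos[0], strand=str(strands[r]),
                cigar=cigar, seq="".join(bases),
            )
        )
    return reads


def simulate_sample_reads(
    genome: ToyGenome,
    truth: list[TruthSite],
    decoy_snps: list[PlantedSnp],
    sample_idx: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[SimRead]:
    """All primary reads of one sample: site-targeted coverage at every
    planted position, spliced background reads over genes, then PCR
    duplicates appended as exact copies."""
    reads: list[SimRead] = []
    for site in truth:
        reads += _targeted_reads(
            site.site_id, site.chrom, site.pos,
            genome.sequences[site.chrom], site.edited_base,
            float(site.per_sample_ratio[sample_idx]), site.strand,
            sample_idx, config, rng,
        )
    for snp in decoy_snps:
        p_alt = float(snp.dosages[sample_idx]) / 2.0
        reads += _targeted_reads(
            snp.snp_id, snp.chrom, snp.pos,
            genome.sequences[snp.chrom], snp.alt_base, p_alt, snp.strand,
            sample_idx, config, rng,
        )
    exonic_by_gene: dict[str, list[TruthSite]] = {}
    for s in truth:
        if s.gene_id is not None and s.context in {"CDS", "UTR3", "near_splice"}:
            exonic_by_gene.setdefault(s.gene_id, []).append(s)
    for gene in genome.genes:
        reads += _background_reads(
            gene, genome, exonic_by_gene.get(gene.gene_id, []),
            sample_idx, config, rng,
        )
    dup_mask = rng.random(len(reads)) < config.duplicate_rate
    dups = [
        SimRead(
            read_id=reads[i].read_id + "_dup",
            chrom=reads[i].chrom, start=reads[i].start,
            strand=reads[i].strand, cigar=list(reads[i].cigar),
            seq=reads[i].seq,
        )
        for i in np.flatnonzero(dup_mask)
    ]
    reads += dups
    reads.sort(key=lambda r: (r.chrom, r.start, r.read_id))
    return reads


def write_sam(
    reads: list[SimRead],
    genome: ToyGenome,
    path: str | Path,
    config: SimConfig,
    mapq: int = 255,
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": name, "LN": len(seq)} for name, seq in genome.sequences.items()
        ],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.seq
            a.flag = 16 if r.strand == "-" else 0
            a.reference_name = r.chrom
            a.reference_start = r.start
            a.mapping_quality = mapq
            a.cigartuples = r.cigar
            a.query_qualities = pysam.qualitystring_to_array(
                chr(config.base_quality + 33) * len(r.seq)
            )
            out.write(a)


def make_secondary_reads(
    reads: list[SimRead], config: SimConfig, rng: np.random.Generator
) -> tuple[list[SimRead], set[str]]:
    """Secondary-aligner version of the reads: identical except for a
    ``discordant_fraction`` of reads shifted 10 bp, which fails the >99%
    start-stop overlap criterion. Returns the reads and the ids made
    discordant."""
    out, discordant = [], set()
    flags = rng.random(len(reads)) < config.discordant_fraction
    for r, bad in zip(reads, flags):
        if bad:
            out.append(
                SimRead(
                    read_id=r.read_id, chrom=r.chrom, start=r.start + 10,
                    strand=r.strand, cigar=list(r.cigar), seq=r.seq,
                )
            )
            discordant.add(r.read_id)
        else:
            out.append(r)
    return out, discordant


# ---------------------------------------------------------------------------
# Whole-study orchestration


@dataclass
class StudyData:
    config: SimConfig
    genome: ToyGenome
    truth: list[TruthSite]
    decoy_snps: list[PlantedSnp]
    cohort: Cohort
    outdir: Path
    sam_paths: dict[str, Path]
    secondary_paths: dict[str, Path]

    def truth_by_position(self) -> dict[tuple[str, int], TruthSite]:
        return {(s.chrom, s.pos): s for s in self.truth}


def write_annotation_files(genome: ToyGenome, outdir: Path) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "gtf": outdir / "genes.gtf",
        "repeats": outdir / "repeats.bed",
        "simple_repeats": outdir / "simple_repeats.bed",
        "excluded": outdir / "excluded.bed",
    }
    eio.write_reference(genome.sequences, paths["fasta"])
    with open(paths["gtf"], "w") as fh:
        for g in genome.genes:
            tx = g.gene_id + ".t1"
            attrs = (
                f'gene_id "{g.gene_id}"; transcript_id "{tx}"; '
                f'gene_name "{g.symbol}"; gene_biotype "protein_coding";'
            )
            lo, hi = g.span
            for feat, s, e, frame in (
                [("gene", lo, hi, "."), ("transcript", lo, hi, ".")]
                + [("exon", s, e, ".") for s, e in g.exons]
                + [("CDS", s, e, str(f)) for s, e, f in g.cds_frames()]
            ):
                fh.write(
                    f"{g.chrom}\ttoy\t{feat}\t{s + 1}\t{e}\t.\t{g.strand}\t{frame}\t{attrs}\n"
                )
    with open(paths["repeats"], "w") as fh:
        for r in genome.repeats:
            iv = r.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.name}\n")
    with open(paths["simple_repeats"], "w") as fh:
        for iv in genome.simple_repeats:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tsimple\n")
    with open(paths["excluded"], "w") as fh:
        for iv in genome.excluded:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\texcluded\n")
    return paths


def write_snp_vcf(snps: list[PlantedSnp], genome: ToyGenome, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in genome.sequences.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(snps, key=lambda s: (s.chrom, s.pos)):
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t{s.snp_id}\t{s.ref_base}\t"
                f"{s.alt_base}\t.\tPASS\t.\n"
            )


def write_truth_table(truth: list[TruthSite], path: Path) -> None:
    rows = [
        {
            "site_id": s.site_id, "chrom": s.chrom, "pos": s.pos + 1,
            "ref": s.ref_base, "alt": s.edited_base, "strand": s.strand,
            "context": s.context, "gene_id": s.gene_id or "NA",
            "base_ratio": s.base_ratio, "ratio_sd": s.ratio_sd,
            "genetic_beta": s.genetic_beta, "causal_snp": s.causal_snp or "NA",
            "trait": s.trait or "NA", "trait_beta": s.trait_beta,
        }
        for s in truth
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def simulate_study(config: SimConfig, outdir: str | Path) -> StudyData:
    """Generate the complete toy study on disk and in memory.

    Writes genome.fa, genes.gtf, repeat/simple-repeat/excluded BEDs,
    known_snps.vcf, truth_sites.tsv, cohort TSVs (genotypes, snps,
    covariates, traits, expression, tissues) and one primary plus one
    secondary SAM per sample under sam/ and sam2/.
    """
    outdir = Path(outdir)
    rng = np.random.default_rng(config.seed)
    genome = build_genome(config, rng)
    truth, decoy_snps = plant_truth_sites(genome, config, rng)
    cohort = simulate_cohort(genome, truth, decoy_snps, config, rng)

    write_annotation_files(genome, outdir)
    write_snp_vcf(decoy_snps, genome, outdir / "known_snps.vcf")
    write_truth_table(truth, outdir / "truth_sites.tsv")
    cohort.genotypes.to_csv(outdir / "genotypes.tsv", sep="\t")
    cohort.snp_meta.to_csv(outdir / "snps.tsv", sep="\t")
    cohort.covariates.to_csv(outdir / "covariates.tsv", sep="\t")
    cohort.traits.to_csv(outdir / "traits.tsv", sep="\t")
    cohort.expression.to_csv(outdir / "expression.tsv", sep="\t")
    cohort.tissue.to_csv(outdir / "tissues.tsv", sep="\t")

    (outdir / "sam").mkdir(exist_ok=True)
    (outdir / "sam2").mkdir(exist_ok=True)
    sam_paths, secondary_paths = {}, {}
    for i, sample in enumerate(cohort.samples):
        reads = simulate_sample_reads(genome, truth, decoy_snps, i, config, rng)
        sec, _ = make_secondary_reads(reads, config, rng)
        p1 = outdir / "sam" / f"{sample}.sam"
        p2 = outdir / "sam2" / f"{sample}.sam"
        write_sam(reads, genome, p1, config)
        write_sam(sec, genome, p2, config)
        sam_paths[sample], secondary_paths[sample] = p1, p2
    return StudyData(
        config=config, genome=genome, truth=truth, decoy_snps=decoy_snps,
        cohort=cohort, outdir=outdir, sam_paths=sam_paths,
        secondary_paths=secondary_paths,
    )


# ---------------------------------------------------------------------------
# Cohort-level matrix simulation (for statistical calibration at larger n)


def simulate_editing_matrix(
    n_sites: int = 500,
    n_samples: int = 200,
    depth: int = 30,
    maf: float = 0.3,
    beta: float = 0.0,
    n_effect_sites: int = 0,
    one_snp_per_site: bool = False,
    ratio_range: tuple[float, float] = (0.3, 0.6),
    ratio_sd: float = 0.05,
    seed: int = 0,
) -> tuple[EditingMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Editing-ratio matrix with binomial read noise, skipping read-level
    simulation — for calibration of the association machinery at sample
    sizes where simulating reads would be wasteful.

    Returns (matrix, genotypes, snp_meta, covariates, truth) where truth
    has one row per site with its causal SNP (or NA) and beta.
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    sites = [f"chr1:{1000 + 200 * k}:A-to-G" for k in range(n_sites)]
    n_snps = n_sites if one_snp_per_site else 1
    snp_ids = [f"rs{k:04d}" for k in range(n_snps)]
    G = pd.DataFrame(
        rng.binomial(2, maf, (n_samples, n_snps)), index=samples, columns=snp_ids
    )
    snp_meta = pd.DataFrame(
        {"chrom": "chr1", "pos": [10_000 + 97 * k for k in range(n_snps)],
         "effect_allele": "G"},
        index=pd.Index(snp_ids, name="snp"),
    )
    base = rng.uniform(*ratio_range, n_sites)
    truth_rows = []
    R = np.empty((n_samples, n_sites))
    for j in range(n_sites):
        causal = snp_ids[j % n_snps] if j < n_effect_sites else None
        b = beta if causal else 0.0
        shift = b * G[causal].to_numpy() if causal else 0.0
        R[:, j] = _clamp_ratio(base[j] + shift + rng.normal(0, ratio_sd, n_samples))
        truth_rows.append({"site": sites[j], "causal_snp": causal or "NA", "beta": b})
    edited = rng.binomial(depth, R)
    ratios = edited / depth
    ratios_df = pd.DataFrame(
        np.where(edited > 0, ratios, np.nan).T, index=sites, columns=samples
    )
    support_df = pd.DataFrame(edited.T, index=sites, columns=samples)
    covariates = pd.DataFrame(
        {
            "age": rng.integers(40, 76, n_samples).astype(float),
            "sex": rng.integers(0, 2, n_samples).astype(float),
        },
        index=samples,
    )
    site_meta = pd.DataFrame(
        {"chrom": "chr1", "pos": [1000 + 200 * k for k in range(n_sites)],
         "mismatch_type": "A-to-G"},
        index=sites,
    )
    matrix = EditingMatrix(
        ratios=ratios_df, support=support_df,
        tissue=pd.Series("LIV", index=samples), site_meta=site_meta,
    )
    return matrix, G, snp_meta, covariates, pd.DataFrame(truth_rows).set_index("site")
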