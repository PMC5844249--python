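"""Readers and writers for the standard formats the pipeline touches.

One internal coordinate convention is used everywhere: 0-based half-open
intervals, as in BED. All user-facing output (catalog TSVs, QTL tables)
is written 1-based, matching the convention of genome browsers and the
published editing catalogs this package emulates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam
from Bio import SeqIO
from intervaltree import IntervalTree

VALID_BASES = set("ACGTN")

CATALOG_COLUMNS = [
    "tissue", "library_type", "chrom", "pos", "dna_base", "rna_base", "n_samples",
]

# Column order of the QTL output table: tissue, regulatory SNP, effect allele,
# site coordinate, cis/trans, beta, p, permutation-adjusted p, then annotation.
EDQTL_COLUMNS = [
    "tissue", "snp", "effect_allele", "site", "cis_trans", "beta", "p_value",
    "adjusted_p", "gene_id", "gene_symbol", "biotype", "repeat", "gwas_trait",
    "region", "darned", "rediportal", "eqtl",
]


class ParseError(ValueError):
    """Malformed input file."""


class PairedEndError(ParseError):
    """Paired-end alignments are outside the scope of this pipeline."""


def to_one_based(start0: int) -> int:
    """Convert an internal 0-based coordinate to a 1-based position."""
    return start0 + 1


def to_zero_based(pos1: int) -> int:
    """Convert a 1-based position to the internal 0-based coordinate."""
    return pos1 - 1


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval in internal coordinates (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.start}-{self.end}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class AlignedRead:
    """One aligned single-end sequencing read.

    ``aligned_blocks`` are (ref_start, ref_end) half-open segments split on
    splice (N) and deletion (D) operations. ``block_query_starts`` gives,
    for each block, the query-sequence offset of its first base, so the
    base and quality under any reference position can be recovered without
    reparsing the CIGAR.
    """

    read_id: str
    chrom: str
    strand: str  # '+' or '-'
    aligned_blocks: list[tuple[int, int]]
    block_query_starts: list[int]
    query_sequence: str
    base_qualities: list[int]
    mapq: int
    is_duplicate: bool = False
    soft_clip_left: int = 0
    soft_clip_right: int = 0

    @property
    def reference_start(self) -> int:
        return self.aligned_blocks[0][0]

    @property
    def reference_end(self) -> int:
        return self.aligned_blocks[-1][1]

    @property
    def five_prime_outer(self) -> int:
        """Strand-aware 5' outer coordinate, including soft-clipped bases.

        This is the duplicate-collapse key position: the inferred 5' end of
        the original fragment.
        """
        if self.strand == "+":
            return self.reference_start - self.soft_clip_left
        return self.reference_end + self.soft_clip_right

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.aligned_blocks)

    def iter_aligned(self) -> Iterator[tuple[int, int]]:
        """Yield (reference_position, query_index) over aligned bases."""
        for (rs, re_), qs in zip(self.aligned_blocks, self.block_query_starts):
            for i in range(re_ - rs):
                yield rs + i, qs + i


@dataclass(frozen=True)
class VariantRecord:
    """One known variant (multi-allelic records are split on read)."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref_allele: str
    alt_allele: str
    source: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1")


@dataclass(frozen=True)
class CatalogRow:
    """One aggregated catalog entry (tissue x library x site x change)."""

    tissue: str
    library_type: str
    chrom: str
    pos: int  # 1-based
    dna_base: str
    rna_base: str
    n_samples: int

    def __post_init__(self):
        if self.library_type not in {"Y", "N"}:
            raise ValueError("library_type must be 'Y' or 'N'")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript, internal coordinates."""

    transcript_id: str
    gene_id: str
    gene_symbol: str
    biotype: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int, int]] = field(default_factory=list)  # (start, end, frame)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    def utr_intervals(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """Exonic intervals upstream (5'UTR) / downstream (3'UTR) of the CDS,
        in genomic coordinates but assigned by transcript orientation."""
        if not self.cds:
            return [], []
        cds_lo = min(s for s, _, _ in self.cds)
        cds_hi = max(e for _, e, _ in self.cds)
        left, right = [], []
        for s, e in self.exons:
            if s < cds_lo:
                left.append((s, min(e, cds_lo)))
            if e > cds_hi:
                right.append((max(s, cds_hi), e))
        if self.strand == "+":
            return left, right
        return right, left

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


@dataclass
class GeneModels:
    """All transcripts of a genome, with interval indexes for lookups."""

    transcripts: dict[str, TranscriptModel]

    def __post_init__(self):
        self._trees: dict[str, IntervalTree] = {}
        self._gene_strand: dict[str, str] = {}
        for tx in self.transcripts.values():
            tree = self._trees.setdefault(tx.chrom, IntervalTree())
            tree.addi(tx.start, tx.end, tx)
            self._gene_strand[tx.gene_id] = tx.strand

    @property
    def gene_ids(self) -> list[str]:
        return sorted({t.gene_id for t in self.transcripts.values()})

    def transcripts_at(self, chrom: str, pos: int) -> list[TranscriptModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree[pos]), key=lambda t: t.transcript_id)

    def genes_overlapping(self, chrom: str, start: int, end: int) -> dict[str, str]:
        """gene_id -> strand for genes overlapping [start, end)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return {}
        return {iv.data.gene_id: iv.data.strand for iv in tree[start:end]}

    def gene_strand(self, gene_id: str) -> str:
        return self._gene_strand[gene_id]

    def exon_union_length(self, gene_id: str) -> int:
        """Gene length for RPKM: union of exon intervals across transcripts."""
        ivs = sorted(
            iv
            for tx in self.transcripts.values()
            if tx.gene_id == gene_id
            for iv in tx.exons
        )
        total, cur_s, cur_e = 0, None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
        return total

    def splice_boundaries(self) -> dict[str, set[int]]:
        """Per chromosome, the exon/intron boundary coordinates.

        A boundary is recorded as the internal coordinate of the first base
        to its right, i.e. the intron start and the intron end of each
        intron. Distance of a site to a boundary b is measured in bases:
        position p >= b lies (p - b + 1) bases right of the cut, position
        p < b lies (b - p) bases left of it.
        """
        out: dict[str, set[int]] = {}
        for tx in self.transcripts.values():
            bset = out.setdefault(tx.chrom, set())
            for istart, iend in tx.introns():
                bset.add(istart)
                bset.add(iend)
        return out


@dataclass(frozen=True)
class RepeatElement:
    """One repeat annotation from a RepeatMasker-style BED."""

    interval: GenomicInterval
    family: str  # Alu | LINE | simple | other
    alu_subfamily: str | None  # J | S | Y, only for Alu
    name: str


_SIMPLE_RE = re.compile(r"^\([ACGT]+\)n$", re.IGNORECASE)


def classify_repeat_name(name: str) -> tuple[str, str | None]:
    """Map a RepeatMasker repeat name to (family, Alu subfamily).

    AluJ*/AluS*/AluY* carry the subfamily in the fourth character; L1/L2/
    LINE prefixes map to LINE; '(AC)n'-style names and 'Simple_repeat' map
    to the simple-repeat family; everything else is 'other'.
    """
    if name.startswith("Alu") or name in {"FRAM", "FLAM"}:
        sub = name[3:4]
        return "Alu", sub if sub in {"J", "S", "Y"} else None
    if name.startswith(("L1", "L2", "LINE", "HAL1")):
        return "LINE", None
    if _SIMPLE_RE.match(name) or name.lower().startswith("simple"):
        return "simple", None
    return "other", None


# ---------------------------------------------------------------------------
# FASTA


def read_reference(path: str | Path) -> dict[str, str]:
    """Read a FASTA reference into a name -> uppercase sequence mapping.

    Lowercase (soft-masked) bases are uppercased so masking cannot alter
    downstream calls. Characters outside {A,C,G,T,N} raise a ParseError.
    """
    path = Path(path)
    genome: dict[str, str] = {}
    with open(path) as handle:
        first = handle.read(1)
        if first and first != ">":
            raise ParseError(f"{path}: line 1: expected FASTA header starting with '>'")
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ParseError(
                f"{path}: record {record.id!r} contains illegal characters {sorted(bad)}"
            )
        genome[record.id] = seq
    return genome


def genome_length(genome: dict[str, str]) -> int:
    return sum(len(s) for s in genome.values())


def write_reference(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM

_QUERY_CONSUMERS = {0, 1, 4, 7, 8}  # M, I, S, =, X
_REF_CONSUMERS = {0, 2, 3, 7, 8}  # M, D, N, =, X
_ALLOWED_OPS = {0, 1, 2, 3, 4, 5, 7, 8}  # M I D N S H = X


def _blocks_from_cigar(
    cigartuples: list[tuple[int, int]], ref_start: int
) -> tuple[list[tuple[int, int]], list[int], int, int]:
    """Split a CIGAR into match blocks with their query offsets.

    Returns (blocks, block_query_starts, soft_clip_left, soft_clip_right).
    N (splice), D (deletion) and I (insertion) all break blocks.
    """
    blocks: list[tuple[int, int]] = []
    qstarts: list[int] = []
    rpos, qpos = ref_start, 0
    clip_left = clip_right = 0
    seen_aligned = False
    for op, length in cigartuples:
        if op not in _ALLOWED_OPS:
            raise ParseError(f"unsupported CIGAR op code {op}")
        if op == 4:  # S
            if seen_aligned:
                clip_right += length
            else:
                clip_left += length
            qpos += length
        elif op in (0, 7, 8):  # M, =, X
            blocks.append((rpos, rpos + length))
            qstarts.append(qpos)
            rpos += length
            qpos += length
            seen_aligned = True
        elif op == 1:  # I
            qpos += length
        elif op in (2, 3):  # D, N
            rpos += length
        # H consumes nothing we track
    return blocks, qstarts, clip_left, clip_right


def read_alignments(
    path: str | Path, min_mapq: int = 255
) -> Iterator[AlignedRead]:
    """Stream AlignedRead records from a SAM file.

    Unmapped, secondary and supplementary records and reads below
    ``min_mapq`` are dropped; the default of 255 keeps only reads a
    STAR-style aligner marked uniquely mapped. Paired-end flags raise,
    since the pipeline is defined for single-end libraries.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_paired:
                raise PairedEndError(
                    f"read {rec.query_name!r} carries paired-end flags; "
                    "only single-end libraries are supported"
                )
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            seq = rec.query_sequence
            if seq is None:
                raise ParseError(f"read {rec.query_name!r} has no sequence")
            quals = (
                list(rec.query_qualities)
                if rec.query_qualities is not None
                else [0] * len(seq)
            )
            if len(quals) != len(seq):
                raise ParseError(
                    f"read {rec.query_name!r}: quality/sequence length mismatch"
                )
            blocks, qstarts, cl, cr = _blocks_from_cigar(
                rec.cigartuples, rec.reference_start
            )
            consumed = sum(e - s for s, e in blocks) + cl + cr + sum(
                l for op, l in rec.cigartuples if op == 1
            )
            if consumed != len(seq):
                raise ParseError(
                    f"read {rec.query_name!r}: CIGAR consumes {consumed} query "
                    f"bases but sequence has {len(seq)}"
                )
            yield AlignedRead(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                strand="-" if rec.is_reverse else "+",
                aligned_blocks=blocks,
                block_query_starts=qstarts,
                query_sequence=seq,
                base_qualities=quals,
                mapq=rec.mapping_quality,
                is_duplicate=rec.is_duplicate,
                soft_clip_left=cl,
                soft_clip_right=cr,
            )


# ---------------------------------------------------------------------------
# GTF / BED / VCF / TSV


def read_gene_models(path: str | Path) -> GeneModels:
    """Read GENCODE-style GTF gene models (exon + CDS features)."""
    import pyranges

    df = pyranges.read_gtf(str(path)).df
    required = {"Feature", "Chromosome", "Start", "End", "Strand"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: missing required GTF columns")
    if "transcript_id" not in df.columns:
        raise ParseError(f"{path}: GTF records lack transcript_id attributes")
    txs: dict[str, TranscriptModel] = {}
    sub = df[df.Feature.isin(["exon", "CDS"])]
    for row in sub.itertuples():
        tid = row.transcript_id
        if not isinstance(tid, str) or not tid:
            raise ParseError(f"{path}: exon/CDS record without transcript_id")
        if tid not in txs:
            txs[tid] = TranscriptModel(
                transcript_id=tid,
                gene_id=getattr(row, "gene_id", tid),
                gene_symbol=str(getattr(row, "gene_name", "") or ""),
                biotype=str(getattr(row, "gene_biotype", "") or ""),
                chrom=str(row.Chromosome),
                strand=str(row.Strand),
            )
        tx = txs[tid]
        if row.Feature == "exon":
            tx.exons.append((int(row.Start), int(row.End)))
        else:
            frame = getattr(row, "Frame", ".")
            try:
                frame = int(frame)
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"{path}: CDS of {tid} lacks a numeric frame"
                ) from exc
            tx.cds.append((int(row.Start), int(row.End), frame))
    for tx in txs.values():
        tx.exons.sort()
        tx.cds.sort()
        if not tx.exons:
            raise ParseError(f"transcript {tx.transcript_id} has no exons")
    return GeneModels(transcripts=txs)


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file into internal intervals (already 0-based)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 BED columns")
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            out.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand)
            )
    return sorted(out, key=lambda iv: (iv.chrom, iv.start))


def read_repeats(path: str | Path) -> list[RepeatElement]:
    """Read a BED4+ repeat file; the name column carries the repeat label."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(
                    f"{path}: line {lineno}: repeat BED needs a name column"
                )
            family, sub = classify_repeat_name(parts[3])
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            out.append(
                RepeatElement(
                    interval=GenomicInterval(
                        parts[0], int(parts[1]), int(parts[2]), strand
                    ),
                    family=family,
                    alu_subfamily=sub,
                    name=parts[3],
                )
            )
    return sorted(out, key=lambda r: (r.interval.chrom, r.interval.start))


def read_variants(path: str | Path, source: str = "") -> list[VariantRecord]:
    """Read a VCF into VariantRecords, splitting multi-allelic rows."""
    out = []
    label = source or Path(path).stem
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                out.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        source=label,
                    )
                )
    return out


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix with the first column as the index."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Catalog output


def write_catalog(rows: Iterable[CatalogRow], path: str | Path) -> None:
    """Write the 7-column editing catalog TSV (1-based positions).

    Columns: tissue, library type (Y/N), chromosome, position, DNA base,
    RNA base, number of samples. Rows are sorted by chromosome and
    position for deterministic output.
    """
    ordered = sorted(
        rows, key=lambda r: (r.chrom, r.pos, r.tissue, r.library_type, r.rna_base)
    )
    with open(path, "w") as fh:
        for r in ordered:
            fh.write(
                f"{r.tissue}\t{r.library_type}\t{r.chrom}\t{r.pos}\t"
                f"{r.dna_base}\t{r.rna_base}\t{r.n_samples}\n"
            )


def read_catalog(path: str | Path) -> list[CatalogRow]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ParseError(f"{path}: line {lineno}: expected 7 columns")
            out.append(
                CatalogRow(
                    tissue=parts[0],
                    library_type=parts[1],
                    chrom=parts[2],
                    pos=int(parts[3]),
                    dna_base=parts[4],
                    rna_base=parts[5],
                    n_samples=int(parts[6]),
                )
            )
    return out


def write_edqtl_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write QTL results in the documented column order; absent annotation
    columns are filled with 'NA'."""
    out = df.copy()
    for col in EDQTL_COLUMNS:
        if col not in out.columns:
            out[col] = "NA"
    out[EDQTL_COLUMNS].to_csv(path, sep="\t", index=False)
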