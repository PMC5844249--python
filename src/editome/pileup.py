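"""Duplicate collapsing, pileup construction and candidate-site extraction.

The pileup is the per-reference-position stack of aligned read bases.
Each base remembers its distance from the read's biological 5' end
(strand-aware, in query coordinates), because reads primed with random
hexamers carry excess mismatches near the 5' end and a downstream filter
removes evidence from that window.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple

from .io import AlignedRead, GeneModels


class ReadBase(NamedTuple):
    """One read base stacked on a pileup column."""

    read_id: str
    base: str
    quality: int
    dist_from_5prime: int
    read_start: int
    read_end: int
    read_strand: str


@dataclass
class PileupColumn:
    chrom: str
    pos: int  # 0-based
    ref_base: str
    bases: list[ReadBase]

    @property
    def depth(self) -> int:
        return len(self.bases)


@dataclass
class CandidateSite:
    """A (position, alt base) pair with per-read mismatch evidence."""

    column: PileupColumn
    alt_base: str
    alt_count: int
    total_count: int

    @property
    def chrom(self) -> str:
        return self.column.chrom

    @property
    def pos(self) -> int:
        return self.column.pos

    @property
    def ref_base(self) -> str:
        return self.column.ref_base


def collapse_duplicates(reads: Iterable[AlignedRead]) -> list[AlignedRead]:
    """Collapse PCR duplicates, keeping one read per duplicate group.

    Single-end rmdup semantics: reads sharing (chromosome, strand, 5'
    outer position including soft-clip offset) form one group; the member
    with the highest summed base quality survives, ties broken by
    lexicographically smallest read id. The operation is idempotent.
    """
    groups: dict[tuple[str, str, int], AlignedRead] = {}
    for read in reads:
        key = (read.chrom, read.strand, read.five_prime_outer)
        best = groups.get(key)
        if best is None:
            groups[key] = read
            continue
        score, best_score = sum(read.base_qualities), sum(best.base_qualities)
        if score > best_score or (
            score == best_score and read.read_id < best.read_id
        ):
            groups[key] = read
    return sorted(
        groups.values(), key=lambda r: (r.chrom, r.reference_start, r.read_id)
    )


def build_pileup(
    reads: Iterable[AlignedRead], reference: dict[str, str]
) -> Iterator[PileupColumn]:
    """Stream pileup columns over every covered reference position.

    Deleted and splice-skipped positions contribute no base. Memory is
    bounded by read length: reads are processed in coordinate order and
    finished columns are emitted as soon as no later read can touch them.
    The distance from the 5' end is the query offset for forward reads
    and (read length - 1 - offset) for reverse reads.
    """
    pending: dict[int, list[ReadBase]] = {}
    cur_chrom: str | None = None

    def flush(upto: int | None) -> Iterator[PileupColumn]:
        ref = reference[cur_chrom]
        for pos in sorted(p for p in pending if upto is None or p < upto):
            yield PileupColumn(cur_chrom, pos, ref[pos], pending.pop(pos))

    ordered = sorted(reads, key=lambda r: (r.chrom, r.reference_start))
    for read in ordered:
        if read.chrom not in reference:
            raise KeyError(
                f"read {read.read_id!r} maps to {read.chrom!r}, absent from reference"
            )
        if read.chrom != cur_chrom:
            if cur_chrom is not None:
                yield from flush(None)
            cur_chrom = read.chrom
        else:
            yield from flush(read.reference_start)
        seq = read.query_sequence
        quals = read.base_qualities
        n = len(seq)
        forward = read.strand == "+"
        rid, rstart, rend, rstrand = (
            read.read_id,
            read.reference_start,
            read.reference_end,
            read.strand,
        )
        for (rs, re_), qs in zip(read.aligned_blocks, read.block_query_starts):
            for i in range(re_ - rs):
                qidx = qs + i
                dist = qidx if forward else n - 1 - qidx
                pending.setdefault(rs + i, []).append(
                    ReadBase(rid, seq[qidx], quals[qidx], dist, rstart, rend, rstrand)
                )
    if cur_chrom is not None:
        yield from flush(None)


def scan_candidates(pileup: Iterable[PileupColumn]) -> Iterator[CandidateSite]:
    """Extract candidate mismatch sites from a pileup stream.

    One candidate is emitted per (column, alt base) with at least one
    supporting read; columns whose reference base is N are skipped. No
    minimum coverage is imposed here — the filter cascade decides.
    """
    for col in pileup:
        if col.ref_base == "N":
            continue
        counts = Counter(b.base for b in col.bases)
        for alt, n in sorted(counts.items()):
            if alt == col.ref_base or alt == "N":
                continue
            yield CandidateSite(
                column=col, alt_base=alt, alt_count=n, total_count=col.depth
            )


def infer_strandedness(
    reads: Iterable[AlignedRead],
    gene_models: GeneModels,
    forward_threshold: float = 0.9,
) -> tuple[str, float]:
    """Infer the library protocol from read orientation relative to genes.

    Reads overlapping genes of a single strand vote sense (read strand
    equals gene strand) or antisense; overlaps of genes on both strands
    are ambiguous and dropped. Returns a label in {stranded-forward,
    stranded-reverse, unstranded, undetermined} and the sense fraction.
    """
    sense = antisense = 0
    for read in reads:
        strands = set(
            gene_models.genes_overlapping(
                read.chrom, read.reference_start, read.reference_end
            ).values()
        )
        if len(strands) != 1:
            continue
        if read.strand in strands:
            sense += 1
        else:
            antisense += 1
    total = sense + antisense
    if total == 0:
        return "undetermined", float("nan")
    frac = sense / total
    if frac >= forward_threshold:
        return "stranded-forward", frac
    if frac <= 1 - forward_threshold:
        return "stranded-reverse", frac
    return "unstranded", frac


def count_reads_in_genes(
    reads: Iterable[AlignedRead], gene_models: GeneModels
) -> tuple[int, Counter]:
    """Count reads overlapping any gene; also return per-gene counts.

    A read overlapping several genes increments each gene's counter but
    counts once toward the in-gene total.
    """
    per_gene: Counter = Counter()
    in_genes = 0
    for read in reads:
        hits = gene_models.genes_overlapping(
            read.chrom, read.reference_start, read.reference_end
        )
        if hits:
            in_genes += 1
            for gid in hits:
                per_gene[gid] += 1
    return in_genes, per_gene


def sample_qc(
    reads: Iterable[AlignedRead],
    gene_models: GeneModels,
    min_reads_in_genes: int = 1_000_000,
) -> tuple[bool, int]:
    """Sample-level QC: pass iff strictly more than ``min_reads_in_genes``
    uniquely mapped reads overlap genes (default one million)."""
    count, _ = count_reads_in_genes(reads, gene_models)
    return count > min_reads_in_genes, count


def compute_rpkm(
    read_counts: dict[str, int],
    gene_lengths: dict[str, int],
    total_mapped: int,
) -> dict[str, float]:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM = count * 1e9 / (gene_length_bp * total_mapped). Gene length is
    the union of exon lengths in bp.
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    out = {}
    for gene, length in gene_lengths.items():
        if length <= 0:
            raise ValueError(f"gene {gene!r} has non-positive length")
        out[gene] = read_counts.get(gene, 0) * 1e9 / (length * total_mapped)
    return out
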