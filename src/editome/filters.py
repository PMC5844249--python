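"""The systematic filter cascade applied to candidate mismatch sites.

Stages, in order: region filters (simple repeats, homopolymer runs,
splice-junction windows, excluded regions), known-variant exclusion,
dual-aligner concordance (optional), then read-level evidence criteria
(base quality, distance from the 5' end, single-variant-per-site,
support by at least two non-identical reads). Each stage only removes
candidates; a funnel report records the per-stage counts.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .io import GeneModels, GenomicInterval, VariantRecord
from .pileup import CandidateSite, ReadBase


@dataclass
class CalledEvent:
    """One called editing event in one sample (genomic reference frame)."""

    chrom: str
    pos: int  # 0-based internal
    ref_base: str
    alt_base: str
    edited_count: int
    total_count: int
    supporting: list[ReadBase] = field(default_factory=list)

    @property
    def ratio(self) -> float:
        return self.edited_count / self.total_count


@dataclass
class FunnelReport:
    """Per-stage candidate counts; out of stage k feeds stage k+1."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {name!r}: out ({n_out}) exceeds in ({n_in})")
        if self.stages and self.stages[-1][2] != n_in:
            raise ValueError(f"stage {name!r}: in-count does not chain")
        self.stages.append((name, n_in, n_out))

    def to_tsv(self) -> str:
        lines = ["stage\tcandidates_in\tcandidates_out"]
        lines += [f"{s}\t{i}\t{o}" for s, i, o in self.stages]
        return "\n".join(lines) + "\n"


@dataclass
class CascadeConfig:
    min_baseq: int = 20
    min_dist5p: int = 6  # strict: evidence must lie > this many bases from 5'
    min_support: int = 2
    homopolymer_min_run: int = 5
    homopolymer_flank: int = 1
    splice_window: int = 5
    concordance_min_overlap: float = 0.99


@dataclass
class CascadeResources:
    """Everything the cascade needs besides the candidates themselves."""

    reference: dict[str, str]
    simple_repeats: Sequence[GenomicInterval] = ()
    gene_models: GeneModels | None = None
    excluded_regions: Sequence[GenomicInterval] = ()
    variant_sets: Sequence[Sequence[VariantRecord]] = ()
    secondary_alignments: dict[str, tuple[str, str, int, int]] | None = None


def _interval_tree(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def homopolymer_mask(
    sequence: str, min_run: int = 5, flank: int = 1
) -> set[int]:
    """Positions inside, or within ``flank`` bp of, a homopolymer run of
    at least ``min_run`` identical bases."""
    mask: set[int] = set()
    n = len(sequence)
    i = 0
    while i < n:
        j = i
        while j < n and sequence[j] == sequence[i]:
            j += 1
        if sequence[i] != "N" and j - i >= min_run:
            mask.update(range(max(0, i - flank), min(n, j + flank)))
        i = j
    return mask


def _near_boundary(pos: int, boundaries: Sequence[int], window: int) -> bool:
    """True if pos lies within ``window`` bases of a splice boundary.

    A boundary b is the cut between two bases; the first base on either
    side is at distance 1, so the removed window is [b - window, b +
    window - 1] in internal coordinates.
    """
    for b in boundaries:
        d = pos - b + 1 if pos >= b else b - pos
        if d <= window:
            return True
    return False


def region_filters(
    sites: list[CandidateSite],
    resources: CascadeResources,
    config: CascadeConfig = CascadeConfig(),
) -> tuple[list[CandidateSite], list[tuple[str, int, int]]]:
    """Remove candidates in simple repeats, homopolymer runs, splice-
    junction windows and user-excluded regions (chrM, unplaced contigs,
    MHC are supplied as an excluded-region BED).

    Returns surviving sites and the per-substage funnel rows.
    """
    rows: list[tuple[str, int, int]] = []
    simple_trees = _interval_tree(resources.simple_repeats)
    excl_trees = _interval_tree(resources.excluded_regions)
    hp_masks = {
        chrom: homopolymer_mask(
            seq, config.homopolymer_min_run, config.homopolymer_flank
        )
        for chrom, seq in resources.reference.items()
    }
    boundaries = (
        {c: sorted(b) for c, b in resources.gene_models.splice_boundaries().items()}
        if resources.gene_models is not None
        else {}
    )

    def stage(name, keep):
        nonlocal sites
        n_in = len(sites)
        sites = [s for s in sites if keep(s)]
        rows.append((name, n_in, len(sites)))

    stage(
        "simple_repeat",
        lambda s: not (s.chrom in simple_trees and simple_trees[s.chrom][s.pos]),
    )
    stage("homopolymer", lambda s: s.pos not in hp_masks.get(s.chrom, ()))
    stage(
        "splice_junction",
        lambda s: not _near_boundary(
            s.pos, boundaries.get(s.chrom, ()), config.splice_window
        ),
    )
    stage(
        "excluded_region",
        lambda s: not (s.chrom in excl_trees and excl_trees[s.chrom][s.pos]),
    )
    return sites, rows


def database_filter(
    sites: list[CandidateSite],
    variant_sets: Sequence[Sequence[VariantRecord]],
) -> list[CandidateSite]:
    """Drop candidates at positions recorded in any known-variant set.

    Matching is by position only (allele-agnostic): a database variant at
    the site's position removes it even if the recorded alternate allele
    differs — the conservative reading of discarding listed SNVs.
    """
    known: set[tuple[str, int]] = set()
    for vs in variant_sets:
        for v in vs:
            known.add((v.chrom, v.pos - 1))  # VCF 1-based -> internal
    return [s for s in sites if (s.chrom, s.pos) not in known]


def _concordant(
    primary: tuple[str, str, int, int],
    secondary: tuple[str, str, int, int],
    min_overlap: float,
) -> bool:
    chrom1, strand1, s1, e1 = primary
    chrom2, strand2, s2, e2 = secondary
    if chrom1 != chrom2 or strand1 != strand2:
        return False
    inter = max(0, min(e1, e2) - max(s1, s2))
    frac = inter / max(e1 - s1, e2 - s2)
    return frac > min_overlap


def concordance_filter(
    sites: list[CandidateSite],
    secondary_alignments: dict[str, tuple[str, str, int, int]],
    config: CascadeConfig = CascadeConfig(),
) -> list[CandidateSite]:
    """Drop read evidence whose primary and secondary alignments disagree.

    A read is concordant when both aligners put its start-stop interval
    on the same chromosome and strand with > 99% overlap, the overlap
    fraction being intersection / max(primary length, secondary length).
    Reads missing from the secondary aligner are treated as discordant.
    Sites losing all mismatch support are removed.
    """
    verdict_cache: dict[tuple[str, str, int, int], bool] = {}
    out = []
    for site in sites:
        col = site.column
        kept: list[ReadBase] = []
        for rb in col.bases:
            key = (rb.read_id, rb.read_strand, rb.read_start, rb.read_end)
            ok = verdict_cache.get(key)
            if ok is None:
                sec = secondary_alignments.get(rb.read_id)
                ok = sec is not None and _concordant(
                    (col.chrom, rb.read_strand, rb.read_start, rb.read_end),
                    sec,
                    config.concordance_min_overlap,
                )
                verdict_cache[key] = ok
            if ok:
                kept.append(rb)
        alt_n = sum(1 for rb in kept if rb.base == site.alt_base)
        if alt_n == 0:
            continue
        from .pileup import PileupColumn

        out.append(
            CandidateSite(
                column=PileupColumn(col.chrom, col.pos, col.ref_base, kept),
                alt_base=site.alt_base,
                alt_count=alt_n,
                total_count=len(kept),
            )
        )
    return out


def read_evidence_filter(
    sites: list[CandidateSite],
    config: CascadeConfig = CascadeConfig(),
) -> list[CalledEvent]:
    """Apply the read-level calling criteria and emit called events.

    Evidence bases must have base quality >= min_baseq and lie strictly
    more than min_dist5p bases from the read's 5' end. Positions left
    with two or more distinct alternate bases are removed entirely. A
    call needs at least min_support supporting reads with pairwise
    distinct (start, end, strand) — amplification copies that survived
    duplicate collapse must not count twice. The edited count is the
    number of surviving supporting reads; the total is the surviving
    column depth.
    """
    by_pos: dict[tuple[str, int], list[CandidateSite]] = defaultdict(list)
    for s in sites:
        by_pos[(s.chrom, s.pos)].append(s)

    events: list[CalledEvent] = []
    for (chrom, pos), group in sorted(by_pos.items()):
        col = group[0].column
        surviving = [
            rb
            for rb in col.bases
            if rb.quality >= config.min_baseq
            and rb.dist_from_5prime > config.min_dist5p
        ]
        alt_support = {
            s.alt_base: [rb for rb in surviving if rb.base == s.alt_base]
            for s in group
        }
        alt_support = {a: rbs for a, rbs in alt_support.items() if rbs}
        if len(alt_support) != 1:
            continue  # no surviving variant, or multi-variant position
        alt, support = next(iter(alt_support.items()))
        distinct = {(rb.read_start, rb.read_end, rb.read_strand) for rb in support}
        if len(distinct) < config.min_support:
            continue
        events.append(
            CalledEvent(
                chrom=chrom,
                pos=pos,
                ref_base=col.ref_base,
                alt_base=alt,
                edited_count=len(support),
                total_count=len(surviving),
                supporting=support,
            )
        )
    return events


def run_cascade(
    candidates: Iterable[CandidateSite],
    resources: CascadeResources,
    config: CascadeConfig = CascadeConfig(),
) -> tuple[list[CalledEvent], FunnelReport]:
    """Run all stages in order and return called events plus the funnel.

    Stage order: region filters -> known-variant exclusion -> dual-
    aligner concordance (skipped when no secondary alignments are given)
    -> read-evidence criteria.
    """
    if not resources.reference:
        raise ValueError("cascade requires a loaded reference")
    sites = list(candidates)
    funnel = FunnelReport()
    funnel.add("candidates", len(sites), len(sites))

    sites, region_rows = region_filters(sites, resources, config)
    for name, n_in, n_out in region_rows:
        funnel.add(name, n_in, n_out)

    n_in = len(sites)
    sites = database_filter(sites, resources.variant_sets)
    funnel.add("known_variant", n_in, len(sites))

    if resources.secondary_alignments is not None:
        n_in = len(sites)
        sites = concordance_filter(sites, resources.secondary_alignments, config)
        funnel.add("realignment_concordance", n_in, len(sites))

    n_in = len(sites)
    events = read_evidence_filter(sites, config)
    funnel.add("read_evidence", n_in, len(events))
    return events, funnel
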