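"""Feature mapping, repeat enrichment and protein-recoding consequences.

Sites are assigned a single genomic-feature label by fixed precedence,
intersected with RepeatMasker-style repeat annotations for family and
Alu-subfamily summaries, and, when they fall in coding sequence as an
A→G change on the transcript strand, translated to a codon-level
consequence (synonymous, nonsynonymous or stop-loss). Gaining a stop
codon is impossible for A-to-I editing: no codon acquires a T/U by an
A→G substitution, and all stop codons start with U.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree
from scipy import stats

from .catalog import EditingMatrix
from .io import GeneModels, RepeatElement, TranscriptModel

#: feature labels, highest precedence first
FEATURE_PRECEDENCE = [
    "exonic_cds",
    "splicing",
    "utr3",
    "utr5",
    "ncRNA_exonic",
    "intronic",
    "intergenic",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _tx_feature(pos: int, tx: TranscriptModel, splicing_window: int = 2) -> str | None:
    """Feature of ``pos`` (internal coordinate) within one transcript."""
    if not (tx.start <= pos < tx.end):
        return None
    for istart, iend in tx.introns():
        for b in (istart, iend):
            d = pos - b + 1 if pos >= b else b - pos
            if d <= splicing_window:
                return "splicing"
    in_exon = any(s <= pos < e for s, e in tx.exons)
    if not in_exon:
        return "intronic"
    if not tx.is_coding:
        return "ncRNA_exonic"
    if any(s <= pos < e for s, e, _ in tx.cds):
        return "exonic_cds"
    utr5, utr3 = tx.utr_intervals()
    if any(s <= pos < e for s, e in utr5):
        return "utr5"
    if any(s <= pos < e for s, e in utr3):
        return "utr3"
    return "intronic"  # exonic outside CDS/UTR should not occur; be safe


def assign_feature(
    chrom: str, pos: int, gene_models: GeneModels, splicing_window: int = 2
) -> str:
    """Assign one feature label to a site (internal 0-based position).

    Labels from overlapping transcripts are resolved by the fixed
    precedence exonic_cds > splicing > utr3 > utr5 > ncRNA_exonic >
    intronic > intergenic, except that a splicing hit (within 2 bp of a
    splice boundary in any transcript) outranks everything, since it
    flags positions where alignment around the junction is unreliable.
    """
    labels = set()
    for tx in gene_models.transcripts_at(chrom, pos):
        lab = _tx_feature(pos, tx, splicing_window)
        if lab:
            labels.add(lab)
    if not labels:
        return "intergenic"
    for lab in FEATURE_PRECEDENCE:
        if lab in labels:
            return lab
    return "intergenic"


def merged_family_bp(repeats: Iterable[RepeatElement]) -> dict[str, int]:
    """Total genomic bp per repeat family after merging overlaps."""
    by_family: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for r in repeats:
        by_family.setdefault(r.family, {}).setdefault(r.interval.chrom, []).append(
            (r.interval.start, r.interval.end)
        )
    out = {}
    for fam, chroms in by_family.items():
        total = 0
        for ivs in chroms.values():
            ivs.sort()
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s > cur_e:
                    total += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            total += cur_e - cur_s
        out[fam] = total
    return out


def enrichment_from_counts(
    events_by_family: Mapping[str, int],
    total_events: int,
    family_bp: Mapping[str, int],
    genome_length: int,
) -> pd.DataFrame:
    """Repeat enrichment from aggregated counts.

    event_fraction = events in family / total events; coverage_fraction =
    merged family bp / genome length; enrichment is their ratio.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    rows = []
    for fam in sorted(set(events_by_family) | set(family_bp)):
        ev_frac = events_by_family.get(fam, 0) / total_events if total_events else 0.0
        cov_frac = family_bp.get(fam, 0) / genome_length
        rows.append(
            {
                "family": fam,
                "n_events": events_by_family.get(fam, 0),
                "event_fraction": ev_frac,
                "family_bp": family_bp.get(fam, 0),
                "coverage_fraction": cov_frac,
                "enrichment": ev_frac / cov_frac if cov_frac > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("family")


def _repeat_trees(repeats: Iterable[RepeatElement]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in repeats:
        trees.setdefault(r.interval.chrom, IntervalTree()).addi(
            r.interval.start, r.interval.end, r
        )
    return trees


def repeat_at(
    trees: dict[str, IntervalTree], chrom: str, pos: int
) -> RepeatElement | None:
    tree = trees.get(chrom)
    if tree is None:
        return None
    hits = tree[pos]
    if not hits:
        return None
    return min((iv.data for iv in hits), key=lambda r: (r.interval.start, r.name))


def repeat_enrichment(
    sites: Sequence[tuple[str, int]],
    repeats: Sequence[RepeatElement],
    genome_length: int,
) -> pd.DataFrame:
    """Per-family enrichment of events relative to genomic coverage.

    ``sites`` are (chrom, internal position) of events (redundant entries
    allowed — one per event). A 'nonrepeat' catch-all row makes the
    event fractions sum to one.
    """
    trees = _repeat_trees(repeats)
    counts: dict[str, int] = {}
    for chrom, pos in sites:
        hit = repeat_at(trees, chrom, pos)
        fam = hit.family if hit else "nonrepeat"
        counts[fam] = counts.get(fam, 0) + 1
    bp = merged_family_bp(repeats)
    bp["nonrepeat"] = genome_length - sum(bp.values())
    return enrichment_from_counts(counts, len(sites), bp, genome_length)


@dataclass
class AluSubfamilySummary:
    counts: dict[str, int]  # per subfamily J/S/Y
    fractions: dict[str, float]  # of all events (incl. non-Alu)
    mean_ratios: dict[str, list[float]]  # per-sample mean ratios
    pairwise_p: dict[tuple[str, str], float]  # Mann-Whitney U on mean ratios


def alu_subfamily_summary(
    events: Sequence[tuple[str, int, str, float]],
    repeats: Sequence[RepeatElement],
) -> AluSubfamilySummary:
    """Summarize editing in Alu subfamilies J, S and Y.

    ``events`` are (chrom, internal position, sample_id, ratio) tuples.
    Counts and event fractions are per subfamily; editing strength is
    compared between subfamilies by a two-sided Mann-Whitney U test on
    per-sample mean ratios.
    """
    trees = _repeat_trees([r for r in repeats if r.family == "Alu"])
    counts = {"J": 0, "S": 0, "Y": 0}
    per_sample: dict[str, dict[str, list[float]]] = {"J": {}, "S": {}, "Y": {}}
    total = len(events)
    for chrom, pos, sample, ratio in events:
        hit = repeat_at(trees, chrom, pos)
        if hit is None or hit.alu_subfamily is None:
            continue
        sub = hit.alu_subfamily
        counts[sub] += 1
        per_sample[sub].setdefault(sample, []).append(ratio)
    mean_ratios = {
        sub: [float(np.mean(v)) for _, v in sorted(samples.items())]
        for sub, samples in per_sample.items()
    }
    pairwise = {}
    for a, b in [("J", "S"), ("J", "Y"), ("S", "Y")]:
        if len(mean_ratios[a]) >= 2 and len(mean_ratios[b]) >= 2:
            pairwise[(a, b)] = float(
                stats.mannwhitneyu(
                    mean_ratios[a], mean_ratios[b], alternative="two-sided"
                ).pvalue
            )
        else:
            pairwise[(a, b)] = float("nan")
    fractions = {s: (counts[s] / total if total else 0.0) for s in counts}
    return AluSubfamilySummary(counts, fractions, mean_ratios, pairwise)


@dataclass
class RecodingCall:
    """Codon-level consequence of an A→G edit in coding sequence."""

    chrom: str
    pos: int  # internal 0-based
    gene_id: str
    transcript_id: str
    codon_before: str
    codon_after: str
    aa_before: str
    aa_after: str
    consequence: str  # synonymous | nonsynonymous | stop_loss
    protein_position: int
    aa_change: str  # e.g. Q607R

    def __post_init__(self):
        diff = sum(a != b for a, b in zip(self.codon_before, self.codon_after))
        if diff != 1:
            raise ValueError("edited codon must differ at exactly one position")
        if self.consequence == "stop_loss" and self.aa_before != "*":
            raise ValueError("stop_loss requires a stop codon before editing")


def _cds_positions(tx: TranscriptModel) -> list[int]:
    """Genomic positions of CDS bases in translation order."""
    segs = sorted(tx.cds)
    positions = [p for s, e, _ in segs for p in range(s, e)]
    if tx.strand == "-":
        positions.reverse()
    return positions


def call_recoding(
    chrom: str,
    pos: int,
    tx: TranscriptModel,
    reference: dict[str, str],
) -> RecodingCall | None:
    """Call the codon consequence of an A→G edit at ``pos`` (internal).

    The edit must be A→G on the transcript strand: genomic A in a plus-
    strand CDS, genomic T in a minus-strand CDS; anything else (or a
    position outside the CDS) returns None. The codon is located from
    the CDS segment frames, the edited codon is translated with the
    standard genetic code, and the consequence is classified. An
    incomplete terminal codon is flagged by a ValueError.
    """
    if tx.chrom != chrom or not tx.is_coding:
        return None
    if not any(s <= pos < e for s, e, _ in tx.cds):
        return None
    seq = reference[chrom]
    genomic_ref = seq[pos]
    expected = "A" if tx.strand == "+" else "T"
    if genomic_ref != expected:
        return None

    positions = _cds_positions(tx)
    # leading frame offset of the first segment in translation order
    first = sorted(tx.cds)[0] if tx.strand == "+" else sorted(tx.cds)[-1]
    offset = first[2]
    positions = positions[offset:]
    idx = positions.index(pos)
    codon_idx = idx // 3
    codon_pos = positions[codon_idx * 3 : codon_idx * 3 + 3]
    if len(codon_pos) < 3:
        raise ValueError("incomplete terminal codon")

    codon_before = "".join(
        seq[p] if tx.strand == "+" else seq[p].translate(_COMPLEMENT)
        for p in codon_pos
    )
    codon_after = "".join(
        ("G" if p == pos else c) for p, c in zip(codon_pos, codon_before)
    )
    aa_before = str(Seq(codon_before).translate())
    aa_after = str(Seq(codon_after).translate())
    # A->G cannot create a T/U, and every stop codon starts with U
    assert not (aa_before != "*" and aa_after == "*"), (
        "stop gain is impossible for A-to-I editing"
    )
    if aa_before == "*" and aa_after != "*":
        consequence = "stop_loss"
    elif aa_before == aa_after:
        consequence = "synonymous"
    else:
        consequence = "nonsynonymous"
    protein_position = codon_idx + 1
    return RecodingCall(
        chrom=chrom,
        pos=pos,
        gene_id=tx.gene_id,
        transcript_id=tx.transcript_id,
        codon_before=codon_before,
        codon_after=codon_after,
        aa_before=aa_before,
        aa_after=aa_after,
        consequence=consequence,
        protein_position=protein_position,
        aa_change=f"{aa_before}{protein_position}{aa_after}",
    )


_SEVERITY = {"stop_loss": 2, "nonsynonymous": 1, "synonymous": 0}


def most_severe(calls: Sequence[RecodingCall]) -> RecodingCall | None:
    """Gene-level summary across transcripts: the most severe consequence
    (stop_loss > nonsynonymous > synonymous)."""
    if not calls:
        return None
    return max(calls, key=lambda c: (_SEVERITY[c.consequence], c.transcript_id))


def conserved_site_filter(
    matrix: EditingMatrix,
    min_samples: int = 20,
    min_median_ratio: float = 0.1,
) -> list[str]:
    """Select sites detected in strictly more than ``min_samples`` samples
    overall AND with median editing ratio above ``min_median_ratio`` in at
    least one tissue (median over samples where the site was detected)."""
    det = matrix.detected()
    recurrent = det.sum(axis=1) > min_samples
    medians = matrix.ratios.T.groupby(matrix.tissue).median().T  # sites x tissues
    strong = (medians > min_median_ratio).any(axis=1)
    return sorted(matrix.ratios.index[recurrent & strong])


def recurrence_filter(matrix: EditingMatrix, min_samples: int = 50) -> list[str]:
    """Select sites detected in strictly more than ``min_samples`` samples."""
    det = matrix.detected()
    return sorted(matrix.ratios.index[det.sum(axis=1) > min_samples])
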