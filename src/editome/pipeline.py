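"""End-to-end orchestration: SAM in, called editing events out.

Thin glue over the module chain (alignment reading, duplicate collapse,
pileup, candidate scan, filter cascade) plus truth-set scoring used to
validate the cascade on simulated cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as eio
from .catalog import EditingEvent, build_matrix
from .filters import (
    CalledEvent,
    CascadeConfig,
    CascadeResources,
    FunnelReport,
    run_cascade,
)
from .io import GeneModels
from .pileup import build_pileup, collapse_duplicates, scan_candidates
from .simulate import StudyData, TruthSite


def load_secondary_index(
    path: str | Path,
) -> dict[str, tuple[str, str, int, int]]:
    """Index a secondary-aligner SAM by read id -> (chrom, strand, start,
    end). No MAPQ filter: a realigner's job is only to confirm placement."""
    return {
        r.read_id: (r.chrom, r.strand, r.reference_start, r.reference_end)
        for r in eio.read_alignments(path, min_mapq=0)
    }


def detect_sample(
    sam_path: str | Path,
    resources: CascadeResources,
    min_mapq: int = 255,
    cascade: CascadeConfig = CascadeConfig(),
) -> tuple[list[CalledEvent], FunnelReport]:
    """Run the detection chain on one sample's alignments."""
    reads = collapse_duplicates(eio.read_alignments(sam_path, min_mapq=min_mapq))
    pileup = build_pileup(reads, resources.reference)
    candidates = scan_candidates(pileup)
    return run_cascade(candidates, resources, cascade)


def events_to_catalog(
    events: list[CalledEvent],
    sample_id: str,
    tissue: str,
    library_type: str,
    gene_models: GeneModels | None = None,
) -> list[EditingEvent]:
    """Attach sample metadata and gene strand to cascade output events."""
    out = []
    for ev in events:
        strand = None
        if gene_models is not None:
            strands = set(
                gene_models.genes_overlapping(ev.chrom, ev.pos, ev.pos + 1).values()
            )
            if len(strands) == 1:
                strand = strands.pop()
        out.append(
            EditingEvent(
                sample_id=sample_id,
                tissue=tissue,
                library_type=library_type,
                chrom=ev.chrom,
                pos=eio.to_one_based(ev.pos),
                ref_base=ev.ref_base,
                alt_base=ev.alt_base,
                edited_count=ev.edited_count,
                total_count=ev.total_count,
                gene_strand=strand,
            )
        )
    return out


@dataclass
class StudyDetection:
    events: list[EditingEvent]  # all samples pooled
    funnels: dict[str, FunnelReport]

    def matrix(self):
        return build_matrix(self.events)


def study_resources(
    study: StudyData, use_secondary: bool = True, sample: str | None = None
) -> CascadeResources:
    genome = study.genome
    gene_models = GeneModels(
        transcripts={
            g.gene_id + ".t1": g.to_transcript_model() for g in genome.genes
        }
    )
    variants = eio.read_variants(study.outdir / "known_snps.vcf")
    secondary = None
    if use_secondary and sample is not None:
        secondary = load_secondary_index(study.secondary_paths[sample])
    return CascadeResources(
        reference=genome.sequences,
        simple_repeats=genome.simple_repeats,
        gene_models=gene_models,
        excluded_regions=genome.excluded,
        variant_sets=[variants],
        secondary_alignments=secondary,
    )


def detect_study(
    study: StudyData,
    min_mapq: int = 255,
    use_secondary: bool = True,
    cascade: CascadeConfig = CascadeConfig(),
) -> StudyDetection:
    """Run detection over every sample of a simulated study."""
    genome = study.genome
    gene_models = GeneModels(
        transcripts={
            g.gene_id + ".t1": g.to_transcript_model() for g in genome.genes
        }
    )
    variants = eio.read_variants(study.outdir / "known_snps.vcf")
    base = CascadeResources(
        reference=genome.sequences,
        simple_repeats=genome.simple_repeats,
        gene_models=gene_models,
        excluded_regions=genome.excluded,
        variant_sets=[variants],
    )
    library_type = "Y" if study.config.stranded else "N"
    all_events: list[EditingEvent] = []
    funnels: dict[str, FunnelReport] = {}
    for sample in study.cohort.samples:
        res = CascadeResources(
            reference=base.reference,
            simple_repeats=base.simple_repeats,
            gene_models=base.gene_models,
            excluded_regions=base.excluded_regions,
            variant_sets=base.variant_sets,
            secondary_alignments=(
                load_secondary_index(study.secondary_paths[sample])
                if use_secondary
                else None
            ),
        )
        events, funnel = detect_sample(
            study.sam_paths[sample], res, min_mapq=min_mapq, cascade=cascade
        )
        funnels[sample] = funnel
        all_events += events_to_catalog(
            events,
            sample,
            str(study.cohort.tissue.loc[sample]),
            library_type,
            gene_models,
        )
    return StudyDetection(events=all_events, funnels=funnels)


@dataclass
class DetectionScore:
    sensitivity_high_ratio: float  # site-level, true ratio >= 0.2
    per_pair_sensitivity: float  # (site, sample) pairs, true ratio >= 0.2
    n_detected_sites: int
    n_truth_sites: int
    surviving_snps: int
    surviving_decoys: int
    false_positive_calls: int  # calls at positions with no planted feature


def score_detection(
    detection: StudyDetection,
    study: StudyData,
    min_ratio: float = 0.2,
) -> DetectionScore:
    """Score called events against the planted truth.

    Site-level sensitivity: fraction of non-decoy planted sites with
    mean true ratio >= min_ratio that were called in at least one
    sample. Pair-level sensitivity additionally requires the call in
    each individual sample whose true ratio passes the threshold. Any
    call at a planted-SNP or decoy position, and any call elsewhere
    (a sequencing-error artifact), is counted separately.
    """
    truth_pos = {(s.chrom, s.pos + 1): s for s in study.truth}
    snp_pos = {(s.chrom, s.pos + 1) for s in study.decoy_snps}
    sample_index = {s: i for i, s in enumerate(study.cohort.samples)}

    detected_sites: set[tuple[str, int]] = set()
    detected_pairs: set[tuple[str, int, str]] = set()
    surviving_snps = set()
    surviving_decoys = set()
    false_calls = 0
    for ev in detection.events:
        key = (ev.chrom, ev.pos)
        site = truth_pos.get(key)
        if site is not None:
            if site.is_decoy:
                surviving_decoys.add(key)
            else:
                detected_sites.add(key)
                detected_pairs.add((ev.chrom, ev.pos, ev.sample_id))
        elif key in snp_pos:
            surviving_snps.add(key)
        else:
            false_calls += 1

    targets = [
        s
        for s in study.truth
        if not s.is_decoy and float(np.mean(s.per_sample_ratio)) >= min_ratio
    ]
    n_hit = sum(1 for s in targets if (s.chrom, s.pos + 1) in detected_sites)
    pair_total = pair_hit = 0
    for s in targets:
        for sample, i in sample_index.items():
            if s.per_sample_ratio[i] >= min_ratio:
                pair_total += 1
                if (s.chrom, s.pos + 1, sample) in detected_pairs:
                    pair_hit += 1
    return DetectionScore(
        sensitivity_high_ratio=n_hit / len(targets) if targets else float("nan"),
        per_pair_sensitivity=pair_hit / pair_total if pair_total else float("nan"),
        n_detected_sites=len(detected_sites),
        n_truth_sites=len(targets),
        surviving_snps=len(surviving_snps),
        surviving_decoys=len(surviving_decoys),
        false_positive_calls=false_calls,
    )
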