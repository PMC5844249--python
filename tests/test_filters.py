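"""The filter cascade: each region/database/concordance/read-evidence
rule on exact fixtures, plus funnel bookkeeping and truth-set scoring."""

import numpy as np
import pytest

from editome.filters import (
    CalledEvent,
    CascadeConfig,
    CascadeResources,
    FunnelReport,
    concordance_filter,
    database_filter,
    homopolymer_mask,
    read_evidence_filter,
    region_filters,
    run_cascade,
)
from editome.io import GenomicInterval, GeneModels, TranscriptModel, VariantRecord
from editome.pileup import CandidateSite, PileupColumn, ReadBase


def rb(read_id, base, quality=30, dist=20, start=0, end=50, strand="+"):
    return ReadBase(read_id, base, quality, dist, start, end, strand)


def cand(pos, bases, ref="A", alt="G", chrom="chr1"):
    col = PileupColumn(chrom, pos, ref, bases)
    alt_n = sum(1 for b in bases if b.base == alt)
    return CandidateSite(column=col, alt_base=alt, alt_count=alt_n,
                         total_count=len(bases))


def two_supports(pos, **kw):
    return cand(pos, [rb("r1", "G", start=0, end=50),
                      rb("r2", "G", start=5, end=55),
                      rb("r3", "A", start=2, end=52)], **kw)


class TestHomopolymer:
    def test_run_of_five_masks_with_flank(self):
        mask = homopolymer_mask("CCAAAAATT")
        assert mask == {1, 2, 3, 4, 5, 6, 7}  # run 2..6 plus 1 bp flanks

    def test_run_of_four_kept(self):
        assert homopolymer_mask("CCAAAATT") == set()

    def test_n_runs_ignored(self):
        assert homopolymer_mask("NNNNNNN") == set()


def splice_models():
    # one intron (200, 500): boundaries at 200 and 500
    tx = TranscriptModel("t1", "g1", "G1", "protein_coding", "chr1", "+",
                         exons=[(0, 200), (500, 700)])
    return GeneModels(transcripts={"t1": tx})


class TestRegionFilters:
    def resources(self, ref="ACGT" * 250, **kw):
        return CascadeResources(reference={"chr1": ref},
                                gene_models=splice_models(), **kw)

    def test_simple_repeat_removed(self):
        res = self.resources(simple_repeats=[GenomicInterval("chr1", 90, 110)])
        kept, rows = region_filters([two_supports(100), two_supports(150)], res)
        assert [s.pos for s in kept] == [150]
        assert rows[0] == ("simple_repeat", 2, 1)

    def test_homopolymer_site_removed_below_threshold_kept(self):
        ref = "C" * 100 + "AAAAA" + "C" * 100 + "AAAA" + "C" * 100
        res = self.resources(ref=ref)
        in_run = two_supports(102, ref="A")
        in_short = two_supports(207, ref="A")
        kept, rows = region_filters([in_run, in_short], res)
        assert [s.pos for s in kept] == [207]

    def test_splice_window_inclusive_at_5bp(self):
        res = self.resources()
        # boundary at 200: exonic base 195 is 5 bp away -> removed;
        # 194 is 6 bp away -> kept
        kept, _ = region_filters([two_supports(195), two_supports(194)], res)
        assert [s.pos for s in kept] == [194]

    def test_excluded_region_bed(self):
        res = self.resources(
            excluded_regions=[GenomicInterval("chr1", 0, 1000)]
        )
        kept, rows = region_filters([two_supports(100)], res)
        assert kept == [] and rows[-1] == ("excluded_region", 1, 0)


class TestDatabaseFilter:
    def test_position_hit_removed_allele_agnostic(self):
        # database alt T differs from the site's alt G: still removed
        v = [VariantRecord("chr1", 101, "A", "T", "dbtoy")]
        assert database_filter([two_supports(100)], [v]) == []

    def test_empty_databases_identity(self):
        sites = [two_supports(100)]
        assert database_filter(sites, []) == sites

    def test_multiple_sets_union(self):
        v1 = [VariantRecord("chr1", 101, "A", "G", "a")]
        v2 = [VariantRecord("chr1", 201, "A", "G", "b")]
        kept = database_filter([two_supports(100), two_supports(200),
                                two_supports(300)], [v1, v2])
        assert [s.pos for s in kept] == [300]


class TestConcordance:
    def site(self):
        return cand(25, [rb("r1", "G", start=0, end=100),
                         rb("r2", "G", start=0, end=100)])

    def test_identical_intervals_concordant(self):
        sec = {"r1": ("chr1", "+", 0, 100), "r2": ("chr1", "+", 0, 100)}
        out = concordance_filter([self.site()], sec)
        assert len(out) == 1 and out[0].total_count == 2

    def test_different_chrom_discordant(self):
        sec = {"r1": ("chr2", "+", 0, 100), "r2": ("chr2", "+", 0, 100)}
        assert concordance_filter([self.site()], sec) == []

    def test_two_bp_shift_is_098_and_discordant(self):
        # intersection 98 over max length 100 -> 0.98, below the >0.99 bar
        sec = {"r1": ("chr1", "+", 2, 102), "r2": ("chr1", "+", 0, 100)}
        out = concordance_filter([self.site()], sec)
        assert len(out) == 1 and out[0].alt_count == 1

    def test_missing_secondary_alignment_discordant(self):
        out = concordance_filter([self.site()], {"r2": ("chr1", "+", 0, 100)})
        assert out[0].alt_count == 1

    def test_strand_mismatch_discordant(self):
        sec = {"r1": ("chr1", "-", 0, 100), "r2": ("chr1", "-", 0, 100)}
        assert concordance_filter([self.site()], sec) == []


class TestReadEvidence:
    def test_base_quality_19_excluded(self):
        site = cand(10, [rb("r1", "G", quality=19, start=0),
                         rb("r2", "G", quality=20, start=5, end=55),
                         rb("r3", "G", quality=35, start=9, end=59)])
        (ev,) = read_evidence_filter([site])
        assert ev.edited_count == 2  # the q19 read contributes nothing

    def test_distance_6_excluded_strict(self):
        site = cand(10, [rb("r1", "G", dist=6, start=0),
                         rb("r2", "G", dist=7, start=5, end=55),
                         rb("r3", "G", dist=30, start=9, end=59)])
        (ev,) = read_evidence_filter([site])
        assert ev.edited_count == 2

    def test_two_identical_reads_insufficient(self):
        site = cand(10, [rb("r1", "G", start=0, end=50),
                         rb("r2", "G", start=0, end=50)])
        assert read_evidence_filter([site]) == []

    def test_two_nonidentical_reads_suffice(self):
        site = cand(10, [rb("r1", "G", start=0, end=50),
                         rb("r2", "G", start=0, end=50, strand="-")])
        (ev,) = read_evidence_filter([site])
        assert (ev.edited_count, ev.total_count) == (2, 2)

    def test_multi_variant_position_removed_entirely(self):
        bases = [rb("r1", "G", start=0), rb("r2", "G", start=5, end=55),
                 rb("r3", "T", start=9, end=59), rb("r4", "A", start=11, end=61)]
        col = PileupColumn("chr1", 10, "A", bases)
        sites = [CandidateSite(col, "G", 2, 4), CandidateSite(col, "T", 1, 4)]
        assert read_evidence_filter(sites) == []

    def test_multi_variant_ignored_when_second_alt_fails_quality(self):
        bases = [rb("r1", "G", start=0), rb("r2", "G", start=5, end=55),
                 rb("r3", "T", quality=10, start=9, end=59)]
        col = PileupColumn("chr1", 10, "A", bases)
        sites = [CandidateSite(col, "G", 2, 3), CandidateSite(col, "T", 1, 3)]
        (ev,) = read_evidence_filter(sites)
        assert ev.alt_base == "G" and ev.total_count == 2

    def test_ratio_reconstruction_is_exact(self):
        site = cand(10, [rb(f"r{i}", "G", start=i, end=50 + i) for i in range(3)]
                    + [rb("x", "A", start=20, end=70)])
        (ev,) = read_evidence_filter([site])
        assert ev.ratio * ev.total_count == ev.edited_count


class TestFunnel:
    def test_monotonic_and_chained(self):
        f = FunnelReport()
        f.add("a", 10, 8)
        f.add("b", 8, 8)
        with pytest.raises(ValueError):
            f.add("c", 8, 9)
        with pytest.raises(ValueError):
            f.add("d", 7, 6)

    def test_tsv_layout(self):
        f = FunnelReport()
        f.add("a", 3, 2)
        assert f.to_tsv() == "stage\tcandidates_in\tcandidates_out\na\t3\t2\n"


class TestCascade:
    def test_empty_candidates_empty_output(self):
        res = CascadeResources(reference={"chr1": "C" * 100})
        events, funnel = run_cascade([], res)
        assert events == []
        assert all(i == o == 0 for _, i, o in funnel.stages)

    def test_missing_reference_is_config_error(self):
        with pytest.raises(ValueError):
            run_cascade([], CascadeResources(reference={}))

    def test_region_and_database_filters_commute(self, small_study):
        """Both are set intersections, so their order cannot matter."""
        from editome import io as eio
        from editome.pileup import build_pileup, collapse_duplicates, scan_candidates

        sample = small_study.cohort.samples[0]
        reads = collapse_duplicates(
            eio.read_alignments(small_study.sam_paths[sample], min_mapq=255)
        )
        cands = list(
            scan_candidates(build_pileup(reads, small_study.genome.sequences))
        )
        genome = small_study.genome
        models = GeneModels(transcripts={
            g.gene_id + ".t1": g.to_transcript_model() for g in genome.genes
        })
        variants = eio.read_variants(small_study.outdir / "known_snps.vcf")
        res = CascadeResources(
            reference=genome.sequences, simple_repeats=genome.simple_repeats,
            gene_models=models, excluded_regions=genome.excluded,
            variant_sets=[variants],
        )
        ab, _ = region_filters(database_filter(list(cands), [variants]), res)
        ba = database_filter(region_filters(list(cands), res)[0], [variants])
        key = lambda s: (s.chrom, s.pos, s.alt_base)
        assert sorted(map(key, ab)) == sorted(map(key, ba))

    def test_planted_snp_removed_at_database_stage(self, small_study):
        from editome.pipeline import detect_sample, study_resources

        sample = small_study.cohort.samples[0]
        res = study_resources(small_study, use_secondary=True, sample=sample)
        events, funnel = detect_sample(small_study.sam_paths[sample], res)
        stages = dict((s, (i, o)) for s, i, o in funnel.stages)
        snp_dosage = {
            (s.chrom, s.pos): s.dosages[0] for s in small_study.decoy_snps
        }
        carried = sum(1 for k, d in snp_dosage.items() if d > 0)
        n_in, n_out = stages["known_variant"]
        assert n_in - n_out >= min(carried, 1)
        called = {(e.chrom, e.pos) for e in events}
        assert not (called & set(snp_dosage))

    def test_false_calls_bounded_by_coincident_error_probability(self, tmp_path):
        """With edits off, calls can only arise from >=2 coincident errors;
        the observed count must respect the binomial bound at e=0.001."""
        from scipy import stats

        from editome.pipeline import detect_study
        from editome.simulate import SimConfig, simulate_study

        config = SimConfig(seed=13, n_samples=3, base_ratio_range=(0.02, 0.021))
        study = simulate_study(config, tmp_path / "nulls")
        for site in study.truth:  # silence all edits: error-only dataset
            site.per_sample_ratio = np.zeros_like(site.per_sample_ratio)
        # regenerate alignments with the silenced edits
        from editome.simulate import make_secondary_reads, simulate_sample_reads, write_sam

        rng = np.random.default_rng(99)
        for i, sample in enumerate(study.cohort.samples):
            reads = simulate_sample_reads(
                study.genome, study.truth, study.decoy_snps, i, config, rng
            )
            sec, _ = make_secondary_reads(reads, config, rng)
            write_sam(reads, study.genome, study.sam_paths[sample], config)
            write_sam(sec, study.genome, study.secondary_paths[sample], config)
        det = detect_study(study)
        e = config.error_rate
        depth = config.depth_mean
        # per position/alt: P(>=2 errors to one base among `depth` reads)
        p_one = (e / 3) * (1 - (CascadeConfig().min_dist5p + 1) / config.read_length)
        p_site = 3 * (1 - stats.binom.cdf(1, int(depth * 1.5), p_one))
        covered = 3 * 20_000  # generous per-sample covered-position bound
        lam = covered * p_site * len(study.cohort.samples)
        bound = stats.poisson.ppf(0.999, lam) + 3
        assert len(det.events) <= bound
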