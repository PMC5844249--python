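"""Typing, quantification and summary statistics of called editing events.

A-to-I editing is read out as an A→G mismatch on the edited strand.
With a strand-specific library the transcript strand is known and the
twelve base changes are distinguished; without strand information each
change is merged with its reverse complement into six classes, the
canonical one labeled ``A-to-G(I)``. The noncanonical classes act as an
error proxy: the ratio of an error-only class to the canonical class
estimates the false discovery rate of the calling pipeline.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CatalogRow

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: the twelve ordered base changes
MISMATCH_TYPES = [
    f"{a}-to-{b}" for a in "ACGT" for b in "ACGT" if a != b
]

#: canonical A-to-I class label in unstranded (merged) mode
CANONICAL_UNSTRANDED = "A-to-G(I)"


def _merge_label(ref: str, alt: str) -> str:
    """Merged complement-class label for unstranded data.

    Each change pools with its reverse complement; the class is labeled
    by its alphabetically first member, except the canonical A-to-G/T-to-C
    class which is labeled A-to-G(I).
    """
    rc_ref = ref.translate(_COMPLEMENT)
    rc_alt = alt.translate(_COMPLEMENT)
    a, b = sorted([(ref, alt), (rc_ref, rc_alt)])[0]
    if (a, b) == ("A", "G"):
        return CANONICAL_UNSTRANDED
    return f"{a}-to-{b}"


def classify_event(
    ref_base: str,
    alt_base: str,
    library_type: str,
    gene_strand: str | None = None,
) -> str:
    """Classify a mismatch as one of the twelve changes or a merged class.

    Strand-specific libraries (``library_type='Y'``) report the change on
    the transcript strand: for a site inside a minus-strand gene the
    genomic bases are complemented first, so a genomic T→C in a minus-
    strand gene is reported as A-to-G. Non-strand-specific libraries
    (``'N'``) merge each change with its reverse complement.
    """
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if ref_base == alt_base:
        raise ValueError("ref and alt bases must differ")
    if ref_base not in "ACGT" or alt_base not in "ACGT":
        raise ValueError(f"invalid bases {ref_base!r}->{alt_base!r}")
    if library_type == "N":
        return _merge_label(ref_base, alt_base)
    if library_type != "Y":
        raise ValueError("library_type must be 'Y' or 'N'")
    if gene_strand == "-":
        ref_base = ref_base.translate(_COMPLEMENT)
        alt_base = alt_base.translate(_COMPLEMENT)
    return f"{ref_base}-to-{alt_base}"


@dataclass
class EditingEvent:
    """One called editing event in one sample, user-facing coordinates."""

    sample_id: str
    tissue: str
    library_type: str  # Y (strand-specific) | N
    chrom: str
    pos: int  # 1-based
    ref_base: str
    alt_base: str
    edited_count: int
    total_count: int
    gene_strand: str | None = None

    def __post_init__(self):
        if not (2 <= self.edited_count <= self.total_count):
            raise ValueError(
                "calling criteria require 2 <= edited_count <= total_count"
            )

    @property
    def ratio(self) -> float:
        return self.edited_count / self.total_count

    @property
    def mismatch_type(self) -> str:
        return classify_event(
            self.ref_base, self.alt_base, self.library_type, self.gene_strand
        )

    @property
    def site_key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.mismatch_type)


@dataclass
class MismatchSpectrum:
    """Counts of editing calls per mismatch type (redundant over samples)."""

    counts: Counter = field(default_factory=Counter)
    mode: str = "stranded"  # stranded | unstranded

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def proportions(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {}
        return {k: v / total for k, v in sorted(self.counts.items())}


def mismatch_spectrum(events: Iterable[EditingEvent]) -> MismatchSpectrum:
    """Tally events per mismatch type. Events must share a library mode;
    sites found in several samples count once per sample (redundant)."""
    counts: Counter = Counter()
    modes = set()
    for ev in events:
        modes.add(ev.library_type)
        counts[ev.mismatch_type] += 1
    if len(modes) > 1:
        raise ValueError("events mix strand-specific and non-strand-specific data")
    mode = "unstranded" if modes == {"N"} else "stranded"
    return MismatchSpectrum(counts=counts, mode=mode)


def estimate_fdr(spectrum: MismatchSpectrum | Mapping[str, int]) -> float:
    """Proxy false discovery rate from an error-only mismatch class.

    Strand-specific: G-to-A events cannot arise from A-to-I editing on
    either strand, so FDR = count(G-to-A) / count(A-to-G). Non-strand-
    specific: the merged C-to-G/G-to-C class plays that role, so FDR =
    count(G-to-C class) / count(A-to-G(I)). Returns a fraction; NaN (with
    a warning) when the canonical class is empty.
    """
    if isinstance(spectrum, MismatchSpectrum):
        counts, mode = spectrum.counts, spectrum.mode
    else:
        counts = dict(spectrum)
        mode = "unstranded" if CANONICAL_UNSTRANDED in counts else "stranded"
    if mode == "stranded":
        num = counts.get("G-to-A", 0)
        den = counts.get("A-to-G", 0)
    else:
        num = counts.get("C-to-G", 0) + counts.get("G-to-C", 0)
        den = counts.get(CANONICAL_UNSTRANDED, 0)
    if den == 0:
        warnings.warn("proxy-FDR undefined: no canonical events", stacklevel=2)
        return float("nan")
    return num / den


@dataclass
class ReproducibilityResult:
    jaccard: float
    frac_a: float  # shared / sites in sample a
    frac_b: float
    n_shared: int
    spearman: float  # NaN when fewer than 3 shared sites


def reproducibility(
    events_a: Iterable[EditingEvent], events_b: Iterable[EditingEvent]
) -> ReproducibilityResult:
    """Overlap and ratio concordance between two near-replicate samples.

    The overlap is reported as Jaccard |shared|/|union| (default report)
    plus the two per-sample fractions; ratio stability is the Spearman
    correlation of editing ratios over shared sites (NaN below 3 shared).
    """
    ra = {ev.site_key: ev.ratio for ev in events_a}
    rb = {ev.site_key: ev.ratio for ev in events_b}
    shared = sorted(set(ra) & set(rb))
    union = set(ra) | set(rb)
    jac = len(shared) / len(union) if union else float("nan")
    fa = len(shared) / len(ra) if ra else float("nan")
    fb = len(shared) / len(rb) if rb else float("nan")
    if len(shared) >= 3:
        rho = stats.spearmanr([ra[k] for k in shared], [rb[k] for k in shared]).statistic
    else:
        rho = float("nan")
    return ReproducibilityResult(jac, fa, fb, len(shared), float(rho))


def accumulation_curve(
    sites_by_sample: Mapping[str, set],
    order: Sequence[str] | None = None,
    n_orders: int = 0,
    seed: int = 0,
) -> np.ndarray:
    """Cumulative number of unique sites as samples are added.

    With ``n_orders`` > 0 the curve is averaged over that many random
    sample orders drawn from a seeded generator; otherwise the given (or
    sorted) order is used. The curve is nondecreasing and ends at the
    total number of unique sites.
    """
    samples = list(order) if order is not None else sorted(sites_by_sample)
    if n_orders <= 0:
        seen: set = set()
        out = []
        for s in samples:
            seen |= sites_by_sample[s]
            out.append(len(seen))
        return np.asarray(out, dtype=float)
    rng = np.random.default_rng(seed)
    acc = np.zeros(len(samples))
    for _ in range(n_orders):
        perm = [samples[i] for i in rng.permutation(len(samples))]
        acc += accumulation_curve(sites_by_sample, order=perm)
    return acc / n_orders


@dataclass
class EditingMatrix:
    """Sites x samples editing-ratio matrix with per-cell support counts.

    ``ratios`` holds NaN where a site was not detected in a sample;
    stored cells lie in (0, 1]. ``support`` holds the edited-read count
    behind each stored ratio. ``tissue`` maps sample id -> tissue label.
    Site index labels are '<chrom>:<pos1>:<class>' strings.
    """

    ratios: pd.DataFrame
    support: pd.DataFrame
    tissue: pd.Series
    site_meta: pd.DataFrame  # index as ratios; columns chrom, pos, mismatch_type

    def detected(self) -> pd.DataFrame:
        return self.ratios.notna() & (self.ratios > 0)

    def n_samples_detected(self) -> pd.Series:
        return self.detected().sum(axis=1)


def build_matrix(events: Iterable[EditingEvent]) -> EditingMatrix:
    """Assemble the sites x samples ratio matrix from per-sample events."""
    cells: dict[tuple[str, str], tuple[float, int]] = {}
    meta: dict[str, tuple[str, int, str]] = {}
    tissues: dict[str, str] = {}
    for ev in events:
        key = f"{ev.chrom}:{ev.pos}:{ev.mismatch_type}"
        meta[key] = (ev.chrom, ev.pos, ev.mismatch_type)
        tissues[ev.sample_id] = ev.tissue
        cells[(key, ev.sample_id)] = (ev.ratio, ev.edited_count)
    sites = sorted(meta)
    samples = sorted(tissues)
    ratios = pd.DataFrame(np.nan, index=sites, columns=samples)
    support = pd.DataFrame(0, index=sites, columns=samples)
    for (site, sample), (ratio, edited) in cells.items():
        ratios.loc[site, sample] = ratio
        support.loc[site, sample] = edited
    site_meta = pd.DataFrame(
        [meta[s] for s in sites],
        index=sites,
        columns=["chrom", "pos", "mismatch_type"],
    )
    return EditingMatrix(
        ratios=ratios,
        support=support,
        tissue=pd.Series(tissues).loc[samples],
        site_meta=site_meta,
    )


def tissue_specificity(
    matrix: EditingMatrix, robust_sites: Sequence[str] | None = None
) -> float:
    """Fraction of sites detected in exactly one tissue.

    A site counts as detected in a tissue when at least one sample of
    that tissue carries a non-zero ratio. ``robust_sites`` optionally
    restricts the computation, e.g. to sites in genes with median RPKM
    above a threshold, to control for expression differences.
    """
    det = matrix.detected()
    if robust_sites is not None:
        det = det.loc[[s for s in det.index if s in set(robust_sites)]]
    tissues = matrix.tissue
    if tissues.nunique() < 2:
        raise ValueError("tissue specificity needs at least two tissues")
    per_tissue = det.T.groupby(tissues).any().T  # sites x tissues
    n_tissues = per_tissue.sum(axis=1)
    informative = n_tissues > 0
    if not informative.any():
        return float("nan")
    return float((n_tissues[informative] == 1).mean())


def aggregate_catalog(events: Iterable[EditingEvent]) -> list[CatalogRow]:
    """Aggregate per-sample events into catalog rows keyed by (tissue,
    library type, chrom, pos, DNA base, RNA base), counting samples."""
    samples: dict[tuple, set] = defaultdict(set)
    for ev in events:
        key = (ev.tissue, ev.library_type, ev.chrom, ev.pos, ev.ref_base, ev.alt_base)
        samples[key].add(ev.sample_id)
    return [
        CatalogRow(
            tissue=t, library_type=lt, chrom=c, pos=p, dna_base=d, rna_base=r,
            n_samples=len(ss),
        )
        for (t, lt, c, p, d, r), ss in sorted(samples.items())
    ]
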