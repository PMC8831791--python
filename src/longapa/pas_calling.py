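"""Gene assignment, 3'-end histograms, PAS peak calling, APA summary, metagene.

A polyadenylation/cleavage site (PAS) is called as a peak of read 3'-end
counts within a gene: a local maximum of height >= ``min_height`` (default
4 reads ending at the same nucleotide), with peaks closer than
``min_distance`` (default 18 nt) to an already-accepted higher peak
suppressed. The contract is fully deterministic: plateaus yield a single
candidate at the floor-midpoint, ties in height are broken toward the
smaller coordinate, and suppression is greedy in descending height.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .genome_model import AlignedRead, GenomeAnnotation, three_prime_end

logger = logging.getLogger(__name__)

DEFAULT_MIN_HEIGHT = 4
DEFAULT_MIN_DISTANCE = 18


@dataclass
class ThreePrimeHistogram:
    """Sparse per-gene counts of read 3'-end positions.

    Carries the gene span and strand so peak calling and metagene
    anchoring need no annotation lookup.
    """

    gene_id: str
    start: int
    end: int
    strand: str
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total_ends(self) -> int:
        return sum(self.counts.values())

    def add(self, pos: int) -> None:
        self.counts[pos] = self.counts.get(pos, 0) + 1


@dataclass
class PasCall:
    gene_id: str
    position: int
    height: int
    rank: int


@dataclass
class PasSummary:
    per_gene_counts: dict[str, int]
    count_histogram: dict[int, int]
    frac_multi_pas: float
    frac_gt2_pas: float
    n_genes: int
    n_genes_no_peak: int = 0


@dataclass
class MetageneProfile:
    window: int
    density: dict[int, float]
    n_genes: int


def assign_read_to_gene(
    read: AlignedRead, annotation: GenomeAnnotation, min_read_frac: float = 0.25
) -> Optional[str]:
    """Assign a read to the same-strand gene covering >= ``min_read_frac``
    of the read's aligned hull; largest overlap wins, ties to the gene with
    the smaller start coordinate."""
    rs, re = read.span
    rlen = re - rs
    best: Optional[tuple[int, int, str]] = None  # (-overlap, start, gene_id)
    for g in annotation.genes_on(read.chrom):
        if g.strand != read.strand:
            continue
        ov = min(re, g.end) - max(rs, g.start)
        if ov <= 0 or ov < min_read_frac * rlen:
            continue
        key = (-ov, g.start, g.gene_id)
        if best is None or key < best:
            best = key
    return best[2] if best else None


def build_histograms(
    reads: Iterable[AlignedRead],
    annotation: GenomeAnnotation,
    min_read_frac: float = 0.25,
) -> list[ThreePrimeHistogram]:
    """Per-gene 3'-end histograms over assigned reads.

    Genes with zero assigned reads yield no histogram. Reads that fail
    assignment, or whose 3' end falls outside the assigned gene span, are
    tallied in a log summary.
    """
    hists: dict[str, ThreePrimeHistogram] = {}
    n_unassigned = 0
    n_outside = 0
    for read in reads:
        gid = assign_read_to_gene(read, annotation, min_read_frac)
        if gid is None:
            n_unassigned += 1
            continue
        g = annotation.gene(gid)
        pos = three_prime_end(read)
        if not (g.start <= pos < g.end):
            n_outside += 1
            continue
        h = hists.get(gid)
        if h is None:
            h = hists[gid] = ThreePrimeHistogram(gid, g.start, g.end, g.strand)
        h.add(pos)
    if n_unassigned or n_outside:
        logger.info(
            "build_histograms: %d reads unassigned, %d 3'-ends outside gene span",
            n_unassigned,
            n_outside,
        )
    order = {g.gene_id: i for i, g in enumerate(annotation.genes)}
    return sorted(hists.values(), key=lambda h: order[h.gene_id])


def call_pas_peaks(
    hist: ThreePrimeHistogram,
    min_height: int = DEFAULT_MIN_HEIGHT,
    min_distance: int = DEFAULT_MIN_DISTANCE,
) -> list[PasCall]:
    """Call PAS peaks from a 3'-end histogram.

    Candidates are local maxima of the dense count vector over the gene
    span with count >= ``min_height``; a plateau (maximal run of equal
    counts bounded by strictly smaller values or the span edges) yields one
    candidate at its floor-midpoint. Candidates are processed in descending
    height (ties: smaller coordinate) and greedily accepted if at distance
    >= ``min_distance`` from every already-accepted peak; ranks follow the
    acceptance order.
    """
    n = hist.end - hist.start
    v = np.zeros(n, dtype=np.int64)
    for pos, c in hist.counts.items():
        v[pos - hist.start] = c

    candidates: list[tuple[int, int]] = []  # (offset, height)
    i = 0
    while i < n:
        j = i + 1
        while j < n and v[j] == v[i]:
            j += 1
        if v[i] >= min_height:
            left_ok = i == 0 or v[i - 1] < v[i]
            right_ok = j == n or v[j] < v[i]
            if left_ok and right_ok:
                candidates.append(((i + j - 1) // 2, int(v[i])))
        i = j

    candidates.sort(key=lambda c: (-c[1], c[0]))
    accepted: list[tuple[int, int]] = []
    for off, h in candidates:
        if all(abs(off - q) >= min_distance for q, _ in accepted):
            accepted.append((off, h))

    return [
        PasCall(hist.gene_id, hist.start + off, h, rank)
        for rank, (off, h) in enumerate(accepted, start=1)
    ]


def call_all_peaks(
    histograms: Iterable[ThreePrimeHistogram],
    min_height: int = DEFAULT_MIN_HEIGHT,
    min_distance: int = DEFAULT_MIN_DISTANCE,
) -> dict[str, list[PasCall]]:
    return {
        h.gene_id: call_pas_peaks(h, min_height, min_distance) for h in histograms
    }


def summarize_apa(
    calls_by_gene: Mapping[str, list[PasCall]],
) -> PasSummary:
    """Per-gene peak-count histogram and the fractions of genes with more
    than one and more than two PAS.

    Genes with zero called peaks (insufficient depth) are excluded from the
    fraction denominators and reported separately.
    """
    per_gene = {gid: len(calls) for gid, calls in calls_by_gene.items()}
    detected = {gid: k for gid, k in per_gene.items() if k > 0}
    histo: dict[int, int] = {}
    for k in per_gene.values():
        histo[k] = histo.get(k, 0) + 1
    n = len(detected)
    frac_multi = sum(1 for k in detected.values() if k > 1) / n if n else float("nan")
    frac_gt2 = sum(1 for k in detected.values() if k > 2) / n if n else float("nan")
    return PasSummary(
        per_gene_counts=per_gene,
        count_histogram=dict(sorted(histo.items())),
        frac_multi_pas=frac_multi,
        frac_gt2_pas=frac_gt2,
        n_genes=n,
        n_genes_no_peak=len(per_gene) - n,
    )


def metagene_profile(
    histograms: Iterable[ThreePrimeHistogram],
    calls_by_gene: Mapping[str, list[PasCall]],
    window: int = 50,
) -> MetageneProfile:
    """Transcript-oriented 3'-end density around each gene's primary peak.

    Each gene with at least one called peak contributes its 3'-end counts
    normalized by total_ends, placed at offset (position - primary) in
    transcript orientation (sign flipped on '-'), summed over genes.
    Offsets outside +/-window are dropped, so a gene's contributed mass is
    <= 1 and equals 1 when the window covers all of its ends.
    """
    density: dict[int, float] = {k: 0.0 for k in range(-window, window + 1)}
    n_genes = 0
    for h in histograms:
        calls = calls_by_gene.get(h.gene_id, [])
        if not calls:
            continue
        n_genes += 1
        primary = next(c.position for c in calls if c.rank == 1)
        total = h.total_ends
        sign = 1 if h.strand == "+" else -1
        for pos, c in h.counts.items():
            off = sign * (pos - primary)
            if -window <= off <= window:
                density[off] += c / total
    return MetageneProfile(window=window, density=density, n_genes=n_genes)
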