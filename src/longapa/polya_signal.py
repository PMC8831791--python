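"""PolyA-signal discovery: upstream windows, k-mer enrichment, UAAA distance.

The polyA signal in this system is the tetranucleotide UAAA located a few
to a few dozen nucleotides upstream of the cleavage site. Motif discovery
is an exhaustive k-mer containment scan (k = 4..6 by default) against a
mononucleotide-shuffle background — for a 4-nt motif, exhaustive counting
is complete and deterministic where heuristic motif suites are not.

Window sequences are sense-strand RNA (T -> U), ending 1 nt upstream of
the cleavage position, so the motif is searched literally as "UAAA".
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .genome_model import GenomeAnnotation, revcomp
from .pas_calling import PasCall, ThreePrimeHistogram

SIGNAL = "UAAA"


class MotifError(ValueError):
    pass


@dataclass
class UpstreamWindow:
    gene_id: str
    pas_rank: int
    sequence: str  # sense-strand RNA, 3' end of window abuts the cleavage site
    truncated: bool = False


@dataclass
class MotifReport:
    k: int
    motif: str
    n_containing: int
    fraction: float
    enrichment: float  # log2 fold over shuffle background


@dataclass
class SignalDistance:
    gene_id: str
    distance: int  # nt strictly between the last signal base and the cleavage site


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def extract_upstream_windows(
    calls_by_gene: Mapping[str, list[PasCall]],
    histograms: Iterable[ThreePrimeHistogram],
    genome: Mapping[str, str],
    annotation: GenomeAnnotation,
    rank: int = 1,
    n_top: int = 500,
    width: int = 40,
) -> list[UpstreamWindow]:
    """Sense-strand windows of ``width`` nt immediately upstream of the
    rank-th PAS peak, for the ``n_top`` most expressed eligible genes.

    Expression is proxied by total assigned 3'-end count. Genes lacking a
    peak of the requested rank are skipped. Windows truncated by the
    chromosome (or '+'-strand origin) boundary are flagged.
    """
    hist_by_gene = {h.gene_id: h for h in histograms}
    eligible: list[tuple[int, str, PasCall]] = []
    for gid, calls in calls_by_gene.items():
        call = next((c for c in calls if c.rank == rank), None)
        if call is None or gid not in hist_by_gene:
            continue
        eligible.append((hist_by_gene[gid].total_ends, gid, call))
    # most expressed first; gene_id tie-break for determinism
    eligible.sort(key=lambda t: (-t[0], t[1]))

    windows: list[UpstreamWindow] = []
    for _total, gid, call in eligible[:n_top]:
        gene = annotation.gene(gid)
        seq = genome[gene.chrom]
        p = call.position
        if gene.strand == "+":
            lo = max(0, p - width)
            sense = seq[lo:p]
            truncated = p - width < 0
        else:
            hi = min(len(seq), p + 1 + width)
            sense = revcomp(seq[p + 1 : hi])
            truncated = p + 1 + width > len(seq)
        windows.append(UpstreamWindow(gid, rank, _to_rna(sense), truncated))
    return windows


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def kmer_enrichment(
    windows: Sequence[UpstreamWindow | str],
    k_range: tuple[int, int] = (4, 6),
    background: str = "shuffle",
    n_shuffles: int = 100,
    seed: int | np.random.Generator | None = 0,
    top_n: int = 10,
) -> list[MotifReport]:
    """Exhaustive k-mer containment enrichment over upstream windows.

    For every k-mer of each k in ``k_range`` (inclusive), the foreground
    fraction is the share of windows containing >= 1 occurrence; the
    background fraction is the mean containment over ``n_shuffles``
    mononucleotide-preserving shuffles of each window. Enrichment is
    log2((f + eps) / (bg + eps)) with eps = 1/(2 * n_windows). Reported:
    the ``top_n`` k-mers per k by enrichment, plus any k-mer contained in
    >= 50% of windows; sorted by enrichment descending.
    """
    seqs = [w.sequence if isinstance(w, UpstreamWindow) else w for w in windows]
    if len(seqs) < 10:
        raise MotifError(f"kmer_enrichment: need >= 10 windows, got {len(seqs)}")
    if background != "shuffle":
        raise MotifError(f"unknown background model {background!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ks = list(range(k_range[0], k_range[1] + 1))
    n_windows = len(seqs)
    eps = 1.0 / (2 * n_windows)

    fg: dict[int, Counter] = {k: Counter() for k in ks}
    for s in seqs:
        for k in ks:
            fg[k].update(_kmer_set(s, k))

    bg: dict[int, Counter] = {k: Counter() for k in ks}
    arrays = [np.frombuffer(s.encode(), dtype="S1") for s in seqs]
    for _ in range(n_shuffles):
        for arr in arrays:
            shuf = rng.permutation(arr).tobytes().decode()
            for k in ks:
                bg[k].update(_kmer_set(shuf, k))

    reports: list[MotifReport] = []
    for k in ks:
        rows = []
        for motif, n_cont in fg[k].items():
            frac = n_cont / n_windows
            bg_frac = bg[k][motif] / (n_shuffles * n_windows)
            enr = float(np.log2((frac + eps) / (bg_frac + eps)))
            rows.append(MotifReport(k, motif, n_cont, frac, enr))
        rows.sort(key=lambda r: (-r.enrichment, r.motif))
        keep = rows[:top_n] + [r for r in rows[top_n:] if r.fraction >= 0.5]
        reports.extend(keep)
    reports.sort(key=lambda r: (-r.enrichment, r.k, r.motif))
    return reports


def signal_distance(
    window: UpstreamWindow, match_policy: str = "proximal"
) -> Optional[SignalDistance]:
    """Distance from the UAAA signal to the cleavage site, or None.

    The distance counts nucleotides strictly between the last base of UAAA
    and the cleavage position (the window ends 1 nt upstream of it, so a
    signal flush with the window 3' end has distance 0). ``match_policy``
    'proximal' (default) uses the occurrence closest to the cleavage site;
    'first' uses the leftmost (window 5' end) occurrence.
    """
    s = window.sequence
    if match_policy == "proximal":
        idx = s.rfind(SIGNAL)
    elif match_policy == "first":
        idx = s.find(SIGNAL)
    else:
        raise MotifError(f"unknown match_policy {match_policy!r}")
    if idx < 0:
        return None
    return SignalDistance(window.gene_id, len(s) - (idx + len(SIGNAL)))


@dataclass
class DistanceHistogram:
    counts: dict[int, int]
    mean: float
    min: int
    max: int
    n: int


def distance_histogram(distances: Iterable[SignalDistance | int]) -> DistanceHistogram:
    vals = [d.distance if isinstance(d, SignalDistance) else int(d) for d in distances]
    if not vals:
        raise MotifError("distance_histogram: empty input")
    counts: dict[int, int] = {}
    for v in vals:
        counts[v] = counts.get(v, 0) + 1
    return DistanceHistogram(
        counts=dict(sorted(counts.items())),
        mean=float(np.mean(vals)),
        min=min(vals),
        max=max(vals),
        n=len(vals),
    )
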