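"""Synthetic genome, annotation, and pre-aligned long reads with known truth.

The generator emulates the structure of a polyA-selected long-read dataset
from a compact, intron-poor genome: each gene carries 1-4 weighted
cleavage sites (PAS) in its 3'UTR, a UAAA signal planted a known distance
upstream of most PAS (sense strand), a small set of intron-containing
genes with per-intron retention probabilities (GU..AG introns with a
GUAAGU-like donor and a planted branchpoint adenosine), and log-normal
expression. Reads are emitted pre-aligned (the truth alignment): read 3'
ends are the sampled PAS plus discretized Gaussian jitter, spliced reads
gap exactly at intron boundaries, and every read on an intron gene spans
its intron.

Every quantity the downstream stages estimate (PAS positions and weights,
signal distances, retention, expression) is recorded in :class:`SimTruth`,
so each stage is testable by parameter recovery.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np

from .genome_model import (
    AlignedRead,
    GeneModel,
    GenomeAnnotation,
    IntronModel,
    revcomp,
)

DNA = np.array(list("ACGT"))
SIGNAL_DNA = "TAAA"  # UAAA on the transcript


class SimulationError(ValueError):
    pass


def truncated_geometric_pmf(
    mean: float = 17.0, lo: int = 3, hi: int = 35
) -> dict[int, float]:
    """Discrete distribution on [lo, hi] with pmf proportional to r**(d-lo),
    with r solved by bisection so the mean matches ``mean``.

    The default (mean 17 on 3..35) is a right-skewed stand-in for the
    observed signal-to-cleavage spacing: bounded range with a short modal
    distance and a long tail.
    """
    d = np.arange(lo, hi + 1, dtype=float)
    uniform_mean = (lo + hi) / 2.0
    if not lo < mean < uniform_mean:
        raise SimulationError(f"mean must lie in ({lo}, {uniform_mean})")

    def mean_for(r: float) -> float:
        w = r ** (d - lo)
        return float((d * w).sum() / w.sum())

    lo_r, hi_r = 1e-9, 1.0 - 1e-9
    for _ in range(200):
        mid = 0.5 * (lo_r + hi_r)
        if mean_for(mid) < mean:
            lo_r = mid
        else:
            hi_r = mid
    r = 0.5 * (lo_r + hi_r)
    w = r ** (d - lo)
    w /= w.sum()
    return {int(k): float(p) for k, p in zip(d, w)}


def uniform_distance_pmf(lo: int = 3, hi: int = 35) -> dict[int, float]:
    p = 1.0 / (hi - lo + 1)
    return {d: p for d in range(lo, hi + 1)}


@dataclass
class SimConfig:
    """Generator settings. Defaults are the study conditions the package
    is exercised under: most genes multi-PAS (63% > 1, 34% > 2), UAAA
    planted for 93% of sites at 3-35 nt (mean 17) upstream, 26 single-intron
    genes with retention 0.1-0.9, log-normal expression."""

    n_genes: int = 100
    gene_length_range: tuple[int, int] = (800, 2000)
    frac_genes_with_k_pas: dict[int, float] = field(
        default_factory=lambda: {1: 0.37, 2: 0.29, 3: 0.34}
    )
    pas_min_separation: int = 25
    pas_weight_floor: float = 0.10
    signal_distance_dist: dict[int, float] = field(
        default_factory=truncated_geometric_pmf
    )
    signal_plant_rate: float = 0.93
    end_jitter_sd: float = 2.0
    n_intron_genes: int = 26
    intron_length_range: tuple[int, int] = (60, 300)
    retention_prob_range: tuple[float, float] = (0.1, 0.9)
    expression_sigma: float = 1.0  # log-normal shape (log-scale sd)
    reads_total: int = 20000
    gc: float = 0.55
    utr3_length: int = 200
    intergenic: int = 150
    mask_spurious_signal: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.frac_genes_with_k_pas.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(
                f"frac_genes_with_k_pas sums to {total}, expected 1"
            )
        if any(k not in (1, 2, 3, 4) for k in self.frac_genes_with_k_pas):
            raise SimulationError("PAS counts per gene must be in 1..4")
        recommended = 18 + 2 * (3 * self.end_jitter_sd)
        if self.pas_min_separation < recommended:
            warnings.warn(
                f"pas_min_separation={self.pas_min_separation} < recommended "
                f"{recommended:.0f} for jitter sd {self.end_jitter_sd}; "
                "adjacent true PAS may merge under the peak caller",
                stacklevel=2,
            )
        if self.n_intron_genes > self.n_genes:
            raise SimulationError("n_intron_genes > n_genes")


@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    strand: str
    pas_positions: list[int]  # genomic, primary (highest weight) first
    pas_weights: list[float]
    signal_distances: list[Optional[int]]  # per PAS; None = not planted
    expression_weight: float
    expected_reads: float


@dataclass
class IntronTruth:
    intron_id: str
    gene_id: str
    retention_prob: float


@dataclass
class SimTruth:
    genes: dict[str, GeneTruth]
    introns: dict[str, IntronTruth]

    def to_json(self, path) -> None:
        payload = {
            "genes": {k: asdict(v) for k, v in self.genes.items()},
            "introns": {k: asdict(v) for k, v in self.introns.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            genes={k: GeneTruth(**v) for k, v in payload["genes"].items()},
            introns={k: IntronTruth(**v) for k, v in payload["introns"].items()},
        )


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.arange(4), size=n, p=p)


def _draw_separated_positions(
    rng: np.random.Generator, lo: int, hi: int, k: int, min_sep: int
) -> list[int]:
    """k integers in [lo, hi) pairwise >= min_sep apart (rejection sampling)."""
    if hi - lo < (k - 1) * min_sep + 1:
        raise SimulationError(
            f"PAS placement range {hi - lo} nt cannot hold {k} sites "
            f"{min_sep} nt apart; enlarge utr3_length"
        )
    for _ in range(10_000):
        pos = sorted(int(x) for x in rng.integers(lo, hi, size=k))
        if all(b - a >= min_sep for a, b in zip(pos, pos[1:])):
            return pos
    raise SimulationError("failed to place separated PAS positions")


def _mask_spurious_signal(
    sense: list[str], window_lo: int, window_hi: int, protected: set[int]
) -> None:
    """Rewrite non-planted TAAA occurrences inside [window_lo, window_hi)
    of the sense sequence by T->G (cannot create a new occurrence)."""
    changed = True
    while changed:
        changed = False
        segment = "".join(sense[window_lo:window_hi])
        idx = segment.find(SIGNAL_DNA)
        while idx != -1:
            start = window_lo + idx
            if start not in protected:
                sense[start] = "G"
                changed = True
                break
            idx = segment.find(SIGNAL_DNA, idx + 1)


def simulate_genome(
    cfg: SimConfig,
) -> tuple[dict[str, str], GenomeAnnotation, SimTruth]:
    """Build the toy genome: random background at the configured GC, genes
    laid head-to-tail on alternating random strands, PAS + signals + introns
    planted per config, truth recorded.

    Returns (genome as chrom -> sequence dict, annotation, truth); use
    :func:`genome_to_fasta` / :func:`write_outputs` to serialize.
    """
    rng = np.random.default_rng(cfg.seed)
    chrom = "chr1"

    min_len = cfg.utr3_length + 60  # 3'UTR plus 5' gene body margin
    if cfg.n_intron_genes > 0:
        min_len = cfg.utr3_length + cfg.intron_length_range[1] + 170
    if cfg.gene_length_range[0] < min_len:
        raise SimulationError(
            f"gene_length_range[0]={cfg.gene_length_range[0]} too small for the "
            f"internal gene layout; needs >= {min_len}"
        )
    glens = [
        int(rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1))
        for _ in range(cfg.n_genes)
    ]

    chrom_len = cfg.intergenic * (cfg.n_genes + 1) + sum(glens) + 100
    seq = DNA[_random_seq(chrom_len, cfg.gc, rng)].tolist()

    k_values = sorted(cfg.frac_genes_with_k_pas)
    k_probs = np.array([cfg.frac_genes_with_k_pas[k] for k in k_values])
    dist_vals = np.array(sorted(cfg.signal_distance_dist))
    dist_probs = np.array(
        [cfg.signal_distance_dist[int(d)] for d in dist_vals]
    )
    dist_probs = dist_probs / dist_probs.sum()

    intron_gene_idx = set(range(cfg.n_intron_genes))  # first genes carry introns
    expr = rng.lognormal(0.0, cfg.expression_sigma, size=cfg.n_genes)
    expr /= expr.sum()

    genes: list[GeneModel] = []
    gene_truths: dict[str, GeneTruth] = {}
    intron_truths: dict[str, IntronTruth] = {}
    cursor = cfg.intergenic

    for gi in range(cfg.n_genes):
        L = glens[gi]
        s, e = cursor, cursor + L
        cursor = e + cfg.intergenic
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"G{gi:04d}"

        # work in transcript coordinates on a sense copy of the gene
        sense = [
            seq[s + t] if strand == "+" else revcomp(seq[e - 1 - t])
            for t in range(L)
        ]

        utr_len = cfg.utr3_length
        utr_t = (L - utr_len, L)

        introns: list[IntronModel] = []
        if gi in intron_gene_idx:
            ilen = int(
                rng.integers(cfg.intron_length_range[0], cfg.intron_length_range[1] + 1)
            )
            ti_s = int(rng.integers(100, L - utr_len - ilen - 60))
            ti_e = ti_s + ilen
            # donor consensus, acceptor AG, branchpoint CUAAC context
            sense[ti_s : ti_s + 6] = list("GTAAGT")
            sense[ti_e - 2 : ti_e] = list("AG")
            d_bp = int(rng.integers(10, min(40, ilen - 10) + 1))
            tb = ti_e - d_bp  # branch A transcript position
            sense[tb - 3 : tb + 2] = list("CTAAC")  # branch A at index tb
            retention = float(rng.uniform(*cfg.retention_prob_range))
            iid = f"{gid}.i1"
            if strand == "+":
                g_is, g_ie, g_bp = s + ti_s, s + ti_e, s + tb
            else:
                g_is, g_ie, g_bp = e - ti_e, e - ti_s, e - 1 - tb
            introns.append(
                IntronModel(iid, gid, g_is, g_ie, strand, branchpoint_pos=g_bp)
            )
            intron_truths[iid] = IntronTruth(iid, gid, retention)

        # PAS placement inside the 3'UTR, >= 45 nt from the UTR start so the
        # 40-nt upstream window stays inside the gene body
        k = int(rng.choice(k_values, p=k_probs))
        pas_t = _draw_separated_positions(
            rng, utr_t[0] + 45, L - 8, k, cfg.pas_min_separation
        )
        raw = rng.exponential(1.0, size=k)
        weights = cfg.pas_weight_floor + (1 - k * cfg.pas_weight_floor) * raw / raw.sum()
        order = np.argsort(-weights, kind="stable")  # primary first
        pas_t = [pas_t[i] for i in order]
        weights = [float(weights[i]) for i in order]

        protected: set[int] = set()
        distances: list[Optional[int]] = []
        for tp in pas_t:
            if rng.random() >= cfg.signal_plant_rate:
                distances.append(None)
                continue
            planted = None
            for _ in range(50):
                d = int(rng.choice(dist_vals, p=dist_probs))
                m_lo = tp - d - 4  # motif occupies [m_lo, m_lo+4)
                if m_lo < 0:
                    continue
                if any(p in protected for p in range(m_lo, m_lo + 4)):
                    continue  # never overwrite an already-planted signal
                # a signal must sit in its own PAS's upstream window only:
                # a UAAA inside a neighbouring window would shadow that
                # window's own (possibly less proximal) signal
                if any(
                    tq != tp and m_lo + 4 > tq - 40 and m_lo < tq
                    for tq in pas_t
                ):
                    continue
                sense[m_lo : m_lo + 4] = list(SIGNAL_DNA)
                protected.update(range(m_lo, m_lo + 4))
                planted = d
                break
            distances.append(planted)

        if cfg.mask_spurious_signal:
            for tp in pas_t:
                _mask_spurious_signal(sense, max(0, tp - 40), tp, protected)

        # write the sense copy back to the genome
        for t, base in enumerate(sense):
            if strand == "+":
                seq[s + t] = base
            else:
                seq[e - 1 - t] = revcomp(base)

        if strand == "+":
            utr3 = (e - utr_len, e)
            pas_g = [s + tp for tp in pas_t]
        else:
            utr3 = (s, s + utr_len)
            pas_g = [e - 1 - tp for tp in pas_t]

        genes.append(
            GeneModel(gid, chrom, strand, s, e, utr3=utr3, introns=introns)
        )
        gene_truths[gid] = GeneTruth(
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            pas_positions=pas_g,
            pas_weights=weights,
            signal_distances=distances,
            expression_weight=float(expr[gi]),
            expected_reads=float(expr[gi] * cfg.reads_total),
        )

    genome = {chrom: "".join(seq)}
    annotation = GenomeAnnotation({chrom: chrom_len}, genes)
    return genome, annotation, SimTruth(gene_truths, intron_truths)


def simulate_reads(
    annotation: GenomeAnnotation,
    truth: SimTruth,
    cfg: SimConfig,
    rng: np.random.Generator | int | None = None,
    n_reads: Optional[int] = None,
    retention_probs: Optional[Mapping[str, float]] = None,
) -> list[AlignedRead]:
    """Sample pre-aligned reads from the truth.

    Per read: gene ~ expression; PAS ~ weights; 3' end = PAS + rounded
    Gaussian jitter clipped to the gene span; on intron genes the read
    always spans the intron and is spliced (gap exactly at the intron
    boundaries) with probability 1 - retention. ``retention_probs``
    overrides per-intron retention (e.g. to emulate a second condition).
    """
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(cfg.seed + 1 if rng is None else rng)
    n_reads = cfg.reads_total if n_reads is None else n_reads

    gene_ids = list(truth.genes)
    weights = np.array([truth.genes[g].expression_weight for g in gene_ids])
    weights /= weights.sum()
    gene_idx = rng.choice(len(gene_ids), size=n_reads, p=weights)

    reads: list[AlignedRead] = []
    for ri, gi in enumerate(gene_idx):
        gt = truth.genes[gene_ids[gi]]
        gene = annotation.gene(gt.gene_id)
        pi = int(rng.choice(len(gt.pas_positions), p=np.asarray(gt.pas_weights)))
        pas = gt.pas_positions[pi]
        jitter = int(round(rng.normal(0.0, cfg.end_jitter_sd))) if cfg.end_jitter_sd > 0 else 0
        end3 = int(np.clip(pas + jitter, gene.start, gene.end - 1))

        spliced_out: list[IntronModel] = []
        for intron in gene.introns:
            r = (
                retention_probs[intron.intron_id]
                if retention_probs and intron.intron_id in retention_probs
                else truth.introns[intron.intron_id].retention_prob
            )
            if rng.random() < 1.0 - r:
                spliced_out.append(intron)

        if gene.strand == "+":
            if gene.introns:
                first = min(i.start for i in gene.introns)
                start5 = int(rng.integers(gene.start, first - 10))
            else:
                lo = gene.start
                hi = max(lo + 1, end3 - 150)
                start5 = int(rng.integers(lo, hi))
            lo_g, hi_g = start5, end3 + 1
        else:
            if gene.introns:
                last = max(i.end for i in gene.introns)
                end5 = int(rng.integers(last + 10, gene.end)) + 1
            else:
                lo = min(gene.end, end3 + 151)
                end5 = int(rng.integers(lo, gene.end + 1))
                end5 = max(end5, end3 + 2)
            lo_g, hi_g = end3, min(end5, gene.end)

        cuts = sorted(
            (i.start, i.end) for i in spliced_out if lo_g < i.start and i.end < hi_g
        )
        blocks: list[tuple[int, int]] = []
        pos = lo_g
        for cs, ce in cuts:
            blocks.append((pos, cs))
            pos = ce
        blocks.append((pos, hi_g))
        reads.append(AlignedRead(f"r{ri:06d}", gt.chrom, gene.strand, blocks))
    return reads


def genome_to_fasta(genome: Mapping[str, str], width: int = 70) -> str:
    out = []
    for chrom in sorted(genome):
        out.append(f">{chrom}")
        s = genome[chrom]
        out.extend(s[i : i + width] for i in range(0, len(s), width))
    return "\n".join(out) + "\n"


def make_window_set(
    n: int,
    plant_rate: float,
    distance_pmf: Optional[Mapping[int, float]] = None,
    width: int = 40,
    gc: float = 0.55,
    rng: np.random.Generator | int | None = 0,
    mask: bool = True,
) -> tuple[list[str], list[Optional[int]]]:
    """Stand-alone upstream-window simulator (synthetic windows only):
    random RNA windows with UAAA planted at a drawn distance in a
    ``plant_rate`` fraction, spurious occurrences optionally masked.
    Returns (windows, planted distance or None per window)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    pmf = dict(distance_pmf) if distance_pmf else uniform_distance_pmf()
    vals = np.array(sorted(pmf))
    probs = np.array([pmf[int(v)] for v in vals])
    probs = probs / probs.sum()
    windows: list[str] = []
    truths: list[Optional[int]] = []
    for _ in range(n):
        sense = DNA[_random_seq(width, gc, rng)].tolist()
        planted: Optional[int] = None
        protected: set[int] = set()
        if rng.random() < plant_rate:
            d = int(rng.choice(vals, p=probs))
            if width - d - 4 >= 0:
                m_lo = width - d - 4
                sense[m_lo : m_lo + 4] = list(SIGNAL_DNA)
                protected = set(range(m_lo, m_lo + 4))
                planted = d
        if mask:
            _mask_spurious_signal(sense, 0, width, protected)
        windows.append("".join(sense).replace("T", "U"))
        truths.append(planted)
    return windows, truths
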