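"""Intron-spanning read classification and fraction-spliced quantification.

A read spans an intron when its aligned hull (first block start to last
block end) covers at least ``span_frac`` (default 0.3) of the intron on
the same strand — a spliced read whose gap jumps the intron still spans
it. Fraction spliced = spliced spanning reads / all spanning reads, per
intron.

Two spliced-classification modes are provided. "faithful" counts any
multi-block (gapped) read as spliced, matching the original long-read
accounting; "strict" additionally requires some inter-block gap to match
the annotated intron boundaries within a tolerance, which avoids
overcounting on reads with gaps elsewhere. Faithful is the default.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .genome_model import AlignedRead, GenomeAnnotation, IntronModel
from . import stats_core


class SpliceError(ValueError):
    pass


@dataclass
class SpliceCount:
    intron_id: str
    n_spanning: int
    n_spliced: int
    suppressed: bool = False  # below a caller-imposed coverage floor

    @property
    def fraction_spliced(self) -> Optional[float]:
        if not self.defined:
            return None
        return self.n_spliced / self.n_spanning

    @property
    def defined(self) -> bool:
        return self.n_spanning > 0 and not self.suppressed


def is_intron_spanning(
    read: AlignedRead, intron: IntronModel, span_frac: float = 0.3
) -> bool:
    if read.strand != intron.strand:
        return False
    rs, re = read.span
    ov = min(re, intron.end) - max(rs, intron.start)
    return ov > 0 and ov >= span_frac * intron.length


def is_spliced(
    read: AlignedRead,
    intron: IntronModel,
    mode: str = "faithful",
    boundary_tol: int = 3,
) -> bool:
    if mode == "faithful":
        return read.n_blocks > 1
    if mode == "strict":
        for (_, e1), (s2, _) in zip(read.blocks, read.blocks[1:]):
            if abs(e1 - intron.start) <= boundary_tol and abs(s2 - intron.end) <= boundary_tol:
                return True
        return False
    raise SpliceError(f"unknown mode {mode!r}")


def fraction_spliced_table(
    reads: Iterable[AlignedRead],
    annotation: GenomeAnnotation,
    span_frac: float = 0.3,
    mode: str = "faithful",
    boundary_tol: int = 3,
    min_coverage: int = 1,
) -> list[SpliceCount]:
    """One SpliceCount per annotated intron; a read contributes to every
    intron it spans. Introns with zero spanning reads are kept (flagged,
    fraction undefined), not dropped; introns below ``min_coverage``
    spanning reads keep their tallies but are marked suppressed."""
    introns: list[tuple[str, IntronModel]] = [
        (g.chrom, i) for g, i in annotation.iter_introns()
    ]
    counts = {i.intron_id: SpliceCount(i.intron_id, 0, 0) for _, i in introns}
    for read in reads:
        for chrom, intron in introns:
            if chrom != read.chrom:
                continue
            if not is_intron_spanning(read, intron, span_frac):
                continue
            c = counts[intron.intron_id]
            c.n_spanning += 1
            if is_spliced(read, intron, mode=mode, boundary_tol=boundary_tol):
                c.n_spliced += 1
    out = list(counts.values())
    for c in out:
        if 0 < c.n_spanning < min_coverage:
            c.suppressed = True
    return out


def _paired_fractions(
    table_a: Sequence[SpliceCount], table_b: Sequence[SpliceCount]
) -> tuple[list[str], list[float], list[float]]:
    by_b = {c.intron_id: c for c in table_b}
    ids, fa, fb = [], [], []
    for ca in table_a:
        cb = by_b.get(ca.intron_id)
        if cb is None or not ca.defined or not cb.defined:
            continue
        ids.append(ca.intron_id)
        fa.append(ca.fraction_spliced)
        fb.append(cb.fraction_spliced)
    return ids, fa, fb


def compare_conditions(
    table_a: Sequence[SpliceCount], table_b: Sequence[SpliceCount]
) -> dict:
    """Unpaired two-sided Mann-Whitney U test on the two fraction-spliced
    vectors, plus per-intron deltas (b - a) for the shared defined introns."""
    fa = [c.fraction_spliced for c in table_a if c.defined]
    fb = [c.fraction_spliced for c in table_b if c.defined]
    if len(fa) < 2 or len(fb) < 2:
        raise SpliceError(
            f"compare_conditions: need >= 2 defined fractions per side "
            f"(got {len(fa)} and {len(fb)})"
        )
    result = stats_core.mann_whitney_u(fa, fb)
    ids, pa, pb = _paired_fractions(table_a, table_b)
    deltas = {i: b - a for i, a, b in zip(ids, pa, pb)}
    return {
        "U": result.statistic,
        "p_value": result.p_value,
        "n_a": len(fa),
        "n_b": len(fb),
        "method": result.method,
        "deltas": deltas,
    }


def correlate_fraction_spliced(
    table_a: Sequence[SpliceCount], table_b: Sequence[SpliceCount]
) -> stats_core.TestResult:
    """Pearson correlation of paired per-intron fractions (e.g. two
    conditions, two library preparations, or long- vs short-read)."""
    ids, fa, fb = _paired_fractions(table_a, table_b)
    if len(ids) < 3:
        raise SpliceError(
            f"correlate_fraction_spliced: need >= 3 shared defined introns, got {len(ids)}"
        )
    return stats_core.pearson(fa, fb)


def table_from_tsv(path) -> list[SpliceCount]:
    """Read a fraction-spliced table written by :func:`table_to_tsv` or an
    external per-intron TSV with columns intron_id, n_spanning, n_spliced."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        SpliceCount(str(r.intron_id), int(r.n_spanning), int(r.n_spliced))
        for r in df.itertuples()
    ]


def table_to_tsv(table: Sequence[SpliceCount], path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        {
            "intron_id": [c.intron_id for c in table],
            "n_spanning": [c.n_spanning for c in table],
            "n_spliced": [c.n_spliced for c in table],
            "fraction_spliced": [
                "" if c.fraction_spliced is None else f"{c.fraction_spliced:.6g}"
                for c in table
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)
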