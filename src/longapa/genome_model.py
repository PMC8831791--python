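"""Domain types and I/O for gene annotation and long-read alignments.

All coordinates are 0-based, half-open genomic intervals. BED input stays
native; SAM input is converted from 1-based on the fly. Reads are modelled
as an ordered list of gapless aligned blocks: a gap between blocks marks a
splice (alignment skip), soft-clipped bases are never part of a block.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pysam

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Malformed or internally inconsistent annotation input."""


class AlignmentParseError(ValueError):
    """Malformed alignment record."""


@dataclass
class IntronModel:
    """One annotated intron.

    ``branchpoint_pos`` is the genomic coordinate of the branch adenosine
    (0-based), when known. ``strand`` is carried from the intron BED record
    for stranded overlap tests; it always matches the parent gene's strand.
    """

    intron_id: str
    gene_id: str
    start: int
    end: int
    strand: str = "+"
    branchpoint_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end - self.start < 4:
            raise AnnotationError(
                f"intron {self.intron_id}: length {self.end - self.start} < 4"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"intron {self.intron_id}: bad strand {self.strand!r}")
        if self.branchpoint_pos is not None and not (
            self.start <= self.branchpoint_pos < self.end
        ):
            raise AnnotationError(
                f"intron {self.intron_id}: branchpoint {self.branchpoint_pos} "
                f"outside [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A gene span with optional 3'UTR and its introns (5'->3' in transcript order)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    utr3: Optional[tuple[int, int]] = None
    introns: list[IntronModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise AnnotationError(f"gene {self.gene_id}: bad span [{self.start}, {self.end})")
        if self.utr3 is not None:
            us, ue = self.utr3
            if not (self.start <= us < ue <= self.end):
                raise AnnotationError(
                    f"gene {self.gene_id}: 3'UTR [{us}, {ue}) not inside span"
                )
        self._check_introns()

    def _check_introns(self) -> None:
        for i in self.introns:
            if not (self.start <= i.start and i.end <= self.end):
                raise AnnotationError(
                    f"intron {i.intron_id} [{i.start}, {i.end}) outside gene "
                    f"{self.gene_id} span [{self.start}, {self.end})"
                )
            if i.strand != self.strand:
                raise AnnotationError(
                    f"intron {i.intron_id} strand {i.strand} != gene strand {self.strand}"
                )
        by_pos = sorted(self.introns, key=lambda i: i.start)
        for a, b in zip(by_pos, by_pos[1:]):
            if a.end > b.start:
                raise AnnotationError(
                    f"introns {a.intron_id} and {b.intron_id} overlap in gene {self.gene_id}"
                )
        # transcript order: genomic order on +, reversed on -
        self.introns = by_pos if self.strand == "+" else by_pos[::-1]

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def utr3_length(self) -> Optional[int]:
        if self.utr3 is None:
            return None
        return self.utr3[1] - self.utr3[0]


@dataclass
class GenomeAnnotation:
    chrom_lengths: dict[str, int]
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene id {g.gene_id}")
            seen.add(g.gene_id)
            L = self.chrom_lengths.get(g.chrom)
            if L is None:
                raise AnnotationError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
            if g.end > L:
                raise AnnotationError(
                    f"gene {g.gene_id}: span end {g.end} beyond {g.chrom} length {L}"
                )
        self._by_id = {g.gene_id: g for g in self.genes}
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for lst in by_chrom.values():
            lst.sort(key=lambda g: g.start)
        self._by_chrom = by_chrom

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return self._by_chrom.get(chrom, [])

    def iter_introns(self) -> Iterator[tuple[GeneModel, IntronModel]]:
        for g in self.genes:
            for i in g.introns:
                yield g, i


@dataclass
class AlignedRead:
    """A long-read alignment as ordered, strictly increasing, non-overlapping blocks."""

    read_id: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise AlignmentParseError(f"read {self.read_id}: bad strand {self.strand!r}")
        if not self.blocks:
            raise AlignmentParseError(f"read {self.read_id}: no blocks")
        for s, e in self.blocks:
            if not s < e:
                raise AlignmentParseError(f"read {self.read_id}: empty block [{s}, {e})")
        for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:]):
            if s2 < e1:
                raise AlignmentParseError(
                    f"read {self.read_id}: blocks overlap or are unsorted"
                )

    @property
    def span(self) -> tuple[int, int]:
        """Aligned hull: first block start to last block end."""
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def three_prime_end(read: AlignedRead) -> int:
    """0-based position of the final aligned (template 3') base.

    PolyA tails are assumed trimmed upstream, so the last aligned base is
    the cleavage-adjacent base: last block end - 1 on '+', first block
    start on '-'.
    """
    if read.strand == "+":
        return read.blocks[-1][1] - 1
    return read.blocks[0][0]


# ---------------------------------------------------------------------------
# annotation I/O

_GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "utr3_start", "utr3_end"]


def read_annotation(
    gene_table_path: str | Path,
    intron_bed_path: str | Path | None = None,
    chrom_sizes_path: str | Path | None = None,
) -> GenomeAnnotation:
    """Read a gene table (TSV with header) plus an optional intron BED6(+1).

    Introns are attached to genes by matching the gene_id prefix of the
    intron name. Chromosome lengths come from ``chrom_sizes_path`` (TSV
    chrom<TAB>length) when given, else are inferred as the maximal gene end
    per chromosome.
    """
    genes: list[GeneModel] = []
    gene_table_path = Path(gene_table_path)
    with open(gene_table_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_GENE_COLUMNS)] != _GENE_COLUMNS:
            raise AnnotationError(
                f"{gene_table_path}:1: expected header {_GENE_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 7:
                raise AnnotationError(
                    f"{gene_table_path}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            gid, chrom, start, end, strand, us, ue = parts[:7]
            try:
                utr3 = (int(us), int(ue)) if us != "" and ue != "" else None
                genes.append(
                    GeneModel(gid, chrom, strand, int(start), int(end), utr3=utr3)
                )
            except (ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{gene_table_path}:{lineno}: {exc}") from exc

    by_id = {g.gene_id: g for g in genes}
    gene_ids_by_len = sorted(by_id, key=len, reverse=True)

    if intron_bed_path is not None:
        with open(intron_bed_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 6:
                    raise AnnotationError(
                        f"{intron_bed_path}:{lineno}: BED6 needs >= 6 columns"
                    )
                chrom, start, end, name, _score, strand = parts[:6]
                bp = int(parts[6]) if len(parts) > 6 and parts[6] != "" else None
                owner = next(
                    (gid for gid in gene_ids_by_len if name.startswith(gid)), None
                )
                if owner is None:
                    raise AnnotationError(
                        f"{intron_bed_path}:{lineno}: intron {name!r} matches no gene_id prefix"
                    )
                try:
                    intron = IntronModel(
                        name, owner, int(start), int(end), strand, branchpoint_pos=bp
                    )
                except AnnotationError as exc:
                    raise AnnotationError(f"{intron_bed_path}:{lineno}: {exc}") from exc
                if chrom != by_id[owner].chrom:
                    raise AnnotationError(
                        f"{intron_bed_path}:{lineno}: intron {name} on {chrom}, "
                        f"gene {owner} on {by_id[owner].chrom}"
                    )
                by_id[owner].introns.append(intron)
        for g in genes:
            g._check_introns()

    if chrom_sizes_path is not None:
        chrom_lengths: dict[str, int] = {}
        with open(chrom_sizes_path) as fh:
            for line in fh:
                if line.strip():
                    chrom, length = line.split("\t")[:2]
                    chrom_lengths[chrom] = int(length)
    else:
        chrom_lengths = {}
        for g in genes:
            chrom_lengths[g.chrom] = max(chrom_lengths.get(g.chrom, 0), g.end)

    return GenomeAnnotation(chrom_lengths, genes)


def write_annotation(
    ann: GenomeAnnotation,
    gene_table_path: str | Path,
    intron_bed_path: str | Path,
    chrom_sizes_path: str | Path,
) -> None:
    with open(gene_table_path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in ann.genes:
            us, ue = ("", "") if g.utr3 is None else (str(g.utr3[0]), str(g.utr3[1]))
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t{us}\t{ue}\n"
            )
    with open(intron_bed_path, "w") as fh:
        for g in ann.genes:
            for i in sorted(g.introns, key=lambda i: i.start):
                bp = "" if i.branchpoint_pos is None else str(i.branchpoint_pos)
                fh.write(
                    f"{g.chrom}\t{i.start}\t{i.end}\t{i.intron_id}\t0\t{i.strand}\t{bp}\n"
                )
    with open(chrom_sizes_path, "w") as fh:
        for chrom, length in sorted(ann.chrom_lengths.items()):
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# alignment I/O

def _parse_bed12_line(parts: list[str], lineno: int, path: str) -> AlignedRead:
    chrom = parts[0]
    chrom_start = int(parts[1])
    name = parts[3]
    strand = parts[5]
    block_count = int(parts[9])
    sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
    starts = [int(x) for x in parts[11].rstrip(",").split(",")]
    if len(sizes) != block_count or len(starts) != block_count:
        raise AlignmentParseError(
            f"{path}:{lineno}: blockCount={block_count} but "
            f"{len(sizes)} sizes / {len(starts)} starts"
        )
    blocks = [
        (chrom_start + st, chrom_start + st + sz) for st, sz in zip(starts, sizes)
    ]
    return AlignedRead(name, chrom, strand, blocks)


def read_bed12(path: str | Path) -> Iterator[AlignedRead]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise AlignmentParseError(f"{path}:{lineno}: BED12 needs 12 columns")
            yield _parse_bed12_line(parts, lineno, str(path))


# CIGAR ops that consume reference and stay inside a block (M, D, =, X);
# N splits blocks; S/I/H consume no reference.
_BLOCK_OPS = {0, 2, 7, 8}
_SKIP_OP = 3


def _blocks_from_cigar(pos: int, cigartuples) -> list[tuple[int, int]]:
    blocks: list[tuple[int, int]] = []
    cur_start, cur = pos, pos
    open_block = False
    for op, length in cigartuples:
        if op in _BLOCK_OPS:
            if not open_block:
                cur_start = cur
                open_block = True
            cur += length
        elif op == _SKIP_OP:
            if open_block:
                blocks.append((cur_start, cur))
                open_block = False
            cur += length
    if open_block:
        blocks.append((cur_start, cur))
    return blocks


def read_sam(path: str | Path) -> Iterator[AlignedRead]:
    skipped = {"unmapped": 0, "secondary": 0, "supplementary": 0}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                skipped["unmapped"] += 1
                continue
            if rec.is_secondary:
                skipped["secondary"] += 1
                continue
            if rec.is_supplementary:
                skipped["supplementary"] += 1
                continue
            blocks = _blocks_from_cigar(rec.reference_start, rec.cigartuples)
            strand = "-" if rec.is_reverse else "+"
            yield AlignedRead(rec.query_name, rec.reference_name, strand, blocks)
    if any(skipped.values()):
        logger.info("read_sam(%s): skipped %s", path, skipped)


def read_alignments(path: str | Path, format: str | None = None) -> Iterator[AlignedRead]:
    """Stream AlignedRead records from a BED12 or SAM file.

    ``format`` is 'bed12' or 'sam'; inferred from the file extension when
    omitted. Unmapped/secondary/supplementary SAM records are skipped and
    counted in a log summary.
    """
    if format is None:
        suffix = Path(path).suffix.lower()
        format = "sam" if suffix == ".sam" else "bed12"
    format = format.lower()
    if format == "bed12":
        return read_bed12(path)
    if format in ("sam", "sam-compatible"):
        return read_sam(path)
    raise ValueError(f"unknown alignment format {format!r}")


def write_bed12(reads: Iterable[AlignedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            start, end = r.span
            sizes = ",".join(str(e - s) for s, e in r.blocks)
            starts = ",".join(str(s - start) for s, _ in r.blocks)
            fh.write(
                f"{r.chrom}\t{start}\t{end}\t{r.read_id}\t0\t{r.strand}\t"
                f"{start}\t{end}\t0,0,0\t{len(r.blocks)}\t{sizes}\t{starts}\n"
            )


def write_sam(
    reads: Iterable[AlignedRead], path: str | Path, chrom_lengths: dict[str, int]
) -> None:
    """Write reads as minimal SAM (M/N CIGAR, no sequence)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, length in sorted(chrom_lengths.items()):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for r in reads:
            cigar = []
            for (s1, e1), (s2, _) in zip(r.blocks, r.blocks[1:]):
                cigar.append(f"{e1 - s1}M{s2 - e1}N")
            last = r.blocks[-1]
            cigar.append(f"{last[1] - last[0]}M")
            flag = 16 if r.strand == "-" else 0
            fh.write(
                f"{r.read_id}\t{flag}\t{r.chrom}\t{r.blocks[0][0] + 1}\t60\t"
                f"{''.join(cigar)}\t*\t0\t0\t*\t*\n"
            )


# ---------------------------------------------------------------------------
# genome sequence access

def load_genome(fasta_path: str | Path) -> dict[str, str]:
    """Load a (small) genome FASTA into an uppercase chrom -> sequence dict."""
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path), rebuild=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
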