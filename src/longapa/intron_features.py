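"""Per-intron sequence features and their correlation with fraction spliced.

Features: intron length, GC content, gene 3'UTR length, branchpoint-to-3'SS
distance, and log-odds PWM scores of the donor (5'SS) and acceptor (3'SS)
windows. External per-intron scores (e.g. MaxEnt splice-site scores or
folding minimum free energies computed elsewhere) merge in as extra columns
by intron_id; the in-repo PWM scorer is the self-contained default and each
column is labelled by the scorer that produced it.

Splice-site window convention (transcript orientation; position +1 is the
first intron base at the 5'SS and the first exon base after the intron at
the 3'SS):

    5'SS: exon[-3..-1] | intron[+1..+5]      -> 8 nt
    3'SS: intron[-20..-1] | exon[+1..+3]     -> 23 nt

For a '+'-strand intron [s, e): 5'SS window = genomic [s-3, s+5),
3'SS window = genomic [e-20, e+3). On '-', the mirrored genomic windows
([e-5, e+3) and [s-3, s+20)) are reverse-complemented.
"""
from __future__ import annotations

import logging
import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_model import GenomeAnnotation, IntronModel, revcomp
from .splicing_quant import SpliceCount
from . import stats_core

logger = logging.getLogger(__name__)

RNA_BASES = "ACGU"


class FeatureError(ValueError):
    pass


def gc_content(sequence: str) -> float:
    """(G+C) / (A+C+G+T); N bases are excluded from both counts."""
    s = sequence.upper().replace("U", "T")
    if not s:
        raise FeatureError("gc_content: empty sequence")
    counts = {b: s.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise FeatureError("gc_content: no unambiguous bases")
    return (counts["G"] + counts["C"]) / denom


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def splice_site_windows(
    intron: IntronModel, genome: Mapping[str, str], chrom: str
) -> tuple[str, str]:
    """Transcript-oriented RNA sequences of the donor (8 nt) and acceptor
    (23 nt) windows. Raises when a window runs off the chromosome."""
    seq = genome[chrom]
    s, e = intron.start, intron.end
    if intron.strand == "+":
        lo5, hi5 = s - 3, s + 5
        lo3, hi3 = e - 20, e + 3
        if lo5 < 0 or lo3 < 0 or hi3 > len(seq):
            raise FeatureError(
                f"intron {intron.intron_id}: splice-site window truncated by chromosome"
            )
        return _to_rna(seq[lo5:hi5]), _to_rna(seq[lo3:hi3])
    lo5, hi5 = e - 5, e + 3
    lo3, hi3 = s - 3, s + 20
    if lo3 < 0 or hi5 > len(seq) or hi3 > len(seq):
        raise FeatureError(
            f"intron {intron.intron_id}: splice-site window truncated by chromosome"
        )
    return _to_rna(revcomp(seq[lo5:hi5])), _to_rna(revcomp(seq[lo3:hi3]))


def pwm_scores(
    windows: Mapping[str, str], background: Mapping[str, float]
) -> dict[str, float]:
    """Log-odds PWM score per window against a position frequency matrix
    built from all the windows themselves (+0.5 pseudocounts).

    score(w) = sum_pos log2(f_pos(base) / q(base)); N positions contribute
    0. ``background`` is the genome base composition over ACGU (or ACGT).
    """
    if len(windows) < 5:
        raise FeatureError(f"pwm_scores: need >= 5 windows, got {len(windows)}")
    seqs = {k: _to_rna(v) for k, v in windows.items()}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise FeatureError("pwm_scores: windows must share one length")
    L = lengths.pop()
    q = {_to_rna(b): float(background[b]) for b in background}

    counts = np.full((L, 4), 0.5)
    denom = np.full(L, 2.0)  # 4 bases x 0.5 pseudocount
    index = {b: i for i, b in enumerate(RNA_BASES)}
    for s in seqs.values():
        for pos, base in enumerate(s):
            i = index.get(base)
            if i is not None:
                counts[pos, i] += 1.0
                denom[pos] += 1.0
    freqs = counts / denom[:, None]

    logodds = np.log2(freqs / np.array([q[b] for b in RNA_BASES])[None, :])
    scores: dict[str, float] = {}
    for key, s in seqs.items():
        total = 0.0
        for pos, base in enumerate(s):
            i = index.get(base)
            if i is not None:
                total += logodds[pos, i]
        scores[key] = float(total)
    return scores


def genome_base_composition(genome: Mapping[str, str]) -> dict[str, float]:
    counts = {b: 0 for b in "ACGT"}
    for seq in genome.values():
        s = seq.upper()
        for b in counts:
            counts[b] += s.count(b)
    total = sum(counts.values())
    return {b: c / total for b, c in counts.items()}


FEATURE_COLUMNS = [
    "intron_length",
    "gc_content",
    "utr3_length",
    "bp_to_3ss",
    "ss5_score",
    "ss3_score",
]


def feature_table(
    annotation: GenomeAnnotation,
    genome: Mapping[str, str],
    splice_counts: Sequence[SpliceCount],
    external_scores: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """One row per annotated intron: intrinsic features, PWM splice-site
    scores, fraction spliced, and any external score columns merged by
    intron_id (unknown ids are warned about and dropped)."""
    frac = {c.intron_id: c.fraction_spliced for c in splice_counts}
    rows = []
    ss5_windows: dict[str, str] = {}
    ss3_windows: dict[str, str] = {}
    for gene, intron in annotation.iter_introns():
        iseq = genome[gene.chrom][intron.start : intron.end]
        if intron.branchpoint_pos is None:
            bp_to_3ss = math.nan
        elif intron.strand == "+":
            bp_to_3ss = intron.end - intron.branchpoint_pos
        else:
            bp_to_3ss = intron.branchpoint_pos - intron.start + 1
        try:
            ss5, ss3 = splice_site_windows(intron, genome, gene.chrom)
            ss5_windows[intron.intron_id] = ss5
            ss3_windows[intron.intron_id] = ss3
        except FeatureError as exc:
            logger.warning("%s", exc)
        rows.append(
            {
                "intron_id": intron.intron_id,
                "gene_id": gene.gene_id,
                "intron_length": intron.length,
                "gc_content": gc_content(iseq),
                "utr3_length": gene.utr3_length if gene.utr3_length is not None else math.nan,
                "bp_to_3ss": bp_to_3ss,
                "fraction_spliced": frac.get(intron.intron_id, math.nan),
            }
        )
    df = pd.DataFrame(rows)
    if len(ss5_windows) >= 5:
        q = genome_base_composition(genome)
        s5 = pwm_scores(ss5_windows, q)
        s3 = pwm_scores(ss3_windows, q)
        df["ss5_score"] = df["intron_id"].map(s5)
        df["ss3_score"] = df["intron_id"].map(s3)
    else:
        logger.warning("fewer than 5 scorable introns; PWM score columns omitted")
        df["ss5_score"] = math.nan
        df["ss3_score"] = math.nan

    if external_scores is not None:
        ext = external_scores.copy()
        if "intron_id" not in ext.columns:
            raise FeatureError("external scores need an intron_id column")
        unknown = set(ext["intron_id"]) - set(df["intron_id"])
        if unknown:
            logger.warning(
                "external scores: %d unknown intron ids ignored (%s...)",
                len(unknown),
                sorted(unknown)[:3],
            )
            ext = ext[~ext["intron_id"].isin(unknown)]
        df = df.merge(ext, on="intron_id", how="left")
    return df


def correlate_features(
    rows: pd.DataFrame, features: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Pearson r and two-sided p of each feature against fraction_spliced,
    with pairwise deletion of missing values. Constant features and those
    with < 3 complete pairs are flagged (r, p = NaN)."""
    if features is None:
        features = [
            c
            for c in rows.columns
            if c not in ("intron_id", "gene_id", "fraction_spliced")
            and pd.api.types.is_numeric_dtype(rows[c])
        ]
    out = []
    for feat in features:
        pair = rows[[feat, "fraction_spliced"]].dropna()
        n = len(pair)
        if n < 3:
            out.append({"feature": feat, "n": n, "r": math.nan, "p": math.nan,
                        "flag": "insufficient pairs"})
            continue
        try:
            res = stats_core.pearson(pair[feat].to_numpy(), pair["fraction_spliced"].to_numpy())
        except stats_core.StatsError:
            out.append({"feature": feat, "n": n, "r": math.nan, "p": math.nan,
                        "flag": "constant feature"})
            continue
        out.append({"feature": feat, "n": n, "r": res.statistic, "p": res.p_value,
                    "flag": ""})
    return pd.DataFrame(out)
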