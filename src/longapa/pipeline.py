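"""End-to-end orchestration: simulate -> splice -> PAS -> motif -> features.

``run_all`` executes the full analysis with fixed stage order and writes
TSV outputs, a JSON run manifest (seed, thresholds, output checksums) and
a plain-text summary of the headline numbers. Given the same config and
seed, two runs produce byte-identical outputs (no timestamps anywhere).
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome_model import (
    GenomeAnnotation,
    load_genome,
    read_alignments,
    read_annotation,
    write_annotation,
    write_bed12,
    write_sam,
)
from .intron_features import correlate_features, feature_table
from .pas_calling import (
    DEFAULT_MIN_DISTANCE,
    DEFAULT_MIN_HEIGHT,
    build_histograms,
    call_all_peaks,
    metagene_profile,
    summarize_apa,
)
from .polya_signal import (
    distance_histogram,
    extract_upstream_windows,
    kmer_enrichment,
    signal_distance,
)
from .splicing_quant import (
    compare_conditions,
    correlate_fraction_spliced,
    fraction_spliced_table,
    table_to_tsv,
)
from .synthetic_data import SimConfig, genome_to_fasta, simulate_genome, simulate_reads

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    out_dir: str = "longapa_run"
    seed: int = 0
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # SimConfig field overrides
    condition_names: tuple[str, str] = ("rm", "ln")
    # emulated condition effect: retention-probability shift in condition 2
    retention_shift: float = -0.08
    # paths, used when simulate is false
    genome_fasta: Optional[str] = None
    gene_table: Optional[str] = None
    intron_bed: Optional[str] = None
    chrom_sizes: Optional[str] = None
    reads: dict = field(default_factory=dict)  # condition name -> path
    # thresholds
    min_height: int = DEFAULT_MIN_HEIGHT
    min_distance: int = DEFAULT_MIN_DISTANCE
    span_frac: float = 0.3
    min_read_frac: float = 0.25
    splice_mode: str = "faithful"
    window_width: int = 40
    n_top: int = 500
    metagene_window: int = 50
    kmer_min: int = 4
    kmer_max: int = 6
    n_shuffles: int = 100

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**payload)
        cfg.condition_names = tuple(cfg.condition_names)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_all(config: RunConfig) -> Path:
    """Run every stage in fixed order; returns the report directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cond_a, cond_b = config.condition_names

    if config.simulate:
        sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})
        genome, annotation, truth = simulate_genome(sim_cfg)
        (out / "genome.fa").write_text(genome_to_fasta(genome))
        write_annotation(
            annotation, out / "genes.tsv", out / "introns.bed", out / "chrom.sizes"
        )
        truth.to_json(out / "truth.json")
        shifted = {
            iid: float(np.clip(t.retention_prob + config.retention_shift, 0.0, 1.0))
            for iid, t in truth.introns.items()
        }
        reads_by_cond = {
            cond_a: simulate_reads(
                annotation, truth, sim_cfg, rng=np.random.default_rng(config.seed + 1)
            ),
            cond_b: simulate_reads(
                annotation,
                truth,
                sim_cfg,
                rng=np.random.default_rng(config.seed + 2),
                retention_probs=shifted,
            ),
        }
        for cond, reads in reads_by_cond.items():
            write_bed12(reads, out / f"reads_{cond}.bed12")
            write_sam(reads, out / f"reads_{cond}.sam", annotation.chrom_lengths)
    else:
        for name, value in [
            ("genome_fasta", config.genome_fasta),
            ("gene_table", config.gene_table),
            ("intron_bed", config.intron_bed),
        ]:
            if value is None:
                raise PipelineError(f"config field {name!r} required when simulate=false")
        if not config.reads:
            raise PipelineError("config field 'reads' (condition -> path) is empty")
        genome = load_genome(config.genome_fasta)
        annotation = read_annotation(
            config.gene_table, config.intron_bed, config.chrom_sizes
        )
        reads_by_cond = {
            cond: list(read_alignments(path)) for cond, path in config.reads.items()
        }

    # --- splicing quantification per condition
    splice_tables = {}
    for cond, reads in reads_by_cond.items():
        table = fraction_spliced_table(
            reads, annotation, span_frac=config.span_frac, mode=config.splice_mode
        )
        splice_tables[cond] = table
        table_to_tsv(table, out / f"splice_{cond}.tsv")

    # --- PAS calling per condition
    hists = {}
    calls = {}
    summaries = {}
    for cond, reads in reads_by_cond.items():
        h = build_histograms(reads, annotation, min_read_frac=config.min_read_frac)
        c = call_all_peaks(h, config.min_height, config.min_distance)
        hists[cond], calls[cond] = h, c
        rows = [
            {"gene_id": pc.gene_id, "position": pc.position, "height": pc.height,
             "rank": pc.rank}
            for gene_calls in c.values()
            for pc in gene_calls
        ]
        _write_tsv(pd.DataFrame(rows, columns=["gene_id", "position", "height", "rank"]),
                   out / f"pas_{cond}.tsv")
        summary = summarize_apa(c)
        summaries[cond] = summary
        _write_tsv(
            pd.DataFrame(
                [{"n_pas": k, "n_genes": v} for k, v in summary.count_histogram.items()]
            ),
            out / f"apa_summary_{cond}.tsv",
        )
        profile = metagene_profile(h, c, window=config.metagene_window)
        _write_tsv(
            pd.DataFrame(
                {"offset": list(profile.density), "density": list(profile.density.values())}
            ),
            out / f"metagene_{cond}.tsv",
        )

    # --- polyA signal on the first condition
    windows = extract_upstream_windows(
        calls[cond_a], hists[cond_a], genome, annotation,
        rank=1, n_top=config.n_top, width=config.window_width,
    )
    motif_reports = []
    if len(windows) >= 10:
        motif_reports = kmer_enrichment(
            windows,
            k_range=(config.kmer_min, config.kmer_max),
            n_shuffles=config.n_shuffles,
            seed=np.random.default_rng(config.seed + 3),
        )
        _write_tsv(
            pd.DataFrame([asdict(m) for m in motif_reports]), out / "motifs.tsv"
        )
    dists = [d for w in windows if (d := signal_distance(w)) is not None]
    dist_summary = None
    if dists:
        dist_summary = distance_histogram(dists)
        _write_tsv(
            pd.DataFrame(
                {"gene_id": [d.gene_id for d in dists],
                 "distance": [d.distance for d in dists]}
            ),
            out / "signal_distances.tsv",
        )

    # --- intron features on the first condition
    features = feature_table(annotation, genome, splice_tables[cond_a])
    _write_tsv(features, out / "features.tsv")
    correlations = correlate_features(features)
    _write_tsv(correlations, out / "feature_correlations.tsv")

    # --- condition comparison
    comparison = None
    n_defined = [sum(c.defined for c in t) for t in splice_tables.values()]
    if len(splice_tables) == 2 and all(n >= 3 for n in n_defined):
        comparison = compare_conditions(splice_tables[cond_a], splice_tables[cond_b])
        corr = correlate_fraction_spliced(splice_tables[cond_a], splice_tables[cond_b])
        _write_tsv(
            pd.DataFrame(
                [{"U": comparison["U"], "p_value": comparison["p_value"],
                  "n_a": comparison["n_a"], "n_b": comparison["n_b"],
                  "method": comparison["method"],
                  "pearson_r": corr.statistic, "pearson_p": corr.p_value}]
            ),
            out / "condition_comparison.tsv",
        )

    # --- summary + manifest
    lines = [f"longapa {__version__} run summary", ""]
    for cond, summary in summaries.items():
        lines.append(
            f"[{cond}] genes with >=1 PAS: {summary.n_genes} "
            f"(no peak: {summary.n_genes_no_peak}); "
            f">1 PAS: {100 * summary.frac_multi_pas:.1f}%; "
            f">2 PAS: {100 * summary.frac_gt2_pas:.1f}%"
        )
    if motif_reports:
        top = next(r for r in motif_reports if r.k == config.kmer_min)
        lines.append(
            f"top {config.kmer_min}-mer: {top.motif} in {100 * top.fraction:.1f}% of "
            f"{len(windows)} primary-PAS windows (log2 enrichment {top.enrichment:.2f})"
        )
    if dist_summary:
        lines.append(
            f"signal-to-cleavage distance: mean {dist_summary.mean:.1f} nt, "
            f"range [{dist_summary.min}, {dist_summary.max}], n={dist_summary.n}"
        )
    if comparison:
        lines.append(
            f"fraction spliced {cond_a} vs {cond_b}: U={comparison['U']:.1f}, "
            f"two-sided p={comparison['p_value']:.4g}"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")

    manifest = {
        "tool": "longapa",
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("reads", "sim", "out_dir")
        },
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
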