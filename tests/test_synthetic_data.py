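import numpy as np
import pytest
import scipy.stats

from longapa.genome_model import revcomp, three_prime_end
from longapa.synthetic_data import (
    SimConfig,
    SimulationError,
    genome_to_fasta,
    make_window_set,
    simulate_genome,
    simulate_reads,
    truncated_geometric_pmf,
    uniform_distance_pmf,
)


def _sense_window(genome, gene_truth, pas, width=40):
    seq = genome[gene_truth.chrom]
    if gene_truth.strand == "+":
        return seq[pas - width : pas]
    return revcomp(seq[pas + 1 : pas + 1 + width])


class TestSimConfig:
    def test_pas_fraction_must_sum_to_one(self):
        with pytest.raises(SimulationError, match="sums to"):
            SimConfig(frac_genes_with_k_pas={1: 0.5, 2: 0.4})

    def test_narrow_separation_warns(self):
        with pytest.warns(UserWarning, match="pas_min_separation"):
            SimConfig(pas_min_separation=20, end_jitter_sd=2.0)

    def test_default_distance_distribution_mean(self):
        pmf = truncated_geometric_pmf()
        mean = sum(d * p for d, p in pmf.items())
        assert mean == pytest.approx(17.0, abs=1e-6)
        assert min(pmf) == 3 and max(pmf) == 35

    def test_gene_too_short_for_layout(self):
        cfg = SimConfig(gene_length_range=(300, 400), end_jitter_sd=0)
        with pytest.raises(SimulationError, match="too small"):
            simulate_genome(cfg)


@pytest.fixture(scope="module")
def jitter_free():
    cfg = SimConfig(
        n_genes=30,
        reads_total=6000,
        end_jitter_sd=0.0,
        signal_plant_rate=1.0,
        seed=42,
    )
    genome, annotation, truth = simulate_genome(cfg)
    reads = simulate_reads(annotation, truth, cfg, rng=np.random.default_rng(43))
    return cfg, genome, annotation, truth, reads


class TestSimulateGenome:
    def test_single_gene_single_pas_signal_at_planted_distance(self):
        cfg = SimConfig(
            n_genes=1, n_intron_genes=0, frac_genes_with_k_pas={1: 1.0},
            signal_plant_rate=1.0, reads_total=10, seed=5, end_jitter_sd=0,
        )
        genome, _, truth = simulate_genome(cfg)
        (gt,) = truth.genes.values()
        (pas,) = gt.pas_positions
        (d,) = gt.signal_distances
        window = _sense_window(genome, gt, pas)
        assert window[40 - d - 4 : 40 - d] == "TAAA"

    def test_configured_pas_count_and_separation(self):
        cfg = SimConfig(
            n_genes=100, n_intron_genes=0, frac_genes_with_k_pas={2: 1.0},
            reads_total=10, seed=6, end_jitter_sd=0,
        )
        _, _, truth = simulate_genome(cfg)
        for gt in truth.genes.values():
            assert len(gt.pas_positions) == 2
            a, b = sorted(gt.pas_positions)
            assert b - a >= 25

    def test_same_seed_byte_identical(self):
        cfg = SimConfig(n_genes=10, n_intron_genes=6, reads_total=100, seed=7)
        g1, _, t1 = simulate_genome(cfg)
        g2, _, t2 = simulate_genome(cfg)
        assert genome_to_fasta(g1) == genome_to_fasta(g2)
        assert t1 == t2

    def test_true_pas_inside_utr3(self, jitter_free):
        _, _, ann, truth, _ = jitter_free
        for gt in truth.genes.values():
            lo, hi = ann.gene(gt.gene_id).utr3
            assert all(lo <= p < hi for p in gt.pas_positions)

    def test_planted_signal_recoverable_in_every_window(self, jitter_free):
        """Proximal UAAA search in the 40-nt sense window recovers exactly
        the planted distance for every planted PAS."""
        _, genome, _, truth, _ = jitter_free
        checked = 0
        for gt in truth.genes.values():
            for pas, d in zip(gt.pas_positions, gt.signal_distances):
                if d is None:
                    continue
                window = _sense_window(genome, gt, pas)
                idx = window.rfind("TAAA")
                assert idx >= 0
                assert len(window) - (idx + 4) == d
                checked += 1
        assert checked >= 30

    def test_intron_consensus_planted(self, jitter_free):
        _, genome, ann, _, _ = jitter_free
        n = 0
        for gene, intron in ann.iter_introns():
            seq = genome[gene.chrom][intron.start : intron.end]
            sense = seq if gene.strand == "+" else revcomp(seq)
            assert sense.startswith("GTAAGT") and sense.endswith("AG")
            # branch adenosine at the annotated position
            bp = intron.branchpoint_pos
            base = genome[gene.chrom][bp]
            assert (base if gene.strand == "+" else revcomp(base)) == "A"
            n += 1
        assert n == 26


class TestSimulateReads:
    def test_zero_jitter_ends_exactly_at_pas(self):
        cfg = SimConfig(
            n_genes=5, n_intron_genes=0, frac_genes_with_k_pas={1: 1.0},
            end_jitter_sd=0.0, reads_total=500, seed=8,
        )
        genome, ann, truth = simulate_genome(cfg)
        reads = simulate_reads(ann, truth, cfg, rng=np.random.default_rng(9))
        pas_by_gene = {g.gene_id: g.pas_positions[0] for g in truth.genes.values()}
        from longapa.pas_calling import assign_read_to_gene

        for read in reads:
            gid = assign_read_to_gene(read, ann)
            assert three_prime_end(read) == pas_by_gene[gid]

    def test_full_retention_yields_no_spliced_reads(self):
        cfg = SimConfig(
            n_genes=4, n_intron_genes=4, retention_prob_range=(1.0, 1.0),
            reads_total=400, seed=10,
        )
        _, ann, truth = simulate_genome(cfg)
        reads = simulate_reads(ann, truth, cfg, rng=np.random.default_rng(11))
        assert all(r.n_blocks == 1 for r in reads)

    def test_pas_choice_follows_weights(self):
        """Observed PAS assignment proportions stay within 3-sigma binomial
        bounds of the configured weights."""
        cfg = SimConfig(
            n_genes=1, n_intron_genes=0, frac_genes_with_k_pas={2: 1.0},
            end_jitter_sd=0.0, reads_total=10_000, seed=12,
        )
        _, ann, truth = simulate_genome(cfg)
        reads = simulate_reads(ann, truth, cfg, rng=np.random.default_rng(13))
        (gt,) = truth.genes.values()
        n = len(reads)
        counts = {p: 0 for p in gt.pas_positions}
        for r in reads:
            counts[three_prime_end(r)] += 1
        for p, w in zip(gt.pas_positions, gt.pas_weights):
            sigma = np.sqrt(w * (1 - w) / n)
            assert abs(counts[p] / n - w) <= 3 * sigma

    def test_read_counts_follow_expression(self):
        """Chi-square goodness of fit of per-gene read counts against the
        configured expression weights, over 20 seeds."""
        cfg = SimConfig(n_genes=20, n_intron_genes=0, reads_total=4000, seed=14)
        _, ann, truth = simulate_genome(cfg)
        ids = list(truth.genes)
        expected = np.array([truth.genes[g].expected_reads for g in ids])
        rejections = 0
        for seed in range(20):
            reads = simulate_reads(ann, truth, cfg, rng=np.random.default_rng(seed))
            observed = np.zeros(len(ids))
            by_gene = {g: k for k, g in enumerate(ids)}
            from longapa.pas_calling import assign_read_to_gene

            for r in reads:
                observed[by_gene[assign_read_to_gene(r, ann)]] += 1
            keep = expected >= 5
            stat, p = scipy.stats.chisquare(
                observed[keep], expected[keep] * observed[keep].sum() / expected[keep].sum()
            )
            if p < 0.01:
                rejections += 1
        assert rejections <= 1

    def test_end_to_end_peak_recovery_without_jitter(self, jitter_free):
        """With jitter 0 and adequate depth, peak calling recovers every
        true PAS with >= 4 expected reads exactly."""
        from longapa.pas_calling import build_histograms, call_all_peaks

        _, _, ann, truth, reads = jitter_free
        hists = build_histograms(reads, ann)
        calls = call_all_peaks(hists)
        hist_by_gene = {h.gene_id: h for h in hists}
        for gt in truth.genes.values():
            h = hist_by_gene.get(gt.gene_id)
            if h is None:
                continue
            called = {c.position for c in calls[gt.gene_id]}
            for pas in gt.pas_positions:
                if h.counts.get(pas, 0) >= 4:
                    assert pas in called


class TestMakeWindowSet:
    def test_planted_distance_recorded(self):
        windows, truths = make_window_set(
            50, 1.0, uniform_distance_pmf(), rng=np.random.default_rng(15)
        )
        for w, d in zip(windows, truths):
            assert d is not None
            idx = w.rfind("UAAA")
            assert len(w) - (idx + 4) == d

    def test_unplanted_windows_contain_no_signal_when_masked(self):
        windows, truths = make_window_set(200, 0.0, rng=np.random.default_rng(16))
        assert all(d is None for d in truths)
        assert all("UAAA" not in w for w in windows)
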