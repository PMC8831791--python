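import numpy as np
import pytest

from longapa.genome_model import AlignedRead, GeneModel, GenomeAnnotation
from longapa.pas_calling import (
    ThreePrimeHistogram,
    assign_read_to_gene,
    build_histograms,
    call_all_peaks,
    call_pas_peaks,
    metagene_profile,
    summarize_apa,
)


def brute_force_peaks(counts, span, min_height=4, min_distance=18):
    """Independent reference implementation of the peak contract, written
    as plain scans: plateau candidates at the floor-midpoint, then repeated
    selection of the best remaining compatible candidate."""
    lo, hi = span
    dense = [0] * (hi - lo)
    for pos, c in counts.items():
        dense[pos - lo] = c

    candidates = []
    n = len(dense)
    for i in range(n):
        if dense[i] < min_height:
            continue
        # plateau membership: find the maximal equal run containing i,
        # record a candidate only once (at the run start)
        if i > 0 and dense[i - 1] == dense[i]:
            continue
        j = i
        while j + 1 < n and dense[j + 1] == dense[i]:
            j += 1
        if (i == 0 or dense[i - 1] < dense[i]) and (j == n - 1 or dense[j + 1] < dense[i]):
            candidates.append(((i + j) // 2, dense[i]))

    accepted = []
    remaining = list(candidates)
    while remaining:
        best = None
        for off, h in remaining:
            if best is None or (h, -off) > (best[1], -best[0]):
                best = (off, h)
        remaining.remove(best)
        if all(abs(best[0] - q) >= min_distance for q, _ in accepted):
            accepted.append(best)
    return [(lo + off, h) for off, h in accepted]


def _ann_one_gene(strand="+", start=0, end=1000, chrom_len=2000):
    return GenomeAnnotation(
        {"chr1": chrom_len}, [GeneModel("g1", "chr1", strand, start, end)]
    )


class TestAssignReadToGene:
    def test_read_inside_same_strand_gene(self):
        read = AlignedRead("r", "chr1", "+", [(100, 200)])
        assert assign_read_to_gene(read, _ann_one_gene()) == "g1"

    def test_below_quarter_overlap_unassigned(self):
        # 24 of 100 aligned bases inside the gene
        read = AlignedRead("r", "chr1", "+", [(976, 1076)])
        assert assign_read_to_gene(read, _ann_one_gene()) is None
        # boundary met at exactly 25%
        read = AlignedRead("r", "chr1", "+", [(975, 1075)])
        assert assign_read_to_gene(read, _ann_one_gene()) == "g1"

    def test_antisense_gene_not_assigned(self):
        read = AlignedRead("r", "chr1", "-", [(100, 200)])
        assert assign_read_to_gene(read, _ann_one_gene(strand="+")) is None

    def test_largest_overlap_wins(self):
        ann = GenomeAnnotation(
            {"chr1": 3000},
            [
                GeneModel("a", "chr1", "+", 0, 600),
                GeneModel("b", "chr1", "+", 600, 2000),
            ],
        )
        read = AlignedRead("r", "chr1", "+", [(500, 800)])
        assert assign_read_to_gene(read, ann) == "b"


class TestBuildHistograms:
    def test_counts_and_total(self):
        ann = _ann_one_gene()
        reads = [AlignedRead(f"r{i}", "chr1", "+", [(100, 500)]) for i in range(5)]
        (h,) = build_histograms(reads, ann)
        assert h.counts == {499: 5} and h.total_ends == 5

    def test_gene_without_reads_has_no_histogram(self):
        hists = build_histograms([], _ann_one_gene())
        assert hists == []

    def test_order_invariance(self):
        ann = GenomeAnnotation(
            {"chr1": 5000},
            [GeneModel("a", "chr1", "+", 0, 1000), GeneModel("b", "chr1", "+", 2000, 3000)],
        )
        reads = [
            AlignedRead("r1", "chr1", "+", [(10, 400)]),
            AlignedRead("r2", "chr1", "+", [(2010, 2500)]),
            AlignedRead("r3", "chr1", "+", [(10, 410)]),
        ]
        a = build_histograms(reads, ann)
        b = build_histograms(list(reversed(reads)), ann)
        assert a == b


class TestCallPasPeaks:
    def _hist(self, counts, span=(0, 600)):
        return ThreePrimeHistogram("g1", span[0], span[1], "+", dict(counts))

    def test_single_site(self):
        (call,) = call_pas_peaks(self._hist({500: 5}))
        assert (call.position, call.height, call.rank) == (500, 5, 1)

    def test_below_height_threshold(self):
        assert call_pas_peaks(self._hist({500: 3})) == []

    def test_minimum_distance_suppression(self):
        calls = call_pas_peaks(self._hist({100: 10, 110: 6}))
        assert [(c.position, c.rank) for c in calls] == [(100, 1)]
        calls = call_pas_peaks(self._hist({100: 10, 130: 6}))
        assert [(c.position, c.rank) for c in calls] == [(100, 1), (130, 2)]

    def test_plateau_floor_midpoint(self):
        calls = call_pas_peaks(self._hist({200: 5, 201: 5, 202: 5, 203: 5}))
        assert [(c.position, c.height) for c in calls] == [(201, 5)]

    def test_tie_broken_toward_smaller_coordinate(self):
        calls = call_pas_peaks(self._hist({100: 6, 110: 6}))
        assert [(c.position, c.rank) for c in calls] == [(100, 1)]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_on_random_histograms(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(250):
            length = int(rng.integers(20, 501))
            n_sites = int(rng.integers(1, 12))
            positions = rng.integers(0, length, size=n_sites)
            counts = {}
            for p in positions:
                counts[int(p)] = int(rng.integers(0, 21))
            h = self._hist(counts, span=(0, length))
            ours = [(c.position, c.height) for c in call_pas_peaks(h)]
            assert ours == brute_force_peaks(counts, (0, length))

    @pytest.mark.parametrize("seed", range(2))
    def test_validity_and_maximality_invariants(self, seed):
        """All calls >= min height, pairwise distance >= min distance, and no
        uncalled candidate could be added."""
        rng = np.random.default_rng(100 + seed)
        for _ in range(200):
            length = int(rng.integers(20, 401))
            counts = {
                int(p): int(rng.integers(0, 21))
                for p in rng.integers(0, length, size=int(rng.integers(1, 10)))
            }
            h = self._hist(counts, span=(0, length))
            calls = call_pas_peaks(h)
            positions = [c.position for c in calls]
            assert all(c.height >= 4 for c in calls)
            assert all(
                abs(p - q) >= 18
                for i, p in enumerate(positions)
                for q in positions[:i]
            )
            # maximality: every candidate is either called or within 18 nt
            # of a called peak
            all_candidates = brute_force_candidates(counts, (0, length))
            for pos, _ in all_candidates:
                assert any(abs(pos - p) < 18 for p in positions) or pos in positions


def brute_force_candidates(counts, span, min_height=4):
    lo, hi = span
    dense = [0] * (hi - lo)
    for pos, c in counts.items():
        dense[pos - lo] = c
    out = []
    n = len(dense)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and dense[j + 1] == dense[i]:
            j += 1
        if (
            dense[i] >= min_height
            and (i == 0 or dense[i - 1] < dense[i])
            and (j == n - 1 or dense[j + 1] < dense[i])
        ):
            out.append((lo + (i + j) // 2, dense[i]))
        i = j + 1
    return out


class TestSummarizeApa:
    def test_all_single_peak(self):
        calls = {"a": [_call("a", 10)], "b": [_call("b", 20)]}
        s = summarize_apa(calls)
        assert s.frac_multi_pas == 0.0 and s.frac_gt2_pas == 0.0

    def test_nested_fractions(self):
        calls = {
            "a": [_call("a", 10)],
            "b": [_call("b", 10, rank=r) for r in (1, 2)],
            "c": [_call("c", 10, rank=r) for r in (1, 2, 3, 4)],
            "d": [],
        }
        s = summarize_apa(calls)
        assert s.n_genes == 3 and s.n_genes_no_peak == 1
        assert s.frac_multi_pas == pytest.approx(2 / 3)
        assert s.frac_gt2_pas == pytest.approx(1 / 3)
        assert s.count_histogram == {0: 1, 1: 1, 2: 1, 4: 1}


def _call(gid, pos, height=5, rank=1):
    from longapa.pas_calling import PasCall

    return PasCall(gid, pos, height, rank)


class TestMetageneProfile:
    def test_all_mass_at_primary_peak(self):
        hists = [
            ThreePrimeHistogram(g, 0, 1000, "+", {500: 10}) for g in ("a", "b", "c")
        ]
        calls = {g: [_call(g, 500, 10)] for g in ("a", "b", "c")}
        profile = metagene_profile(hists, calls)
        assert profile.density[0] == pytest.approx(3.0)
        assert sum(profile.density.values()) == pytest.approx(3.0)

    def test_offset_arithmetic_plus_strand(self):
        h = ThreePrimeHistogram("a", 0, 1000, "+", {500: 8, 510: 2})
        calls = {"a": [_call("a", 500, 8)]}
        profile = metagene_profile([h], calls)
        assert profile.density[0] == pytest.approx(0.8)
        assert profile.density[10] == pytest.approx(0.2)

    def test_minus_strand_offsets_are_transcript_oriented(self):
        # on '-', smaller genomic coordinates are downstream
        h = ThreePrimeHistogram("a", 0, 1000, "-", {500: 8, 490: 2})
        calls = {"a": [_call("a", 500, 8)]}
        profile = metagene_profile([h], calls)
        assert profile.density[10] == pytest.approx(0.2)

    def test_per_gene_mass_conservation(self, small_sim):
        """Each gene contributes <= 1; exactly 1 when the window holds all
        its 3' ends."""
        _, _, ann, _, reads = small_sim
        hists = build_histograms(reads, ann)
        calls = call_all_peaks(hists)
        for h in hists:
            if not calls.get(h.gene_id):
                continue
            one = metagene_profile([h], {h.gene_id: calls[h.gene_id]}, window=50)
            mass = sum(one.density.values())
            assert mass <= 1.0 + 1e-9
            primary = next(c.position for c in calls[h.gene_id] if c.rank == 1)
            if all(abs(p - primary) <= 50 for p in h.counts):
                assert mass == pytest.approx(1.0)
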