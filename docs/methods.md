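# Methods

## Coordinates and read model

All genomic intervals are 0-based half-open; BED input is native, SAM is
converted on read. A long-read alignment is an ordered list of gapless
blocks; blocks are derived from BED12 block fields or by splitting a CIGAR
at N (skip) operations, with soft-clipped bases excluded. Secondary and
supplementary records are dropped (one vote per read, not per alignment).
PolyA tails are assumed trimmed upstream, so the read 3′ end is the last
aligned base in transcript orientation: `last block end − 1` on `+`,
`first block start` on `-`.

## PAS calling

Reads are assigned to the same-strand gene whose span covers ≥ 25% of the
read's aligned hull (largest overlap wins; ties go to the smaller start
coordinate). Per gene, the 3′-end counts are materialized as a dense vector
over the gene span and peaks are called by a fully deterministic contract:

1. candidates are local maxima with count ≥ `min_height` (default 4 reads
   ending at the same nucleotide); a plateau — a maximal run of equal
   counts bounded by strictly smaller values or the span edges — yields a
   single candidate at its floor-midpoint;
2. candidates are processed in descending height, ties toward the smaller
   coordinate;
3. a candidate is accepted iff it lies ≥ `min_distance` (default 18 nt)
   from every already-accepted peak; ranks follow acceptance order.

The plateau and tie conventions are pinned so results are bit-reproducible;
standard peak finders leave them implementation-defined. The defaults (4
reads, 18 nt) reflect that cleavage downstream of one polyA signal spreads
over roughly ±20 nt, so closer maxima are jitter of one site rather than
two sites. Peak calling uses the whole gene span, not only the annotated
3′UTR; genes with zero called peaks (insufficient depth) are excluded from
the APA-fraction denominator and reported separately, since including them
would conflate sequencing depth with biology.

The metagene profile anchors each gene at its rank-1 peak, places mass
`count/total_ends` at transcript-oriented offsets (negative 5′ of the
peak), and sums over genes; offsets beyond ±window (default 50) are
dropped, so per-gene contributed mass is ≤ 1 and equals 1 when the window
holds all ends.

## PolyA-signal discovery and distance

For the `n_top` (default 500) genes with the most assigned 3′ ends that
have a peak of the requested rank, a 40-nt sense-strand window ending 1 nt
upstream of the peak is extracted (reverse-complemented for `-` genes,
T→U). Motif discovery is exhaustive k-mer containment for k = 4–6: the
foreground fraction is the share of windows containing the k-mer at least
once; the background is the mean containment over 100
mononucleotide-preserving shuffles of each window; enrichment is
`log2((f+ε)/(bg+ε))` with `ε = 1/(2·n_windows)`. For a 4-nt signal,
exhaustive counting is complete and deterministic where heuristic motif
suites are not, which is why no external motif tool is involved. Reports
keep the top 10 k-mers per k plus any k-mer contained in ≥ 50% of windows.

The signal-to-cleavage distance counts nucleotides strictly between the
last base of UAAA and the cleavage position (a signal flush with the
window's 3′ end has distance 0). This gap-count convention is chosen
because observed minimum spacings of ~3 nt describe a gap, not a
motif-start offset. When several UAAA occur, the peak-proximal one is used
by default (`match_policy="first"` reproduces a leftmost search instead);
the proximal match is what the planted-signal recovery tests pin down.

## Fraction spliced

A read spans an intron when the read strand matches the gene strand and
its aligned hull overlaps ≥ `span_frac` (default 0.3) of the intron — the
hull, not the blocks, so a spliced read whose gap jumps the intron still
spans it. Classification has two modes: **faithful** (default) counts any
multi-block read as spliced, matching the original long-read accounting;
**strict** requires an inter-block gap to match the annotated intron
boundaries within ±3 nt, avoiding overcounting on reads with gaps
elsewhere. Faithful ≥ strict holds on any input and is asserted in tests.
Reads spanning several introns contribute to each ("for each intron"
accounting); introns with zero spanning reads are flagged, not dropped,
and no minimum-coverage filter is applied by default (`min_coverage`
exists, default 1).

## Intron features

Splice-site windows are transcript-oriented with position +1 the first
intron base (donor) or first downstream exon base (acceptor):

```
5'SS  exon[-3..-1] | intron[+1..+5]    -> 8 nt,  genomic [s-3, s+5)  on +
3'SS  intron[-20..-1] | exon[+1..+3]   -> 23 nt, genomic [e-20, e+3) on +
```

(`[s, e)` the intron; mirrored and reverse-complemented on `-`.) Splice
sites are scored with a log-odds PWM built from the windows themselves
(+0.5 pseudocounts, genome base composition as background, N positions
contribute 0) — a self-contained, deterministic scorer. Externally
computed scores (e.g. maximum-entropy splice-site models or folding
minimum free energies) are merged as optional per-intron TSV columns and
labelled as external; such trained or thermodynamic engines are
deliberately not reimplemented. Branchpoints are annotation inputs only
(their curation is manual in practice and not reproducible from sequence
alone); `bp_to_3ss` is the transcript-oriented distance from the branch
adenosine to the intron's 3′ boundary, and a missing branchpoint yields a
missing feature, never zero. Feature–splicing correlations are Pearson r
with pairwise deletion; p-values are reported raw, with no multiple-testing
correction across the handful of features (matching common practice at
n ≈ 26 introns; treat marginal p-values accordingly).

## Statistics

`stats_core` implements the only two tests the pipeline reports. Pearson r
uses the product-moment formula with two-sided p from
`t = r·sqrt((n−2)/(1−r²))` on n−2 df. The Mann–Whitney U test uses
midranks for ties; p comes from exact enumeration of group assignments
when n₁+n₂ ≤ 12 (ties handled naturally; two-sided p counts assignments
with |U−μ| at least as extreme), otherwise from the tie-corrected normal
approximation with a 0.5 continuity correction. Degenerate inputs are
flagged: constant vectors make r undefined (an error, not NaN), all-tied
samples give p = 1.

## Synthetic data generator

The generator emulates the structure of a polyA-selected long-read dataset
from a compact genome; its defaults are the study conditions the package
is exercised under:

| parameter | default | meaning |
|---|---|---|
| `frac_genes_with_k_pas` | {1: 0.37, 2: 0.29, 3: 0.34} | genes with k cleavage sites (63% > 1, 34% > 2) |
| `pas_min_separation` | 25 nt | minimum spacing of true PAS in the 3′UTR |
| `pas_weight_floor` | 0.10 | minimum usage weight of any PAS |
| `signal_plant_rate` | 0.93 | fraction of PAS with a planted upstream UAAA |
| `signal_distance_dist` | truncated geometric, 3–35 nt, mean 17 | signal-to-cleavage gap |
| `end_jitter_sd` | 2 nt | discretized Gaussian 3′-end jitter around the true PAS |
| `n_intron_genes` | 26 | single-intron genes (GUAAGU-like donor, AG acceptor, planted branch A) |
| `retention_prob_range` | [0.1, 0.9] | per-intron retention probability |
| `expression_sigma` | 1.0 | log-normal expression shape |
| `gc` | 0.55 | background GC content |

Genes are laid head-to-tail on alternating random strands; each gene is
built in transcript space (PAS in the 3′UTR ≥ 45 nt from its start so the
upstream window stays inside the gene) and written back to the genome,
reverse-complemented on `-`. Signals are planted so that each UAAA lies in
its own PAS's 40-nt window and in no other's — otherwise a neighbouring
site's signal could shadow the proximal search — and, by default, spurious
background UAAA inside windows are rewritten (T→G, which cannot create a
new occurrence), making planted distances unambiguous for recovery tests;
`mask_spurious_signal=False` turns this off. Reads are emitted pre-aligned
(the truth alignment): gene ∝ expression, PAS ∝ weights, 3′ end = PAS +
rounded Gaussian jitter clipped to the gene span, introns spliced out with
probability 1 − retention with gaps exactly at boundaries, and every read
on an intron gene spans its intron.

The generator deliberately omits sequencing error, chimeras, internal
priming, aligner noise, heavy-tailed cleavage spread, and multi-intron
genes. Passing recovery tests therefore demonstrates correctness of the
estimators under clean sampling noise, not robustness to artifacts of real
libraries.

The jitter interacts with window anchoring: with sd 2 the called peak can
sit 1–2 nt off the true PAS, so measured signal distances spread slightly
beyond the planted 3–35 range and the containing fraction can drift by a
point or two — visible in the acceptance-script output, and intentional.

## Numerical and design choices

- Peak ties, plateaus, and candidate order are fixed (see above) so every
  output is bit-reproducible; `run-all` writes a manifest with a checksum
  per output and no timestamps, and two runs with the same config and seed
  are byte-identical.
- Overlap thresholds are fractions of the *read* for gene assignment
  (0.25) and of the *intron* for spanning (0.3).
- "Block count > 1" is the spliced criterion in faithful mode; the block
  fields of a BED12 record are treated as the authority on gappedness.
- The 500-gene expression ranking for motif windows uses total assigned
  3′-end count as the expression proxy.
- Metagene offsets are transcript-oriented (flipped on `-`), making
  upstream/downstream biologically meaningful.
- The acceptance script runs at 200 genes × 300 reads/gene with log-normal
  expression (σ = 0.8), 10–20× smaller than a real flow cell but deep
  enough that depth-driven peak loss stays small; its APA fractions move a
  few points across seeds as depth varies, which is the same depth/biology
  conflation the no-peak exclusion addresses.

## Known limitations

- Multi-gene-overlapping reads are assigned to exactly one gene (largest
  overlap); the upstream analysis this mirrors did not specify the case.
- The faithful spliced rule overcounts when a gene has gaps away from the
  annotated intron (hence strict mode).
- The PWM splice-site scorer is trained on the very windows it scores —
  fine for ranking ~26 introns against each other, not a calibrated
  strength model.
- No multiple-testing correction across intron features (raw p-values).
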