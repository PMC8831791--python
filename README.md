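# longapa

Long-read analysis of alternative polyadenylation (APA) and intron
retention, built for compact, intron-poor genomes such as that of the red
alga *Cyanidioschyzon merolae* — an organism with only 27 annotated introns,
a reduced spliceosome, and (as long-read sequencing revealed) pervasive use
of multiple polyadenylation cleavage sites per gene.

Given a genome, a gene/intron annotation, and long-read alignments (BED12
or SAM; polyA tails already trimmed so each read's last aligned base abuts
the cleavage site), the package:

- **calls polyadenylation cleavage sites (PAS)** per gene as peaks of the
  read 3′-end histogram: a local maximum with height ≥ 4 reads is a PAS,
  and peaks closer than 18 nt to an already-accepted higher peak are
  suppressed (greedy minimum-distance pruning in descending height);
- **summarizes APA** as the fraction of genes with more than one and more
  than two PAS, plus a metagene 3′-end profile anchored at each gene's
  primary peak (per-gene densities normalized by total 3′-end count);
- **discovers the polyA signal** by exhaustive k-mer containment
  enrichment (k = 4–6) in 40-nt sense-strand windows upstream of ranked
  peaks, against a mononucleotide-shuffle background, and measures the
  distance from the UAAA signal to the cleavage site;
- **quantifies splicing** per intron as fraction spliced
  `f = n_spliced / n_spanning`, where a read spans an intron when its
  aligned hull covers ≥ 30% of it on the same strand, and (in the default
  "faithful" mode) any gapped read counts as spliced;
- **compares conditions** with a two-sided Mann–Whitney U test and Pearson
  correlation (both implemented in `longapa.stats_core` with documented
  tie/continuity conventions), and **correlates intron features** (length,
  GC content, 3′UTR length, branchpoint-to-3′SS distance, log-odds PWM
  splice-site scores, optional external scores) with fraction spliced.

A synthetic long-read generator (`longapa.synthetic_data`) produces a toy
genome with known PAS architecture, planted UAAA signals, known intron
retention, and log-normal expression, so every stage is verified by
parameter recovery.

## Worked example

Run the whole pipeline on simulated data (two emulated growth conditions):

```sh
longapa run-all --seed 7 --out demo
```

```
longapa 0.1.0 run summary

[rm] genes with >=1 PAS: 96 (no peak: 4); >1 PAS: 62.5%; >2 PAS: 26.0%
[ln] genes with >=1 PAS: 96 (no peak: 4); >1 PAS: 61.5%; >2 PAS: 30.2%
top 4-mer: UAAA in 94.8% of 96 primary-PAS windows (log2 enrichment 2.52)
signal-to-cleavage distance: mean 16.0 nt, range [2, 35], n=91
fraction spliced rm vs ln: U=272.0, two-sided p=0.2306
```

Reading the output: of the 96 genes with at least one called PAS, 62.5%
use more than one cleavage site and 26% more than two — the generator's
default multi-PAS mix recovered from the reads. The UAAA tetranucleotide
is the top-enriched 4-mer, contained in 94.8% of the 40-nt windows
upstream of primary peaks, sitting on average 16 nt upstream of the
cleavage site. The Mann–Whitney p compares the 26 per-intron
fraction-spliced values between the two conditions (the second condition
is simulated with retention probabilities lowered by 0.08).

`demo/` also holds the per-stage TSVs (`pas_*.tsv`, `splice_*.tsv`,
`motifs.tsv`, `signal_distances.tsv`, `features.tsv`,
`feature_correlations.tsv`, `metagene_*.tsv`), the simulated inputs and
ground truth, and `manifest.json` with a checksum of every output; the
same config and seed reproduce every file byte-for-byte.

Each stage is also available as its own subcommand (`simulate`, `splice`,
`pas`, `motif`, `signal-distance`, `features`, `compare`) operating on
files, or directly as library functions.

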