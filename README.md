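# m6adyn

Analysis toolkit for multi-tissue N6-methyladenosine (m6A) methylomes from
MeRIP-seq–style data: sliding-window peak calling, RRACH site inference,
metagene profiling, tissue-specificity scoring, sub-motif permutation tests,
poly(A) cleavage-site association, matched-control cross-species constraint
estimation, and population-genetic selection scans. A first-class synthetic
data generator produces a complete miniature study — genome, gene models,
tissue-structured IP/input coverage, cleavage sites, cross-species alignment
table, and population genotypes — with machine-readable ground truth, so the
entire pipeline is testable end to end without any external download.

It is written for computational epigenomics groups who want the bespoke
statistics of tissue m6A atlases as reusable, tested library functions rather
than one-off scripts.

## The statistics at the core

**Peak calling.** Each gene is scanned in spliced transcript coordinates with
100-nt sliding windows (step 50 nt). The enrichment score of a window is

```
winscore = log2( (MeanWinIP / MedianGeneIP) / (MeanWinInput / MedianGeneInput) )
```

with a symmetric pseudocount (default 1) in all four terms. Enriched windows
require IP window RPKM ≥ 10, winscore ≥ 2, and input gene RPKM ≥ 1; merged
enriched windows become consensus peaks when supported (winscore ≥ 2) by at
least two samples of a tissue. m6A sites are the central As of RRACH motifs
(R = A/G, H = A/C/T on the DNA sense of the transcript) inside peaks.

**Tissue specificity.** For a site with average winscore x_i in tissue i
(n tissues, negatives floored at 0),

```
tau = Σ_i (1 − x_i / max(x)) / (n − 1)
```

so tau = 0 for uniformly methylated sites and 1 for single-tissue sites.
Sites with tau < 0.15 are "shared", tau > 0.6 "tissue-specific".

**Sub-motif segregation.** RRACH resolves into GGACH/AGACH/GAACH/AAACH by its
two R bases. Whether GGACH and AAACH occupy different peaks is tested by
permuting sub-motif labels over the motif slots of a sample's peaks (10,000
shuffles); the empirical p is the left-tail fraction of shuffled
co-occurrence counts with a (b+1)/(m+1) floor.

**Evolutionary constraint.** m6A sites are compared with control A sites
(non-m6A RRACH) matched on gene dN/dS decile, position bin along the region
(20 CDS bins), and codon position. With conserved fractions f_m6A and f_ctrl
(aligned base A in the target species), the proportion of sites under
constraint is |(1 − f_m6A) − (1 − f_ctrl)| / (1 − f_ctrl); significance comes
from 10,000 matched resampled control sets.

**Selection scans.** Gain-of-motif SNPs (derived allele completes an RRAC
core) are tested for right-shifted derived-allele-frequency spectra against
matched 3'UTR and intergenic RRACH controls (one-sided Mann–Whitney U);
allele-specific methylation is tested by comparing IP vs input m6A-allele
read ratios per motif position (Kolmogorov–Smirnov); per-SNP population
differentiation uses the Weir–Cockerham (1984) Fst estimator with a strict
Fst > 0.15 high-differentiation filter.

## Worked example

Run the full synthetic demo — 60 genes, 3 tissues × 3 replicates, planted
ground truth — and inspect two of its outputs:

```
$ m6adyn run --outdir demo --seed 7 --n-genes 60 --shuffles 1000 --sets 1000
{
  "config_hash": "d517f37b2d00",
  "seed": 7,
  "n_peaks": 307,
  "n_sites": 197
}
```

307 tissue-consensus peaks yield 197 deduplicated RRACH sites. Tissue
specificity (`demo/tau.tsv`) classifies them as 127 shared, 40
tissue-specific and 30 intermediate — the generator plants 30% of sites as
single-tissue methylated, and those dominate the specific class. The
matched-control constraint test (`demo/constraint.tsv`) reports, per codon
position:

```
codon_pos  observed  control_mean  p_value  constraint_pct
        1  0.968     0.542        0.000999  93.0
        2  0.906     0.661        0.000999  72.4
        3  0.933     0.605        0.000999  83.1
```

`observed` is the conserved fraction of m6A sites in mouse, `control_mean`
the mean over matched control sets; planted conservation probabilities of
0.9 (m6A) vs 0.6 (controls) are recovered as a large, significant constraint
percentage at every codon position. Rerunning with the same seed reproduces
every output checksum in `demo/manifest.json` bit for bit.

Each stage is also available separately (`m6adyn simulate|callpeaks|
metagene|specificity|motifs|cleavage|evolution|popgen|validate`) on standard
formats: FASTA, GTF/BED12, bedGraph, BED, TSV, VCF 4.2.

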