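# Methods

This note documents the models and procedures implemented in `m6adyn`, the
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical conventions used throughout.

## Coordinates and gene models

Internal coordinates are 0-based half-open (BED convention); GTF and VCF are
converted at the boundary. Each gene carries a single isoform; windows, bins
and motif scans operate in spliced transcript coordinates (poly(A)+ data
carry no intronic signal) and are mapped back to genomic blocks for output.
Sites are assigned to the longest containing isoform, ties broken
lexicographically by gene id.

## Winscore peak calling

The window enrichment score is
`winscore = log2((MeanWinIP/MedianGeneIP) / (MeanWinInput/MedianGeneInput))`.
Choices behind the implementation:

- **Window 100 nt, step 50 nt.** The window size is the method's defining
  granularity; the half-window step keeps the window count linear while
  guaranteeing that any 100-nt signal overlaps a window by at least 50 nt. A
  final right-aligned window covers the transcript tail; genes shorter than
  one window get a single truncated window. Both are configurable.
- **Pseudocount 1** is added to all four terms of the ratio. This keeps the
  score defined on zero-coverage windows and makes it exactly antisymmetric
  under IP/input exchange. It sacrifices exact invariance under joint
  rescaling of a gene's coverage (restored exactly at pseudocount 0, which
  tests use); at study-scale coverage (~30x) the distortion is negligible.
- **Gene median coverage** is computed over all transcript bases, zeros
  included.
- **RPKM** of a window is `sum(coverage) * 1e9 / (length * library_size)`,
  with library size the sample's total summed coverage; the gene input RPKM
  is computed analogously over the transcript. Filters: IP window RPKM >= 10,
  winscore >= 2, input gene RPKM >= 1, all inclusive (>=), matching the
  calling rule's notation.
- **Consensus peaks.** Per tissue, enriched windows from all samples are
  merged into candidate regions; within a candidate, the union of the
  supporting samples' windows is re-merged and kept where at least two
  samples contribute an enriched window. A peak's per-sample winscore is the
  maximum over its member windows; a site's per-sample winscore is that of
  its best covering window.
- **Top-50 normalisation.** To remove sample-level RIP-efficiency scale, each
  sample's winscores can be multiplied by a factor mapping the mean of its
  top-50 peak winscores onto the cross-sample average of those means (all
  peaks if fewer than 50).

## Metagene profile

mRNAs are binned 10:50:40 (5'UTR:CDS:3'UTR; 100 bins total), reflecting the
typical relative segment lengths of the human transcriptome, so bin 60 is
the first 3'UTR bin and the stop codon sits at the 59/60 boundary. The bin of
a site is `first_bin + floor(region_relative_position * region_bins)`,
half-open relative position, clamped at the region's last bin. Raw per-bin
fractions are the canonical output; the least-squares polynomial smooth
(default degree 5) is presentation-only and never feeds downstream
statistics. Noncoding-gene sites have no UTR/CDS structure and are excluded
from the 100-bin profile; region annotation uses precedence CDS > UTR >
ncRNA when equal-length isoforms disagree.

## Tissue specificity

Per site, x_i is the mean winscore over tissue i's replicates at the site's
best covering window — computed in every tissue whether or not a peak was
called there, since tau needs a complete profile; uncovered samples
contribute 0. Negative means are floored at 0 so the normalised profile
stays in [0,1]. tau = sum(1 - x_i/max x)/(n-1); all-zero profiles are
undefined and excluded with a reason. Classification uses strict
inequalities: shared tau < 0.15, specific tau > 0.6. "Methylated in tissue
t" for the sharing spectrum means the site lies in a consensus peak of t —
a peak-support criterion, deliberately distinct from the tau thresholds.
Ubiquitously expressed genes are those with expression (input RPKM) > 3 in
every tissue, strict.

## Sub-motif shuffle test

Motif slots are the RRACH occurrences inside a sample's peaks (each sample's
merged enriched windows; replicates are tested separately and then
summarised). The null permutes sub-motif class labels uniformly over all
slots with positions fixed — the minimal null that randomises class-to-peak
assignment, which is exactly what the co-occurrence statistic (number of
peaks containing both GGACH and AAACH) probes. The wording "sub-motif
sequences were shuffled" is ambiguous between shuffling sequences and labels;
the label-permutation reading is adopted because it conserves both margins
(per-peak slot counts and per-class totals) by construction. The empirical
p uses the (b+1)/(m+1) correction, so the smallest attainable p at 10,000
shuffles is 1/10001, and observed/expected counts are mean-centred by
dividing by the mean expected count.

## Cross-species constraint

Control A sites are non-m6A RRACH motifs matched to the m6A set within
strata of (gene dN/dS decile x region-position bin x codon position). Deciles
balance stratum occupancy against matching fidelity for "similar dN/dS"; the
CDS uses 20 position bins. When a stratum is under-populated the pipeline
retries on progressively coarser grids (10x20 → 1x1) and reports the grid
used. "Conserved" requires the aligned base to be exactly A — the methylated
base itself, not merely a purine. The null distribution over 10,000 matched
control sets is computed by summing per-stratum hypergeometric draws of
conserved counts, which is distributionally identical to drawing the sets
explicitly and orders of magnitude faster; a test verifies the equivalence
against explicit draws. p = (#{null >= observed} + 1)/(n + 1). The
constraint proportion |(1-f_m6A)-(1-f_ctrl)|/(1-f_ctrl) is reported as a
percentage with its sign kept in metadata. Site age is the rank of the most
distant species whose aligned base is A (literal reading; conservation in
intermediate species is not required — configurable), 0 when conserved
nowhere. Rejected-substitution-style constraint scores are treated as an
input column; the generator emits a correlated surrogate.

## Selection scans

SNP annotation substitutes each allele into the reference context and
rescans both strands for RRACH; the m6A allele is the allele whose
substitution matches. SNPs where both alleles complete a motif (at different
frames) are flagged ambiguous and excluded from ratio tests. A gain-of-motif
SNP is one whose derived allele (from INFO/AA, upper-case = high confidence;
records without AA are excluded and counted) completes an RRAC core that the
ancestral allele does not. The allele-ratio test aggregates per-(SNP,
compartment) mean m6A-allele ratios and compares IP vs input per motif
position with the two-sample KS test (suppressed below 5 SNPs). DAF spectra
are compared one-sided (m6A group right-shifted) with the Mann–Whitney U
normal approximation with tie correction. Fst is the per-SNP Weir &
Cockerham (1984) variance-components estimator computed from diploid
genotypes; raw values are reported (may be negative), monomorphic records are
skipped, and the high-differentiation filter is strict Fst > 0.15. No
multiple-testing correction is applied by default (raw p values are
reported).

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, at a
miniature scale (defaults: 200 genes of 200 + 999 + 800 nt UTR5/CDS/UTR3 on
one contig each with 600-nt intergenic flanks, 3 tissues x 3 replicates):

- **Sites.** Per-gene site counts are Poisson(1.5/kb); positions mix a
  stop-codon-proximal Gaussian (sd 150 nt, weight 0.6) with a uniform
  component, so metagene recovery is testable. Planted 5-mers are written as
  RRACH in transcript orientation; sub-motif classes default to proportions
  0.45/0.25/0.15/0.15 (GG/AG/GA/AA). A site is single-tissue methylated with
  probability `tissue_specific_fraction` (default 0.3), otherwise methylated
  in all tissues.
- **Background scrubbing.** Background RRACH within ±100 nt of a planted
  site are disrupted (central A mutated), so a planted peak's footprint
  contains exactly the planted motif. Because site inference calls every
  RRACH inside a peak, this is what makes site-level precision a meaningful,
  measurable quantity against the planted truth; background motifs elsewhere
  are left untouched and supply the control pools.
- **Coverage.** Per-base negative binomial (dispersion 10) around depth 30;
  IP means are multiplied by the site's enrichment within ±50 nt of each
  methylated site (matching the 100-nt calling window), with per-site
  enrichment lognormal around 8 (sigma 0.25) so methylation levels vary.
  `enrichment_factor = 8` is a free parameter chosen so winscore >= 2 (a
  4-fold normalised ratio) is comfortably reachable; at 1 the IP and input
  tracks are identically distributed (the null setting).
- **Cleavage sites.** One per coding gene with probability 0.8, in the
  3'UTR; a PAS hexamer (AAUAAA 0.5 / AUUAAA 0.1 / other variant 0.1 / none
  0.3) is planted 21 nt upstream, and 30% of cleavage positions carry an m6A
  site exactly at the cleavage base (those prefer AAACH with probability
  0.5). Noncanonical sites get a C at +1 with probability 0.7. The truth PAS
  class is re-derived from the final sequence, so truth and classifier are
  consistent by construction.
- **Conservation.** Every transcript RRACH A yields one record; each
  species' aligned base is A with probability 0.9 (planted m6A) or 0.6
  (background), independently per species; otherwise a random substitution
  or gap. Gene dN/dS ~ Gamma(2, 0.15) (mean 0.3, a typical coding value),
  shared by all sites of a gene.
- **Genotypes.** Two populations of 100 haplotypes (50 diploids). Neutral
  derived frequencies ~ Beta(0.5, 1.5) (right-skewed toward rare, a cheap
  stand-in for the neutral SFS). Gain-of-motif SNPs are planted at m6A-site,
  background-3'UTR and intergenic RRACH As (60 each); a `selected_fraction`
  of the m6A-group SNPs gets the derived frequency shifted +0.3 in the last
  population, producing both high Fst and a right-shifted global DAF. Loss-
  of-motif SNPs and AA-less records (5%) exercise the remaining code paths.
  Het-SNP pileups simulate input ratios at 0.5 and IP ratios at 0.75 for
  RRAC-position SNPs of methylated sites (0.5 at H), around depth 40.
- **Determinism.** Every artifact draws from a named RNG stream derived from
  the master seed by a CRC32 key, so outputs are bit-identical given
  (config, seed) and adding artifacts never perturbs existing ones.

What the generator does **not** emulate: read-level data (coverage is
simulated directly as per-base counts, since the caller consumes coverage and
mapping is out of scope), sequencing error, fragment-length effects, isoform
diversity (one isoform per gene), realistic linkage disequilibrium between
SNPs (frequencies are drawn independently), phylogenetically correlated
substitution processes (per-species conservation is independent Bernoulli),
or transcriptome-realistic RRACH density around sites (see scrubbing above).
Passing recovery tests therefore demonstrates the correctness and power of
the statistics under their assumed signal model, not robustness to the full
noise structure of real MeRIP-seq.

## Numerical and testing conventions

- All thresholds inclusive (>=) except where the definitions are strict
  (tau classes, FPKM > 3, Fst > 0.15).
- Empirical p values always carry the +1 correction and are never 0.
- The matched-control null is vectorised via hypergeometric draws (above).
- Quartiles in the constraint-vs-level comparison are nearest-rank: bottom
  and top n//4 of the score order, disjoint by construction; fewer than 8
  sites suppresses the comparison.
- p-value calibration suites assert KS-uniformity over >= 200 reduced-size
  null runs for the shuffle, matched-control and Mann–Whitney tests. The
  two-sample KS p is lattice-valued at realistic SNP counts (an exact
  discrete test cannot be KS-uniform even on continuous data), so its suite
  asserts tail validity (P(p <= a) <= a at several a) and non-degeneracy
  instead.
- Problem sizes in the test suite (40–220 genes, 1,000–10,000 resamples,
  20–200 calibration runs) were chosen as the smallest scales at which the
  planted effects are unambiguous; the full demo runs in about a minute on
  one CPU.

## Known limitations

- The sliding step and pseudocount of the winscore method are not pinned by
  any published description; both are configurable and the defaults are
  documented above.
- Site age uses the literal most-distant-species definition; a monotone
  "conserved up to rank k" variant would differ for non-nested conservation
  patterns.
- The "other" canonical PAS group uses a configurable list of ten common
  single-base AAUAAA variants; membership of that group in the wild varies
  by catalogue.
- Heterozygosity thresholds for allele-ratio SNPs (depth >= 10, minor allele
  fraction >= 0.2 when calling from pileups) are pipeline choices; the
  simulated pileups are generated heterozygous by construction.
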