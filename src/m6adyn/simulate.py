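"""Synthetic miniature m6A study with machine-readable ground truth.

Generates a small genome (one gene per contig, flanked by intergenic
sequence), plants RRACH m6A sites with tissue-structured methylation and a
stop-codon-concentrated positional distribution, simulates paired IP/input
coverage with multiplicative IP enrichment around methylated sites,
cleavage sites with planted poly(A) signals, a cross-species aligned-base
table with different conservation probabilities for m6A and control sites,
and population genotypes with known ancestral alleles and optional
selection on gain-of-motif SNPs.

Every artifact draws from its own named RNG stream derived from the master
seed (see `rngs`), so outputs are bit-identical for identical (config, seed)
and adding an artifact never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import CleavageSite, GeneModel, SampleTrack, SnpRecord, revcomp
from .motifs import find_rrach, is_rrach
from .rngs import stream
from . import cleavage as _cleavage

__all__ = [
    "SimConfig",
    "SimTruth",
    "PlantedSite",
    "SimulatedStudy",
    "generate_genome",
    "plant_m6a_sites",
    "simulate_coverage",
    "simulate_alignment_table",
    "simulate_genotypes",
    "simulate_study",
]

BASES = np.array(list("ACGT"))
R_BASES = ("A", "G")
H_BASES = ("A", "C", "T")

# transcript-strand scrub radius around planted sites: background RRACH
# inside the peak footprint would otherwise be called as spurious sites
SCRUB_RADIUS = 100
ENRICH_HALF_WINDOW = 50
PAS_OFFSET = 21  # hexamer start this many nt upstream of the cleavage position


@dataclass
class SimConfig:
    """Study conditions of the synthetic experiment (defaults = demo scale:
    200 genes, 3 tissues x 3 replicates)."""

    seed: int = 0
    n_genes: int = 200
    tissue_names: tuple = ("brain", "heart", "liver")
    replicates_per_tissue: int = 3
    utr5_cds_utr3_lengths: tuple = (200, 999, 800)
    site_density: float = 1.5  # expected planted sites per kb of transcript
    enrichment_factor: float = 8.0  # IP fold enrichment at methylated windows
    depth: float = 30.0  # mean input coverage per base
    tissue_specific_fraction: float = 0.3
    conservation_prob_m6a: float = 0.9
    conservation_prob_control: float = 0.6
    n_populations: int = 2
    n_haplotypes_per_pop: int = 100
    selected_fraction: float = 0.5  # of m6A gain-of-motif SNPs under selection

    # genome geometry
    flank_length: int = 600
    intron_length_range: tuple = (150, 250)
    noncoding_fraction: float = 0.05

    # site planting
    stop_concentration: float = 0.6  # mixture weight of the stop-proximal component
    stop_sd: float = 150.0
    cds_site_weight: float = 1.0  # >1 biases the uniform component into the CDS
    min_site_spacing: int = 12
    submotif_probs: dict = field(
        default_factory=lambda: {"GG": 0.45, "AG": 0.25, "GA": 0.15, "AA": 0.15}
    )
    aaach_excess_tissue: str = ""  # tissue whose specific sites prefer AAACH
    segregate_submotifs: bool = False  # plant GGACH/AAACH in disjoint genes

    # coverage
    nb_dispersion: float = 10.0
    site_enrichment_sigma: float = 0.25  # lognormal spread of per-site enrichment

    # cleavage sites
    cleavage_per_gene_prob: float = 0.8
    cleavage_m6a_fraction: float = 0.3
    aaach_at_cleavage_bias: float = 0.5
    pas_class_probs: dict = field(
        default_factory=lambda: {"AAUAAA": 0.5, "AUUAAA": 0.1, "other": 0.1, "none": 0.3}
    )
    noncanonical_c_downstream: float = 0.7

    # conservation table
    species_panel: tuple = ("chimp", "rhesus", "mouse", "dog", "opossum", "chicken")
    dnds_shape: float = 2.0
    dnds_scale: float = 0.15
    score_winscore_coupling: float = 0.0  # rejection-score surrogate coupling

    # genotypes
    daf_shift: float = 0.3
    neutral_snps_per_kb: float = 1.0
    n_gain_snps_per_group: int = 60
    n_loss_snps: int = 20
    missing_aa_fraction: float = 0.05
    n_ratio_snps: int = 60
    ratio_read_depth: float = 40.0
    ip_allele_bias: float = 0.75

    def validate(self):
        u5, cds, u3 = self.utr5_cds_utr3_lengths
        if min(u5, cds, u3) <= 0:
            raise ValueError("UTR/CDS segment lengths must be positive")
        if cds % 3 != 0:
            raise ValueError(f"CDS length {cds} not divisible by 3")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if not self.tissue_names or len(set(self.tissue_names)) != len(self.tissue_names):
            raise ValueError("tissue_names must be non-empty and unique")
        for name in (
            "tissue_specific_fraction",
            "conservation_prob_m6a",
            "conservation_prob_control",
            "selected_fraction",
            "cleavage_m6a_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_genes < 1 or self.replicates_per_tissue < 1:
            raise ValueError("n_genes and replicates_per_tissue must be >= 1")
        if abs(sum(self.pas_class_probs.values()) - 1) > 1e-9:
            raise ValueError("pas_class_probs must sum to 1")
        return self


@dataclass
class PlantedSite:
    site_id: str
    gene_id: str
    chrom: str
    gpos: int
    strand: str
    tx_offset: int
    motif: str
    tissues: set
    enrichment: float = 1.0
    at_cleavage: bool = False


@dataclass
class SimTruth:
    planted_sites: list = field(default_factory=list)
    planted_cleavage_sites: list = field(default_factory=list)
    constrained_sites: set = field(default_factory=set)
    selected_snps: set = field(default_factory=set)

    def validate(self, genome: dict, genes_by_id: dict):
        """Every planted 5-mer must match RRACH on the transcript strand of
        the emitted reference."""
        for ps in self.planted_sites:
            gene = genes_by_id[ps.gene_id]
            tx = gene.transcript_seq(genome[ps.chrom])
            mer = tx[ps.tx_offset - 2 : ps.tx_offset + 3]
            if not is_rrach(mer) or mer != ps.motif:
                raise AssertionError(f"planted site {ps.site_id} motif mismatch: {mer}")
            if gene.tx_to_genomic(ps.tx_offset) != ps.gpos:
                raise AssertionError(f"planted site {ps.site_id} coordinate mismatch")
        return True


def _random_seq(rng, n: int) -> list:
    return list(rng.choice(BASES, size=n))


def generate_genome(config: SimConfig, rng: np.random.Generator | None = None):
    """Random genome + single-isoform gene models (one gene per contig).

    UTRs stay in the terminal exons; two introns split the CDS. RRACH motifs
    arise naturally in the random sequence both inside and outside the
    regions where sites will later be planted. Deterministic given
    (config, seed).
    """
    config.validate()
    rng = stream(config.seed, "genome") if rng is None else rng
    u5, cds, u3 = config.utr5_cds_utr3_lengths
    tx_len = u5 + cds + u3
    genome, genes = {}, []
    for g in range(config.n_genes):
        chrom = f"chr{g + 1}"
        gene_id = f"gene{g + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        coding = rng.random() >= config.noncoding_fraction
        tx = _random_seq(rng, tx_len)
        # intron insertion points inside the CDS span (or mid-transcript for
        # noncoding genes), keeping UTRs in terminal exons
        lo, hi = (u5 + 30, u5 + cds - 30) if coding else (30, tx_len - 30)
        cuts = sorted(rng.choice(np.arange(lo, hi), size=2, replace=False).tolist())
        ilens = rng.integers(*config.intron_length_range, size=2)
        parts = [tx[: cuts[0]], tx[cuts[0] : cuts[1]], tx[cuts[1] :]]
        introns = [_random_seq(rng, int(n)) for n in ilens]
        flanks = [_random_seq(rng, config.flank_length) for _ in range(2)]

        if strand == "+":
            ordered = parts
            ordered_introns = introns
        else:
            ordered = [list(revcomp("".join(p))) for p in reversed(parts)]
            ordered_introns = list(reversed(introns))
        pieces, exon_spans, pos = [flanks[0]], [], config.flank_length
        for i, exon in enumerate(ordered):
            pieces.append(exon)
            exon_spans.append((pos, pos + len(exon)))
            pos += len(exon)
            if i < 2:
                pieces.append(ordered_introns[i])
                pos += len(ordered_introns[i])
        pieces.append(flanks[1])
        genome[chrom] = "".join("".join(p) for p in pieces)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=exon_spans,
                cds_start=u5 if coding else 0,
                cds_end=u5 + cds if coding else 0,
                coding=coding,
            )
        )
    return genome, genes


def _write_back(gene: GeneModel, tx: list, chrom_seq: str) -> str:
    """Project an edited transcript back onto its chromosome."""
    cs = list(chrom_seq)
    for off in range(gene.tx_length):
        gpos = gene.tx_to_genomic(off)
        cs[gpos] = tx[off] if gene.strand == "+" else revcomp(tx[off])
    return "".join(cs)


def _draw_motif(rng, config: SimConfig, prefer_aaach: bool = False,
                forced_class: str | None = None) -> str:
    if forced_class is not None:
        rr = forced_class
    elif prefer_aaach and rng.random() < config.aaach_at_cleavage_bias:
        rr = "AA"
    else:
        keys = sorted(config.submotif_probs)
        probs = np.array([config.submotif_probs[k] for k in keys])
        rr = keys[rng.choice(len(keys), p=probs / probs.sum())]
    return rr + "AC" + str(rng.choice(np.array(H_BASES)))


def _position_weights(gene: GeneModel, config: SimConfig) -> np.ndarray:
    L = gene.tx_length
    pos = np.arange(L, dtype=float)
    uniform = np.ones(L)
    if gene.coding and config.cds_site_weight != 1.0:
        uniform[gene.cds_start : gene.cds_end] = config.cds_site_weight
    uniform /= uniform.sum()
    if gene.coding:
        stop = gene.cds_end
        gauss = np.exp(-0.5 * ((pos - stop) / config.stop_sd) ** 2)
        gauss /= gauss.sum()
        w = config.stop_concentration * gauss + (1 - config.stop_concentration) * uniform
    else:
        w = uniform
    # keep the 5-mer and enrichment window inside the transcript
    w[:ENRICH_HALF_WINDOW] = 0
    w[L - ENRICH_HALF_WINDOW :] = 0
    return w / w.sum()


def _draw_tissues(rng, config: SimConfig) -> set:
    if rng.random() < config.tissue_specific_fraction:
        return {config.tissue_names[rng.integers(len(config.tissue_names))]}
    return set(config.tissue_names)


def plant_m6a_sites(genes, genome: dict, config: SimConfig,
                    rng: np.random.Generator | None = None):
    """Plant m6A sites and cleavage sites; returns (truth, edited genome).

    Site counts per gene are Poisson(site_density * length/kb); positions mix
    a stop-codon-proximal Gaussian with a uniform component. Each planted
    site's 5-mer is written as RRACH in transcript orientation and background
    RRACH within the peak footprint (+/-100 nt) is disrupted so the planted
    site is the only motif its peak contains. Per-tissue methylation flags
    honour `tissue_specific_fraction`. Cleavage sites (one per coding gene
    with probability `cleavage_per_gene_prob`) get a planted PAS hexamer and,
    for a configured fraction, an m6A site exactly at the cleavage position;
    the truth PAS class is re-derived from the final sequence.
    """
    rng = stream(config.seed, "sites") if rng is None else rng
    truth = SimTruth()
    genome = dict(genome)
    for gi, gene in enumerate(genes):
        tx = list(gene.transcript_seq(genome[gene.chrom]))
        L = gene.tx_length
        planted_offsets: list[int] = []
        site_specs = []  # (tx_offset, motif, tissues, at_cleavage)
        forced_class = None
        if config.segregate_submotifs:
            forced_class = "GG" if gi % 2 == 0 else "AA"

        # --- cleavage site (coding genes only) ---
        cleav = None
        if gene.coding and rng.random() < config.cleavage_per_gene_prob:
            off = int(rng.integers(gene.cds_end + 60, L - 60))
            klass = rng.choice(
                sorted(config.pas_class_probs),
                p=[config.pas_class_probs[k] for k in sorted(config.pas_class_probs)],
            )
            hexamer = {"AAUAAA": "AATAAA", "AUUAAA": "ATTAAA"}.get(klass)
            if klass == "other":
                hexamer = str(rng.choice(np.array(_cleavage.PAS_VARIANTS)))
            if hexamer:
                tx[off - PAS_OFFSET : off - PAS_OFFSET + 6] = list(hexamer)
            has_m6a = rng.random() < config.cleavage_m6a_fraction
            if has_m6a:
                motif = _draw_motif(rng, config, prefer_aaach=True,
                                    forced_class=forced_class)
                tx[off - 2 : off + 3] = list(motif)
                site_specs.append((off, motif, _draw_tissues(rng, config), True))
                planted_offsets.append(off)
            elif rng.random() < config.noncanonical_c_downstream and klass == "none":
                tx[off + 1] = "C"
            cleav = (off, has_m6a)

        # --- density-planted sites ---
        n_sites = rng.poisson(config.site_density * L / 1000.0)
        weights = _position_weights(gene, config)
        attempts = 0
        while n_sites > 0 and attempts < 50 * n_sites:
            attempts += 1
            off = int(rng.choice(L, p=weights))
            if any(abs(off - o) < config.min_site_spacing for o in planted_offsets):
                continue
            motif = _draw_motif(rng, config, forced_class=forced_class)
            tissues = _draw_tissues(rng, config)
            if (
                config.aaach_excess_tissue
                and tissues == {config.aaach_excess_tissue}
                and forced_class is None
                and rng.random() < 0.6
            ):
                motif = "AA" + motif[2:]
            tx[off - 2 : off + 3] = list(motif)
            site_specs.append((off, motif, tissues, False))
            planted_offsets.append(off)
            n_sites -= 1

        # --- scrub background RRACH inside peak footprints ---
        planted_spans = [(o - 2, o + 3) for o in planted_offsets]
        seq_str = "".join(tx)
        for o in planted_offsets:
            lo, hi = max(2, o - SCRUB_RADIUS), min(L - 2, o + SCRUB_RADIUS + 1)
            for a in list(find_rrach(seq_str, lo, hi)):
                if any(s <= a < e for s, e in planted_spans):
                    continue
                tx[a] = "T"
            seq_str = "".join(tx)

        genome[gene.chrom] = _write_back(gene, tx, genome[gene.chrom])

        for off, motif, tissues, at_cleavage in site_specs:
            gpos = gene.tx_to_genomic(off)
            enr = config.enrichment_factor
            if enr > 1 and config.site_enrichment_sigma > 0:
                enr = float(
                    np.exp(np.log(enr) + config.site_enrichment_sigma * rng.standard_normal())
                )
            truth.planted_sites.append(
                PlantedSite(
                    site_id=f"{gene.chrom}:{gpos}:{gene.strand}",
                    gene_id=gene.gene_id,
                    chrom=gene.chrom,
                    gpos=gpos,
                    strand=gene.strand,
                    tx_offset=off,
                    motif=motif,
                    tissues=tissues,
                    enrichment=enr,
                    at_cleavage=at_cleavage,
                )
            )
        if cleav is not None:
            off, has_m6a = cleav
            truth.planted_cleavage_sites.append(
                CleavageSite(
                    chrom=gene.chrom,
                    pos=gene.tx_to_genomic(off),
                    strand=gene.strand,
                    gene_id=gene.gene_id,
                    pas_class=_cleavage.classify_pas(
                        genome[gene.chrom], gene.tx_to_genomic(off), gene.strand
                    ),
                    region="3UTR",
                    has_m6a=has_m6a,
                )
            )
    if config.conservation_prob_m6a > config.conservation_prob_control:
        truth.constrained_sites = {ps.site_id for ps in truth.planted_sites}
    return truth, genome


def simulate_coverage(genes, truth: SimTruth, config: SimConfig,
                      rng: np.random.Generator | None = None):
    """Per-sample IP/input transcript coverage tracks.

    Input coverage is negative-binomial noise around `depth` at every base.
    IP coverage follows the same law with the mean multiplied by the site's
    enrichment within +/-50 nt of each site methylated in the sample's
    tissue. Returns (tracks, design) where design maps sample_id -> tissue.
    """
    rng = stream(config.seed, "coverage") if rng is None else rng
    k = config.nb_dispersion
    sites_by_gene = {}
    for ps in truth.planted_sites:
        sites_by_gene.setdefault(ps.gene_id, []).append(ps)

    tracks, design = [], {}
    for tissue in config.tissue_names:
        for r in range(config.replicates_per_tissue):
            sid = f"{tissue}_rep{r + 1}"
            design[sid] = tissue
            ip_cov, in_cov = {}, {}
            for gene in genes:
                L = gene.tx_length
                in_mean = np.full(L, config.depth)
                ip_mean = np.full(L, config.depth)
                for ps in sites_by_gene.get(gene.gene_id, []):
                    if tissue in ps.tissues and ps.enrichment != 1.0:
                        lo = max(0, ps.tx_offset - ENRICH_HALF_WINDOW)
                        hi = min(L, ps.tx_offset + ENRICH_HALF_WINDOW + 1)
                        ip_mean[lo:hi] *= ps.enrichment
                in_cov[gene.gene_id] = rng.negative_binomial(
                    k, k / (k + in_mean)
                ).astype(float)
                ip_cov[gene.gene_id] = rng.negative_binomial(
                    k, k / (k + ip_mean)
                ).astype(float)
            tracks.append(
                SampleTrack(
                    sample_id=sid,
                    tissue=tissue,
                    ip=ip_cov,
                    input_=in_cov,
                    ip_library_size=float(sum(a.sum() for a in ip_cov.values())),
                    input_library_size=float(sum(a.sum() for a in in_cov.values())),
                )
            )
    return tracks, design


def _site_rows(genes, genome, truth):
    """All RRACH A positions in transcripts with coordinates and annotation."""
    planted = {ps.site_id for ps in truth.planted_sites}
    enr = {ps.site_id: ps.enrichment for ps in truth.planted_sites}
    rows = []
    for gene in genes:
        tx = gene.transcript_seq(genome[gene.chrom])
        L = gene.tx_length
        for a in find_rrach(tx):
            gpos = gene.tx_to_genomic(a)
            site_id = f"{gene.chrom}:{gpos}:{gene.strand}"
            region = gene.region_of(a)
            if region == "5UTR":
                rel = a / gene.cds_start if gene.cds_start else 0.0
            elif region == "CDS":
                rel = (a - gene.cds_start) / (gene.cds_end - gene.cds_start)
            elif region == "3UTR":
                rel = (a - gene.cds_end) / (L - gene.cds_end)
            else:
                rel = a / L
            rows.append(
                {
                    "site_id": site_id,
                    "chrom": gene.chrom,
                    "pos": gpos,
                    "strand": gene.strand,
                    "gene_id": gene.gene_id,
                    "tx_offset": a,
                    "region": region,
                    "rel_pos": rel,
                    "codon_pos": ((a - gene.cds_start) % 3) + 1 if region == "CDS" else 0,
                    "is_m6a": site_id in planted,
                    "enrichment": enr.get(site_id, 1.0),
                }
            )
    return rows


def simulate_alignment_table(genes, genome: dict, truth: SimTruth, config: SimConfig,
                             rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-site aligned bases across the species panel, plus gene dN/dS.

    Every RRACH A in every transcript yields one record. The aligned base in
    each species is A with probability `conservation_prob_m6a` (planted
    sites) or `conservation_prob_control` (background RRACH), independently
    per species; otherwise a substitution or gap. Gene dN/dS ~ Gamma(shape,
    scale), shared by all sites of a gene. A rejection-score surrogate is
    emitted, optionally coupled to the site's planted enrichment.
    """
    rng = stream(config.seed, "alignment") if rng is None else rng
    rows = _site_rows(genes, genome, truth)
    dnds = {g.gene_id: float(rng.gamma(config.dnds_shape, config.dnds_scale)) for g in genes}
    non_a = np.array(["C", "G", "T", "-"])
    for row in rows:
        row["dnds"] = dnds[row["gene_id"]]
        p = config.conservation_prob_m6a if row["is_m6a"] else config.conservation_prob_control
        for sp in config.species_panel:
            row[sp] = "A" if rng.random() < p else str(rng.choice(non_a))
        base = config.score_winscore_coupling * np.log2(row["enrichment"]) if row["is_m6a"] else 0.0
        row["score"] = float(base + rng.standard_normal())
    return pd.DataFrame(rows)


def _neutral_freq(rng) -> float:
    return float(rng.beta(0.5, 1.5))


def simulate_genotypes(genes, genome: dict, truth: SimTruth, config: SimConfig,
                       rng: np.random.Generator | None = None):
    """Biallelic SNPs with ancestral alleles, genotypes and IP/input pileups.

    Gain-of-motif SNPs (reference/derived allele A completing RRACH, ancestral
    allele breaking it) are planted in three groups: at planted 3'UTR m6A
    sites, at background 3'UTR RRACH, and at intergenic RRACH. A
    `selected_fraction` of the m6A-group SNPs get their derived allele
    frequency shifted by `daf_shift` in the last population (high Fst,
    right-shifted DAF); everything else is neutral with both populations
    sharing the ancestral frequency. Also emits loss-of-motif SNPs, neutral
    non-motif SNPs (a few lacking the AA tag), and het-SNP allele-ratio
    pileups for the allele-specific methylation test.

    Returns (snp records, genotypes {snp_id: {pop: dosage array}}, pileups
    DataFrame); selected SNP ids are recorded in `truth.selected_snps`.
    """
    rng = stream(config.seed, "genotypes") if rng is None else rng
    pops = [f"pop{i + 1}" for i in range(config.n_populations)]
    n_hap = config.n_haplotypes_per_pop
    if n_hap % 2:
        raise ValueError("n_haplotypes_per_pop must be even (diploid individuals)")

    site_rows = _site_rows(genes, genome, truth)
    genes_by_id = {g.gene_id: g for g in genes}
    m6a_utr3 = [r for r in site_rows if r["is_m6a"] and r["region"] == "3UTR"]
    bg_utr3 = [r for r in site_rows if not r["is_m6a"] and r["region"] == "3UTR"]
    intergenic = []
    for gene in genes:
        seq = genome[gene.chrom]
        for lo, hi in [(0, config.flank_length),
                       (len(seq) - config.flank_length, len(seq))]:
            for a in find_rrach(seq, lo, hi):
                intergenic.append(
                    {"chrom": gene.chrom, "pos": a, "strand": "+",
                     "gene_id": "", "region": "intergenic"}
                )

    snps, genotypes = [], {}
    counter = [0]

    def _add_snp(chrom, pos, ref, alt, aa, freqs, region):
        counter[0] += 1
        snp_id = f"snp{counter[0]:05d}"
        pop_counts, geno = {}, {}
        for pop, q_alt in zip(pops, freqs):
            hap = (rng.random(n_hap) < q_alt).astype(np.int8)
            geno[pop] = hap.reshape(-1, 2).sum(axis=1)
            pop_counts[pop] = (int(hap.sum()), n_hap)
        rec = SnpRecord(
            snp_id=snp_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
            ancestral=aa, pop_counts=pop_counts, region=region,
        )
        snps.append(rec)
        genotypes[snp_id] = geno
        return rec

    def _plant_gain(rows, n, selectable):
        chosen_idx = rng.choice(len(rows), size=min(n, len(rows)), replace=False)
        for i in sorted(chosen_idx.tolist()):
            r = rows[i]
            # alleles live on the genomic forward strand: the motif allele is
            # the reference base (A, or T for minus-strand genes)
            ref = genome[r["chrom"]][r["pos"]].upper()
            anc_tx = str(rng.choice(np.array(["C", "G", "T"])))
            anc = anc_tx if r["strand"] == "+" else revcomp(anc_tx)
            q_der = _neutral_freq(rng)
            selected = selectable and rng.random() < config.selected_fraction
            freqs_der = [q_der] * config.n_populations
            if selected:
                freqs_der[-1] = min(q_der + config.daf_shift, 0.98)
            rec = _add_snp(
                r["chrom"], r["pos"], ref, anc, anc,
                [1.0 - q for q in freqs_der], r["region"],
            )
            if selected:
                truth.selected_snps.add(rec.snp_id)

    _plant_gain(m6a_utr3, config.n_gain_snps_per_group, selectable=True)
    _plant_gain(bg_utr3, config.n_gain_snps_per_group, selectable=False)
    _plant_gain(intergenic, config.n_gain_snps_per_group, selectable=False)

    # loss-of-motif SNPs: ancestral allele is the m6A allele (A)
    loss_pool = [r for r in site_rows if r["is_m6a"] and r["region"] != "CDS"
                 and r not in m6a_utr3[: config.n_gain_snps_per_group]]
    if loss_pool and config.n_loss_snps:
        idx = rng.choice(len(loss_pool), size=min(config.n_loss_snps, len(loss_pool)),
                         replace=False)
        for i in sorted(idx.tolist()):
            r = loss_pool[i]
            ref = genome[r["chrom"]][r["pos"]].upper()
            alt_tx = str(rng.choice(np.array(["C", "G", "T"])))
            alt = alt_tx if r["strand"] == "+" else revcomp(alt_tx)
            q_alt = _neutral_freq(rng)
            _add_snp(r["chrom"], r["pos"], ref, alt, ref,
                     [q_alt] * config.n_populations, r["region"])

    # neutral background SNPs away from motifs
    motif_positions = {(r["chrom"], r["pos"]) for r in site_rows}
    for gene in genes:
        seq = genome[gene.chrom]
        n = rng.poisson(config.neutral_snps_per_kb * len(seq) / 1000.0)
        for pos in sorted(rng.choice(len(seq) - 10, size=n, replace=False).tolist()):
            pos += 5
            if (gene.chrom, pos) in motif_positions:
                continue
            ref = seq[pos].upper()
            if ref not in "ACGT":
                continue
            alt = str(rng.choice(np.array([b for b in "ACGT" if b != ref])))
            aa = "" if rng.random() < config.missing_aa_fraction else (
                ref if rng.random() < 0.5 else alt
            )
            q_alt = _neutral_freq(rng)
            _add_snp(gene.chrom, pos, ref, alt, aa,
                     [q_alt] * config.n_populations, "neutral")

    pileups = _simulate_pileups(genes_by_id, genome, truth, config, rng)
    return snps, genotypes, pileups


def _simulate_pileups(genes_by_id, genome, truth, config, rng) -> pd.DataFrame:
    """Het-SNP read pileups: m6A-allele ratio ~0.5 in input everywhere and in
    IP at H-position SNPs; biased toward the m6A allele in IP at RRAC-position
    SNPs of methylated sites."""
    labels = ["R1", "R2", "A", "C", "H"]
    rows = []
    pool = [ps for ps in truth.planted_sites if ps.tx_offset >= 2]
    idx = rng.choice(len(pool), size=min(config.n_ratio_snps, len(pool)), replace=False)
    samples = [
        (f"{t}_rep{r + 1}", t)
        for t in config.tissue_names
        for r in range(config.replicates_per_tissue)
    ]
    for n, i in enumerate(sorted(idx.tolist())):
        ps = pool[i]
        j = int(rng.integers(5))
        snp_id = f"ratio{n + 1:04d}"
        for sid, tissue in samples:
            depth_in = int(rng.poisson(config.ratio_read_depth)) + 1
            depth_ip = int(rng.poisson(config.ratio_read_depth)) + 1
            p_ip = 0.5
            if labels[j] != "H" and tissue in ps.tissues:
                p_ip = config.ip_allele_bias
            rows.append({"snp_id": snp_id, "motif_position": labels[j],
                         "sample_id": sid, "compartment": "input",
                         "m6a_reads": int(rng.binomial(depth_in, 0.5)),
                         "total_reads": depth_in})
            rows.append({"snp_id": snp_id, "motif_position": labels[j],
                         "sample_id": sid, "compartment": "IP",
                         "m6a_reads": int(rng.binomial(depth_ip, p_ip)),
                         "total_reads": depth_ip})
    return pd.DataFrame(rows)


@dataclass
class SimulatedStudy:
    config: SimConfig
    genome: dict
    genes: list
    truth: SimTruth
    tracks: list
    design: dict
    conservation: pd.DataFrame
    snps: list
    genotypes: dict
    pileups: pd.DataFrame

    @property
    def genes_by_id(self):
        return {g.gene_id: g for g in self.genes}


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Run every generator stage under named RNG streams."""
    genome, genes = generate_genome(config)
    truth, genome = plant_m6a_sites(genes, genome, config)
    truth.validate(genome, {g.gene_id: g for g in genes})
    tracks, design = simulate_coverage(genes, truth, config)
    conservation = simulate_alignment_table(genes, genome, truth, config)
    snps, genotypes, pileups = simulate_genotypes(genes, genome, truth, config)
    return SimulatedStudy(
        config=config, genome=genome, genes=genes, truth=truth, tracks=tracks,
        design=design, conservation=conservation, snps=snps,
        genotypes=genotypes, pileups=pileups,
    )
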