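"""End-to-end orchestration: synthetic study -> all analysis stages.

Stage functions operate on in-memory objects and are reused by the CLI; the
`run` entry point simulates a study, writes every artifact in its standard
format, executes the stages in dependency order and records a manifest
(config hash, seeds, per-output checksums) so reruns are verifiably
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from collections import defaultdict

import numpy as np
import pandas as pd

from . import cleavage as cl
from . import evolution as ev
from . import io as mio
from . import metagene as mg
from . import motifs as mo
from . import peaks as pk
from . import popgen as pg
from . import specificity as sp
from .rngs import stream
from .simulate import SimConfig, simulate_study

__all__ = [
    "config_hash",
    "stage_peakcall",
    "sample_peak_slots",
    "winscore_matrix",
    "expression_matrix",
    "stage_specificity",
    "stage_metagene",
    "stage_motifs",
    "stage_cleavage",
    "stage_evolution",
    "stage_popgen",
    "run",
]

log = logging.getLogger(__name__)


def config_hash(config: SimConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def stage_peakcall(genes, tracks, design, **params):
    """Window stats, enriched windows, consensus peaks and RRACH sites."""
    genes_by_id = {g.gene_id: g for g in genes}
    stats_by_sample, enriched_by_sample = {}, {}
    for tr in tracks:
        st = pk.call_sample_windows(genes, tr, **params)
        stats_by_sample[tr.sample_id] = st
        enriched_by_sample[tr.sample_id] = {
            g: ws for g, ws in ((g, pk.call_enriched_windows(w)) for g, w in st.items()) if ws
        }
    peaks = pk.consensus_peaks(enriched_by_sample, stats_by_sample, design, genes_by_id)
    return {
        "stats_by_sample": stats_by_sample,
        "enriched_by_sample": enriched_by_sample,
        "peaks": peaks,
    }


def infer_study_sites(peaks, genome, genes, stats_by_sample):
    genes_by_id = {g.gene_id: g for g in genes}
    return pk.infer_sites(peaks, genome, genes_by_id, stats_by_sample)


def sample_peak_slots(enriched_for_sample: dict, genome: dict, genes_by_id: dict):
    """Per-sample candidate peaks (merged enriched windows) -> lists of
    sub-motif class labels for the RRACH occurrences inside each peak."""
    slots = []
    for gid in sorted(enriched_for_sample):
        gene = genes_by_id[gid]
        tx = gene.transcript_seq(genome[gene.chrom])
        merged = pk._merge_intervals(
            [(w.start, w.end) for w in enriched_for_sample[gid]]
        )
        for s, e in merged:
            labels = [
                mo.classify_submotif(tx[a - 2 : a + 3])
                for a in mo.find_rrach(tx, s, e)
                if "N" not in tx[a - 2 : a + 3]
            ]
            if labels:
                slots.append(labels)
    return slots


def winscore_matrix(sites, stats_by_sample) -> pd.DataFrame:
    """Site-by-sample winscores at the best covering window (NaN when the
    sample has no window over the site)."""
    data = {}
    for sid in sorted(stats_by_sample):
        per_gene = stats_by_sample[sid]
        col = {}
        for site in sites:
            col[site.site_id] = pk.site_winscore(
                per_gene.get(site.gene_id, []), site.tx_offset
            )
        data[sid] = col
    return pd.DataFrame(data, dtype=float)


def expression_matrix(tracks, genes) -> pd.DataFrame:
    """Gene x tissue input-RPKM means (FPKM-like expression levels)."""
    rows = defaultdict(dict)
    per_tissue = defaultdict(list)
    for tr in tracks:
        per_tissue[tr.tissue].append(tr)
    for tissue, trs in per_tissue.items():
        for g in genes:
            vals = [
                pk.rpkm(float(tr.input_[g.gene_id].sum()), g.tx_length, tr.input_library_size)
                for tr in trs
                if g.gene_id in tr.input_
            ]
            rows[g.gene_id][tissue] = float(np.mean(vals)) if vals else 0.0
    return pd.DataFrame(rows).T


def stage_specificity(sites, stats_by_sample, design):
    matrix = winscore_matrix(sites, stats_by_sample)
    profiles = sp.tissue_winscore_matrix(matrix, design)
    taus = profiles.apply(sp.compute_tau, axis=1)
    classes = sp.classify_sites(taus)
    n_tissues = len(set(design.values()))
    spectrum = sp.sharing_spectrum({s.site_id: s.tissues for s in sites}, n_tissues)
    return {"matrix": matrix, "profiles": profiles, "taus": taus,
            "classes": classes, "spectrum": spectrum}


def stage_metagene(sites, genes):
    genes_by_id = {g.gene_id: g for g in genes}
    labels = mg.annotate_genic_region(sites, genes)
    assignments = [
        mg.site_to_bin(s.tx_offset, genes_by_id[s.gene_id], s.site_id)
        for s in sites
        if labels[s.site_id] in ("5UTR", "CDS", "3UTR")
    ]
    counts, fractions, smoothed = mg.metagene_profile(assignments)
    ratio = mg.cds_utr3_ratio({"all": labels})["all"]
    return {"labels": labels, "assignments": assignments, "counts": counts,
            "fractions": fractions, "smoothed": smoothed, "cds_utr3_ratio": ratio}


def stage_motifs(enriched_by_sample, genome, genes_by_id, design,
                 n_shuffles=10_000, seed=0):
    """Per-sample sub-motif proportions over peak slots plus the
    GGACH/AAACH co-occurrence shuffle test."""
    props, shuffle_rows = {}, []
    for sid in sorted(enriched_by_sample):
        slots = sample_peak_slots(enriched_by_sample[sid], genome, genes_by_id)
        flat = [lab for peak in slots for lab in peak]
        if not flat:
            continue
        counts = pd.Series(flat).value_counts()
        props[sid] = counts.reindex(mo.SUBMOTIF_CLASSES, fill_value=0) / len(flat)
        try:
            res = mo.cooccurrence_test(
                slots, n_shuffles=n_shuffles, rng=stream(seed, f"shuffle/{sid}")
            )
        except ValueError:
            continue
        shuffle_rows.append({
            "sample_id": sid, "observed": res.observed, "m_expected": res.m_expected,
            "observed_norm": res.observed_norm, "p_value": res.p_value,
        })
    prop_df = pd.DataFrame(props).T
    variability = mo.submotif_variability(prop_df, design) if len(prop_df) > 1 else None
    return {"proportions": prop_df, "variability": variability,
            "shuffle": pd.DataFrame(shuffle_rows)}


def stage_cleavage(sites, cleavage_sites, genome, labels, window=200):
    offsets, counts = cl.distance_distribution(sites, cleavage_sites, window=window)
    utr3_ids = [sid for sid, lab in labels.items() if lab == "3UTR"]
    submotif = cl.submotif_at_cleavage(sites, cleavage_sites, utr3_ids)
    for c in cleavage_sites:
        c.pas_class = cl.classify_pas(genome[c.chrom], c.pos, c.strand)
    profiles, contexts = cl.composition_profile(cleavage_sites, genome)
    m6a_keys = {(s.chrom, s.gpos, s.strand) for s in sites}
    pas_rows = []
    for c in cleavage_sites:
        pas_rows.append({"pas_class": c.pas_class,
                         "has_m6a": (c.chrom, c.pos, c.strand) in m6a_keys})
    return {"offsets": offsets, "distance_counts": counts, "submotif": submotif,
            "composition": profiles, "contexts": contexts,
            "pas_table": pd.DataFrame(pas_rows)}


def stage_evolution(conservation: pd.DataFrame, species: str = "mouse",
                    n_sets: int = 10_000, seed: int = 0):
    """Matched-control constraint test per codon position plus 3'UTR ages."""
    cds = conservation[conservation["region"] == "CDS"]
    results = {}
    # progressively coarser (dN/dS bins, region bins) grids: matching runs at
    # the finest grid whose control strata are all populated
    grids = [(10, 20), (5, 10), (4, 5), (2, 3), (1, 2), (1, 1)]
    for codon in (1, 2, 3):
        sub = cds[cds["codon_pos"] == codon]
        m6a = sub[sub["is_m6a"]]
        pool = sub[~sub["is_m6a"]]
        if len(m6a) < 5:
            continue
        null = None
        for n_dnds, n_region in grids:
            strat = ev.add_strata(pd.concat([m6a, pool]), n_dnds_bins=n_dnds,
                                  n_region_bins=n_region)
            m6a_s = strat[strat["is_m6a"]]
            pool_s = strat[~strat["is_m6a"]]
            try:
                null = ev.null_distribution(
                    m6a_s, pool_s, species, n_sets=n_sets,
                    rng=stream(seed, f"evo/codon{codon}"),
                )
                break
            except ValueError as exc:
                log.info("codon %d grid (%d,%d) infeasible: %s",
                         codon, n_dnds, n_region, exc)
        if null is None:
            log.warning("codon %d: matching infeasible at every grid", codon)
            continue
        f_ctrl = float(null.null_fractions.mean())
        prop = ev.constraint_proportion(null.observed, f_ctrl) if 0 < f_ctrl < 1 else (np.nan, 0)
        results[codon] = {
            "observed": null.observed, "control_mean": f_ctrl, "p_value": null.p_value,
            "constraint_pct": prop[0], "constraint_sign": prop[1],
        }
    panel = [c for c in ("chimp", "rhesus", "mouse", "dog", "opossum", "chicken", "zebrafish")
             if c in conservation.columns]
    ages = ev.utr3_age_profile(conservation, panel)
    return {"codon_tests": results, "age_profile": ages, "species_panel": panel}


def stage_popgen(snps, genotypes, genome, pileups, m6a_positions=None, strand_of=None):
    """SNP motif annotation, allele-ratio test, DAF spectra and per-SNP Fst.

    `m6a_positions`: set of (chrom, pos) of m6A sites; gain-of-motif SNPs at
    those positions form the m6A DAF group, the rest split into the 3'UTR and
    intergenic control groups by their region annotation.
    """
    annotated = pg.annotate_motif_snps(snps, genome, strand_of=strand_of)
    ratio = pg.allele_ratio_test(pileups) if pileups is not None and len(pileups) else None

    daf_test = None
    if m6a_positions is not None:
        daf_groups = defaultdict(list)
        for s in annotated:
            if not s.creates_motif or s.ambiguous:
                continue
            if (s.chrom, s.pos) in m6a_positions:
                daf_groups["m6a"].append(s.daf())
            elif s.region == "3UTR":
                daf_groups["utr3_control"].append(s.daf())
            elif s.region == "intergenic":
                daf_groups["intergenic_control"].append(s.daf())
        if daf_groups.get("m6a"):
            controls = {k: v for k, v in daf_groups.items() if k != "m6a" and v}
            if controls:
                daf_test = pg.daf_spectrum_test(daf_groups["m6a"], controls)

    fst = {}
    for s in annotated:
        est = pg.weir_cockerham_fst(list(genotypes[s.snp_id].values()))
        if est is not None:
            fst[s.snp_id] = est
    fst = pd.Series(fst, dtype=float)
    high = pg.high_fst_filter(fst)
    return {"snps": annotated, "allele_ratio": ratio, "daf_test": daf_test,
            "fst": fst, "high_fst": high}


def validate_inputs(fasta=None, genes_bed=None, design=None, cleavage_bed=None,
                    vcf=None):
    """Pre-flight format and consistency checks.

    Returns a list of (level, message) with level in {"fatal", "warning"};
    callers abort on any fatal finding before executing stages.
    """
    report = []
    genome = None
    if fasta:
        try:
            genome = mio.read_fasta(fasta)
            if not genome:
                report.append(("fatal", f"{fasta}: no sequences"))
        except Exception as exc:  # unparseable FASTA
            report.append(("fatal", f"{fasta}: {exc}"))
    if genes_bed:
        try:
            genes = mio.read_bed12(genes_bed)
            for g in genes:
                if genome is not None and g.chrom not in genome:
                    report.append(("fatal", f"{genes_bed}: chrom {g.chrom} absent from FASTA"))
                if genome is not None and g.span[1] > len(genome[g.chrom]):
                    report.append(("fatal", f"{genes_bed}: {g.gene_id} beyond contig end"))
        except Exception as exc:
            report.append(("fatal", f"{genes_bed}: {exc}"))
    if design:
        try:
            df = mio.read_design(design)
            base = os.path.dirname(design)
            for _, row in df.iterrows():
                for col in ("ip_bedgraph", "input_bedgraph"):
                    path = os.path.join(base, row[col])
                    if not os.path.exists(path):
                        report.append(("fatal", f"{design}: missing track {row[col]}"))
                        continue
                    if genome is not None:
                        for chrom, runs in mio.read_bedgraph(path).items():
                            if chrom not in genome:
                                report.append(
                                    ("fatal", f"{row[col]}: chrom {chrom} absent from FASTA"))
                            for s, e, _ in runs:
                                if e <= s:
                                    report.append(("fatal", f"{row[col]}: interval end <= start"))
        except Exception as exc:
            report.append(("fatal", f"{design}: {exc}"))
    if cleavage_bed:
        try:
            with open(cleavage_bed) as fh:
                for i, line in enumerate(fh, 1):
                    if not line.strip() or line.startswith(("#", "track")):
                        continue
                    f = line.split("\t")
                    if int(f[2]) <= int(f[1]):
                        report.append(("fatal", f"{cleavage_bed}:{i}: interval end <= start"))
                    if f[5].strip() not in ("+", "-"):
                        report.append(("fatal", f"{cleavage_bed}:{i}: bad strand {f[5]!r}"))
        except Exception as exc:
            report.append(("fatal", f"{cleavage_bed}: {exc}"))
    if vcf:
        try:
            with open(vcf) as fh:
                for line in fh:
                    if line.startswith("#"):
                        continue
                    f = line.split("\t")
                    if "AA=" not in f[7]:
                        report.append(
                            ("warning",
                             f"{vcf}: record {f[2]} lacks INFO/AA (excluded from DAF)"))
        except Exception as exc:
            report.append(("fatal", f"{vcf}: {exc}"))
    return report


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: SimConfig, outdir: str, n_shuffles: int = 2000, n_sets: int = 2000):
    """Simulate, write artifacts, run every stage, write outputs + manifest."""
    os.makedirs(outdir, exist_ok=True)
    chash = config_hash(config)
    study = simulate_study(config)
    genes_by_id = study.genes_by_id
    paths = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    mio.write_fasta(study.genome, p("reference.fa"))
    mio.write_gtf(study.genes, p("genes.gtf"), "simulate", chash)
    mio.write_bed12(study.genes, p("genes.bed12"), "simulate", chash)
    bg_paths = {}
    for tr in study.tracks:
        ipf, inf = f"{tr.sample_id}.ip.bedgraph", f"{tr.sample_id}.input.bedgraph"
        mio.write_bedgraph(tr.ip, genes_by_id, p(ipf), "simulate", chash)
        mio.write_bedgraph(tr.input_, genes_by_id, p(inf), "simulate", chash)
        bg_paths[tr.sample_id] = (ipf, inf)
    mio.write_design(study.tracks, bg_paths, p("design.tsv"), "simulate", chash)
    mio.write_cleavage_bed(study.truth.planted_cleavage_sites, p("cleavage.bed"),
                           "simulate", chash)
    mio.write_tsv(study.conservation, p("conservation.tsv"), "simulate", chash)
    mio.write_vcf(study.snps, study.genotypes, p("snps.vcf"), "simulate", chash)
    mio.write_pops(study.genotypes, p("populations.tsv"))
    mio.write_tsv(study.pileups, p("pileups.tsv"), "simulate", chash)
    truth_df = pd.DataFrame(
        [{"site_id": s.site_id, "gene_id": s.gene_id, "chrom": s.chrom, "pos": s.gpos,
          "strand": s.strand, "tx_offset": s.tx_offset, "motif": s.motif,
          "tissues": ",".join(sorted(s.tissues)), "at_cleavage": int(s.at_cleavage)}
         for s in study.truth.planted_sites]
    )
    mio.write_tsv(truth_df, p("truth_sites.tsv"), "simulate", chash)

    # --- analysis stages (from the in-memory study; files are the archive) ---
    res = stage_peakcall(study.genes, study.tracks, study.design)
    sites = infer_study_sites(res["peaks"], study.genome, study.genes,
                              res["stats_by_sample"])
    mio.write_sites_bed(sites, p("m6a_sites.bed"), "peakcall", chash)

    meta = stage_metagene(sites, study.genes)
    mio.write_tsv(
        pd.DataFrame({"bin": np.arange(len(meta["fractions"])),
                      "count": meta["counts"], "fraction": meta["fractions"]}),
        p("metagene.tsv"), "metagene", chash,
    )

    spec = stage_specificity(sites, res["stats_by_sample"], study.design)
    mio.write_tsv(spec["matrix"].reset_index(names="site_id"),
                  p("winscore_matrix.tsv"), "specificity", chash)
    mio.write_tsv(
        pd.DataFrame({"tau": spec["taus"], "class": spec["classes"]})
        .reset_index(names="site_id"),
        p("tau.tsv"), "specificity", chash,
    )

    mot = stage_motifs(res["enriched_by_sample"], study.genome, genes_by_id,
                       study.design, n_shuffles=n_shuffles, seed=config.seed)
    mio.write_tsv(mot["shuffle"], p("submotif_shuffle.tsv"), "motifs", chash)

    clv = stage_cleavage(sites, study.truth.planted_cleavage_sites, study.genome,
                         meta["labels"])
    mio.write_tsv(
        pd.DataFrame({"offset": clv["offsets"], "count": clv["distance_counts"]}),
        p("cleavage_distance.tsv"), "cleavage", chash,
    )

    evo = stage_evolution(study.conservation, n_sets=n_sets, seed=config.seed)
    mio.write_tsv(
        pd.DataFrame(evo["codon_tests"]).T.reset_index(names="codon_pos"),
        p("constraint.tsv"), "evolution", chash,
    )

    pop = stage_popgen(
        study.snps, study.genotypes, study.genome, study.pileups,
        m6a_positions={(s.chrom, s.gpos) for s in sites},
    )
    mio.write_tsv(pop["fst"].rename("fst").rename_axis("snp_id").reset_index(),
                  p("fst.tsv"), "popgen", chash)

    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "n_peaks": len(res["peaks"]),
        "n_sites": len(sites),
        "outputs": {name: _sha256(path) for name, path in sorted(paths.items())},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
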