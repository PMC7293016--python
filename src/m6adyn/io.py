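"""Readers and writers for the pipeline's standard formats.

Internal coordinates are 0-based half-open; BED/bedGraph are native, GTF and
VCF are converted at the boundary (1-based). Text outputs carry a header
comment naming the producing stage and the run's config hash where the
format permits.
"""

from __future__ import annotations

import os
from collections import defaultdict

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .models import CleavageSite, GeneModel, SampleTrack, SnpRecord

__all__ = [
    "write_fasta", "read_fasta",
    "write_gtf", "write_bed12", "read_bed12",
    "write_bedgraph", "read_bedgraph", "project_track",
    "write_design", "read_design",
    "write_cleavage_bed", "read_cleavage_bed",
    "write_sites_bed", "read_sites_bed",
    "write_tsv", "read_tsv",
    "write_vcf", "read_vcf",
]


def _header(stage: str, config_hash: str) -> str:
    return f"# stage={stage} config={config_hash}\n" if stage else ""


def write_fasta(genome: dict, path: str, width: int = 60):
    with open(path, "w") as fh:
        for chrom in sorted(genome, key=lambda c: (len(c), c)):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict:
    fa = Fasta(path, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_gtf(genes, path: str, stage: str = "", config_hash: str = ""):
    with open(path, "w") as fh:
        fh.write(_header(stage, config_hash))
        for g in genes:
            s, e = g.span
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(f"{g.chrom}\tm6adyn\ttranscript\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
            for es, ee in g.exons:
                fh.write(f"{g.chrom}\tm6adyn\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t{attrs}\n")


def write_bed12(genes, path: str, stage: str = "", config_hash: str = ""):
    with open(path, "w") as fh:
        fh.write(_header(stage, config_hash))
        for g in genes:
            s, e = g.span
            if g.coding:
                # CDS bounds back to genomic (thickStart/thickEnd)
                a = g.tx_to_genomic(g.cds_start)
                b = g.tx_to_genomic(g.cds_end - 1)
                thick_s, thick_e = min(a, b), max(a, b) + 1
            else:
                thick_s = thick_e = s
            sizes = ",".join(str(ee - es) for es, ee in g.exons)
            starts = ",".join(str(es - s) for es, ee in g.exons)
            fh.write(
                f"{g.chrom}\t{s}\t{e}\t{g.gene_id}\t0\t{g.strand}\t{thick_s}\t{thick_e}"
                f"\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
            )


def read_bed12(path: str):
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start = f[0], int(f[1])
            name, strand = f[3], f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
            coding = thick_e > thick_s
            g = GeneModel(gene_id=name, chrom=chrom, strand=strand, exons=exons,
                          cds_start=0, cds_end=1 if coding else 0, coding=coding)
            if coding:
                a = g.genomic_to_tx(thick_s)
                b = g.genomic_to_tx(thick_e - 1)
                g.cds_start, g.cds_end = min(a, b), max(a, b) + 1
            genes.append(g)
    return genes


def write_bedgraph(per_gene_cov: dict, genes_by_id: dict, path: str,
                   stage: str = "", config_hash: str = ""):
    """Transcript coverage projected to genomic runs (per-gene exon blocks)."""
    lines = []
    for gid in sorted(per_gene_cov):
        gene = genes_by_id[gid]
        vals = per_gene_cov[gid]
        per_pos = sorted(
            (gene.tx_to_genomic(off), float(vals[off])) for off in range(gene.tx_length)
        )
        run_start, run_end, run_val = None, None, None
        for gpos, v in per_pos:
            if run_start is not None and gpos == run_end and v == run_val:
                run_end += 1
                continue
            if run_start is not None:
                lines.append((gene.chrom, run_start, run_end, run_val))
            run_start, run_end, run_val = gpos, gpos + 1, v
        if run_start is not None:
            lines.append((gene.chrom, run_start, run_end, run_val))
    with open(path, "w") as fh:
        fh.write(_header(stage, config_hash))
        for chrom, s, e, v in lines:
            fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path: str) -> dict:
    """chrom -> list of (start, end, value)."""
    cov = defaultdict(list)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")
            cov[chrom].append((int(s), int(e), float(v)))
    return dict(cov)


def project_track(genes, cov: dict) -> dict:
    """Genomic coverage runs -> per-gene transcript arrays (zeros where
    uncovered)."""
    out = {}
    for gene in genes:
        arr = np.zeros(gene.tx_length)
        span_s, span_e = gene.span
        dense = None
        runs = cov.get(gene.chrom, [])
        if runs:
            dense = np.zeros(span_e - span_s)
            for s, e, v in runs:
                s2, e2 = max(s, span_s), min(e, span_e)
                if s2 < e2:
                    dense[s2 - span_s : e2 - span_s] = v
            for off in range(gene.tx_length):
                arr[off] = dense[gene.tx_to_genomic(off) - span_s]
        out[gene.gene_id] = arr
    return out


def write_design(tracks, paths: dict, path: str, stage: str = "", config_hash: str = ""):
    """Sample sheet: tissue, bedGraph paths and library sizes per sample."""
    with open(path, "w") as fh:
        fh.write(_header(stage, config_hash))
        fh.write("sample_id\ttissue\tip_bedgraph\tinput_bedgraph\tip_libsize\tinput_libsize\n")
        for t in tracks:
            ipf, inf = paths[t.sample_id]
            fh.write(
                f"{t.sample_id}\t{t.tissue}\t{ipf}\t{inf}\t"
                f"{t.ip_library_size:g}\t{t.input_library_size:g}\n"
            )


def read_design(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def load_tracks(design: pd.DataFrame, genes, base_dir: str = ""):
    """Reconstruct SampleTrack objects from a design sheet's bedGraphs."""
    tracks = []
    for _, row in design.iterrows():
        ip = project_track(genes, read_bedgraph(os.path.join(base_dir, row["ip_bedgraph"])))
        inp = project_track(genes, read_bedgraph(os.path.join(base_dir, row["input_bedgraph"])))
        tracks.append(
            SampleTrack(
                sample_id=row["sample_id"], tissue=row["tissue"], ip=ip, input_=inp,
                ip_library_size=float(row["ip_libsize"]),
                input_library_size=float(row["input_libsize"]),
            )
        )
    return tracks


def write_cleavage_bed(sites, path: str, stage: str = "", config_hash: str = ""):
    with open(path, "w") as fh:
        fh.write(_header(stage, config_hash))
        for c in sites:
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.pos + 1}\t{c.gene_id or '.'}"
                f"\t0\t{c.strand}\t{c.pas_class}\t{c.region}\t{int(c.has_m6a)}\n"
            )


def read_cleavage_bed(path: str):
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            sites.append(
                CleavageSite(
                    chrom=f[0], pos=int(f[1]), strand=f[5],
                    gene_id="" if f[3] == "." else f[3],
                    pas_class=f[6] if len(f) > 6 else "none",
                    region=f[7] if len(f) > 7 else "3UTR",
                    has_m6a=bool(int(f[8])) if len(f) > 8 else False,
                )
            )
    return sites


def write_sites_bed(sites, path: str, stage: str = "", config_hash: str = ""):
    """m6A sites as BED6+ (extra: gene, tx offset, motif, tissues)."""
    with open(path, "w") as fh:
        fh.write(_header(stage, config_hash))
        for s in sites:
            tissues = ",".join(sorted(s.tissues)) or "."
            fh.write(
                f"{s.chrom}\t{s.gpos}\t{s.gpos + 1}\t{s.site_id}\t0\t{s.strand}"
                f"\t{s.gene_id}\t{s.tx_offset}\t{s.motif}\t{tissues}\n"
            )


def read_sites_bed(path: str):
    from .models import M6ASite

    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            sites.append(
                M6ASite(
                    site_id=f[3], chrom=f[0], gpos=int(f[1]), strand=f[5],
                    gene_id=f[6], tx_offset=int(f[7]), motif=f[8],
                    tissues=set() if f[9] == "." else set(f[9].split(",")),
                )
            )
    return sites


def write_tsv(df: pd.DataFrame, path: str, stage: str = "", config_hash: str = "",
              index: bool = False):
    with open(path, "w") as fh:
        fh.write(_header(stage, config_hash))
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def write_vcf(snps, genotypes: dict, path: str, stage: str = "", config_hash: str = ""):
    """VCF 4.2 with the ancestral allele in INFO/AA and diploid GTs.

    Sample columns are named {pop}_ind{i}; the population assignment is
    recoverable from the names and is also written by `write_pops`.
    """
    pops = sorted({p for g in genotypes.values() for p in g})
    sample_names = []
    n_ind = {p: len(next(iter(genotypes.values()))[p]) for p in pops} if genotypes else {}
    for p in pops:
        sample_names += [f"{p}_ind{i + 1}" for i in range(n_ind[p])]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if stage:
            fh.write(f"##source=m6adyn {stage} config={config_hash}\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        for snp in sorted(snps, key=lambda s: (len(s.chrom), s.chrom, s.pos)):
            info = f"AA={snp.ancestral}" if snp.ancestral else "."
            gts = []
            geno = genotypes[snp.snp_id]
            for p in pops:
                for dose in geno[p]:
                    gts.append(("0/0", "0/1", "1/1")[int(dose)])
            fh.write(
                f"{snp.chrom}\t{snp.pos + 1}\t{snp.snp_id}\t{snp.ref}\t{snp.alt}"
                f"\t.\tPASS\t{info}\tGT\t" + "\t".join(gts) + "\n"
            )


def write_pops(genotypes: dict, path: str):
    pops = sorted({p for g in genotypes.values() for p in g})
    n_ind = {p: len(next(iter(genotypes.values()))[p]) for p in pops}
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\n")
        for p in pops:
            for i in range(n_ind[p]):
                fh.write(f"{p}_ind{i + 1}\t{p}\n")


def read_vcf(path: str, pops_path: str):
    """Plain-text VCF 4.2 -> (SnpRecords, genotypes dict). Records without
    INFO/AA get ancestral=\"\" (excluded from DAF downstream)."""
    pop_of = {}
    with open(pops_path) as fh:
        next(fh)
        for line in fh:
            sample, pop = line.split()
            pop_of[sample] = pop
    snps, genotypes = [], {}
    with open(path) as fh:
        samples = []
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.rstrip("\n").split("\t")[9:]
                continue
            f = line.rstrip("\n").split("\t")
            chrom, pos, snp_id, ref, alt = f[0], int(f[1]) - 1, f[2], f[3], f[4]
            if len(ref) != 1 or len(alt) != 1 or alt == ".":
                continue  # biallelic SNVs only
            aa = ""
            for kv in f[7].split(";"):
                if kv.startswith("AA="):
                    aa = kv[3:]
            geno = defaultdict(list)
            for sample, gt in zip(samples, f[9:]):
                alleles = gt.replace("|", "/").split("/")
                geno[pop_of[sample]].append(sum(a == "1" for a in alleles))
            geno = {p: np.array(v) for p, v in geno.items()}
            pop_counts = {p: (int(v.sum()), 2 * len(v)) for p, v in geno.items()}
            snps.append(SnpRecord(snp_id=snp_id, chrom=chrom, pos=pos, ref=ref,
                                  alt=alt, ancestral=aa, pop_counts=pop_counts))
            genotypes[snp_id] = geno
    return snps, genotypes
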