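"""Metagene binning and genic-region annotation of m6A sites.

mRNAs are divided into 100 bins reflecting the typical relative lengths of
their segments — 10 bins for the 5'UTR, 50 for the CDS, 40 for the 3'UTR —
so the stop codon sits at the bin 59/60 boundary. Sites on noncoding genes
have no UTR/CDS structure and are excluded from the 100-bin profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import GeneModel

__all__ = [
    "BinAssignment",
    "REGION_BINS",
    "assign_longest_isoform",
    "site_to_bin",
    "metagene_profile",
    "annotate_genic_region",
    "cds_utr3_ratio",
]

# region -> (first bin, bin count)
REGION_BINS = {"5UTR": (0, 10), "CDS": (10, 50), "3UTR": (60, 40)}
N_BINS = 100


@dataclass
class BinAssignment:
    site_id: str
    region: str
    bin: int
    rel_pos: float
    flagged: bool = False


def assign_longest_isoform(chrom: str, gpos: int, strand: str, transcripts):
    """The containing transcript with maximum spliced length (exonic overlap
    required); ties break lexicographically by gene_id. None if intergenic."""
    best = None
    for t in transcripts:
        if t.chrom != chrom or t.strand != strand:
            continue
        if t.genomic_to_tx(gpos) is None:
            continue
        if (
            best is None
            or t.tx_length > best.tx_length
            or (t.tx_length == best.tx_length and t.gene_id < best.gene_id)
        ):
            best = t
    return best


def site_to_bin(tx_offset: int, gene: GeneModel, site_id: str = "") -> BinAssignment:
    """Bin index (0-99) of a transcript offset under the 10:50:40 layout.

    bin = region_first_bin + floor(region_relative_position * region_bins),
    clamped to the region's last bin. A zero-length region cannot contain a
    site; a site at the boundary of a zero-length neighbour is assigned to
    the region it falls in and flagged.
    """
    if not gene.coding:
        raise ValueError(f"{gene.gene_id} is noncoding; no metagene bins")
    if not 0 <= tx_offset < gene.tx_length:
        raise ValueError("offset outside transcript")
    bounds = {
        "5UTR": (0, gene.cds_start),
        "CDS": (gene.cds_start, gene.cds_end),
        "3UTR": (gene.cds_end, gene.tx_length),
    }
    region = gene.region_of(tx_offset)
    rstart, rend = bounds[region]
    rlen = rend - rstart
    flagged = any(hi == lo for lo, hi in bounds.values())
    rel = (tx_offset - rstart) / rlen
    first, nbins = REGION_BINS[region]
    b = first + min(int(rel * nbins), nbins - 1)
    return BinAssignment(site_id=site_id, region=region, bin=b, rel_pos=rel, flagged=flagged)


def metagene_profile(assignments, degree: int = 5):
    """Per-bin site fractions plus a presentation-only polynomial smooth.

    Returns (counts, fractions, smoothed); fractions sum to 1. Smoothing is a
    least-squares polynomial fit over bin counts and never feeds downstream
    statistics.
    """
    assignments = list(assignments)
    if not assignments:
        raise ValueError("no assignable sites")
    counts = np.zeros(N_BINS, dtype=int)
    for a in assignments:
        counts[a.bin] += 1
    fractions = counts / counts.sum()
    x = np.arange(N_BINS)
    coeffs = np.polyfit(x, fractions, deg=degree)
    smoothed = np.polyval(coeffs, x)
    return counts, fractions, smoothed


def annotate_genic_region(sites, transcripts):
    """One label per site: 5UTR | CDS | 3UTR | ncRNA | intergenic.

    A site is assigned to the longest containing isoform; when isoforms of
    equal length disagree, precedence is CDS > UTR > ncRNA. Sites in no
    transcript are intergenic.
    """
    precedence = {"CDS": 0, "5UTR": 1, "3UTR": 1, "ncRNA": 2}
    labels = {}
    for site in sites:
        containing = []
        for t in transcripts:
            if t.chrom != site.chrom or t.strand != site.strand:
                continue
            off = t.genomic_to_tx(site.gpos)
            if off is not None:
                containing.append((t, t.region_of(off)))
        if not containing:
            labels[site.site_id] = "intergenic"
            continue
        max_len = max(t.tx_length for t, _ in containing)
        candidates = [(t, r) for t, r in containing if t.tx_length == max_len]
        candidates.sort(key=lambda tr: (precedence[tr[1]], tr[0].gene_id))
        labels[site.site_id] = candidates[0][1]
    return labels


def cds_utr3_ratio(labels_by_group: dict):
    """|CDS sites| / |3'UTR sites| per group; None when no 3'UTR sites."""
    out = {}
    for group, labels in labels_by_group.items():
        vals = list(labels.values()) if isinstance(labels, dict) else list(labels)
        n_cds = sum(1 for v in vals if v == "CDS")
        n_utr3 = sum(1 for v in vals if v == "3UTR")
        out[group] = (n_cds / n_utr3) if n_utr3 else None
    return out
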