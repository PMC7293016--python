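"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open internally (BED convention); strand-aware
transcript coordinates count from the transcript 5' end after splicing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "revcomp",
    "GeneModel",
    "SampleTrack",
    "WindowStat",
    "Peak",
    "M6ASite",
    "CleavageSite",
    "SnpRecord",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """A single-isoform gene: exon structure plus CDS bounds.

    `exons` are genomic, 0-based half-open, sorted ascending and
    non-overlapping. `cds_start`/`cds_end` are transcript coordinates
    (offsets from the spliced 5' end); for noncoding genes both are 0.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list
    cds_start: int = 0
    cds_end: int = 0
    coding: bool = True

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"bad exon ({s},{e}) in {self.gene_id}")
            if s < prev_end:
                raise ValueError(f"overlapping/unsorted exons in {self.gene_id}")
            prev_end = e
        if self.coding and not (0 <= self.cds_start < self.cds_end <= self.tx_length):
            raise ValueError(f"CDS bounds out of range in {self.gene_id}")

    @property
    def tx_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self):
        return self.exons[0][0], self.exons[-1][1]

    def _tx_order_exons(self):
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def tx_to_genomic(self, off: int) -> int:
        """Genomic position of transcript offset `off`."""
        if not 0 <= off < self.tx_length:
            raise IndexError(f"offset {off} outside transcript {self.gene_id}")
        for s, e in self._tx_order_exons():
            n = e - s
            if off < n:
                return s + off if self.strand == "+" else e - 1 - off
            off -= n
        raise AssertionError("unreachable")

    def genomic_to_tx(self, gpos: int):
        """Transcript offset of genomic position, or None if intronic/outside."""
        acc = 0
        for s, e in self._tx_order_exons():
            if s <= gpos < e:
                return acc + (gpos - s if self.strand == "+" else e - 1 - gpos)
            acc += e - s
        return None

    def tx_interval_to_blocks(self, start: int, end: int):
        """Map a transcript interval to ascending genomic blocks."""
        blocks = []
        acc = 0
        for s, e in self._tx_order_exons():
            n = e - s
            lo, hi = max(start, acc), min(end, acc + n)
            if lo < hi:
                if self.strand == "+":
                    blocks.append((s + (lo - acc), s + (hi - acc)))
                else:
                    blocks.append((e - (hi - acc), e - (lo - acc)))
            acc += n
        return sorted(blocks)

    def transcript_seq(self, chrom_seq: str) -> str:
        seq = "".join(chrom_seq[s:e] for s, e in self.exons)
        return seq if self.strand == "+" else revcomp(seq)

    def region_of(self, off: int) -> str:
        """Genic region of a transcript offset: 5UTR | CDS | 3UTR | ncRNA."""
        if not self.coding:
            return "ncRNA"
        if off < self.cds_start:
            return "5UTR"
        if off < self.cds_end:
            return "CDS"
        return "3UTR"


@dataclass
class SampleTrack:
    """Paired IP/input per-base transcript coverage for one sample.

    `ip` and `input_` map gene_id -> float array of length tx_length.
    Library sizes are totals used for RPKM normalisation.
    """

    sample_id: str
    tissue: str
    ip: dict
    input_: dict
    ip_library_size: float
    input_library_size: float


@dataclass
class WindowStat:
    sample_id: str
    gene_id: str
    start: int
    end: int
    winscore: float
    ip_rpkm: float
    input_gene_rpkm: float


@dataclass
class Peak:
    gene_id: str
    tissue: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    blocks: list
    winscores: dict = field(default_factory=dict)
    support: int = 0

    @property
    def peak_id(self) -> str:
        return f"{self.gene_id}:{self.tx_start}-{self.tx_end}:{self.tissue}"


@dataclass
class M6ASite:
    site_id: str
    chrom: str
    gpos: int
    strand: str
    gene_id: str
    tx_offset: int
    motif: str
    winscores: dict = field(default_factory=dict)
    tissues: set = field(default_factory=set)


@dataclass
class CleavageSite:
    chrom: str
    pos: int
    strand: str
    gene_id: str
    pas_class: str = "none"
    region: str = "3UTR"
    has_m6a: bool = False


@dataclass
class SnpRecord:
    snp_id: str
    chrom: str
    pos: int  # 0-based internally; VCF interface is 1-based
    ref: str
    alt: str
    ancestral: str  # "" when unknown
    pop_counts: dict  # pop -> (alt_allele_count, total_haplotypes)
    motif_position: str = "none"  # R1|R2|A|C|H|none
    m6a_allele: str = ""
    creates_motif: bool = False
    ambiguous: bool = False
    region: str = "intergenic"

    @property
    def derived(self) -> str:
        if self.ancestral not in (self.ref, self.alt):
            return ""
        return self.alt if self.ancestral == self.ref else self.ref

    def alt_freq(self) -> float:
        alt = sum(a for a, _ in self.pop_counts.values())
        tot = sum(t for _, t in self.pop_counts.values())
        return alt / tot if tot else float("nan")

    def daf(self) -> float:
        """Derived allele frequency across all haplotypes (NaN if AA unknown)."""
        if not self.derived:
            return float("nan")
        f = self.alt_freq()
        return f if self.derived == self.alt else 1.0 - f
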