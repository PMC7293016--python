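"""Winscore sliding-window m6A peak calling and RRACH site inference.

Each gene is scanned in transcript (spliced) coordinates with 100-nt windows.
The enrichment score of a window is

    winscore = log2( (MeanWinIP / MedianGeneIP) / (MeanWinInput / MedianGeneInput) )

with a symmetric pseudocount added to all four quantities. Windows pass the
enrichment filter when IP window RPKM >= 10, winscore >= 2 and the gene's
input RPKM >= 1 (all thresholds inclusive). Overlapping enriched windows are
merged per sample into candidate peaks; a consensus peak requires winscore
>= 2 support in at least two samples of a tissue. m6A sites are the central
As of RRACH motifs inside consensus peaks, evaluated on the transcript
strand.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np

from .models import GeneModel, M6ASite, Peak, SampleTrack, WindowStat
from .motifs import find_rrach

__all__ = [
    "compute_window_stats",
    "call_enriched_windows",
    "consensus_peaks",
    "infer_sites",
    "normalize_winscores_top50",
    "call_sample_windows",
    "site_winscore",
]

log = logging.getLogger(__name__)

WINDOW = 100
STEP = 50
PSEUDOCOUNT = 1.0
MIN_WINSCORE = 2.0
MIN_IP_RPKM = 10.0
MIN_INPUT_GENE_RPKM = 1.0
MIN_TISSUE_SUPPORT = 2


def _window_starts(length: int, window: int, step: int):
    """Tiling starts; a gene shorter than the window yields one truncated
    window, and the tail is always covered by a final right-aligned window."""
    if length <= window:
        return [0]
    starts = list(range(0, length - window + 1, step))
    if starts[-1] + window < length:
        starts.append(length - window)
    return starts


def rpkm(count_sum: float, length_nt: int, library_size: float) -> float:
    return count_sum * 1e9 / (length_nt * library_size)


def compute_window_stats(
    gene: GeneModel,
    ip: np.ndarray,
    input_: np.ndarray,
    ip_library_size: float,
    input_library_size: float,
    sample_id: str = "",
    window: int = WINDOW,
    step: int = STEP,
    pseudocount: float = PSEUDOCOUNT,
):
    """Winscore and RPKM for every sliding window of one gene in one sample.

    Returns [] for genes with an all-zero input track (no expression
    evidence; logged and skipped). Library sizes must be positive.
    """
    if ip_library_size <= 0 or input_library_size <= 0:
        raise ValueError("library sizes must be positive")
    L = gene.tx_length
    if len(ip) != L or len(input_) != L:
        raise ValueError(f"coverage length mismatch for {gene.gene_id}")
    input_sum = float(input_.sum())
    if input_sum == 0:
        log.info("gene %s skipped: all-zero input coverage", gene.gene_id)
        return []
    med_ip = float(np.median(ip))
    med_in = float(np.median(input_))
    gene_rpkm = rpkm(input_sum, L, input_library_size)

    out = []
    for s in _window_starts(L, window, step):
        e = min(s + window, L)
        mean_ip = float(ip[s:e].mean())
        mean_in = float(input_[s:e].mean())
        ratio = ((mean_ip + pseudocount) / (med_ip + pseudocount)) / (
            (mean_in + pseudocount) / (med_in + pseudocount)
        )
        ws = float(np.log2(ratio))
        out.append(
            WindowStat(
                sample_id=sample_id,
                gene_id=gene.gene_id,
                start=s,
                end=e,
                winscore=ws,
                ip_rpkm=rpkm(float(ip[s:e].sum()), e - s, ip_library_size),
                input_gene_rpkm=gene_rpkm,
            )
        )
    return out


def call_enriched_windows(
    stats,
    min_winscore: float = MIN_WINSCORE,
    min_ip_rpkm: float = MIN_IP_RPKM,
    min_input_gene_rpkm: float = MIN_INPUT_GENE_RPKM,
):
    """Windows passing all three inclusive filters."""
    return [
        w
        for w in stats
        if w.winscore >= min_winscore
        and w.ip_rpkm >= min_ip_rpkm
        and w.input_gene_rpkm >= min_input_gene_rpkm
    ]


def call_sample_windows(genes, track: SampleTrack, window: int = WINDOW,
                        step: int = STEP, pseudocount: float = PSEUDOCOUNT):
    """All window stats for one sample, keyed by gene_id."""
    stats = {}
    for gene in genes:
        if gene.gene_id not in track.ip:
            continue
        ws = compute_window_stats(
            gene,
            track.ip[gene.gene_id],
            track.input_[gene.gene_id],
            track.ip_library_size,
            track.input_library_size,
            sample_id=track.sample_id,
            window=window,
            step=step,
            pseudocount=pseudocount,
        )
        if ws:
            stats[gene.gene_id] = ws
    return stats


def _merge_intervals(ivals):
    ivals = sorted(ivals)
    merged = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def consensus_peaks(
    enriched_by_sample: dict,
    stats_by_sample: dict,
    design: dict,
    genes_by_id: dict,
    min_support: int = MIN_TISSUE_SUPPORT,
    min_winscore: float = MIN_WINSCORE,
):
    """Tissue-consensus peaks from per-sample enriched windows.

    `enriched_by_sample`: sample_id -> {gene_id: [WindowStat]} (enriched only).
    `stats_by_sample`: same shape with all windows (for per-sample peak
    winscores). `design`: sample_id -> tissue. Candidate regions are the
    merged union of enriched windows across a tissue's samples; within a
    candidate, the union of the supporting samples' windows is re-merged and
    each resulting interval is kept if >= `min_support` samples contribute an
    enriched window to it. Raises for tissues with fewer than two samples.
    """
    tissue_samples = defaultdict(list)
    for sid, tissue in design.items():
        tissue_samples[tissue].append(sid)
    for tissue, sids in tissue_samples.items():
        if len(sids) < min_support:
            raise ValueError(f"tissue {tissue!r} has {len(sids)} sample(s); need >= {min_support}")

    peaks = []
    for tissue, sids in sorted(tissue_samples.items()):
        gene_ids = sorted(
            {g for sid in sids for g in enriched_by_sample.get(sid, {})}
        )
        for gid in gene_ids:
            gene = genes_by_id[gid]
            per_sample = {
                sid: [(w.start, w.end) for w in enriched_by_sample.get(sid, {}).get(gid, [])]
                for sid in sids
            }
            all_ivals = [iv for ivs in per_sample.values() for iv in ivs]
            if not all_ivals:
                continue
            for cs, ce in _merge_intervals(all_ivals):
                support_sids = [
                    sid
                    for sid in sids
                    if any(s < ce and cs < e for s, e in per_sample[sid])
                ]
                if len(support_sids) < min_support:
                    continue
                sup_ivals = [
                    (s, e)
                    for sid in support_sids
                    for s, e in per_sample[sid]
                    if s < ce and cs < e
                ]
                for ps, pe in _merge_intervals(sup_ivals):
                    n_sup = sum(
                        1
                        for sid in support_sids
                        if any(s < pe and ps < e for s, e in per_sample[sid])
                    )
                    if n_sup < min_support:
                        continue
                    winscores = {}
                    for sid in sorted(design):
                        covering = [
                            w.winscore
                            for w in stats_by_sample.get(sid, {}).get(gid, [])
                            if w.start < pe and ps < w.end
                        ]
                        if covering:
                            winscores[sid] = max(covering)
                    peaks.append(
                        Peak(
                            gene_id=gid,
                            tissue=tissue,
                            chrom=gene.chrom,
                            strand=gene.strand,
                            tx_start=ps,
                            tx_end=pe,
                            blocks=gene.tx_interval_to_blocks(ps, pe),
                            winscores=winscores,
                            support=n_sup,
                        )
                    )
    return peaks


def site_winscore(stats_for_gene, tx_offset: int):
    """Winscore of the best window covering a transcript offset (None if
    uncovered)."""
    covering = [w.winscore for w in stats_for_gene if w.start <= tx_offset < w.end]
    return max(covering) if covering else None


def infer_sites(peaks, genome: dict, genes_by_id: dict, stats_by_sample: dict | None = None):
    """RRACH m6A sites within consensus peaks.

    One site per RRACH occurrence (the central A) whose A lies inside a peak,
    evaluated on the transcript strand; motifs spanning N are skipped. Sites
    are deduplicated genome-wide by (chrom, genomic position, strand); the
    per-sample winscore of a site is that of its best covering window, and
    `tissues` accumulates every tissue with a consensus peak over the site.
    """
    tx_seqs = {}
    by_key = {}
    for peak in peaks:
        gene = genes_by_id[peak.gene_id]
        if peak.gene_id not in tx_seqs:
            tx_seqs[peak.gene_id] = gene.transcript_seq(genome[gene.chrom])
        seq = tx_seqs[peak.gene_id]
        for a in find_rrach(seq, peak.tx_start, peak.tx_end):
            mer = seq[a - 2 : a + 3].upper()
            if "N" in mer:
                continue
            gpos = gene.tx_to_genomic(a)
            key = (gene.chrom, gpos, gene.strand)
            if key not in by_key:
                winscores = {}
                if stats_by_sample:
                    for sid, per_gene in stats_by_sample.items():
                        ws = site_winscore(per_gene.get(peak.gene_id, []), a)
                        if ws is not None:
                            winscores[sid] = ws
                by_key[key] = M6ASite(
                    site_id=f"{gene.chrom}:{gpos}:{gene.strand}",
                    chrom=gene.chrom,
                    gpos=gpos,
                    strand=gene.strand,
                    gene_id=peak.gene_id,
                    tx_offset=a,
                    motif=mer,
                    winscores=winscores,
                )
            by_key[key].tissues.add(peak.tissue)
    return sorted(by_key.values(), key=lambda s: (s.chrom, s.gpos, s.strand))


def normalize_winscores_top50(peaks_by_sample: dict, top_n: int = 50):
    """Per-sample scaling factors equalising top-N mean peak winscores.

    `peaks_by_sample`: sample_id -> list of peak winscores (>= 1 each). The
    factor for a sample maps its top-N mean onto the cross-sample average of
    top-N means; multiply a sample's winscores by its factor to normalise.
    """
    top_means = {}
    for sid, scores in peaks_by_sample.items():
        if len(scores) == 0:
            raise ValueError(f"sample {sid!r} has no peaks")
        top = sorted(scores, reverse=True)[:top_n]
        top_means[sid] = float(np.mean(top))
    target = float(np.mean(list(top_means.values())))
    return {sid: target / m for sid, m in top_means.items()}
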