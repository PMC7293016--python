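"""Selection scans on m6A-motif SNPs.

Covers: annotation of SNPs by their position within RRACH motifs (either
allele), the allele-specific methylation test (IP vs input m6A-allele read
ratios, Kolmogorov-Smirnov), derived-allele-frequency spectrum comparisons
(one-sided Mann-Whitney U, m6A group right-shifted under positive selection)
and the per-SNP Weir & Cockerham (1984) Fst estimator with a strict > 0.15
high-differentiation filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import SnpRecord, revcomp
from .motifs import is_rrach

__all__ = [
    "annotate_motif_snps",
    "allele_ratio_test",
    "daf_spectrum_test",
    "weir_cockerham_fst",
    "high_fst_filter",
    "MOTIF_POSITION_LABELS",
]

MOTIF_POSITION_LABELS = {0: "R1", 1: "R2", 2: "A", 3: "C", 4: "H"}


def _motif_frames(chrom_seq: str, pos: int, strand: str, allele: str):
    """Motif indices (0..4) at which `pos` sits inside an RRACH occurrence
    when the base at `pos` is replaced by `allele`, on the given strand."""
    lo = max(0, pos - 4)
    ctx = chrom_seq[lo : pos + 5].upper()
    i = pos - lo
    ctx = ctx[:i] + allele.upper() + ctx[i + 1 :]
    if strand == "-":
        ctx = revcomp(ctx)
        i = len(ctx) - 1 - i
    frames = []
    for j in range(5):  # motif start so that pos is at motif index j
        s = i - j
        if 0 <= s and s + 5 <= len(ctx) and is_rrach(ctx[s : s + 5]):
            frames.append(j)
    return frames


def _matches_rrac(chrom_seq, pos, strand, allele):
    """True if the allele completes an RRAC core (motif indices 0-3)."""
    return any(j <= 3 for j in _motif_frames(chrom_seq, pos, strand, allele))


def annotate_motif_snps(snps, genome: dict, strand_of=None):
    """Annotate SNPs with motif-relative position, m6A allele and
    gain-of-motif status.

    For each SNP both alleles are substituted into the reference context and
    rescanned for RRACH on the relevant strand(s) (`strand_of(snp)` may
    restrict to the host gene's strand; default scans both). The m6A allele
    is the one whose substitution yields an RRACH match; a SNP where both
    alleles complete a motif is flagged ambiguous and excluded from ratio
    tests. `creates_motif` is set when the derived allele creates an RRAC
    core that the ancestral allele does not.
    """
    annotated = []
    for snp in snps:
        seq = genome[snp.chrom]
        strands = [strand_of(snp)] if strand_of and strand_of(snp) else ["+", "-"]
        per_allele = {}
        for allele in (snp.ref, snp.alt):
            hits = []
            for st in strands:
                hits.extend((st, j) for j in _motif_frames(seq, snp.pos, st, allele))
            per_allele[allele] = hits
        ref_hits, alt_hits = per_allele[snp.ref], per_allele[snp.alt]
        snp.ambiguous = bool(ref_hits) and bool(alt_hits)
        if ref_hits or alt_hits:
            hits = ref_hits if ref_hits else alt_hits
            j = min(f for _, f in hits)
            snp.motif_position = MOTIF_POSITION_LABELS[j]
            snp.m6a_allele = snp.ref if ref_hits else snp.alt
        else:
            snp.motif_position = "none"
            snp.m6a_allele = ""
        der = snp.derived
        if der and not snp.ambiguous:
            anc = snp.alt if der == snp.ref else snp.ref
            gains = []
            for st in strands:
                gains.append(
                    _matches_rrac(seq, snp.pos, st, der)
                    and not _matches_rrac(seq, snp.pos, st, anc)
                )
            snp.creates_motif = any(gains)
        else:
            snp.creates_motif = False
        annotated.append(snp)
    return annotated


def allele_ratio_test(observations: pd.DataFrame, min_snps: int = 5):
    """IP vs input m6A-allele ratio comparison per motif position.

    `observations` columns: snp_id, motif_position, compartment (IP|input),
    m6a_reads, total_reads. Ratios are per (snp, compartment) aggregates.
    Returns a frame with the two-sample KS statistic/p and the median-ratio
    difference per position; positions with fewer than `min_snps`
    heterozygous SNPs are suppressed with a reason.
    """
    obs = observations.copy()
    if (obs["total_reads"] <= 0).any():
        raise ValueError("total_reads must be positive")
    obs["ratio"] = obs["m6a_reads"] / obs["total_reads"]
    rows = []
    for position, grp in obs.groupby("motif_position"):
        agg = grp.groupby(["snp_id", "compartment"])["ratio"].mean().unstack()
        agg = agg.dropna(subset=["IP", "input"])
        n = len(agg)
        if n < min_snps:
            rows.append({"motif_position": position, "n_snps": n, "ks_stat": np.nan,
                         "p_value": np.nan, "median_ip_minus_input": np.nan,
                         "note": f"suppressed: {n} < {min_snps} SNPs"})
            continue
        stat, p = sps.ks_2samp(agg["IP"], agg["input"])
        rows.append({
            "motif_position": position, "n_snps": n, "ks_stat": float(stat),
            "p_value": float(p),
            "median_ip_minus_input": float(agg["IP"].median() - agg["input"].median()),
            "note": "",
        })
    return pd.DataFrame(rows).set_index("motif_position")


def daf_spectrum_test(daf_m6a, daf_controls: dict):
    """One-sided Mann-Whitney U: is the m6A-group DAF right-shifted?

    `daf_controls` maps control-group name -> DAF array (e.g. non-m6A RRACH
    in 3'UTRs, RRACH in intergenic regions). NaN DAFs (no ancestral allele)
    are excluded and counted. Uses the normal approximation with tie
    correction.
    """
    m6a = np.asarray(daf_m6a, dtype=float)
    n_excluded = int(np.isnan(m6a).sum())
    m6a = m6a[~np.isnan(m6a)]
    if len(m6a) == 0:
        raise ValueError("no m6A-group SNPs with defined ancestral allele")
    out = {"n_m6a": len(m6a), "n_excluded_m6a": n_excluded, "controls": {}}
    for name, daf in daf_controls.items():
        arr = np.asarray(daf, dtype=float)
        excl = int(np.isnan(arr).sum())
        arr = arr[~np.isnan(arr)]
        stat, p = sps.mannwhitneyu(m6a, arr, alternative="greater", method="asymptotic")
        out["controls"][name] = {
            "n_control": len(arr),
            "n_excluded_control": excl,
            "U": float(stat),
            "p_value": float(p),
        }
    return out


def weir_cockerham_fst(pop_genotypes):
    """Per-SNP Weir & Cockerham (1984) theta for one biallelic SNP.

    `pop_genotypes`: list of integer arrays, one per population, each entry
    the alt-allele dosage of a diploid individual (0/1/2). Returns the raw
    estimate (may be negative); None when the SNP is monomorphic across all
    populations or fewer than two populations have data.
    """
    pops = [np.asarray(g, dtype=float) for g in pop_genotypes if len(g) > 0]
    r = len(pops)
    if r < 2:
        return None
    n_i = np.array([len(g) for g in pops], dtype=float)
    p_i = np.array([g.mean() / 2.0 for g in pops])
    h_i = np.array([np.mean(g == 1) for g in pops])
    if np.all(p_i == p_i[0]) and (p_i[0] in (0.0, 1.0)):
        return None  # monomorphic everywhere
    n_bar = n_i.mean()
    n_total = n_i.sum()
    nc = (n_total - (n_i**2).sum() / n_total) / (r - 1)
    p_bar = (n_i * p_i).sum() / n_total
    s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum() / n_total
    a = (n_bar / nc) * (
        s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
    )
    c = h_bar / 2.0
    denom = a + b + c
    if denom == 0:
        return None
    return float(a / denom)


def high_fst_filter(fst: pd.Series, threshold: float = 0.15) -> pd.Index:
    """SNPs with Fst strictly above the threshold."""
    fst = pd.Series(fst, dtype=float)
    return fst.index[fst > threshold]
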