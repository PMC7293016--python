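"""m6A association with poly(A) cleavage sites and PAS classification.

Cleavage positions are compared with m6A sites in transcript orientation
(downstream positive). The poly(A) signal (PAS) of a cleavage site is the
highest-priority hexamer found in the 40 nt upstream on the sense strand:
AAUAAA, then AUUAAA, then any of a configurable list of common single-base
variants ("other"); sites with none of these are the noncanonical class.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import revcomp
from .motifs import SUBMOTIF_CLASSES, classify_submotif

__all__ = [
    "PAS_VARIANTS",
    "distance_distribution",
    "submotif_at_cleavage",
    "classify_pas",
    "composition_profile",
]

# Common single-base AAUAAA variants (DNA alphabet), after the two
# dedicated classes; the "other" canonical group.
PAS_VARIANTS = (
    "AGTAAA",
    "TATAAA",
    "CATAAA",
    "GATAAA",
    "AATATA",
    "AATACA",
    "AATAGA",
    "AATGAA",
    "ACTAAA",
    "AAGAAA",
)

PAS_SEARCH_NT = 40


def distance_distribution(m6a_sites, cleavage_sites, window: int = 200):
    """Histogram of signed m6A-to-cleavage offsets within +/- window nt.

    Offsets are transcript-oriented: positive = m6A downstream of the
    cleavage position. Returns (offsets array -W..W, counts).
    """
    by_key = defaultdict(list)
    for s in m6a_sites:
        by_key[(s.chrom, s.strand)].append(s.gpos)
    for k in by_key:
        by_key[k] = np.array(sorted(by_key[k]))
    offsets = np.arange(-window, window + 1)
    counts = np.zeros(len(offsets), dtype=int)
    for c in cleavage_sites:
        positions = by_key.get((c.chrom, c.strand))
        if positions is None:
            continue
        lo = np.searchsorted(positions, c.pos - window, side="left")
        hi = np.searchsorted(positions, c.pos + window, side="right")
        for gpos in positions[lo:hi]:
            d = int(gpos - c.pos)
            if c.strand == "-":
                d = -d
            counts[d + window] += 1
    return offsets, counts


def submotif_at_cleavage(m6a_sites, cleavage_sites, utr3_site_ids,
                         min_offset0: int = 5):
    """Sub-motif proportions of m6A sites at cleavage positions vs other
    3'UTR sites, with a chi-square comparison (suppressed below
    `min_offset0` offset-0 sites)."""
    cleav_keys = {(c.chrom, c.pos, c.strand) for c in cleavage_sites}
    utr3 = set(utr3_site_ids)
    counts = pd.DataFrame(0, index=["cleavage", "3UTR"], columns=list(SUBMOTIF_CLASSES))
    for s in m6a_sites:
        if s.site_id not in utr3:
            continue
        group = "cleavage" if (s.chrom, s.gpos, s.strand) in cleav_keys else "3UTR"
        counts.loc[group, classify_submotif(s.motif)] += 1
    props = counts.div(counts.sum(axis=1), axis=0)
    n0 = int(counts.loc["cleavage"].sum())
    result = {"counts": counts, "proportions": props, "chi2_p": None}
    if n0 >= min_offset0 and counts.loc["3UTR"].sum() > 0:
        keep = counts.columns[(counts.sum(axis=0) > 0)]
        chi2, p, _, _ = sps.chi2_contingency(counts[keep].values)
        result["chi2_p"] = float(p)
    return result


def classify_pas(chrom_seq: str, pos: int, strand: str,
                 variants=PAS_VARIANTS, search_nt: int = PAS_SEARCH_NT) -> str:
    """PAS class of a cleavage position from the upstream sense-strand
    sequence: AAUAAA > AUUAAA > other (variant list) > none.

    A truncated upstream window (contig edge) is scanned as-is.
    """
    if strand == "+":
        lo = max(0, pos - search_nt)
        upstream = chrom_seq[lo:pos]
    else:
        hi = min(len(chrom_seq), pos + 1 + search_nt)
        upstream = revcomp(chrom_seq[pos + 1 : hi])
    upstream = upstream.upper()
    if "AATAAA" in upstream:
        return "AAUAAA"
    if "ATTAAA" in upstream:
        return "AUUAAA"
    for v in variants:
        if v in upstream:
            return "other"
    return "none"


def composition_profile(cleavage_sites, genome: dict, flank: int = 50):
    """Per-class base composition around cleavage positions.

    Returns {pas_class: DataFrame} with rows = offsets -flank..flank
    (transcript orientation), columns = A/C/G/T frequencies (rows sum to 1),
    plus {pas_class: list of 5-mer contexts} spanning 2 nt each side of the
    cleavage position.
    """
    width = 2 * flank + 1
    counts = defaultdict(lambda: np.zeros((width, 4), dtype=float))
    contexts = defaultdict(list)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for c in cleavage_sites:
        seq = genome[c.chrom]
        lo, hi = c.pos - flank, c.pos + flank + 1
        if lo < 0 or hi > len(seq):
            continue
        window = seq[lo:hi].upper()
        if c.strand == "-":
            window = revcomp(window)
        for i, b in enumerate(window):
            if b in base_idx:
                counts[c.pas_class][i, base_idx[b]] += 1
        contexts[c.pas_class].append(window[flank - 2 : flank + 3])
    profiles = {}
    for klass, mat in counts.items():
        totals = mat.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        profiles[klass] = pd.DataFrame(
            mat / totals, index=np.arange(-flank, flank + 1), columns=list("ACGT")
        )
    return profiles, dict(contexts)
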