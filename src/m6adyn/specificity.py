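"""Tissue specificity of m6A sites: the tau index and sharing spectrum.

For each site, the per-tissue methylation level x_i is the mean winscore of
its best covering 100-nt window across the tissue's replicates (computed in
every tissue, whether or not a peak was called there; negative means floored
at 0). tau = sum_i (1 - x_i / max(x)) / (n - 1) ranges from 0 (uniform
methylation) to 1 (single-tissue). Sites are shared when tau < 0.15 and
tissue-specific when tau > 0.6 (strict inequalities); everything between is
intermediate.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "tissue_winscore_matrix",
    "compute_tau",
    "classify_sites",
    "sharing_spectrum",
    "ubiquitous_gene_filter",
    "SHARED_TAU",
    "SPECIFIC_TAU",
]

SHARED_TAU = 0.15
SPECIFIC_TAU = 0.6


def tissue_winscore_matrix(site_sample_winscores: pd.DataFrame, design: dict) -> pd.DataFrame:
    """Average per-tissue winscore profile per site.

    `site_sample_winscores`: rows = sites, columns = samples; NaN marks a
    site window uncovered in that sample (treated as 0, i.e. no enrichment
    evidence). Replicates of a tissue are averaged and negatives floored at
    0 so profiles are expression-like.
    """
    filled = site_sample_winscores.fillna(0.0)
    tissues = filled.columns.map(design)
    if tissues.isna().any():
        missing = [c for c, t in zip(filled.columns, tissues) if pd.isna(t)]
        raise ValueError(f"samples missing from design: {missing}")
    profile = filled.T.groupby(tissues.values).mean().T
    return profile.clip(lower=0.0)


def compute_tau(x) -> float:
    """Tissue specificity index tau of a nonnegative profile.

    tau = sum(1 - x_i/max(x)) / (n - 1). Returns NaN for all-zero profiles
    (undefined; callers exclude such sites).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("profile must be a vector over >= 2 tissues")
    if (x < 0).any():
        raise ValueError("profile must be nonnegative (floor winscores first)")
    m = x.max()
    if m <= 0:
        return float("nan")
    xhat = x / m
    return float(np.sum(1.0 - xhat) / (len(x) - 1))


def classify_sites(taus) -> pd.Series:
    """shared (tau < 0.15) | specific (tau > 0.6) | intermediate; NaN tau
    excluded (labelled 'undefined')."""
    taus = pd.Series(taus, dtype=float)

    def _label(t: float) -> str:
        if math.isnan(t):
            return "undefined"
        if t < SHARED_TAU:
            return "shared"
        if t > SPECIFIC_TAU:
            return "specific"
        return "intermediate"

    return taus.map(_label)


def sharing_spectrum(site_tissue_flags: dict, n_tissues: int,
                     ubiquitous_sites=None) -> pd.DataFrame:
    """Histogram of sites methylated in k = 1..n tissues.

    `site_tissue_flags`: site_id -> set of tissues whose consensus peaks
    contain the site. If `ubiquitous_sites` is given, a second column
    restricts the histogram to those sites (sites in ubiquitously expressed
    genes).
    """
    ks = np.arange(1, n_tissues + 1)
    counts = np.zeros(n_tissues, dtype=int)
    counts_ubi = np.zeros(n_tissues, dtype=int)
    ubi = set(ubiquitous_sites) if ubiquitous_sites is not None else None
    for sid, tissues in site_tissue_flags.items():
        k = len(tissues)
        if not 1 <= k <= n_tissues:
            raise ValueError(f"site {sid} methylated in {k} tissues (n={n_tissues})")
        counts[k - 1] += 1
        if ubi is not None and sid in ubi:
            counts_ubi[k - 1] += 1
    out = pd.DataFrame({"k": ks, "n_sites": counts})
    if ubi is not None:
        out["n_sites_ubiquitous"] = counts_ubi
    return out


def ubiquitous_gene_filter(expression: pd.DataFrame, threshold: float = 3.0) -> set:
    """Genes expressed above `threshold` (strict >) in every tissue.

    `expression`: rows = genes, columns = tissues (FPKM-like values).
    """
    mask = (expression > threshold).all(axis=1)
    return set(expression.index[mask])
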