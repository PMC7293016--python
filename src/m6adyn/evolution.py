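"""Cross-species constraint on m6A sites against matched control A sites.

Control A sites (non-m6A RRACH) are matched to m6A sites within strata built
from gene dN/dS deciles, position bins along the region (20 CDS bins), and —
for CDS sites — codon position, so that gene-level selection pressure and
positional effects are controlled. A site is conserved in a species when the
aligned base is exactly A. The null distribution of the conserved fraction
comes from resampling matched control sets; the constraint proportion
converts the observed/control conserved fractions into the percentage of
sites under constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "add_strata",
    "match_controls",
    "conserved_fraction",
    "null_distribution",
    "constraint_proportion",
    "site_age",
    "utr3_age_profile",
    "constraint_vs_level",
    "MatchedNull",
]


def add_strata(table: pd.DataFrame, n_dnds_bins: int = 10,
               n_region_bins: int = 20, use_codon: bool = True) -> pd.DataFrame:
    """Attach a `stratum` column: (dN/dS bin, region-position bin, codon pos).

    dN/dS bins are quantile bins (deciles by default) computed over the whole
    table so m6A and control sites share the grid. `rel_pos` in [0,1] is the
    site's relative position along its region (used for the 20-bin CDS
    geometry); `codon_pos` applies to CDS sites only.
    """
    t = table.copy()
    edges = np.unique(np.quantile(t["dnds"], np.linspace(0, 1, n_dnds_bins + 1)))
    t["dnds_bin"] = np.clip(np.searchsorted(edges, t["dnds"], side="right") - 1,
                            0, len(edges) - 2)
    t["region_bin"] = np.clip((t["rel_pos"] * n_region_bins).astype(int),
                              0, n_region_bins - 1)
    if use_codon and "codon_pos" in t:
        codon = t["codon_pos"].astype(int)
    else:
        codon = pd.Series(0, index=t.index)
    t["stratum"] = (
        "d" + t["dnds_bin"].astype(str)
        + "|r" + t["region_bin"].astype(str)
        + "|c" + codon.astype(str)
    )
    return t


def match_controls(m6a: pd.DataFrame, pool: pd.DataFrame,
                   rng: np.random.Generator) -> pd.DataFrame:
    """One control set matched to `m6a` stratum-for-stratum.

    Both frames must carry a `stratum` column (see `add_strata`). For every
    m6A site one control is drawn uniformly without replacement from the
    same stratum of the pool. Raises if any stratum is under-populated,
    listing the offending strata so the caller can coarsen the bins.
    """
    need = m6a["stratum"].value_counts()
    have = pool["stratum"].value_counts()
    short = [str(s) for s in need.index if have.get(s, 0) < need[s]]
    if short:
        raise ValueError(f"control pool exhausted in strata: {', '.join(sorted(short))}")
    pieces = []
    grouped = pool.groupby("stratum", sort=True)
    for stratum in sorted(need.index):
        members = grouped.get_group(stratum)
        idx = rng.choice(len(members), size=need[stratum], replace=False)
        pieces.append(members.iloc[np.sort(idx)])
    return pd.concat(pieces, axis=0)


def conserved_fraction(table: pd.DataFrame, species: str) -> float:
    """Fraction of sites whose aligned base in `species` is A (gaps and
    substitutions count as not conserved)."""
    if len(table) == 0:
        raise ValueError("empty site set")
    return float((table[species].str.upper() == "A").mean())


@dataclass
class MatchedNull:
    observed: float
    null_fractions: np.ndarray
    p_value: float
    n_sets: int


def null_distribution(m6a: pd.DataFrame, pool: pd.DataFrame, species: str,
                      n_sets: int = 10_000,
                      rng: np.random.Generator | None = None) -> MatchedNull:
    """Null conserved-fraction distribution over matched control sets.

    p = (#{null fraction >= observed} + 1) / (n_sets + 1) — the right-tail
    empirical p with the +1 floor. Per stratum, the conserved count of a
    without-replacement draw is hypergeometric, so the resampling is
    vectorised as independent hypergeometric draws summed across strata
    (exactly equivalent in distribution to drawing the sets explicitly).
    """
    rng = np.random.default_rng() if rng is None else rng
    observed = conserved_fraction(m6a, species)
    need = m6a["stratum"].value_counts()
    total = int(need.sum())
    have = pool.groupby("stratum")[species].agg(
        n="size", conserved=lambda s: int((s.str.upper() == "A").sum())
    )
    short = [str(s) for s in need.index
             if s not in have.index or have.loc[s, "n"] < need[s]]
    if short:
        raise ValueError(f"control pool exhausted in strata: {', '.join(sorted(short))}")
    conserved_counts = np.zeros(n_sets, dtype=np.int64)
    for stratum in sorted(need.index):
        n_pool = int(have.loc[stratum, "n"])
        n_good = int(have.loc[stratum, "conserved"])
        k = int(need[stratum])
        conserved_counts += rng.hypergeometric(n_good, n_pool - n_good, k, size=n_sets)
    fractions = conserved_counts / total
    p = (int(np.sum(fractions >= observed)) + 1) / (n_sets + 1)
    return MatchedNull(observed, fractions, p, n_sets)


def constraint_proportion(f_m6a: float, f_ctrl: float):
    """Percentage of sites under constraint from conserved fractions.

    proportion = |(1 - f_m6a) - (1 - f_ctrl)| / (1 - f_ctrl) * 100, with the
    sign (negative = m6A evolving slower than controls, i.e. constrained)
    returned alongside. Undefined when controls are fully conserved.
    """
    if not (0 < f_ctrl < 1):
        raise ValueError("control conserved fraction must be in (0,1)")
    rate_m6a = 1.0 - f_m6a
    rate_ctrl = 1.0 - f_ctrl
    diff = rate_m6a - rate_ctrl
    return abs(diff) / rate_ctrl * 100.0, float(np.sign(diff))


def site_age(row, species_panel) -> int:
    """Phylostratigraphic age: 1-based rank of the most distant species whose
    aligned base is A; 0 when conserved nowhere (lineage-specific site)."""
    age = 0
    for rank, sp in enumerate(species_panel, start=1):
        if str(row[sp]).upper() == "A":
            age = rank
    return age


def utr3_age_profile(table: pd.DataFrame, species_panel, n_bins: int = 10) -> pd.DataFrame:
    """Mean site age per 3'UTR position bin, split by m6A status."""
    t = table[table["region"] == "3UTR"].copy()
    t["age"] = t.apply(site_age, axis=1, species_panel=species_panel)
    t["bin"] = np.clip((t["rel_pos"] * n_bins).astype(int), 0, n_bins - 1)
    return t.groupby(["bin", "is_m6a"])["age"].agg(["mean", "count"]).reset_index()


def constraint_vs_level(scores, winscores, min_sites: int = 8):
    """Median methylation (winscore) of strong- vs weak-constraint sites.

    Sites in the top score quartile (strong constraint) are compared with the
    bottom quartile; quartiles are nearest-rank and the groups disjoint by
    construction (bottom k and top k of the sorted order, k = n // 4).
    Suppressed (returns None) below `min_sites` sites.
    """
    scores = np.asarray(scores, dtype=float)
    winscores = np.asarray(winscores, dtype=float)
    n = len(scores)
    if n < min_sites:
        return None
    order = np.argsort(scores, kind="mergesort")
    k = n // 4
    low, high = winscores[order[:k]], winscores[order[-k:]]
    stat, p = sps.mannwhitneyu(high, low, alternative="two-sided")
    return {
        "median_high": float(np.median(high)),
        "median_low": float(np.median(low)),
        "n_per_group": int(k),
        "p_value": float(p),
    }
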