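"""RRACH sub-motif classification and the peak co-occurrence shuffle test.

The m6A consensus RRACH (R = A/G, H = A/C/U; DNA alphabet here, so H = A/C/T)
resolves into four sub-motifs by its two R positions: GGACH, AGACH, GAACH and
AAACH. The shuffle test asks whether two sub-motif classes (by default GGACH
and AAACH) segregate into different peaks more than expected when class
labels are randomly permuted over the motif slots of a sample's peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SUBMOTIF_CLASSES",
    "is_rrach",
    "find_rrach",
    "classify_submotif",
    "submotif_proportions",
    "submotif_variability",
    "shuffle_submotifs",
    "cooccurrence_test",
    "ShuffleResult",
]

SUBMOTIF_CLASSES = ("GGACH", "AGACH", "GAACH", "AAACH")

_R = frozenset("AG")
_H = frozenset("ACT")


def is_rrach(mer: str) -> bool:
    """True iff the 5-mer matches RRACH on the DNA alphabet."""
    if len(mer) != 5:
        return False
    m = mer.upper()
    return m[0] in _R and m[1] in _R and m[2] == "A" and m[3] == "C" and m[4] in _H


def find_rrach(seq: str, start: int = 0, end: int | None = None):
    """Yield positions of the methylatable A (motif index 2) of every RRACH
    occurrence whose 5-mer lies fully inside `seq`, with the A position in
    [start, end). Motifs spanning N are skipped."""
    s = seq.upper()
    if end is None:
        end = len(s)
    lo = max(start, 2)
    hi = min(end, len(s) - 2)
    for a in range(lo, hi):
        if s[a] == "A" and is_rrach(s[a - 2 : a + 3]):
            yield a


def classify_submotif(mer: str) -> str:
    """Sub-motif class of an RRACH 5-mer, named by its two R bases."""
    if not is_rrach(mer):
        raise ValueError(f"{mer!r} does not match RRACH")
    return mer[:2].upper() + "ACH"


def submotif_proportions(motifs) -> pd.Series:
    """Proportions of the four sub-motif classes over an iterable of 5-mers."""
    counts = pd.Series(0, index=list(SUBMOTIF_CLASSES), dtype=float)
    n = 0
    for m in motifs:
        counts[classify_submotif(m)] += 1
        n += 1
    if n == 0:
        raise ValueError("no motifs to classify")
    return counts / n


def submotif_variability(sample_props: pd.DataFrame, design: dict) -> pd.DataFrame:
    """Mean and variance of sub-motif proportions across tissues.

    `sample_props`: rows = samples, columns = the four classes.
    `design`: sample_id -> tissue. Replicates are averaged to tissue level
    first; variance is then taken across tissues (ddof=1).
    """
    if sample_props.index.map(design).nunique() < 2:
        raise ValueError("need >= 2 tissues")
    tissue_props = sample_props.groupby(sample_props.index.map(design)).mean()
    return pd.DataFrame(
        {"mean": tissue_props.mean(axis=0), "variance": tissue_props.var(axis=0, ddof=1)}
    )


@dataclass
class ShuffleResult:
    observed: int
    expected: np.ndarray
    m_expected: float
    observed_norm: float
    expected_norm: np.ndarray
    p_value: float
    n_shuffles: int


def _cooccurrence_count(peak_idx: np.ndarray, labels: np.ndarray, n_peaks: int,
                        class_a: str, class_b: str) -> int:
    has_a = np.zeros(n_peaks, dtype=bool)
    has_b = np.zeros(n_peaks, dtype=bool)
    has_a[peak_idx[labels == class_a]] = True
    has_b[peak_idx[labels == class_b]] = True
    return int(np.sum(has_a & has_b))


def _flatten_slots(peak_slots):
    peak_idx, labels = [], []
    for i, slots in enumerate(peak_slots):
        for lab in slots:
            peak_idx.append(i)
            labels.append(lab)
    return np.asarray(peak_idx, dtype=np.int64), np.asarray(labels, dtype=object)


def shuffle_submotifs(peak_slots, rng: np.random.Generator):
    """One random permutation of sub-motif class labels over all motif slots.

    `peak_slots` is a list (one entry per peak) of lists of class labels.
    Positions (per-peak slot counts) are fixed; only labels move, so both
    margins — slots per peak and total count per class — are conserved.
    """
    peak_idx, labels = _flatten_slots(peak_slots)
    if len(labels) < 2:
        raise ValueError("need >= 2 motif occurrences to shuffle")
    perm = rng.permutation(len(labels))
    shuffled = labels[perm]
    out, k = [], 0
    for slots in peak_slots:
        out.append(list(shuffled[k : k + len(slots)]))
        k += len(slots)
    return out


def cooccurrence_test(peak_slots, n_shuffles: int = 10_000,
                      rng: np.random.Generator | None = None,
                      class_a: str = "GGACH", class_b: str = "AAACH") -> ShuffleResult:
    """Permutation test for segregation of two sub-motif classes across peaks.

    Observed statistic: number of peaks containing at least one slot of each
    class. The null permutes class labels uniformly over all slots of the
    sample; the empirical p is the left-tail fraction of the null at or below
    the observed count, with the (b+1)/(m+1) correction so p is never 0.
    """
    rng = np.random.default_rng() if rng is None else rng
    peak_idx, labels = _flatten_slots(peak_slots)
    n_peaks = len(peak_slots)
    present = set(labels.tolist())
    if class_a not in present and class_b not in present:
        raise ValueError(f"no {class_a} or {class_b} occurrences in sample")
    observed = _cooccurrence_count(peak_idx, labels, n_peaks, class_a, class_b)

    expected = np.empty(n_shuffles, dtype=np.int64)
    for i in range(n_shuffles):
        shuffled = labels[rng.permutation(len(labels))]
        expected[i] = _cooccurrence_count(peak_idx, shuffled, n_peaks, class_a, class_b)

    m_exp = float(expected.mean())
    p = (int(np.sum(expected <= observed)) + 1) / (n_shuffles + 1)
    if m_exp > 0:
        obs_norm = observed / m_exp
        exp_norm = expected / m_exp
    else:  # degenerate null: report raw values
        obs_norm = float(observed)
        exp_norm = expected.astype(float)
    return ShuffleResult(observed, expected, m_exp, obs_norm, exp_norm, p, n_shuffles)
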