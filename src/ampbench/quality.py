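"""Raw-read quality characterization, trimming, sub-sampling, rarefaction.

Edit distances to the mock community are *infix* (semi-global) Levenshtein
distances: the read aligns inside a full-length reference with free end gaps
on the reference, so a perfect substring scores 0.  A global distance would
be dominated by the length difference between a ~250 nt read and a ~1.5 kb
16S gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .refs import ReferenceSet

__all__ = [
    "ReadRecord",
    "nearest_reference_edit_distance",
    "moving_average_q",
    "select_trim_lengths",
    "trim_read",
    "subsample_reads",
    "rarefaction_curve",
    "sample_read_stats",
]


@dataclass
class ReadRecord:
    """A sequencing read with per-base Phred qualities."""

    id: str
    bases: str
    quals: list[int]

    def __post_init__(self):
        if len(self.bases) != len(self.quals):
            raise ValueError(f"read {self.id!r}: bases/quals length mismatch")
        if self.quals and (min(self.quals) < 0 or max(self.quals) > 60):
            raise ValueError(f"read {self.id!r}: Q outside [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def mean_q(self) -> float:
        return float(np.mean(self.quals)) if self.quals else float("nan")


def nearest_reference_edit_distance(read: str, refs: ReferenceSet) -> tuple[int, str]:
    """Minimum infix edit distance of a read over all references.

    N bases in the read mismatch everything (edlib treats unequal characters
    as mismatches, and references are strictly A/C/G/T).  Ties are broken by
    the first reference in input order.
    """
    if not read:
        raise ValueError("empty read")
    if len(refs) == 0:
        raise ValueError("empty reference set")
    best_d, best_id = None, None
    for rid, seq, _ in refs.members:
        d = edlib.align(read, seq, mode="HW", task="distance")["editDistance"]
        if best_d is None or d < best_d:
            best_d, best_id = d, rid
    return best_d, best_id


def moving_average_q(q: np.ndarray, window: int = 10) -> np.ndarray:
    """Trailing moving average; prefixes shorter than the window use the plain
    prefix mean."""
    q = np.asarray(q, dtype=float)
    cs = np.concatenate([[0.0], np.cumsum(q)])
    n = len(q)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i + 1 - window)
        out[i] = (cs[i + 1] - cs[lo]) / (i + 1 - lo)
    return out


def select_trim_lengths(
    q_matrix_r1: np.ndarray,
    q_matrix_r2: np.ndarray,
    amplicon_length: int,
    window: int = 10,
    q_threshold: float = 30.0,
    min_overlap: int = 30,
) -> tuple[int, int]:
    """Pick R1/R2 truncation lengths from per-position mean Q vectors.

    For each mate the candidate length is the largest prefix over which the
    moving-average Q (window default 10) stays at or above the threshold
    (default Q30).  If the implied merge overlap ``len_r1 + len_r2 -
    amplicon_length`` falls below ``min_overlap``, lengths are extended in
    1-nt steps into sub-threshold territory — R2 first, then R1, alternating
    per step — until the overlap constraint holds or both reads are
    exhausted.  A returned 0 means "no truncation" (the whole read passed).
    """
    q1 = np.asarray(q_matrix_r1, dtype=float)
    q2 = np.asarray(q_matrix_r2, dtype=float)
    if q1.size == 0 or q2.size == 0:
        raise ValueError("empty Q vector")
    if amplicon_length <= min_overlap:
        raise ValueError("amplicon_length must exceed min_overlap")

    def candidate(q):
        ma = moving_average_q(q, window)
        below = np.nonzero(ma < q_threshold)[0]
        return len(q) if below.size == 0 else int(below[0])

    len1, len2 = candidate(q1), candidate(q2)
    full1, full2 = len(q1), len(q2)
    # extend in 1-nt steps into sub-threshold territory, R2 before R1
    while len1 + len2 - amplicon_length < min_overlap:
        if len2 < full2:
            len2 += 1
        elif len1 < full1:
            len1 += 1
        else:
            deficit = min_overlap - (len1 + len2 - amplicon_length)
            raise ValueError(
                f"overlap constraint unsatisfiable at full read lengths "
                f"({full1}+{full2} vs amplicon {amplicon_length}): {deficit} nt short")
    return (0 if len1 == full1 else len1, 0 if len2 == full2 else len2)


def trim_read(read: ReadRecord, error_cutoff: float = 0.01,
              min_length: int = 200) -> ReadRecord | None:
    """Quality-trim a read to its best contiguous segment (modified Mott).

    Each position scores ``error_cutoff - 10**(-Q/10)``; the maximal-sum
    contiguous segment is retained (first such segment on ties).  Reads whose
    retained segment is shorter than ``min_length`` are rejected (None).
    """
    q = np.asarray(read.quals, dtype=float)
    scores = error_cutoff - 10.0 ** (-q / 10.0)
    best_sum, best_span = 0.0, None
    run_sum, run_start = 0.0, 0
    for i, s in enumerate(scores):
        if run_sum <= 0:
            run_sum, run_start = s, i
        else:
            run_sum += s
        if run_sum > best_sum:
            best_sum, best_span = run_sum, (run_start, i + 1)
    if best_span is None:
        return None
    lo, hi = best_span
    if hi - lo < min_length:
        return None
    return ReadRecord(read.id, read.bases[lo:hi], read.quals[lo:hi])


def subsample_reads(reads: list, depth: int, with_replacement: bool = True,
                    rng: np.random.Generator | int = 0) -> list:
    """Randomly sub-sample reads to a fixed depth (rarefying).

    Default is with replacement, matching the rarefying convention of
    drawing a consistent per-sample depth near the first quartile of the
    run's read-count distribution.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not reads:
        raise ValueError("no reads to sub-sample")
    if not with_replacement and depth > len(reads):
        raise ValueError("depth exceeds read count for sampling without replacement")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    idx = rng.choice(len(reads), size=depth, replace=with_replacement)
    return [reads[i] for i in idx]


def rarefaction_curve(variant_counts, depths) -> pd.DataFrame:
    """Analytic expected richness when ``d`` reads are drawn without replacement.

    E[S(d)] = sum_i [1 - C(N - n_i, d) / C(N, d)] with N the total count;
    depths beyond N are clamped to the observed richness.
    """
    n = np.asarray(variant_counts, dtype=np.int64)
    if (n < 0).any():
        raise ValueError("negative counts")
    n = n[n > 0]
    if n.size == 0:
        raise ValueError("need at least one positive count")
    N = int(n.sum())
    s_obs = int(n.size)

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    rows = []
    for d in np.asarray(depths, dtype=np.int64):
        if d < 0:
            raise ValueError("negative depth")
        if d >= N:
            rows.append((int(d), float(s_obs)))
            continue
        keep = N - n >= d  # variants small enough that all-miss is possible
        miss = np.zeros(n.size)
        miss[keep] = np.exp(log_comb(N - n[keep], d) - log_comb(N, d))
        rows.append((int(d), float(np.sum(1.0 - miss))))
    return pd.DataFrame(rows, columns=["depth", "expected_richness"])


def sample_read_stats(reads: list[ReadRecord], refs: ReferenceSet,
                      error_cutoff: float = 0.01, min_length: int = 200) -> dict:
    """Per-sample summary: mean nearest-reference edit distance, mean Q, and
    mean trimmed length (rejected reads contribute length 0)."""
    dists, lengths = [], []
    for r in reads:
        d, _ = nearest_reference_edit_distance(r.bases, refs)
        dists.append(d)
        t = trim_read(r, error_cutoff, min_length)
        lengths.append(len(t) if t is not None else 0)
    return {
        "n_reads": len(reads),
        "mean_edit_distance": float(np.mean(dists)),
        "mean_q": float(np.mean([r.mean_q for r in reads])),
        "mean_trimmed_length": float(np.mean(lengths)),
    }
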