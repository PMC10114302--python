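"""Pair merging, 100%-identity clustering, and exact matching to the mock.

This is the package's own pre-denoising pipeline: R1 and its
reverse-complemented mate are merged at the ungapped offset maximizing
overlap matches (the substitution-only error model makes gapped overlap
alignment unnecessary), merged amplicons are quality-trimmed, clustered at a
similarity threshold of 100% (exact deduplication), and counted against the
mock community.  The resulting variant table is the same shape the triage
stage accepts from external denoisers (DADA2/QIIME2/mothur exports).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quality import ReadRecord
from .refs import ReferenceSet, revcomp

__all__ = ["MergedAmplicon", "merge_pair", "cluster_identical", "exact_match"]


@dataclass
class MergedAmplicon:
    id: str
    bases: str
    quals: list[int]
    overlap_length: int
    mismatches_in_overlap: int


def _best_offset(a: np.ndarray, b: np.ndarray, min_overlap: int):
    """Ungapped offset of b relative to a maximizing overlap matches.

    Offset t places b[j] against a[j + t]; negative offsets hang b off a's
    left end.  Ties prefer the larger overlap.  Returns
    (offset, matches, overlap) or None if no offset has enough overlap.
    """
    la, lb = len(a), len(b)
    best = None
    for t in range(-(lb - min_overlap), la - min_overlap + 1):
        lo_a, hi_a = max(0, t), min(la, lb + t)
        ov = hi_a - lo_a
        if ov < min_overlap:
            continue
        m = int(np.count_nonzero(a[lo_a:hi_a] == b[lo_a - t:hi_a - t]))
        key = (m, ov)
        if best is None or key > best[0]:
            best = (key, t)
    if best is None:
        return None
    (m, ov), t = best
    return t, m, ov


def merge_pair(r1: ReadRecord, r2: ReadRecord, min_overlap: int = 50,
               max_overlap_mismatch_frac: float = 0.1) -> MergedAmplicon | None:
    """Merge a read pair into an amplicon, or return None on failure.

    R2 is reverse complemented (qualities reversed); the ungapped offset
    maximizing overlap matches is chosen (ties -> largest overlap).  The
    merge succeeds iff the overlap spans at least ``min_overlap`` nt and its
    mismatch fraction is at most ``max_overlap_mismatch_frac``.  At overlap
    mismatches the higher-Q base wins and its quality becomes the difference
    of the two; at agreements the higher Q is kept.

    A negative best offset means the mates read through each other (the
    template is shorter than the reads, with adapter read-through on both
    sides), so only the overlapped region is emitted.
    """
    if not r1.bases or not r2.bases:
        raise ValueError("empty read")
    b1 = np.frombuffer(r1.bases.encode(), dtype="S1")
    b2 = np.frombuffer(revcomp(r2.bases).encode(), dtype="S1")
    q1 = np.asarray(r1.quals)
    q2 = np.asarray(r2.quals[::-1])
    hit = _best_offset(b1, b2, min_overlap)
    if hit is None:
        return None
    t, matches, ov = hit
    mismatches = ov - matches
    if mismatches / ov > max_overlap_mismatch_frac:
        return None

    lo_a, hi_a = max(0, t), min(len(b1), len(b2) + t)
    ca = b1[lo_a:hi_a].copy()
    cq = q1[lo_a:hi_a].copy()
    ob = b2[lo_a - t:hi_a - t]
    oq = q2[lo_a - t:hi_a - t]
    take2 = oq > cq
    agree = ca == ob
    cq = np.where(agree, np.maximum(cq, oq), np.abs(cq - oq))
    ca = np.where(take2, ob, ca)
    consensus = ca.tobytes().decode()
    cons_q = cq.tolist()

    if t < 0:  # read-through: amplicon is the overlap itself
        bases, quals = consensus, cons_q
    else:
        bases = r1.bases[:lo_a] + consensus + b2[hi_a - t:].tobytes().decode()
        quals = r1.quals[:lo_a] + cons_q + q2[hi_a - t:].tolist()
    return MergedAmplicon(r1.id, bases, quals, ov, int(mismatches))


def cluster_identical(amplicons: list[MergedAmplicon],
                      sample_of: dict[str, str]) -> pd.DataFrame:
    """Cluster amplicons at 100% similarity: exact-sequence deduplication.

    Returns the variant table — one row per distinct sequence with
    per-sample read counts.  Variant ids are assigned by descending total
    count, then lexicographic sequence.
    """
    if not amplicons:
        raise ValueError("no amplicons to cluster")
    rows = [(a.bases, sample_of[a.id]) for a in amplicons]
    df = pd.DataFrame(rows, columns=["sequence", "sample"])
    counts = df.groupby(["sequence", "sample"]).size().unstack(fill_value=0)
    counts = counts.reindex(columns=sorted(counts.columns))
    total = counts.sum(axis=1)
    order = sorted(counts.index, key=lambda s: (-total[s], s))
    counts = counts.loc[order]
    out = counts.reset_index()
    out.insert(0, "variant_id", [f"V{i + 1:05d}" for i in range(len(out))])
    out.columns.name = None
    return out


def exact_match(variant: str, refs: ReferenceSet) -> tuple[bool, list[str]]:
    """Exact containment of a variant in the mock community.

    True iff the variant occurs as a contiguous substring of at least one
    reference, or a reference occurs inside the variant (edit distance zero
    excluding length differences, i.e. free end gaps in either direction).
    Returns all matching reference ids.
    """
    if not variant:
        raise ValueError("empty variant")
    hits = [rid for rid, seq, _ in refs.members if variant in seq or seq in variant]
    return bool(hits), hits
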