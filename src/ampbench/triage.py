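"""Six-way triage of representative sequence variants.

Every variant from a denoised (or merged/clustered) table is assigned
exactly one category by a fixed cascade, each test applied only to variants
all earlier tests rejected:

1. ``exact`` — zero edit distance to a mock reference excluding length
   differences (substring containment either way);
2. ``primer_dimer`` — contains an exact IUPAC-aware match to either primer
   or its reverse complement;
3. ``chimera`` — a two-parent (bimera) model explains the variant far
   better than any single reference;
4. ``off_target`` — too dissimilar from every reference, or dominated by a
   homopolymeric tract (low-complexity sequencing artifact);
5. ``mismatch`` vs ``contaminant`` — remaining variants are clustered
   together with the reference region sequences by average linkage (UPGMA)
   on pairwise alignment distances and the tree is cut at a distance
   cutoff (default 15%): variants sharing a clade with a reference are
   erroneous copies of community members (mismatch), the rest contaminants.

The bimera search is reference-based: for a variant of length L it finds
the breakpoint k and ordered parent pair (A, B) minimizing the infix edit
distance of the prefix ``v[:k]`` to A plus that of the suffix ``v[k:]`` to
B.  Both distance profiles over all k are obtained from one forward and one
reverse semi-global DP sweep per reference, so the search over all
(A, B, k) is exact at O(refs * L * M) total cost.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .merge import exact_match
from .refs import PrimerSet, ReferenceSet, in_silico_pcr, match_primer, revcomp

__all__ = [
    "ChimeraCall",
    "TriageParams",
    "detect_primer_dimer",
    "prefix_distance_profile",
    "detect_chimera",
    "alignment_identity",
    "detect_off_target",
    "partition_mismatch_contaminant",
    "triage",
]

TRIAGE_CATEGORIES = ("exact", "primer_dimer", "chimera", "off_target", "mismatch", "contaminant")


@dataclass
class ChimeraCall:
    is_chimeric: bool
    parent_a: str | None = None
    parent_b: str | None = None
    breakpoint: int | None = None
    two_parent_distance: int | None = None
    one_parent_distance: int | None = None


@dataclass
class TriageParams:
    """Tunables of the cascade; defaults are the package's documented choices."""

    chimera_margin: int = 4
    chimera_max_two_parent_frac: float = 0.01
    offtarget_identity_threshold: float = 0.6
    offtarget_homopolymer_frac: float = 0.5
    clade_cutoff: float = 0.15


def detect_primer_dimer(variant: str, primers: PrimerSet) -> tuple[bool, tuple[int, int] | None]:
    """Does the variant contain a primer sequence?

    Checks the forward primer, the reverse primer, and both reverse
    complements, IUPAC-aware, ungapped, exact.  Returns the first hit span
    (0-based half-open) or None.
    """
    if not variant:
        raise ValueError("empty variant")
    for p in (primers.forward, primers.reverse,
              revcomp(primers.forward), revcomp(primers.reverse)):
        hits = match_primer(p, variant) if len(p) <= len(variant) else []
        if hits:
            return True, (hits[0], hits[0] + len(p))
    return False, None


def prefix_distance_profiles(variant: str, refs: list[str]) -> np.ndarray:
    """Infix edit distance of every prefix of ``variant`` against each reference.

    Returns an (n_refs, len(variant)+1) array whose entry [r, k] is the
    semi-global Levenshtein distance of ``variant[:k]`` to the
    best-matching substring of ``refs[r]`` (free gaps at both reference
    ends).  One DP sweep over the variant handles all references at once,
    each row vectorized over an (n_refs, M) matrix; the in-row
    left-to-right insertion dependence is resolved with a prefix-minimum
    scan.  References are right-padded with a sentinel that matches
    nothing, which cannot lower any row minimum.
    """
    v = np.frombuffer(variant.encode(), dtype=np.uint8)
    L = len(v)
    n = len(refs)
    lens = np.array([len(r) for r in refs], dtype=np.int64)
    M = int(lens.max())
    R = np.zeros((n, M), dtype=np.uint8)  # 0 is a sentinel matching nothing
    for idx, r in enumerate(refs):
        R[idx, :len(r)] = np.frombuffer(r.encode(), dtype=np.uint8)
    return _prefix_sweep(v, R, lens)


def _prefix_sweep_numpy(v, R, lens):
    n, M = R.shape
    L = len(v)
    out = np.empty((n, L + 1), dtype=np.int64)
    out[:, 0] = 0
    prev = np.zeros((n, M + 1), dtype=np.int64)  # D[0][j] = 0: free start on ref
    js = np.arange(M + 1)
    col0 = np.empty((n, 1), dtype=np.int64)
    for i in range(1, L + 1):
        sub = prev[:, :-1] + (v[i - 1] != R)
        col0[:] = i
        cand = np.minimum(prev + 1, np.concatenate([col0, sub], axis=1))
        # D[i][j] = min_{k<=j} cand[k] + (j - k)
        cur = np.minimum.accumulate(cand - js, axis=1) + js
        out[:, i] = cur.min(axis=1)
        prev = cur
    return out


try:
    from numba import njit

    @njit(cache=False)
    def _prefix_sweep_jit(v, R, lens):  # pragma: no cover - exercised via wrapper
        n, _ = R.shape
        L = len(v)
        out = np.empty((n, L + 1), dtype=np.int64)
        for r in range(n):
            M = lens[r]
            out[r, 0] = 0
            prev = np.zeros(M + 1, dtype=np.int64)
            cur = np.empty(M + 1, dtype=np.int64)
            for i in range(1, L + 1):
                cur[0] = i
                best = i
                for j in range(1, M + 1):
                    c = prev[j - 1] + (1 if v[i - 1] != R[r, j - 1] else 0)
                    if prev[j] + 1 < c:
                        c = prev[j] + 1
                    if cur[j - 1] + 1 < c:
                        c = cur[j - 1] + 1
                    cur[j] = c
                    if c < best:
                        best = c
                out[r, i] = best
                prev, cur = cur, prev
        return out

    _prefix_sweep = _prefix_sweep_jit
except ImportError:  # pragma: no cover
    _prefix_sweep = _prefix_sweep_numpy


def prefix_distance_profile(variant: str, ref: str) -> np.ndarray:
    """Single-reference convenience wrapper around
    :func:`prefix_distance_profiles`."""
    return prefix_distance_profiles(variant, [ref])[0]


def detect_chimera(variant: str, refs: ReferenceSet, margin: int = 4,
                   max_two_parent_frac: float = 0.01) -> ChimeraCall:
    """Reference-based bimera test.

    The variant is called chimeric iff the best two-parent decomposition
    (ordered parents A != B, breakpoint k strictly inside) beats the best
    single parent by at least ``margin`` edits AND fits the two-parent model
    within ``ceil(max_two_parent_frac * len)`` edits.  The margin guards
    against calling plain mismatched variants chimeric; the fit cap rejects
    sequences that no pair of references explains (contaminants).
    """
    if len(refs) < 2:
        raise ValueError("chimera detection needs >= 2 references")
    if not variant:
        raise ValueError("empty variant")
    L = len(variant)
    ids = refs.ids
    seqs = [seq for _, seq, _ in refs.members]
    pref = prefix_distance_profiles(variant, seqs)
    suf_rev = prefix_distance_profiles(variant[::-1], [s[::-1] for s in seqs])
    suf = suf_rev[:, ::-1]  # suf[r, k] = infix distance of variant[k:] to ref r

    one_parent = int(pref[:, L].min())

    ks = np.arange(1, L)  # breakpoints strictly inside
    p = pref[:, 1:L]  # (refs, L-1)
    s = suf[:, 1:L]
    # best and runner-up over refs at each breakpoint, to honor A != B
    pi = np.argsort(p, axis=0, kind="stable")
    si = np.argsort(s, axis=0, kind="stable")
    p1, p2 = np.take_along_axis(p, pi[:2], axis=0)
    s1, s2 = np.take_along_axis(s, si[:2], axis=0)
    same = pi[0] == si[0]
    total = np.where(same, np.minimum(p1 + s2, p2 + s1), p1 + s1)
    best_k = int(np.argmin(total))
    two_parent = int(total[best_k])
    if same[best_k]:
        if p1[best_k] + s2[best_k] <= p2[best_k] + s1[best_k]:
            a_idx, b_idx = pi[0, best_k], si[1, best_k]
        else:
            a_idx, b_idx = pi[1, best_k], si[0, best_k]
    else:
        a_idx, b_idx = pi[0, best_k], si[0, best_k]

    is_chimeric = (one_parent - two_parent >= margin
                   and two_parent <= int(np.ceil(max_two_parent_frac * L)))
    return ChimeraCall(
        is_chimeric=bool(is_chimeric),
        parent_a=ids[int(a_idx)],
        parent_b=ids[int(b_idx)],
        breakpoint=int(ks[best_k]),
        two_parent_distance=two_parent,
        one_parent_distance=one_parent,
    )


def _cigar_columns(cigar: str) -> int:
    return sum(int(n) for n, _ in re.findall(r"(\d+)([=XIDM])", cigar))


def alignment_identity(query: str, target: str) -> float:
    """Identity (matches / alignment columns) of the best infix alignment of
    the shorter sequence inside the longer (terminal gaps on the longer are
    free)."""
    if len(query) > len(target):
        query, target = target, query
    res = edlib.align(query, target, mode="HW", task="path")
    cols = _cigar_columns(res["cigar"])
    return 1.0 - res["editDistance"] / cols if cols else 0.0


def longest_homopolymer(seq: str) -> int:
    return max((len(m.group(0)) for m in re.finditer(r"(.)\1*", seq)), default=0)


def detect_off_target(variant: str, refs: ReferenceSet,
                      identity_threshold: float = 0.6,
                      homopolymer_frac: float = 0.5) -> tuple[bool, float, int]:
    """Off-target / sequencing-failure test.

    True iff the best infix identity to any reference falls below the
    threshold, or a single homopolymer run covers at least
    ``homopolymer_frac`` of the variant.  Returns (flag, best identity,
    longest homopolymer run).
    """
    if not variant:
        raise ValueError("empty variant")
    best = max(alignment_identity(variant, seq) for _, seq, _ in refs.members)
    run = longest_homopolymer(variant)
    flag = best < identity_threshold or run >= homopolymer_frac * len(variant)
    return flag, best, run


def partition_mismatch_contaminant(variants: list[str], refs: ReferenceSet,
                                   cutoff: float = 0.15,
                                   reference_inserts: list[str] | None = None
                                   ) -> list[str]:
    """Split leftover variants into ``mismatch`` vs ``contaminant``.

    Variants and the reference region sequences are clustered by average
    linkage (UPGMA) on pairwise infix alignment distances (1 - identity,
    terminal gaps free — the sequences are fragments) and the dendrogram is
    cut at ``cutoff`` (inclusive).  A variant whose cluster contains at
    least one reference sequence is a mismatched copy of a community
    member; the rest are contamination.

    ``reference_inserts`` supplies the region sequences; by default the
    full references are used, which is safe because distances are infix.
    """
    if not variants:
        return []
    ref_seqs = reference_inserts if reference_inserts is not None \
        else [seq for _, seq, _ in refs.members]
    seqs = list(variants) + list(dict.fromkeys(ref_seqs))
    n = len(seqs)
    if n == 1:
        return ["contaminant"]
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - alignment_identity(seqs[i], seqs[j])
            dm[i, j] = dm[j, i] = d
    Z = linkage(squareform(dm, checks=False), method="average")
    labels = fcluster(Z, t=cutoff, criterion="distance")
    ref_clusters = set(labels[len(variants):])
    return ["mismatch" if labels[i] in ref_clusters else "contaminant"
            for i in range(len(variants))]


def triage(table: pd.DataFrame, refs: ReferenceSet, primers: PrimerSet,
           params: TriageParams | None = None) -> pd.DataFrame:
    """Apply the full cascade to a variant table.

    ``table`` needs ``variant_id`` and ``sequence`` columns (any per-sample
    count columns are carried along untouched by the caller).  Returns the
    triage table: one row per variant with its category and category-
    specific evidence.  The chimera and mismatch/contaminant stages compare
    against the amplified region of each reference (extracted by in-silico
    PCR) rather than the full gene, since variants are region fragments;
    when a primer set does not amplify the community the full references
    are used instead.
    """
    params = params or TriageParams()
    try:
        amp_with = in_silico_pcr(refs, primers, include_primers=True)
        amp_without = in_silico_pcr(refs, primers, include_primers=False)
        have_amplicons = len(amp_with) >= 2
    except ValueError:
        have_amplicons = False
    if have_amplicons:
        chimera_refs = ReferenceSet([(rid, amp_with.amplicons[rid], 0.0)
                                     for rid in amp_with.amplicons])
        clade_inserts = list(dict.fromkeys(amp_without.amplicons.values()))
    else:
        chimera_refs = refs
        clade_inserts = None

    rows = []
    leftovers: list[tuple[int, str]] = []
    for i, (vid, seq) in enumerate(zip(table["variant_id"], table["sequence"])):
        row = {"variant_id": vid, "category": None, "evidence": ""}
        is_exact, hit_ids = exact_match(seq, refs)
        if is_exact:
            row.update(category="exact", evidence=",".join(hit_ids))
            rows.append(row)
            continue
        dimer, span = detect_primer_dimer(seq, primers)
        if dimer:
            row.update(category="primer_dimer", evidence=f"primer_hit={span[0]}-{span[1]}")
            rows.append(row)
            continue
        call = detect_chimera(seq, chimera_refs, params.chimera_margin,
                              params.chimera_max_two_parent_frac)
        if call.is_chimeric:
            row.update(category="chimera",
                       evidence=(f"parents={call.parent_a},{call.parent_b};"
                                 f"breakpoint={call.breakpoint};"
                                 f"d2={call.two_parent_distance};d1={call.one_parent_distance}"))
            rows.append(row)
            continue
        off, ident, run = detect_off_target(seq, refs,
                                            params.offtarget_identity_threshold,
                                            params.offtarget_homopolymer_frac)
        if off:
            row.update(category="off_target",
                       evidence=f"best_identity={ident:.3f};homopolymer={run}")
            rows.append(row)
            continue
        row["evidence"] = f"best_identity={ident:.3f}"
        leftovers.append((len(rows), seq))
        rows.append(row)

    if leftovers:
        labels = partition_mismatch_contaminant(
            [seq for _, seq in leftovers], refs, params.clade_cutoff,
            reference_inserts=clade_inserts)
        for (idx, _), lab in zip(leftovers, labels):
            rows[idx]["category"] = lab
    out = pd.DataFrame(rows, columns=["variant_id", "category", "evidence"])
    assert out["category"].notna().all()
    return out
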