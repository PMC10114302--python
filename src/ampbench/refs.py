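"""Mock-community references, degenerate primers, and in-silico PCR.

The ground truth of a mock-community benchmark is a set of named full-length
16S rRNA gene sequences with approximate input relative abundances (e.g.
qPCR-derived 16S copy fractions).  A primer pair delimits the amplified
variable region on each reference; because distinct community members can be
identical (or polymorphic) within a region, the number of *expected unique
sequence variants* for a primer set is usually smaller than the number of
community members and is the denominator of the coverage metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "IUPAC",
    "ReferenceSet",
    "PrimerSet",
    "AmpliconSet",
    "revcomp",
    "match_primer",
    "in_silico_pcr",
    "expected_variants",
]

# IUPAC nucleotide codes -> set of concrete bases each code matches.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceSet:
    """Named mock-community reference sequences with input abundances.

    Parameters
    ----------
    members : list of (id, sequence, input_abundance)
        ``sequence`` is uppercase DNA over {A,C,G,T}; ``input_abundance`` is a
        nonnegative fraction.  When any abundance is provided they must sum to
        1 (within 1e-9).
    """

    members: list[tuple[str, str, float]]

    def __post_init__(self):
        ids = [m[0] for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("reference ids must be unique")
        for rid, seq, ab in self.members:
            if not seq:
                raise ValueError(f"reference {rid!r} has an empty sequence")
            if set(seq) - set("ACGT"):
                raise ValueError(f"reference {rid!r} contains non-ACGT characters")
            if ab < 0:
                raise ValueError(f"reference {rid!r} has negative abundance")
        total = sum(m[2] for m in self.members)
        if total > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total!r}, expected 1")

    @property
    def ids(self) -> list[str]:
        return [m[0] for m in self.members]

    def sequence(self, rid: str) -> str:
        for m in self.members:
            if m[0] == rid:
                return m[1]
        raise KeyError(rid)

    @property
    def abundances(self) -> dict[str, float]:
        return {m[0]: m[2] for m in self.members}

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PrimerSet:
    """A forward/reverse primer pair bracketing a 16S variable region.

    The reverse primer is stored as synthesized (5'->3' on the minus strand),
    i.e. it is matched on the reference plus strand via its reverse
    complement.  ``expected_amplicon_length`` is informational (nt).
    """

    name: str
    forward: str
    reverse: str
    expected_amplicon_length: int = 0

    def __post_init__(self):
        for label, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not p:
                raise ValueError(f"{label} primer is empty")
            bad = set(p) - set(IUPAC)
            if bad:
                raise ValueError(f"{label} primer has non-IUPAC codes: {sorted(bad)}")


# The three primer pairs of the multi-factorial benchmark design
# (V3-V4 357f/806r, V4-V4 515f/806r, V4-V5 541f/914r).
STANDARD_PRIMERS: dict[str, PrimerSet] = {
    "V3-V4": PrimerSet("V3-V4", "CCTACGGGAGGCAGCAG", "GGACTACNVGGGTWTCTAAT", 432),
    "V4-V4": PrimerSet("V4-V4", "GTGYCAGCMGCCGCGGTAA", "GGACTACNVGGGTWTCTAAT", 254),
    "V4-V5": PrimerSet("V4-V5", "GYCAGCMGCMGCGGTAATAC", "GYCCCCGTCWATTCMTTTGAGTTT", 373),
}


@dataclass
class AmpliconSet:
    """Per-reference extracted amplicons.

    ``amplicons`` maps reference id -> insert string between (and excluding,
    unless extracted with ``include_primers=True``) the primer binding sites;
    ``coordinates`` maps reference id -> 0-based half-open interval of that
    string on the reference plus strand.  References without both primer
    sites are listed in ``non_amplifiable``.
    """

    amplicons: dict[str, str] = field(default_factory=dict)
    coordinates: dict[str, tuple[int, int]] = field(default_factory=dict)
    non_amplifiable: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.amplicons)


def match_primer(primer: str, sequence: str) -> list[int]:
    """All 0-based start positions where an IUPAC primer matches exactly.

    Matching is ungapped and length-exact: position ``p`` is reported iff for
    every primer offset ``i`` the IUPAC set of ``primer[i]`` contains
    ``sequence[p+i]``.  An ``N`` in the *sequence* never matches (only
    concrete A/C/G/T sequence bases can satisfy a primer position).
    """
    if not primer or not sequence:
        raise ValueError("primer and sequence must be nonempty")
    bad = set(primer) - set(IUPAC)
    if bad:
        raise ValueError(f"primer has non-IUPAC codes: {sorted(bad)}")
    sets = [IUPAC[c] for c in primer]
    k = len(primer)
    hits = []
    for p in range(len(sequence) - k + 1):
        window = sequence[p:p + k]
        if all(b in s for b, s in zip(window, sets)):
            hits.append(p)
    return hits


def in_silico_pcr(
    refs: ReferenceSet,
    primers: PrimerSet,
    include_primers: bool = False,
) -> AmpliconSet:
    """Extract the amplified region from each reference.

    The forward primer is matched on the plus strand; the reverse primer (as
    synthesized) is matched as its reverse complement on the plus strand.  If
    several forward/reverse hit pairs give a positive-length product, the
    innermost pair (shortest insert) is used, mimicking the dominant PCR
    product, and a warning is emitted.  References lacking either site are
    reported as non-amplifiable with a warning.

    With ``include_primers=False`` (default) the amplicon is the insert
    strictly between the two binding sites; with ``True`` it spans them.
    """
    rev_on_plus = revcomp(primers.reverse)
    out = AmpliconSet()
    for rid, seq, _ in refs.members:
        fwd_hits = match_primer(primers.forward, seq)
        rev_hits = match_primer(rev_on_plus, seq)
        if not fwd_hits or not rev_hits:
            warnings.warn(f"reference {rid!r}: no {primers.name} primer site; excluded")
            out.non_amplifiable.append(rid)
            continue
        flen = len(primers.forward)
        rlen = len(primers.reverse)
        pairs = []
        for f in fwd_hits:
            for r in rev_hits:
                if include_primers:
                    start, end = f, r + rlen
                else:
                    start, end = f + flen, r
                if end - start > 0:
                    pairs.append((end - start, start, end))
        if not pairs:
            warnings.warn(f"reference {rid!r}: primer sites in wrong orientation; excluded")
            out.non_amplifiable.append(rid)
            continue
        if len(pairs) > 1:
            warnings.warn(f"reference {rid!r}: multiple {primers.name} products; keeping shortest")
        _, start, end = min(pairs)
        out.amplicons[rid] = seq[start:end]
        out.coordinates[rid] = (start, end)
    return out


def expected_variants(amplicons: AmpliconSet) -> tuple[int, list[tuple[str, list[str]]]]:
    """Deduplicate amplicons into the expected unique sequence variants.

    Returns ``(count, variants)`` where ``variants`` is a list of
    ``(sequence, contributing reference ids)`` ordered by first appearance.
    ``count`` is the coverage denominator: the number of distinct region
    sequences the community is expected to yield.
    """
    if not amplicons.amplicons:
        raise ValueError("empty amplicon set")
    groups: dict[str, list[str]] = {}
    for rid, amp in amplicons.amplicons.items():
        groups.setdefault(amp, []).append(rid)
    variants = [(seq, ids) for seq, ids in groups.items()]
    return len(variants), variants
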