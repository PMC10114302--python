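"""Triage cascade: dimers, chimeras, off-targets, mismatch/contaminant split."""

import math

import edlib
import numpy as np
import pandas as pd
import pytest

from ampbench.refs import ReferenceSet, in_silico_pcr, revcomp
from ampbench.triage import (TriageParams, detect_chimera, detect_off_target,
                             detect_primer_dimer, partition_mismatch_contaminant, triage)

from .conftest import V4, mutate, random_dna


def brute_force_chimera(variant, members, margin=4, max_two_parent_frac=0.01):
    """Oracle: enumerate every (parentA, parentB, breakpoint) with edlib.

    Independent of the package's DP: per-half distances come straight from
    edlib's infix aligner for each concrete split.
    """
    L = len(variant)
    ids = [m[0] for m in members]
    pref = {rid: [None] * (L + 1) for rid in ids}
    suf = {rid: [None] * (L + 1) for rid in ids}
    for rid, seq, _ in members:
        for k in range(1, L):
            pref[rid][k] = edlib.align(variant[:k], seq, mode="HW")["editDistance"]
            suf[rid][k] = edlib.align(variant[k:], seq, mode="HW")["editDistance"]
    one = min(edlib.align(variant, seq, mode="HW")["editDistance"]
              for _, seq, _ in members)
    two = None
    for a in ids:
        for b in ids:
            if a == b:
                continue
            for k in range(1, L):
                d = pref[a][k] + suf[b][k]
                if two is None or d < two:
                    two = d
    chim = one - two >= margin and two <= math.ceil(max_two_parent_frac * L)
    return chim, one, two


class TestDetectPrimerDimer:
    def test_canonical_dimer_detected(self):
        dimer = "GTGTCAGCAGCCGCGGTAA" + revcomp("GGACTACAAGGGTATCTAAT")
        found, span = detect_primer_dimer(dimer, V4)
        assert found and span == (0, 19)

    def test_primer_free_variant_is_clean(self):
        rng = np.random.default_rng(0)
        from ampbench.refs import match_primer

        while True:
            v = random_dna(rng, 200)
            if not any(match_primer(p, v) for p in
                       (V4.forward, V4.reverse, revcomp(V4.forward), revcomp(V4.reverse))):
                break
        assert detect_primer_dimer(v, V4) == (False, None)

    def test_embedded_degenerate_reverse_primer_expansion(self):
        rng = np.random.default_rng(1)
        # a concrete expansion of the degenerate reverse primer 806r
        concrete = "GGACTACTCGGGTATCTAAT"  # N->T, V->C, W->A
        v = random_dna(rng, 90) + concrete + random_dna(rng, 90)
        found, _ = detect_primer_dimer(v, V4)
        assert found


class TestDetectChimera:
    def _panel(self, seed=2, n=4, length=200):
        rng = np.random.default_rng(seed)
        return ReferenceSet([(f"p{i}", random_dna(rng, length), 0.0) for i in range(n)])

    def test_reference_itself_is_not_chimeric(self, mock_small):
        amp = in_silico_pcr(mock_small, V4)
        panel = ReferenceSet([(r, s, 0.0) for r, s in amp.amplicons.items()])
        insert = next(iter(amp.amplicons.values()))
        call = detect_chimera(insert, panel)
        assert not call.is_chimeric
        assert call.one_parent_distance == 0

    def test_constructed_bimera_recovered(self):
        panel = self._panel()
        a, b = panel.members[0][1], panel.members[1][1]
        variant = a[:120] + b[120:]
        call = detect_chimera(variant, panel)
        assert call.is_chimeric
        assert call.two_parent_distance == 0
        assert {call.parent_a, call.parent_b} == {"p0", "p1"}
        # recovered breakpoint lies where a-prefix + b-suffix reproduces the variant
        assert a[:call.breakpoint] + b[call.breakpoint:] == variant

    def test_single_substitution_is_not_chimeric(self):
        rng = np.random.default_rng(3)
        panel = self._panel()
        variant = mutate(panel.members[2][1], 1, rng)
        call = detect_chimera(variant, panel)
        assert not call.is_chimeric
        assert call.one_parent_distance == 1

    def test_needs_two_references(self):
        only = ReferenceSet([("x", "ACGTACGTACGT", 1.0)])
        with pytest.raises(ValueError):
            detect_chimera("ACGTACGT", only)

    @pytest.mark.parametrize("case", range(25))
    def test_agrees_with_exhaustive_oracle(self, case):
        rng = np.random.default_rng(100 + case)
        n_refs = int(rng.integers(2, 5))
        length = int(rng.integers(30, 90))
        members = [(f"r{i}", random_dna(rng, length), 0.0) for i in range(n_refs)]
        panel = ReferenceSet(members)
        mode = case % 3
        if mode == 0:  # true bimera
            a, b = rng.choice(n_refs, 2, replace=False)
            k = int(rng.integers(5, length - 5))
            variant = members[a][1][:k] + members[b][1][k:]
        elif mode == 1:  # mutated single parent
            variant = mutate(members[0][1], int(rng.integers(0, 4)), rng)
        else:  # unrelated sequence
            variant = random_dna(rng, length)
        call = detect_chimera(variant, panel)
        chim, one, two = brute_force_chimera(variant, members)
        assert call.is_chimeric == chim
        assert call.one_parent_distance == one
        assert call.two_parent_distance == two


class TestDetectOffTarget:
    def test_reference_substring_is_on_target(self, mock_small):
        _, seq, _ = mock_small.members[0]
        flag, ident, _ = detect_off_target(seq[50:250], mock_small)
        assert not flag and ident == 1.0

    def test_homopolymer_rule(self, mock_small):
        flag, _, run = detect_off_target("A" * 200, mock_small)
        assert flag and run == 200

    def test_random_sequences_fall_below_identity_threshold(self, mock_small):
        rng = np.random.default_rng(4)
        idents = []
        for _ in range(30):
            flag, ident, _ = detect_off_target(random_dna(rng, 250), mock_small)
            idents.append(ident)
        assert np.mean(idents) < 0.62
        assert np.mean([i < 0.6 for i in idents]) > 0.8


class TestPartitionMismatchContaminant:
    def test_near_reference_variant_is_mismatch(self, mock_small):
        rng = np.random.default_rng(5)
        amp = in_silico_pcr(mock_small, V4)
        insert = next(iter(amp.amplicons.values()))
        v = mutate(insert, max(1, len(insert) // 100), rng)  # ~1% distance
        labels = partition_mismatch_contaminant([v], mock_small, cutoff=0.15)
        assert labels == ["mismatch"]

    def test_distant_variant_is_contaminant(self, mock_small):
        rng = np.random.default_rng(6)
        amp = in_silico_pcr(mock_small, V4)
        insert = next(iter(amp.amplicons.values()))
        v = mutate(insert, int(0.4 * len(insert)), rng)  # ~40% distance
        labels = partition_mismatch_contaminant([v], mock_small, cutoff=0.15)
        assert labels == ["contaminant"]

    def test_chained_variants_join_reference_clade(self, mock_small):
        rng = np.random.default_rng(7)
        amp = in_silico_pcr(mock_small, V4)
        insert = next(iter(amp.amplicons.values()))
        v1 = mutate(insert, int(0.10 * len(insert)), rng)
        v2 = mutate(v1, int(0.05 * len(v1)), rng)
        v3 = mutate(v1, int(0.05 * len(v1)), rng)
        labels = partition_mismatch_contaminant([v1, v2, v3], mock_small, cutoff=0.15)
        assert labels == ["mismatch"] * 3


class TestTriageCascade:
    def _table(self, seqs):
        return pd.DataFrame({"variant_id": [f"V{i}" for i in range(len(seqs))],
                             "sequence": seqs})

    def test_noise_free_variants_all_exact(self, mock_small):
        amp = in_silico_pcr(mock_small, V4)
        seqs = sorted(set(amp.amplicons.values()))
        tri = triage(self._table(seqs), mock_small, V4)
        assert (tri["category"] == "exact").all()

    def test_cascade_order_dimer_beats_chimera(self, mock_small):
        amp = in_silico_pcr(mock_small, V4)
        inserts = sorted(set(amp.amplicons.values()))
        a, b = inserts[0], inserts[1]
        chimera_with_primer = (a[:90] + b[90:])[:150] + "GTGTCAGCAGCCGCGGTAA"
        tri = triage(self._table([chimera_with_primer]), mock_small, V4)
        assert tri.loc[0, "category"] == "primer_dimer"

    def test_each_truth_category_recovered(self, mock_small):
        rng = np.random.default_rng(8)
        amp = in_silico_pcr(mock_small, V4)
        inserts = sorted(set(amp.amplicons.values()))
        a, b = inserts[0], inserts[1]
        seqs = {
            "exact": a,
            "primer_dimer": "GTGTCAGCAGCCGCGGTAA" + revcomp("GGACTACAAGGGTATCTAAT"),
            "chimera": a[:100] + b[100:],
            "off_target": "G" * 150 + random_dna(rng, 30),
            "mismatch": mutate(b, 3, rng),
            "contaminant": mutate(a, int(0.3 * len(a)), rng),
        }
        table = self._table(list(seqs.values()))
        tri = triage(table, mock_small, V4)
        assert list(tri["category"]) == list(seqs)

    def test_labels_invariant_to_input_order(self, mock_small):
        rng = np.random.default_rng(9)
        amp = in_silico_pcr(mock_small, V4)
        inserts = sorted(set(amp.amplicons.values()))
        seqs = [inserts[0], mutate(inserts[1], 2, rng),
                inserts[0][:100] + inserts[1][100:],
                mutate(inserts[2], int(0.35 * len(inserts[2])), rng)]
        t1 = triage(self._table(seqs), mock_small, V4)
        t2 = triage(self._table(seqs[::-1]), mock_small, V4)
        m1 = dict(zip(self._table(seqs)["sequence"], t1["category"]))
        m2 = dict(zip(self._table(seqs[::-1])["sequence"], t2["category"]))
        assert m1 == m2

    def test_categories_partition_the_table(self, mock_small):
        rng = np.random.default_rng(10)
        amp = in_silico_pcr(mock_small, V4)
        inserts = sorted(set(amp.amplicons.values()))
        seqs = [inserts[0], inserts[1], mutate(inserts[0], 2, rng),
                random_dna(rng, 150)]
        tri = triage(self._table(seqs), mock_small, V4)
        assert len(tri) == len(seqs)
        assert tri["category"].isin(
            ["exact", "primer_dimer", "chimera", "off_target",
             "mismatch", "contaminant"]).all()
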