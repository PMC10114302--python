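"""Accuracy/coverage/bias metrics and the statistical helpers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ampbench.metrics import (accuracy, anova_eta_squared, chimera_fraction,
                              compositional_bias, coverage, crosstalk_analysis,
                              hedges_g, ks_statistic, variance_explained)


def _tables(categories, counts):
    tri = pd.DataFrame({"variant_id": [f"V{i}" for i in range(len(categories))],
                        "category": categories, "evidence": ""})
    cnt = pd.DataFrame({"variant_id": [f"V{i}" for i in range(len(categories))],
                        "sequence": ["ACGT"] * len(categories), "s1": counts})
    return tri, cnt


class TestAccuracy:
    def test_worked_example_1141_of_1192(self):
        tri, cnt = _tables(["exact", "mismatch"], [1141, 51])
        assert accuracy(tri, cnt) == 1141 / 1192
        assert f"{int(accuracy(tri, cnt) * 100) / 100:.2f}" == "0.95"

    def test_all_exact_is_one(self):
        tri, cnt = _tables(["exact", "exact"], [10, 20])
        assert accuracy(tri, cnt) == 1.0

    def test_no_exact_is_zero(self):
        tri, cnt = _tables(["chimera", "contaminant"], [10, 20])
        assert accuracy(tri, cnt) == 0.0

    def test_empty_counts_undefined(self):
        tri, cnt = _tables(["exact"], [0])
        assert np.isnan(accuracy(tri, cnt))

    def test_mismatched_ids_error(self):
        tri, cnt = _tables(["exact"], [5])
        tri["variant_id"] = ["OTHER"]
        with pytest.raises(ValueError):
            accuracy(tri, cnt)


class TestCoverage:
    def _expected(self, n):
        return n, [(f"MOCKSEQ{i:02d}" + "A" * 20, [f"m{i}"]) for i in range(n)]

    def test_worked_example_10_of_25(self):
        exp = self._expected(25)
        seqs = [exp[1][i][0] for i in range(10)]
        tri = pd.DataFrame({"variant_id": [f"V{i}" for i in range(10)],
                            "category": "exact", "evidence": ""})
        assert coverage(tri, exp, sequences={f"V{i}": s for i, s in enumerate(seqs)}) == 0.4

    def test_duplicate_hits_count_once(self):
        exp = self._expected(5)
        mock0 = exp[1][0][0]
        tri = pd.DataFrame({"variant_id": ["V0", "V1"], "category": "exact",
                            "evidence": ""})
        seqs = {"V0": mock0, "V1": "TT" + mock0 + "GG"}
        assert coverage(tri, exp, sequences=seqs) == 1 / 5

    def test_full_recovery_is_one(self):
        exp = self._expected(4)
        seqs = {f"V{i}": exp[1][i][0] for i in range(4)}
        tri = pd.DataFrame({"variant_id": list(seqs), "category": "exact",
                            "evidence": ""})
        assert coverage(tri, exp, sequences=seqs) == 1.0


class TestChimeraFraction:
    def test_no_chimeras_zero(self):
        tri, cnt = _tables(["exact", "mismatch"], [5, 5])
        assert chimera_fraction(tri, cnt) == 0.0

    def test_all_chimeric_one(self):
        tri, cnt = _tables(["chimera", "chimera"], [5, 5])
        assert chimera_fraction(tri, cnt) == 1.0

    def test_read_weighted_fraction(self):
        tri, cnt = _tables(["exact", "chimera"], [96, 4])
        assert chimera_fraction(tri, cnt) == 0.04


class TestCompositionalBias:
    def test_monotone_output_is_one(self):
        a_in = {"a": 0.1, "b": 0.3, "c": 0.6}
        a_out = {"a": 0.05, "b": 0.2, "c": 0.75}
        assert compositional_bias(a_in, a_out) == pytest.approx(1.0)

    def test_reversed_output_is_minus_one(self):
        a_in = {"a": 0.1, "b": 0.3, "c": 0.6}
        a_out = {"a": 0.6, "b": 0.3, "c": 0.1}
        assert compositional_bias(a_in, a_out) == pytest.approx(-1.0)

    def test_tied_ranks_hand_example(self):
        a_in = dict(zip("abcd", [1, 2, 3, 4]))
        a_out = dict(zip("abcd", [1, 2, 2, 4]))
        # ranks of output: 1, 2.5, 2.5, 4 -> Pearson on ranks = 1.5/sqrt(2.5)
        assert compositional_bias(a_in, a_out) == pytest.approx(1.5 / np.sqrt(2.5))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        a_in = {f"m{i}": float(v) for i, v in enumerate(rng.random(10))}
        a_out = {f"m{i}": float(v) for i, v in enumerate(rng.random(10))}
        base = compositional_bias(a_in, a_out)
        squashed = {k: np.exp(3 * v) for k, v in a_out.items()}
        assert compositional_bias(a_in, squashed) == pytest.approx(base)

    def test_empty_output_is_nan(self):
        assert np.isnan(compositional_bias({"a": 0.5, "b": 0.3, "c": 0.2}, {}))


class TestHedgesG:
    def test_hand_example_sqrt_two(self):
        assert hedges_g([9, 11], [7, 9]) == pytest.approx(np.sqrt(2))

    def test_equal_means_zero(self):
        assert hedges_g([1, 2, 3], [3, 2, 1]) == 0.0

    def test_scale_invariance(self):
        x, y = [3.0, 5.0, 8.0], [1.0, 2.0, 2.5]
        assert hedges_g([7 * v for v in x], [7 * v for v in y]) == \
            pytest.approx(hedges_g(x, y))

    def test_zero_pooled_sd_is_nan(self):
        assert np.isnan(hedges_g([2, 2], [1, 1]))


class TestKS:
    def test_shifted_triples(self):
        d, _ = ks_statistic([1, 2, 3], [2, 3, 4])
        assert d == pytest.approx(1 / 3)

    def test_identical_samples_zero(self):
        d, _ = ks_statistic([1, 5, 9], [1, 5, 9])
        assert d == 0.0

    def test_separated_supports_one(self):
        d, p = ks_statistic([1, 2, 3], [10, 11, 12])
        assert d == 1.0
        assert p < 0.2


class TestAnova:
    def _balanced(self):
        # 2x2 full factorial, 3 replicates per cell
        rows = []
        effects = {("a1", "b1"): 1.0, ("a1", "b2"): 2.0,
                   ("a2", "b1"): 3.0, ("a2", "b2"): 6.0}
        for (a, b), mu in effects.items():
            for r in (-0.1, 0.0, 0.1):
                rows.append({"A": a, "B": b, "y": mu + r})
        return pd.DataFrame(rows)

    def test_balanced_two_by_two_matches_hand_decomposition(self):
        df = self._balanced()
        out = anova_eta_squared(df["y"], df[["A", "B"]], order=2)
        # hand SS: grand mean 3; A means 1.5/4.5 -> SS_A = 12*(1.5^2)/2... per level:
        # SS_A = 6*(1.5-3)^2 + 6*(4.5-3)^2 = 27; SS_B = 6*(2-3)^2+6*(4-3)^2 = 12
        assert out.loc["C(A)", "sum_sq"] == pytest.approx(27.0)
        assert out.loc["C(B)", "sum_sq"] == pytest.approx(12.0)
        assert out.loc["C(A):C(B)", "sum_sq"] == pytest.approx(3.0)
        assert out.loc["Residual", "sum_sq"] == pytest.approx(0.08)

    def test_eta_squared_sums_to_one_with_residual(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"A": rng.choice(["x", "y", "z"], 60),
                           "B": rng.choice(["u", "v"], 60)})
        y = rng.normal(size=60)
        out = anova_eta_squared(y, df, order=2)
        assert out["eta_sq"].sum() == pytest.approx(1.0)

    def test_pure_factor_response_explains_everything(self):
        df = pd.DataFrame({"A": ["x"] * 5 + ["y"] * 5})
        y = [1.0] * 5 + [4.0] * 5
        assert variance_explained(y, df["A"]) == pytest.approx(1.0)

    def test_null_response_eta_near_df_over_n(self):
        rng = np.random.default_rng(2)
        n = 6000
        f = rng.choice(list("abcde"), n)
        y = rng.normal(size=n)
        ve = variance_explained(y, f)
        assert ve == pytest.approx(4 / (n - 1), abs=4 * np.sqrt(2 * 4) / n)

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError):
            variance_explained([1.0, 2.0], ["a", "a"])


class TestCrosstalk:
    def _reads(self, combos, qs):
        i7 = [(f"r{i}", c[0], [q] * 8) for i, (c, q) in enumerate(zip(combos, qs))]
        i5 = [(f"r{i}", c[1], [q] * 8) for i, (c, q) in enumerate(zip(combos, qs))]
        return i7, i5

    def test_all_expected_rate_zero_tests_skipped(self):
        combos = [("AAAAAAAA", "CCCCCCCC")] * 10
        i7, i5 = self._reads(combos, [35] * 10)
        rep = crosstalk_analysis(i7, i5, {("AAAAAAAA", "CCCCCCCC")})
        assert rep.rate == 0.0
        assert np.isnan(rep.per_index["welch_t"]).all()

    def test_five_in_two_thousand(self):
        expected = ("AAAAAAAA", "CCCCCCCC")
        combos = [expected] * 1995 + [("GGGGGGGG", "TTTTTTTT")] * 5
        i7, i5 = self._reads(combos, [35] * 2000)
        rep = crosstalk_analysis(i7, i5, {expected})
        assert rep.rate == pytest.approx(0.0025)
        assert rep.n_unexpected == 5

    def test_q_penalty_recovered_with_positive_effect_size(self):
        rng = np.random.default_rng(3)
        expected = ("AAAAAAAA", "CCCCCCCC")
        combos = [expected] * 400 + [("GGGGGGGG", "TTTTTTTT")] * 100
        qs = np.concatenate([np.clip(rng.normal(35, 1, 400), 2, 41),
                             np.clip(rng.normal(30, 1, 100), 2, 41)])
        i7 = [(f"r{i}", c[0], [float(q)] * 8) for i, (c, q) in enumerate(zip(combos, qs))]
        i5 = [(f"r{i}", c[1], [float(q)] * 8) for i, (c, q) in enumerate(zip(combos, qs))]
        rep = crosstalk_analysis(i7, i5, {expected})
        row = rep.per_index.set_index("index_read").loc["i7"]
        assert row["hedges_g"] > 2
        assert row["mean_q_expected"] - row["mean_q_unexpected"] == pytest.approx(5.0, abs=0.5)
        assert row["p_value"] < 1e-6

    def test_unaligned_ids_error(self):
        i7 = [("a", "AAAAAAAA", [35] * 8)]
        i5 = [("b", "CCCCCCCC", [35] * 8)]
        with pytest.raises(ValueError):
            crosstalk_analysis(i7, i5, {("AAAAAAAA", "CCCCCCCC")})


def test_accuracy_coverage_scatter_writes_figure(tmp_path):
    from ampbench.metrics import plot_accuracy_coverage

    rep = pd.DataFrame({"accuracy": [0.9, 1.0, 0.7], "coverage": [0.5, 0.52, 0.75]})
    out = tmp_path / "tradeoff.png"
    plot_accuracy_coverage(rep, out)
    assert out.stat().st_size > 0
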