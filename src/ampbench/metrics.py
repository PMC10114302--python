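"""Workflow-level metrics and statistical summaries.

accuracy
    fraction of denoised reads belonging to exact-match variants:
    ``reads in exact variants / total denoised reads``.
coverage
    fraction of the community's expected unique region variants recovered:
    ``distinct expected variants hit by an exact workflow variant / expected
    variant count``.  Two workflow variants hitting the same mock variant
    count once.
compositional bias
    Spearman's rank correlation between input (qPCR-style) member
    abundances and the output relative abundance of exact matches.
chimera fraction
    fraction of reads in chimera-category variants.
cross-talk
    fraction of reads whose (i7, i5) index combination is not assigned to
    any sample, plus Welch t and Hedges g comparing index read Q between
    expected and unexpected combinations.

Statistical helpers: Hedges g (pooled, weighted SD; no small-sample
correction), the two-sample KS statistic, and sequential (type-I) ANOVA
with per-term eta squared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "accuracy",
    "coverage",
    "compositional_bias",
    "chimera_fraction",
    "abundance_out",
    "CrosstalkReport",
    "crosstalk_analysis",
    "hedges_g",
    "ks_statistic",
    "anova_eta_squared",
    "variance_explained",
    "plot_accuracy_coverage",
]

_COUNT_EXCLUDE = {"variant_id", "sequence", "category", "evidence"}


def _count_columns(counts: pd.DataFrame) -> list[str]:
    return [c for c in counts.columns if c not in _COUNT_EXCLUDE]


def _merged(triage: pd.DataFrame, counts: pd.DataFrame) -> pd.DataFrame:
    if set(triage["variant_id"]) != set(counts["variant_id"]):
        raise ValueError("triage and count tables disagree on variant ids")
    return counts.merge(triage[["variant_id", "category"]], on="variant_id")


def _category_read_fraction(triage: pd.DataFrame, counts: pd.DataFrame,
                            category: str) -> float:
    df = _merged(triage, counts)
    cols = _count_columns(counts)
    total = int(df[cols].to_numpy().sum())
    if total == 0:
        return float("nan")
    hit = int(df.loc[df["category"] == category, cols].to_numpy().sum())
    return hit / total


def accuracy(triage: pd.DataFrame, counts: pd.DataFrame) -> float:
    """Fraction of reads that exactly match mock sequence variants.

    NaN when the table holds no reads at all (undefined, not zero).
    """
    return _category_read_fraction(triage, counts, "exact")


def chimera_fraction(triage: pd.DataFrame, counts: pd.DataFrame) -> float:
    """Fraction of reads in putatively chimeric variants."""
    return _category_read_fraction(triage, counts, "chimera")


def coverage(triage: pd.DataFrame, expected, counts: pd.DataFrame | None = None,
             sequences: dict[str, str] | None = None) -> float:
    """Fraction of expected unique mock variants recovered as exact matches.

    ``expected`` is the output of the expected-variants computation:
    ``(count, [(variant_sequence, member_ids), ...])``.  A mock variant is
    recovered when at least one exact-category workflow variant contains it
    or is contained by it; duplicate hits count once.  ``sequences`` maps
    variant_id to sequence when the triage table lacks a sequence column.
    """
    expected_count, expected_variants = expected
    if expected_count < 1:
        raise ValueError("expected variant count must be >= 1")
    if sequences is None:
        if counts is None or "sequence" not in counts.columns:
            raise ValueError("need variant sequences to match against expected variants")
        sequences = dict(zip(counts["variant_id"], counts["sequence"]))
    exact_ids = triage.loc[triage["category"] == "exact", "variant_id"]
    hit = set()
    for vid in exact_ids:
        seq = sequences[vid]
        for i, (mock_seq, _) in enumerate(expected_variants):
            if mock_seq in seq or seq in mock_seq:
                hit.add(i)
    return len(hit) / expected_count


def abundance_out(triage: pd.DataFrame, counts: pd.DataFrame,
                  refs) -> dict[str, float]:
    """Relative abundance of each mock member among exact-match reads.

    A member's read count is the total over exact variants matching it;
    variants matching several identical-region members contribute their full
    count to each (region-level ambiguity is inherent).  Fractions are
    normalized by total exact reads.  Empty when there are no exact reads.
    """
    from .merge import exact_match

    df = _merged(triage, counts)
    cols = _count_columns(counts)
    member_reads: dict[str, float] = {}
    total = 0
    for _, row in df[df["category"] == "exact"].iterrows():
        n = int(row[cols].sum())
        total += n
        _, hits = exact_match(row["sequence"], refs)
        for rid in hits:
            member_reads[rid] = member_reads.get(rid, 0) + n
    if total == 0:
        return {}
    return {rid: c / total for rid, c in member_reads.items()}


def compositional_bias(abundance_in: dict[str, float],
                       abundance_out: dict[str, float]) -> float:
    """Spearman's rho between input and output member abundances.

    Members absent from the output get abundance 0.  Workflows without any
    exact matches should be omitted upstream (an empty output dict yields
    NaN).  Ties receive mean ranks; an all-constant vector yields NaN.
    """
    if not abundance_out:
        return float("nan")
    members = sorted(abundance_in)
    if len(members) < 3:
        raise ValueError("need >= 3 members for a rank correlation")
    x = np.array([abundance_in[m] for m in members])
    y = np.array([abundance_out.get(m, 0.0) for m in members])
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def hedges_g(x, y) -> float:
    """Standardized mean difference with pooled, weighted SD.

    g = (mean_x - mean_y) / sqrt(((n_x-1) s_x^2 + (n_y-1) s_y^2)
    / (n_x + n_y - 2)); no small-sample correction.  NaN when the pooled SD
    is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        return float("nan")
    return float((x.mean() - y.mean()) / math.sqrt(sp2))


def ks_statistic(x, y) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov statistic D and p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be nonempty")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class CrosstalkReport:
    """Index cross-talk audit of one sequencing run."""

    n_reads: int
    n_unexpected: int
    rate: float
    per_index: pd.DataFrame  # rows i7/i5: mean Q expected/unexpected, Welch t, df, p, g


def crosstalk_analysis(index_reads_i7, index_reads_i5,
                       expected_combinations: set[tuple[str, str]]) -> CrosstalkReport:
    """Classify every read's (i7, i5) combination and compare index quality.

    Reads are expected iff their exact index pair is in the plan.  The rate
    is unexpected/total.  Per index read, per-read mean Q of expected vs
    unexpected groups is compared with a Welch two-sample t-test and
    Hedges g (tests are skipped when either group has < 2 reads).
    """
    if not expected_combinations:
        raise ValueError("expected combination set is empty")
    if [r[0] for r in index_reads_i7] != [r[0] for r in index_reads_i5]:
        raise ValueError("i7 and i5 reads are not id-aligned")
    combos = [(a[1], b[1]) for a, b in zip(index_reads_i7, index_reads_i5)]
    unexpected = np.array([c not in expected_combinations for c in combos])
    n = len(combos)
    rows = []
    for name, reads in (("i7", index_reads_i7), ("i5", index_reads_i5)):
        mq = np.array([np.mean(q) for _, _, q in reads])
        exp_q, une_q = mq[~unexpected], mq[unexpected]
        row = {"index_read": name,
               "mean_q_expected": float(exp_q.mean()) if exp_q.size else float("nan"),
               "mean_q_unexpected": float(une_q.mean()) if une_q.size else float("nan"),
               "welch_t": float("nan"), "welch_df": float("nan"),
               "p_value": float("nan"), "hedges_g": float("nan")}
        if exp_q.size >= 2 and une_q.size >= 2:
            res = stats.ttest_ind(exp_q, une_q, equal_var=False)
            row.update(welch_t=float(res.statistic), welch_df=float(res.df),
                       p_value=float(res.pvalue), hedges_g=hedges_g(exp_q, une_q))
        rows.append(row)
    return CrosstalkReport(n, int(unexpected.sum()), float(unexpected.mean()),
                           pd.DataFrame(rows))


def anova_eta_squared(response, factors: pd.DataFrame, order: int = 2) -> pd.DataFrame:
    """Sequential (type-I) ANOVA with per-term eta squared.

    Fits an OLS model with all main effects and, for ``order=2``, all
    two-way interactions, in the column order of ``factors``.  Returns the
    term table (sum_sq, df, F, p, eta_sq) including the residual row.
    eta_sq = SS_term / SS_total.  Sequential SS is the natural match for a
    near-balanced full-factorial design; the factor order is the column
    order and is recorded in the output.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = factors.copy()
    names = list(df.columns)
    for c in names:
        if df[c].nunique() < 2:
            raise ValueError(f"factor {c!r} has fewer than 2 levels")
    df["_y"] = np.asarray(response, dtype=float)
    terms = [f"C({c})" for c in names]
    if order >= 2:
        terms += [f"C({a}):C({b})" for a, b in combinations(names, 2)]
    formula = "_y ~ " + " + ".join(terms)
    model = smf.ols(formula, data=df).fit()
    if model.df_resid <= 0:
        raise ValueError("design is saturated: n <= model df")
    try:
        table = sm.stats.anova_lm(model, typ=1)
    except Exception as err:  # singular design
        raise ValueError(f"singular design: {err}") from err
    ss_total = table["sum_sq"].sum()
    table = table.rename(columns={"PR(>F)": "p"})
    table["eta_sq"] = table["sum_sq"] / ss_total
    return table


def variance_explained(response, factor) -> float:
    """Proportion of variation explained by one factor: SS_factor / SS_total."""
    df = pd.DataFrame({"f": pd.Categorical(factor)})
    table = anova_eta_squared(response, df.rename(columns={"f": "factor"}), order=1)
    return float(table.loc["C(factor)", "eta_sq"])


def plot_accuracy_coverage(report: pd.DataFrame, path=None):
    """Minimal accuracy-vs-coverage scatter, the trade-off view."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(report["coverage"], report["accuracy"], s=18, alpha=0.8)
    ax.set_xlabel("coverage")
    ax.set_ylabel("accuracy")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
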