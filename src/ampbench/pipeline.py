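"""End-to-end evaluation: cross-talk audit -> demultiplex -> rarefy -> QC ->
merge/trim/cluster -> triage -> per-workflow metrics.

The unit of evaluation is a sample (one workflow realization).  The stage
order follows the benchmark's logic: index cross-talk is audited over all
reads first; reads whose index combination is not assigned to any sample
are excluded; each sample is rarefied to a fixed depth by sub-sampling with
replacement; reads are QC-profiled, merged, quality-trimmed, clustered at
100% identity; and the resulting variant table is triaged and scored.
An externally produced variant table (any denoiser's TSV + FASTA export)
can be injected instead of the merge stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as aio
from . import metrics as M
from .merge import cluster_identical, merge_pair
from .quality import ReadRecord, rarefaction_curve, sample_read_stats, subsample_reads, trim_read
from .refs import PrimerSet, ReferenceSet, expected_variants, in_silico_pcr
from .triage import TriageParams, triage

log = logging.getLogger("ampbench")

__all__ = ["PipelineParams", "EvaluationResult", "evaluate_run", "evaluate_variant_table"]


@dataclass
class PipelineParams:
    """Tunables of the evaluation pipeline (the benchmark's printed constants)."""

    subsample_depth: int = 1000
    subsample_with_replacement: bool = True
    min_merge_overlap: int = 50
    max_overlap_mismatch_frac: float = 0.1
    trim_error_cutoff: float = 0.01
    min_amplicon_length: int = 200
    triage: TriageParams = field(default_factory=TriageParams)
    compute_read_stats: bool = True
    rarefaction_depths: tuple[int, ...] = ()
    seed: int = 0


@dataclass
class EvaluationResult:
    crosstalk: M.CrosstalkReport | None
    read_stats: pd.DataFrame | None
    variant_table: pd.DataFrame
    triage_table: pd.DataFrame
    report: pd.DataFrame  # one row per sample: metrics + any factor metadata
    rarefaction: pd.DataFrame | None

    def write(self, outdir) -> None:
        outdir = aio.ensure_dir(outdir)
        aio.write_variant_table(self.variant_table, outdir / "variants.tsv",
                                outdir / "variants.fasta")
        self.triage_table.to_csv(outdir / "triage.tsv", sep="\t", index=False)
        self.report.to_csv(outdir / "workflow_report.tsv", sep="\t", index=False)
        if self.crosstalk is not None:
            self.crosstalk.per_index.assign(
                rate=self.crosstalk.rate, n_reads=self.crosstalk.n_reads,
                n_unexpected=self.crosstalk.n_unexpected,
            ).to_csv(outdir / "crosstalk.tsv", sep="\t", index=False)
        if self.read_stats is not None:
            self.read_stats.to_csv(outdir / "read_stats.tsv", sep="\t", index=False)
        if self.rarefaction is not None:
            self.rarefaction.to_csv(outdir / "rarefaction.tsv", sep="\t", index=False)


def _demultiplex(r1, r2, i7, i5, plan: dict[str, tuple[str, str]]):
    """Assign read pairs to samples by exact index-combination match."""
    by_combo = {v: k for k, v in plan.items()}
    idx7 = {rid: seq for rid, seq, _ in i7}
    idx5 = {rid: seq for rid, seq, _ in i5}
    pairs: dict[str, list[tuple[ReadRecord, ReadRecord]]] = {s: [] for s in plan}
    for (rid1, b1, q1), (rid2, b2, q2) in zip(r1, r2):
        if rid1 != rid2:
            raise ValueError("R1/R2 are not id-aligned")
        sample = by_combo.get((idx7.get(rid1), idx5.get(rid1)))
        if sample is not None:
            pairs[sample].append((ReadRecord(rid1, b1, q1), ReadRecord(rid2, b2, q2)))
    return pairs


def _merge_sample(pairs, params: PipelineParams):
    merged = []
    for k, (a, b) in enumerate(pairs):
        amp = merge_pair(a, b, params.min_merge_overlap, params.max_overlap_mismatch_frac)
        if amp is None:
            continue
        trimmed = trim_read(ReadRecord(f"{a.id}#{k}", amp.bases, [min(q, 60) for q in amp.quals]),
                            params.trim_error_cutoff, params.min_amplicon_length)
        if trimmed is None:
            continue
        amp.id, amp.bases, amp.quals = trimmed.id, trimmed.bases, trimmed.quals
        merged.append(amp)
    return merged


def evaluate_run(
    refs: ReferenceSet,
    primers: PrimerSet,
    r1, r2,
    i7=None, i5=None,
    index_plan: dict[str, tuple[str, str]] | None = None,
    metadata: pd.DataFrame | None = None,
    params: PipelineParams | None = None,
) -> EvaluationResult:
    """Evaluate a sequencing run (simulated or real) against the mock community.

    ``r1``/``r2`` are lists of (id, bases, quals); ``i7``/``i5`` optional
    index reads.  Without index reads the cross-talk stage is skipped with a
    warning and all reads belong to the single sample of ``index_plan`` (or
    "sample1").  ``metadata`` (indexed by sample) is carried into the report.
    """
    params = params or PipelineParams()
    rng = np.random.default_rng(params.seed)

    crosstalk = None
    if i7 is not None and i5 is not None and index_plan:
        crosstalk = M.crosstalk_analysis(i7, i5, set(index_plan.values()))
        pairs_by_sample = _demultiplex(r1, r2, i7, i5, index_plan)
    else:
        log.warning("index reads missing: cross-talk stage skipped")
        name = next(iter(index_plan)) if index_plan else "sample1"
        pairs_by_sample = {name: [(ReadRecord(*a), ReadRecord(*b)) for a, b in zip(r1, r2)]}

    amp = in_silico_pcr(refs, primers)
    expected = expected_variants(amp)

    stats_rows, merged_all, sample_of = [], [], {}
    for sample, pairs in sorted(pairs_by_sample.items()):
        if not pairs:
            log.warning("sample %s: no reads after demultiplexing", sample)
            continue
        depth = min(params.subsample_depth, len(pairs)) \
            if not params.subsample_with_replacement else params.subsample_depth
        pairs = subsample_reads(pairs, depth, params.subsample_with_replacement, rng)
        if params.compute_read_stats:
            st = sample_read_stats([a for a, _ in pairs], refs,
                                   params.trim_error_cutoff, params.min_amplicon_length)
            stats_rows.append({"sample": sample, **st})
        merged = _merge_sample(pairs, params)
        for m in merged:
            sample_of[m.id] = sample
        merged_all.extend(merged)

    if not merged_all:
        raise ValueError("no read pair merged successfully in any sample")
    table = cluster_identical(merged_all, sample_of)
    return _score(table, refs, primers, expected, params,
                  crosstalk=crosstalk,
                  read_stats=pd.DataFrame(stats_rows) if stats_rows else None,
                  metadata=metadata)


def evaluate_variant_table(
    table: pd.DataFrame,
    refs: ReferenceSet,
    primers: PrimerSet,
    metadata: pd.DataFrame | None = None,
    params: PipelineParams | None = None,
) -> EvaluationResult:
    """Triage + metrics for an externally denoised variant table.

    The ingestion path: any upstream program's variant counts TSV plus
    representative sequences can be scored without raw reads.
    """
    params = params or PipelineParams()
    expected = expected_variants(in_silico_pcr(refs, primers))
    return _score(table, refs, primers, expected, params, metadata=metadata)


def _score(table, refs, primers, expected, params,
           crosstalk=None, read_stats=None, metadata=None) -> EvaluationResult:
    tri = triage(table, refs, primers, params.triage)
    samples = [c for c in table.columns if c not in ("variant_id", "sequence")]
    abundance_in = refs.abundances
    rows = []
    for s in samples:
        sub = table[["variant_id", "sequence", s]].rename(columns={s: "count"})
        sub = sub[sub["count"] > 0]
        tri_s = tri[tri["variant_id"].isin(sub["variant_id"])]
        acc = M.accuracy(tri_s, sub)
        cov = M.coverage(tri_s, expected, counts=sub)
        chi = M.chimera_fraction(tri_s, sub)
        ab_out = M.abundance_out(tri_s, sub, refs)
        rho = M.compositional_bias(abundance_in, ab_out) if ab_out else float("nan")
        rows.append({"sample": s, "n_reads_denoised": int(sub["count"].sum()),
                     "accuracy": acc, "coverage": cov, "chimera_fraction": chi,
                     "spearman_rho": rho})
    report = pd.DataFrame(rows)
    if metadata is not None:
        report = report.merge(metadata, on="sample", how="left")

    rarefaction = None
    depths = params.rarefaction_depths
    if depths:
        rare_rows = []
        exact_ids = set(tri.loc[tri["category"] == "exact", "variant_id"])
        for s in samples:
            counts = table.loc[table["variant_id"].isin(exact_ids), s]
            counts = counts[counts > 0].to_numpy()
            if counts.size == 0:
                continue
            rc = rarefaction_curve(counts, [d for d in depths if d >= 1])
            rc.insert(0, "sample", s)
            rare_rows.append(rc)
        if rare_rows:
            rarefaction = pd.concat(rare_rows, ignore_index=True)

    return EvaluationResult(crosstalk, read_stats, table, tri, report, rarefaction)
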