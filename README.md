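# ampbench

Benchmarking toolkit for 16S rRNA amplicon sequencing workflows evaluated
against a **mock bacterial community** — a defined pool of isolates with
known sequences and approximate (qPCR-style) input abundances. It is aimed
at groups who validate or compare library-preparation and bioinformatic
choices (primer set, polymerase, PCR indexing scheme, elongation time,
denoiser) and want every number traceable to ground truth.

## What it computes

For a sequencing run (real or simulated) and a reference community, the
pipeline audits **index cross-talk** over all i7 × i5 combinations, rarefies
each sample by sub-sampling with replacement, characterizes raw reads
(infix edit distance to the nearest mock member, mean Q, quality-trimmed
length), merges R1/R2 at the best ungapped overlap (minimum 50 nt), trims
amplicons to their high-quality region (minimum 200 nt), clusters at 100 %
identity, and assigns every resulting sequence variant to exactly one of
six categories by a fixed cascade:

```
exact  →  primer_dimer  →  chimera  →  off_target  →  { mismatch | contaminant }
```

* **exact** — edit distance 0 to a mock sequence excluding length
  differences (substring containment either way);
* **primer_dimer** — contains an IUPAC-aware match to a primer or its
  reverse complement;
* **chimera** — a reference-based bimera test: with per-reference prefix
  and suffix infix-distance profiles `pre_A(k)`, `suf_B(k)` computed by
  semi-global dynamic programming, the variant is chimeric when

  `min_{A≠B,k} [pre_A(k) + suf_B(k)] ≤ ⌈0.01·L⌉` and the single-parent
  distance exceeds that minimum by a margin (default 4 edits);
* **off_target** — best infix identity to any reference below 0.6, or a
  homopolymer run covering ≥ half the variant;
* **mismatch** vs **contaminant** — remaining variants are UPGMA-clustered
  with the reference region sequences at a 15 % distance cutoff; variants
  sharing a clade with a reference are mismatches, the rest contaminants.

Per-workflow metrics follow the standard mock-community definitions:
**accuracy** = exact-match reads / denoised reads, **coverage** = distinct
expected region variants recovered / expected variant count, plus the
chimeric read fraction, Spearman's ρ between input and output member
abundances (compositional bias), and the cross-talk rate with Welch-*t* /
Hedges-*g* comparisons of index-read quality. Statistical helpers include
analytic rarefaction, the two-sample KS statistic, and sequential (type-I)
ANOVA with per-term η².

A fully labeled **synthetic-data generator** makes every stage verifiable
without sequencing data: it emits R1/R2/I1/I2 FASTQ plus a per-read truth
table, with templates drawn from community amplicons by abundance,
two-parent chimeras whose rate decays exponentially with a PCR
elongation-time knob, contaminant / primer-dimer / low-complexity
templates, positionally decaying Q profiles (R2 worse than R1),
substitution errors at 10^(−Q/10), and index cross-talk with lowered index
Q-scores.

## Worked example

```python
from ampbench import STANDARD_PRIMERS
from ampbench.simulate import (SimConfig, default_index_plan, simulate_run,
                               synthetic_reference_set)
from ampbench.pipeline import PipelineParams, evaluate_run

refs = synthetic_reference_set(seed=7)          # 37 members, 23 V4 variants
cfg = SimConfig(refs=refs, primers=STANDARD_PRIMERS["V4-V4"],
                index_plan=default_index_plan(2, 7), n_reads_per_sample=2000,
                elongation_s=30, contaminant_rate=0.01, crosstalk_rate=0.003,
                seed=7)
print("chimera rate at 30 s elongation:", round(cfg.chimera_rate, 4))
run = simulate_run(cfg)
res = evaluate_run(refs, cfg.primers, run.r1, run.r2, run.i7, run.i5,
                   cfg.index_plan,
                   params=PipelineParams(subsample_depth=1000, seed=1,
                                         compute_read_stats=False))
print("cross-talk rate:", round(res.crosstalk.rate, 4))
print(res.report.round(3).to_string(index=False))
```

prints

```
chimera rate at 30 s elongation: 0.0376
cross-talk rate: 0.0035
sample  n_reads_denoised  accuracy  coverage  chimera_fraction  spearman_rho
   S01               966     0.910       1.0             0.037         0.393
   S02               968     0.926       1.0             0.028         0.354
```

Reading: a 30 s elongation maps to a 3.8 % injected chimera rate; the
audit recovers a 0.35 % cross-talk rate (30 s-run injection was 0.3 %);
after rarefying to 1000 reads, ~91 % of denoised reads match the mock
exactly (substitution errors push the rest into `mismatch`/`chimera`),
every one of the 23 expected V4 variants is recovered, and the detected
chimeric fraction tracks the injected rate. The moderate ρ reflects
region-level ambiguity, not workflow bias: members sharing an identical V4
variant are indistinguishable in the output, so their ranks collapse. The same `evaluate` stage
accepts any external denoiser's variant table (TSV + representative FASTA)
in place of the built-in merge/cluster step.

The same pipeline is available from a shell:

```bash
ampbench simulate --out run/ --samples 2 --reads-per-sample 2000 --seed 7 \
    --elongation-s 30 --crosstalk-rate 0.003
ampbench evaluate --run-dir run/ --out results/ --depth 1000
```

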