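"""Fully labeled synthetic amplicon sequencing runs.

Generates paired reads (R1/R2), index reads (i7/i5) and a per-read ground
truth table for a mock community, so that every downstream stage — read QC,
merging, clustering, the six-way triage cascade, and the cross-talk audit —
can be verified against known labels without real sequencing data.

The generator emulates the statistical structure the analysis assumes:

* templates drawn from community amplicons proportional to input abundance;
* two-parent chimeric templates at a configurable rate, with an
  elongation-time knob under which the rate decays exponentially (the
  documented convention for the empirical trend that longer PCR elongation
  yields fewer chimeras);
* contaminant, primer-dimer, and low-complexity off-target templates;
* Illumina-like positionally decaying Q profiles with R2 worse than R1, and
  substitution errors at per-base probability 10**(-Q/10);
* index cross-talk, where a small fraction of reads is emitted under an
  i7 x i5 combination not assigned to any sample and those index reads carry
  lower Q-scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .refs import IUPAC, AmpliconSet, PrimerSet, ReferenceSet, in_silico_pcr, revcomp

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SyntheticRun",
    "q_profile",
    "chimera_rate_for_elongation",
    "concrete_primer",
    "synthetic_reference_set",
    "simulate_templates",
    "simulate_reads",
    "simulate_indices",
    "simulate_run",
]

_BASES = np.array(list("ACGT"))

CATEGORIES = ("exact", "mismatch_error", "chimera", "contaminant", "primer_dimer", "off_target")


def q_profile(read_length: int, q_start: float, q_end: float) -> np.ndarray:
    """Linearly decaying per-position mean Q, the usual Illumina shape."""
    return np.linspace(q_start, q_end, read_length)


def chimera_rate_for_elongation(elongation_s: float, rate_at_15s: float = 0.04,
                                decay: float = math.log(2) / 165.0) -> float:
    """Map PCR elongation time (seconds) to a chimera rate.

    The rate decays exponentially with elongation time, ``rate_at_15s *
    exp(-decay * (t - 15))``.  The default calibration halves the rate
    between 15 s and 180 s (0.04 -> 0.02), matching the observed span of
    mean chimeric fractions over that elongation range; the exponential form
    itself is this simulator's convention, chosen for monotonicity.
    """
    if elongation_s <= 0:
        raise ValueError("elongation time must be positive")
    return rate_at_15s * math.exp(-decay * (elongation_s - 15.0))


def concrete_primer(primer: str, rng: np.random.Generator) -> str:
    """One concrete expansion of a degenerate IUPAC primer."""
    return "".join(sorted(IUPAC[c])[rng.integers(len(IUPAC[c]))] for c in primer)


@dataclass
class TruthRecord:
    """Ground-truth label of one simulated read pair."""

    read_id: str
    sample: str
    category: str  # one of CATEGORIES
    parent_ids: tuple[str, ...]  # 1 reference id, or 2 for a chimera
    breakpoint: int | None  # 0-based template position, chimeras only
    true_indices: tuple[str, str]  # (i7, i5) of the read's sample
    emitted_indices: tuple[str, str] | None = None  # set by simulate_indices

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "chimera":
            if len(self.parent_ids) != 2 or self.breakpoint is None:
                raise ValueError("chimera requires two parents and a breakpoint")
        elif self.breakpoint is not None:
            raise ValueError("breakpoint is only meaningful for chimeras")


@dataclass
class SimConfig:
    """All knobs of a synthetic run.

    Rates are fractions of reads; artifact rates (chimera, contaminant,
    primer-dimer, off-target) must sum below 1, the remainder being clean
    community reads.  ``elongation_s``, when set, overrides ``chimera_rate``
    via :func:`chimera_rate_for_elongation`.  ``errors_enabled=False`` turns
    base miscalls off entirely (Q profiles still apply), giving noise-free
    runs for closed-loop checks.
    """

    refs: ReferenceSet
    primers: PrimerSet
    index_plan: dict[str, tuple[str, str]]
    n_reads_per_sample: int = 1000
    read_length: int = 250
    q_start_r1: float = 38.0
    q_end_r1: float = 31.0
    q_start_r2: float = 37.0
    q_end_r2: float = 24.0
    q_sd: float = 2.0
    errors_enabled: bool = True
    chimera_rate: float = 0.0
    elongation_s: float | None = None
    breakpoint_margin: int = 20
    contaminant_rate: float = 0.0
    contaminant_pool: list[str] | None = None
    contaminant_divergence: float = 0.25
    primer_dimer_rate: float = 0.0
    offtarget_rate: float = 0.0
    crosstalk_rate: float = 0.0
    crosstalk_q_penalty: float = 5.0
    index_q_mean: float = 35.0
    index_q_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.elongation_s is not None:
            self.chimera_rate = chimera_rate_for_elongation(self.elongation_s)
        rates = [self.chimera_rate, self.contaminant_rate,
                 self.primer_dimer_rate, self.offtarget_rate, self.crosstalk_rate]
        if any(r < 0 or r > 1 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if sum(rates[:4]) > 1:
            raise ValueError("artifact rates must not sum above 1")
        if self.read_length < 50:
            raise ValueError("read_length must be >= 50")
        if self.n_reads_per_sample < 1:
            raise ValueError("n_reads_per_sample must be >= 1")
        if not self.index_plan:
            raise ValueError("index_plan must name at least one sample")
        for s, (i7, i5) in self.index_plan.items():
            if len(i7) != 8 or len(i5) != 8:
                raise ValueError(f"sample {s!r}: indices must be 8 nt")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute a ``divergence`` fraction of positions (always to another base)."""
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    k = int(round(divergence * len(seq)))
    pos = rng.choice(len(seq), size=k, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(3)]
    return "".join(arr)


def default_index_plan(n_samples: int, rng: np.random.Generator | int = 0) -> dict[str, tuple[str, str]]:
    """Distinct 8-nt i7/i5 indices per sample (no index shared between samples)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    plan = {}
    seen: set[str] = set()
    for i in range(n_samples):
        while True:
            i7, i5 = _random_dna(rng, 8), _random_dna(rng, 8)
            if i7 not in seen and i5 not in seen and i7 != i5:
                seen.update((i7, i5))
                break
        plan[f"S{i + 1:02d}"] = (i7, i5)
    return plan


def synthetic_reference_set(
    n_members: int = 37,
    n_variants: int = 23,
    region_length: int = 230,
    flank: int = 250,
    divergence: float | None = None,
    primers: PrimerSet | None = None,
    abundance_sigma: float = 0.8,
    seed: int = 0,
) -> ReferenceSet:
    """Build a mock community with a known expected-variant structure.

    Each member is ``flank + forward site + insert + reverse site + flank``
    with member-specific random flanks, so every member amplifies with the
    given primer pair.  Members are partitioned over ``n_variants`` insert
    groups; members in a group share an identical insert, so the expected
    unique variant count for the region is exactly ``n_variants`` (37
    members collapsing to 23 variants mirrors a real soil-isolate pool in
    the V4 region).

    ``divergence=None`` draws each variant insert independently at random
    (pairwise distance around 75%, a "well separated" community for
    detector-identifiability studies); a float instead mutates a common
    ancestral insert by that per-variant fraction, giving pairwise
    divergences near twice the value, which is closer to real 16S variable
    regions.

    Input abundances are uneven: lognormal(0, ``abundance_sigma``) draws,
    normalized — emulating qPCR-derived 16S copy fractions.
    """
    if n_variants > n_members:
        raise ValueError("cannot have more variants than members")
    rng = np.random.default_rng(seed)
    primers = primers or PrimerSet("V4-V4", "GTGYCAGCMGCCGCGGTAA", "GGACTACNVGGGTWTCTAAT", 254)
    fwd_site = concrete_primer(primers.forward, rng)
    rev_site = revcomp(concrete_primer(primers.reverse, rng))
    if divergence is None:
        inserts = [_random_dna(rng, region_length) for _ in range(n_variants)]
    else:
        ancestor = _random_dna(rng, region_length)
        inserts = [_mutate(ancestor, divergence, rng) for _ in range(n_variants)]
    if len(set(inserts)) != n_variants:
        raise ValueError("insert collision; increase region_length or divergence")
    # partition members over variant groups as evenly as possible
    group_of = np.sort(np.concatenate([np.arange(n_variants),
                                       rng.integers(0, n_variants, n_members - n_variants)]))
    abund = rng.lognormal(0.0, abundance_sigma, n_members)
    abund /= abund.sum()
    members = []
    for i in range(n_members):
        seq = (_random_dna(rng, flank) + fwd_site + inserts[group_of[i]]
               + rev_site + _random_dna(rng, flank))
        members.append((f"MOCK{i + 1:03d}", seq, float(abund[i])))
    # renormalize exactly (float noise)
    total = sum(m[2] for m in members)
    members = [(r, s, a / total) for r, s, a in members]
    return ReferenceSet(members)


def _contaminant_pool(amplicons: AmpliconSet, divergence: float,
                      rng: np.random.Generator, n: int = 5) -> list[str]:
    """16S-like contaminants: community amplicons mutated beyond the clade cutoff.

    Divergence well above 15% keeps them out of reference clades while their
    identity to references stays high enough not to look like off-target
    amplification.
    """
    seqs = list(amplicons.amplicons.values())
    return [_mutate(seqs[rng.integers(len(seqs))], divergence, rng) for _ in range(n)]


def _offtarget_template(rng: np.random.Generator) -> str:
    """Low-complexity artifact with a dominant homopolymeric tract."""
    n = int(rng.integers(120, 200))
    run = int(math.ceil(0.6 * n))
    base = "ACGT"[rng.integers(4)]
    rest = n - run
    left = int(rng.integers(0, rest + 1))
    return _random_dna(rng, left) + base * run + _random_dna(rng, rest - left)


def simulate_templates(config: SimConfig, rng: np.random.Generator
                       ) -> list[tuple[str, TruthRecord]]:
    """Draw per-read templates and their ground-truth labels.

    Templates of clean reads are community amplicon inserts (primer-trimmed
    world: reads are simulated from the region between the primers) drawn
    proportional to input abundance.  Chimeric templates join a left parent
    prefix to a right parent suffix at a breakpoint drawn uniformly at least
    ``breakpoint_margin`` nt from either end — partial extension products
    shorter than that lack a stably annealing 3' end, so breakpoints hugging
    the template ends are not generated.
    """
    amplicons = in_silico_pcr(config.refs, config.primers)
    ids = list(amplicons.amplicons)
    seqs = [amplicons.amplicons[i] for i in ids]
    if config.chimera_rate > 0 and len(set(seqs)) < 2:
        raise ValueError("chimera simulation needs >= 2 distinct amplicons")
    ab = config.refs.abundances
    w = np.array([ab[i] for i in ids], dtype=float)
    w /= w.sum()
    pool = config.contaminant_pool
    if pool is None and config.contaminant_rate > 0:
        pool = _contaminant_pool(amplicons, config.contaminant_divergence, rng)

    p_artifact = [config.primer_dimer_rate, config.chimera_rate,
                  config.contaminant_rate, config.offtarget_rate]
    probs = np.array(p_artifact + [1.0 - sum(p_artifact)])
    kinds = np.array(["primer_dimer", "chimera", "contaminant", "off_target", "exact"])

    out: list[tuple[str, TruthRecord]] = []
    counter = 0
    for sample, true_idx in config.index_plan.items():
        kind_draw = kinds[rng.choice(len(kinds), size=config.n_reads_per_sample, p=probs)]
        for kind in kind_draw:
            counter += 1
            rid = f"read{counter:07d}"
            if kind == "exact":
                j = rng.choice(len(ids), p=w)
                rec = TruthRecord(rid, sample, "exact", (ids[j],), None, true_idx)
                template = seqs[j]
            elif kind == "chimera":
                ja = rng.choice(len(ids), p=w)
                while True:
                    jb = rng.choice(len(ids), p=w)
                    if seqs[jb] != seqs[ja]:
                        break
                lo = config.breakpoint_margin
                hi = min(len(seqs[ja]), len(seqs[jb])) - config.breakpoint_margin
                if hi <= lo:
                    raise ValueError("amplicons too short for breakpoint_margin")
                k = int(rng.integers(lo, hi))
                template = seqs[ja][:k] + seqs[jb][k:]
                rec = TruthRecord(rid, sample, "chimera", (ids[ja], ids[jb]), k, true_idx)
            elif kind == "contaminant":
                template = pool[rng.integers(len(pool))]
                rec = TruthRecord(rid, sample, "contaminant", (), None, true_idx)
            elif kind == "primer_dimer":
                template = (concrete_primer(config.primers.forward, rng)
                            + revcomp(concrete_primer(config.primers.reverse, rng)))
                rec = TruthRecord(rid, sample, "primer_dimer", (), None, true_idx)
            else:  # off_target
                template = _offtarget_template(rng)
                rec = TruthRecord(rid, sample, "off_target", (), None, true_idx)
            out.append((template, rec))
    return out


def _simulate_mate(template: str, length: int, means: np.ndarray, config: SimConfig,
                   rng: np.random.Generator) -> tuple[str, list[int], bool]:
    """One mate: template prefix, adapter padding if short, Q draw, miscalls.

    Returns (bases, quals, any_miscall_in_template_region).
    """
    bases = list(template[:length])
    n_template = len(bases)
    if n_template < length:  # adapter read-through past a short template
        bases += list(_random_dna(rng, length - n_template))
    q = np.rint(means + rng.normal(0.0, config.q_sd, length)).astype(int)
    q = np.clip(q, 2, 60)
    hit_template = False
    if config.errors_enabled:
        p = 10.0 ** (-q / 10.0)
        miss = rng.random(length) < p
        for i in np.nonzero(miss)[0]:
            choices = [b for b in "ACGT" if b != bases[i]]
            bases[i] = choices[rng.integers(3)]
            if i < n_template:
                hit_template = True
    return "".join(bases), q.tolist(), hit_template


def simulate_reads(templates: list[tuple[str, TruthRecord]], config: SimConfig,
                   rng: np.random.Generator):
    """Paired R1/R2 records from templates.

    R1 is the first ``read_length`` nt of the template plus strand, R2 of the
    reverse complement; both are padded with random adapter-like bases when
    the template is shorter than the read (adapter read-through).  Base
    miscall probability is 10**(-Q/10), uniform over the other three bases.
    A clean read whose template region receives any miscall has its truth
    category upgraded from ``exact`` to ``mismatch_error``.
    """
    if not templates:
        raise ValueError("no templates")
    if config.read_length < 1:
        raise ValueError("read_length must be >= 1")
    m1 = q_profile(config.read_length, config.q_start_r1, config.q_end_r1)
    m2 = q_profile(config.read_length, config.q_start_r2, config.q_end_r2)
    r1, r2 = [], []
    for template, rec in templates:
        b1, q1, hit1 = _simulate_mate(template, config.read_length, m1, config, rng)
        b2, q2, hit2 = _simulate_mate(revcomp(template), config.read_length, m2, config, rng)
        if rec.category == "exact" and (hit1 or hit2):
            rec.category = "mismatch_error"
        r1.append((rec.read_id, b1, q1))
        r2.append((rec.read_id, b2, q2))
    return r1, r2


def simulate_indices(truth: list[TruthRecord], config: SimConfig,
                     rng: np.random.Generator):
    """i7/i5 index reads, with cross-talk events.

    With probability ``crosstalk_rate`` a read's emitted index pair is
    swapped to a combination absent from the index plan; such unexpected
    combinations carry index Q-scores lowered by ``crosstalk_q_penalty``.
    """
    plan_combos = set(config.index_plan.values())
    all_i7 = sorted({c[0] for c in plan_combos})
    all_i5 = sorted({c[1] for c in plan_combos})
    unexpected = sorted({(a, b) for a in all_i7 for b in all_i5} - plan_combos)
    if config.crosstalk_rate > 0 and not unexpected:
        raise ValueError("cross-talk needs >= 2 samples with distinct indices")
    i7_recs, i5_recs = [], []
    for rec in truth:
        if config.crosstalk_rate > 0 and rng.random() < config.crosstalk_rate:
            combo = unexpected[rng.integers(len(unexpected))]
        else:
            combo = rec.true_indices
        rec.emitted_indices = combo
        mean_q = config.index_q_mean - (config.crosstalk_q_penalty
                                        if combo not in plan_combos else 0.0)
        for recs, idx_seq in ((i7_recs, combo[0]), (i5_recs, combo[1])):
            q = np.rint(mean_q + rng.normal(0.0, config.index_q_sd, 8)).astype(int)
            recs.append((rec.read_id, idx_seq, np.clip(q, 2, 41).tolist()))
    return i7_recs, i5_recs


@dataclass
class SyntheticRun:
    """A complete simulated run: 4 read sets plus the ground-truth table."""

    r1: list
    r2: list
    i7: list
    i5: list
    truth: pd.DataFrame
    config: SimConfig

    def write(self, outdir) -> None:
        """Write R1/R2/I1/I2 FASTQ, the truth TSV, and the resolved config."""
        from . import io as aio

        outdir = aio.ensure_dir(outdir)
        combos = dict(zip(self.truth["read_id"],
                          zip(self.truth["emitted_i7"], self.truth["emitted_i5"])))
        for name, recs, readnum in (("R1", self.r1, 1), ("R2", self.r2, 2),
                                    ("I1", self.i7, 1), ("I2", self.i5, 2)):
            desc = {rid: f"{readnum}:N:0:{combos[rid][0]}+{combos[rid][1]}"
                    for rid, _, _ in recs}
            aio.write_fastq(outdir / f"{name}.fastq", recs, desc)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        with open(outdir / "samples.tsv", "w") as fh:
            fh.write("sample\ti7\ti5\n")
            for s, (i7, i5) in self.config.index_plan.items():
                fh.write(f"{s}\t{i7}\t{i5}\n")
        with open(outdir / "sim_config.txt", "w") as fh:
            for k, v in vars(self.config).items():
                if k in ("refs", "contaminant_pool"):
                    continue
                fh.write(f"{k}\t{v}\n")
        aio.write_reference_set(self.config.refs, outdir / "refs.fasta",
                                outdir / "abundances.tsv")


def _truth_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    rows = []
    for t in truth:
        rows.append({
            "read_id": t.read_id,
            "sample": t.sample,
            "category": t.category,
            "parent_ids": ",".join(t.parent_ids),
            "breakpoint": "" if t.breakpoint is None else t.breakpoint,
            "true_i7": t.true_indices[0],
            "true_i5": t.true_indices[1],
            "emitted_i7": t.emitted_indices[0],
            "emitted_i5": t.emitted_indices[1],
        })
    return pd.DataFrame(rows)


def simulate_run(config: SimConfig) -> SyntheticRun:
    """Run the three simulation stages under one seeded generator.

    Reruns with the same config (including seed) are byte-identical.
    """
    rng = np.random.default_rng(config.seed)
    templates = simulate_templates(config, rng)
    r1, r2 = simulate_reads(templates, config, rng)
    truth = [rec for _, rec in templates]
    i7, i5 = simulate_indices(truth, config, rng)
    return SyntheticRun(r1, r2, i7, i5, _truth_frame(truth), config)
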