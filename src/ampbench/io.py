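"""File-format plumbing: FASTA, FASTQ (Phred+33), TSV tables, primer config.

All on-disk formats are plain text.  FASTA/FASTQ go through Biopython;
tables go through pandas.
"""

from __future__ import annotations

import configparser
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .refs import PrimerSet, ReferenceSet

__all__ = [
    "read_fasta", "write_fasta",
    "read_fastq", "write_fastq",
    "read_reference_set", "write_reference_set",
    "read_primer_config", "write_primer_config",
    "read_variant_table", "write_variant_table",
]


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA; id is the first whitespace-delimited header token."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: list[tuple[str, str]]) -> None:
    """Write FASTA wrapped at 80 columns."""
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str, list[int]]]:
    """Read Phred+33 FASTQ into (id, bases, qualities) tuples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append((rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]))
    return out


def write_fastq(path, records, descriptions: dict[str, str] | None = None) -> None:
    """Write Phred+33 FASTQ; qualities are capped at Q41 on write."""
    recs = []
    for rid, bases, quals in records:
        desc = descriptions.get(rid, "") if descriptions else ""
        rec = SeqRecord(Seq(bases), id=rid, description=desc)
        rec.letter_annotations["phred_quality"] = [min(int(q), 41) for q in quals]
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def read_reference_set(fasta_path, abundance_tsv=None) -> ReferenceSet:
    """Load references from FASTA plus an optional (id, abundance) sidecar TSV.

    Without a sidecar, members get equal abundances.
    """
    seqs = read_fasta(fasta_path)
    if abundance_tsv is not None:
        ab = pd.read_csv(abundance_tsv, sep="\t", header=None, names=["id", "abundance"],
                         comment="#", dtype={"id": str})
        ab_map = dict(zip(ab["id"], ab["abundance"].astype(float)))
        members = [(rid, seq, ab_map[rid]) for rid, seq in seqs]
    else:
        members = [(rid, seq, 1.0 / len(seqs)) for rid, seq in seqs]
    return ReferenceSet(members)


def write_reference_set(refs: ReferenceSet, fasta_path, abundance_tsv=None) -> None:
    write_fasta(fasta_path, [(rid, seq) for rid, seq, _ in refs.members])
    if abundance_tsv is not None:
        with open(abundance_tsv, "w") as fh:
            for rid, _, ab in refs.members:
                fh.write(f"{rid}\t{ab:.10g}\n")


def read_primer_config(path) -> dict[str, PrimerSet]:
    """Read primer pairs from an INI-style key-value config.

    Each section is a primer set::

        [V4-V4]
        forward = GTGYCAGCMGCCGCGGTAA
        reverse = GGACTACNVGGGTWTCTAAT
        expected_amplicon_length = 254
    """
    cp = configparser.ConfigParser()
    with open(path) as fh:
        cp.read_file(fh)
    out = {}
    for name in cp.sections():
        sec = cp[name]
        out[name] = PrimerSet(
            name=name,
            forward=sec["forward"].strip().upper(),
            reverse=sec["reverse"].strip().upper(),
            expected_amplicon_length=sec.getint("expected_amplicon_length", 0),
        )
    return out


def write_primer_config(path, primers: dict[str, PrimerSet]) -> None:
    cp = configparser.ConfigParser()
    for name, ps in primers.items():
        cp[name] = {
            "forward": ps.forward,
            "reverse": ps.reverse,
            "expected_amplicon_length": str(ps.expected_amplicon_length),
        }
    with open(path, "w") as fh:
        cp.write(fh)


def read_variant_table(tsv_path, fasta_path=None) -> pd.DataFrame:
    """Read a variant count table (variant_id, sequence, one column per sample).

    When the TSV lacks a ``sequence`` column (external denoiser export), a
    companion representative FASTA supplies sequences keyed by variant_id.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"variant_id": str})
    if "sequence" not in df.columns:
        if fasta_path is None:
            raise ValueError("variant table lacks sequences and no FASTA was given")
        seq_map = dict(read_fasta(fasta_path))
        df.insert(1, "sequence", df["variant_id"].map(seq_map))
        if df["sequence"].isna().any():
            missing = df.loc[df["sequence"].isna(), "variant_id"].tolist()
            raise ValueError(f"representative FASTA missing variants: {missing[:5]}")
    return df


def write_variant_table(df: pd.DataFrame, tsv_path, fasta_path=None) -> None:
    df.to_csv(tsv_path, sep="\t", index=False)
    if fasta_path is not None:
        write_fasta(fasta_path, list(zip(df["variant_id"], df["sequence"])))


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
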