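"""Shared file I/O: FASTA/FASTQ, SAM ingestion, TSV and VCF-like output.

FASTA/FASTQ pass through Biopython; SAM through pysam.  TSV tables carry
``#`` header comments recording the parameters that produced them; variant
calls are written in a minimal VCF-like tab format with CHROM/POS/REF/ALT
and an INFO column holding AF, DP and P.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_sam",
    "write_tsv",
    "read_tsv",
    "write_vcf_like",
]


def read_fasta(path) -> list[tuple[str, str]]:
    """(name, sequence) pairs; empty file gives an empty list."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_fastq(path) -> list[tuple[str, str, str]]:
    """(name, sequence, quality-string) triples (Phred+33).

    Malformed or truncated records raise ValueError with the failing
    record index.
    """
    out = []
    try:
        with open(path) as fh:
            for i, (title, seq, qual) in enumerate(SeqIO.QualityIO.FastqGeneralIterator(fh)):
                out.append((title, seq, qual))
    except ValueError as err:
        raise ValueError(f"malformed FASTQ record at index {len(out)}: {err}") from err
    return out


def write_fastq(records, path) -> None:
    """``records``: iterables of (name, seq, qual)."""
    with open(path, "w") as fh:
        for name, seq, qual in records:
            if len(seq) != len(qual):
                raise ValueError(f"sequence/quality length mismatch for {name!r}")
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_sam(path):
    """Primary alignments from a SAM/BAM file as a ReadSet (sequences on
    the original read strand), for downstream re-analysis with identical
    semantics to FASTQ input."""
    import pysam

    from .isscan.align import ReadSet
    from .isscan.references import revcomp

    names, seqs, quals = [], [], []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary or rec.query_sequence is None:
                continue
            seq = rec.query_sequence
            qual = (
                "".join(chr(q + 33) for q in rec.query_qualities)
                if rec.query_qualities is not None
                else "I" * len(seq)
            )
            if rec.is_reverse:
                seq = revcomp(seq)
                qual = qual[::-1]
            names.append(rec.query_name)
            seqs.append(seq)
            quals.append(qual)
    return ReadSet(names, seqs, quals)


def write_tsv(df: pd.DataFrame, path, params: dict | None = None) -> None:
    """TSV with ``# key=value`` header comments recording parameters."""
    with open(path, "w") as fh:
        for key, val in (params or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_vcf_like(calls, path, chrom: str = "plasmid") -> None:
    """Minimal VCF-like variant table: CHROM POS ID REF ALT QUAL FILTER INFO."""
    with open(path, "w") as fh:
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            info = f"AF={c.frequency:.6f};DP={c.depth};P={c.p_value:.3e}"
            fh.write(f"{chrom}\t{c.position}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\n")
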