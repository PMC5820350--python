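"""Low-frequency SNP calling from deep plasmid pileups.

Per position and alternative allele, the observed alt count is tested
one-sided against a fixed per-base sequencing error rate with a binomial
test; calls require p < alpha (default 1%), frequency >= min_freq (default
0.25%) and at least ``min_reads`` supporting reads (default 3, which at
7200x depth corresponds to a 0.04% floor).  Clipped read portions never
enter the pileup, so
breakpoint-carrying reads contribute only their reference-aligned segment.

The internal (FASTQ) alignment path is ungapped, hence substitution-only;
short indels surface as breakpoint clusters instead, or can be supplied via
pre-aligned SAM input whose CIGARs carry the indels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .align import ReadSet, align_to_reference
from .references import PlasmidReference

__all__ = ["VariantCall", "call_variants", "pileup"]

_BASES = "ACGT"
_CODE = {ord(b): i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class VariantCall:
    position: int  # 1-based
    ref: str
    alt: str
    supporting: int
    depth: int
    p_value: float

    @property
    def frequency(self) -> float:
        return self.supporting / self.depth


def pileup(reads: ReadSet, ref: PlasmidReference, max_mismatch: int = 3) -> np.ndarray:
    """Base-count matrix of shape (len(ref), 4) over A, C, G, T from the
    unclipped aligned portions of all reads."""
    L = len(ref)
    counts = np.zeros((L, 4), dtype=np.int64)
    alignments = align_to_reference(reads, ref, max_mismatch=max_mismatch)
    code_lut = np.full(256, -1, dtype=np.int8)
    for b, i in _CODE.items():
        code_lut[b] = i
    for aln in alignments:
        if aln is None:
            continue
        seg = aln.oriented_seq[aln.qstart : aln.qend]
        codes = code_lut[np.frombuffer(seg.encode(), dtype=np.uint8)]
        pos = (aln.ref_start + np.arange(codes.size)) % L
        valid = codes >= 0
        np.add.at(counts, (pos[valid], codes[valid]), 1)
    return counts


def call_variants(
    reads: ReadSet,
    ref: PlasmidReference,
    min_freq: float = 0.0025,
    alpha: float = 0.01,
    min_reads: int = 3,
    error_rate: float = 0.003,
    max_mismatch: int = 3,
) -> list[VariantCall]:
    """Binomial-error-model SNP calls above the configured floor."""
    if error_rate >= min_freq:
        warnings.warn(
            "per-base error rate >= minimum frequency: detection power is reduced",
            stacklevel=2,
        )
    counts = pileup(reads, ref, max_mismatch=max_mismatch)
    depth = counts.sum(axis=1)
    calls: list[VariantCall] = []
    ref_arr = np.frombuffer(ref.seq.encode(), dtype=np.uint8)
    candidate = np.nonzero(depth > 0)[0]
    for pos in candidate:
        ref_base = chr(ref_arr[pos])
        d = int(depth[pos])
        for j, alt in enumerate(_BASES):
            if alt == ref_base:
                continue
            n_alt = int(counts[pos, j])
            if n_alt < min_reads or n_alt / d < min_freq:
                continue
            p = float(stats.binom.sf(n_alt - 1, d, error_rate))
            if p < alpha:
                calls.append(
                    VariantCall(
                        position=int(pos) + 1,
                        ref=ref_base,
                        alt=alt,
                        supporting=n_alt,
                        depth=d,
                        p_value=p,
                    )
                )
    return calls
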