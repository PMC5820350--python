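"""Seeded ungapped read alignment against small circular references.

Purpose-built mapper for deep plasmid sequencing: references are a few kb,
reads are short (~150 bp) with low substitution error, and the signal of
interest is the *soft clip* — the maximal contiguous read segment aligns
with few mismatches and the remainder (derived from inserted foreign
sequence) is clipped.  The aligner is exact-seeded (k-mer lookup on the
doubled reference, so circular origins are transparent) and evaluates each
candidate diagonal with a two-pointer scan for the longest window
containing at most ``max_mismatch`` mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .references import revcomp

__all__ = ["Read", "ReadSet", "Alignment", "ReadAligner", "align_to_reference"]


@dataclass(frozen=True)
class Read:
    name: str
    seq: str


class ReadSet:
    """In-memory read collection with optional provenance labels.

    Synthetic reads carry a molecule-of-origin label (parsed from an
    ``origin=`` tag in the read name); real reads carry none.
    """

    def __init__(self, names, seqs, quals=None):
        self.names = list(names)
        self.seqs = list(seqs)
        self.quals = list(quals) if quals is not None else None
        if len(self.names) != len(self.seqs):
            raise ValueError("names and seqs must be equal length")
        self._aln_cache: dict[int, list] = {}

    def __len__(self) -> int:
        return len(self.seqs)

    def __iter__(self):
        return (Read(n, s) for n, s in zip(self.names, self.seqs))

    @property
    def labels(self) -> list[str | None]:
        out = []
        for n in self.names:
            tag = None
            for fieldstr in n.split("|"):
                if fieldstr.startswith("origin="):
                    tag = fieldstr[len("origin=") :]
            out.append(tag)
        return out

    @classmethod
    def from_fastq(cls, *paths) -> "ReadSet":
        from ..interface_io import read_fastq

        names, seqs, quals = [], [], []
        for p in paths:
            for name, seq, qual in read_fastq(p):
                names.append(name)
                seqs.append(seq)
                quals.append(qual)
        return cls(names, seqs, quals)


@dataclass(frozen=True)
class Alignment:
    """Ungapped local alignment of one read to one reference.

    ``ref_start`` is the 0-based reference offset (mod reference length) of
    the first aligned read base; ``qstart``/``qend`` delimit the aligned
    segment on the (plus-strand-oriented) read; bases outside are soft
    clipped.  ``oriented_seq`` is the read sequence on the reference plus
    strand.
    """

    read_index: int
    ref_name: str
    strand: str  # '+' or '-'
    ref_start: int
    qstart: int
    qend: int
    mismatches: int
    oriented_seq: str

    @property
    def aligned_len(self) -> int:
        return self.qend - self.qstart

    @property
    def left_clip(self) -> str:
        return self.oriented_seq[: self.qstart]

    @property
    def right_clip(self) -> str:
        return self.oriented_seq[self.qend :]

    @property
    def ref_end(self) -> int:
        """0-based ref offset one past the last aligned base (not wrapped)."""
        return self.ref_start + self.aligned_len

    @property
    def score(self) -> int:
        return self.aligned_len - 2 * self.mismatches


#: Window edges are trimmed past any mismatch closer than this many bases
#: to the end, so alignments never absorb the mismatch-dense fringe of an
#: insertion junction.
EDGE_TRIM = 4


def _best_window(mismatch_pos: np.ndarray, n: int, max_mm: int) -> tuple[int, int, int]:
    """Longest window [start, end) of a length-n sequence containing at most
    max_mm of the given (sorted) mismatch positions, with mismatch-dense
    edges trimmed.  Returns (start, end, mismatches_in_window)."""
    m = mismatch_pos
    if m.size <= max_mm:
        s, e = 0, n
    else:
        # sentinel-extended: window between mismatch i-1 and mismatch i+max_mm
        ext = np.concatenate(([-1], m, [n]))
        best_len, s, e = -1, 0, 0
        for i in range(ext.size - max_mm - 1):
            start = ext[i] + 1
            end = ext[i + max_mm + 1]
            if end - start > best_len:
                best_len = end - start
                s, e = int(start), int(end)
    # trim: no mismatch may sit within EDGE_TRIM bases of either window end
    if m.size:
        while True:
            inside = m[(m >= s) & (m < e)]
            if inside.size and inside[0] < s + EDGE_TRIM:
                s = int(inside[0]) + 1
            elif inside.size and inside[-1] >= e - EDGE_TRIM:
                e = int(inside[-1])
            else:
                break
            if e <= s:
                break
    if e <= s:
        return 0, 0, 0
    mm_in = int(np.count_nonzero((m >= s) & (m < e)))
    return s, e, mm_in


class ReadAligner:
    """K-mer-seeded ungapped aligner over one or more circular references."""

    def __init__(self, references, k: int = 20, max_mismatch: int = 3, min_align: int = 25):
        """``references``: iterable of (name, sequence) pairs."""
        self.k = k
        self.max_mismatch = max_mismatch
        self.min_align = min_align
        self.refs: dict[str, tuple[str, np.ndarray, int]] = {}
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in references:
            seq = seq.upper()
            L = len(seq)
            doubled = seq + seq  # circular origin transparent to slicing
            arr = np.frombuffer(doubled.encode(), dtype=np.uint8)
            self.refs[name] = (doubled, arr, L)
            for i in range(L):  # seeds only from first copy; diagonal mod L
                kmer = doubled[i : i + k]
                self.index.setdefault(kmer, []).append((name, i))

    def _candidates(self, seq: str):
        """Candidate (ref_name, diagonal) pairs from sampled seeds."""
        k = self.k
        n = len(seq)
        if n < k:
            return []
        offsets = sorted({0, n // 3, (2 * n) // 3, n - k})
        cands = {}
        for off in offsets:
            for name, pos in self.index.get(seq[off : off + k], ()):
                L = self.refs[name][2]
                d = (pos - off) % L
                cands[(name, d)] = None
        return list(cands)

    def _evaluate(self, seq_arr: np.ndarray, name: str, d: int) -> tuple[int, int, int] | None:
        _, ref_arr, L = self.refs[name]
        n = seq_arr.size
        window = ref_arr[d : d + n]
        if window.size < n:  # can only happen for reads longer than L
            return None
        mm = np.nonzero(window != seq_arr)[0]
        return _best_window(mm, n, self.max_mismatch)

    def align(self, seq: str, read_index: int = -1) -> Alignment | None:
        """Best ungapped alignment of a read over all references/strands.

        Returns None when no seeded diagonal yields an aligned segment of at
        least ``min_align`` bases.
        """
        best: Alignment | None = None
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            arr = np.frombuffer(oriented.encode(), dtype=np.uint8)
            for name, d in self._candidates(oriented):
                res = self._evaluate(arr, name, d)
                if res is None:
                    continue
                qs, qe, mm = res
                if qe - qs < self.min_align:
                    continue
                aln = Alignment(
                    read_index=read_index,
                    ref_name=name,
                    strand=strand,
                    ref_start=(d + qs) % self.refs[name][2],
                    qstart=qs,
                    qend=qe,
                    mismatches=mm,
                    oriented_seq=oriented,
                )
                if best is None or aln.score > best.score:
                    best = aln
            # fast path: a clean full-length plus-strand hit cannot be beaten
            if best is not None and best.aligned_len == len(seq) and best.mismatches == 0:
                break
        return best

    def ref_length(self, name: str) -> int:
        return self.refs[name][2]


def align_to_reference(reads: ReadSet, ref, k: int = 20, max_mismatch: int = 3) -> list:
    """Align every read in ``reads`` to a PlasmidReference; cached on the
    ReadSet so repeated pipeline stages reuse one pass."""
    key = (id(ref), max_mismatch)
    cached = reads._aln_cache.get(key)
    if cached is not None:
        return cached
    aligner = ReadAligner([(ref.name, ref.seq)], k=k, max_mismatch=max_mismatch)
    out = [aligner.align(s, i) for i, s in enumerate(reads.seqs)]
    reads._aln_cache[key] = out
    return out
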