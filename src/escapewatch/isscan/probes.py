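"""Junction probes and competitive quantification of insertion frequency.

For each insertion event two 80-bp junction probes are built (40 bp plasmid
flank + 40 bp IS terminus, honouring orientation and the target-site
duplication) together with, per junction side, an 80-bp uninterrupted
reference probe centred on that junction.  Each candidate read is aligned
locally to its side's probe pair; a read supports a probe when the best
alignment covers the probe midpoint with at least ``span_core`` aligned
bases on each side at identity >= ``min_identity`` over the aligned region.
Reads scoring equally on both probes of a pair are ambiguous and discarded.
Counts are pooled over the two sides:

    frequency = junction support / (junction support + reference support)

Each side is quantified against its *own* reference probe; pooling the two
junction sides against a single shared reference count would double-count
junction coverage and bias the frequency upward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skbio.alignment import pair_align

from .align import ReadSet, align_to_reference
from .breakpoints import InsertionEvent
from .references import ISCatalog, PlasmidReference, revcomp

logger = logging.getLogger(__name__)

__all__ = ["JunctionProbeSet", "InsertionFrequency", "build_junction_probes", "quantify_insertion"]


@dataclass(frozen=True)
class JunctionProbeSet:
    """Probes for one insertion event (all ``2 * flank`` bp)."""

    event: InsertionEvent
    left_junction: str
    left_reference: str
    right_junction: str
    right_reference: str
    flank: int


@dataclass(frozen=True)
class InsertionFrequency:
    """Competitive junction/reference support for one event, one sample.

    ``junction_support`` sums junction-crossing reads over the two junction
    sides (each read counted once); ``reference_support`` counts distinct
    reads showing the uninterrupted site.  The frequency is the mean over
    junction sides with at least one junction-crossing read of the side's
    junction/(junction+reference) ratio — each disrupted molecule exposes
    two junctions but an intact molecule only one uninterrupted site, so
    the per-side ratio, not the pooled one, is the unbiased estimator.
    """

    event: InsertionEvent
    junction_support: int
    reference_support: int
    side_counts: tuple[tuple[int, int], ...] = ()  # (junction, reference) per side

    @property
    def frequency(self) -> float:
        ratios = [j / (j + r) for j, r in self.side_counts if j > 0]
        if ratios:
            return float(sum(ratios) / len(ratios))
        return self.junction_support / (self.junction_support + self.reference_support)


def build_junction_probes(
    event: InsertionEvent,
    ref: PlasmidReference,
    catalog: ISCatalog,
    flank: int = 40,
) -> JunctionProbeSet:
    """Build the junction and per-side reference probes for an event.

    With position p (last reference base before the insertion), TSD length
    t and element E (reverse-complemented for '-' orientation):

        left junction  = ref[p-flank+1 .. p]            + E[:flank]
        right junction = E[-flank:] + ref[p-t+1 .. p-t+flank]
        left/right reference = 80 bp of uninterrupted reference centred on
        the respective junction coordinate.

    The reference is circular, so flanks wrap across the origin.
    """
    el = catalog[event.subgroup]
    elem = el.seq if event.orientation == "+" else revcomp(el.seq)
    if flank > len(elem):
        raise ValueError("flank exceeds element length")
    p, t = event.position, event.tsd_length
    left_j = ref.subseq(p - flank + 1, p) + elem[:flank]
    q = p - t + 1  # first reference base after the element (TSD start)
    right_j = elem[-flank:] + ref.subseq(q, q + flank - 1)
    left_ref = ref.subseq(p - flank + 1, p + flank)
    right_ref = ref.subseq(q - flank, q + flank - 1)
    return JunctionProbeSet(
        event=event,
        left_junction=left_j,
        left_reference=left_ref,
        right_junction=right_j,
        right_reference=right_ref,
        flank=flank,
    )


def _probe_alignment(read: str, probe: str, min_identity: float, span_core: int):
    """Score of the best local alignment of ``read`` vs ``probe`` if it
    spans the probe midpoint with >= span_core aligned bases each side at
    sufficient identity; else None."""
    res = pair_align(read, probe, mode="local", sub_score=(1.0, -2.0), gap_cost=2.5, max_paths=1)
    if not res.paths:
        return None
    path = res.paths[0]
    (q0, q1), (p0, p1) = path.ranges
    mid = len(probe) // 2
    if not (p0 <= mid - span_core and p1 >= mid + span_core):
        return None
    # walk the path to compute identity over the aligned region
    matches = cols = 0
    qi, pi = q0, p0
    for length, state in zip(path.lengths, path.states.ravel()):
        if state == 0:  # aligned columns
            a = read[qi : qi + length]
            b = probe[pi : pi + length]
            matches += sum(x == y for x, y in zip(a, b))
            cols += length
            qi += length
            pi += length
        elif state == 1:  # gap in seq1 (read)
            pi += length
            cols += length
        else:  # gap in seq2 (probe)
            qi += length
            cols += length
    if cols == 0 or matches / cols < min_identity:
        return None
    return res.score


def _best_probe(read: str, junction: str, reference: str, min_identity: float, span_core: int):
    """'junction', 'reference', or None (no support / ambiguous tie)."""
    sj = _probe_alignment(read, junction, min_identity, span_core)
    sr = _probe_alignment(read, reference, min_identity, span_core)
    if sj is None and sr is None:
        return None
    if sj is not None and (sr is None or sj > sr):
        return "junction"
    if sr is not None and (sj is None or sr > sj):
        return "reference"
    return None  # tie: ambiguous, discarded


def quantify_insertion(
    reads: ReadSet,
    probes: JunctionProbeSet,
    ref: PlasmidReference,
    min_identity: float = 0.6,
    span_core: int = 10,
    max_mismatch: int = 3,
) -> InsertionFrequency | None:
    """Competitively count junction- vs reference-supporting reads.

    Candidate reads are taken from the cached reference alignments: reads
    whose (clip-extended) footprint overlaps a window around either
    junction, plus unmapped reads screened by exact shared k-mers with the
    junction probes.  Clean reads fully covering a junction midpoint within
    their unclipped, low-mismatch alignment are counted as reference
    support directly; all other candidates are resolved by local alignment
    against the side's probe pair.  Each read is counted at most once per
    event.  Returns None (row dropped) when no read spans either junction.
    """
    L = len(ref)
    flank = probes.flank
    alignments = align_to_reference(reads, ref, max_mismatch=max_mismatch)
    p = probes.event.position
    q = p - probes.event.tsd_length + 1
    sides = (
        (p, probes.left_junction, probes.left_reference),
        (q - 1, probes.right_junction, probes.right_reference),
    )
    # midpoint k-mers of junction probes for screening unmapped reads
    kscreen = 14
    screen = set()
    for _, junction, _ in sides:
        mid = len(junction) // 2
        for off in range(mid - kscreen, mid + 1):
            s = junction[off : off + kscreen]
            screen.add(s)
            screen.add(revcomp(s))

    side_j = [0, 0]
    side_r = [0, 0]
    reference_reads = 0
    for i, aln in enumerate(alignments):
        votes: list[str | None] = [None, None]
        if aln is None:
            # unmapped reads (e.g. mostly element-interior) are screened by
            # exact shared k-mers around the junction midpoints
            seq = reads.seqs[i]
            if not any(seq[j : j + kscreen] in screen for j in range(0, len(seq) - kscreen + 1)):
                continue
            for si, (_, junction, reference) in enumerate(sides):
                for oriented in (seq, revcomp(seq)):
                    v = _best_probe(oriented, junction, reference, min_identity, span_core)
                    if v == "junction":
                        votes[si] = v
                        break
                    if v == "reference" and votes[si] is None:
                        votes[si] = v
        else:
            # footprint of the full read around its alignment (unwrapped)
            start = aln.ref_start - aln.qstart
            end = start + len(aln.oriented_seq)
            clipped = aln.qstart > 0 or aln.qend < len(aln.oriented_seq)
            for si, (mid_c, junction, reference) in enumerate(sides):
                # the window is replicated across the circular origin
                for base in (mid_c, mid_c + L, mid_c - L):
                    if end <= base - flank or start >= base + flank:
                        continue
                    covers = (
                        aln.ref_start + span_core <= base
                        and aln.ref_end - span_core >= base
                    )
                    if covers and not clipped:
                        # clean read fully covering the junction midpoint
                        # inside its unclipped alignment: reference support
                        votes[si] = "reference"
                    else:
                        votes[si] = _best_probe(
                            aln.oriented_seq, junction, reference, min_identity, span_core
                        )
                    break
        if votes[0] is None and votes[1] is None:
            continue
        # A junction vote marks the read's molecule as disrupted: it must
        # not also count as reference on the other side, where its
        # TSD-duplicated flank mimics an uninterrupted site.  A read with
        # no junction vote counts as reference on every side it covers
        # (intact molecules present one uninterrupted site to both sides).
        if "junction" in votes:
            side_j[votes.index("junction")] += 1
        else:
            reference_reads += 1
            for si in (0, 1):
                if votes[si] == "reference":
                    side_r[si] += 1

    junction_n = side_j[0] + side_j[1]
    if junction_n == 0:
        logger.info(
            "event %s@%d: no junction-spanning reads; row disregarded",
            probes.event.subgroup,
            probes.event.position,
        )
        return None
    return InsertionFrequency(
        event=probes.event,
        junction_support=junction_n,
        reference_support=reference_reads,
        side_counts=((side_j[0], side_r[0]), (side_j[1], side_r[1])),
    )
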