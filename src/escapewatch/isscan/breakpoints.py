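"""Broken-read breakpoint detection and IS terminus assignment.

A read crossing an insertion junction aligns to the plasmid with a
soft-clipped tail derived from the inserted element.  Clipped reads are
clustered by (clip coordinate, clip side); a cluster's tail consensus is
then matched against the catalogued IS termini.  An insertion with a
target-site duplication (TSD) of t bases produces a *crossed-over* pair of
clusters: the left-junction cluster at the last reference base before the
insertion (position p) and the right-junction cluster at p - t + 1, i.e.
the right breakpoint lies *before* the left one and the reference gap
between them equals the TSD length (the 3-12 bp signature).

Junction microhomology (IS terminus bases identical to the flanking
reference) shifts the apparent clip coordinate; the offset is recovered
from where the tail consensus lands inside the element sequence, so
reported positions are microhomology-corrected.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import edlib

from .align import ReadSet, align_to_reference
from .references import ISCatalog, PlasmidReference, revcomp

logger = logging.getLogger(__name__)

__all__ = ["BreakpointCluster", "InsertionEvent", "detect_breakpoints", "assign_termini"]


@dataclass(frozen=True)
class BreakpointCluster:
    """Reads sharing a clip boundary.

    ``side`` is ``"right_clip"`` when the alignment ends at ``coord`` (the
    clipped tail extends rightward: a left junction on the plus strand) and
    ``"left_clip"`` when the alignment starts at ``coord``.  ``coord`` is
    1-based.  Tails of right-clip clusters are stored left-anchored at the
    boundary; left-clip tails right-anchored.
    """

    side: str
    coord: int
    support: int
    tails: tuple[str, ...]
    consensus: str


@dataclass(frozen=True)
class InsertionEvent:
    """A located IS insertion.

    ``position`` is the 1-based coordinate of the last reference base
    before the inserted material on the plus strand; ``tsd_length`` the
    target-site duplication length; ``support`` the (left, right)
    broken-read counts.
    """

    position: int
    subgroup: str
    orientation: str  # '+' or '-'
    tsd_length: int
    support: tuple[int, int] = (0, 0)


def _consensus(tails: list[str], anchored: str) -> str:
    """Majority-vote consensus of variable-length tails sharing one anchor.

    ``anchored="left"`` for right-clip tails (all begin at the boundary),
    ``"right"`` for left-clip tails (all end at the boundary).
    """
    if not tails:
        return ""
    n = max(len(t) for t in tails)
    cols = []
    for i in range(n):
        counts: dict[str, int] = {}
        for t in tails:
            j = i if anchored == "left" else len(t) - n + i
            if 0 <= j < len(t):
                counts[t[j]] = counts.get(t[j], 0) + 1
        cols.append(max(counts, key=counts.get) if counts else "N")
    return "".join(cols)


def detect_breakpoints(
    reads: ReadSet,
    ref: PlasmidReference,
    max_mismatch: int = 3,
    min_clip: int = 20,
    min_support: int = 1,
) -> list[BreakpointCluster]:
    """Cluster soft-clipped read alignments by clip coordinate and side.

    Reads must align locally to the reference with at most ``max_mismatch``
    mismatches in the aligned region and carry a clipped tail of at least
    ``min_clip`` bases to contribute.  Clusters with fewer than
    ``min_support`` reads are dropped.
    """
    if min_clip < 15:
        raise ValueError("min_clip must be >= 15")
    if len(ref) < max((len(s) for s in reads.seqs), default=0):
        raise ValueError("reference shorter than read length")
    alignments = align_to_reference(reads, ref, max_mismatch=max_mismatch)
    L = len(ref)
    groups: dict[tuple[str, int], list[str]] = defaultdict(list)
    for aln in alignments:
        if aln is None:
            continue
        rc = aln.right_clip
        if len(rc) >= min_clip:
            # last aligned base, 1-based
            coord = (aln.ref_end - 1) % L + 1
            groups[("right_clip", coord)].append(rc)
        lc = aln.left_clip
        if len(lc) >= min_clip:
            coord = aln.ref_start % L + 1  # first aligned base, 1-based
            groups[("left_clip", coord)].append(lc)
    clusters = []
    for (side, coord), tails in sorted(groups.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        if len(tails) < min_support:
            continue
        cons = _consensus(tails, anchored="left" if side == "right_clip" else "right")
        clusters.append(
            BreakpointCluster(
                side=side, coord=coord, support=len(tails), tails=tuple(tails), consensus=cons
            )
        )
    return clusters


def _locate_tail(tail: str, element_seq: str, max_divergence: float):
    """Best semi-global placement of ``tail`` inside ``element_seq``.

    Returns (start, end, distance) with 0-based inclusive ends, or None
    when the edit distance exceeds ``max_divergence * len(tail)``.
    """
    if not tail:
        return None
    kmax = int(max_divergence * len(tail))
    res = edlib.align(tail, element_seq, mode="HW", task="locations", k=kmax)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    return start, end, res["editDistance"]


def assign_termini(
    clusters: list[BreakpointCluster],
    catalog: ISCatalog,
    tsd_range: tuple[int, int] = (3, 12),
    max_tail_divergence: float = 0.1,
    min_support: int = 1,
    ref_length: int | None = None,
) -> tuple[list[InsertionEvent], list[BreakpointCluster]]:
    """Pair left/right breakpoint clusters into IS insertion events.

    A right-clip cluster's tail must match the *start* of an element (its
    left terminus, or the reverse complement's start for '-' orientation)
    and the partner left-clip cluster's tail the element *end*; the
    reference-coordinate gap between the pair, corrected for junction
    microhomology, must fall inside ``tsd_range``.  Tails matching two
    subgroups equally well are ambiguous and excluded.  Unpaired or
    unmatched clusters are returned as unassigned structural variation.
    """

    def best_match(tail: str, end: str):
        """end='start': tail should sit at an element start (offset = match
        start); end='end': at an element end (offset = distance from match
        end to element end).  Returns (subgroup, orientation, offset) or
        None (no match / ambiguous)."""
        hits = []
        for el in catalog:
            for orient, seq in (("+", el.seq), ("-", revcomp(el.seq))):
                loc = _locate_tail(tail, seq, max_tail_divergence)
                if loc is None:
                    continue
                start, endpos, dist = loc
                offset = start if end == "start" else len(seq) - 1 - endpos
                if offset <= el.terminus_len:
                    hits.append((dist, el.name, orient, offset))
        if not hits:
            return None
        hits.sort()
        if len(hits) > 1 and hits[0][0] == hits[1][0] and hits[0][1] != hits[1][1]:
            logger.info("ambiguous tail match between %s and %s; excluded", hits[0][1], hits[1][1])
            return None
        _, name, orient, offset = hits[0]
        return name, orient, offset

    lefts, rights, unassigned = [], [], []
    for cl in clusters:
        if cl.support < min_support:
            continue
        if cl.side == "right_clip":
            m = best_match(cl.consensus, "start")
            (lefts if m else unassigned).append((cl, m) if m else cl)
        else:
            m = best_match(cl.consensus, "end")
            (rights if m else unassigned).append((cl, m) if m else cl)

    # pair strongest clusters first: boundary jitter from read errors can
    # shadow a true cluster with low-support satellites at nearby
    # coordinates, which must not steal the true partner
    lefts.sort(key=lambda item: -item[0].support)
    rights.sort(key=lambda item: -item[0].support)
    events = []
    used_r = set()
    for cl_l, (name_l, orient_l, off_l) in lefts:
        pos = cl_l.coord - off_l  # microhomology-corrected insertion point
        partner = None
        for j, (cl_r, (name_r, orient_r, off_r)) in enumerate(rights):
            if j in used_r or name_r != name_l or orient_r != orient_l:
                continue
            start_r = cl_r.coord + off_r  # corrected first ref base after IS
            gap = pos - start_r + 1
            if ref_length:
                gap = (pos - start_r) % ref_length + 1
            if tsd_range[0] <= gap <= tsd_range[1]:
                partner = (j, cl_r, gap)
                break
        if partner is None:
            unassigned.append(cl_l)
            continue
        j, cl_r, gap = partner
        used_r.add(j)
        events.append(
            InsertionEvent(
                position=pos,
                subgroup=name_l,
                orientation=orient_l,
                tsd_length=gap,
                support=(cl_l.support, cl_r.support),
            )
        )
    for j, (cl_r, _) in enumerate(rights):
        if j not in used_r:
            unassigned.append(cl_r)
    # merge events that resolve to the same insertion (residual boundary
    # jitter from read errors can split one junction across clusters)
    merged: dict[tuple, InsertionEvent] = {}
    for ev in events:
        key = (ev.position, ev.subgroup, ev.orientation, ev.tsd_length)
        if key in merged:
            prev = merged[key]
            merged[key] = InsertionEvent(
                position=ev.position,
                subgroup=ev.subgroup,
                orientation=ev.orientation,
                tsd_length=ev.tsd_length,
                support=(prev.support[0] + ev.support[0], prev.support[1] + ev.support[1]),
            )
        else:
            merged[key] = ev
    # suppress jitter satellites: a weaker event of the same subgroup and
    # orientation within the TSD-signature radius of a stronger one is an
    # artefact of shifted breakpoints, not an independent insertion
    kept: list[InsertionEvent] = []
    for ev in sorted(merged.values(), key=lambda e: -(e.support[0] + e.support[1])):
        if any(
            k.subgroup == ev.subgroup
            and k.orientation == ev.orientation
            and abs(k.position - ev.position) <= tsd_range[1]
            for k in kept
        ):
            continue
        kept.append(ev)
    events = sorted(kept, key=lambda e: e.position)
    return events, unassigned
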