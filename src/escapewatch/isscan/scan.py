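"""Convenience pipeline: breakpoints -> events -> junction quantification."""

from __future__ import annotations

from .align import ReadSet
from .breakpoints import assign_termini, detect_breakpoints
from .probes import InsertionFrequency, build_junction_probes, quantify_insertion
from .references import ISCatalog, PlasmidReference

__all__ = ["scan_insertions"]


def scan_insertions(
    reads: ReadSet,
    ref: PlasmidReference,
    catalog: ISCatalog,
    max_mismatch: int = 3,
    min_clip: int = 20,
    min_support: int = 3,
    tsd_range: tuple[int, int] = (3, 12),
    flank: int = 40,
    min_identity: float = 0.6,
    span_core: int = 10,
):
    """Detect IS insertion events in one sample and quantify each.

    Returns ``(frequencies, events, unassigned)`` where ``frequencies`` is
    a list of :class:`InsertionFrequency` (events without junction-spanning
    reads are dropped), ``events`` the detected insertion events, and
    ``unassigned`` breakpoint clusters not attributable to catalogued
    element termini.
    """
    clusters = detect_breakpoints(
        reads, ref, max_mismatch=max_mismatch, min_clip=min_clip, min_support=min_support
    )
    events, unassigned = assign_termini(
        clusters, catalog, tsd_range=tsd_range, min_support=min_support, ref_length=len(ref)
    )
    freqs: list[InsertionFrequency] = []
    for ev in events:
        probes = build_junction_probes(ev, ref, catalog, flank=flank)
        row = quantify_insertion(
            reads, probes, ref, min_identity=min_identity, span_core=span_core,
            max_mismatch=max_mismatch,
        )
        if row is not None:
            freqs.append(row)
    return freqs, events, unassigned
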