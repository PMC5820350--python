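"""Total mobile-element fraction by competitive read mapping.

Reads are mapped competitively against a combined reference (production
plasmid + every catalogued mobile-element subgroup); each read contributes
its aligned bases to its single best hit.  The mobile-element fraction of a
sample is

    sum over subgroups of mean per-base depth / mean per-base depth of the
    plasmid reference,

a proxy for the disrupted share of plasmid molecules: it approaches 0 for a
pure intact population and ~1 when every molecule carries one element.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import ReadAligner, ReadSet
from .references import ISCatalog, PlasmidReference

__all__ = ["MEFractionResult", "me_fraction"]


@dataclass(frozen=True)
class MEFractionResult:
    fraction: float
    plasmid_depth: float
    subgroup_depth: dict  # mean per-base depth per subgroup
    unmapped_reads: int


def me_fraction(
    reads: ReadSet,
    ref: PlasmidReference,
    catalog: ISCatalog,
    max_mismatch: int = 3,
) -> MEFractionResult:
    """Mobile-element to plasmid coverage ratio for one sample."""
    refs = [(ref.name, ref.seq)] + [(el.name, el.seq) for el in catalog]
    aligner = ReadAligner(refs, max_mismatch=max_mismatch)
    bases = {name: 0 for name, _ in refs}
    unmapped = 0
    for i, seq in enumerate(reads.seqs):
        aln = aligner.align(seq, i)
        if aln is None:
            unmapped += 1
            continue
        bases[aln.ref_name] += aln.aligned_len
    plasmid_depth = bases[ref.name] / len(ref)
    if plasmid_depth == 0:
        raise ValueError("zero plasmid coverage: mobile-element fraction undefined")
    sub_depth = {el.name: bases[el.name] / len(el) for el in catalog}
    fraction = sum(sub_depth.values()) / plasmid_depth
    return MEFractionResult(
        fraction=fraction,
        plasmid_depth=plasmid_depth,
        subgroup_depth=sub_depth,
        unmapped_reads=unmapped,
    )
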