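"""Reference containers: circular production plasmid and IS catalog."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

__all__ = ["PlasmidReference", "ISElement", "ISCatalog", "revcomp", "DEFAULT_MERGE_RULES"]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class PlasmidReference:
    """Circular plasmid reference, 1-based coordinates.

    ``annotations`` maps gene names (e.g. atoB, ERG13, tHMGR) to 1-based
    inclusive (start, end) intervals.
    """

    name: str
    seq: str
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        seq = self.seq.upper()
        if set(seq) - set("ACGTN"):
            raise ValueError("reference alphabet must be ACGTN")
        object.__setattr__(self, "seq", seq)
        L = len(seq)
        for gene, (s, e) in self.annotations.items():
            if not (1 <= s <= L and 1 <= e <= L):
                raise ValueError(f"annotation {gene} outside reference bounds")

    def __len__(self) -> int:
        return len(self.seq)

    def subseq(self, start: int, end: int) -> str:
        """1-based inclusive circular slice; ``start`` may exceed ``end``
        across the origin, and coordinates outside [1, L] wrap."""
        L = len(self.seq)
        s = (start - 1) % L
        n = (end - start) % L + 1
        doubled = self.seq + self.seq
        return doubled[s : s + n]

    @classmethod
    def from_fasta(cls, path, annotations: dict | None = None) -> "PlasmidReference":
        rec = next(SeqIO.parse(str(path), "fasta"))
        return cls(name=rec.id, seq=str(rec.seq), annotations=annotations or {})

    def to_fasta(self, path) -> None:
        Path(path).write_text(f">{self.name}\n{self.seq}\n")


#: Merge rules for mobile-element subgroups that are indistinguishable at
#: the junction level: IS10R/IS10L are reported jointly as IS10 and
#: IS1A/B/F as IS1.
DEFAULT_MERGE_RULES = {
    "IS10R": "IS10",
    "IS10L": "IS10",
    "IS1A": "IS1",
    "IS1B": "IS1",
    "IS1F": "IS1",
}


@dataclass(frozen=True)
class ISElement:
    """One mobile-element subgroup with annotated 40-bp termini."""

    name: str
    seq: str
    copy_number: int | None = None
    members: tuple[str, ...] = ()
    terminus_len: int = 40

    def __post_init__(self):
        seq = self.seq.upper()
        if set(seq) - set("ACGTN"):
            raise ValueError("IS alphabet must be ACGTN")
        if len(seq) < 2 * self.terminus_len:
            raise ValueError("IS sequence shorter than its two termini")
        object.__setattr__(self, "seq", seq)
        if not self.members:
            object.__setattr__(self, "members", (self.name,))

    @property
    def left_terminus(self) -> str:
        return self.seq[: self.terminus_len]

    @property
    def right_terminus(self) -> str:
        return self.seq[-self.terminus_len :]

    def __len__(self) -> int:
        return len(self.seq)


class ISCatalog:
    """Catalog of mobile-element subgroups, with merge rules applied.

    When several subgroups merge under one name the first member's sequence
    is kept as the representative and member names are recorded.
    """

    def __init__(self, elements, merge_rules: dict | None = None):
        rules = DEFAULT_MERGE_RULES if merge_rules is None else merge_rules
        merged: dict[str, ISElement] = {}
        for el in elements:
            name = rules.get(el.name, el.name)
            if name in merged:
                prev = merged[name]
                merged[name] = ISElement(
                    name=name,
                    seq=prev.seq,
                    copy_number=prev.copy_number,
                    members=prev.members + (el.name,),
                    terminus_len=prev.terminus_len,
                )
            else:
                merged[name] = ISElement(
                    name=name,
                    seq=el.seq,
                    copy_number=el.copy_number,
                    members=(el.name,),
                    terminus_len=el.terminus_len,
                )
        self._elements = merged

    def __iter__(self):
        return iter(self._elements.values())

    def __len__(self) -> int:
        return len(self._elements)

    def __getitem__(self, name: str) -> ISElement:
        return self._elements[name]

    def __contains__(self, name: str) -> bool:
        return name in self._elements

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._elements)

    @classmethod
    def from_fasta(cls, path, merge_rules: dict | None = None, terminus_len: int = 40) -> "ISCatalog":
        els = [
            ISElement(name=rec.id, seq=str(rec.seq), terminus_len=terminus_len)
            for rec in SeqIO.parse(str(path), "fasta")
        ]
        return cls(els, merge_rules=merge_rules)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for el in self:
                fh.write(f">{el.name}\n{el.seq}\n")
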