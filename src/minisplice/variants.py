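"""Mutations, variant calls and barcoded minigene variants.

Coordinates are 1-based along the minigene insert; position 1 is the first
nucleotide of the cloned fragment. A mutation is identified by the triple
(position, ref, alt); indels follow the anchored-allele convention of VCF
(the ref/alt strings share their first base).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

_NUCS = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class Mutation:
    """A single substitution, insertion or deletion on the minigene."""

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= _NUCS:
                raise ValueError(f"invalid allele {allele!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")

    @property
    def kind(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "substitution"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def indel_length(self) -> int:
        """Number of inserted/deleted bases (0 for a substitution)."""
        return abs(len(self.alt) - len(self.ref))

    @property
    def label(self) -> str:
        """Compact name: ``G742C`` for substitutions, ``742:AG>A`` otherwise."""
        if self.kind == "substitution":
            return f"{self.ref}{self.position}{self.alt}"
        return f"{self.position}:{self.ref}>{self.alt}"

    @classmethod
    def from_label(cls, label: str) -> "Mutation":
        if ":" in label:
            pos, alleles = label.split(":")
            ref, alt = alleles.split(">")
            return cls(int(pos), ref, alt)
        return cls(int(label[1:-1]), label[0], label[-1])

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True)
class VariantCall:
    """A mutation call with its penetrance (allele frequency among a barcode's reads)."""

    mutation: Mutation
    af: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.af <= 1.0:
            raise ValueError(f"penetrance AF must be in [0, 1], got {self.af}")


@dataclass(frozen=True)
class MinigeneVariant:
    """A barcoded minigene and its mutation set.

    ``penetrances`` maps each mutation to its allele frequency in the
    barcode's long reads; ``ccs_support`` is the number of circular consensus
    reads supporting the barcode.
    """

    barcode: str
    mutations: tuple[Mutation, ...] = ()
    ccs_support: int = 0
    penetrances: Mapping[Mutation, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (14 <= len(self.barcode) <= 16) or not set(self.barcode) <= _NUCS:
            raise ValueError(f"barcode must be a 14-16 nt ACGT string, got {self.barcode!r}")
        if self.ccs_support < 0:
            raise ValueError("ccs_support must be >= 0")
        object.__setattr__(self, "mutations", tuple(sorted(self.mutations)))

    @property
    def is_wildtype(self) -> bool:
        return not self.mutations

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)

    def max_indel_length(self) -> int:
        return max((m.indel_length for m in self.mutations), default=0)


def variant_map(variants: Sequence[MinigeneVariant]) -> dict[str, MinigeneVariant]:
    """Index variants by barcode, rejecting duplicates."""
    out: dict[str, MinigeneVariant] = {}
    for v in variants:
        if v.barcode in out:
            raise ValueError(f"duplicate barcode {v.barcode}")
        out[v.barcode] = v
    return out
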