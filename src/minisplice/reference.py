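"""Minigene reference: exon/intron layout, canonical splice sites, splicing.

The reference is a three-exon / two-intron reporter insert (the layout of a
CD19 exon 1-3 minigene). Junctions are written as (donor, acceptor) pairs
where the donor is the last exonic base of the upstream exon and the
acceptor the first exonic base of the downstream exon, both 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

Junction = tuple[int, int]
Chain = tuple[Junction, ...]

_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class MinigeneReference:
    """Reference sequence plus exon layout and translation start."""

    sequence: str
    exons: tuple[tuple[int, int], ...]
    orf_start: int
    name: str = "minigene"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        if not set(seq) <= set("ACGTN"):
            raise ValueError("reference sequence contains non-nucleotide characters")
        prev_end = 0
        for start, end in self.exons:
            if not (1 <= start <= end <= len(seq)):
                raise ValueError(f"exon ({start}, {end}) outside reference bounds")
            if start <= prev_end:
                raise ValueError("exon intervals must be sorted and non-overlapping")
            prev_end = end
        e1 = self.exons[0]
        if not (e1[0] <= self.orf_start <= e1[1] - 2):
            raise ValueError("orf_start must lie inside the first exon")
        for a, b in self.introns:
            if self.sequence[a - 1 : a + 1] != "GT" or self.sequence[b - 2 : b] != "AG":
                raise ValueError(
                    f"intron {a}-{b} lacks canonical GT..AG dinucleotides"
                )

    # ------------------------------------------------------------------ layout
    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intervals between consecutive exons (1-based inclusive)."""
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        )

    @property
    def donor_sites(self) -> tuple[int, ...]:
        """Canonical donors: last exonic base of each non-terminal exon."""
        return tuple(e[1] for e in self.exons[:-1])

    @property
    def acceptor_sites(self) -> tuple[int, ...]:
        """Canonical acceptors: first exonic base of each non-initial exon."""
        return tuple(e[0] for e in self.exons[1:])

    @property
    def inclusion_chain(self) -> Chain:
        """Junction chain of the fully spliced (all exons) isoform."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    # ---------------------------------------------------------------- splicing
    def splice(self, chain: Chain) -> str:
        """Mature transcript sequence for a junction chain.

        An empty chain returns the unspliced insert. Junctions must be
        ordered, non-overlapping, with donor < acceptor.
        """
        segments = self.exonic_segments(chain)
        return "".join(self.sequence[a - 1 : b] for a, b in segments)

    def exonic_segments(self, chain: Chain) -> tuple[tuple[int, int], ...]:
        """Retained genomic intervals (1-based inclusive) for a chain."""
        pos = 1
        segments: list[tuple[int, int]] = []
        prev_acceptor = 0
        for donor, acceptor in chain:
            if not (1 <= donor < acceptor - 1 and acceptor <= self.length):
                raise ValueError(f"invalid junction ({donor}, {acceptor})")
            if donor < pos or donor <= prev_acceptor:
                raise ValueError("junctions must be ordered and non-overlapping")
            segments.append((pos, donor))
            pos = acceptor
            prev_acceptor = acceptor
        segments.append((pos, self.length))
        return tuple(segments)

    def to_mature_coordinate(self, genomic_pos: int, chain: Chain) -> int | None:
        """Map a genomic position into mature-transcript coordinates (1-based).

        Returns None when the position is spliced out by the chain.
        """
        offset = 0
        for a, b in self.exonic_segments(chain):
            if a <= genomic_pos <= b:
                return offset + (genomic_pos - a) + 1
            offset += b - a + 1
        return None

    def to_genomic_coordinate(self, mature_pos: int, chain: Chain) -> int:
        """Map a 1-based mature-transcript position back to the genome."""
        offset = 0
        for a, b in self.exonic_segments(chain):
            seg_len = b - a + 1
            if mature_pos <= offset + seg_len:
                return a + (mature_pos - offset) - 1
            offset += seg_len
        raise ValueError(f"mature position {mature_pos} beyond transcript end")


def generate_reference(
    exon_lengths: Sequence[int] = (100, 267, 300),
    intron_lengths: Sequence[int] = (250, 283),
    orf_start: int = 30,
    seed: int = 0,
    name: str = "minigene",
) -> MinigeneReference:
    """Generate a random minigene reference with the requested layout.

    The sequence carries canonical GT/AG dinucleotides at every intron
    boundary, an ATG at ``orf_start`` and a single in-frame stop codon near
    the end of the last exon of the fully spliced isoform; intervening
    in-frame stops are rewritten so the inclusion isoform has a clean ORF.
    """
    if len(exon_lengths) != len(intron_lengths) + 1:
        raise ValueError("need one more exon than introns")
    if len(exon_lengths) < 2:
        raise ValueError("layout needs at least two exons")
    if any(l < 4 for l in intron_lengths):
        raise ValueError("introns shorter than 4 nt cannot carry GT..AG dinucleotides")
    if any(l < 1 for l in exon_lengths):
        raise ValueError("exon lengths must be positive")

    rng = np.random.default_rng(seed)
    total = sum(exon_lengths) + sum(intron_lengths)
    seq = list(rng.choice(list("ACGT"), size=total))

    exons: list[tuple[int, int]] = []
    pos = 1
    for i, el in enumerate(exon_lengths):
        exons.append((pos, pos + el - 1))
        pos += el
        if i < len(intron_lengths):
            il = intron_lengths[i]
            seq[pos - 1 : pos + 1] = ["G", "T"]
            seq[pos + il - 3 : pos + il - 1] = ["A", "G"]
            pos += il

    e1 = exons[0]
    if not (e1[0] <= orf_start <= e1[1] - 2):
        raise ValueError("orf_start must lie inside the first exon")
    seq[orf_start - 1 : orf_start + 2] = ["A", "T", "G"]

    # Mature (inclusion) coordinates -> genomic, to manage the reading frame.
    mature_to_genomic = [g for a, b in exons for g in range(a, b + 1)]
    mature = lambda: "".join(seq[g - 1] for g in mature_to_genomic)  # noqa: E731
    orf_m = mature_to_genomic.index(orf_start)  # 0-based mature offset of ATG

    m = mature()
    n_codons = (len(m) - orf_m) // 3
    stop_codon_idx = n_codons - 4  # leave a short 3' trailer after the stop
    if stop_codon_idx < 2:
        raise ValueError("spliced ORF too short to place start and stop codons")
    stop_m = orf_m + 3 * stop_codon_idx
    for k, base in enumerate("TAA"):
        seq[mature_to_genomic[stop_m + k] - 1] = base

    # Remove premature in-frame stops; rewriting the wobble base to C never
    # creates a new stop and exonic interiors are free of layout constraints.
    m = mature()
    for ci in range(stop_codon_idx):
        start = orf_m + 3 * ci
        if m[start : start + 3] in _STOPS:
            g = mature_to_genomic[start + 2]
            seq[g - 1] = "C"

    ref = MinigeneReference("".join(seq), tuple(exons), orf_start, name=name)
    mat = ref.splice(ref.inclusion_chain)
    assert mat[orf_m : orf_m + 3] == "ATG"
    return ref
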