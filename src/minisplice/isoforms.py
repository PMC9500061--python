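"""Splice-isoform reconstruction and per-minigene frequency tables.

Read pairs are represented as CIGAR-style match/skip operation lists against
the unspliced minigene. A pair is usable for isoform reconstruction when it
maps in proper orientation, both mates agree on the junctions they jointly
cover, and both mates cross the constitutive exon boundaries with at least
10 aligned nt inside the flanking constitutive exon on their side, so every
asserted junction is firmly anchored.

Junctions are (donor, acceptor) pairs: last exonic base of the upstream
segment and first exonic base of the downstream segment, 1-based.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import Chain, Junction, MinigeneReference

DISCARDED = "discarded"

_CIGAR_RE = re.compile(r"(\d+)([MN])")


class Rejection(str, Enum):
    """Typed reasons a read pair is unusable for isoform reconstruction."""

    IMPROPER_ORIENTATION = "improper-orientation"
    INCONSISTENT_OVERLAP = "inconsistent-overlap"
    INSUFFICIENT_OVERHANG = "insufficient-overhang"


@dataclass(frozen=True)
class ReadPairAlignment:
    """Alignment of a read pair: per-mate start, match/skip ops and strand."""

    start1: int
    ops1: tuple[tuple[str, int], ...]
    strand1: str
    start2: int
    ops2: tuple[tuple[str, int], ...]
    strand2: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ops1", tuple((k, int(n)) for k, n in self.ops1))
        object.__setattr__(self, "ops2", tuple((k, int(n)) for k, n in self.ops2))
        for ops in (self.ops1, self.ops2):
            if not ops:
                raise ValueError("empty operation list")
            for kind, n in ops:
                if kind not in ("M", "N"):
                    raise ValueError(f"unsupported operation {kind!r}")
                if n < 1:
                    raise ValueError("operations must consume at least 1 nt")
            if ops[0][0] != "M" or ops[-1][0] != "M":
                raise ValueError("operation list must start and end with a match")
        if self.strand1 not in "+-" or self.strand2 not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if min(self.start1, self.start2) < 1:
            raise ValueError("alignment start must be >= 1")

    @classmethod
    def from_cigar(
        cls, start1: int, cigar1: str, strand1: str, start2: int, cigar2: str, strand2: str
    ) -> "ReadPairAlignment":
        return cls(start1, _parse_cigar(cigar1), strand1, start2, _parse_cigar(cigar2), strand2)

    @property
    def proper_orientation(self) -> bool:
        return self.strand1 != self.strand2


def _parse_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
    ops = tuple((m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar))
    if "".join(f"{n}{k}" for k, n in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r} (only M/N supported)")
    return ops


def _mate_geometry(start: int, ops: Sequence[tuple[str, int]]):
    """Aligned blocks, junctions and span of one mate."""
    blocks: list[tuple[int, int]] = []
    junctions: list[Junction] = []
    pos = start
    for kind, n in ops:
        if kind == "M":
            if blocks and blocks[-1][1] == pos - 1:
                blocks[-1] = (blocks[-1][0], pos + n - 1)
            else:
                blocks.append((pos, pos + n - 1))
        else:
            junctions.append((pos - 1, pos + n))
        pos += n
    return blocks, junctions, (start, pos - 1)


def reconstruct_isoform(
    pair: ReadPairAlignment, ref: MinigeneReference, min_overhang: int = 10
) -> Chain | Rejection:
    """Merge both mates' junction chains or return a typed rejection."""
    if not pair.proper_orientation:
        return Rejection.IMPROPER_ORIENTATION

    blocks1, junc1, span1 = _mate_geometry(pair.start1, pair.ops1)
    blocks2, junc2, span2 = _mate_geometry(pair.start2, pair.ops2)
    if blocks1[-1][1] > ref.length or blocks2[-1][1] > ref.length:
        raise ValueError("mate maps beyond the reference")

    aligned1 = _position_set(blocks1)
    aligned2 = _position_set(blocks2)
    skip1 = _skip_set(junc1)
    skip2 = _skip_set(junc2)
    if (aligned1 & skip2) or (aligned2 & skip1):
        return Rejection.INCONSISTENT_OVERLAP

    merged = sorted(set(junc1) | set(junc2))
    for (d1, a1), (d2, a2) in zip(merged, merged[1:]):
        if a1 - 1 >= d2 + 1:  # overlapping skipped intervals, not identical
            return Rejection.INCONSISTENT_OVERLAP

    # Overhang across the constitutive exon boundaries: each mate must be
    # anchored by >= min_overhang aligned nt inside the constitutive exon on
    # its side (first exon for the left mate, last exon for the right), so a
    # mate ending a few nt into a constitutive exon cannot assert a junction.
    b1 = ref.exons[0][1]
    b2 = ref.exons[-1][0]
    left_aligned, right_aligned = (
        (aligned1, aligned2) if span1[0] <= span2[0] else (aligned2, aligned1)
    )
    if sum(1 for p in left_aligned if p <= b1) < min_overhang:
        return Rejection.INSUFFICIENT_OVERHANG
    if sum(1 for p in right_aligned if p >= b2) < min_overhang:
        return Rejection.INSUFFICIENT_OVERHANG

    return tuple(merged)


def _position_set(blocks: Iterable[tuple[int, int]]) -> set[int]:
    return {p for a, b in blocks for p in range(a, b + 1)}


def _skip_set(junctions: Iterable[Junction]) -> set[int]:
    return {p for d, a in junctions for p in range(d + 1, a)}


# --------------------------------------------------------------------- naming

def canonical_chains(
    ref: MinigeneReference,
    alt_exon2_offset: int = 24,
    alt_exon3_offset: int = 21,
) -> dict[str, Chain]:
    """Junction chains of the five major isoforms of a three-exon reporter.

    alt-exon2 / alt-exon3 use an alternative 3' splice site ``offset`` nt
    downstream of the canonical acceptor of exon 2 / exon 3.
    """
    if len(ref.exons) != 3:
        raise ValueError("canonical chains are defined for a three-exon layout")
    (s1, e1), (s2, e2), (s3, e3) = ref.exons
    return {
        "inclusion": ((e1, s2), (e2, s3)),
        "skipping": ((e1, s3),),
        "intron2-retention": ((e1, s2),),
        "alt-exon2": ((e1, s2 + alt_exon2_offset), (e2, s3)),
        "alt-exon3": ((e1, s2), (e2, s3 + alt_exon3_offset)),
    }


def isoform_name(chain: Chain, canonical: Mapping[str, Chain]) -> str:
    """Major-isoform name when the chain is canonical, else a coordinate name."""
    for name, c in canonical.items():
        if tuple(chain) == tuple(c):
            return name
    if not chain:
        return "unspliced"
    return "J" + "|".join(f"{d}-{a}" for d, a in chain)


def classify_chain(chain: Chain, ref: MinigeneReference, canonical: Mapping[str, Chain] | None = None) -> str:
    """Coarse isoform class: major name, 'unspliced', or 'cryptic'."""
    canonical = canonical if canonical is not None else canonical_chains(ref)
    name = isoform_name(chain, canonical)
    if not name.startswith("J"):
        return name
    return "cryptic"


@dataclass(frozen=True)
class IsoformStructure:
    """A named splice isoform: junction chain plus coarse class."""

    name: str
    chain: Chain
    iso_class: str

    @classmethod
    def from_chain(cls, chain: Chain, ref: MinigeneReference, canonical: Mapping[str, Chain] | None = None):
        canonical = canonical if canonical is not None else canonical_chains(ref)
        return cls(isoform_name(chain, canonical), tuple(chain), classify_chain(chain, ref, canonical))


# ----------------------------------------------------------- artefact merging

@dataclass(frozen=True)
class ArtifactSpec:
    """Internal exon fragment whose exclusion is an RT artefact.

    The fragment is flanked by a direct repeat of ``repeat_length`` nt, so
    its exclusion maps to ``repeat_length`` shift-equivalent junctions.
    """

    fragment_start: int
    fragment_end: int
    repeat_length: int = 8

    def placements(self) -> tuple[Junction, ...]:
        return tuple(
            (self.fragment_start - 1 + k, self.fragment_end + 1 + k)
            for k in range(self.repeat_length)
        )


def merge_artifact_isoforms(
    counts: Mapping[Chain, int], artifact: ArtifactSpec
) -> dict[Chain, int]:
    """Fold shift-equivalent artefact exclusions into their base isoforms."""
    placements = set(artifact.placements())
    merged: dict[Chain, int] = {}
    for chain, n in counts.items():
        hits = [j for j in chain if j in placements]
        if len(hits) > 1:
            raise ValueError(
                f"chain {chain} matches several artefact placements; base isoform ambiguous"
            )
        base = tuple(j for j in chain if j not in placements)
        merged[base] = merged.get(base, 0) + n
    return merged


# ------------------------------------------------------------- quantification

@dataclass(frozen=True)
class IsoformFrequencyTable:
    """Per-minigene isoform frequencies with parallel read-pair counts."""

    counts: pd.DataFrame
    total_pairs: pd.Series

    @property
    def frequencies(self) -> pd.DataFrame:
        return self.counts.div(self.total_pairs, axis=0)

    @property
    def isoforms(self) -> list:
        return [c for c in self.counts.columns if c != DISCARDED]

    def validate(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if not np.allclose(self.frequencies.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("frequency rows do not sum to 1")


def quantify_isoforms(
    reconstructions: Mapping[str, Mapping],
    min_pairs: int = 100,
    min_freq: float = 0.01,
    min_reads: int = 2,
) -> IsoformFrequencyTable:
    """Build the filtered isoform frequency table.

    ``reconstructions`` maps minigene barcode -> {isoform key: pair count}.
    Minigenes with fewer than ``min_pairs`` usable pairs are dropped. An
    isoform is kept when it reaches both ``min_freq`` and ``min_reads`` in at
    least one retained minigene; all others are pooled into 'discarded' so
    row counts are conserved.
    """
    counts = pd.DataFrame.from_dict(
        {bc: dict(c) for bc, c in reconstructions.items()}, orient="index"
    ).fillna(0).astype(int)
    counts = counts.sort_index(axis=1, key=lambda c: c.map(str))
    total = counts.sum(axis=1)
    counts = counts.loc[total >= min_pairs]
    total = total.loc[counts.index]
    if counts.empty:
        return IsoformFrequencyTable(
            counts.assign(**{DISCARDED: pd.Series(dtype=int)}), total
        )

    freq = counts.div(total, axis=0)
    keep = [
        iso
        for iso in counts.columns
        if ((counts[iso] >= min_reads) & (freq[iso] >= min_freq)).any()
    ]
    pooled = counts.drop(columns=keep).sum(axis=1)
    out = counts[keep].copy()
    out[DISCARDED] = out.get(DISCARDED, 0) + pooled
    return IsoformFrequencyTable(out, total)


def define_isoform_set(
    tables: Sequence[IsoformFrequencyTable],
    min_freq: float = 0.05,
    min_minigenes: int = 2,
) -> tuple[list, list[IsoformFrequencyTable]]:
    """Replicate-level isoform set: keep isoforms at >= min_freq in at least
    ``min_minigenes`` minigenes in any single replicate; pool the rest.

    The minigene count is evaluated within each replicate separately.
    """
    kept: set = set()
    for t in tables:
        freq = t.frequencies
        for iso in t.isoforms:
            if iso in freq.columns and (freq[iso] >= min_freq).sum() >= min_minigenes:
                kept.add(iso)
    kept_sorted = sorted(kept, key=str)
    out_tables = []
    for t in tables:
        cols = [c for c in kept_sorted if c in t.counts.columns]
        pooled = t.counts.drop(columns=cols + ([DISCARDED] if DISCARDED in t.counts else [])).sum(axis=1)
        new = t.counts[cols].copy()
        new[DISCARDED] = t.counts.get(DISCARDED, 0) + pooled
        out_tables.append(IsoformFrequencyTable(new, t.total_pairs))
    return kept_sorted, out_tables


# ------------------------------------------------------ usage and junction PSI

def splice_site_usage(
    table: IsoformFrequencyTable,
    structures: Mapping,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-minigene splice-site usage and per-site maximum over minigenes.

    ``structures`` maps each retained isoform key to its junction chain.
    Usage of a site in a minigene is the summed frequency of isoforms whose
    chains use the site, divided by the minigene's total isoform frequency.
    """
    freq = table.frequencies
    missing = [iso for iso in table.isoforms if iso not in structures]
    if missing:
        raise KeyError(f"no structure for isoforms {missing}")
    sites = sorted(
        {("donor", d) for iso in table.isoforms for d, _ in structures[iso]}
        | {("acceptor", a) for iso in table.isoforms for _, a in structures[iso]}
    )
    total = freq.sum(axis=1)
    usage = pd.DataFrame(0.0, index=freq.index, columns=pd.MultiIndex.from_tuples(sites) if sites else [])
    for side, pos in sites:
        users = [
            iso
            for iso in table.isoforms
            if any((side == "donor" and d == pos) or (side == "acceptor" and a == pos)
                   for d, a in structures[iso])
        ]
        usage[(side, pos)] = freq[users].sum(axis=1) / total
    return usage, usage.max(axis=0)


def junction_psi(
    counts: Mapping[Junction, float], lsv: Sequence[Junction]
) -> dict[Junction, float]:
    """Percent-selected-index of each junction within a local splicing variation."""
    if not lsv:
        raise ValueError("LSV is empty")
    vals = {j: float(counts.get(j, 0.0)) for j in lsv}
    if any(v < 0 for v in vals.values()):
        raise ValueError("negative junction counts")
    total = sum(vals.values())
    if total == 0:
        raise ValueError("all junction counts are zero; PSI undefined")
    return {j: v / total for j, v in vals.items()}


def count_chains(
    pairs: Iterable[ReadPairAlignment], ref: MinigeneReference, min_overhang: int = 10
) -> tuple[Counter, Counter]:
    """Reconstruct every pair; return (chain counts, rejection-reason counts)."""
    chains: Counter = Counter()
    rejected: Counter = Counter()
    for p in pairs:
        res = reconstruct_isoform(p, ref, min_overhang=min_overhang)
        if isinstance(res, Rejection):
            rejected[res] += 1
        else:
            chains[res] += 1
    return chains, rejected
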