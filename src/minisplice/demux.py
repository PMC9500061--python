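"""Barcode demultiplexing and variant-table filtering.

Two extraction modes mirror the two sequencing arms of a minigene screen:
long-read (CCS) DNA sequencing, where the barcode sits in the last 50 nt of
the read, and paired-end RNA sequencing, where read 1 carries the barcode
between two fixed restriction-site anchors. Extracted barcodes of 14-16 nt
are accepted, tolerating a single inserted or deleted base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .variants import MinigeneVariant, VariantCall

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_LEFT_ANCHOR = "TGCAGAATTC"
DEFAULT_RIGHT_ANCHOR = "GGATCC"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AnchorSpec:
    """Fixed sequences flanking the barcode, with a per-anchor mismatch budget."""

    left: str = DEFAULT_LEFT_ANCHOR
    right: str = DEFAULT_RIGHT_ANCHOR
    max_mismatch: int = 0
    barcode_lengths: tuple[int, ...] = (14, 15, 16)


def _match_at(seq: str, pattern: str, start: int, max_mismatch: int) -> bool:
    if start < 0 or start + len(pattern) > len(seq):
        return False
    mm = 0
    for a, b in zip(seq[start : start + len(pattern)], pattern):
        if a != b:
            mm += 1
            if mm > max_mismatch:
                return False
    return True


def _find_flanked(seq: str, anchors: AnchorSpec) -> str | None:
    """First barcode between the two anchors, scanning left to right."""
    for i in range(len(seq) - len(anchors.left) + 1):
        if not _match_at(seq, anchors.left, i, anchors.max_mismatch):
            continue
        inner = i + len(anchors.left)
        for bl in anchors.barcode_lengths:
            if _match_at(seq, anchors.right, inner + bl, anchors.max_mismatch):
                return seq[inner : inner + bl]
    return None


def extract_barcode_longread(
    read: str,
    anchors: AnchorSpec | None = None,
    search_window: int = 50,
    length_bounds: tuple[int, int] = (150, 1150),
) -> str | None:
    """Barcode from the last 50 nt of a long read, trying both strands.

    Reads outside the configured length bounds are no-calls. The forward
    strand is searched first; the first hit wins.
    """
    anchors = anchors or AnchorSpec()
    read = read.upper()
    if not length_bounds[0] <= len(read) <= length_bounds[1]:
        return None
    for seq in (read, reverse_complement(read)):
        hit = _find_flanked(seq[-search_window:], anchors)
        if hit is not None:
            return hit
    return None


def extract_barcode_pair(
    read1: str,
    anchors: AnchorSpec | None = None,
    min_length: int = 305,
) -> str | None:
    """Barcode from read 1 between the two restriction-site anchors.

    Each anchor tolerates one mismatch by default; the intervening segment
    must be 14-16 nt.
    """
    anchors = anchors or AnchorSpec(max_mismatch=1)
    read1 = read1.upper()
    if len(read1) < min_length:
        return None
    return _find_flanked(read1, anchors)


def filter_barcode_support(
    read_counts: Mapping[str, int], min_support: int = 4
) -> set[str]:
    """Barcodes supported by at least ``min_support`` CCS reads."""
    if any(c < 0 for c in read_counts.values()):
        raise ValueError("read counts must be >= 0")
    return {bc for bc, c in read_counts.items() if c >= min_support}


def penetrance_filter(
    calls: Sequence[VariantCall], af_cut: float = 0.8, max_low_frac: float = 0.25
) -> bool:
    """Keep a barcode unless too many of its calls have low penetrance.

    Discards (returns False) when strictly more than ``max_low_frac`` of the
    calls have AF < ``af_cut``; an empty call list (wild type) is kept.
    """
    if not calls:
        return True
    for c in calls:
        if not 0.0 <= c.af <= 1.0:
            raise ValueError(f"AF outside [0, 1]: {c.af}")
    low = sum(1 for c in calls if c.af < af_cut)
    return low / len(calls) <= max_low_frac


def exclude_large_indels(
    variants: Iterable[MinigeneVariant], max_indel: int = 10
) -> list[MinigeneVariant]:
    """Drop variants carrying any insertion/deletion of >= ``max_indel`` nt."""
    return [v for v in variants if v.max_indel_length() < max_indel]


def demultiplex(
    reads: Iterable[str],
    mode: str = "longread",
    anchors: AnchorSpec | None = None,
    **kwargs,
) -> dict[str, int]:
    """Count extracted barcodes over a read stream. Order-independent."""
    if mode == "longread":
        extract = lambda r: extract_barcode_longread(r, anchors, **kwargs)  # noqa: E731
    elif mode == "pair":
        extract = lambda r: extract_barcode_pair(r, anchors, **kwargs)  # noqa: E731
    else:
        raise ValueError(f"unknown mode {mode!r}")
    counts: dict[str, int] = {}
    for read in reads:
        bc = extract(read)
        if bc is not None:
            counts[bc] = counts.get(bc, 0) + 1
    return counts
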