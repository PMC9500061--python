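"""Splice-site strength scanning, mutation-driven site-gain prediction,
coding-potential classification, and joins against external predictors.

Site strength is scored with an additive position-weight (log-odds) model
over fixed windows: 9 nt for donors (GT required at window positions 4-5)
and 23 nt for acceptors (AG required at positions 19-20). The scorer is
pluggable; externally derived parameter tables (e.g. maximum-entropy
models) can be loaded from TSV, and a generic consensus-derived matrix is
built in for exploratory scans.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .reference import Chain, MinigeneReference
from .variants import Mutation

_BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(_BASES)}

DONOR_WIDTH = 9
ACCEPTOR_WIDTH = 23
# 0-based offsets of the obligate dinucleotide within each window
DONOR_GT = (3, 4)
ACCEPTOR_AG = (18, 19)


@dataclass(frozen=True)
class LogOddsScorer:
    """Additive per-position log-odds scoring of donor/acceptor windows."""

    donor: np.ndarray  # (9, 4), columns A C G T
    acceptor: np.ndarray  # (23, 4)

    def __post_init__(self) -> None:
        if self.donor.shape != (DONOR_WIDTH, 4) or self.acceptor.shape != (ACCEPTOR_WIDTH, 4):
            raise ValueError("donor matrix must be 9x4 and acceptor matrix 23x4")

    def width(self, side: str) -> int:
        return DONOR_WIDTH if side == "donor" else ACCEPTOR_WIDTH

    def matrix(self, side: str) -> np.ndarray:
        return self.donor if side == "donor" else self.acceptor

    def passes_filter(self, window: str, side: str) -> bool:
        i, j = DONOR_GT if side == "donor" else ACCEPTOR_AG
        need = "GT" if side == "donor" else "AG"
        return window[i] + window[j] == need

    def score(self, window: str, side: str) -> float:
        m = self.matrix(side)
        if len(window) != m.shape[0]:
            raise ValueError(f"window length {len(window)} != {m.shape[0]}")
        return float(sum(m[k, _IDX[b]] for k, b in enumerate(window)))

    @classmethod
    def from_tsv(cls, donor_path, acceptor_path) -> "LogOddsScorer":
        load = lambda p: pd.read_csv(p, sep="\t", index_col=0)[list(_BASES)].to_numpy(float)  # noqa: E731
        return cls(load(donor_path), load(acceptor_path))

    @classmethod
    def consensus(cls) -> "LogOddsScorer":
        """Generic metazoan splice-site consensus weights (built-in default).

        Log-odds of the classic donor MAG|GTRAGT and polypyrimidine-tract /
        YAG acceptor consensus against uniform background; adequate for
        ranking candidate sites, not a calibrated strength model.
        """
        def pwm(consensus_cols, weight=0.85):
            m = np.zeros((len(consensus_cols), 4))
            for k, allowed in enumerate(consensus_cols):
                if allowed == "N":
                    continue
                p_hit = weight / len(allowed)
                p_miss = (1 - weight) / (4 - len(allowed))
                for b in _BASES:
                    m[k, _IDX[b]] = np.log((p_hit if b in allowed else p_miss) / 0.25)
            return m

        donor = pwm(["AC", "A", "G", "G", "T", "AG", "A", "G", "T"])
        acceptor = pwm(["CT"] * 15 + ["N", "C", "A", "A", "G", "G", "N", "N"])
        return cls(donor, acceptor)


@dataclass(frozen=True)
class SpliceSiteWindow:
    side: str
    start: int  # 1-based window start on the scanned sequence
    window: str
    passes: bool
    score: float | None


def scan_splice_sites(
    seq: str,
    scorer: LogOddsScorer,
    sides: Sequence[str] = ("donor", "acceptor"),
) -> pd.DataFrame:
    """Slide fixed-width windows over ``seq``, flagging and scoring each.

    Windows failing the obligate GT/AG dinucleotide filter are emitted with
    ``passes=False`` and no score. Sequences shorter than the window give an
    empty frame.
    """
    seq = seq.upper()
    rows = []
    for side in sides:
        w = scorer.width(side)
        for start in range(len(seq) - w + 1):
            window = seq[start : start + w]
            ok = scorer.passes_filter(window, side) and set(window) <= set(_BASES)
            rows.append(
                {
                    "side": side,
                    "start": start + 1,
                    "window": window,
                    "passes": ok,
                    "score": scorer.score(window, side) if ok else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["side", "start", "window", "passes", "score"])


def canonical_site_scores(ref: MinigeneReference, scorer: LogOddsScorer) -> dict[tuple[str, int], float]:
    """Scores of the canonical donor/acceptor windows of the reference.

    The donor window places the GT of the downstream intron at window
    positions 4-5, so it starts 3 nt before the intron; the acceptor window
    places the terminal AG at positions 19-20, starting 18 nt before the
    exon. Sites whose windows fall off the sequence are skipped.
    """
    out: dict[tuple[str, int], float] = {}
    for d in ref.donor_sites:
        start = d - DONOR_GT[0] + 1  # window pos 4 (1-based) = first intron base d+1
        window = ref.sequence[start - 1 : start - 1 + DONOR_WIDTH]
        if len(window) == DONOR_WIDTH and scorer.passes_filter(window, "donor"):
            out[("donor", d)] = scorer.score(window, "donor")
    for a in ref.acceptor_sites:
        start = a - ACCEPTOR_AG[1] - 1  # window pos 20 = last intron base a-1
        window = ref.sequence[start - 1 : start - 1 + ACCEPTOR_WIDTH]
        if len(window) == ACCEPTOR_WIDTH and scorer.passes_filter(window, "acceptor"):
            out[("acceptor", a)] = scorer.score(window, "acceptor")
    return out


def mutation_site_gain(
    ref: MinigeneReference,
    scorer: LogOddsScorer,
    positions: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Scan all possible point substitutions for splice-site gain.

    For each position x alternative base, only windows overlapping the
    mutated position are re-scored (incremental rescoring). A record is
    emitted for every mutant window that passes the dinucleotide filter,
    with the WT window score (NaN when the WT window fails the filter), the
    delta, and whether the mutant score exceeds the canonical site of the
    same side at the nearest exon boundary.
    """
    canon = canonical_site_scores(ref, scorer)
    seq = ref.sequence
    rows = []
    for pos in positions if positions is not None else range(1, ref.length + 1):
        refbase = seq[pos - 1]
        for alt in _BASES:
            if alt == refbase:
                continue
            for side in ("donor", "acceptor"):
                w = scorer.width(side)
                for start in range(max(1, pos - w + 1), min(pos, ref.length - w + 1) + 1):
                    wt_window = seq[start - 1 : start - 1 + w]
                    k = pos - start
                    mut_window = wt_window[:k] + alt + wt_window[k + 1 :]
                    if not scorer.passes_filter(mut_window, side):
                        continue
                    mut_score = scorer.score(mut_window, side)
                    wt_ok = scorer.passes_filter(wt_window, side)
                    wt_score = scorer.score(wt_window, side) if wt_ok else np.nan
                    canon_side = {p: s for (sd, p), s in canon.items() if sd == side}
                    if canon_side:
                        nearest = min(canon_side, key=lambda p: abs(p - pos))
                        canon_score = canon_side[nearest]
                        exceeds = mut_score > canon_score
                    else:
                        nearest, canon_score, exceeds = None, np.nan, False
                    rows.append(
                        {
                            "position": pos,
                            "ref": refbase,
                            "alt": alt,
                            "side": side,
                            "window_start": start,
                            "mut_score": mut_score,
                            "wt_score": wt_score,
                            "delta": mut_score - wt_score if wt_ok else np.nan,
                            "canonical_site": nearest,
                            "canonical_score": canon_score,
                            "exceeds_canonical": exceeds,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "position", "ref", "alt", "side", "window_start", "mut_score",
            "wt_score", "delta", "canonical_site", "canonical_score",
            "exceeds_canonical",
        ],
    )


# ----------------------------------------------------------- coding potential

@dataclass(frozen=True)
class CodingClass:
    """Coding-potential category of an isoform relative to inclusion."""

    category: str  # in_frame | out_of_frame | ptc
    length_delta_mod3: int
    stop_codon_index: int | None  # codons translated before the stop
    protein_length_reference: int


def _codon_trim(seq: str) -> str:
    return seq[: len(seq) - len(seq) % 3]


def classify_coding(chain: Chain, ref: MinigeneReference) -> CodingClass:
    """Classify an isoform's ORF against the reference inclusion isoform.

    A mature-length difference not divisible by 3 is a frameshift
    (out_of_frame); frameshift takes precedence over an early stop. In-frame
    isoforms that terminate at a stop codon other than (and upstream of) the
    reference stop are PTC; everything else is in_frame — this includes
    isoforms shortened or extended but ending at the reference stop.
    """
    inclusion = ref.inclusion_chain
    mature_ref = ref.splice(inclusion)
    orf_ref = ref.to_mature_coordinate(ref.orf_start, inclusion)
    assert orf_ref is not None
    prot_ref = str(Seq(_codon_trim(mature_ref[orf_ref - 1 :])).translate(to_stop=True))
    ref_stop_genomic = ref.to_genomic_coordinate(orf_ref + 3 * len(prot_ref), inclusion)

    mature = ref.splice(chain)
    orf_m = ref.to_mature_coordinate(ref.orf_start, chain)
    if orf_m is None:
        raise ValueError("translation start is spliced out of this isoform")

    delta_mod3 = (len(mature) - len(mature_ref)) % 3
    if delta_mod3 != 0:
        return CodingClass("out_of_frame", delta_mod3, None, len(prot_ref))

    prot = str(Seq(_codon_trim(mature[orf_m - 1 :])).translate(to_stop=True))
    stop_mature = orf_m + 3 * len(prot)  # first base of the stop codon
    if stop_mature + 2 <= len(mature):
        stop_genomic = ref.to_genomic_coordinate(stop_mature, chain)
        if stop_genomic != ref_stop_genomic and len(prot) < len(prot_ref):
            return CodingClass("ptc", 0, len(prot), len(prot_ref))
    return CodingClass("in_frame", 0, len(prot), len(prot_ref))


def classify_isoform_set(
    chains: Mapping[object, Chain], ref: MinigeneReference
) -> pd.DataFrame:
    """Classify every isoform; the categories partition the set."""
    rows = []
    for name, chain in chains.items():
        cc = classify_coding(chain, ref)
        rows.append(
            {
                "isoform": name,
                "category": cc.category,
                "length_delta_mod3": cc.length_delta_mod3,
                "stop_codon_index": cc.stop_codon_index,
            }
        )
    return pd.DataFrame(rows, columns=["isoform", "category", "length_delta_mod3", "stop_codon_index"])


# ------------------------------------------------- external prediction joins

def assign_gain_loss(chain: Chain, ref: MinigeneReference) -> list[tuple[str, int, int]]:
    """Pair each non-canonical site of a chain with the canonical site it
    replaces (nearest canonical site of the same side), as (side, gained,
    lost) triples — the convention used to join against external gain/loss
    predictors that report site pairs.
    """
    donors = set(ref.donor_sites)
    acceptors = set(ref.acceptor_sites)
    out = []
    for d, a in chain:
        if d not in donors and donors:
            out.append(("donor", d, min(donors, key=lambda p: abs(p - d))))
        if a not in acceptors and acceptors:
            out.append(("acceptor", a, min(acceptors, key=lambda p: abs(p - a))))
    return out


def match_external_predictions(
    records: pd.DataFrame,
    associations: pd.DataFrame,
    max_position: int | None = None,
) -> pd.DataFrame:
    """Join external gain/loss site predictions with prevalence associations.

    ``records`` needs columns (mutation, gain_pos, loss_pos, gain_score,
    loss_score); ``associations`` needs (mutation, gain_pos, loss_pos,
    score). Records where the gain score does not exceed the loss score are
    dropped; the join is exact on (mutation, gain_pos, loss_pos).
    """
    for df, cols in (
        (records, ("mutation", "gain_pos", "loss_pos", "gain_score", "loss_score")),
        (associations, ("mutation", "gain_pos", "loss_pos", "score")),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise KeyError(f"missing columns {missing}")
    if max_position is not None:
        pos = pd.concat([records["gain_pos"], records["loss_pos"]])
        if ((pos < 1) | (pos > max_position)).any():
            raise ValueError("positions outside the reference; coordinate systems differ?")
    gains = records[records["gain_score"] > records["loss_score"]]
    merged = gains.merge(associations, on=["mutation", "gain_pos", "loss_pos"], how="inner")
    return merged.rename(columns={"score": "prevalence_score"})[
        ["mutation", "gain_pos", "loss_pos", "gain_score", "loss_score", "prevalence_score"]
    ]
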