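"""Mutation-isoform association via the prevalence score, plus positional
enrichment of splicing-affecting calls.

The prevalence score links a mutation to an isoform by multiplying two
conditional frequencies: (i) how often the mutation is present when the
isoform level is high (> 5% by default), and (ii) how often the isoform is
high when the mutation is present. A score of 1 means the carrier set and
the high set coincide; independent mutation/isoform give scores near the
product of their marginals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .isoforms import DISCARDED, IsoformFrequencyTable
from .variants import MinigeneVariant, Mutation


@dataclass(frozen=True)
class PrevalenceScore:
    """The two conditional frequencies and their product for one pair."""

    mutation: Mutation | None
    isoform: object
    f_mut_given_high: float | None
    f_high_given_mut: float | None
    score: float | None
    n_high: int
    n_mut: int
    n_both: int

    @property
    def defined(self) -> bool:
        return self.score is not None


def prevalence_score(
    mutation_present: pd.Series,
    isoform_freqs: pd.Series,
    high_cut: float = 0.05,
    mutation: Mutation | None = None,
    isoform=None,
) -> PrevalenceScore:
    """Score one mutation-isoform pair over a shared minigene set.

    'High' means isoform frequency strictly above ``high_cut``. When there
    are no carriers or no high minigenes the score is undefined (None),
    never 0: absence of evidence is not evidence of absence.
    """
    if len(mutation_present) == 0:
        raise ValueError("empty minigene set")
    present = mutation_present.astype(bool)
    freqs = isoform_freqs.reindex(present.index)
    if freqs.isna().any():
        raise ValueError("mutation flags and isoform frequencies must share their index")
    high = freqs > high_cut
    n_high = int(high.sum())
    n_mut = int(present.sum())
    n_both = int((high & present).sum())
    if n_high == 0 or n_mut == 0:
        return PrevalenceScore(mutation, isoform, None, None, None, n_high, n_mut, n_both)
    f1 = n_both / n_high
    f2 = n_both / n_mut
    return PrevalenceScore(mutation, isoform, f1, f2, f1 * f2, n_high, n_mut, n_both)


def associate_all(
    variants: Mapping[str, MinigeneVariant] | Sequence[MinigeneVariant],
    table: IsoformFrequencyTable | pd.DataFrame,
    isoforms: Sequence | None = None,
    min_score: float = 0.25,
    high_cut: float = 0.05,
) -> pd.DataFrame:
    """Score every (observed mutation, isoform) pair; keep score > min_score.

    ``isoforms`` defaults to every non-discarded column of the table (pass
    the cryptic subset to reproduce a cryptic-isoform association scan).
    Rows are sorted by descending score.
    """
    freq = table.frequencies if isinstance(table, IsoformFrequencyTable) else table
    if not isinstance(variants, Mapping):
        variants = {v.barcode: v for v in variants}
    barcodes = [bc for bc in freq.index if bc in variants]
    freq = freq.loc[barcodes]
    if isoforms is None:
        isoforms = [c for c in freq.columns if c != DISCARDED]

    observed = sorted({m for bc in barcodes for m in variants[bc].mutations})
    carrier = {
        m: pd.Series([m in variants[bc].mutations for bc in barcodes], index=barcodes)
        for m in observed
    }
    rows = []
    for iso in isoforms:
        col = freq[iso]
        for m in observed:
            ps = prevalence_score(carrier[m], col, high_cut=high_cut, mutation=m, isoform=iso)
            if ps.defined and ps.score > min_score:
                rows.append(
                    {
                        "mutation": m.label,
                        "isoform": iso,
                        "f_mut_given_high": ps.f_mut_given_high,
                        "f_high_given_mut": ps.f_high_given_mut,
                        "score": ps.score,
                        "n_high": ps.n_high,
                        "n_mut": ps.n_mut,
                        "n_both": ps.n_both,
                    }
                )
    out = pd.DataFrame(
        rows,
        columns=[
            "mutation", "isoform", "f_mut_given_high", "f_high_given_mut",
            "score", "n_high", "n_mut", "n_both",
        ],
    )
    return out.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 contingency table with odds ratio and two-sided Fisher exact P."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float


def positional_enrichment(
    affected_positions: Sequence[int],
    region: tuple[int, int],
    universe: Sequence[int],
) -> EnrichmentResult:
    """Fisher's exact test for enrichment of affected positions in a region.

    The 2x2 table crosses {affected, not affected} with {inside region,
    outside}; the region must be contained in the position universe.
    """
    universe_set = set(universe)
    affected = set(affected_positions)
    if not affected <= universe_set:
        raise ValueError("affected positions must be a subset of the universe")
    lo, hi = region
    in_region = {p for p in universe_set if lo <= p <= hi}
    if not in_region:
        raise ValueError("region contains no universe positions")
    a = len(affected & in_region)
    b = len(affected - in_region)
    c = len(in_region - affected)
    d = len(universe_set - in_region - affected)
    if b and c:
        odds = (a * d) / (b * c)
    else:
        odds = np.inf if a * d > 0 else 0.0
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(((a, b), (c, d)), float(odds), float(p))
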