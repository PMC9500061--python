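"""Synthetic minigene libraries with known ground-truth splicing effects.

The generator emulates the statistical structure of an error-prone-PCR
minigene screen: ~10,000 barcoded variants carrying Poisson-distributed
point mutations (mean 9.7 per variant, the screen's measured load) plus
~194 wild-type barcodes, read out in replicate experiments whose isoform
frequencies follow an additive-in-logit softmax model with sparse true
effects and multinomial read sampling.

One master seed drives everything; per-stage substreams are derived
deterministically, so a fixed seed yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import softmax

from .isoforms import ReadPairAlignment
from .reference import Chain, MinigeneReference
from .variants import MinigeneVariant, Mutation

ISOFORM_LABELS = (
    "inclusion",
    "skipping",
    "intron2-retention",
    "alt-exon2",
    "alt-exon3",
    "other",
)

# Baseline wild-type isoform frequencies: exon-2 inclusion dominates, with
# skipping, intron-2 retention and the two alternative 3'ss isoforms as
# minor species, matching the qualitative WT pattern of the CD19 reporter.
DEFAULT_WT_FREQS = (0.80, 0.06, 0.05, 0.03, 0.02, 0.04)

_STAGES = ("effects", "mutations", "barcodes", "support", "counts", "reads")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic screen."""

    n_variants: int = 10295
    n_wt: int = 194
    mutation_rate: float = 9.7
    indel_fraction: float = 0.10
    large_indel_fraction: float = 0.0
    effect_sparsity: float = 150 / 3600
    effect_scale: float = 2.0
    coverage_min: int = 100
    coverage_mean: float = 300.0
    coverage_shape: float = 5.0
    n_replicates: int = 2
    barcode_length: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mutation_rate <= 0:
            raise ValueError("mutation_rate must be > 0")
        if not 0.0 <= self.effect_sparsity <= 1.0:
            raise ValueError("effect_sparsity must be in [0, 1]")
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ValueError("indel_fraction must be in [0, 1]")
        if not 0.0 <= self.large_indel_fraction <= 1.0 - self.indel_fraction:
            raise ValueError("large_indel_fraction must fit alongside indel_fraction")
        if self.coverage_min < 0 or self.coverage_mean < self.coverage_min:
            raise ValueError("coverage_mean must be >= coverage_min >= 0")
        if self.n_variants < 0 or self.n_wt < 0 or self.n_replicates < 1:
            raise ValueError("counts must be non-negative, n_replicates >= 1")

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage substream of the master seed."""
        if stage not in _STAGES:
            raise KeyError(f"unknown stage {stage!r}")
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(len(_STAGES))[_STAGES.index(stage)]
        )


@dataclass(frozen=True)
class GroundTruth:
    """True additive softmax model generating the synthetic readout."""

    intercepts: np.ndarray
    effects: Mapping[Mutation, np.ndarray]
    isoform_labels: tuple[str, ...] = ISOFORM_LABELS

    def wt_frequencies(self) -> np.ndarray:
        return softmax(self.intercepts)

    def variant_logits(self, mutations: Sequence[Mutation]) -> np.ndarray:
        logits = self.intercepts.copy()
        for m in mutations:
            offset = self.effects.get(m)
            if offset is not None:
                logits = logits + offset
        return logits

    def variant_frequencies(self, mutations: Sequence[Mutation]) -> np.ndarray:
        return softmax(self.variant_logits(mutations))

    def single_mutation_delta(self, mutation: Mutation) -> np.ndarray:
        return self.variant_frequencies([mutation]) - self.wt_frequencies()


def _all_point_mutations(ref: MinigeneReference) -> list[Mutation]:
    out = []
    for pos in range(1, ref.length + 1):
        r = ref.sequence[pos - 1]
        for alt in "ACGT":
            if alt != r:
                out.append(Mutation(pos, r, alt))
    return out


def draw_ground_truth(
    ref: MinigeneReference,
    cfg: SimConfig,
    wt_frequencies: Sequence[float] = DEFAULT_WT_FREQS,
) -> GroundTruth:
    """Sample sparse true effects over all possible point substitutions."""
    rng = cfg.rng("effects")
    candidates = _all_point_mutations(ref)
    n_true = int(round(cfg.effect_sparsity * len(candidates)))
    chosen = rng.choice(len(candidates), size=n_true, replace=False)
    k = len(ISOFORM_LABELS)
    effects: dict[Mutation, np.ndarray] = {}
    for idx in sorted(chosen):
        mask = rng.random(k) < 0.3
        if not mask.any():
            mask[rng.integers(k)] = True
        vec = np.where(mask, rng.normal(0.0, cfg.effect_scale, size=k), 0.0)
        effects[candidates[idx]] = vec
    intercepts = np.log(np.asarray(wt_frequencies, dtype=float))
    intercepts = intercepts - intercepts.mean()
    return GroundTruth(intercepts=intercepts, effects=effects)


def _draw_barcodes(n: int, length: int, rng: np.random.Generator, retries: int = 50) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    bases = np.array(list("ACGT"))
    for _ in range(n):
        for attempt in range(retries + 1):
            bc = "".join(rng.choice(bases, size=length))
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
                break
        else:
            raise RuntimeError("barcode collision retry budget exhausted")
    return out


def _draw_mutation(ref: MinigeneReference, pos: int, rng: np.random.Generator,
                   cfg: SimConfig, spectrum: Mapping[str, Mapping[str, float]] | None) -> Mutation:
    u = rng.random()
    seq = ref.sequence
    r = seq[pos - 1]
    if u < cfg.indel_fraction + cfg.large_indel_fraction:
        length = (
            int(rng.integers(1, 4))
            if u < cfg.indel_fraction
            else int(rng.integers(10, 31))
        )
        if rng.random() < 0.5 and pos + length <= ref.length:  # deletion
            return Mutation(pos, seq[pos - 1 : pos + length], r)
        ins = "".join(rng.choice(list("ACGT"), size=length))
        return Mutation(pos, r, r + ins)
    alts = [b for b in "ACGT" if b != r]
    if spectrum is None:
        alt = alts[rng.integers(3)]
    else:
        w = np.array([spectrum[r].get(a, 0.0) for a in alts], dtype=float)
        alt = alts[rng.choice(3, p=w / w.sum())]
    return Mutation(pos, r, alt)


def generate_library(
    ref: MinigeneReference,
    cfg: SimConfig,
    spectrum: Mapping[str, Mapping[str, float]] | None = None,
    wt_frequencies: Sequence[float] = DEFAULT_WT_FREQS,
) -> tuple[list[MinigeneVariant], GroundTruth]:
    """Generate barcoded variants plus the ground-truth effect model.

    Mutation counts per mutated variant are Poisson(rate) truncated at >= 1;
    positions are uniform over the insert; the substitution spectrum is
    uniform over the three alternatives unless a spectrum table is given.
    """
    truth = draw_ground_truth(ref, cfg, wt_frequencies)
    rng = cfg.rng("mutations")
    barcodes = _draw_barcodes(cfg.n_variants + cfg.n_wt, cfg.barcode_length, cfg.rng("barcodes"))
    support_rng = cfg.rng("support")

    variants: list[MinigeneVariant] = []
    for i in range(cfg.n_variants):
        n_mut = 0
        while n_mut == 0:
            n_mut = int(rng.poisson(cfg.mutation_rate))
        positions = rng.choice(ref.length, size=min(n_mut, ref.length), replace=False) + 1
        muts = tuple(_draw_mutation(ref, int(p), rng, cfg, spectrum) for p in sorted(positions))
        support = 4 + int(support_rng.poisson(12))
        variants.append(
            MinigeneVariant(
                barcode=barcodes[i],
                mutations=muts,
                ccs_support=support,
                penetrances={m: 1.0 for m in muts},
            )
        )
    for j in range(cfg.n_wt):
        variants.append(
            MinigeneVariant(
                barcode=barcodes[cfg.n_variants + j],
                mutations=(),
                ccs_support=4 + int(support_rng.poisson(12)),
            )
        )
    return variants, truth


def simulate_isoform_counts(
    library: Sequence[MinigeneVariant],
    truth: GroundTruth,
    cfg: SimConfig,
) -> list[pd.DataFrame]:
    """Multinomial per-replicate read-pair counts for every variant.

    Coverage per variant and replicate is ``coverage_min`` plus a
    negative-binomial excess with mean ``coverage_mean - coverage_min`` and
    shape ``coverage_shape``. Replicates share the truth but are sampled
    independently.
    """
    rng = cfg.rng("counts")
    k = len(truth.isoform_labels)
    probs = np.empty((len(library), k))
    for i, v in enumerate(library):
        logits = truth.variant_logits(v.mutations)
        if not np.all(np.isfinite(logits)):
            raise ValueError(f"non-finite logits for barcode {v.barcode}")
        probs[i] = softmax(logits)

    excess_mean = cfg.coverage_mean - cfg.coverage_min
    tables = []
    for _ in range(cfg.n_replicates):
        if excess_mean > 0:
            p = cfg.coverage_shape / (cfg.coverage_shape + excess_mean)
            coverage = cfg.coverage_min + rng.negative_binomial(cfg.coverage_shape, p, size=len(library))
        else:
            coverage = np.full(len(library), cfg.coverage_min)
        counts = np.vstack(
            [rng.multinomial(int(c), pr) for c, pr in zip(coverage, probs)]
        )
        tables.append(
            pd.DataFrame(counts, index=[v.barcode for v in library], columns=list(truth.isoform_labels))
        )
    return tables


def frequencies_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalise a count table into isoform frequencies."""
    total = counts.sum(axis=1)
    if (total == 0).any():
        raise ValueError("minigene with zero reads cannot be normalised")
    return counts.div(total, axis=0)


def simulate_read_pairs(
    ref: MinigeneReference,
    chain: Chain,
    n_pairs: int,
    read1_length: int = 260,
    read2_length: int = 320,
    max_start_jitter: int = 8,
    rng: np.random.Generator | None = None,
) -> list[ReadPairAlignment]:
    """Error-free read-pair alignments sampled from a mature transcript.

    Mate 1 starts at the 5' end of the transcript (plus a small uniform
    jitter) on the forward strand; mate 2 covers the 3' end on the reverse
    strand, emulating an amplicon sequenced from both ends. Alignments are
    returned as match/skip operation lists against the unspliced reference.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    segments = ref.exonic_segments(chain)
    mature_len = sum(b - a + 1 for a, b in segments)
    pairs = []
    for _ in range(n_pairs):
        j1 = int(rng.integers(0, max_start_jitter + 1))
        j2 = int(rng.integers(0, max_start_jitter + 1))
        m1 = _mature_interval_to_ops(segments, j1, min(j1 + read1_length, mature_len))
        start2 = max(mature_len - read2_length - j2, 0)
        m2 = _mature_interval_to_ops(segments, start2, mature_len - j2)
        pairs.append(
            ReadPairAlignment(
                start1=m1[0], ops1=m1[1], strand1="+",
                start2=m2[0], ops2=m2[1], strand2="-",
            )
        )
    return pairs


def _mature_interval_to_ops(
    segments: Sequence[tuple[int, int]], m_start: int, m_end: int
) -> tuple[int, list[tuple[str, int]]]:
    """Convert a 0-based half-open mature interval to (genomic start, ops)."""
    if m_end <= m_start:
        raise ValueError("empty mature interval")
    ops: list[tuple[str, int]] = []
    g_start = None
    offset = 0
    prev_seg_end = None
    for a, b in segments:
        seg_len = b - a + 1
        lo = max(m_start - offset, 0)
        hi = min(m_end - offset, seg_len)
        if lo < hi:
            if g_start is None:
                g_start = a + lo
            elif prev_seg_end is not None:
                ops.append(("N", a - prev_seg_end - 1))
            ops.append(("M", hi - lo))
            prev_seg_end = b
        offset += seg_len
    assert g_start is not None
    return g_start, ops
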