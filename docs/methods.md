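# Methods

## Scope and data model

The package analyses barcoded minigene splicing screens: a three-exon /
two-intron reporter (~1.2 kb, modelled on *CD19* exons 1–3), ~10,000
mutagenised variants each tagged by a 15-nt barcode, and paired DNA/RNA
readouts linked through that barcode. All coordinates are 1-based along the
cloned insert. Junctions are written (donor, acceptor) = (last exonic base
upstream, first exonic base downstream); an empty junction chain denotes the
unspliced transcript.

## Synthetic library generator

The generator reproduces the statistical structure the analysis assumes,
not raw sequencer output (no base-call errors, no PCR chimeras).

Study-condition defaults of `SimConfig`:

| parameter | default | rationale |
|---|---|---|
| `n_variants` / `n_wt` | 10,295 / 194 | library composition of the screen being emulated |
| `mutation_rate` | 9.7 | measured mean mutations per variant; per-variant counts are Poisson truncated at ≥ 1 (only the mean is reported, and a "mutated" variant has at least one mutation) |
| `indel_fraction` | 0.10 | error-prone PCR produces mostly substitutions with a minority of short (1–3 nt) indels; the exact spectrum is not reported, so this is a fixed, realistic choice |
| `large_indel_fraction` | 0 | ≥ 10 nt indels only generated on request, to exercise the downstream exclusion filter |
| `effect_sparsity` | 150/3600 | ≈ 150 of the 3L possible point substitutions carry true effects, the order of magnitude recovered by the screen relative to its library size |
| `effect_scale` | 2.0 | s.d. of non-zero logit offsets; 2 logits moves an 80% isoform to ~35% — the magnitude of splice-site-disrupting mutations |
| coverage | min 100, mean 300, NB shape 5 | every minigene passes the ≥ 100 read-pair filter; overdispersed like real per-barcode depth |
| `n_replicates` | 2 | two independent multinomial readouts sharing the truth |

Substitutions draw the alternative base uniformly unless a spectrum table is
supplied (the mutagenesis kit's transition bias is not quantified).
Ground-truth effect vectors pick each of the six categories with probability
0.3 (at least one) and draw offsets from N(0, `effect_scale`). Wild-type
intercepts are the log of (0.80, 0.06, 0.05, 0.03, 0.02, 0.04) — an
inclusion-dominated pattern matching the reporter's wild-type behaviour.
One master seed is expanded into fixed per-stage substreams
(`effects`, `mutations`, `barcodes`, `support`, `counts`, `reads`), so a
fixed seed yields bit-identical libraries and counts.

The reference generator writes GT/AG at every intron boundary, an ATG at
`orf_start`, one in-frame TAA near the end of the last exon, and rewrites
any earlier in-frame stop of the inclusion reading frame (wobble base → C),
so the inclusion isoform always has a clean ORF for coding classification.

Simulated read pairs mirror an amplicon sequenced from both ends: mate 1
covers the transcript 5′ end (260 nt, the post-trimming read-1 length),
mate 2 the 3′ end. Mate 2 defaults to 320 nt so that, with this layout's
300-nt third exon, both junctions of every major isoform fall inside the
pair — the property the reconstruction oracle tests rely on.

## Isoform reconstruction rules

A read pair is usable when (i) mates map on opposite strands, (ii) mates
agree on splice junctions: no mate may align over positions the other mate
skips, and distinct junctions may not skip overlapping intervals, and
(iii) each mate is anchored with ≥ 10 aligned nt inside the constitutive
exon on its side (first exon for the left mate, last exon for the right).
We read the published 10-nt rule as this anchoring requirement — a mate
ending a few nucleotides into a constitutive exon cannot assert a junction —
which is the junction-overhang convention of spliced aligners. Rejections
are typed (improper-orientation, inconsistent-overlap,
insufficient-overhang), never silent.

Isoform filtering follows the screen's thresholds: minigenes need ≥ 100
usable pairs; an isoform is kept when it reaches ≥ 1% frequency *and* ≥ 2
read pairs in at least one minigene; the replicate-level isoform set keeps
isoforms at ≥ 5% in ≥ 2 minigenes of any single replicate (the ≥ 2-minigene
count is evaluated within each replicate, not pooled — the published
phrasing is ambiguous and per-replicate is the stricter reading). Everything
filtered is pooled into an explicit `discarded` column so frequency rows
always sum to 1 and counts are conserved.

The RT artefact that drops an internal exon-2 fragment flanked by an 8-nt
repeat is merged by folding all eight shift-equivalent exclusion junctions
into the parent isoform. The fragment interval is a configurable
`ArtifactSpec` (the endogenous coordinates are not printed); a chain
matching two placements at once is an error, not a guess.

## Effect model

Six response categories: the five major isoforms plus `other`. Minigenes
whose summed cryptic frequency exceeds 5% are removed; for the rest the
cryptic mass becomes `other`. Each minigene contributes six
pseudo-observations weighted by its measured frequencies — mathematically
identical to frequency-weighted multinomial cross-entropy — with unit
per-minigene weight by default (read-depth weighting is available but off,
since no depth weighting is described for the original analysis). The
penalised fit uses scikit-learn's saga solver (L1, intercepts unpenalised,
full six-column parameterisation; the penalty resolves the softmax gauge,
and all reported quantities are on the gauge-invariant frequency scale).
Default tolerance 1e-6 and max 10,000 epochs; non-convergence raises with
diagnostics rather than returning silently. Intercept-only designs use the
closed-form multinomial MLE.

Cross-validation: a single seeded K-fold split (default 10); the score is
the mean over folds and isoforms of the Pearson correlation between
predicted and measured test-fold frequencies; ties break toward larger C
(weaker penalty); default grid {0.01, 0.1, 1, 10, 100} around the published
optimum C = 10. Folds too small to define a correlation contribute NaN and
are ignored; if no fold defines one (leave-one-out), the largest C is
returned.

Splicing-affecting calls: per isoform and replicate, cutoffs are the
empirical 2.5%/97.5% order-statistic quantiles (linear interpolation) of
the wild-type minigene frequencies; a warning is issued below 40 wild-type
minigenes. "Beyond the cutoff" is strict inequality — a prediction exactly
at the quantile is not called — and both replicates must agree in
direction.

The occurrence-accuracy procedure refits the model with a mutation's
single-mutation minigenes held out and a controlled number of
multi-mutation carriers included (up to 7 random draws per occurrence
level), reporting the spread of prediction minus direct measurement.

## Prevalence score and enrichment

prevalence = P(mutation | isoform high) × P(isoform high | mutation), with
"high" strictly above 5%. Undefined scores (no carriers, or no high
minigenes) are reported as missing, never 0. The association scan keeps
pairs strictly above 0.25 by default. Positional enrichment uses the
two-sided Fisher exact test (scipy) on the {affected, not} × {in region,
not} table; the tests verify it against exhaustive hypergeometric
enumeration for all tables with margins ≤ 12.

## Sequence features

Splice-site strength is an additive position-weight (log-odds) score over
9-nt donor windows (obligate GT at window positions 4–5) and 23-nt acceptor
windows (obligate AG at 19–20). The scorer is pluggable: externally derived
parameter tables (e.g. maximum-entropy models) load from TSV; a generic
consensus-derived matrix is built in for exploratory scans and all tests
use toy matrices — scores are for ranking sites under one scorer, not
calibrated strengths. The all-mutations gain scan rescores only windows
overlapping the mutated base (verified against a full rescan) and flags
mutant windows exceeding the canonical site of the same side at the nearest
exon boundary (a documented choice; "any canonical site" would be the
alternative).

Coding classification compares each isoform to the reference inclusion
isoform: a mature-length difference not divisible by 3 is `out_of_frame`
(frameshift takes precedence over any early stop, keeping the three
categories mutually exclusive); in-frame isoforms terminating at a stop
codon other than — and upstream of — the reference stop are `ptc`;
everything else, including shortened or extended proteins that end at the
reference stop, is `in_frame`. No NMD 50-nt rule is applied. External
gain/loss predictions join on exact (mutation, gained position, lost
position) and require gain score > loss score.

## What the synthetic data does and does not show

Passing tests demonstrate that the pipeline's rules and estimator behave
correctly under the generative model they assume: additive logit effects,
independent multinomial sampling, error-free barcodes and alignments. Real
screens add alignment artefacts, barcode cross-talk, PCR jackpotting and
overdispersion between replicates (an optional extra-dispersion knob is
deliberately absent from the defaults); recovery correlations measured here
are therefore upper bounds on real-data performance. Test and acceptance
problem sizes (2,000 mutated minigenes for recovery and null calibration;
50-mutation rescoring oracles) are the package's chosen desk-scale working
points: large enough for stable statistics, small enough to run routinely.

## Known limitations

- No epistasis: the additive model cannot represent interaction effects.
- Variant calling (alignment, haplotype assembly) is consumed, not
  reimplemented; inputs are VCF-like call tables.
- Barcodes are matched as exact strings after extraction; no fuzzy merging
  of 14/15/16-nt variants of the same barcode.
- The coding classifier assumes a single ORF defined on the inclusion
  isoform and the standard nuclear genetic code.
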