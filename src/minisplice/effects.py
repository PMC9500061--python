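"""Single-mutation splicing-effect inference by additive softmax regression.

Each minigene carries several mutations, so single-mutation effects cannot
be read off directly. The model assumes per-mutation logit offsets that add
up across a minigene's mutations:

    p(minigene m) = softmax(b0 + sum_{j in m} beta_j)

over six splicing categories (five major isoforms plus a lumped 'other').
The measured isoform frequencies serve as fractional multinomial targets:
each minigene contributes one pseudo-observation per category, weighted by
its measured frequency, which is identical to frequency-weighted
cross-entropy. An L1 penalty with inverse strength C (intercepts
unpenalised) keeps the coefficient matrix sparse; C is chosen by
cross-validation on held-out minigenes.

The module follows the Model / Results convention: build a
``SplicingEffectModel`` from an isoform frequency table plus the barcode ->
mutation map, call ``fit`` (or ``fit_cv``) and work with the returned
``SplicingEffectResults``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import softmax
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from .isoforms import DISCARDED, IsoformFrequencyTable
from .variants import MinigeneVariant, Mutation

MAJOR_ISOFORMS = ("inclusion", "skipping", "intron2-retention", "alt-exon2", "alt-exon3")
OTHER = "other"
RESPONSE_CATEGORIES = MAJOR_ISOFORMS + (OTHER,)

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


class ConvergenceError(RuntimeError):
    """Raised when the penalised fit does not converge within max_iter."""


@dataclass(frozen=True)
class DesignMatrix:
    """Binary minigene x mutation incidence with 6-category responses."""

    incidence: sparse.csr_matrix
    response: np.ndarray
    barcodes: tuple[str, ...]
    mutations: tuple[Mutation, ...]
    weights: np.ndarray
    categories: tuple[str, ...] = RESPONSE_CATEGORIES

    @property
    def n_minigenes(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_mutations(self) -> int:
        return self.incidence.shape[1]


def build_design(
    table: IsoformFrequencyTable | pd.DataFrame,
    variants: Mapping[str, MinigeneVariant] | Sequence[MinigeneVariant],
    cryptic_cut: float = 0.05,
    weights: pd.Series | None = None,
) -> DesignMatrix:
    """Assemble the regression design from a frequency table and variant map.

    Minigenes whose summed cryptic frequency (everything outside the five
    major isoforms) exceeds ``cryptic_cut`` are removed; for the rest the
    cryptic mass is lumped into 'other'. Columns are every mutation observed
    in at least one retained minigene.
    """
    freq = table.frequencies if isinstance(table, IsoformFrequencyTable) else table
    if not isinstance(variants, Mapping):
        variants = {v.barcode: v for v in variants}
    missing = [bc for bc in freq.index if bc not in variants]
    if missing:
        raise KeyError(f"barcodes missing from variant map: {missing[:5]}")

    major = [c for c in MAJOR_ISOFORMS if c in freq.columns]
    cryptic_mass = freq.drop(columns=major).sum(axis=1)
    keep = cryptic_mass <= cryptic_cut
    freq = freq.loc[keep]

    response = np.zeros((len(freq), len(RESPONSE_CATEGORIES)))
    for k, cat in enumerate(MAJOR_ISOFORMS):
        if cat in freq.columns:
            response[:, k] = freq[cat].to_numpy()
    response[:, -1] = cryptic_mass.loc[keep].to_numpy()
    totals = response.sum(axis=1)
    if not np.allclose(totals, 1.0, atol=1e-6):
        raise ValueError("response rows do not sum to 1")
    response /= totals[:, None]

    barcodes = tuple(freq.index)
    mutation_set = sorted({m for bc in barcodes for m in variants[bc].mutations})
    col = {m: j for j, m in enumerate(mutation_set)}
    rows, cols = [], []
    for i, bc in enumerate(barcodes):
        for m in variants[bc].mutations:
            rows.append(i)
            cols.append(col[m])
    incidence = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(barcodes), len(mutation_set))
    )
    w = (
        np.ones(len(barcodes))
        if weights is None
        else weights.reindex(list(barcodes)).to_numpy(dtype=float)
    )
    return DesignMatrix(incidence, response, barcodes, tuple(mutation_set), w)


def _fit_penalised_softmax(
    design: DesignMatrix, C: float, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Weighted-pseudo-observation L1 multinomial fit; returns (b0, beta, iters)."""
    if C <= 0:
        raise ValueError("C must be > 0")
    n, K = design.response.shape
    if design.n_mutations == 0:
        # intercept-only: the penalised MLE is the weighted mean frequency
        p = np.average(design.response, axis=0, weights=design.weights)
        b0 = np.log(np.clip(p, 1e-300, None))
        return b0 - b0.max(), np.zeros((0, K)), 0
    X = design.incidence
    w = (design.weights[:, None] * design.response).ravel()
    keep = w > 0
    X_exp = X[np.repeat(np.arange(n), K)][keep]
    y_exp = np.tile(np.arange(K), n)[keep]
    w_exp = w[keep]
    present = np.unique(y_exp)

    clf = LogisticRegression(
        l1_ratio=1.0, C=C, solver="saga", fit_intercept=True,
        tol=tol, max_iter=max_iter, random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(X_exp, y_exp, sample_weight=w_exp)
        except ConvergenceWarning as exc:  # pragma: no cover - diagnostics path
            raise ConvergenceError(
                f"L1 softmax fit did not converge in {max_iter} iterations (C={C})"
            ) from exc
    coef = np.zeros((K, design.n_mutations))
    intercept = np.full(K, -np.inf)
    if len(present) == 2:
        # sklearn collapses two classes to one coefficient row
        coef[present[0]] = -clf.coef_[0] / 2
        coef[present[1]] = clf.coef_[0] / 2
        intercept[present[0]] = -clf.intercept_[0] / 2
        intercept[present[1]] = clf.intercept_[0] / 2
    else:
        coef[present] = clf.coef_
        intercept[present] = clf.intercept_
    n_iter = int(np.max(clf.n_iter_))
    return intercept, coef.T, n_iter


class SplicingEffectModel:
    """Additive L1-softmax model of single-mutation splicing effects."""

    def __init__(self, design: DesignMatrix):
        self.design = design

    @classmethod
    def from_tables(
        cls,
        table: IsoformFrequencyTable | pd.DataFrame,
        variants: Mapping[str, MinigeneVariant] | Sequence[MinigeneVariant],
        cryptic_cut: float = 0.05,
        weights: pd.Series | None = None,
    ) -> "SplicingEffectModel":
        return cls(build_design(table, variants, cryptic_cut=cryptic_cut, weights=weights))

    def fit(
        self, C: float = 10.0, tol: float = 1e-6, max_iter: int = 10_000
    ) -> "SplicingEffectResults":
        if self.design.n_minigenes == 0:
            raise ValueError("empty design")
        intercepts, coef, n_iter = _fit_penalised_softmax(self.design, C, tol, max_iter)
        return SplicingEffectResults(self, intercepts, coef, C, n_iter)

    def fit_cv(
        self,
        grid: Sequence[float] = DEFAULT_C_GRID,
        folds: int = 10,
        seed: int = 0,
        tol: float = 1e-4,
        max_iter: int = 10_000,
    ) -> "SplicingEffectResults":
        """Choose C by K-fold cross-validation, then refit on all minigenes.

        The selection score is the mean, over folds and isoforms, of the
        Pearson correlation between predicted and measured test-fold
        frequencies; ties break toward larger C (weaker penalty).
        """
        C, report = cross_validate_C(
            self.design, folds=folds, grid=grid, seed=seed, tol=tol, max_iter=max_iter
        )
        res = self.fit(C=C, tol=tol, max_iter=max_iter)
        res.cv_report = report
        return res


def cross_validate_C(
    design: DesignMatrix,
    folds: int = 10,
    grid: Sequence[float] = DEFAULT_C_GRID,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 10_000,
) -> tuple[float, pd.DataFrame]:
    """K-fold CV over the penalty grid; every minigene is tested exactly once."""
    if len(grid) == 0:
        raise ValueError("penalty grid is empty")
    if design.n_minigenes < folds:
        raise ValueError("need at least as many minigenes as folds")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for C in grid:
        for fold, (train, test) in enumerate(kf.split(np.arange(design.n_minigenes))):
            sub = DesignMatrix(
                design.incidence[train],
                design.response[train],
                tuple(design.barcodes[i] for i in train),
                design.mutations,
                design.weights[train],
                design.categories,
            )
            b0, beta, _ = _fit_penalised_softmax(sub, C, tol, max_iter)
            logits = design.incidence[test] @ beta + b0
            pred = softmax(logits, axis=1)
            meas = design.response[test]
            for k, cat in enumerate(design.categories):
                if np.std(meas[:, k]) == 0 or np.std(pred[:, k]) == 0:
                    r = np.nan
                else:
                    r = float(np.corrcoef(pred[:, k], meas[:, k])[0, 1])
                rows.append({"C": C, "fold": fold, "isoform": cat, "pearson_r": r})
    report = pd.DataFrame(rows)
    score = report.groupby("C")["pearson_r"].mean()
    if score.isna().all():  # e.g. leave-one-out: correlation undefined per fold
        chosen = max(grid)
    else:
        best = score.max()
        chosen = max(c for c in grid if score.loc[c] >= best - 1e-12)
    return float(chosen), report


@dataclass
class SplicingEffectResults:
    """Fitted intercepts and per-mutation logit offsets, plus predictions."""

    model: SplicingEffectModel
    intercepts: np.ndarray
    coefficients_: np.ndarray  # (n_mutations, K)
    C: float
    n_iter: int
    cv_report: pd.DataFrame | None = None

    @property
    def categories(self) -> tuple[str, ...]:
        return self.model.design.categories

    @property
    def mutations(self) -> tuple[Mutation, ...]:
        return self.model.design.mutations

    @property
    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coefficients_,
            index=[m.label for m in self.mutations],
            columns=list(self.categories),
        )

    @property
    def baseline(self) -> pd.Series:
        """Predicted wild-type isoform frequencies, softmax of the intercepts."""
        return pd.Series(softmax(self.intercepts), index=list(self.categories))

    def predict(self, mutation_sets: Iterable[Sequence[Mutation]]) -> pd.DataFrame:
        """Predicted frequencies for minigenes given their mutation sets."""
        col = {m: j for j, m in enumerate(self.mutations)}
        rows = []
        for muts in mutation_sets:
            logits = self.intercepts.copy()
            for m in muts:
                j = col.get(m)
                if j is not None:
                    logits = logits + self.coefficients_[j]
            rows.append(softmax(logits))
        return pd.DataFrame(rows, columns=list(self.categories))

    def predict_design(self) -> pd.DataFrame:
        """In-sample predicted frequencies for the fitted design."""
        logits = self.model.design.incidence @ self.coefficients_ + self.intercepts
        return pd.DataFrame(
            softmax(logits, axis=1),
            index=list(self.model.design.barcodes),
            columns=list(self.categories),
        )

    def predict_single(self, mutation: Mutation) -> tuple[pd.Series, pd.Series, bool]:
        """Frequencies and deltas of a hypothetical single-mutation minigene.

        Returns (frequencies, deltas, known); an unknown mutation yields the
        baseline with zero deltas and known=False.
        """
        col = {m: j for j, m in enumerate(self.mutations)}
        j = col.get(mutation)
        base = self.baseline
        if j is None:
            return base, base * 0.0, False
        freqs = pd.Series(
            softmax(self.intercepts + self.coefficients_[j]), index=list(self.categories)
        )
        return freqs, freqs - base, True

    def single_mutation_table(self, mutations: Sequence[Mutation] | None = None) -> pd.DataFrame:
        """Predicted single-mutation frequencies and deltas, one row per mutation."""
        muts = self.mutations if mutations is None else mutations
        records = []
        for m in muts:
            freqs, deltas, known = self.predict_single(m)
            rec = {"mutation": m.label, "known": known}
            for cat in self.categories:
                rec[cat] = freqs[cat]
                rec[f"delta_{cat}"] = deltas[cat]
            records.append(rec)
        return pd.DataFrame(records).set_index("mutation")

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefficients_))

    def summary(self) -> str:
        d = self.model.design
        lines = [
            "Additive L1-softmax splicing-effect model",
            "=" * 48,
            f"minigenes:            {d.n_minigenes}",
            f"mutations (features): {d.n_mutations}",
            f"categories:           {', '.join(d.categories)}",
            f"inverse penalty C:    {self.C:g}",
            f"non-zero coefficients:{self.n_nonzero} / {self.coefficients_.size}",
            f"saga iterations:      {self.n_iter}",
            "",
            "baseline (WT) frequencies:",
        ]
        for cat, f in self.baseline.items():
            lines.append(f"  {cat:<20s} {f:8.4f}")
        if self.cv_report is not None:
            score = self.cv_report.groupby("C")["pearson_r"].mean()
            lines.append("")
            lines.append("cross-validation mean Pearson r by C:")
            for c, s in score.items():
                mark = " *" if c == self.C else ""
                lines.append(f"  C={c:<8g} {s:8.4f}{mark}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "categories": list(self.categories),
            "C": self.C,
            "intercepts": self.intercepts.tolist(),
            "mutations": [m.label for m in self.mutations],
            "coefficients": self.coefficients_.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# ------------------------------------------------- WT quantiles and the caller

@dataclass(frozen=True)
class WTDistribution:
    """Empirical WT isoform-frequency sample with two-sided quantile cutoffs."""

    sample: pd.DataFrame
    q: tuple[float, float] = (0.025, 0.975)
    lower: pd.Series = field(init=False)
    upper: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        if self.sample.empty:
            raise ValueError("empty WT set")
        lo = self.sample.quantile(self.q[0], interpolation="linear")
        hi = self.sample.quantile(self.q[1], interpolation="linear")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)


def wt_quantiles(
    wt_table: pd.DataFrame, q: tuple[float, float] = (0.025, 0.975)
) -> WTDistribution:
    """Order-statistic quantiles of the empirical WT frequency distribution."""
    if wt_table.empty:
        raise ValueError("empty WT set")
    if len(wt_table) < 40:
        warnings.warn(
            f"only {len(wt_table)} WT minigenes; quantile cutoffs will be noisy",
            stacklevel=2,
        )
    return WTDistribution(wt_table.copy(), q)


def call_splicing_affecting(
    pred_rep1: pd.DataFrame,
    pred_rep2: pd.DataFrame,
    wt: WTDistribution,
) -> pd.DataFrame:
    """Replicate-concordant empirical-quantile caller.

    A (mutation, isoform) pair is affected when both replicate predictions
    lie strictly outside the WT [lower, upper] interval on the same side.
    Inputs are single-mutation frequency tables indexed by mutation label
    with one column per isoform.
    """
    common = pred_rep1.index.intersection(pred_rep2.index)
    isoforms = [c for c in wt.sample.columns if c in pred_rep1.columns and c in pred_rep2.columns]
    rows = []
    for mut in common:
        for iso in isoforms:
            p1, p2 = pred_rep1.loc[mut, iso], pred_rep2.loc[mut, iso]
            lo, hi = wt.lower[iso], wt.upper[iso]
            up = p1 > hi and p2 > hi
            down = p1 < lo and p2 < lo
            rows.append(
                {
                    "mutation": mut,
                    "isoform": iso,
                    "pred_rep1": p1,
                    "pred_rep2": p2,
                    "direction": "up" if up else ("down" if down else "none"),
                    "affected": up or down,
                }
            )
    return pd.DataFrame(rows)


def occurrence_accuracy(
    table: IsoformFrequencyTable | pd.DataFrame,
    variants: Mapping[str, MinigeneVariant],
    target_mutations: Sequence[Mutation],
    occurrences: Sequence[int] = tuple(range(1, 11)),
    max_repeats: int = 7,
    C: float = 10.0,
    cryptic_cut: float = 0.05,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 10_000,
) -> pd.DataFrame:
    """Prediction error of single-mutation effects versus mutation occurrence.

    For each target mutation and each occurrence level, the model is refitted
    on minigenes excluding the mutation's single-mutation carriers and
    including the stated number of randomly chosen multi-mutation carriers
    (up to ``max_repeats`` random draws per level). The error is the
    difference between the model's single-mutation prediction and the direct
    measurement (mean frequency over the held-out single-mutation minigenes).
    """
    freq = table.frequencies if isinstance(table, IsoformFrequencyTable) else table
    rng = np.random.default_rng(seed)
    rows = []
    for mut in target_mutations:
        singles = [
            bc for bc in freq.index
            if variants[bc].mutations == (mut,)
        ]
        if not singles:
            raise ValueError(f"no single-mutation minigenes for {mut.label}")
        multi = [
            bc for bc in freq.index
            if mut in variants[bc].mutations and len(variants[bc].mutations) > 1
        ]
        base = [bc for bc in freq.index if mut not in variants[bc].mutations]
        direct = freq.loc[singles].mean()
        for occ in occurrences:
            if occ > len(multi):
                warnings.warn(
                    f"occurrence {occ} exceeds availability for {mut.label}; skipped",
                    stacklevel=2,
                )
                continue
            n_rep = 1 if occ == 0 else min(max_repeats, len(multi))
            for rep in range(n_rep):
                chosen = list(rng.choice(multi, size=occ, replace=False)) if occ else []
                train = freq.loc[base + chosen]
                model = SplicingEffectModel.from_tables(train, variants, cryptic_cut=cryptic_cut)
                res = model.fit(C=C, tol=tol, max_iter=max_iter)
                pred, _, _ = res.predict_single(mut)
                for iso in res.categories:
                    if iso in direct.index:
                        rows.append(
                            {
                                "mutation": mut.label,
                                "occurrence": occ,
                                "repeat": rep,
                                "isoform": iso,
                                "predicted": pred[iso],
                                "direct": direct[iso],
                                "error": pred[iso] - direct[iso],
                            }
                        )
    return pd.DataFrame(rows)


def occurrence_error_curve(detail: pd.DataFrame, isoform: str = "inclusion") -> pd.Series:
    """Standard deviation of (prediction - measurement) per occurrence level."""
    sub = detail[detail["isoform"] == isoform]
    return sub.groupby("occurrence")["error"].apply(lambda e: float(np.sqrt(np.mean(e**2))))
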