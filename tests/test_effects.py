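import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import softmax

import minisplice as ms
from minisplice.effects import (
    RESPONSE_CATEGORIES,
    SplicingEffectModel,
    SplicingEffectResults,
    build_design,
    cross_validate_C,
    occurrence_accuracy,
    occurrence_error_curve,
)
from minisplice.variants import MinigeneVariant, Mutation

M1 = Mutation(10, "A", "C")
M2 = Mutation(20, "G", "T")


def mk_freq(rows):
    df = pd.DataFrame(rows).T
    return df.div(df.sum(axis=1), axis=0)


def wt_variant(bc):
    return MinigeneVariant(bc, ())


class TestBuildDesign:
    def mk_inputs(self, cryptic):
        bc = "ACGTACGTACGTACG"
        rows = {
            bc: {"inclusion": 0.8 - cryptic, "skipping": 0.1, "intron2-retention": 0.05,
                 "alt-exon2": 0.03, "alt-exon3": 0.02, "crypticX": cryptic},
        }
        return pd.DataFrame(rows).T, {bc: MinigeneVariant(bc, (M1,))}

    def test_cryptic_above_cut_excluded(self):
        freq, variants = self.mk_inputs(0.06)
        design = build_design(freq, variants)
        assert design.n_minigenes == 0

    def test_cryptic_below_cut_lumped_into_other(self):
        freq, variants = self.mk_inputs(0.03)
        design = build_design(freq, variants)
        assert design.n_minigenes == 1
        other = design.response[0, RESPONSE_CATEGORIES.index("other")]
        assert other == pytest.approx(0.03)

    def test_wt_row_all_zero(self):
        bc = "ACGTACGTACGTACG"
        freq = pd.DataFrame({bc: {"inclusion": 1.0}}).T
        design = build_design(freq, {bc: wt_variant(bc)})
        assert design.incidence.nnz == 0

    def test_missing_barcode_is_error(self):
        bc = "ACGTACGTACGTACG"
        freq = pd.DataFrame({bc: {"inclusion": 1.0}}).T
        with pytest.raises(KeyError):
            build_design(freq, {})


class TestFit:
    def test_intercept_only_matches_pooled_mean(self):
        bcs = ["ACGTACGTACGT" + "".join(t) for t in itertools.product("ACGT", repeat=3)][:8]
        rng = np.random.default_rng(0)
        rows = {}
        for bc in bcs:
            f = rng.dirichlet([40, 5, 4, 2, 2, 3])
            rows[bc] = dict(zip(RESPONSE_CATEGORIES, f))
        freq = pd.DataFrame(rows).T
        variants = {bc: wt_variant(bc) for bc in bcs}
        res = SplicingEffectModel.from_tables(freq, variants, cryptic_cut=1.0).fit(C=10.0, tol=1e-8)
        np.testing.assert_allclose(
            res.baseline.to_numpy(), freq.mean().to_numpy(), atol=1e-4
        )

    def test_strong_penalty_zeroes_coefficients(self, small_screen):
        cfg, library, truth, tables = small_screen
        freq = ms.frequencies_from_counts(tables[0])
        model = SplicingEffectModel.from_tables(freq, ms.variant_map(library), cryptic_cut=1.0)
        res = model.fit(C=1e-4, tol=1e-6)
        assert np.abs(res.coefficients_).max() < 1e-3

    def test_matches_dense_grid_search_on_two_category_toy(self):
        """The penalised optimum agrees with an exhaustive grid search.

        Two categories, one mutation, three minigenes with fractional
        targets: the problem reduces to a penalised binary logistic fit of
        the logit difference t = a + x b with penalty |b| / C, scanned on a
        dense (a, b) grid (the oracle never calls the fitting routine).
        """
        C = 10.0
        f = np.array([0.30, 0.70, 0.65])  # P(category 2)
        x = np.array([0.0, 1.0, 1.0])

        def objective(a, b):
            t = a + x * b
            ll = f * np.log1p(np.exp(-t)) + (1 - f) * np.log1p(np.exp(t))
            return ll.sum() + abs(b) / C

        a_star = b_star = 0.0
        lo_a, hi_a = -4.0, 4.0
        lo_b, hi_b = -4.0, 4.0
        for _ in range(3):  # coarse-to-fine grid refinement
            ga = np.linspace(lo_a, hi_a, 201)
            gb = np.linspace(lo_b, hi_b, 201)
            vals = np.array([[objective(a, b) for b in gb] for a in ga])
            ia, ib = np.unravel_index(np.argmin(vals), vals.shape)
            a_star, b_star = ga[ia], gb[ib]
            da, db = (hi_a - lo_a) / 200, (hi_b - lo_b) / 200
            lo_a, hi_a = a_star - 2 * da, a_star + 2 * da
            lo_b, hi_b = b_star - 2 * db, b_star + 2 * db
        p_star = 1 / (1 + np.exp(-(a_star + x * b_star)))

        bcs = ["ACGTACGTACGTAC" + s for s in "GTA"]
        freq = pd.DataFrame(
            {bc: {"inclusion": 1 - fi, "skipping": fi} for bc, fi in zip(bcs, f)}
        ).T
        variants = {
            bcs[0]: wt_variant(bcs[0]),
            bcs[1]: MinigeneVariant(bcs[1], (M1,)),
            bcs[2]: MinigeneVariant(bcs[2], (M1,)),
        }
        res = SplicingEffectModel.from_tables(freq, variants).fit(C=C, tol=1e-10)
        pred = res.predict_design()["skipping"].to_numpy()
        np.testing.assert_allclose(pred, p_star, atol=1e-3)

    def test_empty_design_rejected(self):
        bc = "ACGTACGTACGTACG"
        freq = pd.DataFrame({bc: {"inclusion": 0.5, "crypticX": 0.5}}).T
        model = SplicingEffectModel.from_tables(freq, {bc: wt_variant(bc)})
        with pytest.raises(ValueError, match="empty"):
            model.fit()


def mk_results(intercepts, coef, mutations):
    """Results object with prescribed parameters (no fitting)."""
    bc = "ACGTACGTACGTACG"
    freq = pd.DataFrame({bc: dict(zip(RESPONSE_CATEGORIES, softmax(intercepts)))}).T
    design = build_design(freq, {bc: MinigeneVariant(bc, tuple(mutations))}, cryptic_cut=1.0)
    model = SplicingEffectModel(design)
    return SplicingEffectResults(model, np.asarray(intercepts, float),
                                 np.asarray(coef, float), C=10.0, n_iter=0)


class TestPrediction:
    def test_zero_coefficients_give_zero_delta(self):
        res = mk_results(np.zeros(6), np.zeros((1, 6)), [M1])
        _, deltas, known = res.predict_single(M1)
        assert known and (deltas == 0).all()

    def test_closed_form_two_category(self):
        # beta0 = 0, beta = (ln 3, 0, ...) on category 1 -> 0.75 vs baseline 1/6
        coef = np.zeros((1, 6))
        coef[0, 0] = np.log(3)
        res = mk_results(np.zeros(6), coef, [M1])
        freqs, _, _ = res.predict_single(M1)
        expected = softmax([np.log(3), 0, 0, 0, 0, 0])
        np.testing.assert_allclose(freqs.to_numpy(), expected, rtol=1e-12)

    def test_double_mutant_logits_add(self):
        rng = np.random.default_rng(1)
        coef = rng.normal(size=(2, 6))
        b0 = rng.normal(size=6)
        res = mk_results(b0, coef, [M1, M2])
        pred = res.predict([[M1, M2]]).iloc[0].to_numpy()
        np.testing.assert_allclose(pred, softmax(b0 + coef[0] + coef[1]), rtol=1e-12)

    def test_gauge_invariance(self):
        rng = np.random.default_rng(2)
        coef = rng.normal(size=(1, 6))
        b0 = rng.normal(size=6)
        r1 = mk_results(b0, coef, [M1])
        r2 = mk_results(b0 + 3.7, coef + 1.1, [M1])
        f1, _, _ = r1.predict_single(M1)
        f2, _, _ = r2.predict_single(M1)
        np.testing.assert_allclose(f1.to_numpy(), f2.to_numpy(), rtol=1e-12)

    def test_unknown_mutation_flagged_baseline(self):
        res = mk_results(np.zeros(6), np.zeros((1, 6)), [M1])
        freqs, deltas, known = res.predict_single(M2)
        assert not known and (deltas == 0).all()
        np.testing.assert_allclose(freqs.to_numpy(), res.baseline.to_numpy())


class TestCrossValidation:
    def test_single_value_grid_returned(self, small_screen):
        cfg, library, truth, tables = small_screen
        freq = ms.frequencies_from_counts(tables[0]).iloc[:60]
        design = build_design(freq, ms.variant_map(library), cryptic_cut=1.0)
        C, report = cross_validate_C(design, folds=5, grid=[3.3], tol=1e-3)
        assert C == 3.3
        assert set(report["C"]) == {3.3}

    def test_each_minigene_tested_once_loo(self, small_screen):
        cfg, library, truth, tables = small_screen
        freq = ms.frequencies_from_counts(tables[0]).iloc[:12]
        design = build_design(freq, ms.variant_map(library), cryptic_cut=1.0)
        C, report = cross_validate_C(design, folds=12, grid=[10.0], tol=1e-3)
        assert report["fold"].nunique() == 12

    def test_sparse_truth_prefers_intermediate_penalty(self, small_screen):
        """Degenerate penalties score worse than a finite, moderate C."""
        cfg, library, truth, tables = small_screen
        freq = ms.frequencies_from_counts(tables[0])
        design = build_design(freq, ms.variant_map(library), cryptic_cut=1.0)
        C, report = cross_validate_C(design, folds=5, grid=[1e-4, 10.0], tol=1e-3)
        assert C == 10.0

    def test_empty_grid_rejected(self, small_screen):
        cfg, library, truth, tables = small_screen
        freq = ms.frequencies_from_counts(tables[0]).iloc[:20]
        design = build_design(freq, ms.variant_map(library), cryptic_cut=1.0)
        with pytest.raises(ValueError, match="grid"):
            cross_validate_C(design, grid=[])


class TestWTQuantiles:
    def test_known_distribution_quantiles(self):
        rng = np.random.default_rng(3)
        sample = pd.DataFrame({"inclusion": rng.beta(80, 20, size=2000)})
        wt = ms.wt_quantiles(sample)
        from scipy.stats import beta
        assert wt.lower["inclusion"] == pytest.approx(beta.ppf(0.025, 80, 20), abs=0.01)
        assert wt.upper["inclusion"] == pytest.approx(beta.ppf(0.975, 80, 20), abs=0.01)

    def test_constant_sample(self):
        sample = pd.DataFrame({"inclusion": [0.8] * 50})
        wt = ms.wt_quantiles(sample)
        assert wt.lower["inclusion"] == wt.upper["inclusion"] == 0.8

    def test_extreme_quantiles_are_min_max(self):
        rng = np.random.default_rng(4)
        sample = pd.DataFrame({"x": rng.random(100)})
        wt = ms.wt_quantiles(sample, q=(0.0, 1.0))
        assert wt.lower["x"] == sample["x"].min()
        assert wt.upper["x"] == sample["x"].max()

    def test_empty_rejected_small_warns(self):
        with pytest.raises(ValueError):
            ms.wt_quantiles(pd.DataFrame({"x": []}))
        with pytest.warns(UserWarning, match="WT"):
            ms.wt_quantiles(pd.DataFrame({"x": [0.1, 0.2, 0.3]}))


class TestCaller:
    def mk_wt(self):
        rng = np.random.default_rng(5)
        return ms.wt_quantiles(pd.DataFrame({"inclusion": 0.8 + 0.02 * rng.standard_normal(200)}))

    def test_concordant_up_called(self):
        wt = self.mk_wt()
        hi = wt.upper["inclusion"] + 0.05
        p1 = pd.DataFrame({"inclusion": [hi]}, index=["A10C"])
        calls = ms.call_splicing_affecting(p1, p1 * 1.001, wt)
        row = calls.iloc[0]
        assert row["affected"] and row["direction"] == "up"

    def test_discordant_directions_not_called(self):
        wt = self.mk_wt()
        p1 = pd.DataFrame({"inclusion": [wt.upper["inclusion"] + 0.05]}, index=["A10C"])
        p2 = pd.DataFrame({"inclusion": [wt.lower["inclusion"] - 0.05]}, index=["A10C"])
        calls = ms.call_splicing_affecting(p1, p2, wt)
        assert not calls.iloc[0]["affected"]

    def test_exactly_at_cutoff_not_called(self):
        wt = self.mk_wt()
        p = pd.DataFrame({"inclusion": [wt.upper["inclusion"]]}, index=["A10C"])
        calls = ms.call_splicing_affecting(p, p, wt)
        assert not calls.iloc[0]["affected"]


@pytest.fixture(scope="module")
def planted_screen(ref):
    """Small screen plus single-mutation minigenes for one strong mutation."""
    cfg = ms.SimConfig(n_variants=120, n_wt=40, seed=23, coverage_mean=250,
                       effect_sparsity=0.01, effect_scale=2.5)
    library, truth = ms.generate_library(ref, cfg)
    target = max(truth.effects, key=lambda m: np.abs(truth.effects[m]).sum())
    # ensure carriers and single-mutation minigenes for the target
    extra = []
    rng = np.random.default_rng(99)
    for i in range(12):
        bc = "".join(rng.choice(list("ACGT"), size=15))
        other = library[i].mutations[:3]
        muts = (target,) + tuple(m for m in other if m.position != target.position)
        extra.append(ms.MinigeneVariant(bc, muts, ccs_support=10))
    singles = []
    for i in range(4):
        bc = "".join(rng.choice(list("ACGT"), size=15))
        singles.append(ms.MinigeneVariant(bc, (target,), ccs_support=10))
    full = library + extra + singles
    counts = ms.simulate_isoform_counts(full, truth, cfg)[0]
    freq = ms.frequencies_from_counts(counts)
    return freq, ms.variant_map(full), target, truth


class TestOccurrenceAccuracy:
    def test_error_decreases_with_occurrence(self, planted_screen):
        freq, variants, target, truth = planted_screen
        detail = occurrence_accuracy(
            freq, variants, [target], occurrences=(0, 1, 8), max_repeats=5,
            cryptic_cut=1.0, tol=1e-3, seed=1,
        )
        curve = occurrence_error_curve(detail, isoform="inclusion")
        assert curve[8] <= curve[0]

    def test_occurrence_zero_is_baseline(self, planted_screen):
        freq, variants, target, truth = planted_screen
        detail = occurrence_accuracy(
            freq, variants, [target], occurrences=(0,), max_repeats=3,
            cryptic_cut=1.0, tol=1e-3,
        )
        assert detail["repeat"].nunique() == 1  # single refit at occurrence 0
        sub = detail[detail["isoform"] == "inclusion"]
        # prediction equals the refit WT-baseline frequency, far from the
        # direct single-mutation measurement for a strong mutation
        assert sub["predicted"].nunique() == 1

    def test_unavailable_occurrence_skipped_with_warning(self, planted_screen):
        freq, variants, target, truth = planted_screen
        with pytest.warns(UserWarning, match="availability"):
            detail = occurrence_accuracy(
                freq, variants, [target], occurrences=(500,), cryptic_cut=1.0, tol=1e-3
            )
        assert detail.empty
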