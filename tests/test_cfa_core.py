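import dataclasses
import itertools
import math

import numpy as np
import pytest

import sembeddings as se
from sembeddings.cfa_core import (
    HEYWOOD_BOUND,
    CFAFit,
    ModelSpec,
    classify_fit,
    fit_cfa,
    fit_indices,
    implied_matrix,
    modification_indices,
    ridge_repair,
)
from sembeddings.corpus_io import SquareMatrix

from _oracle import oracle_fit_1f, random_onefactorish_matrix, triad_loadings
from conftest import random_spec_and_population as _random_spec_and_population


class TestImpliedMatrix:
    def test_one_factor_products(self):
        spec = ModelSpec.single_factor(("a", "b", "c"))
        params = {
            "lambda:a:F1": 0.8, "lambda:b:F1": 0.7, "lambda:c:F1": 0.6,
            "theta:a:a": 1 - 0.64, "theta:b:b": 1 - 0.49, "theta:c:c": 1 - 0.36,
        }
        M = implied_matrix(spec, params).values
        assert M[0, 1] == pytest.approx(0.56)
        assert M[0, 2] == pytest.approx(0.48)
        assert M[1, 2] == pytest.approx(0.42)
        np.testing.assert_allclose(np.diag(M), 1.0)

    def test_zero_loadings_give_identity(self):
        spec = ModelSpec.single_factor(("a", "b", "c"))
        params = {f"lambda:{i}:F1": 0.0 for i in "abc"}
        params |= {f"theta:{i}:{i}": 1.0 for i in "abc"}
        np.testing.assert_allclose(implied_matrix(spec, params).values, np.eye(3))

    def test_two_factor_cross_block_entry(self):
        ids = ("a", "b", "c", "d", "e", "f")
        spec = ModelSpec(ids, ("F1", "F2"), {"F1": ids[:3], "F2": ids[3:]})
        params = {f"lambda:{i}:F1": 0.8 for i in ids[:3]}
        params |= {f"lambda:{i}:F2": 0.8 for i in ids[3:]}
        params |= {f"theta:{i}:{i}": 0.36 for i in ids}
        params["phi:F1:F2"] = 0.5
        M = implied_matrix(spec, params).values
        assert M[0, 3] == pytest.approx(0.8 * 0.5 * 0.8)


class TestFitCFA:
    def test_triad_matches_closed_form(self):
        R = np.array([[1, 0.56, 0.48], [0.56, 1, 0.42], [0.48, 0.42, 1.0]])
        S = SquareMatrix(R, ("a", "b", "c"))
        fit = fit_cfa(S, ModelSpec.single_factor(("a", "b", "c")))
        expected = triad_loadings(0.56, 0.48, 0.42)
        assert expected == pytest.approx((0.8, 0.7, 0.6))
        assert fit.df == 0
        assert fit.chisq == pytest.approx(0.0, abs=1e-8)
        for item, lam in zip("abc", expected):
            assert fit.estimates[f"lambda:{item}:F1"] == pytest.approx(lam, abs=1e-6)
        assert math.isnan(fit.rmsea) and math.isnan(fit.tli)

    def test_population_matrix_recovered_exactly(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            spec, S, truth = _random_spec_and_population(rng)
            fit = fit_cfa(S, spec)
            assert fit.converged
            assert fit.F_ml < 1e-10
            for name, val in truth.items():
                assert fit.estimates[name] == pytest.approx(val, abs=1e-6), name

    def test_chisq_scales_linearly_in_pseudo_n(self):
        rng = np.random.default_rng(1)
        S = SquareMatrix(random_onefactorish_matrix(rng, 5), tuple("abcde"))
        spec = ModelSpec.single_factor(tuple("abcde"))
        f1 = fit_cfa(S, spec, n_pseudo=5001)
        f2 = fit_cfa(S, spec, n_pseudo=10001)
        assert f2.chisq == pytest.approx(2 * f1.chisq, rel=1e-6)
        assert f2.chisq == pytest.approx((f2.n_pseudo - 1) * f2.F_ml, abs=1e-9)
        # incremental indices depend on N only through the df offsets, which
        # wash out as N grows; SRMR is N-free and must match exactly
        assert f2.cfi == pytest.approx(f1.cfi, abs=1e-3)
        assert f2.tli == pytest.approx(f1.tli, abs=5e-3)
        assert f2.srmr == pytest.approx(f1.srmr, abs=1e-9)
        # RMSEA satisfies its defining identity in F and N exactly ...
        assert f2.rmsea == pytest.approx(
            math.sqrt(max(f2.F_ml - f2.df / (f2.n_pseudo - 1), 0) / f2.df), abs=1e-12
        )
        # ... whereas at a FIXED chi-square the formula scales by 1/sqrt(2)
        # when the sample doubles
        S_id = np.eye(5)
        *_, r1 = fit_indices(300.0, 5, 1000.0, 10, 5001, S_id, S_id)
        *_, r2 = fit_indices(300.0, 5, 1000.0, 10, 10001, S_id, S_id)
        assert r2 == pytest.approx(r1 / np.sqrt(2), rel=1e-9)

    def test_agrees_with_independent_sem_implementation(self):
        rng = np.random.default_rng(2024)
        n_checked = 0
        for _ in range(20):
            p = int(rng.integers(4, 9))
            S = SquareMatrix(random_onefactorish_matrix(rng, p), tuple(f"i{j}" for j in range(p)))
            spec = ModelSpec.single_factor(S.axis_ids)
            fit = fit_cfa(S, spec, n_pseudo=10_000)
            ref = oracle_fit_1f(S.values, 10_000)
            assert fit.chisq == pytest.approx(ref["chisq"], abs=1e-3 * max(1, ref["chisq"]))
            for idx in ("cfi", "tli", "srmr", "rmsea"):
                assert fit.indices()[idx] == pytest.approx(ref[idx], abs=1e-3), idx
            lam = np.array([fit.estimates[f"lambda:{i}:F1"] for i in S.axis_ids])
            np.testing.assert_allclose(lam, ref["loadings"], atol=1e-3)
            n_checked += 1
        assert n_checked == 20

    def test_heywood_item_is_reported_not_fatal(self):
        # item 'a' correlates far beyond what a common factor + positive
        # uniqueness can produce
        R = np.array(
            [
                [1.0, 0.95, 0.93, 0.90],
                [0.95, 1.0, 0.55, 0.50],
                [0.93, 0.55, 1.0, 0.52],
                [0.90, 0.50, 0.52, 1.0],
            ]
        )
        S = SquareMatrix(R, tuple("abcd"))
        fit = fit_cfa(S, ModelSpec.single_factor(tuple("abcd")))
        assert "a" in fit.heywood
        assert fit.estimates["theta:a:a"] == pytest.approx(HEYWOOD_BOUND, abs=1e-10)

    def test_singular_input_is_ridge_repaired(self):
        lam = np.array([0.8, 0.7, 0.6])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        R4 = np.zeros((4, 4))
        R4[:3, :3] = R
        R4[3, :3] = R4[:3, 3] = R[0, :3]  # item d duplicates item a
        R4[3, 3] = 1.0
        R4[0, 3] = R4[3, 0] = 1.0
        S = SquareMatrix(R4, tuple("abcd"))
        fit = fit_cfa(S, ModelSpec.single_factor(tuple("abcd")))
        assert fit.ridge_delta > 0
        assert np.isfinite(fit.chisq)

    def test_model_with_more_parameters_than_moments_rejected(self):
        with pytest.raises(ValueError, match="free parameters"):
            ModelSpec.single_factor(("a", "b"))


class TestFitIndices:
    def test_perfect_fit_boundary(self):
        S = np.eye(4)
        cfi, tli, srmr, rmsea = fit_indices(0.0, 2, 1000.0, 6, 10_000, S, S)
        assert (cfi, rmsea, srmr) == (1.0, 0.0, 0.0)

    def test_t_equal_df_gives_zero_rmsea(self):
        S = np.eye(4)
        *_, rmsea = fit_indices(2.0, 2, 1000.0, 6, 10_000, S, S)
        assert rmsea == 0.0

    def test_textbook_substitution(self):
        S = np.eye(4)
        cfi, tli, srmr, rmsea = fit_indices(300.0, 2, 1000.0, 6, 10_000, S, S)
        assert cfi == pytest.approx(1 - 298 / 994, abs=1e-9)
        assert tli == pytest.approx(0.10060, abs=1e-5)
        assert rmsea == pytest.approx(0.12207, abs=1e-5)

    def test_df_zero_reports_not_applicable(self):
        S = np.eye(3)
        _, tli, _, rmsea = fit_indices(0.0, 0, 100.0, 3, 10_000, S, S)
        assert math.isnan(tli) and math.isnan(rmsea)

    def test_srmr_includes_diagonal_residuals(self):
        S = np.eye(2)
        sigma = np.array([[0.9, 0.0], [0.0, 1.0]])
        *_, srmr, _ = fit_indices(1.0, 1, 10.0, 1, 100, S, sigma)
        assert srmr == pytest.approx(math.sqrt(0.1**2 / 3), abs=1e-12)


class TestModificationIndices:
    def _misfit_setup(self, value=0.2):
        # 5 items: in a 4-item model, freeing a residual pair and freeing its
        # complement are equivalent models, so the top MI would be tied
        lam = np.array([0.8, 0.75, 0.65, 0.6, 0.5])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        R[0, 1] = R[1, 0] = lam[0] * lam[1] + value
        S = SquareMatrix(R, tuple("vwxyz"))
        spec = ModelSpec.single_factor(tuple("vwxyz"))
        return S, spec, fit_cfa(S, spec)

    def test_free_parameters_are_excluded_from_candidates(self):
        S, spec, fit = self._misfit_setup()
        freed = spec.with_freed("residual_cov", "v", "w")
        fit2 = fit_cfa(S, freed)
        table = modification_indices(S, freed, fit2, "score")
        assert ("v", "w") not in {(r.lhs, r.rhs) for r in table.rows}

    def test_injected_residual_pair_is_top_ranked(self):
        S, spec, fit = self._misfit_setup(0.2)
        for method in ("score", "refit"):
            table = modification_indices(S, spec, fit, method)
            top = table.top()
            assert (top.lhs, top.rhs) == ("v", "w")
            assert top.rank == 1
            assert all(r.mi >= 0 for r in table.rows)
            assert [r.mi for r in table.rows] == sorted(
                (r.mi for r in table.rows), reverse=True
            )

    def test_refit_mi_equals_nested_chisq_difference(self):
        S, spec, fit = self._misfit_setup(0.15)
        table = modification_indices(S, spec, fit, "refit")
        top = table.top()
        freed_fit = fit_cfa(S, spec.with_freed("residual_cov", top.lhs, top.rhs))
        assert top.mi == pytest.approx(fit.chisq - freed_fit.chisq, abs=1e-6)
        # freeing the right parameter restores perfect fit at population level
        assert freed_fit.chisq == pytest.approx(0.0, abs=1e-6)

    def test_score_mi_tracks_refit_mi_for_top_candidate(self):
        rng = np.random.default_rng(99)
        for _ in range(5):
            value = rng.uniform(0.1, 0.25)
            S, spec, fit = self._misfit_setup(value)
            top_score = modification_indices(S, spec, fit, "score").top()
            top_refit = modification_indices(S, spec, fit, "refit").top()
            assert (top_score.lhs, top_score.rhs) == (top_refit.lhs, top_refit.rhs)
            assert top_score.mi == pytest.approx(top_refit.mi, rel=0.10)


class TestClassifyFit:
    @staticmethod
    def _fit_with(cfi, tli, srmr, rmsea):
        return CFAFit(
            estimates={}, F_ml=0.0, chisq=0.0, df=2, n_pseudo=10_000,
            cfi=cfi, tli=tli, srmr=srmr, rmsea=rmsea,
            baseline_chisq=1.0, baseline_df=6, converged=True, n_iter=1,
            heywood=(), grad_norm=0.0,
        )

    @pytest.mark.parametrize(
        "indices,expected",
        [
            ((0.95, 0.93, 0.03, 0.05), "adequate"),
            ((0.89, 0.88, 0.03, 0.05), "misfit"),
            ((0.89, 0.92, 0.03, 0.05), "adequate"),
        ],
    )
    def test_published_rule_examples(self, indices, expected):
        verdict = classify_fit(self._fit_with(*indices))
        assert verdict.verdict == expected

    def test_full_truth_table_of_poor_flag_combinations(self):
        good = {"cfi": 0.95, "tli": 0.95, "srmr": 0.03, "rmsea": 0.03}
        bad = {"cfi": 0.80, "tli": 0.80, "srmr": 0.15, "rmsea": 0.15}
        for combo in itertools.product([False, True], repeat=4):
            vals = {
                k: (bad[k] if flag else good[k])
                for k, flag in zip(("cfi", "tli", "srmr", "rmsea"), combo)
            }
            verdict = classify_fit(self._fit_with(**vals))
            assert verdict.n_poor == sum(combo)
            assert verdict.verdict == ("misfit" if sum(combo) >= 2 else "adequate")

    def test_nan_index_counts_as_not_poor_but_is_flagged(self):
        fit = self._fit_with(0.85, float("nan"), 0.15, float("nan"))
        verdict = classify_fit(fit)
        assert verdict.n_poor == 2  # only cfi and srmr can be judged
        assert set(verdict.not_applicable) == {"tli", "rmsea"}

    def test_custom_cutoffs_are_respected(self):
        fit = self._fit_with(0.93, 0.93, 0.05, 0.05)
        assert classify_fit(fit, (0.95, 0.04)).verdict == "misfit"


class TestRidgeRepair:
    def test_well_conditioned_matrix_untouched(self):
        R = np.array([[1.0, 0.3], [0.3, 1.0]])
        out, delta = ridge_repair(R)
        assert delta == 0.0
        np.testing.assert_array_equal(out, R)

    def test_singular_matrix_repaired_to_pd_unit_diagonal(self):
        R = np.ones((3, 3))
        out, delta = ridge_repair(R)
        assert delta > 0
        assert np.linalg.eigvalsh(out)[0] > 0
        np.testing.assert_allclose(np.diag(out), 1.0)
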