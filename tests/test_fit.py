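"""Affinity conversion, OLS model fitting, leave-one-out stability, and
external prediction, cross-checked against scikit-learn and closed forms."""

import numpy as np
import pytest

from liece.chem_io import EnergyTableRow
from liece.energy import EnergyTerms
from liece.fit import (FitError, FitStatistics, LieceModel, VARIANTS,
                       evaluate_external, fit_liece, fit_statistics, ki_to_dg,
                       loo_cv, predict_dg)
from liece.synthetic import TableSpec, gen_energy_table


def rows_from_arrays(X, y):
    return [EnergyTableRow(ligand_id=f"L{i}", dE_vdw=float(x[0]),
                           dE_coul=float(x[1]), dG_solv=float(x[2]),
                           dg_exp=float(t))
            for i, (x, t) in enumerate(zip(X, y))]


NOISELESS = TableSpec(alpha=0.2, beta=-0.03, gamma=-0.05, delta=-3.0,
                      noise_sd=0.0, n=20, seed=11)


class TestKiConversion:
    @pytest.mark.parametrize("ki,expected", [
        (10 ** -8.27, -11.27),
        (1.0, 0.0),
        (10 ** -10.0, -13.63),
    ])
    def test_reported_endpoints(self, ki, expected):
        assert ki_to_dg(ki) == pytest.approx(expected, abs=0.01)

    def test_nonpositive_ki_rejected(self):
        with pytest.raises(ValueError):
            ki_to_dg(0.0)
        with pytest.raises(ValueError):
            ki_to_dg(-1e-9)


class TestFitLiece:
    def test_noiseless_coefficients_recovered(self):
        model = fit_liece(gen_energy_table(NOISELESS), "full_int")
        assert model.alpha == pytest.approx(0.2, abs=1e-8)
        assert model.beta == pytest.approx(-0.03, abs=1e-8)
        assert model.gamma == pytest.approx(-0.05, abs=1e-8)
        assert model.delta == pytest.approx(-3.0, abs=1e-7)
        assert model.fit.r2 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_matches_sklearn_linear_regression(self, variant):
        sklearn = pytest.importorskip("sklearn.linear_model")
        rows = gen_energy_table(TableSpec(noise_sd=1.0, n=40, seed=5))
        model = fit_liece(rows, variant)
        terms = (["dE_vdw", "dE_coul", "dG_solv"]
                 if variant.startswith("full") else ["dE_vdw"])
        X = np.array([[getattr(r, t) for t in terms] for r in rows])
        y = np.array([r.dg_exp for r in rows])
        ref = sklearn.LinearRegression(
            fit_intercept=variant.endswith("_int")).fit(X, y)
        got = [model.alpha] + [c for c in (model.beta, model.gamma)
                               if c is not None]
        np.testing.assert_allclose(got, ref.coef_, atol=1e-10)
        if variant.endswith("_int"):
            assert model.delta == pytest.approx(ref.intercept_, abs=1e-10)
        else:
            assert model.delta is None

    def test_vdwonly_variants_have_no_electrostatic_coefficients(self):
        model = fit_liece(gen_energy_table(NOISELESS), "vdwonly_noint")
        assert model.beta is None and model.gamma is None and model.delta is None

    def test_insufficient_rows_rejected(self):
        rows = gen_energy_table(NOISELESS)[:4]
        with pytest.raises(FitError, match="at least 5"):
            fit_liece(rows, "full_int")

    def test_collinear_design_rejected_with_names(self):
        rows = gen_energy_table(NOISELESS)
        for r in rows:
            r.dE_coul = 2.0 * r.dE_vdw
        with pytest.raises(FitError, match="collinear"):
            fit_liece(rows, "full_noint")

    def test_ols_optimality_under_coefficient_perturbation(self):
        """Perturbing any fitted coefficient never lowers the in-sample SSE."""
        rows = gen_energy_table(TableSpec(noise_sd=0.7, n=30, seed=2))
        model = fit_liece(rows, "full_int")
        y = np.array([r.dg_exp for r in rows])

        def sse(a, b, g, d):
            pred = np.array([a * r.dE_vdw + b * r.dE_coul + g * r.dG_solv + d
                             for r in rows])
            return np.sum((pred - y) ** 2)

        base = sse(model.alpha, model.beta, model.gamma, model.delta)
        for i in range(4):
            for sign in (+1, -1):
                c = [model.alpha, model.beta, model.gamma, model.delta]
                c[i] += sign * 1e-3
                assert sse(*c) >= base - 1e-12


class TestPredict:
    def test_zero_terms(self):
        zero = EnergyTerms(0.0, 0.0, 0.0)
        stats = FitStatistics(r2=1.0, rmse=0.0, n=5)
        noint = LieceModel("full_noint", 0.2, -0.03, -0.05, None, 5, stats)
        withint = LieceModel("full_int", 0.2, -0.03, -0.05, -3.0, 5, stats)
        assert predict_dg(noint, zero) == 0.0
        assert predict_dg(withint, zero) == -3.0

    def test_explicit_arithmetic(self):
        stats = FitStatistics(r2=1.0, rmse=0.0, n=5)
        m = LieceModel("full_int", 0.17, -0.032, -0.054, -2.903, 5, stats)
        t = EnergyTerms(-55.0, -12.0, 25.0)
        expected = 0.17 * -55.0 + -0.032 * -12.0 + -0.054 * 25.0 + -2.903
        assert predict_dg(m, t) == pytest.approx(expected, abs=1e-12)


class TestFitStatistics:
    def test_perfect_and_mean_predictions(self):
        obs = [-10.0, -9.0, -8.0]
        perfect = fit_statistics(obs, obs)
        assert (perfect.r2, perfect.rmse) == (1.0, 0.0)
        at_mean = fit_statistics([-9.0] * 3, obs)
        assert at_mean.r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_case(self):
        stats = fit_statistics([-10.0, -9.0, -7.0], [-10.0, -9.0, -8.0])
        assert stats.rmse == pytest.approx(np.sqrt(1 / 3))
        assert stats.r2 == pytest.approx(1 - 1 / 2)

    def test_zero_variance_observations_flagged(self):
        stats = fit_statistics([-9.0, -8.0], [-9.0, -9.0])
        assert stats.r2 is None
        assert stats.rmse == pytest.approx(np.sqrt(0.5))


class TestLeaveOneOut:
    def test_noiseless_data_gives_zero_spread(self):
        rows = gen_energy_table(NOISELESS)
        report = loo_cv(rows, "full_int")
        assert all(v == pytest.approx(0.0, abs=1e-7)
                   for v in report.coef_std.values())
        assert report.mean_ddg == pytest.approx(0.0, abs=1e-8)
        assert len(report.per_fold) == len(rows)

    def test_minimum_row_guard(self):
        rows = gen_energy_table(NOISELESS)[:5]
        with pytest.raises(FitError, match="at least 6"):
            loo_cv(rows, "full_int")

    def test_zero_residual_duplicate_fold_keeps_coefficients(self):
        """Deleting one copy of a duplicated zero-residual row leaves the
        OLS plane unchanged (points on the plane carry no gradient, so
        their multiplicity is irrelevant)."""
        rows = gen_energy_table(TableSpec(noise_sd=0.5, n=12, seed=9))
        base = fit_liece(rows, "full_int")
        on_plane = EnergyTableRow(
            ligand_id="dup", dE_vdw=-45.0, dE_coul=-12.0, dG_solv=20.0,
            dg_exp=base.alpha * -45.0 + base.beta * -12.0
            + base.gamma * 20.0 + base.delta)
        extended = rows + [on_plane,
                           EnergyTableRow(**{**on_plane.__dict__,
                                             "ligand_id": "dup2"})]
        full = fit_liece(extended, "full_int")
        report = loo_cv(extended, "full_int", full_model=full)
        fold = next(f for f in report.per_fold if f[0] == "dup")
        for k, v in fold[1].items():
            assert v == pytest.approx(full.coefficients[k], abs=1e-6)

    def test_both_ddg_conventions_available(self):
        rows = gen_energy_table(TableSpec(noise_sd=0.5, n=15, seed=4))
        left_out = loo_cv(rows, "full_int", ddg_mode="left_out")
        over_all = loo_cv(rows, "full_int", ddg_mode="all")
        assert left_out.ddg_mode == "left_out"
        assert over_all.ddg_mode == "all"
        assert np.isfinite(left_out.mean_ddg) and np.isfinite(over_all.mean_ddg)


class TestEvaluateExternal:
    def test_training_rows_reproduce_in_sample_fit(self):
        rows = gen_energy_table(TableSpec(noise_sd=0.5, n=25, seed=6))
        model = fit_liece(rows, "full_int")
        stats = evaluate_external(model, rows)
        assert stats.r2 == pytest.approx(model.fit.r2, abs=1e-12)
        assert stats.rmse == pytest.approx(model.fit.rmse, abs=1e-12)

    def test_zero_model_rmse_closed_form(self):
        rows = gen_energy_table(TableSpec(noise_sd=0.5, n=25, seed=6))
        zero = LieceModel("full_noint", 0.0, 0.0, 0.0, None, 25,
                          FitStatistics(None, 0.0, 25))
        stats = evaluate_external(zero, rows)
        expected = np.sqrt(np.mean([r.dg_exp ** 2 for r in rows]))
        assert stats.rmse == pytest.approx(expected, abs=1e-12)

    def test_empty_rows_rejected(self):
        model = fit_liece(gen_energy_table(NOISELESS), "full_int")
        with pytest.raises(FitError, match="empty"):
            evaluate_external(model, [])
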