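"""Box-Behnken design, quadratic response-surface fitting and the
published composition->rheology prediction models."""

import dataclasses

import numpy as np
import pytest

from inkflow import rsm, synth
from inkflow.rsm import (CompositionRatio, PUBLISHED_K_MODEL, PUBLISHED_N_MODEL,
                         SingularDesignError, backward_eliminate,
                         enumerate_feasible_region, fit_quadratic,
                         full_quadratic_terms, make_bb_design, pareto_effects,
                         predict_K, predict_n, prediction_accuracy)

# Published validation table: composition -> (n_pred, K_pred) at 2 dp.
TABLE2 = {
    (10.0, 4.0, 3.0): (0.45, 161.44),
    (6.0, 5.0, 4.0): (0.55, 81.57),
    (7.0, 4.0, 4.0): (0.59, 62.85),
    (7.5, 3.0, 2.0): (0.67, 12.80),
    (9.0, 5.0, 3.0): (0.46, 184.07),
}


class TestDesign:
    def test_seventeen_runs_with_five_centres(self, bb_design):
        assert bb_design.n_runs == 17
        centre = np.all(bb_design.coded == 0, axis=1)
        assert centre.sum() == 5
        noncentre = bb_design.coded[~centre]
        assert len(noncentre) == 12
        # each non-centre run: one factor at 0, two at +-1
        assert np.all((noncentre == 0).sum(axis=1) == 1)
        assert np.all(np.isin(noncentre, (-1.0, 0.0, 1.0)))

    def test_single_centre_gives_thirteen_runs(self):
        assert make_bb_design(center_replicates=1).n_runs == 13

    def test_balance(self, bb_design):
        noncentre = bb_design.coded[np.any(bb_design.coded != 0, axis=1)]
        assert np.all(noncentre.sum(axis=0) == 0)
        assert np.all((noncentre != 0).sum(axis=0) == 8)

    def test_coded_uncoded_round_trip(self, bb_design):
        X = bb_design.to_uncoded()
        np.testing.assert_allclose(bb_design.to_coded(X), bb_design.coded, atol=1e-12)

    def test_uncoded_levels(self, bb_design):
        np.testing.assert_allclose(
            bb_design.to_uncoded(np.array([[1.0, 0.0, -1.0]]))[0], [10.0, 4.0, 2.0])

    def test_non_monotone_levels_rejected(self):
        with pytest.raises(ValueError, match="low < centre < high"):
            make_bb_design({"A": (1, 3, 2), "B": (0, 1, 2), "C": (0, 1, 2)})


class TestFitQuadratic:
    def test_noise_free_coefficient_recovery(self, bb_design):
        resp = synth.synth_bb_responses(bb_design, 0.0, 0.0, seed=0)
        model, report = fit_quadratic(bb_design, resp["n"].to_numpy())
        for term, truth in PUBLISHED_N_MODEL.coefficients.items():
            assert model.coefficients[term] == pytest.approx(truth, abs=1e-6)
        assert report.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_constant_response_flagged(self, bb_design):
        model, report = fit_quadratic(bb_design, np.full(17, 3.3))
        assert report.zero_variance
        assert report.r_squared == 0.0
        for term, beta in model.coefficients.items():
            if term != "1":
                assert beta == pytest.approx(0.0, abs=1e-8)

    def test_coefficients_within_three_se(self, bb_design):
        """Calibrated: >=95% of recovered coefficients fall within 3 SE of
        truth over 500 seeded noisy replicates (measured 98.2%)."""
        ok = total = 0
        for seed in range(500):
            resp = synth.synth_bb_responses(bb_design, 0.01, 0.0, seed=seed)
            _, report = fit_quadratic(bb_design, resp["n"].to_numpy())
            for term, truth in PUBLISHED_N_MODEL.coefficients.items():
                i = report.terms.index(term)
                total += 1
                ok += abs(report.coefficients[i] - truth) <= 3 * report.standard_errors[i]
        assert ok / total >= 0.95

    def test_press_identity_matches_explicit_refits(self, bb_design):
        resp = synth.synth_bb_responses(bb_design, 0.01, 0.0, seed=7)
        y = resp["n"].to_numpy()
        _, report = fit_quadratic(bb_design, y)
        X = bb_design.to_uncoded()
        press = 0.0
        for i in range(17):
            mask = np.arange(17) != i
            sub = dataclasses.replace(bb_design, coded=bb_design.coded[mask])
            m_i, _ = fit_quadratic(sub, y[mask])
            press += (y[i] - m_i.predict(X[i])) ** 2
        assert report.press == pytest.approx(press, abs=1e-8)

    def test_predicted_r2_below_r2(self, bb_design):
        for seed in range(20):
            resp = synth.synth_bb_responses(bb_design, 0.01, 2.0, seed=seed)
            for col in ("n", "K_pa_s"):
                _, report = fit_quadratic(bb_design, resp[col].to_numpy())
                assert report.pred_r_squared <= report.r_squared
                assert report.press >= report.ss_residual
                assert report.adj_r_squared <= report.r_squared

    def test_lack_of_fit_uses_centre_replicates(self, bb_design):
        resp = synth.synth_bb_responses(bb_design, 0.01, 0.0, seed=5)
        _, report = fit_quadratic(bb_design, resp["n"].to_numpy())
        assert report.lack_of_fit_p is not None
        assert 0.0 <= report.lack_of_fit_p <= 1.0

    def test_rank_deficiency_raises(self, bb_design):
        # duplicate term column via a design with a collapsed factor range
        sub = dataclasses.replace(bb_design, coded=np.zeros_like(bb_design.coded))
        with pytest.raises(SingularDesignError):
            fit_quadratic(sub, np.ones(17))


class TestBackwardElimination:
    def test_all_significant_is_noop(self, bb_design):
        resp = synth.synth_bb_responses(bb_design, 0.0, 0.0, seed=0)
        full_model, full_report = fit_quadratic(
            bb_design, resp["n"].to_numpy(),
            term_mask=tuple(PUBLISHED_N_MODEL.coefficients))
        assert np.all(full_report.term_p[1:] < 1e-8)
        model, _ = backward_eliminate(bb_design, resp["n"].to_numpy(),
                                      term_mask=tuple(PUBLISHED_N_MODEL.coefficients))
        assert set(model.terms) == set(PUBLISHED_N_MODEL.coefficients)

    def test_only_truly_absent_terms_are_removed(self, bb_design):
        """Calibrated over 200 replicates: the removed set is always a
        subset of the interactions absent from the generating model, and
        exactly equals it in >=55% of replicates (measured 64%); the
        predicted-R^2 retention veto keeps a null term in the rest."""
        absent = {"Gel*SA", "SA*MC"}
        exact = 0
        for seed in range(200):
            resp = synth.synth_bb_responses(bb_design, 0.005, 0.0, seed=seed)
            model, _ = backward_eliminate(bb_design, resp["n"].to_numpy())
            removed = set(full_quadratic_terms(bb_design.factor_names)) - set(model.terms)
            assert removed <= absent
            exact += removed == absent
        assert exact / 200 >= 0.55

    def test_hierarchy_protects_linear_terms(self, bb_design):
        # response built only from Gel*MC: both parent linear terms survive
        X = bb_design.to_uncoded()
        y = 0.5 * X[:, 0] * X[:, 2]
        rng = np.random.default_rng(0)
        model, _ = backward_eliminate(bb_design, y + 1e-6 * rng.standard_normal(17))
        if "Gel*MC" in model.terms:
            assert "Gel" in model.terms and "MC" in model.terms


class TestPublishedModels:
    @pytest.mark.parametrize("comp, expected", list(TABLE2.items()))
    def test_table_predictions_to_two_decimals(self, comp, expected):
        ratio = CompositionRatio(*comp)
        assert round(predict_n(ratio), 2) == pytest.approx(expected[0])
        assert round(predict_K(ratio), 2) == pytest.approx(expected[1])

    def test_low_and_high_viscosity_reference_inks(self):
        assert round(predict_n(CompositionRatio(7, 4, 3)), 2) == 0.65
        assert round(predict_K(CompositionRatio(7, 4, 3)), 2) == 17.24
        assert round(predict_n(CompositionRatio(9, 4, 3)), 2) == 0.54
        assert round(predict_K(CompositionRatio(9, 4, 3)), 2) == 93.05

    def test_k_unit_scale_factor(self):
        """The printed K polynomial evaluates 1000x the tabulated Pa*s
        values at every validation composition; the stored 1e-3 output
        scale corrects that."""
        for comp, (_, k_tab) in TABLE2.items():
            raw = sum(
                c * v for c, v in zip(
                    [1.0, comp[0], comp[1], comp[2], comp[0] ** 2, comp[1] ** 2,
                     comp[2] ** 2, comp[0] * comp[1], comp[0] * comp[2],
                     comp[1] * comp[2]],
                    [PUBLISHED_K_MODEL.coefficients[t] for t in
                     ("1", "Gel", "SA", "MC", "Gel^2", "SA^2", "MC^2",
                      "Gel*SA", "Gel*MC", "SA*MC")]))
            assert raw * 1e-3 == pytest.approx(k_tab, abs=0.005)
        assert PUBLISHED_K_MODEL.output_scale == 1e-3

    def test_outside_cube_warns(self):
        with pytest.warns(UserWarning, match="outside the design cube"):
            CompositionRatio(12.0, 4.0, 3.0)

    def test_json_round_trip(self):
        back = rsm.QuadraticModel.from_json(PUBLISHED_K_MODEL.to_json())
        assert back == PUBLISHED_K_MODEL


class TestAccuracyConvention:
    def test_normalisation_by_prediction_matches_published_K_cells(self):
        published_acc = {
            (10.0, 4.0, 3.0): (146.02, 90.44),
            (6.0, 5.0, 4.0): (80.98, 99.28),
            (7.0, 4.0, 4.0): (60.52, 96.30),
            (7.5, 3.0, 2.0): (15.41, 79.62),
            (9.0, 5.0, 3.0): (147.79, 80.29),
        }
        for comp, (measured, acc_pct) in published_acc.items():
            predicted = TABLE2[comp][1]
            assert 100 * prediction_accuracy(predicted, measured) == pytest.approx(
                acc_pct, abs=0.02)

    def test_perfect_prediction_is_unity(self):
        assert prediction_accuracy(3.3, 3.3) == 1.0

    def test_nonpositive_measurement_rejected(self):
        with pytest.raises(ValueError):
            prediction_accuracy(1.0, 0.0)


class TestParetoAndFeasibleRegion:
    def test_gel_dominates_on_synthetic_fit(self, bb_design):
        """On data simulated from the published n model, the gelatin main
        effect carries the largest standardized effect (coded units make
        the effects comparable)."""
        resp = synth.synth_bb_responses(bb_design, 0.002, 0.0, seed=2)
        _, report = fit_quadratic(bb_design, resp["n"].to_numpy(), uncoded=False)
        ranked = pareto_effects(report)
        assert ranked[0][0] == "Gel"

    def test_tie_break_is_alphabetical(self, bb_design):
        resp = synth.synth_bb_responses(bb_design, 0.0, 0.0, seed=0)
        _, report = fit_quadratic(bb_design, resp["n"].to_numpy())
        ranked = pareto_effects(report)
        effects = [e for _, e in ranked]
        assert effects == sorted(effects, reverse=True)
        for (t1, e1), (t2, e2) in zip(ranked, ranked[1:]):
            if e1 == e2:
                assert t1 < t2

    def test_grid_includes_cube_corners(self):
        region = enumerate_feasible_region(grid_steps=2)
        pts = set(map(tuple, region[["gel_wtpct", "sa_wtpct", "mc_wtpct"]].to_numpy()))
        assert (6.0, 3.0, 2.0) in pts and (10.0, 5.0, 4.0) in pts
        assert len(region) == 8

    def test_grid_hits_validation_composition(self):
        region = enumerate_feasible_region(grid_steps=5)  # step 1 / 0.5 / 0.5 wt%
        row = region[(region.gel_wtpct == 10.0) & (region.sa_wtpct == 4.0)
                     & (region.mc_wtpct == 3.0)]
        assert len(row) == 1
        assert round(float(row.n.iloc[0]), 2) == 0.45
        assert round(float(row.K_pa_s.iloc[0]), 2) == 161.44

    def test_K_positive_over_quarter_percent_grid(self):
        region = enumerate_feasible_region(grid_steps=17)  # 0.25 wt% on Gel
        assert (region.K_pa_s > 0).all()
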