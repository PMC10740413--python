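"""Latin-hypercube sampling, surrogate training/scoring and regime
classification of the flow-rate surface."""

import numpy as np
import pandas as pd
import pytest

from inkflow import surrogate as sg
from inkflow.surrogate import (SAMPLING_BOX, ErrorReport, build_flow_dataset,
                               classify_regimes, evaluate_surrogate,
                               flow_surface, latin_hypercube, train_surrogate)


def stratification_holds(values, lo, hi, n):
    strata = np.floor((values - lo) / (hi - lo) * n).astype(int)
    strata = np.clip(strata, 0, n - 1)
    return sorted(strata) == list(range(n))


class TestLatinHypercube:
    @pytest.mark.parametrize("n_samples", [1, 7, 50, 300])
    def test_one_point_per_stratum_on_every_axis(self, n_samples):
        ss = latin_hypercube(n_samples=n_samples, seed=42)
        assert len(ss) == n_samples
        for col in ("n", "K_pa_s", "P_kpa"):
            lo, hi = SAMPLING_BOX[col]
            vals = ss.points[col].to_numpy()
            assert np.all((vals >= lo) & (vals <= hi))
            assert stratification_holds(vals, lo, hi, n_samples)

    def test_seed_determinism(self):
        a = latin_hypercube(n_samples=40, seed=9)
        b = latin_hypercube(n_samples=40, seed=9)
        pd.testing.assert_frame_equal(a.points, b.points)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            latin_hypercube({"n": (0.7, 0.45), "K_pa_s": (10, 100),
                             "P_kpa": (50, 350)}, 10, 0)


class TestBuildFlowDataset:
    def test_all_points_solve_on_default_geometry(self, geometry):
        ss = build_flow_dataset(latin_hypercube(n_samples=60, seed=5), geometry)
        assert ss.failures == ()
        assert ss.points["Q_ul_s"].notna().all()
        assert (ss.points["Q_ul_s"] > 0).all()

    def test_pressure_monotonicity_within_strata(self, geometry):
        """At fixed (n, K), higher pressure means more flow."""
        base = latin_hypercube(n_samples=12, seed=3).points
        stacked = pd.concat([base.assign(P_kpa=p) for p in (100.0, 200.0, 300.0)],
                            ignore_index=True)
        ss = build_flow_dataset(
            sg.SampleSet(points=stacked, bounds=dict(SAMPLING_BOX), seed=3),
            geometry)
        q = ss.points["Q_ul_s"].to_numpy().reshape(3, 12)
        assert np.all(np.diff(q, axis=0) > 0)

    def test_flow_rates_of_reported_magnitude(self, geometry):
        """The sampled box yields flow rates on the order of the reported
        0-4 uL/s interval (envelope check; the exact channel differs)."""
        ss = build_flow_dataset(latin_hypercube(n_samples=60, seed=5), geometry)
        q = ss.points["Q_ul_s"]
        assert q.median() < 4.0
        assert q.max() < 400.0


class TestSurrogate:
    @pytest.fixture(scope="class")
    def trained(self, geometry):
        train = build_flow_dataset(latin_hypercube(n_samples=300, seed=17), geometry)
        return train, train_surrogate(train, seed=17)

    def test_seed_determinism(self, geometry):
        train = build_flow_dataset(latin_hypercube(n_samples=60, seed=2), geometry)
        m1 = train_surrogate(train, seed=4)
        m2 = train_surrogate(train, seed=4)
        X = train.points[["n", "K_pa_s", "P_kpa"]].to_numpy()
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))

    def test_easy_linear_target(self):
        """A noise-free linear map Q = aP is learned to well under 0.5% of
        range."""
        rng = np.random.default_rng(0)
        pts = pd.DataFrame({
            "n": rng.uniform(0.45, 0.7, 120),
            "K_pa_s": rng.uniform(10, 100, 120),
            "P_kpa": rng.uniform(50, 350, 120)})
        pts["Q_ul_s"] = 0.01 * pts["P_kpa"]
        ds = sg.SampleSet(points=pts, bounds=dict(SAMPLING_BOX), seed=0)
        model = train_surrogate(ds, seed=0)
        test = pts.sample(40, random_state=1)
        err = evaluate_surrogate(model, test[["n", "K_pa_s", "P_kpa"]].to_numpy(),
                                 test["Q_ul_s"].to_numpy())
        assert err.mae_pct_of_range < 0.5

    def test_held_out_error_under_one_percent(self, trained, geometry, rng):
        train, model = trained
        lo = np.array([SAMPLING_BOX[k][0] for k in ("n", "K_pa_s", "P_kpa")])
        hi = np.array([SAMPLING_BOX[k][1] for k in ("n", "K_pa_s", "P_kpa")])
        X = rng.uniform(lo, hi, size=(50, 3))
        test = build_flow_dataset(
            sg.SampleSet(points=pd.DataFrame(X, columns=["n", "K_pa_s", "P_kpa"]),
                         bounds=dict(SAMPLING_BOX), seed=0), geometry)
        err = evaluate_surrogate(model, X, test.points["Q_ul_s"].to_numpy())
        assert err.mae_pct_of_range < 1.0

    def test_json_round_trip(self, trained):
        _, model = trained
        back = sg.SurrogateModel.from_json(model.to_json())
        X = np.array([[0.5, 50.0, 200.0], [0.65, 20.0, 120.0]])
        np.testing.assert_allclose(back.predict(X), model.predict(X), rtol=1e-12)

    def test_extrapolation_flagging(self, trained):
        _, model = trained
        flags = model.extrapolating(np.array([[0.5, 50.0, 200.0],
                                              [0.9, 50.0, 200.0]]))
        assert flags.tolist() == [False, True]

    def test_rbf_backend_same_interface(self, geometry):
        train = build_flow_dataset(latin_hypercube(n_samples=60, seed=2), geometry)
        model = train_surrogate(train, backend="rbf", ridge=0.0)
        X = train.points[["n", "K_pa_s", "P_kpa"]].to_numpy()
        # unsmoothed interpolant passes through its training data
        np.testing.assert_allclose(model.predict(X),
                                   train.points["Q_ul_s"].to_numpy(), rtol=1e-6)

    def test_error_decreases_with_training_size(self, geometry):
        """Median held-out MAE over 5 seeds improves from 75 to 300
        training points."""
        lo = np.array([SAMPLING_BOX[k][0] for k in ("n", "K_pa_s", "P_kpa")])
        hi = np.array([SAMPLING_BOX[k][1] for k in ("n", "K_pa_s", "P_kpa")])
        medians = []
        for size in (75, 300):
            maes = []
            for seed in range(5):
                train = build_flow_dataset(
                    latin_hypercube(n_samples=size, seed=500 + seed), geometry)
                model = train_surrogate(train, seed=500 + seed)
                rng = np.random.default_rng(900 + seed)
                X = rng.uniform(lo, hi, size=(50, 3))
                test = build_flow_dataset(
                    sg.SampleSet(points=pd.DataFrame(
                        X, columns=["n", "K_pa_s", "P_kpa"]),
                        bounds=dict(SAMPLING_BOX), seed=0), geometry)
                maes.append(evaluate_surrogate(
                    model, X, test.points["Q_ul_s"].to_numpy()).mae)
            medians.append(np.median(maes))
        assert medians[1] < medians[0]


class TestErrorReport:
    def test_hand_arithmetic(self):
        # observed (1, 2) vs predicted (1, 4): MAE 1, RMSE sqrt(2)
        err = _report_from(np.array([1.0, 2.0]), np.array([1.0, 4.0]))
        assert err.mae == pytest.approx(1.0)
        assert err.rmse == pytest.approx(np.sqrt(2.0))

    def test_perfect_predictions(self):
        err = _report_from(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert err.mae == 0.0 and err.rmse == 0.0

    def test_rmse_at_least_mae(self, rng):
        for _ in range(20):
            y = rng.normal(size=11)
            resid = rng.normal(size=11)
            err = _report_from(y, y + resid)
            assert err.rmse >= err.mae >= 0

    def test_single_point(self):
        err = _report_from(np.array([3.0]), np.array([2.0]))
        assert err.mae == err.rmse == pytest.approx(1.0)

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            _report_from(np.array([]), np.array([]))


def _report_from(y_true, y_pred):
    class _Fixed:
        def predict(self, X):
            return y_pred
    return evaluate_surrogate(_Fixed(), np.zeros((y_true.size, 3)), y_true)


class TestRegimes:
    def test_separable_blobs_recovered(self, rng):
        centers = np.array([[0.5, 20.0, 0.2], [0.6, 50.0, 2.0], [0.68, 90.0, 8.0]])
        rows, truth = [], []
        for i, c in enumerate(centers):
            for _ in range(30):
                rows.append(c + rng.normal(scale=[0.004, 0.5, 0.02], size=3))
                truth.append(i)
        df = pd.DataFrame(rows, columns=["n", "K_pa_s", "Q_ul_s"])
        lab = classify_regimes(df, seed=1)
        # clusters are canonical by mean Q, so blob i should map to cluster i
        assert lab["cluster"].tolist() == truth

    def test_seed_determinism_and_canonical_labels(self, geometry):
        surf = flow_surface(250.0, grid_steps=8, geometry=geometry)
        a = classify_regimes(surf, seed=3)
        b = classify_regimes(surf, seed=3)
        assert a["cluster"].tolist() == b["cluster"].tolist()
        means = a.groupby("regime")["Q_ul_s"].mean()
        assert (means["high-viscosity"] < means["medium-viscosity"]
                < means["low-viscosity"])

    def test_thick_ink_corner_is_high_viscosity(self, geometry):
        """The (n=0.45, K=100) corner -- the thickest ink -- belongs to the
        high-viscosity regime, which also shows the least flow-rate
        variability (calibrated empirical assertion)."""
        surf = flow_surface(250.0, grid_steps=20, geometry=geometry)
        lab = classify_regimes(surf, seed=0)
        corner = lab[(lab.n == 0.45) & (lab.K_pa_s == 100.0)]
        assert corner["regime"].iloc[0] == "high-viscosity"
        variances = lab.groupby("regime")["Q_ul_s"].var()
        assert variances["high-viscosity"] == variances.min()

    def test_k_exceeding_points_rejected(self):
        df = pd.DataFrame({"n": [0.5, 0.6], "K_pa_s": [20.0, 30.0],
                           "Q_ul_s": [1.0, 2.0]})
        with pytest.raises(ValueError, match="exceeds"):
            classify_regimes(df, k=3)


class TestFlowSurface:
    def test_pointwise_pressure_monotonicity(self, geometry):
        s150 = flow_surface(150.0, grid_steps=6, geometry=geometry)
        s300 = flow_surface(300.0, grid_steps=6, geometry=geometry)
        assert np.all(s300["Q_ul_s"].to_numpy() > s150["Q_ul_s"].to_numpy())

    def test_steepest_gradient_at_low_n_low_K(self, geometry):
        surf = flow_surface(250.0, grid_steps=10, geometry=geometry)
        Q = surf["Q_ul_s"].to_numpy().reshape(10, 10)  # rows: n, cols: K
        dq_dn = np.abs(np.diff(Q, axis=0))
        assert dq_dn.argmax() == 0  # first n step at the lowest K

    def test_surrogate_matches_solver_surface(self, geometry):
        """Calibrated agreement bounds: mean deviation well under 0.5% of
        range; the worst point (the steep low-n/low-K corner) under 15%."""
        train = build_flow_dataset(latin_hypercube(n_samples=300, seed=23), geometry)
        model = train_surrogate(train, seed=23)
        solver_surf = flow_surface(250.0, grid_steps=20, geometry=geometry)
        sur_surf = flow_surface(250.0, grid_steps=20, model=model)
        dev = np.abs(sur_surf["Q_ul_s"].to_numpy() - solver_surf["Q_ul_s"].to_numpy())
        rng_ = np.ptp(solver_surf["Q_ul_s"].to_numpy())
        assert not sur_surf["extrapolated"].any()
        assert dev.mean() / rng_ < 0.005
        assert dev.max() / rng_ < 0.15
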