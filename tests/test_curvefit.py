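import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from pfcurve.curvefit import (
    SUBSET_FRACTIONS,
    InsufficientDataError,
    PressureFlowCurve,
    PressureFlowModel,
    curve_area,
    curve_areas,
    fit_pressure_flow,
    predict_drop,
    subset_rmse,
)
from pfcurve.protocol import SweepResult


def quadratic_points(f, s, flows):
    flows = np.asarray(flows, dtype=float)
    return np.column_stack([flows, f * flows + s * flows ** 2])


class TestFit:
    def test_noiseless_quadratic_recovered_exactly(self):
        pts = quadratic_points(1.2, 0.8, np.arange(0.5, 3.6, 0.5))
        curve = fit_pressure_flow(pts)
        assert curve.f == pytest.approx(1.2, abs=1e-10)
        assert curve.s == pytest.approx(0.8, abs=1e-10)
        assert curve.rmse == pytest.approx(0.0, abs=1e-12)

    def test_pure_linear_hits_constraint_boundary(self):
        pts = quadratic_points(2.0, 0.0, [0.5, 1.0, 1.5, 2.0])
        curve = fit_pressure_flow(pts)
        assert curve.f == pytest.approx(2.0, abs=1e-10)
        assert curve.s == 0.0

    def test_noisy_fit_matches_grid_search_oracle(self):
        """Brute-force grid search over (f, s) agrees with the direct
        constrained least-squares solution to the grid resolution."""
        rng = np.random.default_rng(42)
        flows = np.linspace(0.4, 1.6, 7)
        drops = (1.5 * flows + 2.5 * flows ** 2) * (1 + 0.02 * rng.standard_normal(7))
        curve = fit_pressure_flow(np.column_stack([flows, drops]))

        f_grid = np.linspace(0.0, 4.0, 801)
        s_grid = np.linspace(0.0, 5.0, 1001)
        fg, sg = np.meshgrid(f_grid, s_grid, indexing="ij")
        sse = ((drops[None, None, :] - fg[..., None] * flows
                - sg[..., None] * flows ** 2) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert curve.f == pytest.approx(f_grid[i], abs=(f_grid[1] - f_grid[0]))
        assert curve.s == pytest.approx(s_grid[j], abs=(s_grid[1] - s_grid[0]))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        f0=st.floats(0.0, 50.0),
        s0=st.floats(0.0, 50.0),
        i=st.integers(0, 6),
        j=st.integers(0, 6),
    )
    def test_exact_recovery_from_any_two_point_subset(self, f0, s0, i, j):
        """Any two distinct-flow points of exact quadratic data identify
        the curve."""
        flows = np.arange(1, 8) * 0.3
        if i == j:
            j = (j + 1) % 7
        pts = quadratic_points(f0, s0, flows[[i, j]])
        curve = fit_pressure_flow(pts)
        assert curve.f == pytest.approx(f0, rel=1e-8, abs=1e-8)
        assert curve.s == pytest.approx(s0, rel=1e-8, abs=1e-8)

    def test_fit_invariant_to_point_ordering(self):
        rng = np.random.default_rng(3)
        flows = np.linspace(0.3, 2.0, 7)
        drops = 1.1 * flows + 0.9 * flows ** 2 + 0.05 * rng.standard_normal(7)
        pts = np.column_stack([flows, np.abs(drops)])
        a = fit_pressure_flow(pts)
        b = fit_pressure_flow(pts[::-1])
        assert a.f == pytest.approx(b.f, rel=1e-12)
        assert a.s == pytest.approx(b.s, rel=1e-12)

    def test_fitted_rmse_beats_zero_curve(self):
        rng = np.random.default_rng(7)
        flows = np.linspace(0.3, 2.0, 7)
        drops = np.abs(2.0 * flows + 0.5 * rng.standard_normal(7))
        curve = fit_pressure_flow(np.column_stack([flows, drops]))
        zero_rmse = float(np.sqrt(np.mean(drops ** 2)))
        assert curve.rmse <= zero_rmse

    def test_iterative_mode_agrees_with_direct(self):
        rng = np.random.default_rng(5)
        flows = np.linspace(0.4, 1.6, 7)
        drops = (1.5 * flows + 2.5 * flows ** 2) * (1 + 0.02 * rng.standard_normal(7))
        model = PressureFlowModel(flows, drops)
        direct = model.fit()
        iterative = model.fit(method="iterative")
        assert iterative.f == pytest.approx(direct.f, abs=1e-8)
        assert iterative.s == pytest.approx(direct.s, abs=1e-8)

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_pressure_flow([(1.0, 2.0)])
        with pytest.raises(InsufficientDataError):
            fit_pressure_flow([(1.0, 2.0), (1.0, 2.1)])
        with pytest.raises(InsufficientDataError):
            fit_pressure_flow([(0.0, 0.0), (0.0, 0.0)])


class TestPredictAndAreas:
    def test_curve_through_origin(self):
        curve = PressureFlowCurve(f=3.0, s=1.0, n_points=7, rmse=0.0)
        assert predict_drop(curve, 0.0) == 0.0

    def test_direct_arithmetic(self):
        curve = PressureFlowCurve(f=1.2, s=0.8, n_points=7, rmse=0.0)
        assert predict_drop(curve, 2.0) == pytest.approx(5.6)

    def test_negative_flow_rejected(self):
        curve = PressureFlowCurve(f=1.0, s=1.0, n_points=2, rmse=0.0)
        with pytest.raises(ValueError):
            predict_drop(curve, -1.0)
        with pytest.raises(ValueError):
            curve_area(curve, -1.0)

    @pytest.mark.parametrize(
        "f,s,q,expected",
        [(2.0, 0.0, 1.0, 1.0), (0.0, 3.0, 1.0, 1.0)],
    )
    def test_area_closed_form(self, f, s, q, expected):
        curve = PressureFlowCurve(f=f, s=s, n_points=2, rmse=0.0)
        assert curve_area(curve, q) == pytest.approx(expected, rel=1e-12)

    def test_area_matches_numerical_quadrature(self):
        curve = PressureFlowCurve(f=1.2, s=0.8, n_points=7, rmse=0.0)
        for q in [1.0, 2.0]:
            oracle, _ = quad(lambda x: predict_drop(curve, x), 0.0, q, epsabs=1e-13)
            assert curve_area(curve, q) == pytest.approx(oracle, abs=1e-10)

    def test_areas_ordered_and_monotone(self):
        curve = PressureFlowCurve(f=1.0, s=1.0, n_points=2, rmse=0.0)
        ar = curve_areas(curve)
        assert 0 <= ar.s1 <= ar.s2
        assert curve_area(curve, 0.0) == 0.0
        bigger = PressureFlowCurve(f=2.0, s=1.0, n_points=2, rmse=0.0)
        assert curve_area(bigger, 1.0) > curve_area(curve, 1.0)


def patient_like_sweep(f, s, noise_sigma=0.0, seed=0):
    fractions = SUBSET_FRACTIONS[7]
    # flows as they would arise from falling resistance
    flows = np.array([0.36, 0.41, 0.48, 0.57, 0.71, 0.93, 1.36])
    drops = f * flows + s * flows ** 2
    if noise_sigma:
        rng = np.random.default_rng(seed)
        eps = np.clip(rng.normal(0, noise_sigma, 7), -3 * noise_sigma, 3 * noise_sigma)
        drops = drops * (1 + eps)
    prov = [{"condition": f"{fr:g}%", "fraction_percent": fr} for fr in fractions]
    return SweepResult(flow=flows, drop=drops, provenance=prov)


class TestSubsetRmse:
    def test_noiseless_subsets_are_exact(self):
        sweep = patient_like_sweep(2.2, 1.9)
        for k in (7, 4, 3, 2):
            assert subset_rmse(sweep, k) == pytest.approx(0.0, abs=1e-10)

    def test_two_point_subset_uses_extreme_fractions(self):
        assert SUBSET_FRACTIONS[2] == (100.0, 25.0)
        assert SUBSET_FRACTIONS[3] == (100.0, 62.5, 25.0)
        assert SUBSET_FRACTIONS[4] == (100.0, 75.0, 50.0, 25.0)

    def test_fewer_points_mean_larger_error_under_noise(self):
        rmse7, rmse2 = [], []
        for seed in range(100):
            sweep = patient_like_sweep(2.2, 1.9, noise_sigma=0.02, seed=seed)
            rmse7.append(subset_rmse(sweep, 7))
            rmse2.append(subset_rmse(sweep, 2))
        assert np.mean(rmse2) >= np.mean(rmse7)

    def test_missing_fraction_rejected(self):
        sweep = patient_like_sweep(2.2, 1.9)
        partial = SweepResult(
            flow=sweep.flow[:5], drop=sweep.drop[:5], provenance=sweep.provenance[:5]
        )
        with pytest.raises(ValueError):
            subset_rmse(partial, 2)

    def test_unfractioned_sweep_rejected(self):
        sweep = SweepResult(flow=[0.5, 1.0], drop=[1.0, 3.0])
        with pytest.raises(ValueError):
            subset_rmse(sweep, 2)


class TestResultsSurface:
    def test_summary_reports_all_indices(self):
        pts = quadratic_points(1.2, 0.8, np.arange(0.5, 3.6, 0.5))
        res = PressureFlowModel(pts[:, 0], pts[:, 1]).fit()
        text = res.summary()
        for token in ("f (viscous)", "s (expansion)", "S1", "S2", "RMSE"):
            assert token in text
        d = res.to_dict()
        assert d["s1"] == pytest.approx(1.2 / 2 + 0.8 / 3)
        assert d["s2"] == pytest.approx(1.2 / 2 * 4 + 0.8 / 3 * 8)

    def test_plot_returns_axis(self):
        import matplotlib

        matplotlib.use("Agg")
        pts = quadratic_points(1.0, 1.0, [0.5, 1.0, 1.5])
        res = PressureFlowModel(pts[:, 0], pts[:, 1]).fit()
        ax = res.plot()
        assert ax.get_xlabel()
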