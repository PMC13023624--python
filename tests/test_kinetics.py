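"""Kinetic model curves, nonlinear fitting and first-order hydrolysis."""

import numpy as np
import pytest

from biomethane import kinetics as kin
from biomethane.gas_preprocess import YieldCurve
from biomethane.synthetic_data import generate_yield_curve

TRUE_PARAMS = {
    "modified_gompertz": {"B0": 300.0, "Rmax": 150.0, "lambda_": 0.2},
    "logistic": {"B0": 320.0, "Rmax": 140.0, "lambda_": 0.3},
    "cone": {"B0": 370.0, "k": 0.85, "n_shape": 1.8},
    "first_order": {"B0": 374.72, "k": 0.64},
}


class TestModelCurve:
    def test_gompertz_at_lag(self):
        spec = kin.KineticModelSpec("modified_gompertz", TRUE_PARAMS["modified_gompertz"])
        b = kin.model_curve(spec, [0.2])[0]
        assert b == pytest.approx(300.0 * np.exp(-np.e), rel=1e-12)

    def test_logistic_at_lag(self):
        spec = kin.KineticModelSpec("logistic", TRUE_PARAMS["logistic"])
        b = kin.model_curve(spec, [0.3])[0]
        assert b == pytest.approx(320.0 / (1 + np.e**2), rel=1e-12)

    def test_first_order_asymptote(self):
        spec = kin.KineticModelSpec("first_order", TRUE_PARAMS["first_order"])
        assert kin.model_curve(spec, [1e4])[0] == pytest.approx(374.72, rel=1e-9)

    def test_cone_continuous_extension_at_zero(self):
        spec = kin.KineticModelSpec("cone", TRUE_PARAMS["cone"])
        assert kin.model_curve(spec, [0.0])[0] == 0.0

    @pytest.mark.parametrize("name", kin.MODEL_NAMES)
    def test_monotone_and_bounded(self, name):
        spec = kin.KineticModelSpec(name, TRUE_PARAMS[name])
        t = np.linspace(0, 60, 600)
        b = kin.model_curve(spec, t)
        assert np.all(np.diff(b) >= -1e-12)
        assert np.all(b <= spec.params["B0"] * (1 + 1e-12))

    def test_invalid_b0_rejected(self):
        with pytest.raises(ValueError):
            kin.KineticModelSpec("first_order", {"B0": -1.0, "k": 0.5})

    def test_negative_time_rejected(self):
        spec = kin.KineticModelSpec("first_order", TRUE_PARAMS["first_order"])
        with pytest.raises(ValueError):
            kin.model_curve(spec, [-1.0])


class TestFitKinetic:
    @pytest.mark.parametrize("name", kin.MODEL_NAMES)
    def test_noiseless_self_fit_recovers_parameters(self, name, daily_grid):
        """Each model refitted to its own noiseless 26-point daily curve
        recovers every parameter to <= 1e-6 relative."""
        spec = kin.KineticModelSpec(name, TRUE_PARAMS[name])
        curve = YieldCurve(daily_grid, kin.model_curve(spec, daily_grid))
        fit = kin.fit_kinetic(curve, name)
        assert fit.converged
        for pname, true in spec.params.items():
            assert fit.spec.params[pname] == pytest.approx(true, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_first_order_rate_recovered(self, daily_grid):
        """A first-order curve with ultimate yield 374.72 mL/g VS refits to
        k = 0.64 1/d."""
        spec = kin.KineticModelSpec("first_order", {"B0": 374.72, "k": 0.64})
        curve = YieldCurve(daily_grid, kin.model_curve(spec, daily_grid))
        fit = kin.fit_kinetic(curve, "first_order")
        assert round(fit.spec.params["k"], 2) == 0.64

    def test_all_zero_curve_errors(self, daily_grid):
        curve = YieldCurve(daily_grid, np.zeros_like(daily_grid))
        with pytest.raises(ValueError, match="no fittable signal"):
            kin.fit_kinetic(curve, "first_order")

    def test_too_few_points_errors(self):
        curve = YieldCurve(np.array([0.0, 1, 2]), np.array([0.0, 1, 2.0]))
        with pytest.raises(ValueError, match="too few"):
            kin.fit_kinetic(curve, "modified_gompertz")


class TestFitAllModels:
    def test_shape_contract(self, gompertz_curve):
        curve, _ = gompertz_curve
        table = kin.fit_all_models(curve)
        assert len(table) == 4
        assert set(table["model"]) == set(kin.MODEL_NAMES)
        r2 = table["R2_pct"].dropna()
        assert ((r2 >= 0) & (r2 <= 100)).all()

    def test_cone_self_fit_perfect(self, daily_grid):
        spec = kin.KineticModelSpec("cone", TRUE_PARAMS["cone"])
        curve = YieldCurve(daily_grid, kin.model_curve(spec, daily_grid))
        table = kin.fit_all_models(curve).set_index("model")
        assert table.loc["cone", "R2_pct"] == 100.00

    def test_cone_beats_first_order_on_noisy_sigmoid(self, daily_grid):
        """The Cone model's free shape parameter lets it track sigmoidal
        curves at least as well as the first-order model."""
        spec = kin.KineticModelSpec("modified_gompertz", TRUE_PARAMS["modified_gompertz"])
        curve = generate_yield_curve(spec, daily_grid, noise_frac=0.02, seed=42)
        table = kin.fit_all_models(curve).set_index("model")
        assert table.loc["cone", "R2_pct"] >= table.loc["first_order", "R2_pct"]


class TestHydrolysis:
    @pytest.mark.parametrize(
        "removal,t,expected,ndigits",
        [
            (0.9796, 4.0, 0.97, 2),  # day-4 removal of a fast carbohydrate
            (0.0, 3.0, 0.0, 12),
            (1 - np.exp(-2.0), 1.0, 2.00, 2),
        ],
    )
    def test_single_point_inversion(self, removal, t, expected, ndigits):
        assert round(kin.hydrolysis_k_single_point(removal, t), ndigits) == expected

    @pytest.mark.parametrize("removal,t", [(1.0, 4.0), (-0.1, 4.0), (0.5, 0.0)])
    def test_single_point_invalid_inputs(self, removal, t):
        with pytest.raises(ValueError):
            kin.hydrolysis_k_single_point(removal, t)

    @pytest.mark.parametrize("method", ["nls", "log-linear"])
    def test_noiseless_recovery(self, method):
        t = np.linspace(0, 10, 21)
        s = 10.0 * np.exp(-0.97 * t)
        fit = kin.fit_hydrolysis(t, s, method=method)
        assert fit.s0 == pytest.approx(10.0, rel=1e-8)
        assert fit.k_deg == pytest.approx(0.97, rel=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_constant_series_gives_zero_rate(self):
        fit = kin.fit_hydrolysis(np.arange(5.0), np.full(5, 7.0))
        assert fit.k_deg == 0.0

    def test_agrees_with_single_point_on_noiseless_data(self):
        t = np.array([0.0, 2.0, 4.0])
        s = 8.0 * np.exp(-0.5 * t)
        fit = kin.fit_hydrolysis(t, s)
        k_sp = kin.hydrolysis_k_single_point(1 - s[-1] / s[0], t[-1])
        assert fit.k_deg == pytest.approx(k_sp, rel=1e-9)

    def test_nonpositive_concentrations_excluded_with_warning(self):
        t = np.arange(6.0)
        s = 5.0 * np.exp(-0.8 * t)
        s[3] = 0.0
        with pytest.warns(UserWarning, match="non-positive"):
            fit = kin.fit_hydrolysis(t, s)
        assert fit.k_deg == pytest.approx(0.8, rel=1e-6)

    def test_noisy_simulation_recovers_mean_rate(self):
        """With 2% multiplicative noise over 50 replicates, the mean fitted
        rate lies within 5% of the truth."""
        from biomethane.synthetic_data import generate_substrate_series

        t = np.linspace(0, 5, 11)
        ks = []
        for seed in range(50):
            s = generate_substrate_series(10.0, 0.97, t, noise_cv=0.02, seed=seed)
            ks.append(kin.fit_hydrolysis(t, s).k_deg)
        assert np.mean(ks) == pytest.approx(0.97, rel=0.05)
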