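"""Heat of adsorption, Young's modulus, polymer-water distance, trend fits."""

import numpy as np
import pandas as pd
import pytest

from sdpdiff.materials import (
    GAS_CONSTANT_KJ,
    H_LATENT_WATER,
    BAR_NM3_TO_KJ_MOL,
    EnthalpyInputs,
    MaterialRecord,
    TrendFitError,
    enthalpy_from_thermo,
    fit_property_trends,
    heat_of_adsorption,
    polymer_water_distance,
    records_to_frame,
    young_modulus,
)
from sdpdiff.synthetic import gen_stress_strain
from sdpdiff.trajectory import Box, StressStrainTable, ThermoSeries


def hwv(n_water, T):
    return 4.0 * n_water * GAS_CONSTANT_KJ * T


class TestHeatOfAdsorption:
    def test_zero_binding_leaves_minus_latent_heat(self):
        inputs = EnthalpyInputs(H_p=1000.0, H_c=1000.0 + hwv(10, 300), n_water=10, T=300)
        assert heat_of_adsorption(inputs) == pytest.approx(-40.68, abs=1e-12)

    def test_strong_sorption_scale(self):
        # per-mole binding of 83.68 kJ leaves Q_ad = 43 kJ/mol after the
        # liquid-water reference correction
        inputs = EnthalpyInputs(
            H_p=1000.0, H_c=1000.0 + hwv(10, 300) - 836.8, n_water=10, T=300
        )
        assert heat_of_adsorption(inputs) == pytest.approx(43.0)

    def test_intensive_in_system_size(self):
        binding_per_mol = 50.0
        small = EnthalpyInputs(
            H_p=500.0, H_c=500.0 + hwv(5, 310) - 5 * binding_per_mol, n_water=5, T=310
        )
        large = EnthalpyInputs(
            H_p=500.0, H_c=500.0 + hwv(10, 310) - 10 * binding_per_mol, n_water=10, T=310
        )
        assert heat_of_adsorption(small) == pytest.approx(heat_of_adsorption(large))

    def test_linear_in_mixture_enthalpy(self):
        base = EnthalpyInputs(H_p=100.0, H_c=50.0, n_water=4.0, T=300)
        bumped = EnthalpyInputs(H_p=100.0, H_c=60.0, n_water=4.0, T=300)
        slope = (heat_of_adsorption(bumped) - heat_of_adsorption(base)) / 10.0
        assert slope == pytest.approx(-1.0 / 4.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            EnthalpyInputs(H_p=0, H_c=0, n_water=0, T=300)

    def test_enthalpy_from_thermo_keeps_pv_covariance(self):
        series = ThermoSeries(
            U=[100.0, 100.0], P=[1.0, 3.0], V=[10.0, 20.0], T=[300.0, 300.0]
        )
        # <PV> = (10 + 60)/2 = 35 bar nm^3, not <P><V> = 30
        assert enthalpy_from_thermo(series) == pytest.approx(
            100.0 + 35.0 * BAR_NM3_TO_KJ_MOL
        )


class TestYoungModulus:
    def test_exact_line(self):
        table = gen_stress_strain(2.0)
        assert len(table) == 101
        assert young_modulus(table).E == pytest.approx(2.0, abs=1e-12)

    def test_noisy_line_within_ci(self):
        table = gen_stress_strain(2.0, noise=0.01, seed=3)
        fit = young_modulus(table)
        lo, hi = fit.ci95
        assert lo <= 2.0 <= hi

    def test_points_above_linear_regime_rejected(self):
        table = StressStrainTable(strain=[0.02, 0.03, 0.04], stress=[1.0, 1.5, 2.0])
        with pytest.raises(ValueError, match="at least 3 points"):
            young_modulus(table)

    def test_scale_equivariance(self):
        table = gen_stress_strain(2.0, noise=0.01, seed=4)
        scaled = StressStrainTable(strain=table.strain, stress=3.0 * table.stress)
        assert young_modulus(scaled).E == pytest.approx(3.0 * young_modulus(table).E)


class TestPolymerWaterDistance:
    def test_single_pair(self):
        res = polymer_water_distance(
            np.array([[1.0, 1.0, 1.0]]), np.array([[1.3, 1.0, 1.0]]), Box.cubic(5.0)
        )
        assert res.d_pw == pytest.approx(0.3)

    def test_minimum_image_distance(self):
        res = polymer_water_distance(
            np.array([[0.05, 1.0, 1.0]]), np.array([[4.95, 1.0, 1.0]]), Box.cubic(5.0)
        )
        assert res.d_pw == pytest.approx(0.1)

    def test_moving_waters_sit_farther_than_waiting(self):
        polymer = np.array([[0.0, 0.0, 0.0]])
        waters = np.array([[0.25, 0.0, 0.0], [0.3, 0.0, 0.0], [0.8, 0.0, 0.0]])
        labels = np.array([0, 0, 1])  # two waiting near the chain, one moving far
        res = polymer_water_distance(waters, polymer, Box.cubic(5.0), labels)
        assert res.d_pw_m > res.d_pw_w

    def test_all_moving_equals_overall_mean(self):
        waters = np.array([[0.25, 0.0, 0.0], [0.8, 0.0, 0.0]])
        res = polymer_water_distance(
            waters, np.array([[0.0, 0.0, 0.0]]), Box.cubic(5.0), np.array([1, 1])
        )
        assert res.d_pw_m == pytest.approx(res.d_pw)
        assert np.isnan(res.d_pw_w)

    def test_requires_both_species(self):
        with pytest.raises(ValueError, match="at least one water"):
            polymer_water_distance(np.empty((0, 3)), np.ones((1, 3)), Box.cubic(5.0))


TREND_CASES = [
    ("Q_ad", lambda m: 30 * np.exp(-8 * m) + 13, {"a": 30.0, "b": 8.0, "c": 13.0}),
    ("E", lambda m: 4 * (1 + m) ** -3, {"a": 4.0, "b": -3.0}),
    ("p_p", lambda m: 1 / (np.exp(-25 * m + 5) + 1), {"a": 25.0, "b": 5.0}),
    ("d_pw", lambda m: np.sqrt(m + 0.05) + 0.25, {"a": -0.05, "b": 0.5, "c": 0.25}),
]


class TestTrendFits:
    @pytest.mark.parametrize("prop,func,truth", TREND_CASES, ids=[c[0] for c in TREND_CASES])
    def test_noiseless_recovery(self, prop, func, truth):
        m = np.linspace(0.0, 0.3, 7)
        df = pd.DataFrame({"m": m, prop: func(m)})
        fit = fit_property_trends(df, prop)
        for name, value in truth.items():
            assert fit.params[name] == pytest.approx(value, abs=1e-6)
        np.testing.assert_allclose(fit.predict(m), func(m), atol=1e-8)

    def test_constant_sigmoid_series_fails(self):
        df = pd.DataFrame({"m": np.linspace(0, 0.3, 6), "p_p": np.full(6, 0.4)})
        with pytest.raises(TrendFitError, match="constant"):
            fit_property_trends(df, "p_p")

    def test_too_few_records(self):
        df = pd.DataFrame({"m": [0.0, 0.1, 0.2], "E": [4.0, 3.0, 2.5]})
        with pytest.raises(TrendFitError, match="at least 4"):
            fit_property_trends(df, "E")

    def test_unknown_property(self):
        with pytest.raises(ValueError, match="property must be one of"):
            fit_property_trends(pd.DataFrame({"m": [0, 0.1]}), "density")

    def test_records_round_trip(self):
        rec = MaterialRecord(label="demo", m=0.1, Q_ad=20.0, E=3.0, p_p=0.2, D_mu=0.5)
        df = records_to_frame([rec])
        assert df.loc[0, "Q_ad"] == 20.0
        with pytest.raises(ValueError):
            MaterialRecord(label="bad", m=0.1, Q_ad=20.0, E=3.0, p_p=1.4, D_mu=0.5)
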