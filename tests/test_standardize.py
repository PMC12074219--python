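"""Internal calibration, scanner-parameter fit, energy mapping, estimator."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone
from sklearn.pipeline import Pipeline

from lungct.io import RawMeasurement, ScanProtocol
from lungct.phantom import MaterialSpec, PhantomDefinition, PhysicsConstants
from lungct.simulate import SimulationConfig, forward_hu, simulate_scan
from lungct.standardize import (
    CTNumberStandardizer,
    alpha_of_foam,
    compute_offsets,
    energy_map,
    estimate_alpha_bar,
    internal_calibrate,
    rescale,
    standardize_scan,
    unrescale,
)
from conftest import random_measurement

NOISELESS = SimulationConfig(sigma0=0.0, sigma_cal=0.0, sigma_water=0.0)


def measurement(phantom, **hu):
    """Nominal values with selected materials overridden (alias keys)."""
    alias = {"air": "Air", "ref1": "Reference 1", "ref2": "Reference 2",
             "ref3": "Reference 3", "lung": "Lung", "water": "Water"}
    values = {m.name: m.nominal_ct for m in phantom.materials}
    for key, v in hu.items():
        values[alias[key]] = v
    return RawMeasurement(protocol=ScanProtocol("t"), values=values)


class TestRescale:
    @pytest.mark.parametrize("ct, h", [(-1000.0, 0.0), (0.0, 1.0), (-835.0, 0.165)])
    def test_anchors(self, ct, h):
        assert rescale(ct) == pytest.approx(h, abs=1e-15)

    @given(ct=st.floats(-1100, 500))
    def test_round_trip(self, ct):
        assert unrescale(rescale(ct)) == pytest.approx(ct, abs=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            rescale(float("nan"))


class TestOffsets:
    def test_zero_for_perfect_scanner(self, phantom, nominal_measurement):
        d1, da, delta = compute_offsets(nominal_measurement, phantom)
        assert d1 == 0.0 and da == 0.0
        assert all(v == 0.0 for v in delta.values())

    def test_basis_shift_scales_with_density(self, phantom):
        # ref1 five HU hot, air exact: offsets interpolate by rho ratio
        m = measurement(phantom, ref1=-695.0)
        d1, da, delta = compute_offsets(m, phantom)
        assert d1 == 5.0 and da == 0.0
        assert delta["Reference 2"] == pytest.approx(5 * 192.6 / 321.0)  # 3.0 HU
        assert delta["Reference 2"] == pytest.approx(3.0)
        assert delta["Reference 1"] == 5.0
        assert delta["Air"] == 0.0

    def test_air_shift_interpolates_downward(self, phantom):
        m = measurement(phantom, air=-995.0)
        d1, da, delta = compute_offsets(m, phantom)
        assert da == 5.0 and d1 == 0.0
        assert delta["Reference 2"] == pytest.approx((0 - 5) * 0.6 + 5)  # 2.0 HU
        assert delta["Air"] == 5.0

    def test_basis_and_air_deltas_exact(self, phantom):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = random_measurement(rng, phantom)
            d1, da, delta = compute_offsets(m, phantom)
            assert delta["Reference 1"] == d1
            assert delta["Air"] == da


class TestInternalCalibrate:
    def test_nominal_is_fixed_point(self, phantom, nominal_measurement):
        h = internal_calibrate(nominal_measurement, phantom)
        for m in phantom.calibrated_materials:
            assert h[m.name] == pytest.approx(rescale(m.nominal_ct), abs=1e-15)

    @given(b=st.floats(-20, 20))
    def test_global_shift_absorbed_at_basis(self, b):
        from lungct import default_phantom

        phantom = default_phantom()
        values = {m.name: m.nominal_ct + b for m in phantom.materials}
        values["Air"] = max(values["Air"], -1090.0)
        m = RawMeasurement(protocol=ScanProtocol("t"), values=values)
        h = internal_calibrate(m, phantom)
        # a pure miscalibration offset is absorbed for every material
        for mat in phantom.calibrated_materials:
            assert h[mat.name] == pytest.approx(rescale(mat.nominal_ct), abs=1e-12)

    def test_water_basis_propagates_water_error_by_density(self, water_phantom):
        # one of the observed water instability values
        m = measurement(water_phantom, water=19.5)
        _, _, delta = compute_offsets(m, water_phantom)
        assert delta["Water"] == pytest.approx(19.5)
        assert delta["Reference 2"] == pytest.approx(19.5 * 0.1926)
        assert delta["Lung"] == pytest.approx(19.5 * 0.1602)
        h = internal_calibrate(m, water_phantom)
        # foams were measured at nominal, so water's error leaks into them
        assert unrescale(h["Reference 2"]) == pytest.approx(-820.0 - 19.5 * 0.1926)

    def test_calibrated_foams_within_unit_interval(self, phantom):
        rng = np.random.default_rng(11)
        for _ in range(50):
            m = random_measurement(rng, phantom)
            h = internal_calibrate(m, phantom)
            for mat in phantom.calibrated_materials:
                assert -0.05 <= h[mat.name] <= 1.05


class TestAlphaOfFoam:
    def test_water_like_limit(self, phantom):
        c = phantom.constants
        assert alpha_of_foam(0.3, 0.3, c) == pytest.approx(1.0, abs=1e-12)

    def test_photoelectric_limit(self, phantom):
        c = phantom.constants
        assert alpha_of_foam(0.3 * c.z_pow, 0.3, c) == pytest.approx(0.0, abs=1e-12)

    @given(alpha=st.floats(0.85, 1.05), rho=st.floats(0.05, 1.0))
    def test_inverts_forward_model(self, alpha, rho):
        c = PhysicsConstants()
        h = rho * c.scale(alpha)
        assert alpha_of_foam(h, rho, c) == pytest.approx(alpha, abs=1e-12)

    def test_air_excluded(self, phantom):
        with pytest.raises(ValueError, match="rho_e"):
            alpha_of_foam(0.0, 0.0, phantom.constants)


def two_foam_phantom():
    """Minimal phantom for closed-form alpha_bar checks."""
    c = PhysicsConstants()
    mats = (
        MaterialSpec("Air", 0.0, -1000.0, 0.0, "air"),
        MaterialSpec("B", 100.0, -900.0, 0.1, "reference_foam"),
        MaterialSpec("A", 300.0, -700.0, 0.3, "basis_foam"),
    )
    return PhantomDefinition(materials=mats, basis_high="A", constants=c)


class TestEstimateAlphaBar:
    def test_consistent_scanner_recovered_exactly(self, phantom):
        c = phantom.constants
        for mode in ("wls", "mean"):
            h = {
                m.name: m.electron_density_ratio * c.scale(0.95)
                for m in phantom.regression_foams
            }
            ab, resid = estimate_alpha_bar(h, phantom, mode=mode)
            assert ab == pytest.approx(0.95, abs=1e-12)
            assert resid == pytest.approx(0.0, abs=1e-15)

    def test_weighted_and_unweighted_closed_forms(self):
        ph = two_foam_phantom()
        c = ph.constants
        h = {"A": 0.3 * c.scale(1.0), "B": 0.1 * c.scale(0.8)}
        ab_wls, _ = estimate_alpha_bar(h, ph, mode="wls")
        ab_mean, _ = estimate_alpha_bar(h, ph, mode="mean")
        # rho^2-weighted: (0.09*1.0 + 0.01*0.8) / 0.10
        assert ab_wls == pytest.approx(0.98, abs=1e-12)
        assert ab_mean == pytest.approx(0.9, abs=1e-12)

    def test_alpha_bar_within_per_foam_range(self, phantom):
        rng = np.random.default_rng(3)
        c = phantom.constants
        for _ in range(50):
            h = {
                m.name: m.electron_density_ratio
                * c.scale(rng.uniform(0.9, 1.0))
                for m in phantom.regression_foams
            }
            for mode in ("wls", "mean"):
                ab, _ = estimate_alpha_bar(h, phantom, mode=mode)
                alphas = [
                    alpha_of_foam(h[m.name], m.electron_density_ratio, c)
                    for m in phantom.regression_foams
                ]
                assert min(alphas) - 1e-12 <= ab <= max(alphas) + 1e-12

    def test_too_few_foams_rejected(self, phantom):
        with pytest.raises(ValueError, match="two foams"):
            estimate_alpha_bar({"Reference 1": 0.3}, phantom)


class TestEnergyMap:
    def test_identity_at_reference_energy(self, phantom):
        c = phantom.constants
        rng = np.random.default_rng(7)
        for _ in range(100):
            h = rng.uniform(0.0, 1.0)
            _, h80, ct80 = energy_map(h, c.alpha_80, c)
            assert abs(ct80 - unrescale(h)) < 1e-12

    def test_air_fixed_point(self, phantom):
        rho, h80, ct80 = energy_map(0.0, 0.93, phantom.constants)
        assert rho == 0.0
        assert ct80 == -1000.0

    @given(alpha_s=st.floats(0.9, 1.0))
    def test_composes_with_forward_model(self, alpha_s):
        c = PhysicsConstants()
        rho = 0.1602
        h = rho * c.scale(alpha_s)
        _, _, ct80 = energy_map(h, alpha_s, c)
        expected = 1000.0 * (rho * c.scale(c.alpha_80) - 1.0)
        assert ct80 == pytest.approx(expected, abs=1e-9)


class TestStandardizeScan:
    def test_nominal_pipeline_end_to_end(self, phantom, nominal_measurement):
        model, results = standardize_scan(nominal_measurement, phantom)
        lung = next(r for r in results if r.target_name == "Lung")
        assert lung.stage_values["raw"] == -835.0
        assert lung.stage_values["internal_cal"] == -835.0
        assert not model.flagged
        assert lung.ct80 == pytest.approx((lung.h80 - 1) * 1000, abs=1e-12)

    def test_collapse_across_scanner_alphas(self, phantom):
        ct80 = {}
        for alpha_s in (0.93, 0.97):
            m = simulate_scan(
                ScanProtocol("s", kvp=120.0, ctdi=3.0), phantom, NOISELESS,
                seed=0, alpha_s=alpha_s,
            )
            _, results = standardize_scan(m, phantom)
            ct80[alpha_s] = next(r for r in results if r.target_name == "Lung").ct80
        assert abs(ct80[0.93] - ct80[0.97]) < 1e-9

    def test_offset_invariance(self, phantom):
        base = simulate_scan(
            ScanProtocol("s", kvp=120.0, ctdi=3.0), phantom, NOISELESS,
            seed=0, alpha_s=0.95, cal_offset=0.0,
        )
        shifted = RawMeasurement(
            protocol=base.protocol,
            values={k: v + 8.0 for k, v in base.values.items()},
        )
        _, r0 = standardize_scan(base, phantom)
        _, r8 = standardize_scan(shifted, phantom)
        for a, b in zip(r0, r8):
            assert abs(a.ct80 - b.ct80) < 1e-9

    def test_degenerate_scan_flagged(self, phantom):
        # implausible lung reading far above the basis range
        m = measurement(phantom, lung=400.0)
        model, _ = standardize_scan(m, phantom)
        assert model.flagged
        assert any("Lung" in reason for reason in model.flag_reasons)

    def test_calibration_metadata_serializable(self, phantom, nominal_measurement):
        import json

        model, _ = standardize_scan(nominal_measurement, phantom)
        blob = json.loads(json.dumps(model.to_dict()))
        assert blob["basis"] == "Reference 1"
        assert blob["mode"] == "wls"
        assert set(blob["alpha_per_foam"]) == {
            "Reference 1", "Reference 2", "Reference 3",
        }


class TestOracleEquivalence:
    @staticmethod
    def straight_line_oracle(values, constants):
        """Independent transcription of the five calibration equations."""
        z = constants.z_eff**constants.n
        rho = {"Air": 0.0, "Reference 1": 0.321, "Reference 2": 0.1926,
               "Reference 3": 0.0642, "Lung": 0.1602}
        d1 = values["Reference 1"] - (-700.0)
        da = values["Air"] - (-1000.0)
        h = {}
        for name, r in rho.items():
            delta = (d1 - da) * r / 0.321 + da
            h[name] = (values[name] - delta) / 1000.0 + 1.0
        foams = ("Reference 3", "Reference 2", "Reference 1")
        s = sum(rho[n] * h[n] for n in foams) / sum(rho[n] ** 2 for n in foams)
        alpha_bar = (s - z) / (1.0 - z)
        s80 = constants.alpha_80 * (1.0 - z) + z
        out = {}
        for name in (*foams, "Lung"):
            rho_t = h[name] / (alpha_bar * (1.0 - z) + z)
            out[name] = (rho_t * s80 - 1.0) * 1000.0
        return out

    def test_matches_oracle_on_random_measurements(self, phantom):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            m = random_measurement(rng, phantom)
            _, results = standardize_scan(m, phantom)
            expected = self.straight_line_oracle(m.values, phantom.constants)
            for r in results:
                assert abs(r.ct80 - expected[r.target_name]) < 1e-10


class TestEstimatorInterface:
    def make_X(self, phantom, n=5, seed=0):
        import pandas as pd

        rng = np.random.default_rng(seed)
        rows = [random_measurement(rng, phantom).values for _ in range(n)]
        return pd.DataFrame(
            [
                {
                    "air": v["Air"], "ref1": v["Reference 1"],
                    "ref2": v["Reference 2"], "ref3": v["Reference 3"],
                    "lung": v["Lung"],
                }
                for v in rows
            ]
        )

    def test_fit_transform_matches_standardize_scan(self, phantom):
        X = self.make_X(phantom)
        est = CTNumberStandardizer().fit(X)
        out = est.transform(X)
        assert out.shape == (len(X), len(est.output_names_))
        lung_col = est.output_names_.index("Lung")
        for i, row in X.iterrows():
            m = RawMeasurement(
                protocol=ScanProtocol("x"),
                values={"Air": row["air"], "Reference 1": row["ref1"],
                        "Reference 2": row["ref2"], "Reference 3": row["ref3"],
                        "Lung": row["lung"]},
            )
            _, results = standardize_scan(m, phantom)
            lung = next(r for r in results if r.target_name == "Lung")
            assert out[i, lung_col] == pytest.approx(lung.ct80, abs=1e-12)

    def test_sklearn_protocol(self, phantom):
        est = CTNumberStandardizer(basis="foam1", alpha_mode="mean")
        cloned = clone(est)
        assert cloned.get_params()["alpha_mode"] == "mean"
        X = self.make_X(phantom)
        pipe = Pipeline([("standardize", CTNumberStandardizer())])
        out = pipe.fit_transform(X)
        assert out.shape[0] == len(X)
        names = pipe.named_steps["standardize"].get_feature_names_out()
        assert "Lung_hu80" in list(names)

    def test_array_input_uses_declared_order(self, phantom):
        X = self.make_X(phantom)
        est_df = CTNumberStandardizer().fit(X)
        est_arr = CTNumberStandardizer().fit(X.to_numpy())
        np.testing.assert_allclose(
            est_df.transform(X), est_arr.transform(X.to_numpy()), atol=1e-12
        )

    def test_missing_column_rejected(self, phantom):
        X = self.make_X(phantom).drop(columns=["ref2"])
        with pytest.raises(ValueError, match="missing required"):
            CTNumberStandardizer().fit(X)
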