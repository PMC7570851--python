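"""Digital-twin behaviour: mixing, electrode responses, measurement protocols."""

import numpy as np
import pytest

from etongue.calibration import fit_loglinear
from etongue.ions import SolutionSample, baseline_solution, mix_solutions
from etongue.sensors import (ElectrodeSpec, electrode_emf, measure_dcm,
                             measure_msam, simulate_ec_ph)


def nitrate_spec(noise=0.0):
    return ElectrodeSpec("NO3", -22.86, 208.47, {}, 1.0, noise, True)


class TestMixing:
    @pytest.mark.parametrize("parts,ion,expected", [
        ([(SolutionSample({"K": 100}), 10), (SolutionSample({"K": 0}), 10)], "K", 50.0),
        ([(SolutionSample({"NO3": 1328}), 10), (SolutionSample({"NO3": 0}), 30)], "NO3", 332.0),
    ])
    def test_volume_weighted_mass_balance(self, parts, ion, expected):
        assert mix_solutions(parts).conc(ion) == pytest.approx(expected)

    def test_single_part_is_identity(self):
        s = SolutionSample({"Na": 42.0, "Cl": 7.0}, 19.0)
        out = mix_solutions([(s, 25.0)])
        assert out.concentrations == s.concentrations
        assert out.temperature == s.temperature

    def test_temperature_mixes_by_volume(self):
        out = mix_solutions([(SolutionSample({}, 15.0), 30),
                             (SolutionSample({}, 35.0), 10)])
        assert out.temperature == pytest.approx(20.0)

    def test_zero_total_volume_rejected(self):
        with pytest.raises(ValueError):
            mix_solutions([(SolutionSample({"K": 1}), 0.0)])


class TestElectrodeEmf:
    def test_nitrate_working_curve_value(self):
        # -22.86 ln(100) + 208.47
        s = SolutionSample({"NO3": 100.0}, 25.0)
        assert electrode_emf(s, nitrate_spec()) == pytest.approx(103.1958, abs=1e-3)

    def test_intercept_at_floor(self):
        s = SolutionSample({"NO3": 1.0}, 25.0)
        assert electrode_emf(s, nitrate_spec()) == pytest.approx(208.47)

    def test_drift_offset_is_additive(self):
        s = SolutionSample({"NO3": 57.0}, 25.0)
        base = electrode_emf(s, nitrate_spec())
        assert electrode_emf(s, nitrate_spec(), drift_offset=5.0) == \
            pytest.approx(base + 5.0)

    def test_floor_clamps_response_below_detection_limit(self):
        lo = SolutionSample({"NO3": 0.01}, 25.0)
        at_floor = SolutionSample({"NO3": 1.0}, 25.0)
        assert electrode_emf(lo, nitrate_spec()) == \
            electrode_emf(at_floor, nitrate_spec())

    def test_nernstian_temperature_scaling(self):
        """Slope recovered at 35 degC equals 25 degC slope x 308.15/298.15."""
        grid = np.geomspace(5, 1000, 12)
        slopes = {}
        for temp in (25.0, 35.0):
            pots = [electrode_emf(SolutionSample({"NO3": c}, temp),
                                  nitrate_spec()) for c in grid]
            slopes[temp] = np.polyfit(np.log(grid), pots, 1)[0]
        assert slopes[35.0] == pytest.approx(
            slopes[25.0] * 308.15 / 298.15, abs=1e-9)

    def test_cation_emf_monotone_in_selective_ion(self):
        spec = ElectrodeSpec("K", 23.07, -237.03, {"NH4": 0.05}, 1.0, 0.0, True)
        emfs = [electrode_emf(SolutionSample({"K": 50.0, "NH4": a}, 25.0), spec)
                for a in np.linspace(0, 120, 25)]
        assert np.all(np.diff(emfs) >= 0)

    def test_opposite_sign_interference_rejected(self):
        spec = ElectrodeSpec("NO3", -22.86, 208.47, {"K": 0.01}, 1.0, 0.0, True)
        with pytest.raises(ValueError, match="opposite-sign"):
            electrode_emf(SolutionSample({"NO3": 10, "K": 10}), spec)

    def test_slope_sign_must_match_charge(self):
        with pytest.raises(ValueError, match="slope sign"):
            ElectrodeSpec("NO3", +22.0, 0.0)
        with pytest.raises(ValueError, match="slope sign"):
            ElectrodeSpec("K", -22.0, 0.0)


class TestEcPh:
    def test_blank_solution(self, quiet_array):
        ec, ph = simulate_ec_ph(SolutionSample({}, 25.0), quiet_array)
        assert ec == 0.0
        assert ph == pytest.approx(quiet_array.ph_baseline)

    def test_ec_is_linear_in_concentrations(self, quiet_array, mixed_sample):
        ec1, _ = simulate_ec_ph(mixed_sample, quiet_array)
        doubled = SolutionSample(
            {k: 2 * v for k, v in mixed_sample.concentrations.items()}, 22.0)
        ec2, _ = simulate_ec_ph(doubled, quiet_array)
        assert ec2 == pytest.approx(2 * ec1)

    def test_ph_monotone_nonincreasing_in_phosphate(self, quiet_array):
        phs = [simulate_ec_ph(SolutionSample({"H2PO4": c}, 25.0),
                              quiet_array)[1]
               for c in np.linspace(0, 678, 40)]
        assert np.all(np.diff(phs) <= 0)


class TestProtocols:
    def test_msam_reproducible_without_randomness(self, quiet_array, mixed_sample):
        base = baseline_solution()
        r1 = measure_msam(base, mixed_sample, quiet_array, seed=3)
        r2 = measure_msam(base, mixed_sample, quiet_array, seed=99)
        np.testing.assert_array_equal(r1.ux, r2.ux)
        np.testing.assert_array_equal(r1.u0, r2.u0)

    def test_sample_equal_to_baseline_gives_zero_difference(self, quiet_array):
        base = baseline_solution()
        rec = measure_msam(base, base.copy(), quiet_array, seed=0)
        np.testing.assert_allclose(rec.ux, rec.u0, atol=1e-12)

    @pytest.mark.parametrize("drift_sd", [1.0, 5.0, 50.0])
    def test_session_drift_cancels_in_difference(self, quiet_array,
                                                 mixed_sample, drift_sd):
        from dataclasses import replace
        drifty = replace(quiet_array, drift_sd=drift_sd)
        base = baseline_solution()
        clean = measure_msam(base, mixed_sample, quiet_array, seed=7)
        drifted = measure_msam(base, mixed_sample, drifty, seed=7)
        np.testing.assert_array_equal(drifted.ux - drifted.u0,
                                      clean.ux - clean.u0)
        assert not np.allclose(drifted.ux, clean.ux)

    def test_dcm_equals_sample_phase_when_quiet(self, quiet_array, mixed_sample):
        base = baseline_solution()
        msam = measure_msam(base, mixed_sample, quiet_array, seed=0)
        dcm = measure_dcm(mixed_sample, quiet_array, seed=0)
        np.testing.assert_allclose(dcm[:8], msam.ux, atol=1e-12)
        assert dcm[8] == mixed_sample.temperature

    def test_dcm_deterministic_given_seed(self, noisy_array, mixed_sample):
        a = measure_dcm(mixed_sample, noisy_array, seed=5)
        b = measure_dcm(mixed_sample, noisy_array, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_dcm_retains_drift(self, quiet_array, mixed_sample):
        from dataclasses import replace
        drifty = replace(quiet_array, drift_sd=10.0)
        clean = measure_dcm(mixed_sample, quiet_array, seed=2)
        drifted = measure_dcm(mixed_sample, drifty, seed=2)
        assert not np.allclose(drifted[:8], clean[:8])

    def test_missing_seed_warns_and_uses_session_seed(self, noisy_array,
                                                      mixed_sample):
        base = baseline_solution()
        with pytest.warns(UserWarning, match="session_seed"):
            r1 = measure_msam(base, mixed_sample, noisy_array)
        r2 = measure_msam(base, mixed_sample, noisy_array,
                          seed=noisy_array.session_seed)
        np.testing.assert_array_equal(r1.ux, r2.ux)

    def test_single_ion_series_is_exactly_loglinear(self, quiet_array):
        """No interference, one varied ion: DCM readings fit R^2 = 1."""
        spec = nitrate_spec()
        grid = np.geomspace(5, 1300, 10)
        pots = [electrode_emf(SolutionSample({"NO3": c}, 25.0), spec)
                for c in grid]
        fit = fit_loglinear(grid, pots)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(-22.86, abs=1e-9)
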