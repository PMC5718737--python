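"""TLD reading reduction: sensitivity normalization, decay correction,
background subtraction, and uncertainty combination."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import tg43seed as t
from tg43seed.errors import CalibrationError, DomainError, ValidationError


class TestSensitivityFactors:
    def test_identical_readings_give_unit_factors(self):
        factors = t.sensitivity_factors({"a": 50.0, "b": 50.0, "c": 50.0})
        assert all(f == 1.0 for f in factors.values())

    def test_two_chip_example(self):
        factors = t.sensitivity_factors({"a": 90.0, "b": 110.0})
        assert factors == {"a": 0.9, "b": 1.1}

    @given(
        readings=st.lists(st.floats(1.0, 1e4), min_size=2, max_size=20)
    )
    def test_batch_mean_is_exactly_one(self, readings):
        factors = t.sensitivity_factors({f"c{i}": v for i, v in enumerate(readings)})
        assert np.mean(list(factors.values())) == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_reading_rejected(self):
        with pytest.raises(CalibrationError):
            t.sensitivity_factors({"a": 0.0, "b": 100.0})

    def test_single_chip_rejected(self):
        with pytest.raises(CalibrationError):
            t.sensitivity_factors({"a": 100.0})


class TestEffectiveExposureTime:
    def test_one_hour_with_17_day_half_life(self):
        # (1 − e^{−λT})/λ with λT ≪ 1: frozen closed-form value
        assert t.effective_exposure_time(1.0, 17.0) == pytest.approx(0.9991510, abs=1e-6)

    def test_short_exposure_limit_ratio_one(self):
        T = 1e-6
        assert t.effective_exposure_time(T, 17.0) / T == pytest.approx(1.0, rel=1e-9)

    def test_one_half_life_exposure(self):
        # T = one half-life: t_eff = (1/2)/λ ≈ 12.264 days
        T_hours = 17.0 * 24.0
        teff_days = t.effective_exposure_time(T_hours, 17.0) / 24.0
        assert teff_days == pytest.approx(12.2629, abs=1e-3)

    def test_nonpositive_arguments_rejected(self):
        with pytest.raises(DomainError):
            t.effective_exposure_time(0.0, 17.0)
        with pytest.raises(DomainError):
            t.effective_exposure_time(1.0, -1.0)


def _simple_setup(readings, bg=(10.0, 10.0), T=1.0):
    rs = t.TLDReadingSet(
        readings=readings, background_readings=list(bg), exposure_hours=T
    )
    cal = t.CalibrationSet(
        epsilon_lambda=2.0,
        sensitivity={c.chip_id: 1.0 for c in readings},
    )
    return rs, cal


class TestReduce:
    def test_reading_at_background_level_gives_zero_dose(self):
        rs, cal = _simple_setup([t.ChipReading("a", 5.0, 90.0, 10.0)])
        rows = t.reduce(rs, cal, sk=1.0)
        assert rows[0].dose_per_sk == 0.0
        assert not rows[0].clamped

    def test_below_background_clamped_with_warning(self):
        rs, cal = _simple_setup([t.ChipReading("a", 5.0, 90.0, 8.0)])
        with pytest.warns(UserWarning, match="clamped"):
            rows = t.reduce(rs, cal, sk=1.0)
        assert rows[0].dose_per_sk == 0.0
        assert rows[0].clamped

    def test_zero_noise_synthetic_recovers_truth_exactly(self, noiseless_config):
        rs, cal, truth = t.simulate_tld_experiment(
            noiseless_config, reading_noise_sigma=0.0, chip_sensitivity_sigma=0.04
        )
        rows = t.reduce(rs, cal, sk=truth.sk_true)
        at_ref = next(r for r in rows if r.r == 1.0)
        assert at_ref.dose_per_sk == pytest.approx(truth.lambda_true, rel=1e-12)
        assert at_ref.type_a_percent == pytest.approx(0.0, abs=1e-9)

    def test_linearity_under_global_scaling(self, noiseless_config):
        rs, cal, truth = t.simulate_tld_experiment(noiseless_config)
        scaled = t.TLDReadingSet(
            readings=[
                t.ChipReading(c.chip_id, c.r, c.theta, 3.0 * c.reading)
                for c in rs.readings
            ],
            background_readings=[3.0 * b for b in rs.background_readings],
            exposure_hours=rs.exposure_hours,
        )
        base = t.reduce(rs, cal, sk=truth.sk_true)
        tripled = t.reduce(scaled, cal, sk=truth.sk_true)
        for b, s in zip(base, tripled):
            assert s.dose_per_sk == pytest.approx(3.0 * b.dose_per_sk, rel=1e-12)
            assert s.type_a_percent == pytest.approx(b.type_a_percent, rel=1e-9)

    def test_invariant_to_chip_relabeling(self, noiseless_config):
        rs, cal, truth = t.simulate_tld_experiment(noiseless_config)
        mapping = {c.chip_id: f"relabeled_{c.chip_id}" for c in rs.readings}
        rs2 = t.TLDReadingSet(
            readings=[
                t.ChipReading(mapping[c.chip_id], c.r, c.theta, c.reading)
                for c in rs.readings
            ],
            background_readings=list(rs.background_readings),
            exposure_hours=rs.exposure_hours,
        )
        cal2 = t.CalibrationSet(
            epsilon_lambda=cal.epsilon_lambda,
            sensitivity={mapping[k]: v for k, v in cal.sensitivity.items()},
        )
        r1 = t.reduce(rs, cal, sk=truth.sk_true)
        r2 = t.reduce(rs2, cal2, sk=truth.sk_true)
        for a, b in zip(r1, r2):
            assert a.dose_per_sk == b.dose_per_sk
            assert a.type_a_percent == b.type_a_percent

    def test_missing_sensitivity_factor_rejected(self):
        rs, cal = _simple_setup([t.ChipReading("a", 1.0, 90.0, 20.0)])
        bad_cal = t.CalibrationSet(epsilon_lambda=2.0, sensitivity={"other": 1.0})
        with pytest.raises(CalibrationError, match="a"):
            t.reduce(rs, bad_cal, sk=1.0)

    def test_missing_energy_response_entry_rejected(self):
        rs, _ = _simple_setup([t.ChipReading("a", 1.0, 90.0, 20.0)])
        cal = t.CalibrationSet(
            epsilon_lambda=2.0,
            sensitivity={"a": 1.0},
            energy_response={(2.0, 90.0): 1.05},
        )
        with pytest.raises(CalibrationError, match="energy response"):
            t.reduce(rs, cal, sk=1.0)

    def test_replicates_averaged_and_type_a_is_relative_sd(self):
        chips = [
            t.ChipReading("a", 1.0, 90.0, 110.0),
            t.ChipReading("b", 1.0, 90.0, 90.0),
        ]
        rs, cal = _simple_setup(chips, bg=(0.0, 0.0))
        rows = t.reduce(rs, cal, sk=1.0)
        assert len(rows) == 1
        doses = np.array([110.0, 90.0])
        assert rows[0].type_a_percent == pytest.approx(
            doses.std(ddof=1) / doses.mean() * 100.0, rel=1e-12
        )
        assert rows[0].n_chips == 2


class TestUncertainty:
    def test_three_four_five(self):
        budget = t.combine_uncertainty(3.0, 4.0)
        assert budget.combined == 5.0

    def test_zero_type_b_identity(self):
        assert t.combine_uncertainty(2.9, 0.0).combined == 2.9

    def test_measurement_budget_magnitude(self):
        # 2.9% type A with a 6.37% type B budget combines to ≈7%
        assert t.combine_uncertainty(2.9, 6.37).combined == pytest.approx(7.0, abs=0.01)

    def test_negative_component_rejected(self):
        with pytest.raises(DomainError):
            t.combine_uncertainty(-1.0, 2.0)

    def test_budget_invariant_enforced(self):
        with pytest.raises(ValidationError):
            t.UncertaintyBudget(type_a=3.0, type_b=4.0, combined=6.0)

    def test_calibration_type_b_quadrature(self):
        cal = t.CalibrationSet(
            epsilon_lambda=1.0,
            sensitivity={"a": 1.0, "b": 1.0},
            type_b_components=(("energy response", 3.0), ("positioning", 4.0)),
        )
        assert cal.type_b_combined == 5.0


class TestRecoveryOverManyExperiments:
    def test_mean_lambda_within_one_percent_and_dispersion_matches(self):
        lam_means = []
        chip_devs = []
        truth_lambda = None
        for seed in range(50):
            cfg = t.SimulatorConfig(random_seed=seed)
            rs, cal, truth = t.simulate_tld_experiment(
                cfg, reading_noise_sigma=0.01, chip_sensitivity_sigma=0.03
            )
            truth_lambda = truth.lambda_true
            rows = t.reduce(rs, cal, sk=truth.sk_true)
            at_ref = next(r for r in rows if r.r == 1.0)
            lam_means.append(at_ref.dose_per_sk)
            chip_devs.append(at_ref.type_a_percent / 100.0)
        assert np.mean(lam_means) == pytest.approx(truth_lambda, rel=0.01)
        # pooled per-chip dispersion should match the injected 1% within 30%
        pooled = np.sqrt(np.mean(np.square(chip_devs)))
        assert pooled == pytest.approx(0.01, rel=0.30)
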