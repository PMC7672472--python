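"""Unit and property tests for the synthetic digestion generator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exoprofile import fixtures
from exoprofile.errors import InvalidParameterError
from exoprofile.models import (
    AptamerSpec,
    BindingParams,
    DigestionParams,
    LigandCondition,
    SamplingSchedule,
    SDParams,
)
from exoprofile.simulate import (
    expected_fluorescence,
    fraction_bound,
    simulate_panel,
    simulate_sd_readout,
    simulate_timecourse,
)


class TestFractionBound:
    @pytest.mark.parametrize(
        "c, kd, expected",
        [
            (0.0, 15.0, 0.0),
            (15.0, 15.0, 0.5),
            (200.0, 15.0, 200.0 / 215.0),
            (500.0, None, 0.0),  # non-binder sentinel
        ],
    )
    def test_isotherm(self, c, kd, expected):
        assert fraction_bound(c, kd) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("c, kd", [(-1.0, 15.0), (10.0, 0.0), (10.0, -5.0),
                                       (10.0, math.inf)])
    def test_invalid_parameters(self, c, kd):
        with pytest.raises(InvalidParameterError):
            fraction_bound(c, kd)

    def test_ligand_excess_warning(self, caplog):
        with caplog.at_level("WARNING"):
            fraction_bound(5.0, 15.0, aptamer_concentration=1.0)
        assert "ligand-excess" in caplog.text


class TestExpectedFluorescence:
    def test_intact_at_time_zero(self, mmc_aptamer):
        for mode in ("slow", "fast"):
            params = DigestionParams(
                k_unprotected=0.05, k_leak=0.002, amplitude=800.0,
                background=20.0, exchange_mode=mode,
            )
            for theta in (0.0, 0.4, 1.0):
                assert expected_fluorescence(0.0, theta, mmc_aptamer, params) == (
                    pytest.approx(820.0)
                )

    def test_unbound_single_exponential(self, mmc_aptamer):
        """theta=0, k_leak=0: F(1/k_u) = B + A/e (closed form)."""
        params = DigestionParams(k_unprotected=0.05, k_leak=0.0, amplitude=100.0,
                                 background=7.0)
        f = expected_fluorescence(1 / 0.05, 0.0, mmc_aptamer, params)
        assert f == pytest.approx(7.0 + 100.0 / math.e, rel=1e-12)

    def test_saturated_plateau_is_protected_fraction(self, mmc_aptamer):
        """theta=1, k_leak=0, large t: plateau at A*P/N (41/46-style retained
        product)."""
        params = DigestionParams(k_unprotected=0.05, k_leak=0.0, amplitude=100.0)
        f = expected_fluorescence(1e4, 1.0, mmc_aptamer, params)
        assert f == pytest.approx(100.0 * 42 / 73, rel=1e-6)

    @given(
        k_u=st.floats(0.005, 0.5),
        amplitude=st.floats(1.0, 1e4),
        t=st.floats(0.0, 500.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_exchange_modes_coincide_at_theta_zero(self, k_u, amplitude, t):
        apt = AptamerSpec(aptamer_id="a", full_length_nt=50, protected_length_nt=40)
        slow = DigestionParams(k_unprotected=k_u, k_leak=k_u / 20, amplitude=amplitude,
                               exchange_mode="slow")
        fast = slow.model_copy(update={"exchange_mode": "fast"})
        f_slow = expected_fluorescence(t, 0.0, apt, slow)
        f_fast = expected_fluorescence(t, 0.0, apt, fast)
        assert f_slow == pytest.approx(f_fast, rel=1e-12)

    @given(
        theta=st.floats(0.0, 1.0),
        k_u=st.floats(0.005, 0.2),
        mode=st.sampled_from(["slow", "fast"]),
    )
    @settings(max_examples=50, deadline=None)
    def test_noiseless_curve_non_increasing_in_time(self, theta, k_u, mode):
        apt = AptamerSpec(aptamer_id="a", full_length_nt=73, protected_length_nt=42)
        params = DigestionParams(k_unprotected=k_u, k_leak=k_u / 30,
                                 exchange_mode=mode)
        t = np.linspace(0, 300, 121)
        f = expected_fluorescence(t, theta, apt, params)
        assert np.all(np.diff(f) <= 1e-9)

    @pytest.mark.parametrize("mode", ["slow", "fast"])
    def test_protection_monotone_in_occupancy(self, mmc_aptamer, mode):
        """More occupancy means more retained signal at every t > 0 (holds
        when omega * k_u >= k_leak, true for all bundled parameters)."""
        params = fixtures.DEFAULT_DIGESTION.model_copy(
            update={"noise_cv": 0.0, "exchange_mode": mode}
        )
        t = np.linspace(1.0, 240.0, 80)
        curves = [
            expected_fluorescence(t, theta, mmc_aptamer, params)
            for theta in np.linspace(0, 1, 6)
        ]
        for lo, hi in zip(curves, curves[1:]):
            assert np.all(hi >= lo - 1e-9)


class TestSimulateTimecourse:
    def test_noiseless_matches_model_exactly(self, mmc_aptamer, noiseless_params,
                                             schedule):
        cond = LigandCondition(ligand_id="mephedrone", concentration=200.0)
        binding = BindingParams(aptamer_id="MMC1", ligand_id="mephedrone", kd_app=15.0)
        tc = simulate_timecourse(mmc_aptamer, cond, binding, noiseless_params,
                                 schedule, seed=7)
        theta = fraction_bound(200.0, 15.0)
        expected = expected_fluorescence(
            np.asarray(schedule.times), theta, mmc_aptamer, noiseless_params
        )
        assert np.allclose(tc.fluorescence, expected, rtol=0, atol=0)

    def test_same_seed_is_deterministic(self, mmc_aptamer, schedule):
        params = fixtures.DEFAULT_DIGESTION
        cond = LigandCondition(ligand_id="mephedrone", concentration=200.0)
        binding = BindingParams(aptamer_id="MMC1", ligand_id="mephedrone", kd_app=15.0)
        a = simulate_timecourse(mmc_aptamer, cond, binding, params, schedule, seed=11)
        b = simulate_timecourse(mmc_aptamer, cond, binding, params, schedule, seed=11)
        assert a == b
        c = simulate_timecourse(mmc_aptamer, cond, binding, params, schedule, seed=12)
        assert a != c

    def test_trajectory_ratio_matches_closed_form(self):
        """Final/initial expected ratio reproduces the model formula evaluated
        independently (kd=15 uM, c=200 uM, k_u=0.05, k_leak=0.002, N=73,
        P=42, 15-min sampling to 240 min)."""
        apt = AptamerSpec(aptamer_id="x", full_length_nt=73, protected_length_nt=42)
        params = DigestionParams(k_unprotected=0.05, k_leak=0.002, amplitude=1000.0,
                                 background=0.0, noise_cv=0.0)
        schedule = SamplingSchedule.regular(240.0, 15.0)
        cond = LigandCondition(ligand_id="L", concentration=200.0)
        binding = BindingParams(aptamer_id="x", ligand_id="L", kd_app=15.0)
        tc = simulate_timecourse(apt, cond, binding, params, schedule, seed=0)
        # independent evaluation of the slow-exchange formula
        theta = 200.0 / 215.0
        omega = 42 / 73
        t = 240.0
        f_end = 1000.0 * (
            (1 - theta) * math.exp(-0.05 * t)
            + theta * (omega + (1 - omega) * math.exp(-0.05 * t)) * math.exp(-0.002 * t)
        )
        assert tc.fluorescence[-1] / tc.fluorescence[0] == pytest.approx(
            f_end / 1000.0, rel=1e-12
        )


class TestSimulatePanel:
    def test_counts_control_added_automatically(self, mmc_aptamer, noiseless_params,
                                                schedule):
        conds = [LigandCondition(ligand_id="mephedrone", concentration=200.0)]
        binding = [BindingParams(aptamer_id="MMC1", ligand_id="mephedrone",
                                 kd_app=15.0)]
        exp = simulate_panel([mmc_aptamer], conds, binding, 3, noiseless_params,
                             schedule, seed=1)
        assert len(exp.timecourses) == 6  # (control + target) x 3 replicates

    def test_candidate_screen_shape(self, noiseless_params, schedule):
        aptamers, conds, binding = fixtures.mephedrone_screen_panel()
        exp = simulate_panel(aptamers, conds, binding, 2, noiseless_params,
                             schedule, seed=1)
        assert len(exp.timecourses) == 116  # 29 x (control + target) x 2

    def test_all_non_binders_match_control_exactly(self, noiseless_params, schedule):
        aptamers = [
            AptamerSpec(aptamer_id=f"a{i}", full_length_nt=73, protected_length_nt=42)
            for i in range(3)
        ]
        conds = [LigandCondition(ligand_id="L", concentration=400.0)]
        binding = [BindingParams(aptamer_id=a.aptamer_id, ligand_id="L", kd_app=None)
                   for a in aptamers]
        exp = simulate_panel(aptamers, conds, binding, 1, noiseless_params,
                             schedule, seed=1)
        for apt in aptamers:
            curves = [tc.fluorescence for tc in exp.timecourses
                      if tc.aptamer_id == apt.aptamer_id]
            assert curves[0] == curves[1]

    def test_missing_binding_entry_is_non_binder_and_logged(
        self, mmc_aptamer, noiseless_params, schedule, caplog
    ):
        conds = [LigandCondition(ligand_id="unknown", concentration=100.0)]
        with caplog.at_level("INFO"):
            exp = simulate_panel([mmc_aptamer], conds, [], 1, noiseless_params,
                                 schedule, seed=1)
        assert "non-binder" in caplog.text
        ligand = [tc for tc in exp.timecourses if not tc.is_control][0]
        control = [tc for tc in exp.timecourses if tc.is_control][0]
        assert ligand.fluorescence == control.fluorescence

    def test_panel_bit_reproducible(self, schedule):
        aptamers, conds, binding = fixtures.mephedrone_screen_panel()
        a = simulate_panel(aptamers, conds, binding, 2, fixtures.DEFAULT_DIGESTION,
                           schedule, seed=42)
        b = simulate_panel(aptamers, conds, binding, 2, fixtures.DEFAULT_DIGESTION,
                           schedule, seed=42)
        assert a.timecourses == b.timecourses

    def test_replicate_mean_converges_to_noiseless_curve(self, mmc_aptamer, schedule):
        """Sample mean over 200 replicates lies within 3*sigma/sqrt(n) of the
        model curve at every time point."""
        n = 200
        params = fixtures.DEFAULT_DIGESTION.model_copy(update={"noise_cv": 0.05})
        conds = [LigandCondition(ligand_id="mephedrone", concentration=200.0)]
        binding = [BindingParams(aptamer_id="MMC1", ligand_id="mephedrone",
                                 kd_app=15.0)]
        exp = simulate_panel([mmc_aptamer], conds, binding, n, params, schedule,
                             seed=3)
        curves = np.array([tc.fluorescence for tc in exp.timecourses
                           if not tc.is_control])
        clean = expected_fluorescence(
            np.asarray(schedule.times), fraction_bound(200.0, 15.0), mmc_aptamer,
            params,
        )
        tol = 3 * params.noise_cv * clean / math.sqrt(n)
        assert np.all(np.abs(curves.mean(axis=0) - clean) <= tol + 1e-9)


class TestStrandDisplacement:
    def setup_method(self):
        self.sd = SDParams(f_max=1000.0, quench_efficiency=0.9, kd_sd=60.0,
                           max_displacement=0.85)

    def test_no_ligand_gives_quenched_baseline(self):
        cond = LigandCondition(ligand_id="L", concentration=0.0)
        f, f0 = simulate_sd_readout(cond, None, self.sd, seed=0)
        assert f == f0 == pytest.approx(100.0)  # (1 - 0.9) * 1000

    def test_attenuating_artifact_masks_a_true_binder(self):
        """Strong binder with a -90%% fluorophore artifact reads below the
        ligand-free baseline even though displacement happened."""
        cond = LigandCondition(ligand_id="chlorpromazine", concentration=400.0,
                               dye_artifact_factor=0.1)
        binding = BindingParams(aptamer_id="a", ligand_id="chlorpromazine",
                                kd_app=0.6)
        f, f0 = simulate_sd_readout(cond, binding, self.sd, seed=0)
        delta = 0.85 * 400.0 / 460.0
        expected_true = 100.0 + 900.0 * delta
        assert f == pytest.approx(0.1 * expected_true, rel=1e-12)
        assert f < f0

    def test_enhancing_artifact_fakes_a_non_binder_positive(self):
        cond = LigandCondition(ligand_id="acetyl-fentanyl", concentration=400.0,
                               dye_artifact_factor=1.3)
        binding = BindingParams(aptamer_id="a", ligand_id="acetyl-fentanyl",
                                kd_app=None)
        f, f0 = simulate_sd_readout(cond, binding, self.sd, seed=0)
        assert f == pytest.approx(1.3 * 100.0, rel=1e-12)
        assert f > f0
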