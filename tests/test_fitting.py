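"""Closed-form moment inversion, clamping rules, and bootstrap SEs."""

import math

import numpy as np
import pytest

import hostpar as hp
from hostpar import fitting
from hostpar.design import AMBIENT, NO_PARASITOID


def make_vials(host, parasitoid, timing, fly_counts, wasp_counts=None,
               eggs=50):
    wasp_counts = wasp_counts or [0] * len(fly_counts)
    cell = hp.DesignCell(host, parasitoid, timing)
    return [hp.VialRecord(cell, f"r{i+1}", eggs=eggs, flies=f, wasps=w)
            for i, (f, w) in enumerate(zip(fly_counts, wasp_counts))]


class TestBaselineMortality:
    def test_full_survival_boundary(self, constants):
        vials = make_vials("h", NO_PARASITOID, AMBIENT, [50] * 6)
        assert hp.fit_baseline_mortality(vials, constants) == 0.0

    def test_hand_computed_value(self, constants):
        # six vials totalling 204 flies: m0 = -ln(0.68)/8
        vials = make_vials("h", NO_PARASITOID, AMBIENT,
                           [34, 34, 34, 34, 34, 34])
        m0 = hp.fit_baseline_mortality(vials, constants)
        assert m0 == pytest.approx(0.048208, abs=5e-7)
        assert m0 == pytest.approx(-math.log(0.68) / 8, rel=1e-12)

    def test_zero_emergence_is_degenerate(self, constants):
        vials = make_vials("h", NO_PARASITOID, AMBIENT, [0] * 6)
        with pytest.raises(hp.DegenerateEstimateError, match="infinite"):
            hp.fit_baseline_mortality(vials, constants)

    def test_mixed_strata_rejected(self, constants):
        vials = (make_vials("h", NO_PARASITOID, AMBIENT, [30])
                 + make_vials("g", NO_PARASITOID, AMBIENT, [30]))
        with pytest.raises(hp.ValidationError, match="mix hosts"):
            hp.fit_baseline_mortality(vials, constants)


class TestHeatMortality:
    def test_equal_emergence_means_zero_differential(self, constants):
        ambient = make_vials("h", NO_PARASITOID, AMBIENT, [34] * 6)
        m0 = hp.fit_baseline_mortality(ambient, constants)
        heated = make_vials("h", NO_PARASITOID, "during", [34] * 6)
        assert hp.fit_heat_mortality(heated, m0, constants) == \
            pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self, constants):
        # ambient mean 34 (m0 = 0.048208), heated mean 25:
        # m_tau = -ln(0.5) - 0.385662
        m0 = -math.log(0.68) / 8
        heated = make_vials("h", NO_PARASITOID, "during", [25] * 6)
        m_tau = hp.fit_heat_mortality(heated, m0, constants)
        assert m_tau == pytest.approx(0.307485, abs=5e-7)

    def test_survival_benefit_warns_and_is_negative(self, constants):
        m0 = -math.log(0.68) / 8
        heated = make_vials("h", NO_PARASITOID, "before", [40] * 6)
        with pytest.warns(UserWarning, match="survival benefit"):
            m_tau = hp.fit_heat_mortality(heated, m0, constants)
        assert m_tau < 0


class TestAttackRateAndConversion:
    M0 = -math.log(0.68) / 8  # control expectation = 34 flies

    def test_control_level_emergence_gives_zero(self, constants):
        # mean flies equal to the no-parasitoid expectation of 34
        vials = make_vials("h", "w", AMBIENT, [34] * 6, [0] * 6)
        a0 = hp.fit_attack_rate(vials, self.M0, constants)
        assert a0 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self, constants):
        vials = make_vials("h", "w", AMBIENT, [20] * 6, [11] * 6)
        a0 = hp.fit_attack_rate(vials, self.M0, constants)
        # exact closed form: ln(34/20)/3
        assert a0 == pytest.approx(math.log(34 / 20) / 3, rel=1e-12)
        assert a0 == pytest.approx(0.176876, abs=5e-7)

    def test_clamp_when_above_expectation(self, constants):
        vials = make_vials("h", "w", AMBIENT, [40] * 6, [2] * 6)
        with pytest.warns(UserWarning, match="clamped"):
            assert hp.fit_attack_rate(vials, self.M0, constants) == 0.0

    def test_conversion_inverts_attack_example(self, constants):
        # mean wasps 11.2 with a0 = 0.176895: infected pool = 14 hosts
        a0 = -math.log(20 / 34) / 3
        vials = make_vials("h", "w", AMBIENT, [20] * 5,
                           [11, 11, 11, 11, 12])  # mean 11.2
        eps = hp.fit_conversion(vials, self.M0, a0, constants)
        assert eps == pytest.approx(0.8, abs=1e-9)

    def test_zero_wasps_gives_zero_conversion(self, constants):
        vials = make_vials("h", "w", AMBIENT, [20] * 6, [0] * 6)
        a0 = -math.log(20 / 34) / 3
        assert hp.fit_conversion(vials, self.M0, a0, constants) == 0.0

    def test_conversion_clamped_to_one(self, constants):
        vials = make_vials("h", "w", AMBIENT, [20] * 6, [15] * 6)
        a0 = -math.log(20 / 34) / 3
        with pytest.warns(UserWarning, match="clamped"):
            assert hp.fit_conversion(vials, self.M0, a0, constants) == 1.0

    def test_wasps_without_attacks_inconsistent(self, constants):
        vials = make_vials("h", "w", AMBIENT, [34] * 6, [3] * 6)
        with pytest.raises(hp.DataError, match="attack rate is zero"):
            hp.fit_conversion(vials, self.M0, 0.0, constants)


class TestFitAll:
    def test_self_consistency_moment_inversion(self, additive_dataset,
                                               constants):
        """Fitted params reproduce every fitting stratum's observed means:
        the closed forms are exact moment inversions."""
        fit = hp.fit_all(additive_dataset, constants, n_bootstrap=0)
        assert not any("clamped" in w for w in fit.warnings)
        for host in hp.HOSTS:
            for timing in hp.TIMINGS:
                cell = hp.DesignCell(host, NO_PARASITOID, timing)
                vials = hp.select(additive_dataset, host=host,
                                  parasitoid=NO_PARASITOID,
                                  heat_timing=timing)
                f, _ = hp.expected_emergence(fit.params, cell, constants)
                observed = sum(v.flies for v in vials) / len(vials)
                assert f == pytest.approx(observed, abs=1e-9)
            for para in hp.PARASITOIDS:
                cell = hp.DesignCell(host, para, AMBIENT)
                vials = hp.select(additive_dataset, host=host,
                                  parasitoid=para, heat_timing=AMBIENT)
                f, w = hp.expected_emergence(fit.params, cell, constants)
                assert f == pytest.approx(
                    sum(v.flies for v in vials) / len(vials), abs=1e-9)
                assert w == pytest.approx(
                    sum(v.wasps for v in vials) / len(vials), abs=1e-9)

    def test_missing_stratum_listed(self, additive_dataset, constants):
        pruned = [v for v in additive_dataset
                  if not (v.cell.host == "birchii"
                          and v.cell.parasitoid == NO_PARASITOID
                          and v.cell.heat_timing == "during")]
        with pytest.raises(hp.ValidationError,
                           match=r"\(birchii, none, during\)"):
            hp.fit_all(pruned, constants, n_bootstrap=0)

    def test_no_bootstrap_flags_skipped_ses(self, additive_dataset,
                                            constants):
        fit = hp.fit_all(additive_dataset, constants, n_bootstrap=0)
        assert all(se is None for se in fit.standard_errors.values())
        assert any("bootstrap skipped" in w for w in fit.warnings)

    def test_bootstrap_reproducible_and_positive(self, additive_dataset,
                                                 constants):
        a = hp.fit_all(additive_dataset, constants, n_bootstrap=100, rng=3)
        b = hp.fit_all(additive_dataset, constants, n_bootstrap=100, rng=3)
        assert a.standard_errors == b.standard_errors
        assert all(se is not None and se > 0
                   for se in a.standard_errors.values())

    def test_parameter_recovery_large_replicates(self, truth, constants):
        """With 200 vials per stratum every estimate lands close to the
        generating truth (tolerances ~4 sampling SDs per parameter)."""
        from dataclasses import replace
        big = replace(constants, replicates_per_cell=200)
        scenario = hp.Scenario("additive_null", truth, big, seed=21)
        fit = hp.fit_all(hp.generate(scenario), big, n_bootstrap=0)
        for host, value in truth.m0.items():
            assert fit.params.m0[host] == pytest.approx(value, rel=0.08)
        for key, value in truth.a0.items():
            assert fit.params.a0[key] == pytest.approx(value, rel=0.12)
        for key, value in truth.epsilon.items():
            assert fit.params.epsilon[key] == pytest.approx(value, rel=0.12)
        for key, value in truth.m_tau.items():
            assert fit.params.m_tau[key] == pytest.approx(value, rel=0.20)

    def test_recovery_improves_with_replicates(self, truth, constants):
        """Median relative error of the fitted parameters shrinks as
        replicates per cell grow 6 -> 60 -> 600 (estimator consistency)."""
        from dataclasses import replace
        flat_truth = hp.FitResult(truth, {}, {}).flat_estimates()
        medians = []
        for n_reps in (6, 60, 600):
            big = replace(constants, replicates_per_cell=n_reps)
            errors = []
            for seed in range(50):
                scenario = hp.Scenario("additive_null", truth, big,
                                       seed=1000 + seed)
                fit = hp.fit_all(hp.generate(scenario), big, n_bootstrap=0)
                flat = fit.flat_estimates()
                errors.extend(abs(flat[k] - v) / abs(v)
                              for k, v in flat_truth.items() if v != 0)
            medians.append(float(np.median(errors)))
        assert medians[0] > medians[1] > medians[2]

    def test_pooled_epsilon_option(self, additive_dataset, constants):
        fit = hp.fit_all(additive_dataset, constants, n_bootstrap=0,
                         pool_epsilon=True)
        for para in hp.PARASITOIDS:
            values = {fit.params.epsilon[(h, para)] for h in hp.HOSTS}
            assert len(values) == 1  # one epsilon per parasitoid

    def test_low_wasp_stratum_flagged(self, constants):
        dataset = []
        for timing in hp.TIMINGS:
            dataset += make_vials("h", NO_PARASITOID, timing, [34] * 6)
        dataset += make_vials("h", "w", AMBIENT, [20] * 6,
                              [1, 0, 0, 0, 0, 0])
        fit = hp.fit_all(dataset, constants, n_bootstrap=0)
        assert any("low wasp total" in w for w in fit.warnings)

    def test_flat_frame_layout(self, additive_dataset, constants):
        fit = hp.fit_all(additive_dataset, constants, n_bootstrap=50, rng=0)
        frame = fit.to_frame()
        assert list(frame.columns) == ["key", "estimate", "se", "n_vials",
                                       "warning"]
        # 3 m0 + 9 m_tau + 9 a0 + 9 epsilon
        assert len(frame) == 30
        assert (frame["n_vials"] == 6).all()

    def test_fit_result_round_trip(self, additive_dataset, constants,
                                   tmp_path):
        fit = hp.fit_all(additive_dataset, constants, n_bootstrap=50, rng=0)
        path = tmp_path / "fit.json"
        fit.save(path)
        back = hp.FitResult.load(path)
        assert back.params == fit.params
        assert back.standard_errors == fit.standard_errors
        assert back.warnings == fit.warnings


class TestInvertFunctions:
    def test_exact_inversion_on_noiseless_means(self, truth, constants):
        """Feeding the model's exact expected means through the inversion
        chain returns the generating parameters to 1e-9."""
        h0, t_end, p = (constants.eggs_per_vial, constants.end_day,
                        constants.wasp_count)
        for host in hp.HOSTS:
            cell = hp.DesignCell(host, NO_PARASITOID, AMBIENT)
            f, _ = hp.expected_emergence(truth, cell, constants)
            m0 = fitting.invert_baseline_mortality(f, h0, t_end)
            assert m0 == pytest.approx(truth.m0[host], abs=1e-9)
            for timing in ("before", "during", "after"):
                cell_t = hp.DesignCell(host, NO_PARASITOID, timing)
                ft, _ = hp.expected_emergence(truth, cell_t, constants)
                m_tau = fitting.invert_heat_mortality(ft, h0, m0, t_end)
                assert m_tau == pytest.approx(truth.m_tau[(host, timing)],
                                              abs=1e-9)
            for para in hp.PARASITOIDS:
                cell_p = hp.DesignCell(host, para, AMBIENT)
                fp, wp = hp.expected_emergence(truth, cell_p, constants)
                a0, clamped = fitting.invert_attack_rate(fp, h0, m0, t_end,
                                                         p)
                assert not clamped
                assert a0 == pytest.approx(truth.a0[(host, para)], abs=1e-9)
                eps, clamped = fitting.invert_conversion(wp, h0, m0, t_end,
                                                         a0, p)
                assert not clamped
                assert eps == pytest.approx(truth.epsilon[(host, para)],
                                            abs=1e-9)
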