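"""Biolayer-interferometry kinetics: models, preprocessing, and global fitting."""

import numpy as np
import pytest

from readerscreen import (
    KineticFit,
    ReportPoint,
    Sensorgram,
    dissociation_shift,
    global_fit_1to1,
    kd_from_rates,
    model_association,
    model_dissociation,
    reference_subtract,
    regeneration_qc,
    report_point_displacement,
)
from readerscreen.bli import (
    dissociation_decay_fraction,
    fit_dissociation_rate,
    rezero_association,
)

KA, KD_RATE = 9.43e4, 1.35e-3  # H3K4me3 peptide on Spindlin1, reported rates


def make_sensorgram(ka, kd_rate, conc, rmax, run_id="run", dt=0.5,
                    t_base=10.0, t_assoc=120.0, t_diss=120.0):
    """Exact noiseless 1:1 sensorgram with baseline/association/dissociation."""
    tb = np.arange(0.0, t_base, dt)
    ta = np.arange(0.0, t_assoc, dt)
    td = np.arange(0.0, t_diss, dt)
    rb = np.zeros_like(tb)
    ra = model_association(ta, ka, kd_rate, conc, rmax)
    r_end = model_association(t_assoc, ka, kd_rate, conc, rmax)
    rd = model_dissociation(td, kd_rate, r_end)
    time = np.concatenate([tb, t_base + ta, t_base + t_assoc + td])
    resp = np.concatenate([rb, ra, rd])
    phase = (["baseline"] * tb.size + ["association"] * ta.size
             + ["dissociation"] * td.size)
    return Sensorgram(time, resp, phase, conc, run_id=run_id)


class TestLangmuirModels:
    def test_association_starts_at_zero(self):
        assert model_association(0.0, KA, KD_RATE, 1e-7, 1.0) == 0.0

    def test_association_saturates_at_occupancy_limit(self):
        # R(inf) = Rmax * c/(c + KD)
        c, rmax = 1e-6, 1.2
        kd_eq = KD_RATE / KA
        r_inf = model_association(1e6, KA, KD_RATE, c, rmax)
        assert r_inf == pytest.approx(rmax * c / (c + kd_eq), rel=1e-12)

    def test_association_hand_value(self):
        # 120 s at 100 nM with the reported rates:
        # (9.43e-3/1.078e-2)*(1 - e^(-1.078e-2*120)) = 0.63484 nm
        r = model_association(120.0, KA, KD_RATE, 1e-7, 1.0)
        kobs = KA * 1e-7 + KD_RATE
        expected = (KA * 1e-7 / kobs) * (1.0 - np.exp(-kobs * 120.0))
        assert r == pytest.approx(expected, rel=1e-12)
        assert r == pytest.approx(0.63484, abs=5e-4)

    def test_dissociation_hand_value(self):
        # 0.6 nm decaying for 120 s at 1.35e-3 /s: 0.6*e^(-0.162)
        r = model_dissociation(120.0, KD_RATE, 0.6)
        assert r == pytest.approx(0.6 * np.exp(-0.162), rel=1e-12)
        assert r == pytest.approx(0.5102, abs=5e-4)

    def test_association_monotone_dissociation_decreasing(self):
        t = np.linspace(0.0, 300.0, 200)
        assert np.all(np.diff(model_association(t, KA, KD_RATE, 1e-7, 1.0)) > 0)
        assert np.all(np.diff(model_dissociation(t, KD_RATE, 0.6)) < 0)

    def test_dissociation_half_life(self):
        t_half = np.log(2.0) / KD_RATE
        assert model_dissociation(t_half, KD_RATE, 1.0) == pytest.approx(0.5, rel=1e-12)


class TestKdFromRates:
    def test_peptide_reported_rates(self):
        # k_a 9.43e4, k_d 1.35e-3 -> K_D ~ 14.3 nM
        assert kd_from_rates(KA, KD_RATE) == pytest.approx(14.32e-9, abs=5e-12)

    def test_small_molecule_reported_rates(self):
        assert kd_from_rates(6.54e4, 8.63e-4) == pytest.approx(13.2e-9, abs=1e-11)

    def test_zero_off_rate_gives_zero(self):
        assert kd_from_rates(1e5, 0.0) == 0.0

    def test_nonpositive_on_rate_rejected(self):
        with pytest.raises(ValueError):
            kd_from_rates(0.0, 1e-3)


class TestSensorgramStructure:
    def test_phases_must_be_ordered(self):
        t = np.arange(0.0, 4.0, 1.0)
        with pytest.raises(ValueError):
            Sensorgram(t, np.zeros(4),
                       ["association", "baseline", "dissociation", "dissociation"],
                       1e-7)

    def test_unknown_phase_rejected(self):
        t = np.arange(0.0, 4.0, 1.0)
        with pytest.raises(ValueError):
            Sensorgram(t, np.zeros(4), ["baseline", "loading", "loading",
                                        "loading"], 1e-7)

    def test_rezero_subtracts_late_baseline_mean(self):
        sg = make_sensorgram(KA, KD_RATE, 1e-7, 1.0)
        shifted = Sensorgram(sg.time, np.asarray(sg.response) + 0.25, sg.phase,
                             sg.analyte_concentration, run_id=sg.run_id)
        back = rezero_association(shifted)
        assert np.allclose(back.response, sg.response, atol=1e-12)


class TestReferenceSubtract:
    def test_identical_traces_cancel(self):
        sg = make_sensorgram(KA, KD_RATE, 1e-7, 1.0)
        out = reference_subtract(sg, sg)
        assert np.allclose(out.response, 0.0)

    def test_zero_reference_is_identity(self):
        sg = make_sensorgram(KA, KD_RATE, 1e-7, 1.0)
        ref = Sensorgram(sg.time, np.zeros_like(sg.response), sg.phase, 0.0,
                         run_id="reference")
        out = reference_subtract(sg, ref)
        assert np.allclose(out.response, sg.response)

    def test_shared_linear_drift_removed(self):
        sg = make_sensorgram(KA, KD_RATE, 1e-7, 1.0)
        drift = 1e-4 * np.asarray(sg.time)
        drifted = Sensorgram(sg.time, np.asarray(sg.response) + drift,
                             sg.phase, sg.analyte_concentration)
        ref = Sensorgram(sg.time, drift, sg.phase, 0.0, run_id="reference")
        out = reference_subtract(drifted, ref)
        assert np.allclose(out.response, sg.response, atol=1e-9)

    def test_non_overlapping_time_ranges_rejected(self):
        sg = make_sensorgram(KA, KD_RATE, 1e-7, 1.0)
        ref = Sensorgram(np.asarray(sg.time) + 1000.0,
                         np.zeros(len(sg.response)), sg.phase, 0.0)
        with pytest.raises(ValueError):
            reference_subtract(sg, ref)


class TestGlobalFit:
    concs = (2.5e-8, 5e-8, 1e-7, 2e-7, 4e-7)

    def _curves(self, ka, kd_rate, rmax=1.0):
        return [make_sensorgram(ka, kd_rate, c, rmax, run_id=f"c{i}")
                for i, c in enumerate(self.concs)]

    def test_noiseless_round_trip_at_reported_rates(self):
        fit = global_fit_1to1(self._curves(KA, KD_RATE))
        assert fit.converged
        assert fit.ka == pytest.approx(KA, rel=1e-6)
        assert fit.kd_rate == pytest.approx(KD_RATE, rel=1e-6)
        assert fit.rmax == pytest.approx(1.0, rel=1e-6)
        assert fit.kd_eq == pytest.approx(KD_RATE / KA, rel=1e-6)

    @pytest.mark.parametrize("ka,kdr", [(1e3, 1e-4), (1e6, 1e-1), (5e4, 1e-2)])
    def test_noiseless_round_trip_across_rate_span(self, ka, kdr):
        fit = global_fit_1to1(self._curves(ka, kdr), min_decay=0.0)
        assert fit.ka == pytest.approx(ka, rel=1e-5)
        assert fit.kd_rate == pytest.approx(kdr, rel=1e-5)

    def test_misstated_concentration_scales_ka(self):
        # doubling every nominal concentration halves the fitted k_a, leaving
        # k_obs = ka*c + kd unchanged
        curves = self._curves(KA, KD_RATE)
        doubled = [Sensorgram(c.time, c.response, list(c.phase),
                              2.0 * c.analyte_concentration, run_id=c.run_id)
                   for c in curves]
        fit = global_fit_1to1(doubled)
        assert fit.ka == pytest.approx(KA / 2.0, rel=1e-6)
        assert fit.kd_rate == pytest.approx(KD_RATE, rel=1e-6)

    def test_slow_dissociation_flagged_low_decay(self):
        fit = global_fit_1to1(self._curves(1e5, 1e-5))
        assert fit.low_decay_curves
        assert "k_d reliability" in fit.message

    def test_decay_fraction_closed_form(self):
        sg = make_sensorgram(KA, KD_RATE, 1e-7, 1.0)
        frac = dissociation_decay_fraction(sg)
        td = sg.phase_arrays("dissociation")[0]
        span = td[-1] - td[0]
        assert frac == pytest.approx(1.0 - np.exp(-KD_RATE * span), rel=1e-9)

    def test_requires_two_curves(self):
        with pytest.raises(ValueError):
            global_fit_1to1([make_sensorgram(KA, KD_RATE, 1e-7, 1.0)])


class TestLocalDissociation:
    def test_exact_rate_recovery(self):
        sg = make_sensorgram(KA, 5e-3, 1e-7, 1.0)
        assert fit_dissociation_rate(sg) == pytest.approx(5e-3, rel=1e-6)

    def test_rate_shift_identities(self):
        assert dissociation_shift(2.7e-3, KD_RATE) == pytest.approx(2.0)
        assert dissociation_shift(KD_RATE, KD_RATE) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            dissociation_shift(0.0, KD_RATE)

    def test_short_dissociation_phase_rejected(self):
        sg = make_sensorgram(KA, KD_RATE, 1e-7, 1.0, t_diss=1.0)
        with pytest.raises(ValueError):
            fit_dissociation_rate(sg)


class TestReportPointDisplacement:
    def _with_scale(self, scale):
        sg = make_sensorgram(KA, KD_RATE, 1e-7, 1.0)
        return Sensorgram(sg.time, scale * np.asarray(sg.response), sg.phase,
                          sg.analyte_concentration)

    def test_uninhibited_sample_reads_zero(self):
        sg = self._with_scale(1.0)
        assert report_point_displacement(sg, sg) == pytest.approx(0.0)

    def test_fully_blocked_sample_reads_hundred(self):
        control = self._with_scale(1.0)
        blocked = self._with_scale(0.0)
        assert report_point_displacement(blocked, control) == pytest.approx(100.0)

    def test_half_signal_reads_fifty(self):
        control = self._with_scale(1.0)
        half = self._with_scale(0.5)
        assert report_point_displacement(half, control) == pytest.approx(50.0)

    def test_misaligned_grids_rejected(self):
        control = self._with_scale(1.0)
        sample = make_sensorgram(KA, KD_RATE, 1e-7, 1.0, dt=0.4)
        with pytest.raises(ValueError):
            report_point_displacement(sample, control)

    def test_custom_report_offset(self):
        control = self._with_scale(1.0)
        half = self._with_scale(0.5)
        val = report_point_displacement(half, control, rp=ReportPoint(20.0))
        assert val == pytest.approx(50.0)


class TestRegenerationQc:
    def test_identical_cycles_are_stable(self):
        res = regeneration_qc([0.6] * 5)
        assert res["stable"]
        assert res["cv"] == pytest.approx(0.0)

    def test_decaying_surface_flagged(self):
        res = regeneration_qc([0.6, 0.45, 0.3, 0.2, 0.1])
        assert not res["stable"]

    def test_fifteen_cycles_with_noise_remain_stable(self):
        rng = np.random.default_rng(7)
        caps = 0.6 * (1.0 + 0.03 * rng.standard_normal(15))
        res = regeneration_qc(caps)
        assert res["stable"]
        assert res["usable_cycles"] == 15

    def test_requires_two_cycles(self):
        with pytest.raises(ValueError):
            regeneration_qc([0.6])
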