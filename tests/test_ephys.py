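"""Spike-train tuning analysis: geometry, curves, classification, widths."""

import numpy as np
import pytest

from mothcompass.angles import circ_diff, wrap360
from mothcompass.ephys import (BIN_CENTERS, CellClassification, RotationSweep,
                               TuningCurve, baseline_stats, bin_tuning_curve,
                               classify_response, fit_model, half_width,
                               map_time_to_angle, phi_max_per_sweep,
                               smooth_curve, snr, spike_angles,
                               tuning_variability, vonmises_halfmax_width)
from mothcompass.synth import CellSpec, gen_cell_sweeps


def _sweep(spikes=(), direction="CW", velocity=30.0, start=0.0,
           correction=0.0, pre=5.0):
    return RotationSweep(spike_times=np.asarray(spikes, dtype=float),
                         rotation_start=pre, rotation_end=pre + 360.0 / velocity,
                         angular_velocity=velocity, direction=direction,
                         start_angle=start, initial_heading_correction=correction,
                         pre_stimulus_window=pre)


def _vm_curve(mu=180.0, kappa=3.0, base=2.0, gain=18.0, direction="CW"):
    rate = base + gain * np.exp(kappa * (np.cos(np.deg2rad(BIN_CENTERS - mu)) - 1.0))
    return TuningCurve(bin_centers=BIN_CENTERS, rate=rate, direction=direction,
                       smoothed=True, dwell_s=1.0 / 30.0)


# ---------------------------------------------------------------------------
# time -> angle geometry
# ---------------------------------------------------------------------------


class TestRotationGeometry:
    def test_30_deg_per_s_sweep_lasts_12_s(self):
        s = _sweep(velocity=30.0)
        assert s.rotation_end - s.rotation_start == pytest.approx(12.0)

    def test_angle_at_start_is_start_plus_correction(self):
        s = _sweep(start=40.0, correction=90.0)
        assert float(map_time_to_angle(s, s.rotation_start)) == pytest.approx(130.0)

    def test_ccw_mirrors_cw(self):
        cw = _sweep(direction="CW", start=30.0)
        ccw = _sweep(direction="CCW", start=30.0)
        for t in np.linspace(cw.rotation_start, cw.rotation_end, 25):
            total = float(map_time_to_angle(cw, t)) + float(map_time_to_angle(ccw, t))
            assert total % 360.0 == pytest.approx((2 * 30.0) % 360.0, abs=1e-9)

    def test_correction_composition(self):
        # applying correction c then c' equals applying (c + c') mod 360
        s1 = _sweep(correction=90.0)
        t = np.linspace(s1.rotation_start, s1.rotation_end, 13)
        once = wrap360(map_time_to_angle(s1, t) + 180.0)
        s2 = _sweep(correction=(90.0 + 180.0) % 360.0)
        assert np.allclose(once, map_time_to_angle(s2, t))

    def test_time_outside_sweep_raises(self):
        s = _sweep()
        with pytest.raises(ValueError):
            map_time_to_angle(s, s.rotation_end + 1.0)

    def test_wrong_span_raises(self):
        with pytest.raises(ValueError, match="360"):
            RotationSweep(spike_times=[], rotation_start=0.0, rotation_end=5.0,
                          angular_velocity=30.0, direction="CW")


# ---------------------------------------------------------------------------
# binning and smoothing
# ---------------------------------------------------------------------------


class TestTuningCurves:
    def test_zero_spikes_give_flat_zero_curve(self):
        c = bin_tuning_curve(_sweep())
        assert c.rate.shape == (360,)
        assert np.all(c.rate == 0.0)

    @pytest.mark.parametrize("velocity", [30.0, 36.0, 45.0])
    def test_exactly_360_bins_at_any_velocity(self, velocity):
        c = bin_tuning_curve(_sweep(spikes=[6.0, 7.0], velocity=velocity))
        assert c.bin_centers.size == 360

    def test_spike_mass_conserved_through_binning_and_smoothing(self, rng):
        spikes = rng.uniform(5.0, 17.0, 200)
        s = _sweep(spikes=spikes)
        c = bin_tuning_curve(s)
        assert c.rate.sum() * c.dwell_s == pytest.approx(200.0, abs=1e-9)
        sm = smooth_curve(c, 5.0)
        assert sm.rate.sum() * sm.dwell_s == pytest.approx(200.0, abs=1e-9)

    def test_homogeneous_poisson_rate_recovery(self, rng):
        rate = 10.0
        dur = 12.0
        spikes = np.sort(rng.uniform(5.0, 5.0 + dur, rng.poisson(rate * dur * 50)))
        # fold 50 nominal sweeps into one by averaging: single long run
        c = bin_tuning_curve(_sweep(spikes=spikes))
        mean_rate = c.rate.mean() / 50.0
        assert mean_rate == pytest.approx(rate, rel=0.05)

    def test_flat_curve_unchanged_by_smoothing(self):
        c = TuningCurve(bin_centers=BIN_CENTERS, rate=np.full(360, 7.0),
                        direction="CW", dwell_s=1 / 30)
        assert np.allclose(smooth_curve(c, 5.0).rate, 7.0)

    def test_delta_smooths_to_symmetric_wrapped_kernel(self):
        rate = np.zeros(360)
        rate[0] = 30.0
        c = TuningCurve(bin_centers=BIN_CENTERS, rate=rate, direction="CW",
                        dwell_s=1 / 30)
        sm = smooth_curve(c, 5.0).rate
        assert np.argmax(sm) == 0
        assert np.allclose(sm[1:180], sm[-1:-180:-1], atol=1e-9)  # wrap symmetry


# ---------------------------------------------------------------------------
# phi_max
# ---------------------------------------------------------------------------


class TestPhiMax:
    def test_noiseless_vonmises_peak(self):
        assert phi_max_per_sweep(_vm_curve(mu=180.0), "excited",
                                 baseline=2.0) == pytest.approx(180.0, abs=0.5)

    def test_inhibited_trough_not_antipode(self):
        mu = 140.0
        rate = 20.0 - 18.0 * np.exp(
            3.0 * (np.cos(np.deg2rad(BIN_CENTERS - mu)) - 1.0))
        c = TuningCurve(bin_centers=BIN_CENTERS, rate=rate, direction="CW",
                        smoothed=True, dwell_s=1 / 30)
        est = phi_max_per_sweep(c, "inhibited", baseline=20.0)
        assert est == pytest.approx(mu, abs=0.5)

    def test_flat_curve_flags_no_tuning(self):
        c = TuningCurve(bin_centers=BIN_CENTERS, rate=np.full(360, 5.0),
                        direction="CW", dwell_s=1 / 30)
        assert phi_max_per_sweep(c, "excited", baseline=5.0) is None

    def test_recovery_across_seeds(self):
        # kappa >= 2, 20 Hz peak over 2 Hz baseline: |phi - mu| <= 5° on the
        # per-direction mean curve (successive rotations of one recording)
        from mothcompass.ephys import mean_tuning_curve

        errs = []
        for seed in range(30):
            spec = CellSpec(category=1, phi_max_deg=137.0, kappa=2.0,
                            baseline_hz=2.0, modulation_hz=18.0,
                            phi_jitter_deg=0.0, sweeps_per_direction=3,
                            seed=seed)
            cw, ccw, _ = gen_cell_sweeps(spec)
            c = smooth_curve(mean_tuning_curve([bin_tuning_curve(s) for s in cw]), 5.0)
            est = phi_max_per_sweep(c, "excited", baseline=2.0)
            errs.append(abs(float(circ_diff(est, 137.0))))
        assert np.mean(errs) <= 5.0


class TestVariability:
    def test_identical_sweeps_zero(self):
        assert tuning_variability([45.0, 45.0, 45.0]) == pytest.approx(0.0, abs=1e-6)

    def test_rotation_invariance(self):
        phis = [10.0, 30.0, 350.0]
        assert tuning_variability(phis) == pytest.approx(
            tuning_variability([(p + 111.0) % 360 for p in phis]), abs=1e-9)

    def test_injected_jitter_recovered(self, rng):
        ests = []
        for _ in range(40):
            phis = rng.normal(200.0, 10.0, 12) % 360.0
            ests.append(tuning_variability(phis))
        assert np.mean(ests) == pytest.approx(10.0, abs=3.0)

    def test_single_sweep_raises(self):
        with pytest.raises(ValueError):
            tuning_variability([10.0])


# ---------------------------------------------------------------------------
# model fits and classification
# ---------------------------------------------------------------------------


class TestModelFits:
    def test_m2a_fit_matches_grid_oracle(self, rng):
        theta = wrap360(np.rad2deg(rng.vonmises(np.deg2rad(100.0), 3.0, 400)))
        p, logL, k = fit_model("M2A", theta)
        assert k == 2
        # dense grid oracle
        from mothcompass.circstats import vonmises_logpdf
        mus = np.arange(0, 360, 0.1)
        kappas = np.arange(0.5, 8.0, 0.01)
        best = -np.inf
        for kap in kappas:
            ll = vonmises_logpdf(theta[None, :], mus[:, None], kap).sum(axis=1)
            best = max(best, ll.max())
        assert logL == pytest.approx(best, abs=0.01)
        assert p["mu"] == pytest.approx(100.0, abs=5.0)

    def test_aic_selection_rotation_invariant(self, rng):
        theta = wrap360(np.rad2deg(rng.vonmises(0.0, 2.0, 300)))
        counts0, _ = np.histogram(theta, bins=360, range=(0, 360))
        shift = 90
        counts1 = np.roll(counts0, shift)
        from mothcompass.ephys import _aic_select
        b0, a0, _ = _aic_select(BIN_CENTERS, counts0.astype(float))
        b1, a1, _ = _aic_select(BIN_CENTERS, counts1.astype(float))
        for m in a0:
            assert a0[m] == pytest.approx(a1[m], abs=0.2)


class TestClassification:
    def test_homogeneous_poisson_is_uniform_model(self):
        # uniform cells pass the response screen as M1 in the vast majority
        # of runs (the residue is the screen's nominal type-I error)
        m1 = 0
        for seed in range(15):
            spec = CellSpec(category=1, modulation_hz=0.0, baseline_hz=8.0,
                            seed=seed)
            cw, ccw, _ = gen_cell_sweeps(spec)
            cls = classify_response(cw, ccw)
            if cls.model_id == "M1":
                m1 += 1
                assert cls.category is None
                assert cls.phi_max is None
        assert m1 >= 12

    def test_too_few_spikes_unclassifiable(self):
        spec = CellSpec(category=1, baseline_hz=0.1, modulation_hz=0.5, seed=1)
        cw, ccw, _ = gen_cell_sweeps(spec)
        cls = classify_response(cw, ccw)
        assert cls.category is None and cls.model_id is None

    def test_unimodal_generator_selects_m2_family(self):
        ok = 0
        for seed in range(10):
            cw, ccw, _ = gen_cell_sweeps(CellSpec.for_category(1, seed=seed))
            cls = classify_response(cw, ccw)
            ok += cls.model_id is not None and cls.model_id.startswith("M2")
        assert ok >= 9

    def test_axial_generator_recovers_antipodal_peaks(self):
        cw, ccw, truth = gen_cell_sweeps(
            CellSpec.for_category(4, phi_max_deg=60.0, seed=11))
        cls = classify_response(cw, ccw)
        assert cls.model_id.startswith("M4")
        p1, p2 = cls.phi_max
        sep = abs(float(circ_diff(p2, p1)))
        assert sep == pytest.approx(180.0, abs=25.0)
        err = min(abs(float(circ_diff(p1, 60.0))), abs(float(circ_diff(p2, 60.0))))
        assert err <= 10.0

    def test_inhibited_cell_assigned_category_2(self):
        cw, ccw, _ = gen_cell_sweeps(CellSpec.for_category(2, seed=21))
        cls = classify_response(cw, ccw)
        assert cls.response_sign == "inhibited"
        assert cls.category == 2


# ---------------------------------------------------------------------------
# half-width
# ---------------------------------------------------------------------------


class TestHalfWidth:
    def test_halfmax_width_monotone_decreasing_in_kappa(self):
        widths = [vonmises_halfmax_width(k) for k in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_inhibited_noiseless_curve_matches_closed_form(self):
        for kappa in (1.0, 3.0, 6.0):
            rate = 25.0 - 20.0 * np.exp(
                kappa * (np.cos(np.deg2rad(BIN_CENTERS - 180.0)) - 1.0))
            c = TuningCurve(bin_centers=BIN_CENTERS, rate=rate, direction="CW",
                            smoothed=True, dwell_s=1 / 30)
            cls = CellClassification(
                model_id="M2A", aic_table={}, phi_max=180.0, category=2,
                response_sign="inhibited", direction_selective=False, params={})
            w = half_width(cls, curve=c)
            assert w == pytest.approx(vonmises_halfmax_width(kappa), abs=2.0)

    def test_bootstrap_iqr_approaches_analytic_von_mises_iqr(self, rng):
        kappa = 3.0
        theta = wrap360(np.rad2deg(rng.vonmises(np.pi, kappa, 20_000)))
        cls = CellClassification(
            model_id="M2A", aic_table={}, phi_max=180.0, category=1,
            response_sign="excited", direction_selective=False, params={})
        w = half_width(cls, spike_angles_deg=theta, n_boot=60, seed=5)
        # numeric-integration quantile oracle for the vM IQR
        grid = np.linspace(-np.pi, np.pi, 200_001)
        pdf = np.exp(kappa * np.cos(grid))
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]
        q75 = grid[np.searchsorted(cdf, 0.75)]
        iqr_oracle = np.rad2deg(2.0 * q75)
        assert w == pytest.approx(iqr_oracle, abs=2.0)

    def test_bimodal_cells_not_applicable(self):
        cls = CellClassification(
            model_id="M4A", aic_table={}, phi_max=(0.0, 180.0), category=4,
            response_sign="excited", direction_selective=True, params={})
        assert half_width(cls, spike_angles_deg=[1.0]) is None


# ---------------------------------------------------------------------------
# SNR
# ---------------------------------------------------------------------------


class TestSNR:
    def test_tuned_cell_beats_untuned_at_equal_mean_rate(self):
        # equal mean spike counts, one concentrated at a peak
        tuned_spec = CellSpec(category=1, baseline_hz=4.0, modulation_hz=30.0,
                              kappa=4.0, sweeps_per_direction=1,
                              phi_jitter_deg=0.0, seed=2)
        cw_t, _, _ = gen_cell_sweeps(tuned_spec)
        mean_extra = 30.0 * np.mean(np.exp(4.0 * (np.cos(np.linspace(0, 2 * np.pi, 360)) - 1)))
        flat_spec = CellSpec(category=1, baseline_hz=4.0 + mean_extra,
                             modulation_hz=0.0, sweeps_per_direction=1, seed=2)
        cw_f, _, _ = gen_cell_sweeps(flat_spec)
        assert snr(cw_t[0]) > snr(cw_f[0])

    def test_doubling_peak_rate_roughly_doubles_snr(self, rng):
        ratios = []
        for seed in range(15):
            s1 = gen_cell_sweeps(CellSpec(category=1, modulation_hz=20.0,
                                          baseline_hz=5.0, phi_jitter_deg=0.0,
                                          sweeps_per_direction=1, seed=seed))[0][0]
            s2 = gen_cell_sweeps(CellSpec(category=1, modulation_hz=45.0,
                                          baseline_hz=5.0, phi_jitter_deg=0.0,
                                          sweeps_per_direction=1, seed=seed))[0][0]
            v1, v2 = snr(s1), snr(s2)
            if np.isfinite(v1) and np.isfinite(v2) and v1 > 0:
                ratios.append(v2 / v1)
        assert np.median(ratios) == pytest.approx(2.0, abs=0.6)

    def test_zero_pre_stimulus_variance_flagged_infinite(self):
        s = _sweep(spikes=np.arange(5.5, 16.5, 0.5))   # silent pre window
        with pytest.warns(UserWarning, match="infinite"):
            assert np.isinf(snr(s))

    def test_baseline_stats_needs_two_bins(self):
        s = _sweep(pre=1.0)
        with pytest.raises(ValueError):
            baseline_stats(s)
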