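"""Current-clamp feature extraction and FS/RS classification."""

import numpy as np
import pytest

from prescout.ephys import (
    SpikeAnalysisError,
    SweepError,
    SweepSet,
    analyze_cell,
    ap_features,
    classify_fs_rs,
    detect_spikes,
    firing_analysis,
    input_resistance,
    read_sweeps_csv,
    resting_membrane_potential,
    spike_frequency_accommodation,
    write_sweeps_csv,
)
from prescout.simulate import (
    EphysProtocol,
    RIN_PROTOCOL,
    fs_template_spec,
    gen_ephys_cell,
    gen_rin_sweeps,
    rs_template_spec,
)

FS_RATE = 20_000.0


def flat_sweeps(level=-70.0, currents=(0.0, 10.0), n=20_000):
    v = np.full((len(currents), n), level)
    return SweepSet(FS_RATE, 0.2, 0.5, list(currents), v)


class TestSweepSetValidation:
    def test_low_sampling_rate_rejected(self):
        with pytest.raises(SweepError, match="10 kHz"):
            SweepSet(5_000, 0.2, 0.5, [0.0], np.zeros((1, 100)))

    def test_nonincreasing_currents_rejected(self):
        with pytest.raises(SweepError, match="increasing"):
            SweepSet(FS_RATE, 0.2, 0.5, [10.0, 10.0], np.zeros((2, 100)))


class TestRMP:
    def test_flat_trace(self):
        assert resting_membrane_potential(flat_sweeps(-70.0)) == pytest.approx(-70.0)

    def test_noisy_baseline_within_clt_bound(self, rng):
        s = flat_sweeps(-70.0)
        s.voltages = s.voltages + rng.normal(0, 0.5, s.voltages.shape)
        # 50 ms at 20 kHz = 1000 samples; |error| < 4 * 0.5/sqrt(1000)
        assert resting_membrane_potential(s) == pytest.approx(-70.0, abs=0.2)

    def test_linear_drift_gives_window_mean(self):
        s = flat_sweeps(-70.0)
        n = s.voltages.shape[1]
        drift = np.linspace(0, 2.0, n)  # +2 mV over the sweep
        s.voltages = s.voltages + drift
        win = slice(int(0.15 * FS_RATE), int(0.2 * FS_RATE))
        expected = -70.0 + drift[win].mean()
        assert resting_membrane_potential(s) == pytest.approx(expected, abs=1e-9)

    def test_requires_zero_current_sweep(self):
        s = flat_sweeps(currents=(10.0, 20.0))
        with pytest.raises(SweepError):
            resting_membrane_potential(s)


class TestInputResistance:
    def _rc_sweeps(self, r_mohm=100.0, tau_ms=10.0, noise=0.0, rng=None):
        fs = 20_000.0
        onset, dur = 0.2, 0.5
        currents = np.arange(-50.0, 21.0, 10.0)
        t = np.arange(int((onset + dur + 0.1) * fs)) / fs
        sweeps = []
        for i_pa in currents:
            v = np.full(t.size, -70.0)
            step = (t >= onset) & (t < onset + dur)
            dt = t[step] - onset
            v[step] += (i_pa / 1000.0) * r_mohm * (1 - np.exp(-dt * 1000 / tau_ms))
            if noise:
                v = v + rng.normal(0, noise, v.shape)
            sweeps.append(v)
        return SweepSet(fs, onset, dur, currents, np.vstack(sweeps))

    def test_ideal_ohmic_cell(self):
        assert input_resistance(self._rc_sweeps(100.0)) == pytest.approx(100.0, abs=0.5)

    def test_zero_response_is_zero(self):
        s = flat_sweeps(currents=(-30.0, -20.0, -10.0, 0.0, 10.0))
        assert input_resistance(s) == pytest.approx(0.0, abs=1e-9)

    def test_noisy_cell_within_five_percent(self, rng):
        s = self._rc_sweeps(150.0, noise=0.3, rng=rng)
        assert input_resistance(s) == pytest.approx(150.0, rel=0.05)

    def test_too_few_subthreshold_sweeps_rejected(self):
        s = flat_sweeps(currents=(0.0, 10.0))
        with pytest.raises(SweepError, match=">=3"):
            input_resistance(s)


def template_trace(peak_times_s, fs=50_000.0, total_s=1.2, theta=-40.0, amp=80.0,
                   hw_ms=0.4, fahp=15.0, base=-60.0):
    """Piecewise-linear spikes on a flat baseline (generator-independent)."""
    n = int(total_s * fs)
    v = np.full(n, base)
    t_rise = hw_ms / 1000.0
    t_fall = t_rise * (amp + fahp) / amp
    for tp in peak_times_s:
        i_p = int(tp * fs)
        i_0 = i_p - int(t_rise * fs)
        i_f = i_p + int(t_fall * fs)
        v[i_0:i_p] = np.linspace(theta, theta + amp, i_p - i_0, endpoint=False)
        v[i_p] = theta + amp
        v[i_p + 1 : i_f] = np.linspace(theta + amp, theta - fahp, i_f - i_p - 1)
        i_r = min(n, i_f + int(0.005 * fs))
        v[i_f:i_r] = np.linspace(theta - fahp, base, i_r - i_f)
    return v


class TestDetectSpikes:
    def test_flat_subthreshold_trace(self):
        assert detect_spikes(np.full(10_000, -70.0), FS_RATE).size == 0

    def test_five_template_spikes_found_at_peaks(self):
        fs = 50_000.0
        times = [0.3, 0.4, 0.5, 0.65, 0.9]
        v = template_trace(times, fs)
        peaks = detect_spikes(v, fs)
        assert peaks.size == 5
        expected = (np.array(times) * fs).astype(int)
        assert np.all(np.abs(peaks - expected) <= 1)

    def test_doublet_within_refractory_counted_once(self):
        fs = 50_000.0
        v = template_trace([0.3, 0.3004], fs)  # 0.4 ms apart < 1 ms
        assert detect_spikes(v, fs).size == 1

    def test_subthreshold_peak_not_counted(self):
        fs = 50_000.0
        v = template_trace([0.3], fs, theta=-40.0, amp=30.0)  # peak at -10 < 0 mV
        assert detect_spikes(v, fs).size == 0


class TestFiring:
    def test_forty_spikes_is_fifty_hz(self):
        fs = 50_000.0
        times = 0.21 + np.arange(40) * 0.019  # all within the 0.8 s step
        v = template_trace(times, fs)
        quiet = np.full(v.size, -70.0)
        s = SweepSet(fs, 0.2, 0.8, [25.0, 50.0], np.vstack([quiet, v]))
        fr = firing_analysis(s)
        assert fr.counts[50.0] == 40
        assert fr.frequencies[50.0] == pytest.approx(50.0)
        assert fr.rheobase == 50.0
        assert fr.max_firing_frequency == pytest.approx(50.0)

    def test_no_spikes_rheobase_undefined(self):
        s = flat_sweeps(currents=(25.0, 50.0))
        fr = firing_analysis(s)
        assert fr.rheobase is None and fr.max_firing_frequency is None
        with pytest.raises(SpikeAnalysisError):
            analyze_cell(s)


class TestAPFeatures:
    def test_template_cell_recovery_noise_free(self):
        rng = np.random.default_rng(3)
        spec = fs_template_spec(rng)
        spec.noise_sd = 0.0
        sweeps, truth = gen_ephys_cell(spec, seed=1)
        ap = ap_features(sweeps, spec.rheobase)
        assert ap.threshold == pytest.approx(spec.threshold, abs=1.0)
        assert ap.amplitude == pytest.approx(spec.amplitude, abs=2.0)
        assert ap.half_width == pytest.approx(spec.half_width, abs=0.05)
        assert ap.fahp == pytest.approx(spec.fahp, abs=2.0)

    def test_triangular_pseudo_spike_half_width_closed_form(self):
        # symmetric triangle: rise and fall slopes are both 200 mV/ms by
        # construction, so the width at half amplitude above the detected
        # threshold is amplitude/200 ms exactly
        fs = 50_000.0
        theta, amp, hw = -40.0, 80.0, 0.4  # slopes: amp/hw = 2*amp/(2*hw)
        v = template_trace([0.3], fs, theta=theta, amp=amp, hw_ms=hw, fahp=amp)
        s = SweepSet(fs, 0.2, 0.8, [100.0], v[None, :])
        ap = ap_features(s, 50.0)
        slope = amp / hw  # 200 mV/ms on both flanks
        assert ap.half_width == pytest.approx(ap.amplitude / slope, abs=0.04)

    def test_two_spike_trace_truncates_fahp_window(self):
        fs = 50_000.0
        theta, amp, fahp = -40.0, 80.0, 15.0
        v = template_trace([0.3, 0.302], fs, theta=theta, amp=amp, fahp=fahp)
        s = SweepSet(fs, 0.2, 0.8, [100.0], v[None, :])
        ap = ap_features(s, 50.0)
        # the trough between the spikes, not 10 ms of trace, bounds the fAHP
        assert ap.fahp <= fahp + 2.0

    def test_no_spike_on_required_sweep_raises(self):
        s = flat_sweeps(currents=(25.0, 75.0))
        with pytest.raises(SpikeAnalysisError):
            ap_features(s, 25.0)

    def test_clipped_peak_rejected(self):
        fs = 50_000.0
        v = template_trace([0.3], fs)
        pk = int(0.3 * fs)
        v[pk - 25 : pk + 25] = v[pk]  # 1 ms flat top
        s = SweepSet(fs, 0.2, 0.8, [100.0], v[None, :])
        with pytest.raises(SpikeAnalysisError, match="clip"):
            ap_features(s, 50.0)


class TestSFA:
    def test_forced_ratio(self):
        assert spike_frequency_accommodation([0.0, 0.1, 0.25, 0.45]) == pytest.approx(2.0)

    def test_regular_train_is_one(self):
        assert spike_frequency_accommodation(np.arange(10) * 0.02) == pytest.approx(1.0)

    def test_needs_three_spikes(self):
        with pytest.raises(SpikeAnalysisError):
            spike_frequency_accommodation([0.1, 0.2])

    def test_invariant_to_time_rescaling_and_shift(self, rng):
        t = np.sort(rng.uniform(0, 1, 8))
        base = spike_frequency_accommodation(t)
        assert spike_frequency_accommodation(3.7 * t) == pytest.approx(base)
        assert spike_frequency_accommodation(t + 11.0) == pytest.approx(base)


class TestClassifier:
    @pytest.mark.parametrize(
        "features,label,n_met",
        [
            ((0.30, 120.0, 20.0, 1.2), "FS", 4),
            ((0.70, 30.0, 10.0, 3.5), "RS", 0),
            ((0.40, 60.0, 10.0, 3.0), "RS", 2),
        ],
    )
    def test_worked_feature_vectors(self, features, label, n_met):
        got, met = classify_fs_rs(*features)
        assert got == label
        assert sum(met.values()) == n_met

    def test_thresholds_are_strict_inequalities(self):
        assert classify_fs_rs(0.5, 50.0, 15.0, 2.0)[0] == "RS"
        assert classify_fs_rs(0.499, 50.1, 15.0, 2.0)[0] == "RS"  # only 2 met
        assert classify_fs_rs(0.499, 50.1, 15.1, 2.0)[0] == "FS"

    def test_missing_sfa_requires_all_three(self):
        assert classify_fs_rs(0.3, 120.0, 20.0, None)[0] == "FS"
        assert classify_fs_rs(0.3, 120.0, 10.0, None)[0] == "RS"


class TestInvariances:
    def test_voltage_offset_shifts_threshold_not_amplitude(self):
        rng = np.random.default_rng(8)
        spec = fs_template_spec(rng)
        spec.noise_sd = 0.0
        sweeps, _ = gen_ephys_cell(spec, seed=2)
        ap0 = ap_features(sweeps, spec.rheobase)
        shifted = SweepSet(
            sweeps.sampling_rate, sweeps.stim_onset, sweeps.stim_duration,
            sweeps.currents, sweeps.voltages + 5.0,
        )
        ap1 = ap_features(shifted, spec.rheobase)
        assert ap1.threshold == pytest.approx(ap0.threshold + 5.0, abs=0.1)
        assert ap1.amplitude == pytest.approx(ap0.amplitude, abs=0.1)
        assert ap1.half_width == pytest.approx(ap0.half_width, abs=0.01)
        assert ap1.fahp == pytest.approx(ap0.fahp, abs=0.1)

    def test_time_padding_shifts_nothing_but_indices(self):
        # prepending baseline (shifting stim_onset) leaves all features alone
        rng = np.random.default_rng(9)
        spec = rs_template_spec(rng)
        spec.noise_sd = 0.0
        proto_a = EphysProtocol(stim_onset=0.2)
        proto_b = EphysProtocol(stim_onset=0.35)
        ap_a = ap_features(gen_ephys_cell(spec, proto_a, seed=3)[0], spec.rheobase)
        ap_b = ap_features(gen_ephys_cell(spec, proto_b, seed=3)[0], spec.rheobase)
        assert ap_b.threshold == pytest.approx(ap_a.threshold, abs=0.2)
        assert ap_b.half_width == pytest.approx(ap_a.half_width, abs=0.01)


class TestCellAnalysisAndIO:
    def test_full_cell_with_rin_protocol(self):
        rng = np.random.default_rng(21)
        spec = fs_template_spec(rng)
        sweeps, truth = gen_ephys_cell(spec, seed=4)
        rin = gen_rin_sweeps(spec, seed=5)
        phys = analyze_cell(sweeps, rin)
        assert phys.classification == "FS"
        assert phys.rmp == pytest.approx(spec.rmp, abs=0.3)
        assert phys.rin == pytest.approx(spec.r_mohm, rel=0.05)
        assert phys.rheobase == spec.rheobase
        assert phys.sfa == pytest.approx(spec.sfa, rel=0.1)

    def test_sweeps_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(22)
        spec = rs_template_spec(rng)
        sweeps, _ = gen_ephys_cell(spec, seed=6)
        p = tmp_path / "sweeps.csv"
        write_sweeps_csv(sweeps, p)
        back = read_sweeps_csv(p, sweeps.stim_onset, sweeps.stim_duration)
        assert back.sampling_rate == pytest.approx(sweeps.sampling_rate, rel=1e-6)
        assert back.currents == pytest.approx(sweeps.currents)
        assert back.voltages == pytest.approx(sweeps.voltages)
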