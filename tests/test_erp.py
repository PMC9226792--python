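import numpy as np
import pytest
from scipy import signal as spsig

from stopsig.erp import (ConfigurationError, MissingComponentError,
                         average_epochs, bandpass, design_bandpass_sos, epoch,
                         grand_average, measure_component, measure_session,
                         reject_amplitude, remove_blinks)
from stopsig.simulate import (ALL_CHANNELS, ErpTemplateParams,
                              simulate_eeg)


SFREQ = 500.0


def sine(freq, n=5000, sfreq=SFREQ, amp=1.0):
    t = np.arange(n) / sfreq
    return amp * np.sin(2 * np.pi * freq * t)


def tone_gain(freq: float, n: int = 20000) -> float:
    """Amplitude gain of the band-pass at one frequency, read out by
    projecting the filtered probe tone back onto the probe (insensitive to
    the slow high-pass edge transient)."""
    t = np.arange(n) / SFREQ
    x = np.sin(2 * np.pi * freq * t)[None, :]
    y = bandpass(x, SFREQ)[0]
    probe = np.exp(-2j * np.pi * freq * t)
    return float(2.0 * np.abs(np.mean(y * probe)))


class TestBandpass:
    def test_passband_gain(self):
        assert tone_gain(10.0) >= 0.95

    def test_line_noise_attenuated(self):
        atten_db = 20 * np.log10(tone_gain(60.0))
        assert atten_db < -20

    def test_dc_removed(self):
        x = np.full((1, 5000), 50.0)
        y = bandpass(x, SFREQ)
        assert abs(y.mean()) < 1.0

    def test_response_matches_design_oracle(self):
        """Measured tone gains across the band equal the squared magnitude
        of the designed response (filtfilt applies the filter twice)."""
        sos = design_bandpass_sos(0.1, 45.0, SFREQ)
        freqs = np.array([2.0, 5.0, 10.0, 20.0, 30.0, 40.0, 60.0, 80.0])
        _, h = spsig.sosfreqz(sos, worN=freqs, fs=SFREQ)
        expected = np.abs(h) ** 2
        measured = np.array([tone_gain(f) for f in freqs])
        np.testing.assert_allclose(measured, expected, rtol=0.05, atol=1e-3)

    def test_high_edge_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            design_bandpass_sos(0.1, 260.0, SFREQ)


class TestEpoching:
    def test_noiseless_roundtrip_at_cz(self, noiseless_session):
        sess = noiseless_session
        es = epoch(sess.eeg_uv, sess.ch_names, sess.sfreq, sess.events,
                   "go", trial_type="go")
        erp = average_epochs(es)
        tpl = sess.erp_params.p3go
        cz = list(sess.ch_names).index("Cz")
        t = es.times_ms
        expected = np.where(t >= 0, tpl.waveform(np.maximum(t, 0.0)), 0.0)
        expected -= expected[(t >= -200) & (t <= 0)].mean()
        np.testing.assert_allclose(erp[cz], expected, atol=1e-6)

    def test_epoch_count_matches_markers(self, noiseless_session):
        sess = noiseless_session
        es = epoch(sess.eeg_uv, sess.ch_names, sess.sfreq, sess.events,
                   "stop", condition="proactive", direction="right")
        n_markers = len(sess.events.query(
            "event == 'stop' and condition == 'proactive' "
            "and direction == 'right'"))
        assert es.data.shape[0] == n_markers

    def test_edge_event_flagged_not_raised(self, noiseless_session):
        sess = noiseless_session
        ev = sess.events.copy()
        ev.loc[ev.index[0], "onset_sample"] = 10
        es = epoch(sess.eeg_uv, sess.ch_names, sess.sfreq, ev,
                   ev.iloc[0]["event"])
        assert es.rejected[0] == "edge"

    def test_baseline_zero_mean(self, noiseless_session):
        sess = noiseless_session
        es = epoch(sess.eeg_uv, sess.ch_names, sess.sfreq, sess.events, "cue")
        t = es.times_ms
        mask = (t >= -200) & (t <= 0)
        base = es.data[:, :, mask].mean(axis=2)
        assert np.abs(base).max() < 1e-9


class TestAmplitudeRejection:
    def test_threshold_boundary(self, noiseless_session):
        sess = noiseless_session
        es = epoch(sess.eeg_uv, sess.ch_names, sess.sfreq, sess.events, "cue")
        es.data[0, 0, 250] = 120.0   # above threshold
        es.data[1, 0, 250] = 80.0    # below
        out = reject_amplitude(es, 100.0)
        assert out.rejected[0] == "amplitude"
        assert out.rejected[1] is None

    def test_eog_channel_exempt(self, noiseless_session):
        sess = noiseless_session
        es = epoch(sess.eeg_uv, sess.ch_names, sess.sfreq, sess.events, "cue")
        eog = list(sess.ch_names).index("EOG")
        es.data[2, eog, 100] = 500.0
        out = reject_amplitude(es, 100.0)
        assert out.rejected[2] is None

    def test_rejection_monotone_in_threshold(self, small_schedule,
                                             small_behavior):
        tpl = ErpTemplateParams(noise_rms_uv=20.0, blink_rate_per_min=0.0,
                                gross_artifact_p=0.1)
        sess = simulate_eeg(small_schedule, small_behavior, tpl, seed=8)
        es = epoch(sess.eeg_uv, sess.ch_names, sess.sfreq, sess.events, "cue")
        kept = [reject_amplitude(es, thr).retained.sum()
                for thr in (150.0, 100.0, 60.0, 30.0)]
        assert all(a >= b for a, b in zip(kept, kept[1:]))

    def test_forced_rejection(self, small_schedule, small_behavior):
        tpl = ErpTemplateParams(noise_rms_uv=0.0, blink_rate_per_min=0.0,
                                gross_artifact_p=1.0, gross_artifact_uv=150.0)
        sess = simulate_eeg(small_schedule, small_behavior, tpl, seed=9)
        es = epoch(sess.eeg_uv, sess.ch_names, sess.sfreq, sess.events, "go")
        out = reject_amplitude(es, 100.0)
        assert out.retained.sum() == 0


class TestBlinkRemoval:
    def test_blink_rms_halved(self, small_schedule, small_behavior):
        tpl = ErpTemplateParams(noise_rms_uv=2.0, blink_rate_per_min=12.0,
                                gross_artifact_p=0.0)
        sess = simulate_eeg(small_schedule, small_behavior, tpl, seed=21)
        clean, report = remove_blinks(sess.eeg_uv, sess.ch_names)
        assert report.zeroed_components
        fz = list(sess.ch_names).index("Fz")
        mask = np.zeros(sess.eeg_uv.shape[1], bool)
        for a, b in sess.blink_intervals:
            mask[a:b] = True
        pre = np.sqrt(np.mean(sess.eeg_uv[fz, mask] ** 2))
        post = np.sqrt(np.mean(clean[fz, mask] ** 2))
        assert post < 0.5 * pre

    def test_blink_free_record_untouched(self, small_schedule,
                                         small_behavior):
        tpl = ErpTemplateParams(noise_rms_uv=5.0, blink_rate_per_min=0.0,
                                gross_artifact_p=0.0)
        sess = simulate_eeg(small_schedule, small_behavior, tpl, seed=22)
        clean, report = remove_blinks(sess.eeg_uv, sess.ch_names)
        assert report.zeroed_components == []
        for k in range(len(sess.ch_names)):
            r = np.corrcoef(clean[k], sess.eeg_uv[k])[0, 1]
            assert r > 0.99

    def test_missing_eog_rejected(self, noiseless_session):
        with pytest.raises(ConfigurationError):
            remove_blinks(noiseless_session.eeg_uv[:6],
                          noiseless_session.ch_names[:6])


class TestAveraging:
    def test_idempotent_on_identical_epochs(self, noiseless_session):
        sess = noiseless_session
        es = epoch(sess.eeg_uv, sess.ch_names, sess.sfreq, sess.events, "cue")
        one = es.data[0]
        es.data = np.stack([one, one])
        es.events = es.events.iloc[:2]
        es.rejected = [None, None]
        np.testing.assert_allclose(average_epochs(es), one)

    def test_group_average_of_equal_subjects(self):
        erp = np.arange(20.0).reshape(2, 10)
        assert np.allclose(grand_average([erp] * 30), erp)

    def test_order_invariance(self, small_schedule, small_behavior):
        tpl = ErpTemplateParams(noise_rms_uv=5.0, blink_rate_per_min=0.0,
                                gross_artifact_p=0.0)
        sess = simulate_eeg(small_schedule, small_behavior, tpl, seed=23)
        es = epoch(sess.eeg_uv, sess.ch_names, sess.sfreq, sess.events, "cue")
        avg = average_epochs(es)
        perm = np.random.default_rng(0).permutation(es.data.shape[0])
        es.data = es.data[perm]
        es.rejected = [es.rejected[i] for i in perm]
        np.testing.assert_allclose(average_epochs(es), avg)


class TestComponentMeasurement:
    def _times(self):
        return -200.0 + np.arange(500) / SFREQ * 1000.0

    def _wave(self, bumps):
        t = self._times()
        x = np.zeros((len(ALL_CHANNELS), t.size))
        for ch_i, lat, amp, width in bumps:
            x[ch_i] += amp * np.exp(-0.5 * ((t - lat) / width) ** 2)
        return x, t

    def test_single_bump_p3go(self):
        cz = ALL_CHANNELS.index("Cz")
        x, t = self._wave([(cz, 400.0, 5.0, 40.0)])
        m = measure_component(x, t, ALL_CHANNELS, "P3go", "Cz")
        assert m.amplitude_uv == pytest.approx(5.0, abs=1e-9)
        assert m.latency_ms == pytest.approx(400.0, abs=2.0)

    def test_n2_second_negative_peak(self):
        """Two troughs at 150/250 ms: only the 250 ms one is in-window and
        it is the second negative peak overall, so it is returned directly
        (oracle = exhaustive local-extremum scan)."""
        fz = ALL_CHANNELS.index("Fz")
        x, t = self._wave([(fz, 150.0, -3.0, 20.0), (fz, 250.0, -2.0, 20.0)])
        m = measure_component(x, t, ALL_CHANNELS, "N2stop", "Fz")
        # tolerance covers the 150 ms bump's Gaussian tail under the trough
        assert m.amplitude_uv == pytest.approx(-2.0, abs=1e-3)
        assert m.latency_ms == pytest.approx(250.0, abs=2.0)
        assert not m.fallback
        # oracle: scan every sample for local minima
        post = x[fz][t >= 0]
        tp = t[t >= 0]
        minima = [(tp[i], post[i]) for i in range(1, len(post) - 1)
                  if post[i] < post[i - 1] and post[i] < post[i + 1]
                  and post[i] < 0]
        assert len(minima) == 2
        assert minima[1][0] == pytest.approx(m.latency_ms, abs=2.0)

    def test_n2_two_in_window(self):
        fz = ALL_CHANNELS.index("Fz")
        x, t = self._wave([(fz, 220.0, -3.0, 15.0), (fz, 320.0, -2.0, 15.0)])
        m = measure_component(x, t, ALL_CHANNELS, "N2stop", "Fz")
        assert m.latency_ms == pytest.approx(320.0, abs=2.0)

    def test_n2_single_minimum_fallback(self):
        fz = ALL_CHANNELS.index("Fz")
        x, t = self._wave([(fz, 270.0, -1.5, 30.0)])
        m = measure_component(x, t, ALL_CHANNELS, "N2stop", "Fz")
        assert m.fallback
        assert m.amplitude_uv == pytest.approx(-1.5, abs=1e-6)

    def test_flat_waveform_missing_component(self):
        x = np.zeros((len(ALL_CHANNELS), 500))
        with pytest.raises(MissingComponentError):
            measure_component(x, self._times(), ALL_CHANNELS, "N2stop", "Fz")

    def test_window_not_covered(self):
        x = np.zeros((len(ALL_CHANNELS), 50))
        t = np.arange(50) / SFREQ * 1000.0
        with pytest.raises(ConfigurationError):
            measure_component(x, t, ALL_CHANNELS, "P3cue", "Fz")


class TestPipelineLinearity:
    def test_noiseless_measures_recover_templates(self, noiseless_session):
        """simulate -> epoch -> average -> measure is exact without noise."""
        mt = measure_session(noiseless_session, clean_blinks=False,
                             filter_band=None)
        truth = {"P3cue": (3.5, 400.0), "P3go": (2.2, 380.0),
                 "N2stop": (-1.5, 270.0), "P3stop": (3.2, 380.0)}
        for comp, (amp, lat) in truth.items():
            sub = mt[mt.component == comp]
            assert not sub.empty
            assert np.abs(sub.amplitude_uv - amp).max() < 1e-6
            assert np.abs(sub.latency_ms - lat).max() <= 2.0
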