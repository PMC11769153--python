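"""Preprocessing chain: filter contracts, re-referencing, ICA round trips,
component labelling rules, and resting-period extraction."""
import numpy as np
import pytest
import scipy.signal

import restmdd as rm
from restmdd.recording import CHANNELS_1020, Annotation, EEGRecording

from conftest import periodogram_band_fraction


def _sine_recording(freq, fs=200.0, seconds=90.0, n_ch=2):
    t = np.arange(int(seconds * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return EEGRecording(data=data, fs=fs,
                        channel_names=CHANNELS_1020[:n_ch])


# steady-state window: skip one filter-kernel length at each edge
_MID = slice(7000, -7000)


class TestBandpass:
    def test_passband_tone_preserved(self):
        rec = _sine_recording(10.0)
        out = rm.bandpass_fir(rec)
        ratio = out.data[0, _MID].std() / rec.data[0, _MID].std()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_stopband_tone_rejected(self):
        rec = _sine_recording(50.0)
        out = rm.bandpass_fir(rec)
        assert out.data[0, _MID].std() <= 0.01 * rec.data[0, _MID].std()

    def test_zero_in_zero_out(self):
        rec = EEGRecording(data=np.zeros((3, 4000)), fs=200.0,
                           channel_names=CHANNELS_1020[:3])
        out = rm.bandpass_fir(rec)
        assert np.allclose(out.data, 0.0)

    def test_invalid_cutoffs_rejected(self):
        rec = _sine_recording(10.0)
        with pytest.raises(ValueError, match="cutoff"):
            rm.bandpass_fir(rec, low=0.1, high=120.0)

    def test_passband_flat_within_1db(self):
        """Designed response stays within +-1 dB over 1-35 Hz (applied
        forward-backward)."""
        taps = rm.preprocess.design_bandpass(0.1, 40.0, 200.0)
        w, h = scipy.signal.freqz(taps, worN=1 << 16, fs=200.0)
        gain_db = 40 * np.log10(np.maximum(np.abs(h), 1e-12))
        band = (w >= 1.0) & (w <= 35.0)
        assert np.all(np.abs(gain_db[band]) <= 1.0)
        i50 = np.argmin(np.abs(w - 50.0))
        assert gain_db[i50] <= -40.0


class TestAverageReference:
    def test_antisymmetric_pair_unchanged(self):
        rec = EEGRecording(data=np.array([[1.0] * 100, [-1.0] * 100]),
                           fs=200.0, channel_names=["Fp1", "Fp2"])
        out = rm.average_reference(rec)
        assert np.allclose(out.data, rec.data)

    def test_common_mode_removed(self):
        rec = EEGRecording(data=np.full((4, 50), 3.7), fs=200.0,
                           channel_names=CHANNELS_1020[:4])
        out = rm.average_reference(rec)
        assert np.allclose(out.data, 0.0)

    def test_zero_channel_mean_after_rereference(self, recording):
        out = rm.average_reference(recording)
        rms = out.data.std()
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9 * rms

    def test_single_channel_rejected(self):
        rec = EEGRecording(data=np.zeros((1, 10)), fs=200.0,
                           channel_names=["Fp1"])
        with pytest.raises(ValueError):
            rm.average_reference(rec)

    def test_filter_and_rereference_commute_on_band_power(self, recording):
        """Both operators are linear, so their order changes band power by
        under 1%."""
        a = rm.average_reference(rm.bandpass_fir(recording))
        b = rm.bandpass_fir(rm.average_reference(recording))
        pa = np.mean(a.data ** 2, axis=1)
        pb = np.mean(b.data ** 2, axis=1)
        assert np.allclose(pa, pb, rtol=0.01)


class TestICA:
    def test_known_mixture_recovery(self):
        """A sinusoid/sawtooth mixture is recovered up to order and sign."""
        fs = 200.0
        t = np.arange(4000) / fs
        s1 = np.sin(2 * np.pi * 10 * t)
        s2 = scipy.signal.sawtooth(2 * np.pi * 3 * t)
        A = np.array([[1.0, 0.6], [0.4, 1.0]])
        rec = EEGRecording(data=A @ np.vstack([s1, s2]), fs=fs,
                           channel_names=["Fp1", "Fp2"])
        decomp = rm.ica_decompose(rec, n_components=2, seed=0)
        cors = np.abs(np.corrcoef(np.vstack([decomp.sources, s1, s2]))[:2, 2:])
        # each true source matches some component
        assert cors.max(axis=0).min() > 0.95

    def test_too_many_components_rejected(self, recording):
        with pytest.raises(ValueError):
            rm.ica_decompose(recording, n_components=25, seed=0)

    def test_rank_deficient_request_rejected(self):
        rank2 = np.random.default_rng(0).standard_normal((2, 1000))
        data = np.vstack([rank2, rank2.sum(axis=0, keepdims=True)])
        rec = EEGRecording(data=data, fs=200.0,
                           channel_names=CHANNELS_1020[:3])
        with pytest.raises(ValueError, match="rank"):
            rm.ica_decompose(rec, n_components=3, seed=0)

    def test_seeded_determinism(self, recording):
        reref = rm.average_reference(recording)
        a = rm.ica_decompose(reref, seed=5)
        b = rm.ica_decompose(reref, seed=5)
        assert np.array_equal(a.mixing, b.mixing)

    def test_round_trip_reconstruction(self, recording):
        """Dropping nothing reconstructs the input within 1e-6 relative."""
        reref = rm.average_reference(recording)
        decomp = rm.ica_decompose(reref, seed=1)
        out = rm.remove_components(reref, decomp, drop=set())
        err = np.linalg.norm(out.data - reref.data) / np.linalg.norm(reref.data)
        assert err < 1e-6


class TestComponentLabels:
    def _decomp_with_sources(self, sources, mixing):
        n_comp = sources.shape[0]
        return rm.ComponentDecomposition(
            unmixing=np.linalg.pinv(mixing), mixing=mixing,
            sources=sources, mean=np.zeros(mixing.shape[0]))

    def test_pure_mains_tone_labelled_line_noise(self, recording):
        t = np.arange(recording.n_samples) / recording.fs
        src = np.sin(2 * np.pi * 50 * t)[None, :]
        mixing = np.ones((19, 1))
        d = self._decomp_with_sources(src, mixing)
        assert rm.classify_components(d, recording) == ["LINE_NOISE"]

    def test_frontal_lowfreq_component_labelled_eye(self, recording):
        rng = np.random.default_rng(0)
        src = scipy.signal.sosfiltfilt(
            scipy.signal.butter(4, 2.0, output="sos", fs=200.0),
            rng.standard_normal(recording.n_samples))[None, :]
        mixing = np.full((19, 1), 0.1)
        mixing[recording.channel_index("Fp1")] = 1.0
        mixing[recording.channel_index("Fp2")] = 1.0
        d = self._decomp_with_sources(src, mixing)
        assert rm.classify_components(d, recording) == ["EYE"]

    def test_broadband_uniform_component_labelled_brain(self, recording):
        rng = np.random.default_rng(1)
        n = recording.n_samples
        spec = np.fft.rfft(rng.standard_normal(n))
        freqs = np.fft.rfftfreq(n, d=1 / 200)
        spec[1:] *= freqs[1:] ** -0.5
        src = np.fft.irfft(spec, n=n)[None, :]
        d = self._decomp_with_sources(src, np.ones((19, 1)))
        assert rm.classify_components(d, recording) == ["BRAIN"]

    def test_injected_blink_component_labelled_eye(self, subject,
                                                   short_protocol):
        rec = rm.synth_recording(subject, protocol=short_protocol)
        art = rm.inject_artifacts(
            rec, rm.ArtifactSpec(blink_rate=12, blink_amplitude=150,
                                 line_noise_amplitude=0, drift_amplitude=0),
            seed=2)
        reref = rm.average_reference(rm.bandpass_fir(art))
        decomp = rm.ica_decompose(reref, seed=0)
        labels = rm.classify_components(decomp, reref)
        assert "EYE" in labels


class TestRemoveComponents:
    def test_drop_all_gives_mean_only(self, recording):
        reref = rm.average_reference(recording)
        decomp = rm.ica_decompose(reref, seed=1)
        out = rm.remove_components(reref, decomp,
                                   drop=set(range(decomp.n_components)))
        assert np.allclose(out.data, decomp.mean[:, None], atol=1e-8)

    def test_out_of_range_index_rejected(self, recording):
        reref = rm.average_reference(recording)
        decomp = rm.ica_decompose(reref, seed=1)
        with pytest.raises(IndexError):
            rm.remove_components(reref, decomp, drop={99})

    def test_line_component_removal_suppresses_mains_peak(self, subject,
                                                          short_protocol):
        """Dropping the labelled mains component cuts 50 Hz power by
        >=20 dB (measured before the 40 Hz lowpass would mask it)."""
        rec = rm.synth_recording(subject, protocol=short_protocol)
        art = rm.inject_artifacts(
            rec, rm.ArtifactSpec(blink_rate=0, blink_amplitude=0,
                                 line_noise_amplitude=20.0,
                                 drift_amplitude=0), seed=3)
        reref = rm.average_reference(art)  # keep 50 Hz: no lowpass here
        decomp = rm.ica_decompose(reref, seed=0)
        labels = rm.classify_components(decomp, reref)
        assert "LINE_NOISE" in labels
        drop = {k for k, lab in enumerate(labels) if lab == "LINE_NOISE"}
        out = rm.remove_components(reref, decomp, drop)

        def p50(x):
            spec = np.abs(np.fft.rfft(x)) ** 2
            freqs = np.fft.rfftfreq(len(x), d=1 / 200)
            return spec[(freqs >= 49) & (freqs <= 51)].sum()

        before = np.mean([p50(reref.data[c]) for c in range(19)])
        after = np.mean([p50(out.data[c]) for c in range(19)])
        assert 10 * np.log10(before / after) >= 20.0


class TestRestingPeriods:
    def test_default_protocol_yields_five_alternating_segments(self, segments):
        assert len(segments) == 5
        conds = [s.condition for s in segments]
        assert all(a != b for a, b in zip(conds, conds[1:]))

    def test_too_few_periods_rejected(self):
        rec = EEGRecording(
            data=np.zeros((2, 6000)), fs=200.0,
            channel_names=["Fp1", "Fp2"],
            annotations=[Annotation(0, 10, "EYES_OPEN"),
                         Annotation(10, 10, "EYES_CLOSED"),
                         Annotation(20, 10, "EYES_OPEN")])
        with pytest.raises(ValueError, match="3"):
            rm.extract_resting_periods(rec)

    def test_segments_exclude_photic_and_hyperventilation(
            self, segments, short_protocol):
        rest_seconds = sum(p.duration for p in short_protocol.resting_phases)
        total = sum(s.duration for s in segments)
        assert total == pytest.approx(rest_seconds)


class TestChain:
    def test_artifact_attenuation_end_to_end(self, subject, short_protocol):
        """Blink and mains injection are undone to within 25% of the
        artifact-free recording's frontal delta and pooled 50 Hz power."""
        clean = rm.synth_recording(subject, protocol=short_protocol)
        art = rm.inject_artifacts(clean, rm.ArtifactSpec(), seed=8)
        ref, _ = rm.preprocess_recording(clean, seed=3)
        got, log = rm.preprocess_recording(art, seed=3)
        assert log["dropped"], "expected at least one artifact component"
        fp1 = clean.channel_index("Fp1")

        def welch_band(x, lo, hi):
            f, P = scipy.signal.welch(x, fs=200.0, nperseg=1600, axis=-1)
            sel = (f >= lo) & (f <= hi)
            return P[..., sel].sum(axis=-1)

        delta_ratio = welch_band(got.data[fp1], 0.5, 4) / \
            welch_band(ref.data[fp1], 0.5, 4)
        p50_ratio = welch_band(got.data, 49, 51).mean() / \
            welch_band(ref.data, 49, 51).mean()
        assert 0.75 <= delta_ratio <= 1.25
        assert 0.75 <= p50_ratio <= 1.25

    def test_drop_policy_none_skips_ica(self, recording):
        out, log = rm.preprocess_recording(recording, drop_policy="none")
        assert log["dropped"] == []
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9 * out.data.std()
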