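"""The 208-feature baseline: shapes, binary contracts and signal oracles."""

import numpy as np
import pytest

from speechenc import features as F
from speechenc.datatypes import Segmentation


@pytest.fixture(scope="module")
def tone_1khz():
    fs = 16000.0
    t = np.arange(int(fs)) / fs
    return np.sin(2 * np.pi * 1000.0 * t), fs


class TestSpectrogram:
    def test_tone_peaks_at_correct_log_bin(self, tone_1khz):
        wave, fs = tone_1khz
        spec = F.compute_spectrogram(wave, fs)
        centers = F.spectrogram_center_frequencies()
        # average over interior frames, find the dominant bin
        peak = np.argmax(spec.values[:, 10:-10].mean(axis=1))
        target = np.argmin(np.abs(centers - 1000.0))
        assert abs(peak - target) <= 1

    def test_silence_gives_zero_magnitudes(self):
        spec = F.compute_spectrogram(np.zeros(16000), 16000.0)
        np.testing.assert_allclose(spec.values, 0.0, atol=1e-12)

    def test_amplitude_linearity(self, tone_1khz):
        wave, fs = tone_1khz
        s1 = F.compute_spectrogram(wave, fs).values
        s2 = F.compute_spectrogram(2 * wave, fs).values
        np.testing.assert_allclose(s2, 2 * s1, atol=1e-10)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            F.compute_spectrogram(np.zeros(8000), 8000.0)

    def test_has_161_rows(self, tone_1khz):
        wave, fs = tone_1khz
        assert F.compute_spectrogram(wave, fs).n_features == 161


class TestPhonetic:
    def test_vowel_carries_exactly_its_bits(self):
        seg = Segmentation([0, 5], [0, 5], ["iy", "t"], 10)
        out = F.phonetic_features(seg)
        names = list(out.feature_names)
        iy_frames = out.values[:, :5]
        on = {names[i] for i in np.nonzero(iy_frames[:, 0])[0]}
        assert on == {"vowel", "high", "front"}
        assert np.all(iy_frames == iy_frames[:, :1])

    def test_silence_segment_is_zero(self):
        seg = Segmentation([0, 4], [0, 4], ["sil", "aa"], 8)
        out = F.phonetic_features(seg)
        np.testing.assert_array_equal(out.values[:, :4], 0.0)

    def test_output_frame_count_matches_segmentation(self, random_segmentations):
        for seg in random_segmentations[:4]:
            assert F.phonetic_features(seg).n_frames == seg.n_frames

    def test_unknown_phoneme_named_in_error(self):
        seg = Segmentation([0], [0], ["qq"], 5)
        with pytest.raises(KeyError, match="qq"):
            F.phonetic_features(seg)

    def test_binary_and_13_rows(self, random_segmentations):
        out = F.phonetic_features(random_segmentations[0])
        assert out.n_features == 13
        assert set(np.unique(out.values)) <= {0.0, 1.0}


class TestPitch:
    def _track(self, rng, T=400, voiced_frac=0.7):
        f0 = np.zeros(T)
        voiced = rng.random(T) < voiced_frac
        f0[voiced] = rng.uniform(80, 300, voiced.sum())
        return f0, voiced

    def test_voiced_frames_have_three_onehots_plus_voicing(self, rng):
        f0, voiced = self._track(rng)
        out = F.pitch_features(f0)
        col_sums = out.values.sum(axis=0)
        np.testing.assert_array_equal(col_sums[voiced], 4.0)

    def test_unvoiced_frames_all_zero(self, rng):
        f0, voiced = self._track(rng)
        out = F.pitch_features(f0)
        np.testing.assert_array_equal(out.values[:, ~voiced], 0.0)

    def test_at_most_one_active_bin_per_subfeature(self, rng):
        f0, _ = self._track(rng)
        out = F.pitch_features(f0)
        for lo in (0, 10, 20):
            assert np.all(out.values[lo:lo + 10].sum(axis=0) <= 1)

    def test_constant_f0_maps_to_middle_bin(self):
        f0 = np.full(50, 120.0)
        out = F.pitch_features(f0)
        rel = out.values[10:20]
        assert np.all(rel[4] == 1.0)  # all mass in the middle bin
        assert rel.sum() == 50

    def test_negative_f0_rejected(self):
        with pytest.raises(ValueError):
            F.pitch_features(np.array([100.0, -50.0, 120.0]))

    def test_31_rows(self, rng):
        f0, _ = self._track(rng)
        assert F.pitch_features(f0).n_features == 31


class TestEnvelope:
    def test_onset_row_counts_sentences(self):
        wave = np.random.default_rng(1).standard_normal(32000)
        out = F.envelope_features(wave, 16000.0, sentence_onsets=[3, 120])
        assert out.values[1].sum() == 2

    def test_single_peak_on_rise(self):
        # envelope rises then falls once: exactly one peak-rate event
        fs = 16000.0
        t = np.arange(int(fs)) / fs
        env = np.exp(-0.5 * ((t - 0.5) / 0.1) ** 2)
        wave = env * np.sin(2 * np.pi * 500 * t)
        out = F.envelope_features(wave, fs, sentence_onsets=[0])
        peaks = np.nonzero(out.values[2])[0]
        assert len(peaks) == 1
        assert 30 < peaks[0] < 50  # steepest rise precedes the 500-ms maximum

    def test_silence_has_no_events(self):
        out = F.envelope_features(np.zeros(16000), 16000.0, sentence_onsets=[0])
        np.testing.assert_array_equal(out.values[0], 0.0)
        assert out.values[2].sum() == 0

    def test_out_of_range_onset_rejected(self):
        with pytest.raises(ValueError):
            F.envelope_features(np.zeros(1600), 16000.0, sentence_onsets=[10**6])


class TestAssembly:
    def test_baseline_is_208_rows_partitioned(self, rng, random_segmentations):
        fs = 16000.0
        seg = random_segmentations[0]
        dur = seg.n_frames / 100.0
        wave = rng.standard_normal(int(dur * fs))
        spec = F.compute_spectrogram(wave, fs, n_frames=seg.n_frames)
        phon = F.phonetic_features(seg)
        f0 = np.where(rng.random(seg.n_frames) < 0.6,
                      rng.uniform(80, 250, seg.n_frames), 0.0)
        pitch = F.pitch_features(f0)
        env = F.envelope_features(wave, fs, [0], n_frames=seg.n_frames)
        base = F.assemble_baseline(spec, phon, pitch, env)
        assert base.n_features == 208
        counts = {s: int(np.sum(base.set_labels == s)) for s in base.sets}
        assert counts == {"spectrogram": 161, "phonetic": 13, "pitch": 31, "envelope": 3}
        for s in ("phonetic", "pitch"):
            vals = base.subset([s]).values
            assert set(np.unique(vals)) <= {0.0, 1.0}

    def test_wrong_partition_rejected(self, rng):
        from speechenc.datatypes import FeatureStream
        bad = FeatureStream(rng.standard_normal((5, 10)), 100.0,
                            ["spectrogram"] * 5, [f"s{i}" for i in range(5)])
        good_ph = FeatureStream(np.zeros((13, 10)), 100.0,
                                ["phonetic"] * 13, [f"p{i}" for i in range(13)])
        good_pi = FeatureStream(np.zeros((31, 10)), 100.0,
                                ["pitch"] * 31, [f"q{i}" for i in range(31)])
        good_env = FeatureStream(np.zeros((3, 10)), 100.0,
                                 ["envelope"] * 3, [f"e{i}" for i in range(3)])
        with pytest.raises(ValueError, match="spectrogram"):
            F.assemble_baseline(bad, good_ph, good_pi, good_env)
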