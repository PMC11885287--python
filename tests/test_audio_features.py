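"""Audio feature tests: I/O, preprocessing, spectrogram, descriptors, cepstra.

Every DERIVED expectation is checked against an independent brute-force
oracle (direct DFT / direct summation) written inline here, never against
the package's own code path.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from birdfuse.audio_features import (
    AudioClip,
    FrameSpec,
    build_feature_set,
    chroma,
    cosine_transform,
    denoise,
    extract_clip_features,
    feature_set_members,
    gfcc_block,
    load_wav,
    mel_filterbank,
    mfcc_block,
    read_feature_csv,
    save_wav,
    segment,
    spectral_descriptors,
    spectrogram,
    summarize,
    tempo_harmonics,
    write_feature_csv,
)
from birdfuse.audio_features.features import FeatureTable
from birdfuse.audio_features.spectral import Spectrogram, frame_signal
from birdfuse.errors import FormatError, InvalidConfigError, InvalidInputError, SchemaError
from birdfuse.feature_selection import SelectionResult

from conftest import TEST_FRAMES, TEST_SR


class TestWavIO:
    def test_round_trip(self, tmp_path, call_clip):
        path = tmp_path / "x.wav"
        save_wav(call_clip, path)
        back = load_wav(path)
        assert back.sample_rate == call_clip.sample_rate
        assert np.max(np.abs(back.samples - call_clip.samples)) <= 1.0 / 32768.0

    def test_stereo_cancellation_averages_to_zero(self, tmp_path):
        from scipy.io import wavfile

        x = (np.sin(np.linspace(0, 40 * np.pi, 4000)) * 20000).astype(np.int16)
        stereo = np.stack([x, -x], axis=1)
        path = tmp_path / "stereo.wav"
        wavfile.write(str(path), 8000, stereo)
        clip = load_wav(path)
        assert np.max(np.abs(clip.samples)) <= 1.0 / 32768.0

    def test_truncated_file_is_format_error(self, tmp_path, call_clip):
        path = tmp_path / "t.wav"
        save_wav(call_clip, path)
        data = path.read_bytes()
        path.write_bytes(data[:20])  # cut inside the header
        with pytest.raises(FormatError):
            load_wav(path)

    def test_missing_file_is_format_error(self, tmp_path):
        with pytest.raises(FormatError, match="nope.wav"):
            load_wav(tmp_path / "nope.wav")

    def test_clip_validation(self):
        with pytest.raises(InvalidInputError):
            AudioClip(np.zeros((2, 5)), 8000)
        with pytest.raises(InvalidInputError):
            AudioClip(np.array([np.nan]), 8000)
        with pytest.raises(InvalidInputError):
            AudioClip(np.array([]), 8000)


class TestDenoise:
    def test_zero_in_zero_out(self):
        clip = AudioClip(np.zeros(TEST_SR), TEST_SR)
        out = denoise(clip)
        assert np.max(np.abs(out.samples)) == 0.0
        assert len(out) == len(clip)

    def test_white_noise_strongly_attenuated(self, noisy_clip):
        out = denoise(noisy_clip)
        rms_in = np.sqrt(np.mean(noisy_clip.samples**2))
        rms_out = np.sqrt(np.mean(out.samples**2))
        assert rms_out < 0.25 * rms_in

    def test_tone_after_silence_preserved(self):
        sr = TEST_SR
        t = np.arange(2 * sr) / sr
        x = 0.5 * np.sin(2 * np.pi * 1000.0 * t)
        x[: sr // 2] = 0.0
        out = denoise(AudioClip(x, sr))

        def band_energy(sig):  # oracle: direct DFT of a steady-state window
            frame = sig[sr : sr + 8192]
            mags = np.abs(np.fft.rfft(frame))
            freqs = np.fft.rfftfreq(8192, 1.0 / sr)
            return float((mags[(freqs > 950) & (freqs < 1050)] ** 2).sum())

        change_db = 10 * np.log10(band_energy(out.samples) / band_energy(x))
        assert abs(change_db) <= 3.0

    def test_too_short_clip_rejected(self):
        with pytest.raises(InvalidInputError):
            denoise(AudioClip(np.zeros(100), TEST_SR), noise_seconds=0.5)


class TestSegment:
    def test_twelve_seconds_gives_three(self):
        clip = AudioClip(np.ones(12 * 1000), 1000)
        parts = segment(clip, 5.0)
        assert len(parts) == 3
        assert all(len(p) == 5000 for p in parts)
        assert np.all(parts[2].samples[2000:] == 0.0)  # padded tail

    def test_short_remainder_dropped(self):
        clip = AudioClip(np.ones(10500), 1000)
        assert len(segment(clip, 5.0)) == 2

    def test_short_clip_single_padded_segment(self):
        clip = AudioClip(np.ones(3000), 1000)
        parts = segment(clip, 5.0)
        assert len(parts) == 1 and len(parts[0]) == 5000

    def test_concatenation_reproduces_prefix(self, call_clip):
        parts = segment(call_clip, 0.75)
        joined = np.concatenate([p.samples for p in parts])
        n = min(len(joined), len(call_clip))
        np.testing.assert_array_equal(joined[: len(call_clip)][:n], call_clip.samples[:n])


class TestSpectrogram:
    def test_zero_clip_zero_magnitudes(self):
        sp = spectrogram(AudioClip(np.zeros(4096), TEST_SR), TEST_FRAMES)
        assert np.all(sp.magnitudes == 0.0)

    def test_bin_count_and_axes(self, call_clip):
        sp = spectrogram(call_clip, TEST_FRAMES)
        assert sp.n_bins == TEST_FRAMES.frame_length // 2 + 1
        assert sp.bin_freqs[0] == 0.0
        assert sp.bin_freqs[-1] == pytest.approx(call_clip.sample_rate / 2)
        assert np.all(np.diff(sp.bin_freqs) > 0)

    def test_sine_peak_bin(self):
        t = np.arange(22050) / 22050
        clip = AudioClip(np.sin(2 * np.pi * 1000.0 * t), 22050)
        spec = FrameSpec(2048, 512)
        sp = spectrogram(clip, spec)
        target = np.argmin(np.abs(sp.bin_freqs - 1000.0))
        # skip boundary frames affected by reflect padding
        for row in sp.magnitudes[2:-2]:
            assert abs(int(np.argmax(row)) - int(target)) <= 1

    def test_matches_naive_dft_oracle(self, call_clip):
        sp = spectrogram(call_clip, TEST_FRAMES)
        frames = frame_signal(call_clip.samples, TEST_FRAMES)
        window = TEST_FRAMES.window
        rng = np.random.default_rng(0)
        n = TEST_FRAMES.frame_length
        for idx in rng.choice(frames.shape[0], size=3, replace=False):
            x = frames[idx] * window
            k = np.arange(n // 2 + 1)
            # brute-force DFT by direct summation
            basis = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n)
            oracle = np.abs(basis @ x)
            np.testing.assert_allclose(sp.magnitudes[idx], oracle, rtol=1e-6, atol=1e-9)

    def test_too_short_clip_rejected(self):
        with pytest.raises(InvalidInputError):
            spectrogram(AudioClip(np.ones(100), TEST_SR), TEST_FRAMES)


def _flat_spect(value: float = 2.0, frames: int = 4) -> Spectrogram:
    spec = FrameSpec(512, 256)
    bins = 257
    return Spectrogram(
        magnitudes=np.full((frames, bins), value),
        bin_freqs=np.arange(bins) * TEST_SR / 512,
        frame_times=np.arange(frames) * 256 / TEST_SR,
        frame_spec=spec,
    )


class TestMfcc:
    def test_flat_spectrum_gives_zero_coefficients(self):
        out = mfcc_block(_flat_spect())
        np.testing.assert_allclose(out[:, :13], 0.0, atol=1e-8)

    def test_gain_invariance_of_static_coefficients(self, call_clip):
        sp = spectrogram(call_clip, TEST_FRAMES)
        scaled = Spectrogram(
            magnitudes=sp.magnitudes * 10.0, bin_freqs=sp.bin_freqs,
            frame_times=sp.frame_times, frame_spec=sp.frame_spec,
        )
        a = mfcc_block(sp)[:, :13]
        b = mfcc_block(scaled)[:, :13]
        assert np.max(np.abs(a - b)) < 1e-6

    def test_width_is_39(self, call_clip):
        assert mfcc_block(spectrogram(call_clip, TEST_FRAMES)).shape[1] == 39

    def test_matches_term_by_term_summation_oracle(self, call_clip):
        sp = spectrogram(call_clip, TEST_FRAMES)
        n_mels, n_keep = 26, 13
        out = mfcc_block(sp, n_mels, n_keep)
        fb = mel_filterbank(n_mels, sp.bin_freqs)
        frame = 5
        log_e = np.log(np.maximum(sp.magnitudes[frame] ** 2 @ fb.T, 1e-10))
        for m in range(1, n_keep + 1):
            # literal term-by-term cosine-transform evaluation
            expected = sum(
                log_e[n - 1] * np.cos(m * (n - 0.5) * np.pi / n_mels)
                for n in range(1, n_mels + 1)
            )
            assert out[frame, m - 1] == pytest.approx(expected, abs=1e-8)

    def test_degenerate_filterbank_rejected(self, call_clip):
        with pytest.raises(InvalidConfigError):
            mfcc_block(spectrogram(call_clip, TEST_FRAMES), n_mels=300)
        with pytest.raises(InvalidConfigError):
            mfcc_block(spectrogram(call_clip, TEST_FRAMES), n_mels=20, n_keep=21)


class TestGfcc:
    def test_column_count(self, call_clip):
        assert gfcc_block(call_clip, spec=TEST_FRAMES).shape[1] == 13

    def test_silent_clip_constant_across_frames(self):
        out = gfcc_block(AudioClip(np.zeros(4096), TEST_SR), spec=TEST_FRAMES)
        assert np.max(np.abs(out - out[0][None, :])) <= 1e-12

    def test_matches_direct_cosine_transform_of_energies(self, noisy_clip):
        from birdfuse.audio_features.cepstral import gammatone_filterbank

        sp = spectrogram(noisy_clip, TEST_FRAMES)
        fb = gammatone_filterbank(26, sp.bin_freqs)
        out = gfcc_block(noisy_clip, spec=TEST_FRAMES)
        frame = 7
        compressed = np.cbrt(sp.magnitudes[frame] ** 2 @ fb.T)
        for m in range(1, 14):
            expected = sum(
                compressed[n - 1] * np.cos(m * (n - 0.5) * np.pi / 26)
                for n in range(1, 27)
            )
            assert out[frame, m - 1] == pytest.approx(expected, abs=1e-8)


class TestSpectralDescriptors:
    def test_single_bin_centroid_and_bandwidth(self):
        sp = _flat_spect(0.0)
        target = np.argmin(np.abs(sp.bin_freqs - 1000.0))
        sp.magnitudes[:, target] = 3.0
        desc = spectral_descriptors(sp, AudioClip(np.ones(1024), TEST_SR))
        np.testing.assert_allclose(desc["centroid"], sp.bin_freqs[target])
        np.testing.assert_allclose(desc["bandwidth"], 0.0, atol=1e-9)

    def test_silent_frame_conventions(self):
        sp = _flat_spect(0.0)
        desc = spectral_descriptors(sp, AudioClip(np.zeros(1024), TEST_SR))
        for key in ("centroid", "bandwidth", "rolloff", "flux"):
            np.testing.assert_array_equal(desc[key], 0.0)

    def test_zcr_extremes(self):
        spec = FrameSpec(512, 256)
        alternating = np.resize(np.array([1.0, -1.0]), 2048)
        desc = spectral_descriptors(
            spectrogram(AudioClip(alternating, TEST_SR), spec),
            AudioClip(alternating, TEST_SR),
        )
        assert desc["zcr"].max() == pytest.approx(1.0)
        constant = np.ones(2048)
        desc_c = spectral_descriptors(
            spectrogram(AudioClip(constant, TEST_SR), spec),
            AudioClip(constant, TEST_SR),
        )
        np.testing.assert_array_equal(desc_c["zcr"], 0.0)

    def test_sine_centroid_near_1khz(self, tone_clip):
        sp = spectrogram(tone_clip, TEST_FRAMES)
        desc = spectral_descriptors(sp, tone_clip)
        bin_width = tone_clip.sample_rate / TEST_FRAMES.frame_length
        inner = desc["centroid"][2:-2]
        assert np.all(np.abs(inner - 1000.0) <= bin_width)

    def test_flux_matches_direct_oracle(self, call_clip):
        sp = spectrogram(call_clip, TEST_FRAMES)
        desc = spectral_descriptors(sp, call_clip)
        assert desc["flux"][0] == 0.0
        t = 9
        inc = np.maximum(sp.magnitudes[t] - sp.magnitudes[t - 1], 0.0)
        assert desc["flux"][t] == pytest.approx(np.sqrt((inc**2).sum()), rel=1e-12)

    def test_all_finite_on_silence(self):
        sp = _flat_spect(0.0)
        desc = spectral_descriptors(sp, AudioClip(np.zeros(1024), TEST_SR))
        for v in desc.values():
            assert np.all(np.isfinite(v))


class TestChroma:
    def _tone_spect(self, freq: float) -> Spectrogram:
        t = np.arange(TEST_SR) / TEST_SR
        return spectrogram(AudioClip(np.sin(2 * np.pi * freq * t), TEST_SR), TEST_FRAMES)

    def test_a440_dominates_pitch_class_a(self):
        ch = chroma(self._tone_spect(440.0))
        # column 9 is A (midi % 12 with C = 0)
        assert np.all(np.argmax(ch[2:-2], axis=1) == 9)
        assert ch[2:-2, 9].max() == pytest.approx(1.0)

    def test_octave_equivalence(self):
        a = chroma(self._tone_spect(440.0))[5]
        b = chroma(self._tone_spect(880.0))[5]
        assert np.argmax(a) == np.argmax(b)

    def test_silent_input_all_zero(self):
        ch = chroma(_flat_spect(0.0))
        np.testing.assert_array_equal(ch, 0.0)


class TestTempoHarmonics:
    def test_click_train_tempo(self):
        sr = TEST_SR
        x = np.zeros(4 * sr)
        x[:: sr // 2] = 1.0  # 2 Hz click train
        out = tempo_harmonics(AudioClip(x, sr), FrameSpec(512, 256))
        assert out["tempo_bpm"] == pytest.approx(120.0, rel=0.05)

    def test_pure_sine_has_no_harmonics(self, tone_clip):
        out = tempo_harmonics(tone_clip, TEST_FRAMES)
        assert out["harmonic_ratio"] < 0.05

    def test_three_harmonic_call_is_harmonic(self, small_config):
        from birdfuse.synth_data import SpeciesSpec, render_call

        spec = SpeciesSpec(
            name="h", f0=900.0, chirp_rate=100.0, n_syllables=3,
            syllable_dur=0.3, hue=0.0, body_aspect=1.0,
        )
        clip = render_call(spec, small_config, seed=1)
        out = tempo_harmonics(clip, TEST_FRAMES)
        assert out["harmonic_ratio"] > 0.2

    def test_sub_second_clip_rejected(self):
        with pytest.raises(InvalidInputError):
            tempo_harmonics(AudioClip(np.ones(TEST_SR // 2), TEST_SR))


class TestSummarize:
    def test_constant_feature(self):
        table = summarize({"x": np.full(10, 3.5)})
        assert table.features["x_mean"] == pytest.approx(3.5)
        assert table.features["x_std"] == 0.0

    def test_single_frame_population_std(self):
        table = summarize({"x": np.array([2.0])})
        assert table.features["x_std"] == 0.0

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(50, 3))
        table = summarize({"v": values})
        for j in range(3):
            col = values[:, j]
            mean = col.sum() / col.size
            std = np.sqrt(((col - mean) ** 2).sum() / col.size)
            assert table.features[f"v{j + 1:02d}_mean"] == pytest.approx(mean, abs=1e-10)
            assert table.features[f"v{j + 1:02d}_std"] == pytest.approx(std, abs=1e-10)


class TestFeatureSets:
    def test_set_sizes(self, call_clip):
        table = extract_clip_features(call_clip, "sp", TEST_FRAMES)
        assert build_feature_set(table, "SET1").size == 10
        assert build_feature_set(table, "SET2").size == 2 + 24 + 78
        assert build_feature_set(table, "SET3").size == 26

    def test_set4_needs_selection_and_has_21(self, call_clip):
        table = extract_clip_features(call_clip, "sp", TEST_FRAMES)
        names = table.names[:21]
        sel = SelectionResult(ranked=tuple(names), k=21)
        assert build_feature_set(table, "SET4", sel).size == 21
        with pytest.raises(InvalidInputError):
            build_feature_set(table, "SET4")

    def test_unknown_set_id(self, call_clip):
        table = extract_clip_features(call_clip, "sp", TEST_FRAMES)
        with pytest.raises(SchemaError):
            build_feature_set(table, "SET9")

    def test_missing_member_named(self):
        table = FeatureTable(features={"a_mean": 1.0}, label="x")
        with pytest.raises(SchemaError, match="centroid_mean"):
            build_feature_set(table, "SET1")

    def test_extra_feature_hook(self, call_clip):
        table = extract_clip_features(
            call_clip, "sp", TEST_FRAMES, extra_features=lambda c: {"custom": 1.5}
        )
        assert table.features["custom"] == 1.5

    def test_all_features_finite_even_for_silence(self):
        silent = AudioClip(np.zeros(2 * TEST_SR), TEST_SR)
        table = extract_clip_features(silent, "quiet", TEST_FRAMES)
        assert all(np.isfinite(v) for v in table.features.values())

    def test_csv_round_trip(self, call_clip, tmp_path):
        t1 = extract_clip_features(call_clip, "sp1", TEST_FRAMES)
        t2 = extract_clip_features(call_clip, "sp2", TEST_FRAMES)
        path = tmp_path / "features.csv"
        write_feature_csv([t1, t2], path)
        back = read_feature_csv(path)
        assert back[0].names == t1.names
        assert back[1].label == "sp2"
        for name in t1.names:
            assert back[0].features[name] == t1.features[name]

    def test_set1_members_documented_order(self):
        members = feature_set_members("SET1")
        assert members[0] == "centroid_mean" and members[-1] == "zcr_std"


@settings(max_examples=25, deadline=None)
@given(
    st.lists(st.floats(min_value=0.1, max_value=100.0), min_size=26, max_size=26),
    st.integers(min_value=1, max_value=13),
)
def test_cosine_transform_matches_direct_sum(energies, m):
    """Property: vectorized midpoint DCT equals the literal summation."""
    e = np.array(energies)
    out = cosine_transform(e, 13)[0]
    expected = sum(
        e[n - 1] * np.cos(m * (n - 0.5) * np.pi / 26) for n in range(1, 27)
    )
    assert out[m - 1] == pytest.approx(expected, abs=1e-8)
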