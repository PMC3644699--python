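"""Streaming filters, referencing, spectra, decimation, and peak mixing."""

import numpy as np
import pytest

from ephyskit.dsp import (
    EEG_BANDS,
    LFP_SPEC,
    SPIKE_SPEC,
    BandpassFilter,
    ConsecutiveAverageFilter,
    FilterSpec,
    NotchFilter,
    ReferenceGroups,
    SampleBlock,
    audio_peak_mix,
    band_power,
    chunk_signal,
    common_average_reference,
    concat_blocks,
    decimate_minmax,
    short_term_spectrum,
)

FS = 25_000.0


def _uneven_chunks(data, fs, seed=0):
    """Split into 7 uneven chunks for block-invariance checks."""
    rng = np.random.default_rng(seed)
    n = data.shape[1]
    cuts = np.sort(rng.choice(np.arange(1, n), size=6, replace=False))
    blocks, start = [], 0
    for c in [*cuts, n]:
        blocks.append(SampleBlock(data[:, start:c], fs, start))
        start = c
    return blocks


class TestFilterSpec:
    def test_band_edges_validated(self):
        with pytest.raises(ValueError):
            FilterSpec(low=500, high=300)
        with pytest.raises(ValueError):
            FilterSpec()
        with pytest.raises(ValueError):
            FilterSpec(low=300, high=20_000).validate_for_fs(FS)

    def test_default_bands(self):
        assert LFP_SPEC.kind == "lowpass" and LFP_SPEC.high == 300
        assert SPIKE_SPEC.low == 300 and SPIKE_SPEC.high == 6000


class TestBandpass:
    def test_dc_rejected_by_spike_band(self):
        x = np.full((1, int(FS)), 50.0)
        f = BandpassFilter(SPIKE_SPEC, FS)
        out = f.process(SampleBlock(x, FS)).data
        assert np.max(np.abs(out[:, -1000:])) < 1e-3

    def test_in_band_tone_passes_at_unit_gain(self):
        t = np.arange(int(2 * FS)) / FS
        x = np.sin(2 * np.pi * 1000 * t)[None, :]
        out = BandpassFilter(SPIKE_SPEC, FS).process(SampleBlock(x, FS)).data
        steady = out[0, int(FS):]
        amp = (steady.max() - steady.min()) / 2
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_block_split_invariance(self, rng):
        x = rng.normal(size=(3, 4000))
        full = BandpassFilter(SPIKE_SPEC, FS).process(SampleBlock(x, FS)).data
        f = BandpassFilter(SPIKE_SPEC, FS)
        parts = np.concatenate(
            [f.process(b).data for b in _uneven_chunks(x, FS)], axis=1
        )
        assert np.max(np.abs(parts - full)) < 1e-9

    def test_band_power_split_on_white_noise(self, rng):
        # LFP and spike band partition the power of white noise according
        # to their bandwidths (checked against periodogram integration)
        x = rng.normal(size=(1, int(8 * FS)))
        lfp = BandpassFilter(LFP_SPEC, FS).process(SampleBlock(x, FS)).data
        spk = BandpassFilter(SPIKE_SPEC, FS).process(SampleBlock(x, FS)).data
        nyq = FS / 2
        assert np.var(lfp) / np.var(x) == pytest.approx(300 / nyq, rel=0.10)
        assert np.var(spk) / np.var(x) == pytest.approx(5700 / nyq, rel=0.10)


class TestNotch:
    def test_line_tone_attenuated_30db(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 60 * t)[None, :]
        out = NotchFilter(60, FS).process(SampleBlock(x, FS)).data
        tail = slice(int(2 * FS), None)
        drop = 20 * np.log10(
            np.sqrt(np.mean(x[:, tail] ** 2)) / np.sqrt(np.mean(out[:, tail] ** 2))
        )
        assert drop >= 30

    def test_passband_tone_within_1db(self):
        t = np.arange(int(2 * FS)) / FS
        x = np.sin(2 * np.pi * 1000 * t)[None, :]
        out = NotchFilter(60, FS).process(SampleBlock(x, FS)).data
        tail = slice(int(FS), None)
        change = 20 * np.log10(
            np.sqrt(np.mean(out[:, tail] ** 2)) / np.sqrt(np.mean(x[:, tail] ** 2))
        )
        assert abs(change) <= 1

    def test_zero_input_zero_output(self):
        out = NotchFilter(50, FS).process(SampleBlock(np.zeros((2, 500)), FS))
        assert np.all(out.data == 0)

    def test_nonstandard_frequency_warns(self):
        with pytest.warns(UserWarning):
            NotchFilter(180, FS)

    def test_block_split_invariance(self, rng):
        x = rng.normal(size=(2, 3000))
        full = NotchFilter(60, FS).process(SampleBlock(x, FS)).data
        f = NotchFilter(60, FS)
        parts = np.concatenate(
            [f.process(b).data for b in _uneven_chunks(x, FS)], axis=1
        )
        assert np.max(np.abs(parts - full)) < 1e-9


class TestConsecutiveAverage:
    def test_periodic_sawtooth_removed(self):
        period, n_periods = 100, 5
        x = np.tile(np.linspace(-50, 50, period), 60)[None, :]
        f = ConsecutiveAverageFilter(period, n_periods, 1)
        out = f.process(SampleBlock(x, 1000.0)).data
        warm = n_periods * period
        residual = np.sqrt(np.mean(out[:, warm:] ** 2))
        assert residual < 0.01 * np.sqrt(np.mean(x[:, warm:] ** 2))

    def test_white_noise_variance_inflation_bounded(self, rng):
        # subtracting the mean of n independent periods adds var/n
        n_periods = 10
        x = rng.normal(size=(1, 40_000))
        f = ConsecutiveAverageFilter(50, n_periods, 1)
        out = f.process(SampleBlock(x, 1000.0)).data
        warm = n_periods * 50
        ratio = np.var(out[:, warm:]) / np.var(x[:, warm:])
        assert 1.0 <= ratio <= 1.0 + 2 / n_periods

    def test_zero_input_zero_output(self):
        f = ConsecutiveAverageFilter(10, 3, 2)
        out = f.process(SampleBlock(np.zeros((2, 300)), 1000.0))
        assert np.all(out.data == 0)

    def test_block_split_invariance(self, rng):
        x = np.tile(np.linspace(0, 10, 25), 40)[None, :] + rng.normal(size=(1, 1000))
        full = ConsecutiveAverageFilter(25, 4, 1).process(SampleBlock(x, 1000.0)).data
        f = ConsecutiveAverageFilter(25, 4, 1)
        parts = np.concatenate(
            [f.process(b).data for b in _uneven_chunks(x, 1000.0)], axis=1
        )
        assert np.max(np.abs(parts - full)) < 1e-9

    def test_fractional_period_suppresses_hum(self):
        # 60 Hz at 31.25 kHz: period 520.8333 samples is not an integer
        fs, f_line = 31_250.0, 60.0
        t = np.arange(int(2 * fs)) / fs
        x = (40 * np.sin(2 * np.pi * f_line * t))[None, :]
        f = ConsecutiveAverageFilter(fs / f_line, 8, 1)
        out = f.process(SampleBlock(x, fs)).data
        tail = slice(int(1.5 * fs), None)
        assert np.sqrt(np.mean(out[:, tail] ** 2)) < 0.1 * np.sqrt(
            np.mean(x[:, tail] ** 2)
        )

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            ConsecutiveAverageFilter(1, 5, 1)
        with pytest.raises(ValueError):
            ConsecutiveAverageFilter(10, 1, 1)


class TestCommonAverageReference:
    def test_all_to_all_forces_zero_mean(self, rng):
        x = rng.normal(size=(8, 200)) + 50
        out = common_average_reference(
            SampleBlock(x, FS), ReferenceGroups.all_to_all(8)
        )
        assert np.max(np.abs(out.data.mean(axis=0))) < 1e-12

    def test_identical_channels_cancel_to_zero(self):
        x = np.tile(np.sin(np.arange(300)), (4, 1))
        out = common_average_reference(
            SampleBlock(x, FS), ReferenceGroups.all_to_all(4)
        )
        assert np.max(np.abs(out.data)) < 1e-12

    def test_subset_reference_hand_arithmetic(self):
        # targets {0,1} referenced to {2,3}: mean(4, 6) = 5 subtracted
        x = np.array([[10.0], [20.0], [4.0], [6.0]])
        groups = ReferenceGroups.from_pairs([((0, 1), (2, 3))])
        out = common_average_reference(SampleBlock(x, FS), groups).data
        assert out[:, 0] == pytest.approx([5.0, 15.0, 4.0, 6.0])

    def test_idempotent_for_all_channels_group(self, rng):
        x = rng.normal(size=(6, 100))
        g = ReferenceGroups.all_to_all(6)
        once = common_average_reference(SampleBlock(x, FS), g)
        twice = common_average_reference(once, g)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            common_average_reference(
                SampleBlock(np.zeros((2, 10)), FS),
                ReferenceGroups.from_pairs([((0,), ())]),
            )


class TestShortTermSpectrum:
    def test_tone_peaks_in_correct_bin_every_frame(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 10 * t)
        times, freqs, power = short_term_spectrum(x, fs, window=500, overlap=0.5)
        peak_bins = freqs[np.argmax(power, axis=1)]
        assert np.all(np.abs(peak_bins - 10.0) <= freqs[1] - freqs[0])

    def test_zero_input_all_zero(self):
        _, _, power = short_term_spectrum(np.zeros(2000), 1000.0, window=256)
        assert np.all(power == 0)

    def test_parseval_on_white_noise(self, rng):
        fs = 1000.0
        x = rng.normal(size=int(20 * fs))
        _, freqs, power = short_term_spectrum(x, fs, window=512, overlap=0.5)
        df = freqs[1] - freqs[0]
        frame_power = power.sum(axis=1) * df
        assert np.mean(frame_power) == pytest.approx(np.var(x), rel=0.10)

    def test_band_summary_isolates_alpha_tone(self):
        fs = 500.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * 10 * t)
        _, freqs, power = short_term_spectrum(x, fs, window=500, overlap=0.5)
        bp = band_power(freqs, power, EEG_BANDS)
        total = sum(v.mean() for v in bp.values())
        assert bp["alpha"].mean() / total > 0.95

    def test_window_longer_than_data_rejected(self):
        with pytest.raises(ValueError):
            short_term_spectrum(np.zeros(100), 1000.0, window=200)


class TestDecimateMinmax:
    def test_one_bucket_per_sample_is_identity(self, rng):
        x = rng.normal(size=64)
        mins, maxs = decimate_minmax(x, 64)
        assert np.array_equal(mins, x) and np.array_equal(maxs, x)

    def test_lone_spike_survives_decimation(self):
        x = np.zeros(10_000)
        x[6173] = -80.0
        mins, _ = decimate_minmax(x, 100)
        assert mins.min() == -80.0

    def test_monotone_ramp_bucket_endpoints(self):
        x = np.arange(16.0)
        mins, maxs = decimate_minmax(x, 4)
        assert np.array_equal(mins, [0, 4, 8, 12])
        assert np.array_equal(maxs, [3, 7, 11, 15])

    def test_matches_brute_force(self, rng):
        x = rng.normal(size=1037)
        n_buckets = 31
        mins, maxs = decimate_minmax(x, n_buckets)
        size = int(np.ceil(x.size / n_buckets))
        for i in range(len(mins)):
            seg = x[i * size : (i + 1) * size]
            assert mins[i] == seg.min() and maxs[i] == seg.max()

    def test_invalid_bucket_counts(self):
        with pytest.raises(ValueError):
            decimate_minmax(np.zeros(10), 0)
        with pytest.raises(ValueError):
            decimate_minmax(np.zeros(10), 11)


class TestAudioPeakMix:
    def test_single_channel_is_identity(self, rng):
        x = rng.normal(size=(3, 50))
        out = audio_peak_mix(SampleBlock(x, FS), [1])
        assert np.array_equal(out, x[1])

    def test_spike_not_averaged_out(self):
        x = np.zeros((2, 100))
        x[1, 40:43] = [-40.0, -80.0, -30.0]
        out = audio_peak_mix(SampleBlock(x, FS), [0, 1])
        assert out[41] == -80.0  # a mean mix would halve this

    def test_sign_preserved_at_largest_magnitude(self):
        x = np.array([[5.0], [-7.0]])
        out = audio_peak_mix(SampleBlock(x, FS), [0, 1])
        assert out[0] == -7.0

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            audio_peak_mix(SampleBlock(np.zeros((2, 10)), FS), [])


class TestChunking:
    def test_chunk_concat_roundtrip(self, rng):
        x = rng.normal(size=(4, 997))
        blocks = list(chunk_signal(x, FS, 100))
        assert blocks[-1].n_samples == 97
        assert [b.start_index for b in blocks][:3] == [0, 100, 200]
        back = concat_blocks(blocks)
        assert np.array_equal(back.data, x)
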