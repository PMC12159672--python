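"""Index formula oracles, analytic cases and invariances.

The brute-force oracles below re-evaluate each index definition with
plain loops on tiny hand-built matrices, independently of the library
implementation.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoacoustics.audio import AudioClip, MeanSpectrum, Spectrogram, bandpass_filter
from phenoacoustics.indices import (
    IndexScaler,
    band_occupancy,
    compute_aci,
    compute_bi,
    compute_h,
    compute_indices,
    compute_np,
    spectral_entropy,
    temporal_entropy,
)

SR = 22050.0


def brute_aci(amp, sums_per_chunk):
    """Loop evaluation of sum over bins/chunks of sum|diff| / sum."""
    total = 0.0
    for row in amp:
        for chunk in sums_per_chunk:
            block = row[chunk]
            s = sum(block)
            if s > 0 and len(block) >= 2:
                d = sum(abs(block[k] - block[k + 1]) for k in range(len(block) - 1))
                total += d / s
    return total


def brute_entropy(p):
    return -sum(x * math.log(x) for x in p if x > 0)


class TestACI:
    def test_hand_example_single_bin(self):
        spec = Spectrogram(
            np.array([[1.0, 2.0, 1.0, 2.0]]), np.array([5000.0]),
            np.arange(4) * 1.0, 512,
        )
        assert compute_aci(spec, 4000, 6000, chunk=100) == pytest.approx(0.5)

    def test_matches_brute_force_on_small_matrix(self):
        rng = np.random.default_rng(5)
        amp = rng.uniform(0, 3, (5, 8))
        freqs = np.linspace(3000, 9000, 5)
        spec = Spectrogram(amp, freqs, np.arange(8) * 1.0, 512)
        got = compute_aci(spec, 2000, 10000, chunk=100)
        want = brute_aci(amp, [slice(0, 8)])
        assert got == pytest.approx(want, abs=1e-9)

    def test_chunking_matches_brute_force(self):
        rng = np.random.default_rng(6)
        amp = rng.uniform(0, 3, (3, 8))
        spec = Spectrogram(
            amp, np.linspace(4000, 6000, 3), np.arange(8) * 1.0, 512
        )
        got = compute_aci(spec, 3000, 7000, chunk=4.0)
        want = brute_aci(amp, [slice(0, 4), slice(4, 8)])
        assert got == pytest.approx(want, abs=1e-9)

    def test_constant_intensities_give_zero(self):
        spec = Spectrogram(
            np.full((4, 8), 2.0), np.linspace(3000, 9000, 4), np.arange(8) * 1.0, 512
        )
        assert compute_aci(spec) == 0.0

    def test_gain_invariance(self):
        rng = np.random.default_rng(7)
        amp = rng.uniform(0, 1, (4, 8))
        freqs = np.linspace(3000, 9000, 4)
        s1 = Spectrogram(amp, freqs, np.arange(8) * 1.0, 512)
        s2 = Spectrogram(amp * 2, freqs, np.arange(8) * 1.0, 512)
        assert compute_aci(s1) == pytest.approx(compute_aci(s2), rel=1e-12)

    def test_empty_band_rejected(self):
        spec = Spectrogram(
            np.ones((2, 4)), np.array([100.0, 200.0]), np.arange(4) * 1.0, 512
        )
        with pytest.raises(ValueError):
            compute_aci(spec, 3000, 10000)


class TestADI:
    def occupancy_entropy(self, occ):
        total = sum(occ)
        if total == 0:
            return 0.0
        return brute_entropy([o / total for o in occ])

    def test_single_band_occupancy_zero(self):
        assert self.occupancy_entropy([0.4, 0, 0, 0]) == 0.0

    def test_two_equal_bands_ln2(self):
        assert self.occupancy_entropy([0.3, 0.3] + [0] * 8) == pytest.approx(
            math.log(2)
        )

    def test_band_occupancy_matches_brute_force(self):
        rng = np.random.default_rng(8)
        amp = rng.uniform(0, 1, (5, 8))
        freqs = np.array([500.0, 1500.0, 2500.0, 3500.0, 4500.0])
        spec = Spectrogram(amp, freqs, np.arange(8) * 1.0, 512)
        occ = band_occupancy(spec, max_freq=5000, db_threshold=-10)
        peak = amp.max()
        for i in range(5):
            cells = amp[i]  # one bin per 1 kHz band here
            want = np.mean(20 * np.log10(cells / peak) > -10)
            assert occ[i] == pytest.approx(want)

    def test_equal_occupancy_all_bands_max_entropy(self):
        # a clip with uniform noise across 0-10 kHz: occupancy equalizes
        rng = np.random.default_rng(9)
        clip = AudioClip(0.5 * np.clip(rng.standard_normal(int(SR)), -3, 3) / 3, SR)
        occ = band_occupancy(
            __import__("phenoacoustics.audio", fromlist=["compute_spectrogram"])
            .compute_spectrogram(clip),
            max_freq=10000,
            db_threshold=-50,
        )
        p = occ / occ.sum()
        assert brute_entropy(p) == pytest.approx(math.log(10), rel=0.01)


class TestBI:
    def test_flat_spectrum_zero(self):
        amp = np.full((4, 3), 0.5)
        spec = Spectrogram(amp, np.linspace(3000, 9000, 4), np.arange(3) * 1.0, 512)
        assert compute_bi(spec) == pytest.approx(0.0, abs=1e-9)

    def test_two_bin_hand_example(self):
        amp = np.array([[10 ** (-10 / 20)], [10 ** (-20 / 20)]])
        spec = Spectrogram(amp, np.array([5000.0, 5086.0]), np.array([0.0]), 512)
        assert compute_bi(spec, 4000, 6000) == pytest.approx(10 * 0.086, rel=1e-6)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(10)
        amp = rng.uniform(0.1, 1.0, (5, 8))
        freqs = np.linspace(3000, 9000, 5)
        spec = Spectrogram(amp, freqs, np.arange(8) * 1.0, 512)
        mean_amp = [sum(row) / len(row) for row in amp]
        db = [20 * math.log10(m) for m in mean_amp]
        width = (freqs[1] - freqs[0]) / 1000
        want = sum((d - min(db)) * width for d in db)
        assert compute_bi(spec, 2000, 10000) == pytest.approx(want, abs=1e-9)

    def test_gain_translation_invariance(self):
        rng = np.random.default_rng(11)
        amp = rng.uniform(0.1, 1.0, (5, 4))
        freqs = np.linspace(3000, 9000, 5)
        s1 = Spectrogram(amp, freqs, np.arange(4) * 1.0, 512)
        s2 = Spectrogram(amp * 3.5, freqs, np.arange(4) * 1.0, 512)
        assert compute_bi(s1) == pytest.approx(compute_bi(s2), abs=1e-9)


class TestH:
    def test_flat_pmfs_give_one(self):
        ms = MeanSpectrum(np.linspace(0, 10000, 8), np.full(8, 1.0))
        assert spectral_entropy(ms) == pytest.approx(1.0)
        assert temporal_entropy(np.full(100, 0.3)) == pytest.approx(1.0)

    def test_point_mass_spectrum_gives_zero(self):
        amp = np.zeros(8)
        amp[3] = 1.0
        ms = MeanSpectrum(np.linspace(0, 10000, 8), amp)
        assert spectral_entropy(ms) == 0.0

    def test_two_bin_base_independence(self):
        ms = MeanSpectrum(np.array([0.0, 1.0]), np.array([0.5, 0.5]))
        assert spectral_entropy(ms) == pytest.approx(1.0)

    def test_matches_brute_force_product(self):
        rng = np.random.default_rng(12)
        amp = rng.uniform(0, 1, 8)
        env = rng.uniform(0, 1, 16)
        ms = MeanSpectrum(np.linspace(0, 10000, 8), amp)
        hf = brute_entropy(amp / amp.sum()) / math.log(8)
        ht = brute_entropy(env / env.sum()) / math.log(16)
        assert spectral_entropy(ms) == pytest.approx(hf, abs=1e-9)
        assert temporal_entropy(env) == pytest.approx(ht, abs=1e-9)

    def test_tone_has_low_h_noise_has_high_h(self):
        rng = np.random.default_rng(13)
        t = np.arange(int(SR * 2)) / SR
        tone = bandpass_filter(
            AudioClip(0.5 * np.sin(2 * np.pi * 5000 * t), SR)
        )
        noise = bandpass_filter(
            AudioClip(0.2 * np.clip(rng.standard_normal(t.size), -3, 3), SR)
        )
        assert compute_h(tone) < 0.5 < compute_h(noise)


class TestNP:
    def test_monotone_spectrum_no_peaks(self):
        ms = MeanSpectrum(np.linspace(0, 11000, 50), np.linspace(0.01, 1.0, 50))
        assert compute_np(ms) == 0

    def test_three_tones_counted(self):
        rng = np.random.default_rng(14)
        t = np.arange(int(SR * 2)) / SR
        x = sum(0.25 * np.sin(2 * np.pi * f * t) for f in (4000, 6000, 8000))
        x = x + 0.001 * rng.standard_normal(t.size)
        from phenoacoustics.audio import mean_spectrum

        ms = mean_spectrum(AudioClip(x / np.max(np.abs(x)) * 0.9, SR))
        assert compute_np(ms) == 3

    def test_peak_outside_count_band_ignored(self):
        t = np.arange(int(SR * 2)) / SR
        from phenoacoustics.audio import mean_spectrum

        ms = mean_spectrum(AudioClip(0.5 * np.sin(2 * np.pi * 2000 * t), SR))
        assert compute_np(ms) == 0

    def test_silent_spectrum_zero(self):
        ms = MeanSpectrum(np.linspace(0, 11000, 20), np.zeros(20))
        assert compute_np(ms) == 0


class TestScaler:
    def test_endpoints_and_midpoint(self):
        df = pd.DataFrame({"aci": [0.0, 5.0, 10.0]})
        scaled = IndexScaler().fit(df).transform(df)
        assert scaled["aci"].iloc[0] == pytest.approx(0.0001)
        assert scaled["aci"].iloc[1] == pytest.approx(0.5)
        assert scaled["aci"].iloc[2] == pytest.approx(0.9999)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=3,
            max_size=30,
        )
    )
    def test_round_trip_recovers_raw(self, values):
        arr = np.array(values)[:, None]
        if np.ptp(arr) <= 1e-6 * (1 + np.max(np.abs(arr))):
            return
        scaler = IndexScaler().fit(arr)
        back = scaler.inverse_transform(scaler.transform(arr))
        assert np.allclose(back, arr, rtol=1e-10, atol=1e-10 * (1 + np.ptp(arr)))

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            IndexScaler().fit(np.ones((5, 2)))

    def test_transform_reusable_on_new_data(self):
        train = np.array([[0.0], [10.0]])
        scaler = IndexScaler().fit(train)
        out = scaler.transform(np.array([[20.0]]))
        assert out[0, 0] == pytest.approx(0.0001 + 2 * 0.9998)


class TestPipelineIndices:
    def test_silent_clip_flagged(self):
        clip = AudioClip(np.zeros(int(SR)) + 1e-7, SR, clip_id="quiet")
        iv = compute_indices(clip)
        assert iv.silent

    def test_discrimination_bi_high_vs_low_coverage(self, library):
        """BI separates busy from empty soundscapes (strong-predictor check)."""
        from datetime import datetime

        from phenoacoustics.synth import ActivityModel, simulate_clip

        rows = []
        for i in range(12):
            for baseline in (3.0, -3.0):
                clip, truth = simulate_clip(
                    datetime(2018, 9, 1, 23, 0), "T1", library,
                    ActivityModel(baseline=baseline),
                    seed=[100 + i, int(baseline > 0)],
                    duration=15.0, sample_rate=SR,
                )
                iv = compute_indices(clip)
                rows.append((truth.coverage, iv.bi))
        df = pd.DataFrame(rows, columns=["coverage", "bi"])
        hi = df.loc[df["coverage"] >= 0.6, "bi"]
        lo = df.loc[df["coverage"] <= 0.2, "bi"]
        assert len(hi) >= 5 and len(lo) >= 5
        assert hi.mean() > lo.mean()
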