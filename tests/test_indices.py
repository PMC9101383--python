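"""Closed forms, ranges and oracle checks for the eco-acoustic indices."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from soundscapemap.audio import AudioClip, SpectrogramParams, compute_spectrogram
from soundscapemap.indices import (ALL_INDICES, FIVE_INDEX_SET, IndexConfig,
                                   IndexSeries, aci, adi, aei, band_occupancy,
                                   bi, compute_all, dsc, entropy_h, ndsi)
from soundscapemap.synth import synth_chirps, synth_traffic, white_noise_clip

from conftest import make_block


def white_block(seed, seconds=1.0):
    clip = white_noise_clip(duration=seconds, seed=seed)
    from soundscapemap.audio import band_mask, tile_windows
    spec = band_mask(compute_spectrogram(clip), 100, 24000)
    return tile_windows(spec, 1.0)[0]


class TestACI:
    def test_constant_columns_give_zero(self):
        block = make_block(np.tile([[1.0], [2.0], [3.0]], 5))
        assert aci(block) == 0.0

    def test_hand_computed_single_bin(self):
        # amplitudes [1, 3, 1]: (|3-1| + |1-3|) / (1+3+1) = 0.8
        block = make_block([[1.0, 3.0, 1.0]])
        assert aci(block) == pytest.approx(0.8)

    def test_zero_bins_contribute_nothing(self):
        block = make_block([[1.0, 3.0, 1.0], [0.0, 0.0, 0.0]])
        assert aci(block) == pytest.approx(0.8)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            aci(make_block([[1.0], [2.0]]))

    def test_white_noise_stable_across_seeds(self):
        vals = [aci(white_block(s)) for s in range(20)]
        vals = np.array(vals)
        assert np.all(vals > 0)
        assert vals.std() / vals.mean() < 0.05


class TestBandOccupancyADIAEI:
    def test_uniform_strong_signal_saturates(self):
        block = make_block(np.ones((513, 10)))
        p = band_occupancy(block, IndexConfig())
        assert np.all(p == 1.0)

    def test_tone_confined_to_one_band(self):
        A = np.zeros((513, 10))
        A[100, :] = 1.0  # 4687.5 Hz -> 5th 1-kHz band (index 4)
        p = band_occupancy(block := make_block(A), IndexConfig())
        assert p[4] > 0
        assert np.all(np.delete(p, 4) == 0)

    def test_half_band_above_threshold(self):
        # construct 1 band of 2 bins x 2 frames, half the cells above -50 dB
        A = np.array([[1.0, 1.0], [1e-4, 1e-4]])
        blk = make_block(A, window_len=96, f0=0.0)  # FR = 500 -> one 1-kHz band
        p = band_occupancy(blk, IndexConfig())
        assert p[0] == pytest.approx(0.5)

    def test_adi_extremes_and_hand_value(self):
        assert adi(np.ones(8)) == pytest.approx(np.log(8))
        assert adi(np.array([0, 0, 0.7, 0])) == 0.0  # single band -> no entropy
        assert adi(np.array([0.75, 0.25])) == pytest.approx(0.5623, abs=1e-4)
        assert adi(np.zeros(5)) == 0.0

    def test_adi_rejects_negative(self):
        with pytest.raises(ValueError):
            adi(np.array([0.5, -0.1]))

    def test_aei_closed_forms(self):
        assert aei(np.ones(6)) == 0.0
        one_of_ten = np.zeros(10)
        one_of_ten[3] = 0.8
        assert aei(one_of_ten) == pytest.approx(0.9)  # (n-1)/n
        assert aei(np.array([0.5, 0.5, 0.0, 0.0])) == pytest.approx(0.5)
        assert aei(np.zeros(4)) == 0.0

    def test_adi_aei_anticorrelated_across_scenes(self):
        # 50 scenes sweeping chirp rate over a traffic bed
        adis, aeis = [], []
        from soundscapemap.audio import band_mask, tile_windows
        for i, rate in enumerate(np.linspace(0, 120, 50)):
            mix = synth_traffic(2.0, -30, seed=500 + i).samples
            mix = mix + synth_chirps(2.0, rate, seed=600 + i).samples
            spec = band_mask(compute_spectrogram(AudioClip(mix, 48000.0)),
                             100, 24000)
            blk = tile_windows(spec, 1.0)[0]
            p = band_occupancy(blk, IndexConfig())
            adis.append(adi(p))
            aeis.append(aei(p))
        rho = spearmanr(adis, aeis).statistic
        assert rho < -0.8


class TestEntropyH:
    def test_white_noise_near_one(self):
        vals = [entropy_h(white_block(s))[0] for s in range(20)]
        assert min(vals) > 0.95

    def test_pure_tone_near_zero(self):
        rate = 48000.0
        t = np.arange(int(rate)) / rate
        clip = AudioClip(np.sin(2 * np.pi * 4687.5 * t), rate)
        from soundscapemap.audio import band_mask, tile_windows
        spec = band_mask(compute_spectrogram(
            clip, SpectrogramParams(window_fn="rectangular")), 100, 24000)
        h, flag = entropy_h(tile_windows(spec, 1.0)[0])
        assert not flag
        assert h < 0.1

    def test_flat_two_frame_block_gives_hf(self):
        A = np.ones((4, 2))
        h, _ = entropy_h(make_block(A))
        assert h == pytest.approx(1.0)  # Ht = Hf = 1

    def test_silent_block_degenerate(self):
        h, flag = entropy_h(make_block(np.zeros((4, 4))))
        assert h == 0.0 and flag

    def test_in_unit_interval_on_random_blocks(self, rng):
        for _ in range(200):
            A = rng.uniform(0, 1, size=(8, 5)) * rng.integers(0, 2, size=(8, 5))
            h, _ = entropy_h(make_block(A))
            assert 0.0 <= h <= 1.0 + 1e-12


class TestBI:
    def test_flat_band_gives_zero(self):
        A = np.ones((513, 4))
        assert bi(make_block(A), IndexConfig()) == pytest.approx(0.0)

    def test_two_bin_hand_value(self):
        # band holds 2 bins at dB [10, 6] re band min -> (4+0) * FR/1000
        cfg = IndexConfig(bi_band=(1000.0, 1100.0))
        A = np.full((513, 2), 1e-6)
        fr = 46.875
        rows = [int(np.ceil(1000 / fr)), int(np.ceil(1000 / fr)) + 1]
        A[rows[0], :] = 10 ** (10 / 20)
        A[rows[1], :] = 10 ** (6 / 20)
        val = bi(make_block(A), cfg)
        assert val == pytest.approx(4 * fr / 1000, abs=1e-6)

    def test_signal_outside_band_gives_zero(self):
        A = np.full((513, 3), 1e-9)
        A[2, :] = 1.0  # ~94 Hz, below the 1 kHz band edge
        assert bi(make_block(A), IndexConfig()) == pytest.approx(0.0, abs=1e-9)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            bi(make_block(np.ones((4, 3))), IndexConfig(bi_band=(1000.0, 8000.0)))


class TestNDSI:
    def test_pure_biophony(self):
        A = np.zeros((513, 4))
        A[43, :] = 1.0  # ~2 kHz, bio band
        v, flag = ndsi(make_block(A), IndexConfig())
        assert v == 1.0 and not flag

    def test_pure_technophony(self):
        A = np.zeros((513, 4))
        A[10, :] = 1.0  # ~469 Hz, anthro band
        v, _ = ndsi(make_block(A), IndexConfig())
        assert v == -1.0

    def test_three_to_one_power_ratio(self):
        A = np.zeros((513, 1))
        A[10, 0] = 1.0               # anthro power 1
        A[43, 0] = np.sqrt(3.0)      # bio power 3
        v, _ = ndsi(make_block(A), IndexConfig())
        assert v == pytest.approx(0.5)

    def test_silent_block_flagged(self):
        v, flag = ndsi(make_block(np.zeros((513, 2))), IndexConfig())
        assert v == 0.0 and flag

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError):
            IndexConfig(ndsi_anthro=(100.0, 2000.0), ndsi_bio=(1000.0, 8000.0))


class TestDSC:
    def test_bin_centred_tone(self):
        A = np.zeros((513, 4))
        k = round(2000 / 46.875)
        A[k, :] = 1.0
        v, flag = dsc(make_block(A))
        assert not flag
        assert v == pytest.approx(k * 46.875 / 1000, abs=0.047)

    def test_two_equal_tones_average(self):
        A = np.zeros((513, 4))
        for f in (1000, 3000):
            A[round(f / 46.875), :] = 1.0
        v, _ = dsc(make_block(A))
        assert v == pytest.approx(2.0, abs=0.05)

    def test_silence_degenerate(self):
        v, flag = dsc(make_block(np.zeros((8, 3))))
        assert v == 0.0 and flag

    def test_centroid_of_mean_spectrum_variant(self):
        A = np.zeros((513, 2))
        A[round(1000 / 46.875), 0] = 1.0
        A[round(3000 / 46.875), 1] = 1.0
        cfg = IndexConfig(dsc_aggregation="centroid_of_mean_spectrum")
        v, _ = dsc(make_block(A), cfg)
        assert v == pytest.approx(2.0, abs=0.05)


class TestComputeAll:
    def test_ten_second_clip_gives_ten_rows(self):
        clip = white_noise_clip(10.0, seed=5)
        series = compute_all(clip)
        assert len(series.values) == 10
        assert list(series.values.columns) == list(ALL_INDICES)

    def test_five_index_subset_drops_bi_ndsi(self):
        clip = white_noise_clip(2.0, seed=5)
        series = compute_all(clip, cfg=IndexConfig(index_set=FIVE_INDEX_SET))
        assert list(series.values.columns) == list(FIVE_INDEX_SET)
        assert "BI" not in series.values.columns

    def test_deterministic(self):
        clip = white_noise_clip(3.0, seed=9)
        a = compute_all(clip).values
        b = compute_all(clip).values
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_range_invariants_on_synthetic_scene(self):
        mix = synth_traffic(5.0, -25, seed=1).samples
        mix = mix + synth_chirps(5.0, 60, seed=2).samples
        series = compute_all(AudioClip(mix, 48000.0)).values
        assert (series["AEI"].between(0, 1)).all()
        assert (series["H"].between(0, 1)).all()
        assert (series["NDSI"].between(-1, 1)).all()
        for col in ("ACI", "ADI", "BI", "DSC"):
            assert (series[col] >= 0).all()

    def test_adding_chirps_never_decreases_adi_or_ndsi(self):
        # monotonicity over 10 replicate scenes at fixed seeds
        for s in range(10):
            base = synth_traffic(3.0, -25, seed=700 + s).samples
            chirps = synth_chirps(3.0, 80, seed=800 + s).samples
            plain = compute_all(AudioClip(base, 48000.0)).values
            mixed = compute_all(AudioClip(base + chirps, 48000.0)).values
            assert mixed["ADI"].mean() >= plain["ADI"].mean()
            assert mixed["NDSI"].mean() >= plain["NDSI"].mean()

    def test_series_csv_roundtrip(self, tmp_path):
        clip = white_noise_clip(2.0, seed=3)
        clip.site_id = "S01"
        series = compute_all(clip)
        p = tmp_path / "s.csv"
        series.to_csv(p)
        back = IndexSeries.from_csv(p)
        assert back.site_id == "S01"
        np.testing.assert_allclose(back.values.to_numpy(),
                                   series.values.to_numpy())


def test_micro_spectrogram_oracle_equivalence(rng):
    """adi/aei/aci on <= 4x4 integer matrices match exhaustive loops."""
    for _ in range(50):
        shape = (int(rng.integers(1, 5)), int(rng.integers(2, 5)))
        A = rng.integers(0, 4, size=shape).astype(float)
        blk = make_block(A)
        # brute-force ACI
        expect = 0.0
        for f in range(shape[0]):
            den = A[f].sum()
            if den > 0:
                expect += sum(abs(A[f, t + 1] - A[f, t])
                              for t in range(shape[1] - 1)) / den
        assert aci(blk) == pytest.approx(expect)
        # brute-force ADI / AEI on a random proportion vector
        p = rng.uniform(0, 1, size=int(rng.integers(1, 6)))
        s = p.sum()
        expect_adi = -sum(q / s * np.log(q / s) for q in p if q > 0)
        assert adi(p) == pytest.approx(expect_adi)
        n, mu = p.size, p.mean()
        expect_aei = sum(abs(a - b) for a in p for b in p) / (2 * n * n * mu)
        assert aei(p) == pytest.approx(expect_aei)
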