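"""Denoising, R-peak detection, segmentation, splitting and balancing."""

import numpy as np
import pytest

import ecgleads as eg
from ecgleads.core import BEAT_LEN, CLASS_NAMES
from ecgleads.preprocess import SignalTooShortError


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestDenoise:
    def test_zero_signal_stays_zero(self):
        assert np.abs(eg.denoise_dwt(np.zeros(4096))).max() == 0.0

    def test_empty_removal_set_is_perfect_reconstruction(self, rng):
        x = rng.normal(size=4096)
        r = eg.denoise_dwt(x, 500, remove_details=(), remove_approx=False)
        assert np.abs(r - x).max() / np.abs(x).max() < 1e-8

    def test_powerline_tone_suppressed_20db(self):
        # 50 Hz sits in the removed D3 band (31.25–62.5 Hz at fs=500)
        t = np.arange(4096) / 500.0
        x = np.sin(2 * np.pi * 50.0 * t)
        y = eg.denoise_dwt(x, 500)
        mid = slice(1024, 3072)
        atten_db = 20 * np.log10(rms(y[mid]) / rms(x[mid]) + 1e-12)
        assert atten_db <= -20.0

    def test_inband_tone_preserved_within_1db(self):
        # 10 Hz sits in retained D5 (7.8–15.6 Hz); central half avoids edges
        t = np.arange(4096) / 500.0
        x = np.sin(2 * np.pi * 10.0 * t)
        y = eg.denoise_dwt(x, 500)
        mid = slice(1024, 3072)
        assert abs(20 * np.log10(rms(y[mid]) / rms(x[mid]))) <= 1.0

    def test_too_short_signal_raises_named_error(self):
        with pytest.raises(SignalTooShortError, match="levels"):
            eg.denoise_dwt(np.zeros(100))

    def test_record_denoising_is_per_lead(self):
        spec = eg.SyntheticSpec(seed=0)
        rec, _ = eg.generate_record(spec, 5)
        clean = eg.denoise_record(rec)
        assert clean.signal.shape == rec.signal.shape
        ref = eg.denoise_dwt(rec.signal[3], rec.fs)
        np.testing.assert_allclose(clean.signal[3], ref)


class TestDetectRPeaks:
    def test_planted_beats_recovered_within_20ms(self):
        spec = eg.SyntheticSpec(seed=3)
        rec, truth = eg.generate_record(spec, 20)
        lead2 = eg.denoise_record(rec).signal[1]
        peaks = eg.detect_r_peaks(lead2, rec.fs).indices
        tol = int(0.020 * rec.fs)
        hits = sum(np.any(np.abs(peaks - t) <= tol) for t in truth)
        assert hits >= 19

    def test_flat_signal_yields_empty_list(self):
        assert len(eg.detect_r_peaks(np.zeros(2000), 500)) == 0

    def test_single_centered_beat_found(self):
        spec = eg.SyntheticSpec(seed=1)
        rec, truth = eg.generate_record(spec, 1)
        sig = np.pad(rec.signal, ((0, 0), (250, 250)))
        padded = eg.EcgRecord("X", sig, label="N")
        peaks = eg.detect_r_peaks(eg.denoise_record(padded).signal[1], 500)
        assert len(peaks) == 1
        assert abs(peaks.indices[0] - (truth[0] + 250)) <= 10

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            eg.detect_r_peaks(np.zeros(100), 500)


class TestSegmentBeats:
    def _record(self, T=3000, label="AF"):
        sig = np.arange(12 * T, dtype=float).reshape(12, T)
        return eg.EcgRecord("R1", sig, label=label)

    def test_interior_peak_slice_bounds(self):
        rec = self._record()
        bs = eg.segment_beats(rec, eg.RPeakList([1000], 500))
        assert bs.beats.shape == (1, 12, 325)
        np.testing.assert_allclose(bs.beats[0], rec.signal[:, 875:1200])

    def test_boundary_peaks_dropped(self):
        rec = self._record()
        bs = eg.segment_beats(rec, eg.RPeakList([100, 1000, 2990], 500))
        assert len(bs) == 1  # only r=1000 fits [r-125, r+199]

    def test_count_matches_boundary_enumeration(self):
        spec = eg.SyntheticSpec(seed=5)
        rec, truth = eg.generate_record(spec, 20)
        bs = eg.segment_beats(rec, eg.RPeakList(truth, rec.fs))
        expected = sum(
            1 for r in truth if r - 125 >= 0 and r + 199 <= rec.n_samples - 1
        )
        assert len(bs) == expected
        assert all(lbl == rec.label for lbl in bs.labels)

    def test_multi_label_record_rejected(self):
        rec = self._record(label="multi")
        with pytest.raises(ValueError, match="multi"):
            eg.segment_beats(rec, eg.RPeakList([1000], 500))

    def test_r_apex_at_index_125_on_synthetic_beats(self, small_dataset):
        # noise-free check of the fiducial contract on lead II
        spec = eg.SyntheticSpec(noise_sd=0.0, powerline_amp=0.0, seed=0,
                                n_beats_per_class=2)
        bs = eg.generate_dataset(spec)
        argmax = bs.beats[:, 1, :].argmax(axis=1)
        assert np.all(np.abs(argmax - 125) <= 10)
        assert bs.beats.shape[2] == BEAT_LEN


class TestSplitDataset:
    def test_eight_two_split_per_class(self):
        spec = eg.SyntheticSpec(n_beats_per_class=10, seed=0)
        bs = eg.generate_dataset(spec)
        tr, te = eg.split_dataset(bs, 0.8, seed=1)
        assert tr.class_counts() == {c: 8 for c in CLASS_NAMES}
        assert te.class_counts() == {c: 2 for c in CLASS_NAMES}

    def test_disjoint_and_exhaustive(self):
        spec = eg.SyntheticSpec(n_beats_per_class=7, seed=2)
        bs = eg.generate_dataset(spec)
        tr, te = eg.split_dataset(bs, 0.8, seed=3)
        assert len(tr) + len(te) == len(bs)
        ids = lambda s: {f"{p}:{l}" for p, l in zip(s.provenance, s.labels)}
        assert ids(tr) | ids(te) == ids(bs)
        assert not (ids(tr) & ids(te))

    def test_total_counts_for_nine_by_100(self):
        spec = eg.SyntheticSpec(n_beats_per_class=100, seed=0, n_classes=9)
        bs = eg.generate_dataset(spec)
        tr, te = eg.split_dataset(bs, 0.8, seed=0)
        assert (len(tr), len(te)) == (720, 180)

    def test_deterministic_under_seed(self):
        spec = eg.SyntheticSpec(n_beats_per_class=6, seed=4)
        bs = eg.generate_dataset(spec)
        tr1, _ = eg.split_dataset(bs, 0.8, seed=9)
        tr2, _ = eg.split_dataset(bs, 0.8, seed=9)
        np.testing.assert_array_equal(tr1.beats, tr2.beats)
        np.testing.assert_array_equal(tr1.provenance, tr2.provenance)

    def test_class_with_single_beat_rejected(self):
        spec = eg.SyntheticSpec(n_beats_per_class=1, seed=0)
        bs = eg.generate_dataset(spec)
        with pytest.raises(ValueError, match="fewer than 2"):
            eg.split_dataset(bs, 0.8, seed=0)


class TestBalance:
    def test_count_arithmetic_under_threshold(self):
        rule = eg.BalanceRule(8000, 3)
        out = eg.balanced_counts({"LBBB": 2356, "STE": 2733, "N": 13027}, rule)
        assert out == {"LBBB": 7068, "STE": 8199, "N": 13027}

    def test_beatset_duplication_block_order(self):
        spec = eg.SyntheticSpec(n_classes=2, n_beats_per_class=4, seed=0)
        bs = eg.generate_dataset(spec)
        out = eg.balance_training(bs, eg.BalanceRule(threshold=5, factor=3))
        assert len(out) == 24
        n_beats = out.beats[out.labels == "N"]
        np.testing.assert_array_equal(n_beats[:4], n_beats[4:8])
        np.testing.assert_array_equal(n_beats[:4], n_beats[8:12])

    def test_classes_at_threshold_unchanged(self):
        spec = eg.SyntheticSpec(n_classes=3, n_beats_per_class=5, seed=1)
        bs = eg.generate_dataset(spec)
        out = eg.balance_training(bs, eg.BalanceRule(threshold=5, factor=3))
        assert len(out) == len(bs)

    def test_total_conservation_identity(self):
        spec = eg.SyntheticSpec(n_classes=4, n_beats_per_class=6, seed=2)
        bs = eg.generate_dataset(spec)
        rule = eg.BalanceRule(threshold=7, factor=4)
        out = eg.balance_training(bs, rule)
        dup = sum(c for c in bs.class_counts().values() if 0 < c < rule.threshold)
        assert len(out) == len(bs) + (rule.factor - 1) * dup

    def test_test_split_rejected(self):
        spec = eg.SyntheticSpec(n_classes=2, n_beats_per_class=4, seed=0)
        bs = eg.generate_dataset(spec)
        _, te = eg.split_dataset(bs, 0.5, seed=0)
        with pytest.raises(ValueError, match="train"):
            eg.balance_training(te, eg.BalanceRule(5, 3))

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            eg.BalanceRule(8000, 0)
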