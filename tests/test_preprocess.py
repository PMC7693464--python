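"""Filtering, window arithmetic, baseline deltas and the 2-SD mask."""

import numpy as np
import pytest
from scipy import stats

from nirsclench.preprocess import (EpochDeltas, ParameterError, TimeCourse,
                                   WindowError, baseline_means, compute_deltas,
                                   extract_windows, lowpass_filter,
                                   mask_artifacts, preprocess_recording)
from nirsclench.synth import CohortConfig, generate_recording

FS = 10.0


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestLowpass:
    def test_dc_passes_unchanged(self):
        x = np.full((500, 3), 1.7)
        assert np.allclose(lowpass_filter(x, 0.2, FS), x, atol=1e-9)

    def test_cardiac_band_attenuated(self):
        t = np.arange(6000) / FS
        x = np.sin(2 * np.pi * 1.2 * t)[:, None]
        y = lowpass_filter(x, 0.2, FS)
        assert _rms(y) < 0.05 * _rms(x)

    def test_slow_band_preserved(self):
        t = np.arange(6000) / FS
        x = np.sin(2 * np.pi * 0.05 * t)[:, None]
        y = lowpass_filter(x, 0.2, FS)
        assert abs(_rms(y) - _rms(x)) < 0.05 * _rms(x)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            lowpass_filter(np.zeros((100, 1)), 5.0, FS)


class TestWindows:
    def test_window_arithmetic_from_events(self):
        tc = TimeCourse.from_events(300.0, 360.0)
        assert (tc.baseline_start, tc.baseline_end) == (230.0, 240.0)
        assert (tc.rest_start, tc.rest_end) == (240.0, 300.0)
        assert (tc.clench_start, tc.clench_end) == (305.0, 360.0)

    def test_sample_counts_100_600_550(self):
        rec = generate_recording(CohortConfig(seed=0), 0)
        tc = TimeCourse.from_events(rec.clench_onset_s, rec.clench_offset_s)
        segs = extract_windows(rec, tc)
        for sp in ("oxy", "deoxy"):
            assert segs[sp]["baseline"].shape == (100, 22)
            assert segs[sp]["rest"].shape == (600, 22)
            assert segs[sp]["clench"].shape == (550, 22)

    def test_too_short_recording_rejected(self):
        rec = generate_recording(CohortConfig(seed=0), 0)
        tc = TimeCourse.from_events(rec.clench_onset_s, rec.clench_offset_s + 120)
        with pytest.raises(WindowError):
            extract_windows(rec, tc)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(WindowError):
            TimeCourse(0, 10, 10, 70, 60, 120)


class TestBaselineAndDeltas:
    def test_constant_baseline(self):
        assert np.allclose(baseline_means(np.full((100, 22), 0.3)), 0.3)

    def test_ramp_baseline_is_midpoint(self):
        ramp = np.linspace(1.0, 2.0, 101)[:, None] * np.ones((1, 22))
        assert np.allclose(baseline_means(ramp), 1.5)

    def _segments(self, rest, clench, baseline):
        return {sp: {"baseline": baseline, "rest": rest, "clench": clench}
                for sp in ("oxy", "deoxy")}

    def test_delta_is_subtraction(self):
        base = np.full((100, 22), 0.10)
        rest = np.full((600, 22), 0.15)
        clench = np.full((550, 22), 0.10)
        ep = compute_deltas(self._segments(rest, clench, base),
                            {"oxy": baseline_means(base), "deoxy": baseline_means(base)})
        assert np.allclose(ep.deltas["oxy"]["rest"], 0.05)
        assert np.allclose(ep.deltas["oxy"]["clench"], 0.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(100, 22))
        rest = rng.normal(size=(600, 22))
        clench = rng.normal(size=(550, 22))

        def deltas(offset):
            segs = self._segments(rest + offset, clench + offset, base + offset)
            means = {sp: baseline_means(segs[sp]["baseline"]) for sp in ("oxy", "deoxy")}
            return compute_deltas(segs, means)

        a, b = deltas(0.0), deltas(3.7)
        assert np.allclose(a.deltas["oxy"]["rest"], b.deltas["oxy"]["rest"])
        assert np.allclose(a.deltas["oxy"]["clench"], b.deltas["oxy"]["clench"])

    def test_channel_permutation_commutes(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(100, 22))
        rest = rng.normal(size=(600, 22))
        clench = rng.normal(size=(550, 22))
        perm = rng.permutation(22)
        segs = self._segments(rest, clench, base)
        means = {sp: baseline_means(segs[sp]["baseline"]) for sp in ("oxy", "deoxy")}
        direct = compute_deltas(segs, means).deltas["oxy"]["rest"][:, perm]
        segs_p = self._segments(rest[:, perm], clench[:, perm], base[:, perm])
        means_p = {sp: baseline_means(segs_p[sp]["baseline"]) for sp in ("oxy", "deoxy")}
        permuted = compute_deltas(segs_p, means_p).deltas["oxy"]["rest"]
        assert np.allclose(direct, permuted)


def _epoch_from(rest, clench):
    d = {sp: {"rest": rest.copy(), "clench": clench.copy()} for sp in ("oxy", "deoxy")}
    return EpochDeltas(subject_id="s", fs=FS, deltas=d)


class TestMasking:
    def test_constant_channel_masks_nothing(self):
        ep = mask_artifacts(_epoch_from(np.full((600, 22), 0.2),
                                        np.full((550, 22), -0.1)))
        assert ep.n_masked() == 0

    def test_gaussian_masked_fraction_near_two_sided_tail(self):
        rng = np.random.default_rng(7)
        ep = mask_artifacts(_epoch_from(rng.normal(size=(600, 22)),
                                        rng.normal(size=(550, 22))))
        frac = ep.mask["oxy"]["rest"].mean()
        expected = 2 * stats.norm.sf(2.0)  # ~0.0455
        assert abs(frac - expected) < 0.01

    def test_single_spike_is_masked_exactly(self):
        # near-constant channel: the spike dominates the window SD, so only
        # the spike sample exceeds the 2-SD threshold
        rest = np.tile(np.linspace(0.0, 1e-6, 600)[:, None], (1, 22))
        rest[123, 4] += 1.0
        ep = mask_artifacts(_epoch_from(rest, np.zeros((550, 22)) + 0.5))
        col = ep.mask["oxy"]["rest"][:, 4]
        assert col[123] and col.sum() == 1
        assert ep.mask["oxy"]["clench"].sum() == 0

    def test_mask_matches_brute_force_rule(self):
        rng = np.random.default_rng(11)
        rest = rng.normal(size=(600, 22))
        clench = rng.normal(size=(550, 22))
        ep = mask_artifacts(_epoch_from(rest, clench))
        for arr, win in ((rest, "rest"), (clench, "clench")):
            for ch in range(22):
                mu, sd = arr[:, ch].mean(), arr[:, ch].std(ddof=1)
                expected = np.abs(arr[:, ch] - mu) > 2 * sd
                assert np.array_equal(ep.mask["oxy"][win][:, ch], expected)

    def test_single_pass_statistics_are_stored(self, noisy_epoch):
        sd_stored = noisy_epoch.stats["oxy"]["rest"]["sd"]
        sd_raw = noisy_epoch.deltas["oxy"]["rest"].std(axis=0, ddof=1)
        assert np.allclose(sd_stored, sd_raw)  # computed on unmasked data


def test_preprocess_recording_end_to_end_shapes():
    rec = generate_recording(CohortConfig(seed=2), 1)
    ep = preprocess_recording(rec)
    assert ep.deltas["oxy"]["rest"].shape == (600, 22)
    assert ep.deltas["deoxy"]["clench"].shape == (550, 22)
    assert ep.mask["oxy"]["rest"].dtype == bool


def test_epoch_save_load_round_trip(tmp_path, noisy_epoch):
    from nirsclench.preprocess import load_epoch, save_epoch

    path = tmp_path / "epoch"
    save_epoch(noisy_epoch, path)
    back = load_epoch(path)
    assert back.subject_id == noisy_epoch.subject_id
    for sp in ("oxy", "deoxy"):
        for w in ("rest", "clench"):
            assert np.array_equal(back.deltas[sp][w], noisy_epoch.deltas[sp][w])
            assert np.array_equal(back.mask[sp][w], noisy_epoch.mask[sp][w])
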