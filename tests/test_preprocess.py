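import numpy as np
import pytest

from eegms.montage import synthetic_montage
from eegms.preprocess import (bandpass_fir, clean, design_bandpass,
                              detect_bad_channels, faster_local_channels,
                              reject_segments, spherical_spline_interpolate)
from eegms.recording import EpochedRecording, Recording, epoch
from eegms.synthetic import default_envelope, noise_sd_for_snr, render_eeg, \
    simulate_labels
from conftest import dipolar_maps


def _clean_recording(montage, seed, snr=4.0, duration=30.0, n_classes=3):
    maps = dipolar_maps(montage, n_classes, seed)
    lab = simulate_labels(duration, 250, 80.0, n_classes, seed=seed)
    env = default_envelope(len(lab.labels), 250)
    sd = noise_sd_for_snr(env, len(montage), snr)
    return render_eeg(lab, maps, 250, env, sd, seed=seed + 1000, montage=montage)


class TestBandpass:
    def test_dc_is_removed(self, small_montage):
        rec = Recording(np.full((16, 2500), 7.0), 250.0, small_montage, "other")
        out = bandpass_fir(rec)
        mid = out.data[:, 900:1600]
        assert np.sqrt((mid**2).mean()) < 0.07  # < 1% of the DC amplitude

    def test_passband_sine_preserved(self, small_montage):
        t = np.arange(250 * 20) / 250
        rec = Recording(np.tile(np.sin(2 * np.pi * 10 * t), (16, 1)),
                        250.0, small_montage, "other")
        out = bandpass_fir(rec)
        mid = out.data[0, 2000: -2000]
        assert abs(mid.max() - 1.0) < 0.05

    def test_impulse_response_is_symmetric(self, small_montage):
        data = np.zeros((16, 2501))
        data[:, 1250] = 1.0
        out = bandpass_fir(Recording(data, 250.0, small_montage, "other"))
        h = out.data[0]
        np.testing.assert_allclose(h, h[::-1], atol=1e-10)

    def test_short_signal_fails(self, small_montage):
        rec = Recording(np.zeros((16, 100)), 250.0, small_montage)
        with pytest.raises(ValueError, match="shorter"):
            bandpass_fir(rec)

    def test_kernel_is_odd_and_symmetric(self):
        k = design_bandpass(250.0)
        assert len(k) % 2 == 1
        np.testing.assert_allclose(k, k[::-1], atol=1e-15)


class TestBadChannels:
    def test_flat_channel_flagged(self, sphere_montage):
        rec = _clean_recording(sphere_montage, seed=0)
        rec.data[7, 1000: 1000 + int(6 * 250)] = 0.42  # flat for 6 s
        assert sphere_montage.names[7] in detect_bad_channels(rec)

    def test_scaled_channel_flagged_by_amplitude(self, sphere_montage):
        rec = _clean_recording(sphere_montage, seed=1)
        rec.data[10] *= 20.0
        assert sphere_montage.names[10] in detect_bad_channels(rec)

    def test_clean_cohort_false_positive_audit(self, sphere_montage):
        """No planted faults: the three rules stay silent on >= 95% of seeds."""
        empty = sum(
            len(detect_bad_channels(_clean_recording(sphere_montage, seed=s))) == 0
            for s in range(20))
        assert empty >= 19

    def test_missing_montage_rule_must_be_disabled_explicitly(self, small_montage):
        rec = Recording(np.random.default_rng(0).normal(size=(16, 1000)),
                        250.0, small_montage)
        out = detect_bad_channels(rec, use_neighbors=False)
        assert isinstance(out, set)


class TestFasterLocalChannels:
    def test_inflated_variance_flagged_and_repaired(self, sphere_montage):
        rec = _clean_recording(sphere_montage, seed=2)
        ep = epoch(rec, 2.0)
        bad_name = sphere_montage.names[3]
        rng = np.random.default_rng(3)
        ep.data[5, 3] += rng.normal(0, 10 * ep.data[5].std(), size=ep.data.shape[2])
        out = faster_local_channels(ep)
        assert bad_name in out.interpolated[5]
        assert out.data[5, 3].var() < ep.data[5, 3].var() / 10

    def test_identical_channels_no_flags(self, small_montage):
        data = np.tile(np.random.default_rng(4).normal(size=(1, 500)), (16, 1))
        ep = epoch(Recording(data, 250.0, small_montage), 2.0)
        out = faster_local_channels(ep)
        assert all(len(s) == 0 for s in out.interpolated)
        assert not out.rejected.any()

    def test_over_fraction_rejects_epoch(self):
        # two distinct fault types (variance + DC offset) flag two channels;
        # with a 5% cap that epoch is rejected rather than over-interpolated
        rec = _clean_recording(synthetic_montage(16, 1.0), seed=5)
        ep = epoch(rec, 2.0)
        rng = np.random.default_rng(5)
        ep.data[2, 3] += rng.normal(0, 20 * ep.data[2].std(), ep.data.shape[2])
        ep.data[2, 9] += 50 * ep.data[2].std()
        out = faster_local_channels(ep, max_fraction=0.05)
        assert out.rejected[2]
        assert out.interpolated[2] == set()


class TestRejectSegments:
    def test_amplitude_spike_rejected(self, small_montage):
        rec = _clean_recording(synthetic_montage(16, 1.0), seed=6)
        ep = epoch(rec, 2.0)
        ep.data[4, 2, 100] = 150.0
        flags = reject_segments(ep)
        assert flags[4]

    def test_identical_epochs_none_rejected(self, small_montage):
        one = np.random.default_rng(7).normal(size=(16, 500))
        data = np.tile(one, (10, 1, 1))
        ep = EpochedRecording(data=data, fs=250.0, montage=small_montage,
                              epoch_len_s=2.0)
        assert not reject_segments(ep).any()

    def test_planted_outlier_found_exactly(self):
        """1 aberrant epoch among 100: flagged alone in >= 90% of seeds."""
        mont = synthetic_montage(8)
        exact = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            data = rng.normal(0, 10, (100, 8, 250))
            out_ep = int(rng.integers(100))
            data[out_ep] += 35.0
            ep = EpochedRecording(data=data, fs=125.0, montage=mont,
                                  epoch_len_s=2.0)
            flags = reject_segments(ep, amp_uv=1e9)  # probability rules only
            exact += set(np.flatnonzero(flags)) == {out_ep}
        assert exact >= 18

    def test_all_rejected_fails_loudly(self, small_montage):
        data = np.full((5, 16, 500), 200.0)
        ep = EpochedRecording(data=data, fs=250.0, montage=small_montage,
                              epoch_len_s=2.0)
        with pytest.raises(ValueError, match="all 5 epochs"):
            reject_segments(ep)

    def test_monotone_in_amplitude_threshold(self, small_montage):
        rng = np.random.default_rng(8)
        data = rng.normal(0, 5, size=(20, 16, 500))
        data[np.arange(20), 0, 0] = np.linspace(10, 200, 20)  # graded spikes
        ep = EpochedRecording(data=data, fs=250.0, montage=small_montage,
                              epoch_len_s=2.0)
        strict = reject_segments(ep, amp_uv=50.0)
        loose = reject_segments(ep, amp_uv=150.0)
        assert np.all(strict | loose == strict)  # lowering only adds epochs
        assert strict.sum() > loose.sum()


class TestSphericalSpline:
    def test_constant_topography_reproduced(self, sphere_montage):
        topo = np.full(64, 2.5)
        out = spherical_spline_interpolate(topo, sphere_montage,
                                           {sphere_montage.names[9]})
        assert out[9] == pytest.approx(2.5, abs=1e-6)

    def test_first_order_harmonic_leave_one_out(self, sphere_montage):
        topo = sphere_montage.positions[:, 2]  # z-dipole pattern
        errs = []
        for c in range(0, 64, 8):
            out = spherical_spline_interpolate(topo, sphere_montage,
                                               {sphere_montage.names[c]})
            errs.append(abs(out[c] - topo[c]) / max(abs(topo[c]), 1e-3))
        assert np.median(errs) < 0.05

    def test_empty_bad_set_is_identity(self, small_montage):
        topo = np.random.default_rng(9).normal(size=16)
        np.testing.assert_array_equal(
            spherical_spline_interpolate(topo, small_montage, set()), topo)

    def test_too_few_good_channels_fail(self):
        mont = synthetic_montage(5)
        with pytest.raises(ValueError, match=">= 4 good"):
            spherical_spline_interpolate(np.zeros(5), mont,
                                         set(mont.names[:2]))


class TestCleanChain:
    def test_deterministic_and_invariants(self, sphere_montage):
        rec = _clean_recording(sphere_montage, seed=10, duration=20.0)
        out1, rep1 = clean(rec, use_neighbors=False)
        out2, rep2 = clean(rec, use_neighbors=False)
        np.testing.assert_array_equal(out1.data, out2.data)
        assert rep1 == rep2
        assert out1.is_average_referenced(atol=1e-9)
        assert out1.n_channels == rec.n_channels  # bads repaired, not dropped

    def test_report_records_thresholds(self, sphere_montage):
        rec = _clean_recording(sphere_montage, seed=11, duration=20.0)
        _, report = clean(rec, amp_uv=80.0, use_neighbors=False)
        assert report["thresholds"]["amp_uv"] == 80.0

    def test_too_many_bad_channels_fail(self, small_montage):
        rng = np.random.default_rng(12)
        data = rng.normal(size=(16, 5000))
        data[:8] *= 1e-12  # half the cap dead
        rec = Recording(data, 250.0, small_montage)
        with pytest.raises(ValueError, match="refusing"):
            clean(rec, use_neighbors=False)
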