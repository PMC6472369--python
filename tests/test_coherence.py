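import numpy as np
import pandas as pd
import pytest

from thetalink import (
    TimeSeriesRecording,
    ValidationError,
    band_coherence,
    binned_coherence,
    coherogram,
    epoch_coherence,
    first_last_bins,
    fractional_change,
    multitaper_coherence,
)
from thetalink.dataio import EpochTable
from thetalink.simulate import analytic_coherence, generate_lfp_pair, generate_ymaze_session
from thetalink.behavior import arm_bouts


def _dup_channel_recording(seed=0, duration=30.0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(int(duration * 1000))
    return TimeSeriesRecording(np.column_stack([x, x]), 1000.0, ("a", "b"))


class TestEstimatorProperties:
    def test_self_coherence_is_one(self):
        rec = _dup_channel_recording()
        est = multitaper_coherence(rec, "a", "b")
        assert np.allclose(est.coherence, 1.0, atol=1e-10)

    def test_symmetry_and_rescaling_invariance(self, theta_spec):
        rec = generate_lfp_pair(theta_spec, None, 30.0, 1000.0, seed=4)
        ab = multitaper_coherence(rec, "dHipp", "PFC")
        ba = multitaper_coherence(rec, "PFC", "dHipp")
        assert np.allclose(ab.coherence, ba.coherence, atol=1e-12)
        scaled = TimeSeriesRecording(
            rec.samples * np.array([5.0, 1.0]), rec.fs, rec.channel_names
        )
        sc = multitaper_coherence(scaled, "dHipp", "PFC")
        assert np.allclose(ab.coherence, sc.coherence, atol=1e-10)

    def test_bounded_unit_interval(self, theta_spec):
        rec = generate_lfp_pair(theta_spec, None, 20.0, 1000.0, seed=1)
        est = multitaper_coherence(rec, "dHipp", "PFC")
        assert (est.coherence >= 0).all() and (est.coherence <= 1).all()

    def test_missing_channel_rejected(self, theta_spec):
        rec = generate_lfp_pair(theta_spec, None, 20.0, 1000.0, seed=1)
        with pytest.raises(ValidationError):
            multitaper_coherence(rec, "dHipp", "vHipp")

    def test_consistency_toward_analytic_value(self, balanced_spec):
        # magnitude convention: sqrt of the analytic squared coherence
        target = np.sqrt(analytic_coherence(balanced_spec, 8.0))
        tolerances = {15.0: 0.15, 60.0: 0.08, 240.0: 0.05}
        for duration, tol in tolerances.items():
            rec = generate_lfp_pair(balanced_spec, None, duration, 1000.0, seed=6)
            est = multitaper_coherence(rec, "dHipp", "PFC")
            i = np.argmin(np.abs(est.frequencies - 8.0))
            assert est.coherence[i] == pytest.approx(target, abs=tol)


class TestBandAndFractional:
    def test_flat_coherence_mean_equals_peak(self):
        rec = _dup_channel_recording()
        est = multitaper_coherence(rec, "a", "b")
        mean_c, peak_c, _ = band_coherence(est, (6, 12))
        assert mean_c == pytest.approx(peak_c)

    def test_injected_peak_frequency_recovered(self, theta_spec):
        rec = generate_lfp_pair(theta_spec, None, 120.0, 1000.0, seed=2)
        est = multitaper_coherence(rec, "dHipp", "PFC")
        _, _, peak_f = band_coherence(est, (6, 12))
        assert peak_f == pytest.approx(8.0, abs=1.0)

    def test_peak_not_below_mean(self, theta_spec):
        rec = generate_lfp_pair(theta_spec, None, 30.0, 1000.0, seed=3)
        est = multitaper_coherence(rec, "dHipp", "PFC")
        mean_c, peak_c, _ = band_coherence(est, (20, 30))
        assert peak_c >= mean_c

    def test_fractional_change(self):
        assert fractional_change(0.6, 0.5) == pytest.approx(0.2)
        assert fractional_change(0.5, 0.5) == 0.0
        with pytest.raises(ValidationError):
            fractional_change(0.5, 0.0)


class TestBinnedCoherence:
    def test_thirty_bins_over_five_minutes(self, theta_spec):
        rec = generate_lfp_pair(theta_spec, None, 300.0, 1000.0, seed=5)
        binned = binned_coherence(rec, "dHipp", "PFC", (6, 12), bin_s=10.0)
        assert (binned["metric"] == "mean_coherence").sum() == 30
        first, last = first_last_bins(binned, "mean_coherence")
        assert 0 <= first <= 1 and 0 <= last <= 1

    def test_coherogram_shape(self, theta_spec):
        rec = generate_lfp_pair(theta_spec, None, 60.0, 1000.0, seed=5)
        cg = coherogram(rec, "dHipp", "PFC", bin_s=10.0)
        assert cg.coherence.shape[0] == 6
        assert ((cg.coherence >= 0) & (cg.coherence <= 1)).all()

    def test_first_vs_last_bin_contrast_calibration(self, balanced_spec):
        # stationary coupling: across-animal paired first-vs-last test stays
        # null; ramping the source up makes last > first in nearly all animals
        from thetalink.stats import paired_test

        firsts, lasts, ramp_wins = [], [], 0
        n = 60000
        env = np.linspace(0.0, 1.5, n)
        for seed in range(8):
            rec = generate_lfp_pair(balanced_spec, None, 60.0, 1000.0, seed=seed)
            b = binned_coherence(rec, "dHipp", "PFC", (6, 12), bin_s=10.0)
            f, l = first_last_bins(b, "mean_coherence")
            firsts.append(f)
            lasts.append(l)
            ramped = generate_lfp_pair(
                balanced_spec, None, 60.0, 1000.0, seed=100 + seed,
                band_envelopes={0: env},
            )
            rb = binned_coherence(ramped, "dHipp", "PFC", (6, 12), bin_s=10.0)
            rf, rl = first_last_bins(rb, "mean_coherence")
            ramp_wins += rl > rf
        assert paired_test(firsts, lasts).table["p"].iloc[0] > 0.05
        assert ramp_wins >= 7

    def test_ramped_coupling_increases_over_session(self, balanced_spec):
        # source amplitude ramps 0 -> full: last-bin coherence above first
        n = 120000
        env = np.linspace(0.0, 1.5, n)
        rec = generate_lfp_pair(
            balanced_spec, None, 120.0, 1000.0, seed=8, band_envelopes={0: env}
        )
        binned = binned_coherence(rec, "dHipp", "PFC", (6, 12), bin_s=10.0)
        first, last = first_last_bins(binned, "mean_coherence")
        assert last > first


class TestEpochCoherence:
    def _epochs(self, rows):
        return EpochTable(
            pd.DataFrame(rows, columns=["onset", "offset", "label", "trial_id", "phase"])
        )

    def test_identical_signal_label_means_agree(self, theta_spec):
        rec = generate_lfp_pair(theta_spec, None, 120.0, 1000.0, seed=9)
        eps = self._epochs(
            [(i * 20.0, i * 20.0 + 8.0, "d", i, "sample" if i % 2 else "choice")
             for i in range(6)]
        )
        out = epoch_coherence(rec, eps, "dHipp", "PFC")
        s = band_coherence(out["sample"], (6, 12))[0]
        c = band_coherence(out["choice"], (6, 12))[0]
        assert s == pytest.approx(c, abs=0.12)

    def test_single_decision_window_bookkeeping(self, theta_spec):
        rec = generate_lfp_pair(theta_spec, None, 60.0, 1000.0, seed=9)
        out = epoch_coherence(
            rec, self._epochs([(10.0, 11.2, "d", 1, "choice")]), "dHipp", "PFC"
        )
        est = out["choice"]
        assert est.n_windows == 1
        assert est.k == 3
        assert est.dof == 6

    def test_label_with_no_usable_epochs_missing(self, theta_spec):
        rec = generate_lfp_pair(theta_spec, None, 60.0, 1000.0, seed=9)
        out = epoch_coherence(
            rec,
            self._epochs(
                [(10.0, 10.2, "d", 1, "choice"), (20.0, 28.0, "d", 2, "sample")]
            ),
            "dHipp",
            "PFC",
        )
        assert "choice" not in out
        assert "sample" in out

    def test_novel_bout_coupling_gain_recovered(self, theta_spec):
        rec, track, polys = generate_ymaze_session(
            0.5, theta_spec, seed=12, novel_theta_gain=2.5
        )
        bouts = arm_bouts(track, polys)
        eps = EpochTable(
            bouts.rename(columns={"arm": "label"})[["onset", "offset", "label"]]
        )
        out = epoch_coherence(rec, eps, "dHipp", "PFC", label_field="label")
        novel = band_coherence(out["novel"], (6, 12))[0]
        familiar = band_coherence(out["familiar"], (6, 12))[0]
        assert novel > familiar
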