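"""Epoch segmentation, band correlations and the one-way ANOVA."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from silentspeech.bandstats import (
    compare_pre_spike,
    epoch_band_correlations,
    f_critical,
    one_way_anova,
    segment_epochs,
)
from silentspeech.preprocess import Annotation, Recording, decompose

RATE = 500.0


def recording_with_events(onsets, duration=40.0, event_s=3.0):
    n = int(duration * RATE)
    t = np.arange(n) / RATE
    x = np.sin(2 * np.pi * 10.0 * t)
    return Recording(np.vstack([x, x]), ["EEG", "EMG"], RATE,
                     annotations=[Annotation(o, event_s) for o in onsets])


class TestSegmentEpochs:
    def test_five_events_give_five_pre_five_spike(self, tongue_recording):
        epochs = segment_epochs(tongue_recording, pre_s=2.0)
        assert len(epochs.by_phase("pre")) == 5
        assert len(epochs.by_phase("spike")) == 5
        reps = [e.repetition for e in epochs.by_phase("spike")]
        assert reps == [0, 1, 2, 3, 4]

    def test_epoch_boundary_arithmetic(self):
        rec = recording_with_events([10.0])
        epochs = segment_epochs(rec, pre_s=2.0, spike_s=3.0)
        pre, spike = epochs.epochs
        assert (pre.start, pre.end) == (8.0, 10.0)
        assert (spike.start, spike.end) == (10.0, 13.0)

    def test_event_too_early_rejected(self):
        with pytest.raises(ValueError, match="pre epoch"):
            segment_epochs(recording_with_events([1.0]), pre_s=2.0)

    def test_events_too_close_rejected(self):
        with pytest.raises(ValueError, match="closer"):
            segment_epochs(recording_with_events([10.0, 13.5]), pre_s=2.0)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no annotated"):
            segment_epochs(recording_with_events([]))

    def test_spike_length_defaults_to_annotated_duration(self):
        rec = recording_with_events([10.0], event_s=4.0)
        epochs = segment_epochs(rec, pre_s=2.0)
        assert epochs.by_phase("spike")[0].end == 14.0


class TestEpochCorrelations:
    def test_self_pair_correlation_is_one(self, tongue_recording):
        bandset = decompose(tongue_recording, ["alpha"])
        epochs = segment_epochs(tongue_recording)
        table = epoch_band_correlations(bandset, epochs,
                                        pairs=[("alpha", "alpha")])
        assert np.allclose(table.valid()["r"], 1.0)

    def test_matches_brute_force_pearson_on_slices(self, tongue_recording):
        bandset = decompose(tongue_recording, ["alpha", "gamma"])
        epochs = segment_epochs(tongue_recording)
        table = epoch_band_correlations(bandset, epochs,
                                        pairs=[("alpha", "gamma")],
                                        use_envelope=False)
        from silentspeech.features import envelope  # noqa: F401
        for ep, row in zip(epochs.epochs, table.rows.itertuples()):
            i0, i1 = int(ep.start * RATE), int(ep.end * RATE)
            expected = np.corrcoef(bandset["alpha"][i0:i1],
                                   bandset["gamma"][i0:i1])[0, 1]
            assert row.r == pytest.approx(expected, abs=1e-10)

    def test_empty_pair_list_gives_empty_table(self, tongue_recording):
        bandset = decompose(tongue_recording, ["alpha"])
        epochs = segment_epochs(tongue_recording)
        assert len(epoch_band_correlations(bandset, epochs, pairs=[]).rows) == 0


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        res = one_way_anova([[1, 2, 3, 4], [1, 2, 3, 4]])
        assert res.f_value == 0.0

    def test_hand_computed_sums_of_squares(self):
        # groups [1,2,3,4] and [2,3,4,5]: SSB = 2, SSW = 10, df = (1, 6)
        res = one_way_anova([[1, 2, 3, 4], [2, 3, 4, 5]])
        assert res.f_value == pytest.approx(1.2, abs=1e-12)
        assert (res.df_between, res.df_within) == (1, 6)
        assert res.p_value == pytest.approx(stats.f.sf(1.2, 1, 6), abs=1e-12)

    def test_two_group_f_equals_squared_t(self, rng):
        a, b = rng.standard_normal(4) + 0.5, rng.standard_normal(4)
        res = one_way_anova([a, b])
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        assert res.f_value == pytest.approx(t ** 2, abs=1e-10)

    def test_agrees_with_scipy_f_oneway(self, rng):
        groups = [rng.standard_normal(6) + mu for mu in (0.0, 0.3, 1.0)]
        res = one_way_anova(groups)
        ref = stats.f_oneway(*groups)
        assert res.f_value == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_constant_everything_gives_p_one(self):
        res = one_way_anova([[2.0, 2.0], [2.0, 2.0]])
        assert (res.f_value, res.p_value) == (0.0, 1.0)

    def test_translation_and_scale_invariance(self, rng):
        groups = [rng.standard_normal(5), rng.standard_normal(5) + 1]
        f0 = one_way_anova(groups).f_value
        shifted = one_way_anova([g + 100.0 for g in groups]).f_value
        scaled = one_way_anova([g * 42.0 for g in groups]).f_value
        assert shifted == pytest.approx(f0, rel=1e-9)
        assert scaled == pytest.approx(f0, rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            one_way_anova([[1.0], [1.0, 2.0]])
        with pytest.raises(ValueError, match="2 groups"):
            one_way_anova([[1.0, 2.0]])

    @pytest.mark.parametrize("seed", range(5))
    def test_p_value_consistent_with_critical_value(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.standard_normal(4), rng.standard_normal(4) + 0.8]
        res = one_way_anova(groups, alpha=0.05)
        assert (res.p_value < 0.05) == (res.f_value > res.f_critical)


class TestFCritical:
    def test_reference_value_at_df_1_6(self):
        assert f_critical(0.05, 1, 6) == pytest.approx(5.987, abs=5e-4)

    def test_monotone_in_alpha(self):
        assert f_critical(0.01, 1, 6) > f_critical(0.05, 1, 6)

    def test_large_df_limit_is_squared_normal_quantile(self):
        assert f_critical(0.05, 1, 10 ** 6) == pytest.approx(
            stats.norm.ppf(0.975) ** 2, abs=1e-3)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            f_critical(0.0, 1, 6)
        with pytest.raises(ValueError):
            f_critical(0.05, 0, 6)


class TestComparePreSpike:
    def test_delta_arithmetic(self, tongue_recording):
        bandset = decompose(tongue_recording, ["alpha", "gamma"])
        epochs = segment_epochs(tongue_recording)
        table = epoch_band_correlations(bandset, epochs,
                                        pairs=[("alpha", "gamma")])
        rows = table.rows
        summary = compare_pre_spike(table)
        pre = rows[rows.phase == "pre"]["r"].mean()
        spike = rows[rows.phase == "spike"]["r"].mean()
        assert summary["delta"].iloc[0] == pytest.approx(spike - pre)

    def test_single_phase_rejected(self, tongue_recording):
        bandset = decompose(tongue_recording, ["alpha", "gamma"])
        epochs = segment_epochs(tongue_recording)
        table = epoch_band_correlations(bandset, epochs,
                                        pairs=[("alpha", "gamma")])
        table.rows = table.rows[table.rows.phase == "pre"]
        with pytest.raises(ValueError, match="phase"):
            compare_pre_spike(table)

    def test_alpha_gamma_correlation_declines_during_movement(self):
        """The configured gamma surge decouples the alpha and gamma
        envelopes, so the alpha–gamma delta is negative in most runs."""
        from silentspeech.synthgen import SynthConfig, simulate_recording

        negatives = 0
        n_runs = 25
        for seed in range(n_runs):
            cfg = SynthConfig(sampling_rate=RATE, duration=40.0,
                              event_times=(5.0, 12.0, 19.0, 26.0, 33.0),
                              seed=seed)
            rec = simulate_recording(cfg)
            bandset = decompose(rec, ["alpha", "gamma"])
            epochs = segment_epochs(rec)
            table = epoch_band_correlations(bandset, epochs,
                                            pairs=[("alpha", "gamma")])
            summary = compare_pre_spike(table)
            if summary["delta"].iloc[0] < 0:
                negatives += 1
        assert negatives >= 0.8 * n_runs
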