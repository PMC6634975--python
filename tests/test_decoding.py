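"""Pseudopopulation assembly, SVM decoding, CTD and behaviour correlation."""

import numpy as np
import pandas as pd
import pytest

from wmpop import core_data as cd
from wmpop import decoding as dec
from tests.conftest import make_binned

REDUCED = dict(c_grid=(0.25, 1.0, 4.0), gamma_grid=(2.0 ** -7, 2.0 ** -4, 1.0))


def _separable_binned(n_units=8, n_per_class=40, n_bins=4, coding_bins=(2, 3),
                      gap=4.0, noise=1.0, seed=0):
    """Rates with class-separated means in the coding bins only."""
    rng = np.random.default_rng(seed)
    rates = rng.normal(5, noise, size=(n_units, 2 * n_per_class, n_bins))
    for b in coding_bins:
        sign = np.where(np.arange(n_units) % 2 == 0, 1.0, -1.0)
        rates[:, :n_per_class, b] += gap * sign[:, None] / 2
        rates[:, n_per_class:, b] -= gap * sign[:, None] / 2
    labels = np.array(["S1"] * n_per_class + ["S2"] * n_per_class)
    return make_binned(rates.clip(0)), labels


def _pop(binned, labels):
    return dec.build_pseudopopulation(dec.normalize_rates(binned), labels)


class TestSelectUnits:
    @staticmethod
    def _session(n_trials_per_class):
        records = []
        tid = 0
        for sample, n in (("S1", n_trials_per_class["S1"]),
                          ("S2", n_trials_per_class["S2"])):
            for _ in range(n):
                tid += 1
                records.append({
                    "trial_id": tid, "task": "DNMS", "subject_id": "M01",
                    "genotype": "control", "sample_odor": sample,
                    "test_odor": "T2" if sample == "S1" else "T1",
                    "relation": "nonmatch", "delay_s": 8.0, "distractor": None,
                    "laser_on": False, "laser_onset_s": None,
                    "laser_duration_s": None, "perturb_epoch": "none",
                    "resp_win_start_s": 11.0, "resp_win_end_s": 11.5,
                    "lick_times_s": [11.2], "outcome": "hit"})
        trials = pd.DataFrame.from_records(records, columns=cd.TRIAL_COLUMNS)
        spikes = pd.DataFrame.from_records(
            [{"unit_id": "u001", "trial_id": t, "spike_times_s": [0.5]}
             for t in trials["trial_id"]], columns=cd.SPIKE_COLUMNS)
        return spikes, trials

    def test_exactly_thirty_trials_excluded(self):
        spikes, trials = self._session({"S1": 30, "S2": 45})
        with pytest.raises(ValueError, match="no unit"):
            dec.select_units(spikes, trials, dec.DecoderConfig())

    def test_thirty_one_trials_included(self):
        spikes, trials = self._session({"S1": 31, "S2": 31})
        assert dec.select_units(spikes, trials, dec.DecoderConfig()) == ["u001"]

    def test_incorrect_trials_do_not_count(self):
        spikes, trials = self._session({"S1": 40, "S2": 40})
        trials.loc[trials.index[:15], "outcome"] = "miss"
        with pytest.raises(ValueError):
            dec.select_units(spikes, trials, dec.DecoderConfig())


class TestNormalizeRates:
    def test_min_max_scaling(self):
        binned = make_binned(np.array([[[2.0], [4.0], [6.0]]]))
        out = dec.normalize_rates(binned)
        assert np.allclose(out.rates[0, :, 0], [0.0, 0.5, 1.0])

    def test_constant_neuron_maps_to_zero(self):
        binned = make_binned(np.full((1, 4, 2), 3.3))
        with pytest.warns(UserWarning, match="constant"):
            out = dec.normalize_rates(binned)
        assert np.all(out.rates == 0.0)

    def test_output_in_unit_interval(self, binned_small):
        binned, _ = binned_small
        out = dec.normalize_rates(binned)
        assert out.rates.min() >= 0.0 and out.rates.max() <= 1.0


class TestDecodeTimecourse:
    def test_separable_classes_high_accuracy(self):
        binned, labels = _separable_binned()
        config = dec.DecoderConfig(n_repeats=60, n_shuffles=1, seed=5, **REDUCED)
        res = dec.decode_timecourse(_pop(binned, labels), config,
                                    compute_null=False)
        assert res.accuracy[2] >= 0.95 and res.accuracy[3] >= 0.95
        assert res.chance_level == 0.5

    def test_noise_bins_near_chance(self):
        binned, labels = _separable_binned()
        config = dec.DecoderConfig(n_repeats=100, n_shuffles=1, seed=6, **REDUCED)
        res = dec.decode_timecourse(_pop(binned, labels), config,
                                    compute_null=False)
        assert 0.35 <= res.accuracy[0] <= 0.65

    def test_class_rename_leaves_accuracy_unchanged(self):
        binned, labels = _separable_binned(seed=7)
        relabel = np.where(labels == "S1", "A1", "A2")
        config = dec.DecoderConfig(n_repeats=30, n_shuffles=1, seed=8, **REDUCED)
        r1 = dec.decode_timecourse(_pop(binned, labels), config,
                                   compute_null=False)
        r2 = dec.decode_timecourse(_pop(binned, relabel), config,
                                   compute_null=False)
        assert np.allclose(r1.accuracy, r2.accuracy)

    def test_duplicated_neurons_redundancy_invariance(self):
        binned, labels = _separable_binned(n_units=6, seed=9)
        doubled = make_binned(np.concatenate([binned.rates, binned.rates]))
        config = dec.DecoderConfig(n_repeats=60, n_shuffles=1, seed=10, **REDUCED)
        r1 = dec.decode_timecourse(_pop(binned, labels), config,
                                   compute_null=False)
        r2 = dec.decode_timecourse(_pop(doubled, labels), config,
                                   compute_null=False)
        assert np.max(np.abs(r1.accuracy - r2.accuracy)) < 0.15

    def test_too_few_trials_per_class_rejected(self):
        binned = make_binned(np.random.default_rng(0).random((3, 2, 2)))
        labels = np.array(["S1", "S2"])
        with pytest.raises(ValueError, match="too few trials"):
            dec.decode_timecourse(_pop(binned, labels), dec.DecoderConfig())

    def test_shuffle_null_brackets_chance(self):
        binned, labels = _separable_binned(n_units=6, n_per_class=25, n_bins=2,
                                           coding_bins=(1,), seed=11)
        config = dec.DecoderConfig(n_repeats=30, n_shuffles=60,
                                   shuffle_repeats=10, seed=12, **REDUCED)
        res = dec.decode_timecourse(_pop(binned, labels), config)
        assert 0.4 <= res.null_accuracies.mean() <= 0.6
        assert res.p_values[1] == pytest.approx(1 / 61)


class TestCrossTemporalDecoding:
    def test_diagonal_equals_timecourse(self):
        binned, labels = _separable_binned(n_units=6, n_per_class=30, seed=13)
        config = dec.DecoderConfig(n_repeats=25, n_shuffles=1, seed=14, **REDUCED)
        pop = _pop(binned, labels)
        res = dec.decode_timecourse(pop, config, compute_null=False)
        ctd = dec.cross_temporal_decoding(pop, config, res)
        assert np.allclose(np.diag(ctd), res.accuracy)

    def test_stationary_code_off_diagonal_matches(self):
        binned, labels = _separable_binned(n_units=8, n_bins=3,
                                           coding_bins=(0, 1, 2), seed=15)
        config = dec.DecoderConfig(n_repeats=40, n_shuffles=1, seed=16, **REDUCED)
        pop = _pop(binned, labels)
        res = dec.decode_timecourse(pop, config, compute_null=False)
        ctd = dec.cross_temporal_decoding(pop, config, res)
        assert np.min(ctd) > 0.9

    def test_orthogonal_epoch_codes_cross_at_chance(self):
        rng = np.random.default_rng(17)
        n_units, n_per = 10, 40
        rates = rng.normal(5, 1, size=(n_units, 2 * n_per, 4))
        sign_a = np.where(np.arange(n_units) < n_units // 2, 1.0, 0.0)
        sign_b = 1.0 - sign_a
        for b, sign in ((0, sign_a), (1, sign_a), (2, sign_b), (3, sign_b)):
            rates[:, :n_per, b] += 4.0 * sign[:, None]
            rates[:, n_per:, b] -= 4.0 * sign[:, None]
        labels = np.array(["S1"] * n_per + ["S2"] * n_per)
        config = dec.DecoderConfig(n_repeats=40, n_shuffles=1, seed=18, **REDUCED)
        pop = _pop(make_binned(rates.clip(0)), labels)
        res = dec.decode_timecourse(pop, config, compute_null=False)
        ctd = dec.cross_temporal_decoding(pop, config, res)
        within = [ctd[0, 1], ctd[1, 0], ctd[2, 3], ctd[3, 2]]
        cross = [ctd[0, 2], ctd[0, 3], ctd[2, 0], ctd[3, 1]]
        assert min(within) > 0.9
        assert max(cross) < 0.75


class TestLabelMapping:
    def test_six_samples_grouped_into_pair_classes(self):
        """MS-DPA mode: six odors map onto two pair-classes; chance follows
        the mapped class count."""
        rng = np.random.default_rng(20)
        n_per = 12
        labels = np.repeat([f"S{i}" for i in range(1, 7)], n_per)
        rates = rng.normal(5, 1, size=(6, 6 * n_per, 2))
        # pair-class coding: S1-S3 high, S4-S6 low in bin 1
        rates[:, :3 * n_per, 1] += 4.0
        label_map = {f"S{i}": "T1" if i <= 3 else "T2" for i in range(1, 7)}
        pop = dec.build_pseudopopulation(
            dec.normalize_rates(make_binned(rates.clip(0))), labels,
            label_map=label_map)
        assert sorted(pop.classes) == ["T1", "T2"]
        config = dec.DecoderConfig(n_repeats=40, n_shuffles=1, seed=21,
                                   **REDUCED)
        res = dec.decode_timecourse(pop, config, compute_null=False)
        assert res.chance_level == 0.5
        assert res.accuracy[1] > 0.9
        assert np.all((res.accuracy >= 0) & (res.accuracy <= 1))


class TestBehaviorCorrelation:
    def test_proportional_conditions_r_squared_one(self):
        acc = [np.full(50, a) for a in (0.9, 0.75, 0.6)]
        perf = [np.repeat([1, 0], [int(100 * a), 100 - int(100 * a)])
                for a in (0.9, 0.75, 0.6)]
        rep = dec.decode_behavior_correlation(acc, perf, n_boot=200, seed=0)
        assert rep.r_squared > 0.95

    def test_independent_conditions_centred_near_zero(self):
        rng = np.random.default_rng(1)
        acc = [0.7 + 0.05 * rng.standard_normal(60) for _ in range(6)]
        perf = [rng.integers(0, 2, 80) for _ in range(6)]
        rep = dec.decode_behavior_correlation(acc, perf, n_boot=300, seed=2)
        assert abs(np.median(rep.r_draws)) < 0.5

    def test_two_conditions_required(self):
        with pytest.raises(ValueError):
            dec.decode_behavior_correlation([np.ones(5)], [np.ones(5)])

    def test_affine_rescaling_preserves_r_magnitude(self):
        rng = np.random.default_rng(3)
        acc = [0.5 + 0.1 * i + 0.01 * rng.standard_normal(40) for i in range(4)]
        perf = [rng.integers(0, 2, 50) for _ in range(4)]
        r1 = dec.decode_behavior_correlation(acc, perf, n_boot=10, seed=4).r
        acc2 = [a * 3.0 + 1.0 for a in acc]
        r2 = dec.decode_behavior_correlation(acc2, perf, n_boot=10, seed=4).r
        assert r1 == pytest.approx(r2, abs=1e-12)
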