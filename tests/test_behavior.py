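"""Outcome classification, performance metrics, training windows, decay fit."""

import numpy as np
import pandas as pd
import pytest

from wmpop import behavior as bh
from wmpop import core_data as cd
from wmpop import synthetic as syn


def _trials(rows):
    base = {
        "task": "DNMS", "subject_id": "M01", "genotype": "control",
        "sample_odor": "S1", "test_odor": "T2", "relation": "nonmatch",
        "delay_s": 8.0, "distractor": None, "laser_on": False,
        "laser_onset_s": None, "laser_duration_s": None,
        "perturb_epoch": "none", "resp_win_start_s": 11.0,
        "resp_win_end_s": 11.5, "lick_times_s": [], "outcome": None,
    }
    records = []
    for i, row in enumerate(rows, start=1):
        rec = dict(base, trial_id=i)
        rec.update(row)
        records.append(rec)
    return pd.DataFrame.from_records(records, columns=cd.TRIAL_COLUMNS)


class TestClassifyOutcomes:
    def test_licking_convention(self):
        trials = _trials([
            {"relation": "nonmatch", "lick_times_s": [11.2]},     # hit
            {"sample_odor": "S1", "test_odor": "T1", "relation": "match",
             "lick_times_s": []},                                 # CR
            {"sample_odor": "S1", "test_odor": "T1", "relation": "match",
             "lick_times_s": [11.2]},                             # FA
            {"relation": "nonmatch", "lick_times_s": []},         # miss
        ])
        out = bh.classify_outcomes(trials)["outcome"].tolist()
        assert out == ["hit", "correct_rejection", "false_alarm", "miss"]

    def test_half_open_window_boundaries(self):
        trials = _trials([
            {"lick_times_s": [10.999]},     # 1 ms before the window: no lick
            {"lick_times_s": [11.0]},       # window start is inclusive
            {"lick_times_s": [11.5]},       # window end is exclusive
        ])
        out = bh.classify_outcomes(trials)["outcome"].tolist()
        assert out == ["miss", "hit", "miss"]

    def test_idempotent_and_row_order_equivariant(self):
        trials = _trials([{"lick_times_s": [11.2]}, {"lick_times_s": []}])
        once = bh.classify_outcomes(trials)
        twice = bh.classify_outcomes(once)
        assert once["outcome"].tolist() == twice["outcome"].tolist()
        flipped = bh.classify_outcomes(trials.iloc[::-1].reset_index(drop=True))
        assert flipped["outcome"].tolist() == once["outcome"].tolist()[::-1]


class TestSummarizePerformance:
    @staticmethod
    def _filled(n_hit, n_miss, n_fa, n_cr, licks_per_hit=1, licks_per_fa=1):
        rows = []
        for _ in range(n_hit):
            rows.append({"relation": "nonmatch",
                         "lick_times_s": list(11.01 + 0.01 * np.arange(licks_per_hit))})
        for _ in range(n_miss):
            rows.append({"relation": "nonmatch", "lick_times_s": []})
        for _ in range(n_fa):
            rows.append({"sample_odor": "S1", "test_odor": "T1", "relation": "match",
                         "lick_times_s": list(11.01 + 0.01 * np.arange(licks_per_fa))})
        for _ in range(n_cr):
            rows.append({"sample_odor": "S1", "test_odor": "T1",
                         "relation": "match", "lick_times_s": []})
        return bh.classify_outcomes(_trials(rows))

    def test_d_prime_against_inverse_normal_oracle(self):
        trials = self._filled(n_hit=84, n_miss=16, n_fa=16, n_cr=84)
        s = bh.summarize_performance(trials)[0]
        assert s.hit_rate == pytest.approx(0.84)
        assert s.false_alarm_rate == pytest.approx(0.16)
        assert s.d_prime == pytest.approx(1.9890, abs=1e-3)

    def test_d_prime_symmetry_and_antisymmetry(self):
        equal = bh.summarize_performance(self._filled(30, 70, 30, 70))[0]
        assert equal.d_prime == pytest.approx(0.0)
        a = bh.summarize_performance(self._filled(84, 16, 16, 84))[0]
        b = bh.summarize_performance(self._filled(16, 84, 84, 16))[0]
        assert a.d_prime == pytest.approx(-b.d_prime)

    def test_lick_efficiency(self):
        trials = self._filled(n_hit=10, n_miss=0, n_fa=10, n_cr=0,
                              licks_per_hit=3, licks_per_fa=1)
        s = bh.summarize_performance(trials)[0]
        assert s.lick_efficiency == pytest.approx(30 / 40)

    def test_outcome_counts_conserved(self, dnms_cohort):
        for s in bh.summarize_performance(dnms_cohort,
                                          group_by=["genotype", "laser_on"]):
            grp = dnms_cohort
            for k, v in s.group.items():
                grp = grp[grp[k] == v]
            assert s.n_trials == len(grp)

    def test_clamped_extreme_rates_finite(self):
        s = bh.summarize_performance(self._filled(20, 0, 0, 20))[0]
        assert np.isfinite(s.d_prime)

    def test_missing_nogo_trials_drop_d_prime(self):
        s = bh.summarize_performance(self._filled(10, 5, 0, 0))[0]
        assert s.d_prime is None


class TestWellTrainedWindows:
    @staticmethod
    def _cohort(correct_pattern, laser_pattern=None):
        n = len(correct_pattern)
        laser_pattern = laser_pattern or [False] * n
        rows = []
        for c, laser in zip(correct_pattern, laser_pattern):
            rows.append({
                "relation": "nonmatch",
                "lick_times_s": [11.2] if c else [],
                "laser_on": laser,
                "laser_onset_s": 1.0 if laser else None,
                "laser_duration_s": 8.0 if laser else None,
                "perturb_epoch": "delay" if laser else "none"})
        return bh.classify_outcomes(_trials(rows))

    def test_forty_consecutive_correct_all_flagged(self):
        trials = self._cohort([True] * 40)
        assert bh.find_well_trained_windows(trials, "w40").all()

    def test_below_threshold_not_flagged(self):
        pattern = [True] * 31 + [False] * 9       # 77.5% < 80%
        trials = self._cohort(pattern)
        assert not bh.find_well_trained_windows(trials, "w40").any()

    def test_threshold_is_inclusive(self):
        pattern = [True] * 32 + [False] * 8       # exactly 80%
        trials = self._cohort(pattern)
        assert bh.find_well_trained_windows(trials, "w40").all()

    def test_interleaved_laser_trials_inherit_membership(self):
        correct = [True] * 41
        laser = [True, False] * 20 + [False]
        # only 21 unperturbed trials -> use the 20-trial criterion; the
        # interleaved laser-on trials inside the span are flagged too
        trials = self._cohort(correct, laser)
        mask = bh.find_well_trained_windows(trials, "w20")
        assert mask[1:].all()
        assert not mask[0]   # leading laser trial precedes the span

    def test_too_few_unperturbed_warns_all_false(self):
        trials = self._cohort([True] * 10)
        with pytest.warns(UserWarning):
            mask = bh.find_well_trained_windows(trials, "w40")
        assert not mask.any()

    def test_block_criterion(self):
        # first 32-trial block has 6 correct unperturbed trials, second has 5
        pattern = ([True] * 6 + [False] * 26) + ([True] * 5 + [False] * 27)
        trials = self._cohort(pattern)
        mask = bh.find_well_trained_windows(trials, "block")
        assert mask[:32].all() and not mask[32:].any()


class TestMemoryDecayFit:
    def test_noiseless_parameter_recovery(self):
        delays = np.array([5.0, 8.0, 12.0, 20.0, 40.0])
        rates = 0.5 + 0.45 * np.exp(-delays / 20.0)
        fit = bh.fit_memory_decay(delays, rates)
        assert fit.amplitude_A == pytest.approx(0.45, abs=1e-6)
        assert fit.tau_s == pytest.approx(20.0, abs=1e-4)
        assert fit.asymptote == pytest.approx(0.5, abs=1e-6)
        assert fit.identifiable

    def test_constant_rates_flagged_unidentifiable(self):
        fit = bh.fit_memory_decay([5, 10, 20, 40], [0.5, 0.5, 0.5, 0.5])
        assert not fit.identifiable

    def test_too_few_delays_rejected(self):
        with pytest.raises(ValueError):
            bh.fit_memory_decay([5, 5, 5], [0.9, 0.8, 0.7])

    def test_asymptote_bounded_to_chance_neighbourhood(self):
        fit = bh.fit_memory_decay([2, 5, 10, 30], [0.99, 0.95, 0.9, 0.85])
        assert 0.45 <= fit.asymptote <= 0.6


class TestDualTaskInterference:
    @staticmethod
    def _dual_cohort(go_deficit=0.0, n_subjects=6, seed=0):
        spec = syn.BehaviorGenSpec(n_subjects=n_subjects,
                                   n_trials_per_subject=90)
        design = syn.TrialDesign(task="DUAL", delays_s=(13.0,))
        trials = syn.simulate_behavior_cohort(spec, design, seed=seed)
        if go_deficit:
            rng = np.random.default_rng(seed + 1)
            go = (trials["distractor"] == "go").to_numpy()
            flip = go & trials["outcome"].isin(["hit", "correct_rejection"]) \
                .to_numpy() & (rng.random(len(trials)) < go_deficit)
            trials.loc[flip & (trials["outcome"] == "hit"), "outcome"] = "miss"
            trials.loc[flip & (trials["outcome"] == "correct_rejection"),
                       "outcome"] = "false_alarm"
        return trials

    def test_summaries_per_distractor_condition(self):
        summaries, res = bh.dual_task_interference(self._dual_cohort())
        assert {s.group["distractor"] for s in summaries} == {"none", "go", "nogo"}
        assert res is not None

    def test_injected_go_deficit_detected(self):
        trials = self._dual_cohort(go_deficit=0.5, n_subjects=10, seed=3)
        _, res = bh.dual_task_interference(trials)
        assert res.p_value < 0.05

    def test_single_condition_returns_no_test(self):
        trials = self._dual_cohort()
        trials = trials[trials["distractor"] == "none"]
        summaries, res = bh.dual_task_interference(trials)
        assert len(summaries) == 1
        assert res is None

    def test_non_dual_task_rejected(self, dnms_cohort):
        with pytest.raises(ValueError):
            bh.dual_task_interference(dnms_cohort)
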