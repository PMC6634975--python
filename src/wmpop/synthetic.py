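"""Synthetic behavioural sessions and spike trains with the statistical
structure the analysis stack assumes.

The behavioural generator draws per-trial outcomes from an exponential
memory-decay performance model (correct probability decaying toward chance
with delay duration), with an optional optogenetic-suppression effect for
ChR2 animals perturbed during the delay, and schedules stimuli in balanced
four-trial blocks with trial- or block-interleaved laser conditions.

The spike generator produces inhomogeneous-Poisson units whose rate is
piecewise constant over trial epochs: a baseline, a multiplicative gain
during sample-odor delivery, an additive sample-selective component during
the delay that decays exponentially, a distractor-odor response mid-delay,
and attenuated selectivity in error trials.  Spikes are drawn by thinning a
homogeneous Poisson process, which is exactly reproducible given the seed.

Trial epochs (seconds from sample onset): sample odor [0, 1), delay
[1, 1 + delay), test odor [1 + delay, 2 + delay), response window
[3 + delay, 3.5 + delay).  A dual-task distractor cue occupies
[4, 4.5) (3 s into the delay).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import (SPIKE_COLUMNS, TRIAL_COLUMNS, expected_relation,
                        validate_trials)

__all__ = [
    "NeuronSpec",
    "BehaviorGenSpec",
    "LaserEffect",
    "TrialDesign",
    "simulate_behavior_cohort",
    "simulate_session",
    "make_population",
    "trial_epochs",
]

SAMPLE_ON_S = 0.0
SAMPLE_OFF_S = 1.0
ODOR_DURATION_S = 1.0
PRE_RESPONSE_DELAY_S = 1.0
RESPONSE_WINDOW_S = 0.5
DISTRACTOR_ONSET_IN_DELAY_S = 3.0
DISTRACTOR_DURATION_S = 0.5


def trial_epochs(delay_s: float) -> dict[str, tuple[float, float]]:
    """Epoch boundaries (half-open, seconds from sample onset) for a trial."""
    test_on = SAMPLE_OFF_S + delay_s
    return {
        "baseline": (-1.0, 0.0),
        "sample": (SAMPLE_ON_S, SAMPLE_OFF_S),
        "delay": (SAMPLE_OFF_S, test_on),
        "distractor": (SAMPLE_OFF_S + DISTRACTOR_ONSET_IN_DELAY_S,
                       SAMPLE_OFF_S + DISTRACTOR_ONSET_IN_DELAY_S + DISTRACTOR_DURATION_S),
        "test": (test_on, test_on + ODOR_DURATION_S),
        "response": (test_on + ODOR_DURATION_S + PRE_RESPONSE_DELAY_S,
                     test_on + ODOR_DURATION_S + PRE_RESPONSE_DELAY_S + RESPONSE_WINDOW_S),
    }


# ---------------------------------------------------------------------------
# Behavioural generator

@dataclass
class LaserEffect:
    """Drop in correct probability from delay-period suppression.

    The effect grows linearly with laser duration and with onset phase
    (fraction of the delay elapsed at laser onset; late onsets hurt more):
    ``drop = duration_slope * duration + phase_slope * phase``.  Applied only
    on laser-on trials of ChR2 animals with ``perturb_epoch == "delay"``.
    """
    duration_slope: float = 0.0   # probability drop per second of laser
    phase_slope: float = 0.0      # probability drop per unit onset phase

    def drop(self, duration_s: float, onset_phase: float) -> float:
        return self.duration_slope * duration_s + self.phase_slope * onset_phase


@dataclass
class BehaviorGenSpec:
    """Parameters of the exponential memory-decay performance model.

    P(correct | delay d) = chance + A * exp(-d / tau) minus any laser drop,
    mixed with a lapse process that responds at chance.
    """
    chance_level: float = 0.5
    amplitude_A: float = 0.45
    decay_tau_s: float = 20.0
    laser_effect: LaserEffect = field(default_factory=LaserEffect)
    lapse_rate: float = 0.0
    #: rewarded-relation bias: +bias/2 on nonmatch/paired trials, -bias/2 on
    #: match/unpaired trials (0 = symmetric performance)
    relation_bias: float = 0.0
    n_subjects: int = 10
    n_trials_per_subject: int = 200

    def correct_probability(self, delay_s: float, laser_drop: float = 0.0,
                            rewarded_relation: bool | None = None) -> float:
        base = self.chance_level + self.amplitude_A * np.exp(-delay_s / self.decay_tau_s)
        base = base - laser_drop
        if rewarded_relation is not None and self.relation_bias:
            base += (0.5 if rewarded_relation else -0.5) * self.relation_bias
        p = (1 - self.lapse_rate) * base + self.lapse_rate * self.chance_level
        return float(np.clip(p, 0.0, 1.0))


@dataclass
class TrialDesign:
    """Trial-schedule parameters for a simulated cohort.

    ``laser_scheme``: "none", "interleaved_trial" (one-trial-on,
    one-trial-off, starting off) or "interleaved_block" (alternating
    24-trial blocks, starting off).  ``delays_s`` cycles per 4-trial block.
    """
    task: str = "DNMS"
    delays_s: tuple[float, ...] = (8.0,)
    laser_scheme: str = "none"
    block_size: int = 24
    laser_onset_s: float = SAMPLE_OFF_S
    laser_duration_s: float | None = None   # None -> whole delay
    perturb_epoch: str = "delay"
    genotypes: tuple[str, ...] = ("ChR2", "control")
    distractor_fraction_none: float = 1 / 3   # dual-task only

    def __post_init__(self):
        if self.laser_scheme not in ("none", "interleaved_trial", "interleaved_block"):
            raise ValueError(f"unknown laser scheme {self.laser_scheme!r}")
        if self.laser_scheme == "interleaved_block" and self.block_size % 2 == 1:
            raise ValueError("block scheme requires an even block size")


_TASK_COMBOS = {
    # four balanced sample/relation combinations per shuffled block
    "DNMS": [("S1", "match"), ("S1", "nonmatch"), ("S2", "match"), ("S2", "nonmatch")],
    "NMS_WOD": [("S1", "match"), ("S1", "nonmatch"), ("S2", "match"), ("S2", "nonmatch")],
    "DPA": [("S1", "paired"), ("S1", "unpaired"), ("S2", "paired"), ("S2", "unpaired")],
    "DUAL": [("S1", "paired"), ("S1", "unpaired"), ("S2", "paired"), ("S2", "unpaired")],
}


def _test_odor_for(task: str, sample: str, relation: str) -> str | None:
    if task == "GNG":
        return None
    s = int(sample[1:])
    if task in ("DNMS", "NMS_WOD"):
        same = relation == "match"
    elif task in ("DPA", "DUAL"):
        same = relation == "paired"
    elif task == "MSDPA":
        paired_test = (s - 1) // 3 + 1
        return f"T{paired_test}" if relation == "paired" else f"T{3 - paired_test}"
    else:
        raise ValueError(task)
    return f"T{s}" if same else f"T{3 - s}"


def simulate_behavior_cohort(spec: BehaviorGenSpec, design: TrialDesign,
                             seed: int) -> pd.DataFrame:
    """Generate a validated trial table for a cohort of simulated subjects.

    Stimulus combinations are balanced within each shuffled 4-trial block,
    laser conditions follow the design's interleaving scheme, outcomes are
    Bernoulli draws from the performance model, and response-window licks
    are emitted exactly on hit and false-alarm trials.
    """
    rng = np.random.default_rng(seed)
    if design.task == "MSDPA":
        combos = None
    else:
        combos = _TASK_COMBOS[design.task]
    records = []
    trial_id = 0
    for subj in range(spec.n_subjects):
        genotype = design.genotypes[subj % len(design.genotypes)]
        subject_id = f"M{subj + 1:02d}"
        for t in range(spec.n_trials_per_subject):
            within = t % 4
            if within == 0:
                if combos is not None:
                    block = [combos[i] for i in rng.permutation(4)]
                else:
                    samples = [f"S{i + 1}" for i in rng.integers(0, 6, size=4)]
                    rels = ["paired", "paired", "unpaired", "unpaired"]
                    order = rng.permutation(4)
                    block = [(samples[i], rels[order[i]]) for i in range(4)]
                delay = design.delays_s[(t // 4) % len(design.delays_s)]
            sample, relation = block[within]
            test = _test_odor_for(design.task, sample, relation)
            if design.laser_scheme == "interleaved_trial":
                laser_on = t % 2 == 1
            elif design.laser_scheme == "interleaved_block":
                laser_on = (t // design.block_size) % 2 == 1
            else:
                laser_on = False
            perturb = design.perturb_epoch if laser_on else "none"
            laser_onset = design.laser_onset_s if laser_on else None
            laser_dur = None
            if laser_on:
                laser_dur = (design.laser_duration_s
                             if design.laser_duration_s is not None else delay)
            drop = 0.0
            if laser_on and genotype == "ChR2" and perturb == "delay":
                phase = (laser_onset - SAMPLE_OFF_S) / delay
                drop = spec.laser_effect.drop(laser_dur, float(np.clip(phase, 0, 1)))
            rewarded = relation in ("nonmatch", "paired", "go")
            p = spec.correct_probability(delay, drop, rewarded_relation=rewarded)
            correct = rng.random() < p
            if rewarded:
                outcome = "hit" if correct else "miss"
            else:
                outcome = "false_alarm" if not correct else "correct_rejection"
            epochs = trial_epochs(delay)
            w0, w1 = epochs["response"]
            licks: list[float] = []
            if outcome in ("hit", "false_alarm"):
                n_licks = int(rng.integers(2, 5))
                licks = sorted(w0 + rng.random(n_licks) * (w1 - w0) * 0.98)
                licks = list(np.unique(np.round(licks, 6)))
            if design.task == "DUAL":
                u = rng.random()
                if u < design.distractor_fraction_none:
                    distractor = "none"
                else:
                    distractor = "go" if u < (1 + design.distractor_fraction_none) / 2 else "nogo"
            else:
                distractor = None
            trial_id += 1
            records.append({
                "trial_id": trial_id, "task": design.task,
                "subject_id": subject_id, "genotype": genotype,
                "sample_odor": sample, "test_odor": test, "relation": relation,
                "delay_s": float(delay), "distractor": distractor,
                "laser_on": bool(laser_on), "laser_onset_s": laser_onset,
                "laser_duration_s": laser_dur, "perturb_epoch": perturb,
                "resp_win_start_s": w0, "resp_win_end_s": w1,
                "lick_times_s": licks, "outcome": outcome,
            })
    trials = pd.DataFrame.from_records(records, columns=TRIAL_COLUMNS)
    validate_trials(trials, source="<synthetic>")
    return trials


# ---------------------------------------------------------------------------
# Spike generator

@dataclass
class NeuronSpec:
    """Rate model of one Poisson unit.

    During sample delivery the baseline is scaled by the preferred/
    non-preferred odor gain; during the delay a selective component of
    ``+/- delay_selectivity_hz/2 * exp(-t_since_delay/tau)`` is added
    (positive for the preferred sample), attenuated by
    ``error_trial_attenuation`` on error trials; a distractor cue scales the
    baseline by ``distractor_gain`` while it is on.  Rates clip at 0.
    """
    baseline_rate_hz: float = 5.0
    odor_gain: float = 2.0            # gain for the preferred sample odor
    odor_gain_nonpref: float = 1.0
    delay_selectivity_hz: float = 0.0
    selectivity_decay_tau_s: float = 8.0
    error_trial_attenuation: float = 1.0
    distractor_gain: float = 1.0
    preferred_sample: str = "S1"
    #: None -> the distractor gain applies to any distractor cue; "go" or
    #: "nogo" restricts it to one cue, giving the unit cue information
    preferred_distractor: str | None = None
    refractory_s: float = 0.0025   # dead time after each spike, as in real units

    def __post_init__(self):
        if self.baseline_rate_hz <= 0:
            raise ValueError("baseline_rate_hz must be > 0")
        if self.selectivity_decay_tau_s <= 0:
            raise ValueError("selectivity_decay_tau_s must be > 0")
        if not 0 <= self.error_trial_attenuation <= 1:
            raise ValueError("error_trial_attenuation must be in [0, 1]")
        for g in (self.odor_gain, self.odor_gain_nonpref, self.distractor_gain):
            if g < 0:
                raise ValueError("gains must be nonnegative")


_ERROR_OUTCOMES = {"miss", "false_alarm"}
_RATE_DT_S = 0.001   # piecewise-constant rate resolution for thinning


def _rate_profile(neuron: NeuronSpec, trial, t0: float, t1: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant rate lambda(t) on a 1 ms grid over [t0, t1)."""
    n = max(int(round((t1 - t0) / _RATE_DT_S)), 0)
    t = t0 + _RATE_DT_S * np.arange(n)
    lam = np.full(n, neuron.baseline_rate_hz)
    epochs = trial_epochs(trial.delay_s)
    s0, s1 = epochs["sample"]
    in_sample = (t >= s0) & (t < s1)
    gain = (neuron.odor_gain if trial.sample_odor == neuron.preferred_sample
            else neuron.odor_gain_nonpref)
    lam[in_sample] = neuron.baseline_rate_hz * gain
    d0, d1 = epochs["delay"]
    in_delay = (t >= d0) & (t < d1)
    sign = 1.0 if trial.sample_odor == neuron.preferred_sample else -1.0
    atten = (neuron.error_trial_attenuation
             if getattr(trial, "outcome", None) in _ERROR_OUTCOMES else 1.0)
    sel = (sign * neuron.delay_selectivity_hz / 2.0
           * np.exp(-(t[in_delay] - d0) / neuron.selectivity_decay_tau_s))
    lam[in_delay] = lam[in_delay] + atten * sel
    dist = getattr(trial, "distractor", None)
    if isinstance(dist, float):   # NaN-encoded absence
        dist = None
    if dist not in (None, "none") and (neuron.preferred_distractor is None
                                       or dist == neuron.preferred_distractor):
        g0, g1 = epochs["distractor"]
        in_dist = (t >= g0) & (t < g1)
        lam[in_dist] = lam[in_dist] * neuron.distractor_gain
    return t, np.clip(lam, 0.0, None)


def simulate_session(neurons: list[NeuronSpec], trials: pd.DataFrame,
                     seed: int,
                     window: tuple[float, float] | None = None) -> pd.DataFrame:
    """Inhomogeneous-Poisson spike trains for every (unit, trial).

    Spikes are generated by thinning a homogeneous process at the trial's
    peak rate; the default window spans the 1 s pre-sample baseline through
    the end of the response window.  Deterministic given (inputs, seed).
    """
    rng = np.random.default_rng(seed)
    records = []
    for ui, neuron in enumerate(neurons):
        unit_id = f"u{ui + 1:03d}"
        for trial in trials.itertuples():
            if window is None:
                t0, t1 = -1.0, float(trial.resp_win_end_s)
            else:
                t0, t1 = window
            if t1 <= t0:
                continue
            t_grid, lam = _rate_profile(neuron, trial, t0, t1)
            lam_max = float(lam.max(initial=0.0))
            times: np.ndarray
            if lam_max <= 0:
                times = np.empty(0)
            else:
                n_cand = rng.poisson(lam_max * (t1 - t0))
                cand = np.sort(rng.random(n_cand) * (t1 - t0) + t0)
                idx = np.minimum(((cand - t0) / _RATE_DT_S).astype(int),
                                 lam.size - 1)
                keep = rng.random(n_cand) < lam[idx] / lam_max
                times = np.unique(cand[keep])
                if neuron.refractory_s > 0 and times.size > 1:
                    kept = [times[0]]
                    for t_sp in times[1:]:
                        if t_sp - kept[-1] >= neuron.refractory_s:
                            kept.append(t_sp)
                    times = np.asarray(kept)
            records.append({"unit_id": unit_id,
                            "trial_id": int(trial.trial_id),
                            "spike_times_s": [float(x) for x in times]})
    return pd.DataFrame.from_records(records, columns=SPIKE_COLUMNS)


def make_population(n_units: int, selective_fraction: float,
                    seed: int,
                    baseline_rate_hz: float = 5.0,
                    delay_selectivity_hz: float = 8.0,
                    selectivity_decay_tau_s: float = 8.0,
                    error_trial_attenuation: float = 0.3,
                    odor_gain: float = 2.0,
                    distractor_gain: float = 1.0) -> list[NeuronSpec]:
    """A population with a configurable fraction of sample-selective units.

    Selective units alternate preferred samples; non-selective units keep
    the baseline model (no odor gain, no delay selectivity).
    """
    if not 0 <= selective_fraction <= 1:
        raise ValueError("selective_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_sel = int(round(n_units * selective_fraction))
    specs = []
    for i in range(n_units):
        base = baseline_rate_hz * float(rng.uniform(0.7, 1.3))
        if i < n_sel:
            specs.append(NeuronSpec(
                baseline_rate_hz=base, odor_gain=odor_gain,
                delay_selectivity_hz=delay_selectivity_hz,
                selectivity_decay_tau_s=selectivity_decay_tau_s,
                error_trial_attenuation=error_trial_attenuation,
                distractor_gain=distractor_gain,
                preferred_sample="S1" if i % 2 == 0 else "S2"))
        else:
            specs.append(NeuronSpec(baseline_rate_hz=base, odor_gain=1.0,
                                    odor_gain_nonpref=1.0))
    return specs


def provenance_dict(spec: BehaviorGenSpec, design: TrialDesign,
                    neurons: list[NeuronSpec] | None, seed: int) -> dict:
    """Full echo of the generating configuration, for provenance JSON."""
    return {
        "seed": seed,
        "behavior_spec": dataclasses.asdict(spec),
        "trial_design": dataclasses.asdict(design),
        "neurons": [dataclasses.asdict(n) for n in (neurons or [])],
    }
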