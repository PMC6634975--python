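"""Trial-outcome classification and behavioural performance metrics.

Outcomes follow the licking convention of go/no-go style olfactory tasks:
a lick inside the half-open response window on a rewarded-type trial
(nonmatch / paired / go) is a hit; the same lick on an unrewarded-type trial
is a false alarm; withholding yields a correct rejection or a miss.
Performance (the "correct rate") is the fraction of hits plus correct
rejections, d' is the inverse-normal-transformed hit rate minus the
inverse-normal-transformed false-choice rate, and lick efficiency is the
fraction of response-window licks that were rewarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_data import REWARDED_RELATIONS
from .resampling import TestResult

__all__ = [
    "BehaviorSummary",
    "MemoryDecayFit",
    "WellTrainedCriterion",
    "classify_outcomes",
    "summarize_performance",
    "find_well_trained_windows",
    "fit_memory_decay",
    "dual_task_interference",
]

CORRECT_OUTCOMES = {"hit", "correct_rejection"}


@dataclass
class BehaviorSummary:
    group: dict
    n_trials: int
    correct_rate: float
    hit_rate: float | None
    miss_rate: float | None
    false_alarm_rate: float | None
    correct_rejection_rate: float | None
    d_prime: float | None
    lick_efficiency: float | None


@dataclass
class MemoryDecayFit:
    """Exponential memory-decay model C(d) = asymptote + A * exp(-d / tau)."""
    amplitude_A: float
    tau_s: float
    asymptote: float
    residual_sse: float
    converged: bool
    identifiable: bool


def _licked_in_window(lick_times, start, end) -> bool:
    return any(start <= t < end for t in lick_times)


def classify_outcomes(trials: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``outcome`` column from licks, response window and relation.

    Pure function of (lick_times_s, response window, relation); idempotent.
    """
    if trials["relation"].isna().any():
        raise ValueError("relation must be present on every trial")
    out = trials.copy()
    outcomes = []
    for row in out.itertuples():
        licked = _licked_in_window(row.lick_times_s, row.resp_win_start_s,
                                   row.resp_win_end_s)
        rewarded = row.relation in REWARDED_RELATIONS
        if licked:
            outcomes.append("hit" if rewarded else "false_alarm")
        else:
            outcomes.append("miss" if rewarded else "correct_rejection")
    out["outcome"] = outcomes
    return out


def _d_prime(hit_rate: float, fa_rate: float, n_go: int, n_nogo: int) -> float:
    # clamp 0/1 rates to 1/(2n) resp. 1 - 1/(2n) to keep norminv finite
    hr = min(max(hit_rate, 1 / (2 * n_go)), 1 - 1 / (2 * n_go))
    fr = min(max(fa_rate, 1 / (2 * n_nogo)), 1 - 1 / (2 * n_nogo))
    return float(stats.norm.ppf(hr) - stats.norm.ppf(fr))


def summarize_performance(trials: pd.DataFrame,
                          group_by: Sequence[str] = ()) -> list[BehaviorSummary]:
    """Per-group outcome rates, d' and lick efficiency.

    d' is reported absent for groups lacking go-type or nogo-type trials.
    Lick efficiency counts response-window licks only: rewarded licks occur
    on hit trials, unrewarded ones on false-alarm trials.
    """
    if trials["outcome"].isna().any():
        raise ValueError("outcomes must be filled; run classify_outcomes first")
    group_by = list(group_by)
    groups = trials.groupby(group_by, sort=True) if group_by else [((), trials)]
    summaries = []
    for key, grp in groups:
        if group_by:
            key = key if isinstance(key, tuple) else (key,)
            gdict = dict(zip(group_by, key))
        else:
            gdict = {}
        n = len(grp)
        counts = grp["outcome"].value_counts()
        hits = int(counts.get("hit", 0))
        misses = int(counts.get("miss", 0))
        fas = int(counts.get("false_alarm", 0))
        crs = int(counts.get("correct_rejection", 0))
        n_go = hits + misses
        n_nogo = fas + crs
        hit_rate = hits / n_go if n_go else None
        fa_rate = fas / n_nogo if n_nogo else None
        d_prime = _d_prime(hit_rate, fa_rate, n_go, n_nogo) if n_go and n_nogo else None
        rewarded_licks = sum(
            sum(1 for t in r.lick_times_s if r.resp_win_start_s <= t < r.resp_win_end_s)
            for r in grp.itertuples() if r.outcome == "hit")
        unrewarded_licks = sum(
            sum(1 for t in r.lick_times_s if r.resp_win_start_s <= t < r.resp_win_end_s)
            for r in grp.itertuples() if r.outcome == "false_alarm")
        total_licks = rewarded_licks + unrewarded_licks
        summaries.append(BehaviorSummary(
            group=gdict, n_trials=n,
            correct_rate=(hits + crs) / n,
            hit_rate=hit_rate,
            miss_rate=misses / n_go if n_go else None,
            false_alarm_rate=fa_rate,
            correct_rejection_rate=crs / n_nogo if n_nogo else None,
            d_prime=d_prime,
            lick_efficiency=rewarded_licks / total_licks if total_licks else None))
    return summaries


@dataclass(frozen=True)
class WellTrainedCriterion:
    """Inclusion criterion over unperturbed (laser-off) trials.

    kind="window": any run of ``n`` consecutive unperturbed trials with
    correct fraction >= ``threshold`` qualifies (>= is inclusive: 32/40
    qualifies at the 80% criterion).  kind="block": trials are cut into
    fixed blocks of ``block_size``; a block qualifies when at least
    ``min_correct`` of its unperturbed trials are correct.
    """
    kind: str = "window"
    n: int = 40
    threshold: float = 0.8
    block_size: int = 32
    min_correct: int = 6

    @classmethod
    def parse(cls, name: str) -> "WellTrainedCriterion":
        name = name.lower()
        if name in ("w40", "window40"):
            return cls("window", n=40)
        if name in ("w20", "window20"):
            return cls("window", n=20)
        if name in ("block", "b32"):
            return cls("block")
        raise ValueError(f"unknown criterion {name!r}")


def find_well_trained_windows(trials: pd.DataFrame,
                              criterion: WellTrainedCriterion | str = "w40"
                              ) -> np.ndarray:
    """Boolean mask of trials lying inside at least one qualifying window.

    Windows are evaluated over unperturbed (laser-off) trials only; a
    qualifying window then flags every trial — including interleaved
    laser-on trials — within the original-index span it covers.
    """
    if isinstance(criterion, str):
        criterion = WellTrainedCriterion.parse(criterion)
    if trials["outcome"].isna().any():
        raise ValueError("outcomes must be filled; run classify_outcomes first")
    correct = trials["outcome"].isin(CORRECT_OUTCOMES).to_numpy()
    laser_off = ~trials["laser_on"].to_numpy(dtype=bool)
    mask = np.zeros(len(trials), dtype=bool)
    if criterion.kind == "window":
        off_idx = np.nonzero(laser_off)[0]
        if off_idx.size < criterion.n:
            warnings.warn("fewer unperturbed trials than the window size; "
                          "no trials qualify", UserWarning, stacklevel=2)
            return mask
        off_correct = correct[off_idx].astype(float)
        csum = np.concatenate([[0.0], np.cumsum(off_correct)])
        for s in range(off_idx.size - criterion.n + 1):
            frac = (csum[s + criterion.n] - csum[s]) / criterion.n
            if frac >= criterion.threshold - 1e-12:
                lo, hi = off_idx[s], off_idx[s + criterion.n - 1]
                mask[lo:hi + 1] = True
        return mask
    if criterion.kind == "block":
        for b0 in range(0, len(trials), criterion.block_size):
            b1 = min(b0 + criterion.block_size, len(trials))
            sel = slice(b0, b1)
            n_corr = int((correct[sel] & laser_off[sel]).sum())
            if n_corr >= criterion.min_correct:
                mask[sel] = True
        return mask
    raise ValueError(f"unknown criterion kind {criterion.kind!r}")


def fit_memory_decay(delays_s, correct_rates,
                     asymptote_bounds: tuple[float, float] = (0.45, 0.6)
                     ) -> MemoryDecayFit:
    """Least-squares fit of the exponential performance-decay model.

    C(d) = asymptote + A * exp(-d / tau), with the asymptote free but
    bounded to the chance neighbourhood for a two-alternative task.  A fit
    with A ~ 0 is flagged unidentifiable (tau is then meaningless).
    """
    d = np.asarray(delays_s, dtype=float)
    c = np.asarray(correct_rates, dtype=float)
    if np.unique(d).size < 3:
        raise ValueError("need at least 3 distinct delays")

    def model(x, asym, amp, tau):
        return asym + amp * np.exp(-x / tau)

    lo = [asymptote_bounds[0], 0.0, 1e-3]
    hi = [asymptote_bounds[1], 1.0, 1e4]
    p0 = [0.5, max(min(c.max() - 0.5, 1.0), 1e-3), max(np.median(d), 1.0)]
    try:
        popt, _ = optimize.curve_fit(model, d, c, p0=p0, bounds=(lo, hi),
                                     maxfev=20000)
        converged = True
    except RuntimeError:
        popt = p0
        converged = False
    asym, amp, tau = (float(v) for v in popt)
    sse = float(np.sum((model(d, *popt) - c) ** 2))
    fit = MemoryDecayFit(amplitude_A=amp, tau_s=tau, asymptote=asym,
                         residual_sse=sse, converged=converged,
                         identifiable=amp > 1e-3)
    if not converged:
        raise RuntimeError(f"memory-decay fit did not converge; best so far: {fit}")
    return fit


def dual_task_interference(trials: pd.DataFrame
                           ) -> tuple[list[BehaviorSummary], TestResult | None]:
    """Outer-task performance split by distractor condition, with a
    one-way repeated-measures test across conditions (subjects repeated).

    Returns per-condition summaries and the omnibus statistic (absent when
    fewer than 2 subjects or a single condition is present).
    """
    import pingouin as pg

    if not (trials["task"] == "DUAL").all():
        raise ValueError("dual-task interference requires task == DUAL trials")
    if trials["distractor"].isna().any():
        raise ValueError("distractor condition must be present on every trial")
    summaries = summarize_performance(trials, group_by=["distractor"])
    conditions = sorted(trials["distractor"].unique())
    subjects = trials["subject_id"].unique()
    if len(conditions) < 2 or len(subjects) < 2:
        return summaries, None
    rows = []
    for (subj, cond), grp in trials.groupby(["subject_id", "distractor"]):
        rows.append({"subject": subj, "condition": cond,
                     "correct": grp["outcome"].isin(CORRECT_OUTCOMES).mean()})
    long = pd.DataFrame(rows)
    aov = pg.rm_anova(data=long, dv="correct", within="condition", subject="subject")
    row = aov.iloc[0]
    return summaries, TestResult(float(row["F"]), float(row["p_unc"]),
                                 n_repeats=0, method="rm-anova")
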