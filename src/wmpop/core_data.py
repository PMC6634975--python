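"""Data model, file IO, spike binning/normalisation and unit quality control.

Trial-structured behavioural sessions are represented as a pandas DataFrame
(one row per trial) and spike trains as a DataFrame with one row per
(unit, trial), holding spike times relative to sample-odor onset (t = 0).
All timestamps are trial-relative seconds; windows are half-open
``[start, stop)``.

The on-disk format is a plain TSV dialect: UTF-8, header row, tab-separated,
lists encoded as comma-joined decimals, missing values as empty fields.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "SPIKE_COLUMNS",
    "TASKS",
    "RELATIONS",
    "FormatError",
    "IntegrityError",
    "BinnedRateMatrix",
    "UnitQCReport",
    "DegenerateBaselineWarning",
    "read_trials",
    "read_spikes",
    "write_trials",
    "write_spikes",
    "load_session",
    "validate_trials",
    "validate_spikes",
    "bin_spikes",
    "zscore_to_baseline",
    "unzscore",
    "qc_filter_units",
]

# ---------------------------------------------------------------------------
# Schema

TRIAL_COLUMNS = [
    "trial_id", "task", "subject_id", "genotype", "sample_odor", "test_odor",
    "relation", "delay_s", "distractor", "laser_on", "laser_onset_s",
    "laser_duration_s", "perturb_epoch", "resp_win_start_s", "resp_win_end_s",
    "lick_times_s", "outcome",
]
SPIKE_COLUMNS = ["unit_id", "trial_id", "spike_times_s"]

TASKS = {"DNMS", "DPA", "GNG", "NMS_WOD", "MSDPA", "DUAL"}
RELATIONS = {"match", "nonmatch", "paired", "unpaired", "go", "nogo"}
DISTRACTORS = {"none", "go", "nogo"}
PERTURB_EPOCHS = {"none", "baseline", "delay"}
GENOTYPES = {"ChR2", "control"}
SAMPLE_ODORS = {f"S{i}" for i in range(1, 7)}
TEST_ODORS = {"T1", "T2"}

#: relations on which a lick in the response window is rewarded
REWARDED_RELATIONS = {"nonmatch", "paired", "go"}

# Per-task sample universe and admissible relations.
_TASK_SAMPLES = {
    "DNMS": {"S1", "S2"},
    "NMS_WOD": {"S1", "S2"},
    "DPA": {"S1", "S2"},
    "DUAL": {"S1", "S2"},
    "GNG": {"S1", "S2"},
    "MSDPA": SAMPLE_ODORS,
}
_TASK_RELATIONS = {
    "DNMS": {"match", "nonmatch"},
    "NMS_WOD": {"match", "nonmatch"},
    "DPA": {"paired", "unpaired"},
    "DUAL": {"paired", "unpaired"},
    "MSDPA": {"paired", "unpaired"},
    "GNG": {"go", "nogo"},
}


class FormatError(ValueError):
    """A session file violates the TSV dialect or the column schema."""


class IntegrityError(ValueError):
    """Tables parse but violate a cross-field or cross-table invariant."""


class DegenerateBaselineWarning(UserWarning):
    """A unit had zero baseline variance; SD was substituted with 1."""


def expected_relation(task: str, sample_odor: str, test_odor: str | None) -> str | None:
    """Relation implied by (sample, test) under the task's pairing map.

    DNMS / NMS_WOD: the test repeats (match) or differs from (nonmatch) the
    sample, with T1/T2 standing for the same odorants as S1/S2.  DPA / DUAL:
    S1-T1 and S2-T2 are the rewarded pairs.  MS-DPA: S1-S3 pair with T1 and
    S4-S6 with T2.  GNG has no test odor; the relation is free (go/nogo).
    """
    if task == "GNG":
        return None
    if test_odor is None:
        return None
    t = int(test_odor[1:])
    s = int(sample_odor[1:])
    if task in ("DNMS", "NMS_WOD"):
        return "match" if s == t else "nonmatch"
    if task in ("DPA", "DUAL"):
        return "paired" if s == t else "unpaired"
    if task == "MSDPA":
        return "paired" if (s - 1) // 3 + 1 == t else "unpaired"
    raise ValueError(f"unknown task {task!r}")


# ---------------------------------------------------------------------------
# Canonical TSV encoding

def _fmt_float(x: float) -> str:
    return repr(float(x))


def _fmt_list(xs: Iterable[float]) -> str:
    return ",".join(_fmt_float(x) for x in xs)


def _fmt_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and math.isnan(value):
        return ""
    if isinstance(value, (bool, np.bool_)):
        return "true" if value else "false"
    if isinstance(value, (list, tuple, np.ndarray)):
        return _fmt_list(value)
    if isinstance(value, (float, np.floating)):
        return _fmt_float(value)
    return str(value)


def _parse_list(cell: str) -> list[float]:
    cell = cell.strip()
    if not cell:
        return []
    return [float(tok) for tok in cell.split(",")]


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table in the canonical TSV dialect (column order fixed)."""
    lines = ["\t".join(TRIAL_COLUMNS)]
    for _, row in trials.iterrows():
        lines.append("\t".join(_fmt_cell(row[c]) for c in TRIAL_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_spikes(spikes: pd.DataFrame, path: str | Path) -> None:
    lines = ["\t".join(SPIKE_COLUMNS)]
    for _, row in spikes.iterrows():
        lines.append("\t".join(_fmt_cell(row[c]) for c in SPIKE_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _err(path, lineno, msg) -> FormatError:
    return FormatError(f"{path}:{lineno}: {msg}")


def read_trials(path: str | Path) -> pd.DataFrame:
    """Parse and validate a trials TSV; errors carry 1-based line numbers."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise _err(path, 1, "empty file")
    header = lines[0].split("\t")
    if header != TRIAL_COLUMNS:
        missing = [c for c in TRIAL_COLUMNS if c not in header]
        raise _err(path, 1, f"bad header; missing/misordered columns {missing or header}")
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(TRIAL_COLUMNS):
            raise _err(path, lineno, f"expected {len(TRIAL_COLUMNS)} fields, got {len(cells)}")
        raw = dict(zip(TRIAL_COLUMNS, cells))
        try:
            rec = {
                "trial_id": int(raw["trial_id"]),
                "task": raw["task"],
                "subject_id": raw["subject_id"],
                "genotype": raw["genotype"],
                "sample_odor": raw["sample_odor"],
                "test_odor": raw["test_odor"] or None,
                "relation": raw["relation"],
                "delay_s": float(raw["delay_s"]),
                "distractor": raw["distractor"] or None,
                "laser_on": {"true": True, "false": False}[raw["laser_on"]],
                "laser_onset_s": float(raw["laser_onset_s"]) if raw["laser_onset_s"] else None,
                "laser_duration_s": float(raw["laser_duration_s"]) if raw["laser_duration_s"] else None,
                "perturb_epoch": raw["perturb_epoch"],
                "resp_win_start_s": float(raw["resp_win_start_s"]),
                "resp_win_end_s": float(raw["resp_win_end_s"]),
                "lick_times_s": _parse_list(raw["lick_times_s"]),
                "outcome": raw["outcome"] or None,
            }
        except (ValueError, KeyError) as exc:
            raise _err(path, lineno, f"cannot parse row: {exc}") from exc
        records.append(rec)
    trials = pd.DataFrame.from_records(records, columns=TRIAL_COLUMNS)
    validate_trials(trials, source=str(path))
    return trials


def read_spikes(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise _err(path, 1, "empty file")
    if lines[0].split("\t") != SPIKE_COLUMNS:
        raise _err(path, 1, f"bad header, expected {SPIKE_COLUMNS}")
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != 3:
            raise _err(path, lineno, f"expected 3 fields, got {len(cells)}")
        try:
            records.append({
                "unit_id": cells[0],
                "trial_id": int(cells[1]),
                "spike_times_s": _parse_list(cells[2]),
            })
        except ValueError as exc:
            raise _err(path, lineno, f"cannot parse row: {exc}") from exc
        times = records[-1]["spike_times_s"]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise IntegrityError(
                f"{path}:{lineno}: spike times not strictly sorted for unit "
                f"{cells[0]!r} trial {cells[1]}")
    return pd.DataFrame.from_records(records, columns=SPIKE_COLUMNS)


def validate_trials(trials: pd.DataFrame, source: str = "<trials>") -> None:
    """Raise on any schema or invariant violation, naming the offending row."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise FormatError(f"{source}: missing required columns {missing}")
    seen_ids = set()
    for idx, row in trials.iterrows():

        def bad(msg):
            return IntegrityError(f"{source} row {idx} (trial {row['trial_id']}): {msg}")

        if row["trial_id"] < 1:
            raise bad("trial_id must be >= 1")
        if row["trial_id"] in seen_ids:
            raise bad("duplicate trial_id")
        seen_ids.add(row["trial_id"])
        if row["task"] not in TASKS:
            raise bad(f"unknown task {row['task']!r}")
        if row["genotype"] not in GENOTYPES:
            raise bad(f"unknown genotype {row['genotype']!r}")
        if row["sample_odor"] not in _TASK_SAMPLES[row["task"]]:
            raise bad(f"sample_odor {row['sample_odor']!r} invalid under task {row['task']}")
        if row["test_odor"] is not None and row["test_odor"] not in TEST_ODORS:
            raise bad(f"test_odor {row['test_odor']!r} invalid")
        if row["relation"] not in _TASK_RELATIONS[row["task"]]:
            raise bad(f"relation {row['relation']!r} invalid under task {row['task']}")
        expect = expected_relation(row["task"], row["sample_odor"], row["test_odor"])
        if expect is not None and row["relation"] != expect:
            raise bad(f"relation {row['relation']!r} inconsistent with stimuli (expected {expect})")
        if not row["delay_s"] > 0:
            raise bad("delay_s must be > 0")
        if row["distractor"] is not None and row["distractor"] not in DISTRACTORS:
            raise bad(f"distractor {row['distractor']!r} invalid")
        if row["perturb_epoch"] not in PERTURB_EPOCHS:
            raise bad(f"perturb_epoch {row['perturb_epoch']!r} invalid")
        def absent(v):
            return v is None or (isinstance(v, float) and math.isnan(v))

        if row["laser_on"]:
            if absent(row["laser_onset_s"]) or absent(row["laser_duration_s"]):
                raise bad("laser_on trials require laser_onset_s and laser_duration_s")
        else:
            if not absent(row["laser_onset_s"]) or not absent(row["laser_duration_s"]):
                raise bad("laser fields must be absent when laser_on is false")
        if not row["resp_win_start_s"] < row["resp_win_end_s"]:
            raise bad("response window start must precede end")
        licks = row["lick_times_s"]
        if any(b <= a for a, b in zip(licks, licks[1:])):
            raise bad("lick_times_s must be strictly sorted")
        if row["outcome"] is not None and row["outcome"] not in {
                "hit", "miss", "false_alarm", "correct_rejection"}:
            raise bad(f"outcome {row['outcome']!r} invalid")


def validate_spikes(spikes: pd.DataFrame, trials: pd.DataFrame,
                    source: str = "<spikes>") -> None:
    known = set(trials["trial_id"])
    for idx, row in spikes.iterrows():
        if row["trial_id"] not in known:
            raise IntegrityError(
                f"{source} row {idx}: spike row references unknown trial {row['trial_id']}")
        times = row["spike_times_s"]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise IntegrityError(
                f"{source} row {idx}: spike times not strictly sorted")


def load_session(trials_path: str | Path,
                 spikes_path: str | Path | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Load and cross-validate a behavioural session (and optional spikes)."""
    trials = read_trials(trials_path)
    spikes = None
    if spikes_path is not None:
        spikes = read_spikes(spikes_path)
        validate_spikes(spikes, trials, source=str(spikes_path))
    return trials, spikes


# ---------------------------------------------------------------------------
# Binning and normalisation

@dataclass
class BinnedRateMatrix:
    """Firing rates, units x trials x bins.

    ``rates`` is in Hz for raw matrices and in Z-score units after
    :func:`zscore_to_baseline`.  Bins are half-open ``[start, start+width)``
    anchored at ``window[0]`` and advancing by ``step_s``; overlapping bins
    (step < width) are allowed.
    """

    rates: np.ndarray
    bin_width_s: float
    step_s: float
    window: tuple[float, float]
    unit_ids: list
    trial_ids: list
    normalized: bool = False
    baseline_window: tuple[float, float] | None = None
    #: per-unit (mean, sd) used for normalisation, for exact inversion
    baseline_stats: np.ndarray | None = None
    degenerate_units: list = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return self.rates.shape[2]

    @property
    def bin_starts(self) -> np.ndarray:
        return self.window[0] + self.step_s * np.arange(self.n_bins)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_starts + self.bin_width_s / 2.0

    def unit_index(self, unit_id) -> int:
        return self.unit_ids.index(unit_id)


def n_bins_for(window: tuple[float, float], bin_width_s: float, step_s: float) -> int:
    t0, t1 = window
    return int(math.floor((t1 - t0 - bin_width_s) / step_s + 1e-9)) + 1


def _trial_spans(trials: pd.DataFrame) -> dict[int, tuple[float, float]]:
    # Recording span per trial: 1 s pre-sample baseline through the end of
    # the response window.
    return {int(r.trial_id): (-1.0, float(r.resp_win_end_s))
            for r in trials.itertuples()}


def bin_spikes(spikes: pd.DataFrame, trials: pd.DataFrame,
               bin_width_s: float, step_s: float,
               window: tuple[float, float],
               check_span: bool = True) -> BinnedRateMatrix:
    """Bin spike times into firing rates (Hz) on a sliding-window grid.

    The rate in bin *b* of unit *u*, trial *k* is the spike count in
    ``[t0 + b*step, t0 + b*step + width)`` divided by the bin width.
    """
    if bin_width_s <= 0 or step_s <= 0:
        raise ValueError("bin_width_s and step_s must be > 0")
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must be non-empty")
    nb = n_bins_for(window, bin_width_s, step_s)
    if nb < 1:
        raise ValueError("window shorter than one bin")
    if check_span:
        spans = _trial_spans(trials)
        offending = [tid for tid, (a, b) in spans.items() if t0 < a or t0 + (nb - 1) * step_s + bin_width_s > b]
        if offending:
            raise ValueError(
                f"binning window {window} outside recorded span for trials {sorted(offending)}")

    unit_ids = list(dict.fromkeys(spikes["unit_id"]))
    trial_ids = [int(t) for t in trials["trial_id"]]
    u_index = {u: i for i, u in enumerate(unit_ids)}
    t_index = {t: i for i, t in enumerate(trial_ids)}
    starts = t0 + step_s * np.arange(nb)
    rates = np.zeros((max(len(unit_ids), 1), len(trial_ids), nb))
    for row in spikes.itertuples():
        ui = u_index[row.unit_id]
        ti = t_index.get(int(row.trial_id))
        if ti is None:
            raise IntegrityError(f"spike row references unknown trial {row.trial_id}")
        times = np.asarray(row.spike_times_s, dtype=float)
        lo = np.searchsorted(times, starts, side="left")
        hi = np.searchsorted(times, starts + bin_width_s, side="left")
        rates[ui, ti, :] = (hi - lo) / bin_width_s
    if not unit_ids:
        rates = np.zeros((0, len(trial_ids), nb))
    return BinnedRateMatrix(rates=rates, bin_width_s=bin_width_s, step_s=step_s,
                            window=(t0, t1), unit_ids=unit_ids, trial_ids=trial_ids)


def _baseline_bin_mask(binned: BinnedRateMatrix,
                       baseline_window: tuple[float, float]) -> np.ndarray:
    b0, b1 = baseline_window
    starts = binned.bin_starts
    mask = (starts >= b0 - 1e-9) & (starts + binned.bin_width_s <= b1 + 1e-9)
    if not mask.any():
        raise ValueError("no bins fall inside the baseline window")
    return mask


def zscore_to_baseline(binned: BinnedRateMatrix,
                       baseline_window: tuple[float, float],
                       trial_mask: np.ndarray | None = None) -> BinnedRateMatrix:
    """Z-score each unit's rates against its pre-sample baseline activity.

    Baseline statistics are the mean and SD of the unit's baseline-window bin
    values pooled over all included trials, so that after normalisation the
    baseline bins themselves have mean 0 and SD 1 per unit.  A unit with zero
    baseline SD gets SD substituted by 1 (its z-values stay finite and its
    constancy is flagged via :class:`DegenerateBaselineWarning`).
    """
    if binned.normalized:
        raise ValueError("matrix is already normalized")
    mask = _baseline_bin_mask(binned, baseline_window)
    if trial_mask is None:
        trial_mask = np.ones(len(binned.trial_ids), dtype=bool)
    base = binned.rates[:, trial_mask][:, :, mask]   # units x trials x base-bins
    mean = base.reshape(base.shape[0], -1).mean(axis=1)
    sd = base.reshape(base.shape[0], -1).std(axis=1, ddof=0)
    degenerate = [binned.unit_ids[i] for i in np.nonzero(sd == 0)[0]]
    if degenerate:
        warnings.warn(f"zero baseline SD for units {degenerate}; substituting SD=1",
                      DegenerateBaselineWarning, stacklevel=2)
    sd = np.where(sd == 0, 1.0, sd)
    z = (binned.rates - mean[:, None, None]) / sd[:, None, None]
    return BinnedRateMatrix(
        rates=z, bin_width_s=binned.bin_width_s, step_s=binned.step_s,
        window=binned.window, unit_ids=list(binned.unit_ids),
        trial_ids=list(binned.trial_ids), normalized=True,
        baseline_window=baseline_window,
        baseline_stats=np.column_stack([mean, sd]),
        degenerate_units=degenerate)


def unzscore(binned: BinnedRateMatrix) -> BinnedRateMatrix:
    """Invert :func:`zscore_to_baseline` using the stored baseline statistics."""
    if not binned.normalized or binned.baseline_stats is None:
        raise ValueError("matrix is not normalized or lacks baseline statistics")
    mean = binned.baseline_stats[:, 0]
    sd = binned.baseline_stats[:, 1]
    raw = binned.rates * sd[:, None, None] + mean[:, None, None]
    return BinnedRateMatrix(
        rates=raw, bin_width_s=binned.bin_width_s, step_s=binned.step_s,
        window=binned.window, unit_ids=list(binned.unit_ids),
        trial_ids=list(binned.trial_ids), normalized=False)


# ---------------------------------------------------------------------------
# Single-unit quality control

@dataclass
class UnitQCReport:
    unit_id: object
    n_spikes: int
    isi_violation_fraction: float
    mean_rate_hz: float
    passes: bool


#: single-unit inclusion thresholds: ISI false-alarm fraction at the 2 ms
#: refractory period, and the minimum mean firing rate
ISI_REFRACTORY_S = 0.002
ISI_VIOLATION_MAX = 0.0015
MIN_MEAN_RATE_HZ = 2.0


def qc_filter_units(spikes: pd.DataFrame, trials: pd.DataFrame) -> list[UnitQCReport]:
    """Screen units on refractory-period violations and mean firing rate.

    A unit passes when at most 0.15% of its inter-spike intervals fall below
    2 ms and its mean rate over the recorded trial time exceeds 2 Hz.  The
    mean rate denominator is the summed duration of the per-trial recording
    windows in which the unit was observed.
    """
    spans = _trial_spans(trials)
    reports = []
    for unit_id, grp in spikes.groupby("unit_id", sort=False):
        n_spikes = 0
        n_isi = 0
        n_viol = 0
        total_time = 0.0
        for row in grp.itertuples():
            times = np.asarray(row.spike_times_s, dtype=float)
            n_spikes += times.size
            if times.size >= 2:
                isi = np.diff(times)
                n_isi += isi.size
                n_viol += int((isi < ISI_REFRACTORY_S).sum())
            a, b = spans[int(row.trial_id)]
            total_time += b - a
        viol_frac = (n_viol / n_isi) if n_isi > 0 else 0.0
        mean_rate = n_spikes / total_time if total_time > 0 else 0.0
        reports.append(UnitQCReport(
            unit_id=unit_id, n_spikes=int(n_spikes),
            isi_violation_fraction=viol_frac, mean_rate_hz=mean_rate,
            passes=(viol_frac <= ISI_VIOLATION_MAX) and (mean_rate > MIN_MEAN_RATE_HZ)))
    return reports
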