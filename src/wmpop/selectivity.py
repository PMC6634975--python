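"""Single-unit odor-coding analyses: selectivity index, auROC, selective
fraction time courses and persistence classes.

The selectivity index contrasts the mean firing rate following the two
sample odors, (FR_S1 - FR_S2) / (FR_S1 + FR_S2), bounded in [-1, 1].  auROC
is the probability that a random S1 trial carries a higher rate than a
random S2 trial (rank convention with tie handling), so swapping the labels
maps it to 1 - auROC.  A unit is called selective in a bin when a label-
permutation test on the absolute mean-rate difference rejects at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .core_data import BinnedRateMatrix
from .resampling import TestResult, chisq_fraction_test

__all__ = [
    "SelectivityProfile",
    "selectivity_index",
    "auroc",
    "selective_fraction_timecourse",
    "classify_persistence",
    "heatmap_order",
]


@dataclass
class SelectivityProfile:
    unit_id: object
    selectivity_index: np.ndarray     # per bin, in [-1, 1]
    auroc: np.ndarray                 # per bin, in [0, 1]
    p_values: np.ndarray | None
    persistence_class: str | None
    condition: str = "correct"


def _two_label_masks(labels) -> tuple[np.ndarray, np.ndarray, list]:
    labels = np.asarray(labels)
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two sample labels, got {uniq}")
    m1 = labels == uniq[0]
    m2 = labels == uniq[1]
    if not m1.any() or not m2.any():
        raise ValueError("a label has zero trials")
    return m1, m2, uniq


def selectivity_index(binned: BinnedRateMatrix, labels) -> np.ndarray:
    """Per-unit per-bin index (FR_S1 - FR_S2)/(FR_S1 + FR_S2).

    Labels sort alphabetically, the first acting as S1.  Bins where both
    per-sample means are 0 get index 0.
    """
    m1, m2, _ = _two_label_masks(labels)
    fr1 = binned.rates[:, m1, :].mean(axis=1)
    fr2 = binned.rates[:, m2, :].mean(axis=1)
    denom = fr1 + fr2
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(denom == 0, 0.0, (fr1 - fr2) / np.where(denom == 0, 1.0, denom))
    return idx


def auroc(binned: BinnedRateMatrix, labels,
          condition_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-unit per-bin auROC for discriminating the two samples.

    The alphabetically-first label is the positive class; ties contribute
    half, matching the Mann-Whitney U statistic divided by n1*n2.
    ``condition_mask`` restricts trials (e.g. correct vs error).
    """
    labels = np.asarray(labels)
    if condition_mask is not None:
        labels = labels[condition_mask]
        rates = binned.rates[:, condition_mask, :]
    else:
        rates = binned.rates
    m1, m2, _ = _two_label_masks(labels)
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("need at least 2 trials per label")
    n_units, _, n_bins = rates.shape
    out = np.empty((n_units, n_bins))
    n1, n2 = int(m1.sum()), int(m2.sum())
    for u in range(n_units):
        for b in range(n_bins):
            x = rates[u, m1, b]
            y = rates[u, m2, b]
            ranks = sp_stats.rankdata(np.concatenate([x, y]))
            u_stat = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
            out[u, b] = u_stat / (n1 * n2)
    return out


def selective_fraction_timecourse(binned: BinnedRateMatrix, labels,
                                  alpha: float = 0.05, n_perm: int = 1000,
                                  seed: int | None = None,
                                  baseline_bin: int | None = None,
                                  method: str = "permutation"
                                  ) -> tuple[np.ndarray, np.ndarray, list[TestResult]]:
    """Fraction of selective units per bin, with chi-square versus baseline.

    A unit is selective in a bin when the label-permutation p-value of the
    absolute mean-rate difference falls below alpha (``method="ranksum"``
    substitutes a Wilcoxon rank-sum p-value instead).  Each bin's selective
    count is compared against the pre-sample baseline bin with a 2x2
    chi-square test.  Returns (fraction per bin, per-unit-per-bin p-values,
    per-bin chi-square results).
    """
    if method not in ("permutation", "ranksum"):
        raise ValueError(f"unknown method {method!r}")
    if method == "permutation" and n_perm < 100:
        raise ValueError("n_perm below 100 gives unstable p-values")
    m1, m2, _ = _two_label_masks(labels)
    if baseline_bin is None:
        # last bin ending at or before sample onset
        ends = binned.bin_starts + binned.bin_width_s
        pre = np.nonzero(ends <= 1e-9)[0]
        if pre.size == 0:
            raise ValueError("no pre-sample baseline bin inside the window")
        baseline_bin = int(pre[-1])
    rng = np.random.default_rng(seed)
    n_units, n_trials, n_bins = binned.rates.shape
    n1 = int(m1.sum())
    if method == "ranksum":
        p = np.empty((n_units, n_bins))
        for u in range(n_units):
            for b in range(n_bins):
                p[u, b] = sp_stats.mannwhitneyu(
                    binned.rates[u, m1, b], binned.rates[u, m2, b],
                    alternative="two-sided").pvalue
    else:
        observed = np.abs(binned.rates[:, m1, :].mean(axis=1)
                          - binned.rates[:, m2, :].mean(axis=1))
        # vectorised label permutations shared across units and bins
        count = np.zeros((n_units, n_bins), dtype=int)
        for _ in range(n_perm):
            perm = rng.permutation(n_trials)
            g1 = binned.rates[:, perm[:n1], :].mean(axis=1)
            g2 = binned.rates[:, perm[n1:], :].mean(axis=1)
            count += np.abs(g1 - g2) >= observed - 1e-12
        p = (count + 1) / (n_perm + 1)
    selective = p < alpha
    fraction = selective.mean(axis=0)
    k_base = int(selective[:, baseline_bin].sum())
    chi = [chisq_fraction_test(int(selective[:, b].sum()), n_units,
                               k_base, n_units)
           for b in range(n_bins)]
    return fraction, p, chi


def classify_persistence(significant_mask: np.ndarray, bin_duration_s: float,
                         persistent_s: float = 5.0,
                         transient_s: float = 0.5) -> str:
    """Persistence class from total significant time across bins.

    More than 5 s of significant selectivity -> "persistent"; more than
    0.5 s -> "transient"; otherwise "nonselective".  All significant bins
    count, not only the longest run.
    """
    total = float(np.asarray(significant_mask, dtype=bool).sum()) * bin_duration_s
    if total > persistent_s:
        return "persistent"
    if total > transient_s:
        return "transient"
    return "nonselective"


def heatmap_order(binned: BinnedRateMatrix, labels,
                  delay_window: tuple[float, float]) -> np.ndarray:
    """Unit ordering index by delay-period FR_S1 - FR_S2 (descending).

    Returns the permutation that sorts units for activity heat maps; the
    plotting itself is left to the caller.
    """
    m1, m2, _ = _two_label_masks(labels)
    starts = binned.bin_starts
    in_delay = (starts >= delay_window[0] - 1e-9) & \
               (starts + binned.bin_width_s <= delay_window[1] + 1e-9)
    if not in_delay.any():
        raise ValueError("no bins inside the delay window")
    fr1 = binned.rates[:, m1, :][:, :, in_delay].mean(axis=(1, 2))
    fr2 = binned.rates[:, m2, :][:, :, in_delay].mean(axis=(1, 2))
    return np.argsort(-(fr1 - fr2), kind="stable")
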