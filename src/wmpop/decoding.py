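"""Population decoding of sample identity with an RBF-kernel SVM.

Single-trial rate vectors are assembled into pseudopopulations: for every
class, each included neuron contributes a pool of same-class single-trial
rates, and a pseudotrial vector draws one value per neuron from its pool.
Each decoding repeat holds out one trial per class per neuron (resampled
leave-one-trial-out), trains on 30 bootstrap pseudotrials per class, and
tests on the held-out pseudotrial vectors; accuracy is averaged over
repeats.  Hyperparameters (c, gamma) are grid-searched once per time bin on
exponential grids 2^[-5..5] and 2^[-10..0] by inner 5-fold cross-validation
on the training pseudotrials.  Significance comes from a label-shuffle
null; cross-temporal decoding (CTD) reuses each training bin's
hyperparameters and random streams, so the CTD diagonal reproduces the
time-resolved accuracy exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC

from .core_data import BinnedRateMatrix

__all__ = [
    "DecoderConfig",
    "Pseudopopulation",
    "DecodingResult",
    "CorrelationReport",
    "select_units",
    "normalize_rates",
    "build_pseudopopulation",
    "decode_timecourse",
    "cross_temporal_decoding",
    "decode_behavior_correlation",
]


@dataclass
class DecoderConfig:
    c_grid: tuple[float, ...] = tuple(2.0 ** i for i in range(-5, 6))
    gamma_grid: tuple[float, ...] = tuple(2.0 ** j for j in range(-10, 1))
    n_repeats: int = 500
    n_train_boot: int = 30
    min_trials_per_class: int = 30     # inclusion is strict: > 30
    n_shuffles: int = 1000
    shuffle_repeats: int = 200
    seed: int = 0

    def __post_init__(self):
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def select_units(spikes, trials, config: DecoderConfig,
                 well_trained_mask: np.ndarray | None = None,
                 label_col: str = "sample_odor") -> list:
    """Units with more than ``min_trials_per_class`` correct well-trained
    trials for every class (strict inequality)."""
    correct = trials["outcome"].isin({"hit", "correct_rejection"}).to_numpy()
    if well_trained_mask is None:
        well_trained_mask = np.ones(len(trials), dtype=bool)
    usable = correct & np.asarray(well_trained_mask, dtype=bool)
    tid_ok = dict(zip(trials["trial_id"].astype(int),
                      zip(usable, trials[label_col])))
    classes = sorted(trials.loc[usable, label_col].unique())
    included = []
    for unit_id, grp in spikes.groupby("unit_id", sort=False):
        counts = dict.fromkeys(classes, 0)
        for tid in grp["trial_id"].astype(int):
            ok, lab = tid_ok[tid]
            if ok and lab in counts:
                counts[lab] += 1
        if classes and all(counts[c] > config.min_trials_per_class for c in classes):
            included.append(unit_id)
    if not included:
        raise ValueError("no unit satisfies the per-class trial-count inclusion rule")
    return included


def normalize_rates(binned: BinnedRateMatrix) -> BinnedRateMatrix:
    """Min-max scale each neuron's rates to [0, 1] over all trials and bins.

    Constant neurons map to all-zeros (with a warning).
    """
    if binned.rates.size == 0:
        raise ValueError("empty rate matrix")
    flat = binned.rates.reshape(binned.rates.shape[0], -1)
    lo = flat.min(axis=1)
    hi = flat.max(axis=1)
    span = hi - lo
    constant = span == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant-rate neuron(s) map to 0",
                      UserWarning, stacklevel=2)
    span = np.where(constant, 1.0, span)
    scaled = (binned.rates - lo[:, None, None]) / span[:, None, None]
    return BinnedRateMatrix(
        rates=scaled, bin_width_s=binned.bin_width_s, step_s=binned.step_s,
        window=binned.window, unit_ids=list(binned.unit_ids),
        trial_ids=list(binned.trial_ids), normalized=binned.normalized)


@dataclass
class Pseudopopulation:
    """Per-class, per-neuron pools of single-trial rates for each bin.

    ``pools[c]`` is a (units x n_c) integer matrix of trial indices into
    ``rates`` (units x trials x bins); a pseudotrial vector takes one entry
    per neuron from its same-class pool.
    """
    rates: np.ndarray
    pools: dict[object, np.ndarray]
    unit_ids: list
    bin_starts: np.ndarray
    bin_width_s: float

    @property
    def classes(self) -> list:
        return list(self.pools)

    @property
    def n_units(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[2]


def build_pseudopopulation(binned: BinnedRateMatrix, labels,
                           trial_mask: np.ndarray | None = None,
                           label_map: dict | None = None) -> Pseudopopulation:
    """Assemble class pools from a (normalised) rate matrix.

    ``label_map`` optionally coarsens labels (e.g. six sample odors into two
    pair-classes); chance level then follows the mapped class count.
    """
    labels = np.asarray(labels)
    if label_map is not None:
        labels = np.asarray([label_map[l] for l in labels])
    if trial_mask is None:
        trial_mask = np.ones(len(labels), dtype=bool)
    pools = {}
    for c in sorted(set(labels[trial_mask])):
        idx = np.nonzero(trial_mask & (labels == c))[0]
        pools[c] = np.tile(idx, (binned.rates.shape[0], 1))
    return Pseudopopulation(rates=binned.rates, pools=pools,
                            unit_ids=list(binned.unit_ids),
                            bin_starts=binned.bin_starts,
                            bin_width_s=binned.bin_width_s)


@dataclass
class DecodingResult:
    accuracy: np.ndarray                  # per bin
    repeat_accuracies: np.ndarray         # bins x repeats
    ci_low: np.ndarray
    ci_high: np.ndarray
    selected_c: np.ndarray
    selected_gamma: np.ndarray
    bin_starts: np.ndarray
    chance_level: float
    null_accuracies: np.ndarray | None = None   # bins x shuffles
    p_values: np.ndarray | None = None
    significance_mask: np.ndarray | None = None
    ctd: np.ndarray | None = None               # train-bin x test-bin
    included_units: list = field(default_factory=list)


def _draw_partition(rng, pools: dict, n_boot: int):
    """Held-out test positions and bootstrap training draws for one repeat.

    Returns per class: test position per unit and (n_boot x units) training
    positions guaranteed to exclude the test position (no leakage by
    construction).
    """
    out = {}
    for c, pool in pools.items():
        n_u, n_c = pool.shape
        test_pos = rng.integers(0, n_c, size=n_u)
        j = rng.integers(0, n_c - 1, size=(n_boot, n_u))
        train_pos = j + (j >= test_pos[None, :])
        assert not np.any(train_pos == test_pos[None, :]), "train/test overlap"
        out[c] = (test_pos, train_pos)
    return out


def _gather(rates_bin: np.ndarray, pool: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """rates_bin (units x trials); pos (... x units) -> values (... x units)."""
    trial_idx = np.take_along_axis(pool, pos.reshape(-1, pool.shape[0]).T,
                                   axis=1).T
    vals = rates_bin[np.arange(pool.shape[0])[None, :], trial_idx]
    return vals.reshape(pos.shape)


def _grid_search(rng, pools, rates, train_bin, config) -> tuple[float, float]:
    classes = list(pools)
    part = _draw_partition(rng, pools, config.n_train_boot)
    X, y = [], []
    rb = rates[:, :, train_bin]
    for ci, c in enumerate(classes):
        _, train_pos = part[c]
        X.append(_gather(rb, pools[c], train_pos))
        y.extend([ci] * config.n_train_boot)
    X = np.vstack(X)
    y = np.asarray(y)
    grid = GridSearchCV(SVC(kernel="rbf"),
                        {"C": list(config.c_grid), "gamma": list(config.gamma_grid)},
                        cv=5, n_jobs=None)
    grid.fit(X, y)
    # deterministic tie-break: smallest c, then smallest gamma
    res = grid.cv_results_
    best = max(zip(res["mean_test_score"],
                   [-p["C"] for p in res["params"]],
                   [-p["gamma"] for p in res["params"]],
                   range(len(res["params"]))))
    params = res["params"][best[3]]
    return float(params["C"]), float(params["gamma"])


def _decode_row(rng, pools, rates, train_bin: int, test_bins, c: float,
                gamma: float, n_repeats: int, n_boot: int) -> np.ndarray:
    """Accuracy (len(test_bins) x n_repeats): train at train_bin, test at
    each test bin with the held-out trials of the same partition."""
    classes = list(pools)
    out = np.zeros((len(test_bins), n_repeats))
    rb_train = rates[:, :, train_bin]
    for r in range(n_repeats):
        part = _draw_partition(rng, pools, n_boot)
        X, y = [], []
        for ci, cls in enumerate(classes):
            _, train_pos = part[cls]
            X.append(_gather(rb_train, pools[cls], train_pos))
            y.extend([ci] * n_boot)
        clf = SVC(kernel="rbf", C=c, gamma=gamma)
        clf.fit(np.vstack(X), np.asarray(y))
        for bi, tb in enumerate(test_bins):
            rb_test = rates[:, :, tb]
            X_test = np.vstack([
                _gather(rb_test, pools[cls], part[cls][0][None, :])
                for cls in classes])
            pred = clf.predict(X_test)
            out[bi, r] = float(np.mean(pred == np.arange(len(classes))))
    return out


def _bin_rngs(seed: int, train_bin: int):
    ss = np.random.SeedSequence([int(seed), int(train_bin)])
    grid_ss, rep_ss, null_ss = ss.spawn(3)
    return (np.random.default_rng(grid_ss), np.random.default_rng(rep_ss),
            np.random.default_rng(null_ss))


def _shuffled_pools(rng, pools: dict) -> dict:
    """Relabel trials: per neuron, permute the pooled trial indices across
    classes and resplit by the original class sizes."""
    classes = list(pools)
    concat = np.concatenate([pools[c] for c in classes], axis=1)
    perm = rng.permuted(concat, axis=1)
    sizes = [pools[c].shape[1] for c in classes]
    offsets = np.cumsum([0] + sizes)
    return {c: perm[:, offsets[i]:offsets[i + 1]] for i, c in enumerate(classes)}


def decode_timecourse(pseudopop: Pseudopopulation, config: DecoderConfig,
                      compute_null: bool = True,
                      sig_alpha: float = 0.001) -> DecodingResult:
    """Time-resolved decoding accuracy with bootstrap band and shuffle null.

    Each class must hold more trials than the test-set size (one per class).
    The per-bin shuffle null re-uses the observed-data hyperparameters and a
    reduced repeat count (``config.shuffle_repeats``); the significance mask
    marks bins whose accuracy exceeds the null at p < ``sig_alpha``.
    """
    for c, pool in pseudopop.pools.items():
        if pool.shape[1] <= 1:
            raise ValueError(f"class {c!r} has too few trials to hold one out")
    n_bins = pseudopop.n_bins
    k = len(pseudopop.classes)
    acc = np.zeros(n_bins)
    reps = np.zeros((n_bins, config.n_repeats))
    sel_c = np.zeros(n_bins)
    sel_g = np.zeros(n_bins)
    nulls = np.zeros((n_bins, config.n_shuffles)) if compute_null else None
    for b in range(n_bins):
        rng_grid, rng_rep, rng_null = _bin_rngs(config.seed, b)
        c_best, g_best = _grid_search(rng_grid, pseudopop.pools,
                                      pseudopop.rates, b, config)
        sel_c[b], sel_g[b] = c_best, g_best
        row = _decode_row(rng_rep, pseudopop.pools, pseudopop.rates, b, [b],
                          c_best, g_best, config.n_repeats, config.n_train_boot)
        reps[b] = row[0]
        acc[b] = row[0].mean()
        if compute_null:
            for s in range(config.n_shuffles):
                sp = _shuffled_pools(rng_null, pseudopop.pools)
                null_row = _decode_row(rng_null, sp, pseudopop.rates, b, [b],
                                       c_best, g_best, config.shuffle_repeats,
                                       config.n_train_boot)
                nulls[b, s] = null_row[0].mean()
    # bootstrap 95% band over repeat accuracies
    rng_ci = np.random.default_rng(np.random.SeedSequence([config.seed, 10 ** 6]))
    idx = rng_ci.integers(0, config.n_repeats, size=(1000, config.n_repeats))
    boot = reps[:, idx].mean(axis=2)
    ci_low, ci_high = np.quantile(boot, [0.025, 0.975], axis=1)
    p_values = None
    sig = None
    if compute_null:
        p_values = (np.sum(nulls >= acc[:, None] - 1e-12, axis=1) + 1) / (config.n_shuffles + 1)
        sig = p_values < sig_alpha
    return DecodingResult(
        accuracy=acc, repeat_accuracies=reps, ci_low=ci_low, ci_high=ci_high,
        selected_c=sel_c, selected_gamma=sel_g,
        bin_starts=pseudopop.bin_starts, chance_level=1.0 / k,
        null_accuracies=nulls, p_values=p_values, significance_mask=sig,
        included_units=list(pseudopop.unit_ids))


def cross_temporal_decoding(pseudopop: Pseudopopulation, config: DecoderConfig,
                            result: DecodingResult) -> np.ndarray:
    """CTD matrix: accuracy(train bin i, test bin j) for all i, j.

    Hyperparameters and random streams per train bin are the ones used by
    :func:`decode_timecourse`, so the diagonal equals ``result.accuracy``.
    """
    n_bins = pseudopop.n_bins
    ctd = np.zeros((n_bins, n_bins))
    all_bins = list(range(n_bins))
    for i in range(n_bins):
        _, rng_rep, _ = _bin_rngs(config.seed, i)
        rows = _decode_row(rng_rep, pseudopop.pools, pseudopop.rates, i,
                           all_bins, float(result.selected_c[i]),
                           float(result.selected_gamma[i]),
                           config.n_repeats, config.n_train_boot)
        ctd[i] = rows.mean(axis=1)
    result.ctd = ctd
    return ctd


@dataclass
class CorrelationReport:
    r: float
    r_squared: float
    ci_low: float
    ci_high: float
    r_draws: np.ndarray


def decode_behavior_correlation(repeat_accuracies: list[np.ndarray],
                                correct_trials: list[np.ndarray],
                                n_boot: int = 1000,
                                seed: int | None = None) -> CorrelationReport:
    """Bootstrap correlation between decoding accuracy and correct rate.

    One entry per condition (e.g. distractor none/nogo/go): the per-repeat
    decoding accuracies and the per-trial correct indicators.  Each
    bootstrap draw resamples both, recomputes the per-condition (accuracy,
    correct-rate) pairs and their Pearson r.
    """
    if len(repeat_accuracies) < 2 or len(repeat_accuracies) != len(correct_trials):
        raise ValueError("need matched accuracy/performance data for >= 2 conditions")
    rng = np.random.default_rng(seed)
    acc_pt = np.array([np.mean(a) for a in repeat_accuracies])
    perf_pt = np.array([np.mean(c) for c in correct_trials])
    r_point = _pearson(acc_pt, perf_pt)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        accs = [np.mean(rng.choice(a, size=len(a), replace=True))
                for a in repeat_accuracies]
        perfs = [np.mean(rng.choice(np.asarray(c, dtype=float), size=len(c),
                                    replace=True))
                 for c in correct_trials]
        draws[b] = _pearson(np.asarray(accs), np.asarray(perfs))
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return CorrelationReport(r=r_point, r_squared=r_point ** 2,
                             ci_low=float(lo), ci_high=float(hi), r_draws=draws)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
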