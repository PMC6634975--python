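"""Resampling statistics: permutation tests, bootstrap CIs, effect sizes,
the mixed between-within ANOVA interaction contract, outlier screens,
fraction comparisons and Bonferroni adjustment.

Permutation tests are two-sided on the absolute difference of means.  When
the number of distinct regroupings (or sign patterns) does not exceed the
requested repeat count the null is enumerated exhaustively and the p-value
is exact; otherwise Monte-Carlo sampling with the +1/(n+1) finite-sample
correction is used, so a Monte-Carlo p-value is never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "permutation_test",
    "paired_permutation_test",
    "bootstrap_ci_mean",
    "cohens_d",
    "mixed_anova_interaction",
    "detect_outliers",
    "chisq_fraction_test",
    "bonferroni_adjust",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_repeats: int
    method: str
    seed: int | None = None
    adjusted_p: float | None = None


def permutation_test(x, y, n_rep: int = 1000, seed: int | None = None) -> TestResult:
    """Two-sample permutation test on the absolute difference of means.

    The two samples are pooled and repeatedly regrouped into subsets matching
    the original group sizes; the p-value is the probability that a permuted
    absolute mean difference equals or exceeds the observed one.  Exhaustive
    when C(n1+n2, n1) <= ``n_rep``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 elements")
    observed = abs(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    n1, n = x.size, x.size + y.size
    total = math.comb(n, n1)
    tol = 1e-12 * max(1.0, abs(observed))
    if total <= n_rep:
        count = 0
        total_sum = pooled.sum()
        for combo in combinations(range(n), n1):
            s1 = pooled[list(combo)].sum()
            diff = abs(s1 / n1 - (total_sum - s1) / (n - n1))
            if diff >= observed - tol:
                count += 1
        return TestResult(observed, count / total, total, "permutation-exact", seed)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_rep):
        perm = rng.permutation(pooled)
        diff = abs(perm[:n1].mean() - perm[n1:].mean())
        if diff >= observed - tol:
            count += 1
    return TestResult(observed, (count + 1) / (n_rep + 1), n_rep, "permutation-mc", seed)


def paired_permutation_test(diffs, n_rep: int = 1000, seed: int | None = None) -> TestResult:
    """Sign-flip permutation test on the mean of paired differences."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 paired differences")
    observed = abs(d.mean())
    if np.all(d == 0):
        return TestResult(0.0, 1.0, 0, "paired-permutation-degenerate", seed)
    tol = 1e-12 * max(1.0, observed)
    n = d.size
    if 2 ** n <= n_rep:
        count = 0
        for pattern in range(2 ** n):
            signs = 1 - 2 * ((pattern >> np.arange(n)) & 1)
            if abs((signs * d).mean()) >= observed - tol:
                count += 1
        return TestResult(observed, count / 2 ** n, 2 ** n, "paired-permutation-exact", seed)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_rep, n))
    null = np.abs((signs * d).mean(axis=1))
    count = int((null >= observed - tol).sum())
    return TestResult(observed, (count + 1) / (n_rep + 1), n_rep, "paired-permutation-mc", seed)


def bootstrap_ci_mean(x, n_rep: int = 1000, alpha: float = 0.05,
                      seed: int | None = None) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_rep, x.size))
    means = x[idx].mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def cohens_d(x, y, paired: bool = False) -> float:
    """Cohen's d effect size (pooled-SD unpaired, or SD-of-differences paired)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 elements")
    if paired:
        if x.size != y.size:
            raise ValueError("paired samples must have equal length")
        d = x - y
        sd = d.std(ddof=1)
        if sd == 0:
            if np.all(d == 0):
                return 0.0
            raise ValueError("zero variance of paired differences")
        return float(d.mean() / sd)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    pooled = math.sqrt(((x.size - 1) * vx + (y.size - 1) * vy) / (x.size + y.size - 2))
    if pooled == 0:
        if x.mean() == y.mean():
            return 0.0
        raise ValueError("zero pooled variance")
    return float((x.mean() - y.mean()) / pooled)


def mixed_anova_interaction(table: pd.DataFrame,
                            subject: str = "subject",
                            between: str = "between",
                            within: str = "within",
                            dv: str = "value") -> TestResult:
    """Between x within interaction of a mixed-design ANOVA.

    ``table`` is long-format with one row per (subject, within-level)
    observation; the between factor (e.g. genotype) is constant per subject
    and the within factor (e.g. laser on/off) is complete for every subject.
    Significance of the interaction is the study's causal criterion.
    """
    import pingouin as pg

    counts = table.groupby([between])[subject].nunique()
    if (counts < 2).any():
        raise ValueError("need at least 2 subjects per between-factor level")
    per_subj = table.groupby([subject])[within].nunique()
    if per_subj.nunique() != 1 or per_subj.iloc[0] != table[within].nunique():
        raise ValueError("within-factor data must be complete for every subject")
    aov = pg.mixed_anova(data=table, dv=dv, within=within,
                         between=between, subject=subject)
    inter = aov.loc[aov["Source"] == "Interaction"].iloc[0]
    return TestResult(float(inter["F"]), float(inter["p_unc"]),
                      n_repeats=0, method="mixed-anova-interaction")


def _grubbs_critical(n: int, alpha: float) -> float:
    t2 = stats.t.ppf(1 - alpha / (2 * n), n - 2) ** 2
    return (n - 1) / math.sqrt(n) * math.sqrt(t2 / (n - 2 + t2))


def detect_outliers(x, method: str = "quantile", alpha: float = 0.05) -> np.ndarray:
    """Flag outliers by the 1.5-IQR fence or iterative two-sided Grubbs' test."""
    x = np.asarray(x, dtype=float)
    if method == "quantile":
        if x.size < 4:
            raise ValueError("quantile method needs at least 4 values")
        q1, q3 = np.quantile(x, [0.25, 0.75])
        iqr = q3 - q1
        return (x > q3 + 1.5 * iqr) | (x < q1 - 1.5 * iqr)
    if method == "grubbs":
        if x.size < 3:
            raise ValueError("grubbs method needs at least 3 values")
        mask = np.zeros(x.size, dtype=bool)
        active = np.arange(x.size)
        while active.size >= 3:
            vals = x[active]
            sd = vals.std(ddof=1)
            if sd == 0:
                break
            g = np.abs(vals - vals.mean()) / sd
            imax = int(np.argmax(g))
            if g[imax] > _grubbs_critical(active.size, alpha):
                mask[active[imax]] = True
                active = np.delete(active, imax)
            else:
                break
        return mask
    raise ValueError(f"unknown method {method!r}")


def chisq_fraction_test(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """2x2 chi-square test (1 df, no continuity correction) of two fractions."""
    if n1 <= 0 or n2 <= 0 or not (0 <= k1 <= n1) or not (0 <= k2 <= n2):
        raise ValueError("invalid counts")
    a, b, c, d = k1, n1 - k1, k2, n2 - k2
    n = n1 + n2
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return TestResult(0.0, 1.0, 0, "chi-square-2x2")
    chi2 = n * (a * d - b * c) ** 2 / denom
    p = float(stats.chi2.sf(chi2, df=1))
    return TestResult(float(chi2), max(p, np.finfo(float).tiny), 0, "chi-square-2x2")


def bonferroni_adjust(p_values) -> list[float]:
    """Bonferroni multiple-comparison adjustment: min(1, p * m)."""
    p = list(p_values)
    m = len(p)
    if any(not (0 < v <= 1) for v in p):
        raise ValueError("p-values must lie in (0, 1]")
    return [min(1.0, v * m) for v in p]
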