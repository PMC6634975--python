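"""Model comparison of task-parameter GLMs for behavioural performance.

Trials sharing a combination of the model's covariates are grouped; the
group-mean correct rate is the response mu and the model is the linear
combination mu = X^T b, fitted by weighted least squares (Gaussian family,
identity link, weights = group sizes).  Candidate models are compared by
their bootstrap AIC and r-squared distributions (trials resampled with
replacement, 500 repeats by default), the winner being the model with the
lowest mean bootstrap AIC.

The delay-duration covariate enters as an exponential time-decay value
exp(-delay / tau), with tau taken from the behavioural memory-decay fit and
held fixed across bootstrap replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, field

import numpy as np
import pandas as pd

from .behavior import CORRECT_OUTCOMES
from .resampling import paired_permutation_test

__all__ = [
    "ModelSpec",
    "ModelFit",
    "ModelComparisonResult",
    "default_candidate_models",
    "build_design",
    "fit_glm",
    "compare_models",
    "project_effects",
]

#: covariate universe: trial-table column (or derived) per term name
COVARIATES = {
    "sample_odor": "categorical",
    "test_odor": "categorical",
    "relation": "categorical",
    "genotype": "categorical",
    "laser_on": "binary",
    "perturb_epoch": "categorical",
    "delay_decay": "numeric",      # exp(-delay_s / tau)
    # effective delay-period suppression: ChR2 genotype AND laser on AND
    # delay-epoch perturbation (the compact model's key indicator)
    "perturb_delay": "binary",
}


@dataclass(frozen=True)
class ModelSpec:
    model_id: int
    terms: tuple[str, ...]
    interactions: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self):
        unknown = [t for t in self.terms if t not in COVARIATES]
        unknown += [t for pair in self.interactions for t in pair if t not in COVARIATES]
        if unknown:
            raise ValueError(f"unknown covariates {sorted(set(unknown))}")

    @property
    def all_terms(self) -> tuple[str, ...]:
        seen = dict.fromkeys(self.terms)
        for pair in self.interactions:
            seen.update(dict.fromkeys(pair))
        return tuple(seen)


def default_candidate_models() -> list[ModelSpec]:
    """The seven default candidate models, from the null model upward.

    #1 null (no task parameter affects performance); #2 sensory cues;
    #3 cues + memory-decay value; #4 adds the trial-level manipulation
    terms; #5 adds their interactions; #6 the compact model: delay-period
    perturbation, match/non-match relation, decay value and all their
    interactions; #7 the saturated main-effects + pairwise-interaction
    model.  These are editable defaults, not a fixed menu.
    """
    cues = ("sample_odor", "test_odor")
    manip = ("relation", "genotype", "laser_on", "perturb_epoch")
    key4 = ("perturb_delay", "relation", "delay_decay")
    full = cues + ("relation", "genotype", "laser_on", "perturb_epoch", "delay_decay")
    return [
        ModelSpec(1, ()),
        ModelSpec(2, cues),
        ModelSpec(3, cues + ("delay_decay",)),
        ModelSpec(4, cues + ("delay_decay",) + manip),
        ModelSpec(5, cues + ("delay_decay",) + manip,
                  interactions=(("relation", "laser_on"),
                                ("genotype", "laser_on"),
                                ("laser_on", "delay_decay"))),
        ModelSpec(6, key4,
                  interactions=(("perturb_delay", "relation"),
                                ("perturb_delay", "delay_decay"),
                                ("relation", "delay_decay"),
                                ("perturb_delay", "relation", "delay_decay"))),
        ModelSpec(7, full,
                  interactions=tuple((a, b) for i, a in enumerate(full)
                                     for b in full[i + 1:])),
    ]


def _covariate_frame(trials: pd.DataFrame, terms: tuple[str, ...],
                     tau_s: float) -> pd.DataFrame:
    cov = pd.DataFrame(index=trials.index)
    for term in terms:
        if term == "delay_decay":
            cov[term] = np.exp(-trials["delay_s"].astype(float) / tau_s)
        elif term == "perturb_delay":
            cov[term] = (trials["laser_on"].astype(bool)
                         & (trials["perturb_epoch"] == "delay")
                         & (trials["genotype"] == "ChR2")).astype(int)
        elif term == "laser_on":
            cov[term] = trials["laser_on"].astype(int)
        elif term in trials.columns:
            cov[term] = trials[term]
        else:
            raise ValueError(f"model term {term!r} absent from the trial table")
    return cov


def _dummy_columns(cov: pd.DataFrame,
                   levels: dict[str, list] | None = None) -> pd.DataFrame:
    """Dummy-code categoricals (drop-first); numerics pass through.

    ``levels`` pins the category sets (from the fitted data) so that a grid
    holding a subset of levels still produces the fitted design columns.
    """
    out = {}
    for col in cov.columns:
        if COVARIATES.get(col) == "categorical":
            vals = cov[col].astype(str)
            if levels and col in levels:
                vals = pd.Categorical(vals, categories=levels[col])
            dummies = pd.get_dummies(vals, prefix=col, prefix_sep="_",
                                     drop_first=True, dtype=float)
            dummies.index = cov.index
            for c in dummies.columns:
                out[c] = dummies[c]
        else:
            out[col] = cov[col].astype(float)
    return pd.DataFrame(out, index=cov.index)


def build_design(trials: pd.DataFrame, spec: ModelSpec, tau_s: float,
                 group_terms: tuple[str, ...] | None = None
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Group trials by covariate combination and build the model design.

    Returns (design matrix with intercept, group-mean correct rates mu,
    group sizes, group covariate frame).  One row per unique combination of
    ``group_terms`` (default: the model's own terms, so the intercept-only
    model collapses to a single overall correct rate); interaction columns
    are products of the (dummy-coded) member columns.  Model comparison
    passes the shared covariate universe as ``group_terms`` so that every
    candidate is fit to the same response vector.
    """
    if trials["outcome"].isna().any():
        raise ValueError("outcomes must be filled before building the design")
    correct = trials["outcome"].isin(CORRECT_OUTCOMES).astype(float)
    terms = spec.all_terms
    if group_terms is None:
        group_terms = terms
    else:
        missing = [t for t in terms if t not in group_terms]
        if missing:
            raise ValueError(f"group_terms must cover the model terms; missing {missing}")
    if not group_terms:
        mu = np.array([correct.mean()])
        return np.ones((1, 1)), mu, np.array([len(trials)]), pd.DataFrame(index=[0])
    cov = _covariate_frame(trials, group_terms, tau_s)
    key = cov.apply(tuple, axis=1)
    groups = correct.groupby(key)
    mu = groups.mean()
    sizes = groups.size()
    group_cov = cov.groupby(key).first().loc[mu.index]
    dummies = _dummy_columns(group_cov)
    cols = [np.ones(len(mu))]
    names = ["intercept"]
    main_cols = {}
    for term in terms:
        tc = [c for c in dummies.columns if c == term or c.startswith(term + "_")]
        main_cols[term] = tc
        if term in spec.terms:
            for c in tc:
                cols.append(dummies[c].to_numpy())
                names.append(c)
    for pair in spec.interactions:
        prod_sets = [main_cols[t] for t in pair]
        # cartesian product of the member dummy columns
        def _recurse(level, current, label):
            if level == len(prod_sets):
                cols.append(current)
                names.append(label)
                return
            for c in prod_sets[level]:
                _recurse(level + 1, current * dummies[c].to_numpy(),
                         f"{label}:{c}" if label else c)
        _recurse(0, np.ones(len(mu)), "")
    X = np.column_stack(cols)
    return X, mu.to_numpy(), sizes.to_numpy().astype(float), group_cov.reset_index(drop=True)


@dataclass
class ModelFit:
    coefficients: np.ndarray
    column_mask: np.ndarray            # columns kept after aliasing
    r_squared: float
    log_likelihood: float
    aic: float
    n_parameters: int
    n_groups: int


def fit_glm(design: np.ndarray, mu: np.ndarray, weights: np.ndarray) -> ModelFit:
    """Weighted least squares of mu on the design (Gaussian, identity link).

    Aliased (rank-deficient) columns are dropped with a warning.  The
    Gaussian log-likelihood uses the weighted MLE variance; AIC = 2k - 2logL
    with k = number of coefficients + 1 for the variance.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(mu, dtype=float)
    w = np.asarray(weights, dtype=float)
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    # drop aliased columns greedily by QR rank
    mask = np.ones(X.shape[1], dtype=bool)
    if np.linalg.matrix_rank(Xw) < X.shape[1]:
        keep: list[int] = []
        for j in range(X.shape[1]):
            cand = keep + [j]
            if np.linalg.matrix_rank(Xw[:, cand]) == len(cand):
                keep.append(j)
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[keep] = True
        warnings.warn(f"dropping {int((~mask).sum())} aliased design column(s)",
                      UserWarning, stacklevel=2)
    Xk = X[:, mask]
    beta, *_ = np.linalg.lstsq(Xk * sw[:, None], y * sw, rcond=None)
    resid = y - Xk @ beta
    n = y.size
    wsse = float(w @ resid ** 2)
    wtot = float(w.sum())
    ybar = float(w @ y / wtot)
    wtss = float(w @ (y - ybar) ** 2)
    r2 = 1.0 - wsse / wtss if wtss > 0 else (1.0 if wsse < 1e-20 else 0.0)
    sigma2 = max(wsse / n, 1e-12)
    logl = -0.5 * (n * np.log(2 * np.pi * sigma2) + wsse / sigma2
                   - np.log(w).sum())
    k = int(beta.size) + 1
    aic = 2 * k - 2 * logl
    coef = np.zeros(X.shape[1])
    coef[mask] = beta
    return ModelFit(coefficients=coef, column_mask=mask, r_squared=r2,
                    log_likelihood=float(logl), aic=float(aic),
                    n_parameters=k, n_groups=n)


@dataclass
class ModelComparisonResult:
    specs: list[ModelSpec]
    point_fits: list[ModelFit]
    aic_distributions: np.ndarray       # models x replicates
    r2_distributions: np.ndarray
    coefficient_draws: dict[int, np.ndarray]   # model_id -> reps x n_coef
    selected_model_id: int
    pairwise_p: dict[tuple[int, int], float]
    tau_s: float
    #: per-categorical-term level sets of the fitted data, for grid coding
    categorical_levels: dict[str, list] = field(default_factory=dict)
    n_dropped_replicate_groups: int = 0


def compare_models(trials: pd.DataFrame, specs: list[ModelSpec],
                   tau_s: float, n_boot: int = 500,
                   seed: int | None = None) -> ModelComparisonResult:
    """Bootstrap AIC/r-squared comparison of candidate models.

    Each replicate resamples trials with replacement, stratified within the
    finest covariate grouping used by any candidate (so no replicate empties
    a design cell), rebuilds every design and refits every model.  All
    candidates are fit to the same response vector — trials grouped by the
    union of every candidate's covariates — so their likelihoods and AICs
    are comparable.  The selected model minimises the mean bootstrap AIC;
    pairwise AIC differences are tested by sign-flip permutation over
    replicates.
    """
    if len(specs) < 1:
        raise ValueError("need at least one candidate model")
    rng = np.random.default_rng(seed)
    universe = tuple(dict.fromkeys(t for s in specs for t in s.all_terms))
    designs = []
    point_fits = []
    for s in specs:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            X, mu0, w, _ = build_design(trials, s, tau_s, group_terms=universe)
            point_fits.append(fit_glm(X, mu0, w))
        designs.append(X)
    # Stratified resampling within the universe cells keeps every cell size
    # fixed, so the designs and weights are constant across replicates and
    # only the cell-mean responses change: the WLS solvers can be cached.
    correct = trials["outcome"].isin(CORRECT_OUTCOMES).to_numpy(dtype=float)
    if universe:
        cov = _covariate_frame(trials, universe, tau_s)
        strata = cov.apply(tuple, axis=1)
        key_order = sorted(set(strata))   # groupby sorts keys the same way
        cell_vals = [correct[(strata == k).to_numpy()] for k in key_order]
    else:
        cell_vals = [correct]
    w = np.array([v.size for v in cell_vals], dtype=float)
    sw = np.sqrt(w)
    wtot = float(w.sum())
    solvers = []
    for X, fit in zip(designs, point_fits):
        Xk = X[:, fit.column_mask]
        Xw = Xk * sw[:, None]
        solvers.append((Xk, np.linalg.pinv(Xw)))
    aics = np.zeros((len(specs), n_boot))
    r2s = np.zeros((len(specs), n_boot))
    coef_draws = {s.model_id: np.zeros((n_boot, f.coefficients.size))
                  for s, f in zip(specs, point_fits)}
    n_cells = len(cell_vals)
    log_w_sum = float(np.log(w).sum())
    for b in range(n_boot):
        mu = np.array([v[rng.integers(0, v.size, size=v.size)].mean()
                       for v in cell_vals])
        ybar = float(w @ mu) / wtot
        wtss = float(w @ (mu - ybar) ** 2)
        for m, spec in enumerate(specs):
            Xk, H = solvers[m]
            beta = H @ (mu * sw)
            resid = mu - Xk @ beta
            wsse = float(w @ resid ** 2)
            sigma2 = max(wsse / n_cells, 1e-12)
            logl = -0.5 * (n_cells * np.log(2 * np.pi * sigma2)
                           + wsse / sigma2 - log_w_sum)
            k_par = beta.size + 1
            aics[m, b] = 2 * k_par - 2 * logl
            r2s[m, b] = 1.0 - wsse / wtss if wtss > 0 else (1.0 if wsse < 1e-20 else 0.0)
            coef = np.zeros(designs[m].shape[1])
            coef[point_fits[m].column_mask] = beta
            coef_draws[spec.model_id][b] = coef
    selected = specs[int(np.argmin(aics.mean(axis=1)))].model_id
    pairwise = {}
    for i in range(len(specs)):
        for j in range(i + 1, len(specs)):
            res = paired_permutation_test(aics[i] - aics[j], n_rep=1000,
                                          seed=int(rng.integers(2 ** 31)))
            pairwise[(specs[i].model_id, specs[j].model_id)] = res.p_value
    levels = {}
    for t in universe:
        if COVARIATES.get(t) == "categorical":
            levels[t] = sorted(trials[t].astype(str).unique())
    return ModelComparisonResult(
        specs=specs, point_fits=point_fits, aic_distributions=aics,
        r2_distributions=r2s, coefficient_draws=coef_draws,
        selected_model_id=selected, pairwise_p=pairwise, tau_s=tau_s,
        categorical_levels=levels)


def project_effects(result: ModelComparisonResult, grid: pd.DataFrame,
                    model_id: int | None = None,
                    ci_alpha: float = 0.05) -> pd.DataFrame:
    """Predicted correct rate X^T b over a covariate grid.

    ``grid`` holds one row per evaluation point with a column for every term
    of the chosen (default: selected) model.  Bootstrap bands come from the
    per-replicate coefficient draws.
    """
    model_id = result.selected_model_id if model_id is None else model_id
    k = next(i for i, s in enumerate(result.specs) if s.model_id == model_id)
    spec = result.specs[k]
    fit = result.point_fits[k]
    missing = [t for t in spec.all_terms if t not in grid.columns]
    if missing:
        raise ValueError(f"grid lacks model terms {missing}")
    extra = [c for c in grid.columns if c not in spec.all_terms]
    if extra:
        raise ValueError(f"grid covariates {extra} outside the model terms")

    def _design_for(frame: pd.DataFrame) -> np.ndarray:
        dummies = _dummy_columns(frame[list(spec.all_terms)],
                                 levels=result.categorical_levels)
        cols = [np.ones(len(frame))]
        main_cols = {}
        for term in spec.all_terms:
            tc = [c for c in dummies.columns if c == term or c.startswith(term + "_")]
            main_cols[term] = tc
            if term in spec.terms:
                for c in tc:
                    cols.append(dummies[c].to_numpy())
        for pair in spec.interactions:
            def _recurse(level, current):
                if level == len(pair):
                    cols.append(current)
                    return
                for c in main_cols[pair[level]]:
                    _recurse(level + 1, current * dummies[c].to_numpy())
            _recurse(0, np.ones(len(frame)))
        return np.column_stack(cols)

    X = _design_for(grid)
    if X.shape[1] != fit.coefficients.size:
        # a grid level absent from the fitted data changes the dummy coding
        raise ValueError("grid levels do not match the fitted design")
    pred = X @ fit.coefficients
    out = grid.copy()
    out["predicted"] = pred
    draws = result.coefficient_draws.get(model_id)
    if draws is not None and draws.shape[1] == X.shape[1]:
        boot = X @ draws.T
        lo, hi = np.quantile(boot, [ci_alpha / 2, 1 - ci_alpha / 2], axis=1)
        out["ci_low"] = lo
        out["ci_high"] = hi
    return out
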