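"""Monte Carlo cross-validated per-marker survival prediction.

For each candidate marker (a protein or a binarized clinical characteristic)
the engine repeats, by default 200 times:

1. stratified split into 85% training / 15% validation patients;
2. scaling of the training and validation blocks separately, each with its
   own statistics (min-max by default, z-score by option) — no statistic is
   transferred between blocks;
3. inner tenfold cross-validation on the training block over a grid of
   inverse L1 penalties, selecting the grid value with the best mean
   inner-fold AUROC (ties favour stronger regularization);
4. refit of the selected L1-logistic model (marker + scheme covariates) on
   the full training block;
5. prediction of survival probabilities for the held-out validation block.

Validation probabilities are pooled across repeats; bootstrap resampling of
the pooled (probability, label) pairs yields AUROC percentile intervals, and
the per-repeat refit marker coefficients yield the beta interval. A
permutation arm repeats the identical pipeline with outcome labels shuffled
per repeat; a two-sample Kolmogorov-Smirnov test between the real and
permutation beta distributions gives the marker's p-value (Bonferroni
adjusted across markers). A marker is declared significant when its median
AUROC exceeds 0.5, its beta interval excludes 0, and its permutation beta
interval contains 0. AUROC below 0.5 is reported as-is — it flags a marker
whose model ranks deaths higher.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from ._solver import (
    _cd_l1_logistic,
    _auroc_ranks,
    auroc,
    fit_l1_logistic,
    predict_proba,
)

__all__ = [
    "MCCVConfig",
    "PredictionScheme",
    "MarkerResult",
    "MCCVMarkerEvaluator",
    "mccv_split",
    "scale_split",
    "select_penalty",
    "auroc",
    "run_marker_mccv",
    "run_permutation_null",
    "bootstrap_intervals",
    "marker_significance",
    "apply_significance_rule",
    "evaluate_marker",
]

DEFAULT_PENALTY_GRID = tuple(np.logspace(-2, 2, 7))


@dataclass
class MCCVConfig:
    n_repeats: int = 200
    train_fraction: float = 0.85
    inner_folds: int = 10
    n_boot: int = 50
    penalty_grid: tuple = DEFAULT_PENALTY_GRID
    n_permutation_repeats: int = 200
    master_seed: int = 0
    bonferroni_m: int = 1
    scaling: str = "minmax"  # or "zscore"
    tol: float = 1e-6

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        for name in ("n_repeats", "inner_folds", "n_boot",
                     "n_permutation_repeats", "bonferroni_m"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.scaling not in ("minmax", "zscore"):
            raise ValueError("scaling must be 'minmax' or 'zscore'")
        if len(self.penalty_grid) < 1 or min(self.penalty_grid) <= 0:
            raise ValueError("penalty_grid must contain positive values")


@dataclass
class PredictionScheme:
    """Outcome definition and scheme covariates.

    outcome: 'all_time_survival' (survived = never died during follow-up) or
    'one_year_survival' (survived unless death occurred within 1 year).
    covariates: subset of {'site_of_origin', 'pgd'}.
    """

    outcome: str = "all_time_survival"
    covariates: tuple = ()

    def __post_init__(self):
        if self.outcome not in ("all_time_survival", "one_year_survival"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        bad = set(self.covariates) - {"site_of_origin", "pgd"}
        if bad:
            raise ValueError(f"unknown covariates: {sorted(bad)}")

    def labels(self, survived, followup_years=None):
        """Per-patient 0/1 survival labels under this scheme."""
        survived = np.asarray(survived, dtype=int)
        if self.outcome == "all_time_survival":
            return survived.copy()
        if followup_years is None:
            raise ValueError("one_year_survival needs follow-up times")
        t = np.asarray(followup_years, dtype=float)
        died_within_1y = (survived == 0) & (t < 1.0)
        return (~died_within_1y).astype(int)


@dataclass
class MarkerResult:
    marker: str
    auroc_q2_5: float
    auroc_median: float
    auroc_q97_5: float
    beta_q2_5: float
    beta_median: float
    beta_q97_5: float
    perm_beta_q2_5: float
    perm_beta_q97_5: float
    p_raw: float
    p_adjusted: float
    significant: bool = False
    pooled_auroc: float = float("nan")
    mean_repeat_auroc: float = float("nan")
    perm_auroc_q2_5: float = float("nan")
    perm_auroc_q97_5: float = float("nan")
    n_repeats: int = 0

    def __post_init__(self):
        if not self.auroc_q2_5 <= self.auroc_median <= self.auroc_q97_5:
            raise ValueError("AUROC quantiles out of order")
        if not self.beta_q2_5 <= self.beta_median <= self.beta_q97_5:
            raise ValueError("beta quantiles out of order")
        for p in (self.p_raw, self.p_adjusted):
            if not 0.0 <= p <= 1.0:
                raise ValueError("p-values must lie in [0, 1]")


def _marker_hash(name: str) -> int:
    return zlib.crc32(str(name).encode()) & 0x7FFFFFFF


def _rng_for(config: MCCVConfig, marker: str, stream: int):
    ss = np.random.SeedSequence(
        [int(config.master_seed), _marker_hash(marker), int(stream)]
    )
    return np.random.default_rng(ss)


def mccv_split(n_patients, labels, train_fraction, rng):
    """One stratified Monte Carlo train/validation split.

    Validation size = ceil((1 - train_fraction) * n); each class contributes
    at least one validation patient (proportional largest-remainder
    allocation) while retaining at least one of each class in training.
    """
    y = np.asarray(labels, dtype=int)
    if n_patients != len(y):
        raise ValueError("labels length differs from n_patients")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to split")
    n_valid = math.ceil((1.0 - train_fraction) * n_patients)
    if n_valid < len(classes) or np.any(counts < 2):
        raise ValueError(
            "cannot place both classes in validation and training"
        )
    raw = n_valid * counts / n_patients
    alloc = np.floor(raw).astype(int)
    rem = n_valid - alloc.sum()
    order = np.argsort(-(raw - alloc))
    alloc[order[:rem]] += 1
    # each class: at least 1 in validation, at least 1 left for training
    alloc = np.clip(alloc, 1, counts - 1)
    while alloc.sum() > n_valid:
        k = int(np.argmax(alloc - 1))
        alloc[k] -= 1
    while alloc.sum() < n_valid:
        room = counts - 1 - alloc
        k = int(np.argmax(room))
        if room[k] <= 0:
            raise ValueError("cannot satisfy validation size with both classes")
        alloc[k] += 1
    valid = []
    for cls, take in zip(classes, alloc):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(idx)
        valid.append(perm[:take])
    valid_idx = np.sort(np.concatenate(valid))
    mask = np.ones(n_patients, dtype=bool)
    mask[valid_idx] = False
    train_idx = np.flatnonzero(mask)
    return train_idx, valid_idx


def _scale_block(block, method):
    block = np.asarray(block, dtype=np.float64)
    if method == "minmax":
        lo = block.min(axis=0)
        span = block.max(axis=0) - lo
        out = np.zeros_like(block)
        ok = span > 0
        out[:, ok] = (block[:, ok] - lo[ok]) / span[ok]
        return out
    if method == "zscore":
        mean = block.mean(axis=0)
        sd = block.std(axis=0)  # population SD
        out = np.zeros_like(block)
        ok = sd > 0
        out[:, ok] = (block[:, ok] - mean[ok]) / sd[ok]
        return out
    raise ValueError(f"unknown scaling method {method!r}")


def scale_split(train_block, valid_block, method="minmax"):
    """Scale the two blocks independently, each with its own statistics.

    No statistic crosses blocks (the validation block is scaled by its own
    min/max or mean/SD). Constant features map to 0 in either method.
    """
    return _scale_block(train_block, method), _scale_block(valid_block, method)


def _stratified_folds(y, n_folds, rng):
    """Round-robin stratified fold assignment; returns fold id per sample."""
    fold = np.empty(len(y), dtype=np.int64)
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def select_penalty(train_X, train_y, config: MCCVConfig, rng):
    """Inner-CV choice of the inverse penalty maximizing mean fold AUROC.

    Folds are reduced to min(inner_folds, minority class count). Inner folds
    whose held-out part lacks a class are skipped; if every fold is unusable
    the selection is an error. Ties prefer the smaller inverse penalty
    (stronger regularization).
    """
    y = np.asarray(train_y, dtype=np.float64)
    counts = np.bincount(y.astype(int), minlength=2)
    n_folds = int(min(config.inner_folds, counts.min()))
    if n_folds < 2:
        raise ValueError("penalty selection error: fewer than 2 usable folds")
    fold = _stratified_folds(y.astype(int), n_folds, rng)
    X = np.ascontiguousarray(train_X, dtype=np.float64)
    grid = sorted(config.penalty_grid)
    best_c, best_score = None, -np.inf
    tol, max_sweeps = config.tol, 200
    for c in grid:
        lam = 1.0 / c
        scores = []
        for f in range(n_folds):
            tr = fold != f
            va = ~tr
            y_tr, y_va = y[tr], y[va]
            if y_va.min() == y_va.max() or y_tr.min() == y_tr.max():
                continue
            w, b = _cd_l1_logistic(
                np.ascontiguousarray(X[tr]), y_tr, lam, tol, max_sweeps
            )
            probs = 1.0 / (1.0 + np.exp(-(X[va] @ w + b)))
            a = _auroc_ranks(probs, y_va)
            if not np.isnan(a):
                scores.append(a)
        if not scores:
            continue
        score = float(np.mean(scores))
        if score > best_score + 1e-12:
            best_score, best_c = score, c
    if best_c is None:
        raise ValueError("penalty selection error: all folds degenerate")
    return float(best_c)


def _single_repeat(X, y, config: MCCVConfig, rng):
    """One MCCV repeat: split, scale, select, refit, predict.

    Returns (validation probabilities, validation labels, marker beta,
    validation AUROC)."""
    train_idx, valid_idx = mccv_split(len(y), y, config.train_fraction, rng)
    X_tr, X_va = scale_split(X[train_idx], X[valid_idx], config.scaling)
    y_tr = np.asarray(y, dtype=np.float64)[train_idx]
    y_va = np.asarray(y, dtype=np.float64)[valid_idx]
    c = select_penalty(X_tr, y_tr, config, rng)
    w, b = _cd_l1_logistic(
        np.ascontiguousarray(X_tr), y_tr, 1.0 / c, config.tol, 200
    )
    probs = 1.0 / (1.0 + np.exp(-(X_va @ w + b)))
    a = _auroc_ranks(probs, y_va)
    return probs, y_va, float(w[0]), float(a)


def _assemble_design(marker_values, covariate_matrix):
    m = np.asarray(marker_values, dtype=np.float64).reshape(-1, 1)
    if covariate_matrix is None:
        return m
    cov = np.asarray(covariate_matrix, dtype=np.float64)
    if cov.ndim == 1:
        cov = cov.reshape(-1, 1)
    if cov.shape[0] != m.shape[0]:
        raise ValueError("marker and covariates differ in length")
    return np.hstack([m, cov])


def run_marker_mccv(marker_values, covariate_matrix, labels,
                    config: MCCVConfig, marker_name="marker"):
    """Execute the MCCV pipeline n_repeats times for one marker.

    Returns a dict with per-repeat validation probabilities/labels (pooled
    arrays plus repeat boundaries), per-repeat refit marker betas, and
    per-repeat validation AUROCs. Per-repeat seeds derive from
    (master_seed, marker name, repeat index) so each marker's run is
    independently reproducible.
    """
    X = _assemble_design(marker_values, covariate_matrix)
    y = np.asarray(labels, dtype=int)
    rng = _rng_for(config, marker_name, stream=0)
    probs, labs, betas, aurocs = [], [], [], []
    for rep in range(config.n_repeats):
        try:
            p, yv, beta, a = _single_repeat(X, y, config, rng)
        except ValueError as err:
            raise ValueError(f"repeat {rep}: {err}") from err
        probs.append(p)
        labs.append(yv)
        betas.append(beta)
        aurocs.append(a)
    return {
        "marker": marker_name,
        "probabilities": np.concatenate(probs),
        "labels": np.concatenate(labs),
        "betas": np.asarray(betas),
        "repeat_aurocs": np.asarray(aurocs),
    }


def run_permutation_null(marker_values, covariate_matrix, labels,
                         config: MCCVConfig, marker_name="marker"):
    """Identical pipeline with labels shuffled independently per repeat.

    Shuffling permutes the observed label vector, preserving class balance.
    Returns n_permutation_repeats null betas and validation AUROCs.
    """
    X = _assemble_design(marker_values, covariate_matrix)
    y = np.asarray(labels, dtype=int)
    rng = _rng_for(config, marker_name, stream=1)
    betas, aurocs = [], []
    for rep in range(config.n_permutation_repeats):
        y_perm = rng.permutation(y)
        try:
            _, _, beta, a = _single_repeat(X, y_perm, config, rng)
        except ValueError as err:
            raise ValueError(f"permutation repeat {rep}: {err}") from err
        betas.append(beta)
        aurocs.append(a)
    return {"betas": np.asarray(betas), "aurocs": np.asarray(aurocs)}


def bootstrap_intervals(validation_probabilities, labels, betas, n_boot,
                        rng, max_redraw=1000):
    """Percentile intervals from bootstrap of pooled validation predictions.

    n_boot resamples (with replacement) of the pooled (probability, label)
    pairs give the AUROC distribution (2.5/50/97.5 percentiles); resamples
    containing a single class are redrawn. Beta percentiles come directly
    from the per-repeat refit betas.
    """
    p = np.asarray(validation_probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if p.shape != y.shape or p.size < 2:
        raise ValueError("need >= 2 pooled predictions with labels")
    if np.unique(y).size < 2:
        raise ValueError("bootstrap undefined: one class only")
    n = p.size
    boot_auroc = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(max_redraw):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if yb.min() != yb.max():
                break
        else:
            raise ValueError("could not draw a two-class bootstrap resample")
        boot_auroc[b] = _auroc_ranks(np.ascontiguousarray(p[idx]), yb)
    betas = np.asarray(betas, dtype=np.float64)
    a_lo, a_med, a_hi = np.percentile(boot_auroc, [2.5, 50, 97.5])
    b_lo, b_med, b_hi = np.percentile(betas, [2.5, 50, 97.5])
    return {
        "auroc_q2_5": float(a_lo), "auroc_median": float(a_med),
        "auroc_q97_5": float(a_hi),
        "beta_q2_5": float(b_lo), "beta_median": float(b_med),
        "beta_q97_5": float(b_hi),
        "bootstrap_aurocs": boot_auroc,
    }


def marker_significance(bootstrap_betas, permutation_betas, bonferroni_m):
    """KS comparison of real vs permutation beta distributions.

    Raw p = two-sample Kolmogorov-Smirnov p-value; adjusted = min(1, raw * m)
    with m the number of markers tested (Bonferroni).
    """
    a = np.asarray(bootstrap_betas, dtype=float)
    b = np.asarray(permutation_betas, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values in each sample")
    res = stats.ks_2samp(a, b)
    raw = float(res.pvalue)
    return raw, min(1.0, raw * int(bonferroni_m))


def apply_significance_rule(result: MarkerResult) -> bool:
    """Three-criterion predictive significance rule.

    Significant iff median AUROC > 0.5, the beta 95% interval excludes the
    null association (0), and the permutation beta 95% interval contains 0.
    """
    auroc_ok = result.auroc_median > 0.5
    beta_excludes_null = not (result.beta_q2_5 <= 0.0 <= result.beta_q97_5)
    perm_contains_null = result.perm_beta_q2_5 <= 0.0 <= result.perm_beta_q97_5
    return bool(auroc_ok and beta_excludes_null and perm_contains_null)


def evaluate_marker(marker_values, covariate_matrix, labels,
                    config: MCCVConfig, marker_name="marker") -> MarkerResult:
    """Full per-marker evaluation: MCCV, bootstrap intervals, permutation
    null, KS significance, and the three-criterion verdict."""
    run = run_marker_mccv(marker_values, covariate_matrix, labels, config,
                          marker_name)
    rng = _rng_for(config, marker_name, stream=2)
    ints = bootstrap_intervals(run["probabilities"], run["labels"],
                               run["betas"], config.n_boot, rng)
    null = run_permutation_null(marker_values, covariate_matrix, labels,
                                config, marker_name)
    perm_lo, perm_hi = np.percentile(null["betas"], [2.5, 97.5])
    perm_a_lo, perm_a_hi = np.percentile(null["aurocs"], [2.5, 97.5])
    p_raw, p_adj = marker_significance(run["betas"], null["betas"],
                                       config.bonferroni_m)
    result = MarkerResult(
        marker=marker_name,
        auroc_q2_5=ints["auroc_q2_5"], auroc_median=ints["auroc_median"],
        auroc_q97_5=ints["auroc_q97_5"],
        beta_q2_5=ints["beta_q2_5"], beta_median=ints["beta_median"],
        beta_q97_5=ints["beta_q97_5"],
        perm_beta_q2_5=float(perm_lo), perm_beta_q97_5=float(perm_hi),
        p_raw=p_raw, p_adjusted=p_adj,
        pooled_auroc=auroc(run["probabilities"], run["labels"]),
        mean_repeat_auroc=float(np.nanmean(run["repeat_aurocs"])),
        perm_auroc_q2_5=float(perm_a_lo), perm_auroc_q97_5=float(perm_a_hi),
        n_repeats=config.n_repeats,
    )
    result.significant = apply_significance_rule(result)
    return result


class MCCVMarkerEvaluator(BaseEstimator):
    """Evaluate each column of X as a survival marker by Monte Carlo CV.

    scikit-learn-style estimator: ``fit(X, y, covariates=...)`` runs the full
    MCCV + bootstrap + permutation machinery for every column of X (each
    modelled as marker + shared covariates) and stores one
    :class:`MarkerResult` per column in ``results_``.

    Parameters mirror :class:`MCCVConfig`; ``bonferroni_m=None`` defaults to
    the number of evaluated markers.
    """

    def __init__(self, n_repeats=200, train_fraction=0.85, inner_folds=10,
                 n_boot=50, penalty_grid=DEFAULT_PENALTY_GRID,
                 n_permutation_repeats=200, scaling="minmax",
                 bonferroni_m=None, random_state=0, tol=1e-6):
        self.n_repeats = n_repeats
        self.train_fraction = train_fraction
        self.inner_folds = inner_folds
        self.n_boot = n_boot
        self.penalty_grid = penalty_grid
        self.n_permutation_repeats = n_permutation_repeats
        self.scaling = scaling
        self.bonferroni_m = bonferroni_m
        self.random_state = random_state
        self.tol = tol

    def _config(self, n_markers):
        return MCCVConfig(
            n_repeats=self.n_repeats, train_fraction=self.train_fraction,
            inner_folds=self.inner_folds, n_boot=self.n_boot,
            penalty_grid=tuple(self.penalty_grid),
            n_permutation_repeats=self.n_permutation_repeats,
            master_seed=self.random_state,
            bonferroni_m=self.bonferroni_m or n_markers,
            scaling=self.scaling, tol=self.tol,
        )

    def fit(self, X, y, covariates=None):
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            if values.ndim == 1:
                values = values.reshape(-1, 1)
            names = [f"marker_{i}" for i in range(values.shape[1])]
        y = np.asarray(y, dtype=int)
        if values.shape[0] != y.shape[0]:
            raise ValueError("X and y have incompatible shapes")
        config = self._config(values.shape[1])
        self.config_ = config
        self.marker_names_ = names
        self.results_ = [
            evaluate_marker(values[:, j], covariates, y, config, names[j])
            for j in range(values.shape[1])
        ]
        self.significant_ = np.array([r.significant for r in self.results_])
        return self

    def results_frame(self):
        import pandas as pd

        if not hasattr(self, "results_"):
            raise AttributeError("call fit first")
        return pd.DataFrame([asdict(r) for r in self.results_])
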