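"""Iterative random-forest imputation and comparator imputers.

The workhorse is the MissForest algorithm of Stekhoven & Bühlmann: missing
cells are initialized with feature means, features are visited in order of
ascending missingness, and each sweep refits a random-forest regressor per
feature (response = the feature, predictors = all other features, training
rows = samples where the feature is observed) to re-predict its missing
cells.  Sweeps continue until the normalized change statistic

    Δ = Σ (X_new − X_old)² / Σ X_new²   (over imputed cells)

first increases, and the matrix from the last Δ-decreasing sweep is
returned.  Forest hyperparameters follow the R ``randomForest`` regression
defaults the reference implementation inherits: 100 trees, mtry = √p,
node size 5.

Comparators: feature-space k-nearest-neighbour averaging, feature-mean
substitution, and a left-censoring surrogate (feature minimum minus a fixed
log2 offset).  All imputers leave observed cells bit-exactly untouched.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.impute import KNNImputer

from .types import DataError, QuantMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ImputerSpec",
    "ImputationResult",
    "impute_missforest",
    "impute_knn",
    "impute_mean",
    "impute_min_shift",
    "score_imputation",
    "benchmark_imputers",
    "get_imputer",
    "IMPUTERS",
]


@dataclass
class ImputerSpec:
    """Imputer identity plus hyperparameters."""

    id: str = "missforest"
    n_trees: int = 100
    max_iterations: int = 10
    # declare convergence when a sweep improves the stopping statistic by
    # less than this relative amount (the matrix change is then negligible)
    rel_tol: float = 0.05
    knn_k: int = 5
    min_shift_offset: float = 1.0  # log2 units below the feature minimum
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees <= 0 or self.max_iterations <= 0 or self.knn_k <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.min_shift_offset < 0:
            raise ValueError("min_shift_offset must be nonnegative")


@dataclass
class ImputationResult:
    matrix: QuantMatrix
    iterations_used: int
    delta_trace: list[float]


def _as_array(m: QuantMatrix, require_samples: bool = True) -> np.ndarray:
    x = m.values.to_numpy(dtype=float)
    if np.isinf(x).any():
        raise DataError("matrix contains non-finite values")
    all_missing_feat = np.isnan(x).all(axis=1)
    if all_missing_feat.any():
        bad = list(m.values.index[all_missing_feat])
        raise DataError(f"features entirely missing: {bad[:5]}")
    if require_samples:
        all_missing_samp = np.isnan(x).all(axis=0)
        if all_missing_samp.any():
            bad = list(m.values.columns[all_missing_samp])
            raise DataError(f"samples entirely missing: {bad[:5]}")
    return x


def _result(m: QuantMatrix, filled: np.ndarray, iters: int, trace: list[float]) -> ImputationResult:
    out = QuantMatrix(
        values=pd.DataFrame(filled, index=m.values.index, columns=m.values.columns),
        level=m.level,
        scale=m.scale,
        feature_meta=None if m.feature_meta is None else m.feature_meta.copy(),
    )
    return ImputationResult(matrix=out, iterations_used=iters, delta_trace=trace)


def _forest_seed(base: int, feature: int, sweep: int) -> int:
    return int(
        np.random.SeedSequence([base, feature, sweep]).generate_state(1)[0] % (2**31)
    )


def impute_missforest(m: QuantMatrix, spec: ImputerSpec | None = None) -> ImputationResult:
    """Iterative random-forest imputation (see module docstring).

    The matrix is oriented with features as responses and samples as
    observations, the natural shape when features outnumber samples.
    Every forest seed derives deterministically from (spec.seed, feature,
    sweep), so a fixed spec reproduces the imputation exactly.
    """
    spec = spec or ImputerSpec(id="missforest")
    x = _as_array(m).T  # samples x features; each feature is a response column
    nan_mask = np.isnan(x)
    if not nan_mask.any():
        return _result(m, x.T, 0, [])

    col_means = np.nanmean(x, axis=0)
    filled = np.where(nan_mask, col_means[None, :], x)
    # ascending missingness: easiest features are re-estimated first
    order = np.argsort(nan_mask.mean(axis=0), kind="stable")
    order = [int(j) for j in order if nan_mask[:, j].any()]

    best = filled.copy()
    prev_delta = np.inf
    trace: list[float] = []
    iters = 0
    for sweep in range(1, spec.max_iterations + 1):
        old = filled.copy()
        for j in order:
            obs_rows = ~nan_mask[:, j]
            predictors = np.delete(filled, j, axis=1)
            rf = RandomForestRegressor(
                n_estimators=spec.n_trees,
                max_features="sqrt",
                min_samples_leaf=5,
                random_state=_forest_seed(spec.seed, j, sweep),
                n_jobs=1,
            )
            rf.fit(predictors[obs_rows], x[obs_rows, j])
            filled[nan_mask[:, j], j] = rf.predict(predictors[~obs_rows])
        num = float(((filled - old)[nan_mask] ** 2).sum())
        den = float((filled[nan_mask] ** 2).sum())
        delta = num / den if den > 0 else 0.0
        trace.append(delta)
        if delta > prev_delta:
            break  # diverging: keep the previous sweep's matrix
        best = filled.copy()
        improved = (prev_delta - delta) / prev_delta if np.isfinite(prev_delta) else 1.0
        prev_delta = delta
        iters = sweep
        if delta == 0.0 or improved < spec.rel_tol:
            break  # converged: further sweeps barely move the imputation
    return _result(m, best.T, iters, trace)


def impute_knn(m: QuantMatrix, spec: ImputerSpec | None = None) -> ImputationResult:
    """k-nearest-neighbour imputation in feature space.

    A missing cell is filled with the average of the k features nearest to
    its own feature (NaN-aware Euclidean distance over mutually observed
    samples) that carry a value in that sample.
    """
    spec = spec or ImputerSpec(id="knn")
    x = _as_array(m)
    k = spec.knn_k
    if k > x.shape[0] - 1:
        k = max(1, x.shape[0] - 1)
        warnings.warn(
            f"knn_k={spec.knn_k} exceeds available neighbour features; "
            f"reduced to {k}",
            stacklevel=2,
        )
    # KNNImputer treats rows as the objects among which neighbours are found,
    # so features-as-rows yields the feature-space neighbourhood we want.
    imputer = KNNImputer(n_neighbors=k, weights="uniform", keep_empty_features=True)
    filled = imputer.fit_transform(x)
    filled = np.where(np.isnan(x), filled, x)
    return _result(m, filled, 1, [])


def impute_mean(m: QuantMatrix, spec: ImputerSpec | None = None) -> ImputationResult:
    """Feature-mean substitution."""
    x = _as_array(m, require_samples=False)
    means = np.nanmean(x, axis=1)
    filled = np.where(np.isnan(x), means[:, None], x)
    return _result(m, filled, 1, [])


def impute_min_shift(m: QuantMatrix, spec: ImputerSpec | None = None) -> ImputationResult:
    """Left-censoring surrogate: feature minimum minus a fixed log2 offset."""
    spec = spec or ImputerSpec(id="min_shift")
    x = _as_array(m, require_samples=False)
    mins = np.nanmin(x, axis=1)
    filled = np.where(np.isnan(x), (mins - spec.min_shift_offset)[:, None], x)
    return _result(m, filled, 1, [])


IMPUTERS = {
    "missforest": impute_missforest,
    "knn": impute_knn,
    "mean": impute_mean,
    "min_shift": impute_min_shift,
}


def get_imputer(imputer_id: str):
    try:
        return IMPUTERS[imputer_id]
    except KeyError:
        raise ValueError(
            f"unknown imputer {imputer_id!r}; registered: {sorted(IMPUTERS)}"
        ) from None


def score_imputation(truth: QuantMatrix, imputed: QuantMatrix, mask: pd.DataFrame) -> dict:
    """RMSE and Pearson r between true and imputed values over masked cells."""
    mk = mask.to_numpy(dtype=bool)
    if not mk.any():
        raise ValueError("mask is empty; nothing to score")
    t = truth.values.to_numpy(dtype=float)[mk]
    p = imputed.values.to_numpy(dtype=float)[mk]
    if np.isnan(p).any():
        raise ValueError("imputed matrix still has missing cells under the mask")
    rmse = float(np.sqrt(np.mean((t - p) ** 2)))
    if len(t) < 2 or np.std(t) == 0 or np.std(p) == 0:
        warnings.warn("Pearson r undefined (zero variance over masked cells)", stacklevel=2)
        r = float("nan")
    else:
        r = float(stats.pearsonr(t, p).statistic)
    return {"rmse": rmse, "pearson_r": r}


def benchmark_imputers(m: QuantMatrix, specs: list[ImputerSpec], exp) -> pd.DataFrame:
    """Score several imputers on identical masks (paired design).

    Returns a long table (imputer, fraction, repeat, rmse, pearson_r,
    failed); per-fraction means can be ranked directly from it.
    """
    from .missingness import mask_completely_at_random, _run_seed

    if not specs:
        raise ValueError("at least one imputer spec required")
    rows = []
    for fi, frac in enumerate(exp.masking_fractions):
        for rep in range(exp.n_repeats):
            run_seed = _run_seed(exp.seed, fi, rep)
            masked, mask = mask_completely_at_random(m, frac, run_seed)
            for spec in specs:
                fn = get_imputer(spec.id)
                seeded = ImputerSpec(**{**spec.__dict__, "seed": run_seed})
                try:
                    res = fn(masked, seeded)
                    scores = score_imputation(m, res.matrix, mask)
                    rows.append({"imputer": spec.id, "fraction": frac,
                                 "repeat": rep, "failed": False, **scores})
                except Exception as err:  # noqa: BLE001
                    logger.warning("%s failed at %.2f/%d: %s", spec.id, frac, rep, err)
                    rows.append({"imputer": spec.id, "fraction": frac, "repeat": rep,
                                 "failed": True, "rmse": np.nan, "pearson_r": np.nan})
    return pd.DataFrame(rows)
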