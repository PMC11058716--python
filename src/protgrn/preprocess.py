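"""Normalization, missingness filtering and imputation.

Preprocessing follows the fixed order log2 -> global median normalization ->
50 % missingness filter -> imputation. Two imputers are provided, matching
the two missingness mechanisms the pipeline later arbitrates between:

* :class:`ProteinKNNImputer` — assumes missingness at random; each missing
  cell is filled with the average of that sample's value over the k nearest
  proteins (Euclidean distance on co-observed cells, overlap-rescaled).
* :class:`MinProbImputer` — assumes left-censoring (low abundance); missing
  cells are drawn from a Gaussian centred at a low quantile of the sample's
  observed distribution.

Both are scikit-learn transformers operating on protein x sample arrays with
NaN marking missing entries, and both are the identity on observed cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics.pairwise import nan_euclidean_distances
from sklearn.utils.validation import check_random_state

from .datasets import CONDITIONS, ExpressionDataset
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputationConfig:
    """Imputer choice and parameters (defaults mirror imputeLCMD)."""

    method: str = "knn"
    knn_k: int = 10
    minprob_quantile: float = 0.01
    minprob_sigma_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in ("knn", "minprob"):
            raise ValidationError("method must be 'knn' or 'minprob'")
        if self.knn_k < 1:
            raise ValidationError("knn_k must be >= 1")
        if not 0 < self.minprob_quantile < 0.5:
            raise ValidationError("minprob_quantile must be in (0, 0.5)")
        if self.minprob_sigma_scale <= 0:
            raise ValidationError("minprob_sigma_scale must be positive")


def log2_transform(data: ExpressionDataset) -> ExpressionDataset:
    """Base-2 log transform of observed cells; the mask is unchanged."""
    obs = ~data.missing_mask
    if np.any(data.values[obs] <= 0):
        raise ValidationError("log2 transform requires positive observed values")
    values = data.values.copy()
    values[obs] = np.log2(values[obs])
    return replace(data, values=values)


def median_normalize(data: ExpressionDataset) -> ExpressionDataset:
    """Shift each sample so its observed-cell median equals the global median."""
    obs = ~data.missing_mask
    if np.any(obs.sum(axis=0) == 0):
        raise ValidationError("a sample with zero observed cells cannot be normalized")
    x = data.observed()
    global_median = np.nanmedian(x)
    col_medians = np.nanmedian(x, axis=0)
    values = data.values + (global_median - col_medians)[None, :]
    values[data.missing_mask] = data.values[data.missing_mask]
    return replace(data, values=values)


def filter_missingness(data: ExpressionDataset, max_frac: float = 0.5) -> ExpressionDataset:
    """Drop proteins whose missing fraction strictly exceeds ``max_frac``."""
    frac = data.missing_mask.mean(axis=1)
    keep = frac <= max_frac
    if not keep.any():
        raise ValidationError("missingness filter removed every protein")
    if not keep.all():
        logger.info("missingness filter dropped %d/%d proteins", (~keep).sum(), len(keep))
    return data.select_proteins(keep)


class ProteinKNNImputer(TransformerMixin, BaseEstimator):
    """KNN imputation over protein rows with a minimum co-observation overlap.

    Parameters
    ----------
    n_neighbors : number of nearest proteins to average (default 10, the
        imputeLCMD default).
    min_overlap : minimum number of co-observed samples for a protein pair to
        count as neighbours; rows with no valid neighbour for a cell fall
        back to the protein-wise observed mean (logged).
    """

    def __init__(self, n_neighbors: int = 10, min_overlap: int = 2):
        self.n_neighbors = n_neighbors
        self.min_overlap = min_overlap

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("expected a 2-D protein x sample array")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        mask = np.isnan(X)
        if not mask.any():
            return X.copy()
        out = X.copy()
        obs = ~mask
        # Pairwise distances on co-observed cells, rescaled by overlap
        # (nan_euclidean convention); pairs below the overlap floor are
        # excluded from the neighbour pool.
        dist = nan_euclidean_distances(X, X)
        overlap = obs.astype(float) @ obs.T.astype(float)
        np.fill_diagonal(dist, np.inf)
        dist[overlap < self.min_overlap] = np.inf
        n_fallback = 0
        for i, j in zip(*np.nonzero(mask)):
            candidates = np.nonzero(obs[:, j] & np.isfinite(dist[i]))[0]
            if candidates.size == 0:
                row = X[i][obs[i]]
                out[i, j] = row.mean() if row.size else np.nanmean(X[:, j])
                n_fallback += 1
                continue
            order = candidates[np.argsort(dist[i, candidates], kind="stable")]
            nearest = order[: self.n_neighbors]
            out[i, j] = X[nearest, j].mean()
        if n_fallback:
            logger.warning("KNN imputer fell back to protein means for %d cell(s)", n_fallback)
        return out


class MinProbImputer(TransformerMixin, BaseEstimator):
    """Left-censored imputation from a Gaussian at a low sample quantile.

    Missing cells in sample s are drawn from N(q_s, sigma^2) where q_s is the
    ``quantile`` (default 0.01) of the sample's observed values and sigma is
    ``sigma_scale`` times the median protein-wise observed standard deviation.
    """

    def __init__(self, quantile: float = 0.01, sigma_scale: float = 1.0,
                 random_state=None):
        self.quantile = quantile
        self.sigma_scale = sigma_scale
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("expected a 2-D protein x sample array")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        mask = np.isnan(X)
        if not mask.any():
            return X.copy()
        rng = check_random_state(self.random_state)
        out = X.copy()
        with np.errstate(invalid="ignore"):
            row_sd = np.nanstd(X, axis=1, ddof=1)
        sigma = self.sigma_scale * np.nanmedian(row_sd)
        if not np.isfinite(sigma) or sigma <= 0:
            sigma = 1e-6
        col_q = np.nanquantile(X, self.quantile, axis=0)
        for j in range(X.shape[1]):
            rows = np.nonzero(mask[:, j])[0]
            if rows.size:
                out[rows, j] = rng.normal(col_q[j], sigma, rows.size)
        return out


def _impute_array(X: np.ndarray, cfg: ImputationConfig, seed: int | None) -> np.ndarray:
    if cfg.method == "knn":
        imputer = ProteinKNNImputer(n_neighbors=cfg.knn_k)
    else:
        imputer = MinProbImputer(
            quantile=cfg.minprob_quantile,
            sigma_scale=cfg.minprob_sigma_scale,
            random_state=seed,
        )
    return imputer.fit_transform(X)


def impute(
    data: ExpressionDataset, cfg: ImputationConfig, seed: int | None = 0,
    per_condition: bool = True,
) -> ExpressionDataset:
    """Fill all missing cells; observed cells are never altered.

    Imputation runs within each condition separately so that no treatment
    signal leaks across groups through borrowed neighbours or quantiles.
    """
    X = data.observed()
    out = X.copy()
    if per_condition:
        for k, cond in enumerate(CONDITIONS):
            m = data.sheet.condition_mask(cond)
            if m.any():
                out[:, m] = _impute_array(
                    X[:, m], cfg, None if seed is None else seed + k
                )
    else:
        out = _impute_array(X, cfg, seed)
    if np.isnan(out).any():
        raise ValidationError("imputation left missing values")
    mask = np.zeros_like(data.missing_mask)
    return replace(data, values=out, missing_mask=mask)


def impute_knn(data: ExpressionDataset, cfg: ImputationConfig | None = None) -> ExpressionDataset:
    cfg = cfg or ImputationConfig(method="knn")
    return impute(data, replace(cfg, method="knn") if cfg.method != "knn" else cfg, seed=None)


def impute_minprob(
    data: ExpressionDataset, cfg: ImputationConfig | None = None, seed: int = 0
) -> ExpressionDataset:
    cfg = cfg or ImputationConfig(method="minprob")
    cfg = replace(cfg, method="minprob") if cfg.method != "minprob" else cfg
    return impute(data, cfg, seed=seed)


def preprocess(
    data: ExpressionDataset, cfg: ImputationConfig | None = None, seed: int = 0,
    max_missing_frac: float = 0.5, log_scale: bool = True,
) -> ExpressionDataset:
    """Full preprocessing chain: log2 -> median normalize -> filter -> impute."""
    cfg = cfg or ImputationConfig()
    if log_scale:
        data = log2_transform(data)
    data = median_normalize(data)
    data = filter_missingness(data, max_missing_frac)
    return impute(data, cfg, seed=seed)
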