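"""Presence-only suitability algorithms behind a single fit/predict interface.

Three deterministic algorithm families produce [0, 1] suitability surfaces
from occurrence environmental vectors:

``bioclim``
    Classic climate-envelope: 1.0 inside the mean +/- ``sd_cutoff`` * sd box
    on every variable, 0.5 inside the min-max envelope, 0.0 outside.  The
    default cutoff 0.674 brackets the central half of a normal variable.

``envelope_score``
    Fraction of variables whose cell value lies within the training min-max
    range; a graded relaxation of the envelope.

``env_distance``
    Environmental-distance model: variables rescaled to [0, 1] by their
    study-area range, distance from each cell to the mean of its
    ``n_nearest_points`` nearest training points under a configurable metric
    (euclidean, mahalanobis, gower or chebyshev); suitability decays linearly
    to zero at ``max_distance_fraction`` of the metric's maximum distance.

Determinism is deliberate: the consensus machinery only requires several
independent [0, 1] predictions with evaluation scores, and exactly
reproducible algorithms keep every downstream contract testable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .raster import EnvStack, Grid, Layer

ALGORITHMS = ("bioclim", "envelope_score", "env_distance")
DISTANCE_METRICS = ("euclidean", "mahalanobis", "gower", "chebyshev")


@dataclass(frozen=True)
class AlgorithmConfig:
    algorithm: str
    params: dict[str, Any] = field(default_factory=dict)
    model_id: str = ""

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        p = dict(self.params)
        if self.algorithm == "bioclim" and p.get("sd_cutoff", 0.674) <= 0:
            raise ValueError("sd_cutoff must be positive")
        if self.algorithm == "env_distance":
            metric = p.get("metric", "euclidean")
            if metric not in DISTANCE_METRICS:
                raise ValueError(f"unknown metric {metric!r}")
            if not (0 < p.get("max_distance_fraction", 0.5) <= 1):
                raise ValueError("max_distance_fraction must be in (0, 1]")
        if not self.model_id:
            object.__setattr__(self, "model_id", self.algorithm)


def default_ensemble() -> list[AlgorithmConfig]:
    """The default model ensemble: two envelope settings, the graded
    envelope, and environmental distance under three metrics.

    The default ensemble is drawn entirely from the centroid-distance family
    (``n_nearest_points=0``): centroid distance gives occurrences the same
    score distribution as the surrounding niche cells, the exchangeability
    the fixed-sensitivity omission threshold assumes.  Exact-envelope models
    (bioclim, envelope_score) score every training occurrence at their
    maximum, which degenerates an order-statistic threshold; they remain
    available for explicit configuration.
    """
    return [
        AlgorithmConfig("env_distance", {"metric": "euclidean",
                                         "n_nearest_points": 0}, "dist_euclidean"),
        AlgorithmConfig("env_distance", {"metric": "euclidean", "n_nearest_points": 0,
                                         "max_distance_fraction": 0.3},
                        "dist_euclidean_sharp"),
        AlgorithmConfig("env_distance", {"metric": "gower",
                                         "n_nearest_points": 0}, "dist_gower"),
        AlgorithmConfig("env_distance", {"metric": "gower", "n_nearest_points": 0,
                                         "max_distance_fraction": 0.3},
                        "dist_gower_sharp"),
        AlgorithmConfig("env_distance", {"metric": "chebyshev",
                                         "n_nearest_points": 0}, "dist_chebyshev"),
        AlgorithmConfig("env_distance", {"metric": "mahalanobis",
                                         "n_nearest_points": 0}, "dist_mahalanobis"),
    ]


@dataclass
class FittedModel:
    config: AlgorithmConfig
    variables: list[str]
    mean: np.ndarray
    sd: np.ndarray
    vmin: np.ndarray
    vmax: np.ndarray
    training: np.ndarray                      # (n, p) raw training vectors
    covariance: np.ndarray | None = None      # mahalanobis only (regularized)

    @property
    def model_id(self) -> str:
        return self.config.model_id


@dataclass
class SuitabilityMap:
    """Per-group suitability surface (the eco-linguistic niche, ELN)."""

    group_id: str
    grid: Grid
    values: np.ndarray
    nodata_mask: np.ndarray
    provenance: list[tuple[str, float]] = field(default_factory=list)
    omission_threshold: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.nodata_mask = np.asarray(self.nodata_mask, bool)
        v = self.values[~self.nodata_mask]
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("suitability outside [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    @property
    def valid(self) -> np.ndarray:
        return ~self.nodata_mask

    def as_layer(self, name: str | None = None) -> Layer:
        vals = np.where(self.nodata_mask, 0.0, self.values)
        return Layer(self.grid, vals, self.nodata_mask.copy(),
                     name or f"eln_{self.group_id}")

    def copy(self) -> "SuitabilityMap":
        return SuitabilityMap(self.group_id, self.grid, self.values.copy(),
                              self.nodata_mask.copy(), list(self.provenance),
                              self.omission_threshold)


def fit(config: AlgorithmConfig, env_vectors: pd.DataFrame) -> FittedModel:
    """Fit per-variable statistics (and covariance for mahalanobis)."""
    X = np.asarray(env_vectors, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 training vectors")
    if not np.all(np.isfinite(X)):
        raise ValueError("training vectors contain missing values")
    model = FittedModel(
        config=config,
        variables=list(env_vectors.columns),
        mean=X.mean(axis=0),
        sd=X.std(axis=0, ddof=1),
        vmin=X.min(axis=0),
        vmax=X.max(axis=0),
        training=X.copy(),
    )
    if config.algorithm == "env_distance" and \
            config.params.get("metric", "euclidean") == "mahalanobis":
        model.covariance = _regularized_covariance(X)
    return model


def _regularized_covariance(X: np.ndarray) -> np.ndarray:
    """Sample covariance, ridge-regularized if not positive definite."""
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    p = cov.shape[0]
    try:
        np.linalg.cholesky(cov)
        return cov
    except np.linalg.LinAlgError:
        eps = 1e-6 * np.trace(cov) / p
        if eps <= 0:
            eps = 1e-6
        warnings.warn("singular covariance; ridge-regularizing diagonal")
        return cov + eps * np.eye(p)


def predict(model: FittedModel, stack: EnvStack, group_id: str = "") -> SuitabilityMap:
    """Apply a fitted model over every valid cell of the stack."""
    stack.require(model.variables)
    mask = stack.shared_mask
    valid = ~mask
    X = np.column_stack([stack[v].values[valid] for v in model.variables])
    algo = model.config.algorithm
    if algo == "bioclim":
        suit = _predict_bioclim(model, X)
    elif algo == "envelope_score":
        suit = _predict_envelope_score(model, X)
    else:
        suit = _predict_env_distance(model, X)
    values = np.zeros(stack.grid.shape)
    values[valid] = suit
    return SuitabilityMap(group_id, stack.grid, values, mask.copy(),
                          provenance=[(model.model_id, 1.0)])


def _predict_bioclim(model: FittedModel, X: np.ndarray) -> np.ndarray:
    cutoff = model.config.params.get("sd_cutoff", 0.674)
    lo = model.mean - cutoff * model.sd
    hi = model.mean + cutoff * model.sd
    core = np.all((X >= lo) & (X <= hi), axis=1)
    envelope = np.all((X >= model.vmin) & (X <= model.vmax), axis=1)
    return np.where(core, 1.0, np.where(envelope, 0.5, 0.0))


def _predict_envelope_score(model: FittedModel, X: np.ndarray) -> np.ndarray:
    inside = (X >= model.vmin) & (X <= model.vmax)
    return inside.mean(axis=1)


def _predict_env_distance(model: FittedModel, X: np.ndarray) -> np.ndarray:
    params = model.config.params
    metric = params.get("metric", "euclidean")
    frac = params.get("max_distance_fraction", 0.5)
    n_nearest = params.get("n_nearest_points", 1)
    p = X.shape[1]

    # rescale by the study-area range so all variables are commensurate
    rng_lo = X.min(axis=0)
    rng_hi = X.max(axis=0)
    span = np.where(rng_hi > rng_lo, rng_hi - rng_lo, 1.0)

    def norm(a: np.ndarray) -> np.ndarray:
        return (a - rng_lo) / span

    Xn = norm(X)
    Tn = norm(model.training)

    if metric == "mahalanobis":
        # covariance estimated on raw training data, rescaled consistently
        cov = _regularized_covariance(model.training / span)
        cov_inv = np.linalg.inv(cov)
        d = _maha_to_reference(Xn, Tn, cov_inv, n_nearest)
        ref = Tn.mean(axis=0)
        diff = Xn - ref
        d_all = np.sqrt(np.einsum("ij,jk,ik->i", diff, cov_inv, diff))
        d_max_metric = float(d_all.max()) if d_all.size else 1.0
    else:
        d = _minkowski_to_reference(Xn, Tn, metric, n_nearest)
        d_max_metric = {"euclidean": float(np.sqrt(p)),
                        "gower": 1.0, "chebyshev": 1.0}[metric]
    d_max = frac * d_max_metric
    if d_max <= 0:
        return (d == 0).astype(float)
    return np.maximum(0.0, 1.0 - d / d_max)


def _pairwise(Xn: np.ndarray, Tn: np.ndarray, metric: str) -> np.ndarray:
    diff = np.abs(Xn[:, None, :] - Tn[None, :, :])
    if metric == "euclidean":
        return np.sqrt((diff ** 2).sum(axis=2))
    if metric == "gower":
        return diff.mean(axis=2)
    return diff.max(axis=2)  # chebyshev


def _minkowski_to_reference(Xn, Tn, metric, n_nearest) -> np.ndarray:
    """Distance from each cell to the mean of its n nearest training points.

    ``n_nearest <= 0`` means all training points (the centroid); the default 1
    reduces to nearest-training-point distance.
    """
    if n_nearest <= 0 or n_nearest >= len(Tn):
        ref = Tn.mean(axis=0)
        diff = np.abs(Xn - ref)
        if metric == "euclidean":
            return np.sqrt((diff ** 2).sum(axis=1))
        if metric == "gower":
            return diff.mean(axis=1)
        return diff.max(axis=1)
    dists = _pairwise(Xn, Tn, metric)
    if n_nearest == 1:
        return dists.min(axis=1)
    idx = np.argpartition(dists, n_nearest - 1, axis=1)[:, :n_nearest]
    out = np.empty(len(Xn))
    for i in range(len(Xn)):
        ref = Tn[idx[i]].mean(axis=0)
        diff = np.abs(Xn[i] - ref)
        if metric == "euclidean":
            out[i] = np.sqrt((diff ** 2).sum())
        elif metric == "gower":
            out[i] = diff.mean()
        else:
            out[i] = diff.max()
    return out


def _maha_to_reference(Xn, Tn, cov_inv, n_nearest) -> np.ndarray:
    if n_nearest <= 0 or n_nearest >= len(Tn):
        ref = Tn.mean(axis=0)
        diff = Xn - ref
        return np.sqrt(np.einsum("ij,jk,ik->i", diff, cov_inv, diff))
    # nearest under mahalanobis, then distance to the local mean
    diff = Xn[:, None, :] - Tn[None, :, :]
    d2 = np.einsum("nij,jk,nik->ni", diff, cov_inv, diff)
    if n_nearest == 1:
        return np.sqrt(d2.min(axis=1))
    idx = np.argpartition(d2, n_nearest - 1, axis=1)[:, :n_nearest]
    out = np.empty(len(Xn))
    for i in range(len(Xn)):
        ref = Tn[idx[i]].mean(axis=0)
        dd = Xn[i] - ref
        out[i] = np.sqrt(dd @ cov_inv @ dd)
    return out
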