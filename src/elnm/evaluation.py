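"""Model evaluation and the weighted elitist consensus.

Presence-only models are scored against random background (pseudo-absence)
cells with three statistics:

* ACC — overall accuracy at a threshold, (TP + TN) / total;
* AUC — rank-based area under the ROC curve (ties count one half);
* partial-ROC ratio — bootstrap mean of the model's partial AUC over the
  high-sensitivity region (sensitivity >= 1 - E) divided by the null
  diagonal's partial AUC over the same region; values above 1 indicate
  better-than-random performance where omission is low.

The consensus is "weighted elitist": keep the top-k models by held-out AUC
(ties broken by partial-ROC ratio, then model id), weight them proportionally
to their score (or equally), and add the weighted predictions.  A fixed
sensitivity omission threshold then zeroes suitability below the level that
would omit at most a fraction ``s`` of the training occurrences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .models import SuitabilityMap
from .raster import EnvStack

DEFAULT_SENSITIVITY = 0.10
BACKGROUND_FACTOR = 10
BACKGROUND_CAP = 10_000


@dataclass
class EvaluationResult:
    model_id: str
    acc: float
    auc: float
    proc_ratio: float
    n_presence: int
    n_background: int
    seed: int | None = None


@dataclass
class ConsensusConfig:
    top_k: int | None = None            # None -> half the models, rounded up
    weighting: str = "score_proportional"
    sensitivity: float = DEFAULT_SENSITIVITY
    split_fraction: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.weighting not in ("score_proportional", "equal"):
            raise ValueError("weighting must be 'score_proportional' or 'equal'")
        if not (0 < self.sensitivity < 1):
            raise ValueError("sensitivity must be in (0, 1)")
        if not (0 < self.split_fraction < 1):
            raise ValueError("split_fraction must be in (0, 1)")


def sample_background(stack: EnvStack, n: int, seed: int | None = None,
                      exclude: np.ndarray | None = None) -> np.ndarray:
    """n uniform random valid cells as (lon, lat) centers, excluding the cells
    containing any of the ``exclude`` points.  Seeded and reproducible."""
    valid = ~stack.shared_mask
    if exclude is not None and len(exclude):
        for lon, lat in np.asarray(exclude, float):
            try:
                r, c = stack.grid.index_of(lon, lat)
            except ValueError:
                continue
            valid[r, c] = False
    rows, cols = np.nonzero(valid)
    if n > len(rows):
        raise ValueError(f"requested {n} background cells, only {len(rows)} available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n, replace=False)
    lons = stack.grid.origin_lon + (cols[idx] + 0.5) * stack.grid.cell_size
    lats = stack.grid.origin_lat - (rows[idx] + 0.5) * stack.grid.cell_size
    return np.column_stack([lons, lats])


def compute_auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based AUC: P(random presence outscores random background), ties 1/2."""
    from scipy.stats import rankdata

    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    if len(p) == 0 or len(b) == 0:
        raise ValueError("need at least one presence and one background score")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[:len(p)].sum() - len(p) * (len(p) + 1) / 2
    return float(u / (len(p) * len(b)))


def compute_acc(presence_scores: np.ndarray, background_scores: np.ndarray,
                threshold: float) -> float:
    """Accuracy treating presence >= threshold as TP, background < threshold as TN."""
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    tp = int((p >= threshold).sum())
    tn = int((b < threshold).sum())
    return (tp + tn) / (len(p) + len(b))


def _roc_curve(presence: np.ndarray, background: np.ndarray):
    """(fpr, tpr) stepping through all distinct score thresholds, descending."""
    thresholds = np.unique(np.concatenate([presence, background]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        tpr.append((presence >= t).mean())
        fpr.append((background >= t).mean())
    tpr.append(1.0)
    fpr.append(1.0)
    return np.array(fpr), np.array(tpr)


def _partial_auc(fpr: np.ndarray, tpr: np.ndarray, min_tpr: float) -> tuple[float, float]:
    """(model pAUC, null pAUC) over the region with sensitivity >= min_tpr.

    The curve is interpolated linearly to the exact sensitivity bound; the
    null pAUC is the area under the diagonal over the same 1-specificity span.
    """
    fpr = np.asarray(fpr, float)
    tpr = np.asarray(tpr, float)
    keep = tpr >= min_tpr
    if not keep.any():
        return 0.0, 0.0
    i0 = int(np.argmax(keep))
    xs = list(fpr[keep])
    ys = list(tpr[keep])
    if i0 > 0 and tpr[i0] > min_tpr:
        # interpolate between the last point below and the first at/above
        x_lo, y_lo = fpr[i0 - 1], tpr[i0 - 1]
        x_hi, y_hi = fpr[i0], tpr[i0]
        if y_hi > y_lo:
            x_cut = x_lo + (min_tpr - y_lo) * (x_hi - x_lo) / (y_hi - y_lo)
        else:
            x_cut = x_lo
        xs = [x_cut, *xs]
        ys = [min_tpr, *ys]
    model = float(np.trapezoid(ys, xs))
    x0 = xs[0]
    null = float((1.0 - x0 ** 2) / 2.0)
    return model, null


def partial_roc_ratio(presence_scores: np.ndarray, background_scores: np.ndarray,
                      omission_e: float = 0.10, n_boot: int = 100,
                      seed: int | None = None) -> float:
    """Bootstrap mean of model/null partial-AUC ratios (sensitivity >= 1 - E).

    Each bootstrap resamples 50% of the presences with replacement; the
    background is fixed.
    """
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    if len(p) < 2:
        raise ValueError("partial ROC needs at least 2 presences")
    rng = np.random.default_rng(seed)
    half = max(1, len(p) // 2)
    ratios = []
    for _ in range(n_boot):
        sample = rng.choice(p, size=half, replace=True)
        fpr, tpr = _roc_curve(sample, b)
        model, null = _partial_auc(fpr, tpr, 1.0 - omission_e)
        if null > 0:
            ratios.append(model / null)
    if not ratios:
        return float("nan")
    return float(np.mean(ratios))


def evaluate_scores(model_id: str, presence_scores, background_scores,
                    threshold: float = 0.5, omission_e: float = 0.10,
                    n_boot: int = 100, seed: int | None = None) -> EvaluationResult:
    """Bundle ACC, AUC and partial-ROC ratio for one model's scores."""
    return EvaluationResult(
        model_id=model_id,
        acc=compute_acc(presence_scores, background_scores, threshold),
        auc=compute_auc(presence_scores, background_scores),
        proc_ratio=partial_roc_ratio(presence_scores, background_scores,
                                     omission_e=omission_e, n_boot=n_boot, seed=seed),
        n_presence=len(presence_scores),
        n_background=len(background_scores),
        seed=seed,
    )


def weighted_elitist_consensus(predictions: list[SuitabilityMap],
                               evaluations: list[EvaluationResult],
                               config: ConsensusConfig | None = None) -> SuitabilityMap:
    """Top-k selection by AUC, score-proportional weighting, weighted addition."""
    config = config or ConsensusConfig()
    if len(predictions) != len(evaluations):
        raise ValueError("one evaluation per prediction required")
    if not predictions:
        raise ValueError("no predictions to combine")
    grid = predictions[0].grid
    for pm in predictions[1:]:
        if pm.grid != grid:
            raise ValueError("all predictions must share one grid")

    k = config.top_k if config.top_k is not None else (len(predictions) + 1) // 2
    if k > len(predictions):
        warnings.warn(f"top_k={k} exceeds {len(predictions)} models; clamping")
        k = len(predictions)
    if k < 1:
        raise ValueError("top_k must be at least 1")

    order = sorted(range(len(predictions)),
                   key=lambda i: (-evaluations[i].auc, -evaluations[i].proc_ratio,
                                  evaluations[i].model_id))
    chosen = order[:k]
    scores = np.array([evaluations[i].auc for i in chosen], float)
    if config.weighting == "equal" or scores.sum() <= 0:
        weights = np.full(k, 1.0 / k)
    else:
        weights = scores / scores.sum()

    values = np.zeros(grid.shape)
    mask = np.zeros(grid.shape, bool)
    provenance = []
    for w, i in zip(weights, chosen):
        values += w * predictions[i].values
        mask |= predictions[i].nodata_mask
        provenance.append((evaluations[i].model_id, float(w)))
    return SuitabilityMap(predictions[0].group_id, grid, values, mask,
                          provenance=provenance)


def fixed_sensitivity_threshold(suitability: SuitabilityMap,
                                occurrence_scores: np.ndarray,
                                s: float = DEFAULT_SENSITIVITY
                                ) -> tuple[float, SuitabilityMap]:
    """Omission threshold at fixed sensitivity.

    tau is the (k+1)-th smallest occurrence suitability with k = floor(s * n),
    so at most a fraction s of the training occurrences fall strictly below
    it.  Cells with suitability < tau are zeroed; tau is stored on the map.
    """
    scores = np.sort(np.asarray(occurrence_scores, float))
    n = len(scores)
    if n == 0:
        raise ValueError("no occurrence scores")
    k = int(np.floor(s * n))
    tau = float(scores[min(k, n - 1)])
    out = suitability.copy()
    out.values = np.where(out.values < tau, 0.0, out.values)
    out.omission_threshold = tau
    return tau, out


def scores_at_points(suitability: SuitabilityMap, points: np.ndarray) -> np.ndarray:
    """Suitability values at point localities (nearest cell)."""
    pts = np.asarray(points, float)
    out = np.empty(len(pts))
    for i, (lon, lat) in enumerate(pts):
        r, c = suitability.grid.index_of(lon, lat)
        out[i] = suitability.values[r, c]
    return out
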