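"""End-to-end orchestration: world -> occurrences -> ensemble -> consensus
-> niche space -> patterns -> potentials -> growing season.

Every stage is a pure call into the library; this module wires them
together, derives per-stage seeds from one global seed, and writes all
artifacts (text rasters, CSV tables, JSON report, Newick dendrogram) with
provenance.  Re-running with the same config reproduces every stochastic
output exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bioclim import monthly_mean_temperature
from .elp import (AccessibilityConfig, DEFAULT_D_MIN, DEFAULT_G_MIN,
                  accessibility_filter, diversity_summary, geographic_overlap_matrix,
                  identify_elps, range_from_eln)
from .evaluation import (BACKGROUND_CAP, BACKGROUND_FACTOR, ConsensusConfig,
                         EvaluationResult, evaluate_scores, fixed_sensitivity_threshold,
                         sample_background, scores_at_points, weighted_elitist_consensus)
from .models import AlgorithmConfig, SuitabilityMap, default_ensemble, fit, predict
from .niche_space import (PROJECTION_THRESHOLD, cluster_niches, dendrogram_newick,
                          dissimilarity, fit_pca, overlap_matrix)
from .occurrences import OccurrenceSet, attach_env, sample_occurrences
from .potentials import delta_eln, eco_linguistic_potential, ecological_risk, growing_season
from .raster import write_raster
from .synthetic import SyntheticWorld, SyntheticWorldConfig, generate_world


@dataclass
class PipelineConfig:
    seed: int = 0
    synthetic: SyntheticWorldConfig | None = None
    occurrence_cap: int = 50
    occurrence_minimum: int = 10
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    algorithms: list[AlgorithmConfig] = field(default_factory=default_ensemble)
    projection_threshold: float = PROJECTION_THRESHOLD
    g_min: float = DEFAULT_G_MIN
    d_min: float = DEFAULT_D_MIN
    out_dir: str | None = None

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2 ** 31)


@dataclass
class GroupResult:
    group_id: str
    family: str
    occurrences: OccurrenceSet
    evaluations: list[EvaluationResult]
    consensus_eval: EvaluationResult
    eln: SuitabilityMap               # consensus after omission thresholding
    eln_raw: SuitabilityMap           # consensus before thresholding
    omission_threshold: float


@dataclass
class PipelineResult:
    config: PipelineConfig
    world: SyntheticWorld
    groups: dict[str, GroupResult]
    overlap_d: pd.DataFrame
    overlap_i: pd.DataFrame
    geo_overlap: pd.DataFrame
    linkage: np.ndarray
    elps: list
    diversity: pd.DataFrame
    delta: "np.ndarray"
    gs_mgs: float
    gs_risk: float | None
    pca_explained: np.ndarray

    @property
    def group_ids(self) -> list[str]:
        return list(self.groups)


def model_group(stack, occ: OccurrenceSet, algorithms, consensus_cfg: ConsensusConfig,
                seed: int, group_id: str = "", variables=None) -> GroupResult:
    """Fit the ensemble for one group and build its thresholded consensus.

    Models are ranked on a held-out occurrence split (fitted on the training
    half, scored on the held-out half against random background); the final
    per-algorithm maps entering the consensus are refitted on all
    occurrences, a standard calibrate-on-all-data ensemble practice.
    """
    rng = np.random.default_rng(seed)
    env = occ.env_vectors
    n = len(env)
    idx = rng.permutation(n)
    n_train = max(2, int(round(consensus_cfg.split_fraction * n)))
    n_train = min(n_train, n - 1) if n > 2 else n
    train_idx, test_idx = idx[:n_train], idx[n_train:]
    if len(test_idx) == 0:
        train_idx = test_idx = idx

    n_bg = min(BACKGROUND_FACTOR * n, BACKGROUND_CAP)
    bg = sample_background(stack, n_bg, seed=seed + 1, exclude=occ.points)

    predictions, evaluations = [], []
    for cfg in algorithms:
        split_model = fit(cfg, env.iloc[train_idx])
        split_map = predict(split_model, stack, group_id=group_id)
        p_scores = scores_at_points(split_map, occ.points[test_idx])
        b_scores = scores_at_points(split_map, bg)
        evaluations.append(evaluate_scores(cfg.model_id, p_scores, b_scores,
                                           seed=seed + 2))
        full_model = fit(cfg, env)
        predictions.append(predict(full_model, stack, group_id=group_id))

    consensus = weighted_elitist_consensus(predictions, evaluations, consensus_cfg)
    occ_scores = scores_at_points(consensus, occ.points)
    tau, eln = fixed_sensitivity_threshold(consensus, occ_scores,
                                           s=consensus_cfg.sensitivity)
    c_eval = evaluate_scores("consensus", scores_at_points(consensus, occ.points),
                             scores_at_points(consensus, bg), seed=seed + 3)
    return GroupResult(group_id, "", occ, evaluations, c_eval, eln, consensus, tau)


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    config = config or PipelineConfig()
    world_cfg = config.synthetic or SyntheticWorldConfig(seed=config.stage_seed("world"))
    world = generate_world(world_cfg)
    stack = world.stack

    groups: dict[str, GroupResult] = {}
    for g in world.groups:
        occ = sample_occurrences(g, world.villages[g.group_id],
                                 cap=config.occurrence_cap,
                                 minimum=config.occurrence_minimum,
                                 seed=config.stage_seed(f"sample:{g.group_id}"))
        attach_env(occ, stack)
        res = model_group(stack, occ, config.algorithms, config.consensus,
                          seed=config.stage_seed(f"model:{g.group_id}"),
                          group_id=g.group_id)
        res.family = g.family
        groups[g.group_id] = res

    elns = [groups[g.group_id].eln for g in world.groups]
    overlap_d, overlap_i = overlap_matrix(elns)
    link = cluster_niches(dissimilarity(overlap_d))

    sea = stack.shared_mask
    ranges = []
    for g in world.groups:
        rng_grid = range_from_eln(groups[g.group_id].eln)
        cfg = AccessibilityConfig(maritime=(g.family == "Austronesian"))
        ranges.append(accessibility_filter(rng_grid, g.polygon, cfg, sea_mask=sea))
    geo = geographic_overlap_matrix(ranges)

    families = world.families
    elps = identify_elps([g.group_id for g in world.groups], geo, overlap_d,
                         g_min=config.g_min, d_min=config.d_min, families=families)
    meta = pd.DataFrame({"group_id": [g.group_id for g in world.groups],
                         "family": [g.family for g in world.groups],
                         "n_languages": [g.n_languages for g in world.groups]}
                        ).set_index("group_id")
    diversity = diversity_summary(elps, meta)

    tng = [groups[g.group_id].eln for g in world.groups if g.family == "TNG"]
    aus = [groups[g.group_id].eln for g in world.groups if g.family == "Austronesian"]
    delta = None
    if tng and aus:
        delta = delta_eln(eco_linguistic_potential(tng, "TNG"),
                          eco_linguistic_potential(aus, "Austronesian"))

    tmean = monthly_mean_temperature(stack.monthly["tmin"], stack.monthly["tmax"])
    gs = growing_season(tmean, stack.monthly["prec"])
    mgs, risk = ecological_risk(gs)

    pca = fit_pca(stack)

    result = PipelineResult(
        config=config, world=world, groups=groups,
        overlap_d=overlap_d, overlap_i=overlap_i, geo_overlap=geo,
        linkage=link, elps=elps, diversity=diversity,
        delta=delta, gs_mgs=mgs, gs_risk=risk,
        pca_explained=pca.explained_variance_fraction,
    )
    if config.out_dir:
        write_artifacts(result, Path(config.out_dir), gs=gs)
    return result


def write_artifacts(result: PipelineResult, out_dir: Path, gs=None) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for gid, gres in result.groups.items():
        write_raster(gres.eln.as_layer(), out_dir / f"eln_{gid}.asc")
    result.overlap_d.to_csv(out_dir / "overlap_schoener_d.csv")
    result.overlap_i.to_csv(out_dir / "overlap_hellinger_i.csv")
    result.geo_overlap.to_csv(out_dir / "geographic_overlap_jaccard.csv")
    result.diversity.to_csv(out_dir / "elp_diversity.csv", index=False)
    labels = result.group_ids
    (out_dir / "niche_dendrogram.nwk").write_text(
        dendrogram_newick(result.linkage, labels))
    if result.delta is not None:
        from .raster import Layer
        delta = result.delta
        lyr = Layer(delta.grid, np.where(delta.nodata_mask, 0.0, delta.values),
                    delta.nodata_mask, "delta_eln")
        write_raster(lyr, out_dir / "delta_eln.asc")
    if gs is not None:
        write_raster(gs, out_dir / "growing_season.asc")
    evals = []
    for gid, gres in result.groups.items():
        for ev in gres.evaluations + [gres.consensus_eval]:
            evals.append({"group_id": gid, "model_id": ev.model_id, "acc": ev.acc,
                          "auc": ev.auc, "proc_ratio": ev.proc_ratio})
    pd.DataFrame(evals).to_csv(out_dir / "evaluations.csv", index=False)
    report = {
        "version": __version__,
        "seed": result.config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(_config_digest(result.config), sort_keys=True).encode()
        ).hexdigest()[:16],
        "n_groups": len(result.groups),
        "n_elps": len(result.elps),
        "elns": labels,
        "mgs": result.gs_mgs,
        "ecological_risk": result.gs_risk,
        "pca_explained_pc1_pc2": [float(f) for f in result.pca_explained[:2]],
        "omission_thresholds": {g: result.groups[g].omission_threshold for g in labels},
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))


def _config_digest(config: PipelineConfig) -> dict:
    d = {
        "seed": config.seed,
        "occurrence_cap": config.occurrence_cap,
        "occurrence_minimum": config.occurrence_minimum,
        "projection_threshold": config.projection_threshold,
        "g_min": config.g_min,
        "d_min": config.d_min,
        "algorithms": [(a.algorithm, a.model_id, sorted(a.params.items()))
                       for a in config.algorithms],
        "consensus": asdict(config.consensus),
    }
    if config.synthetic is not None:
        d["synthetic"] = {k: v for k, v in asdict(config.synthetic).items()}
    return json.loads(json.dumps(d, default=str))
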