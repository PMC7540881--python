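#!/usr/bin/env python
"""Stage 3 — position the niches in ecological space.

Fits a PCA to the standardized 26-variable environment over all land cells,
projects each consensus niche's high-probability cells (suitability > 0.9)
into that space with a 61%-coverage inertia ellipse, computes the pairwise
Schoener's D / Hellinger's I overlap matrices, and clusters the niches by
complete linkage on the 1-overlap dissimilarities.  Writes the matrices,
ellipse parameters, the dendrogram (Newick), and a PCA scatter figure.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from elnm.niche_space import (cluster_niches, dendrogram_newick, dissimilarity,
                              fit_pca, inertia_ellipse, project_eln)
from elnm.pipeline import PipelineConfig, run_pipeline


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/niche_space"))
    args = ap.parse_args()
    warnings.filterwarnings("ignore")

    res = run_pipeline(PipelineConfig(seed=args.seed))
    args.out.mkdir(parents=True, exist_ok=True)
    stack = res.world.stack
    ids = res.group_ids

    pca = fit_pca(stack)
    pd.DataFrame(pca.loadings[:, :4], index=pca.variables,
                 columns=["PC1", "PC2", "PC3", "PC4"]).to_csv(
        args.out / "pca_loadings.csv")

    rows = []
    clouds = {}
    for gid in ids:
        cloud = project_eln(pca, res.groups[gid].eln, stack, threshold=0.9)
        clouds[gid] = cloud
        if cloud.empty:
            rows.append({"group_id": gid, "n_cells": 0})
            continue
        spec = inertia_ellipse(cloud.scores, coverage=0.61)
        rows.append({"group_id": gid, "n_cells": len(cloud.scores),
                     "center_pc1": spec.center[0], "center_pc2": spec.center[1],
                     "ellipse_area": float(np.pi * np.sqrt(
                         max(np.linalg.det(spec.covariance), 0.0)))})
    pd.DataFrame(rows).to_csv(args.out / "eln_ellipses.csv", index=False)

    D, I = res.overlap_d, res.overlap_i
    D.to_csv(args.out / "overlap_schoener_d.csv")
    I.to_csv(args.out / "overlap_hellinger_i.csv")
    link = cluster_niches(dissimilarity(D))
    (args.out / "dendrogram.nwk").write_text(dendrogram_newick(link, ids))

    _plot(pca, clouds, res, args.out / "pca_niches.png")

    print("explained variance (%):",
          np.round(100 * pca.explained_variance_fraction[:4], 2))
    print("mean off-diagonal D:",
          round(float((D.values.sum() - len(ids)) / (len(ids) ** 2 - len(ids))), 3))
    print(f"matrices, ellipses, dendrogram, figure in {args.out}/")


def _plot(pca, clouds, res, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    colors = {"TNG": "tab:green", "Austronesian": "tab:blue"}
    for gid, cloud in clouds.items():
        if cloud.empty:
            continue
        fam = res.groups[gid].family
        ax.scatter(cloud.scores[:, 0], cloud.scores[:, 1], s=2, alpha=0.25,
                   color=colors.get(fam, "gray"))
        spec = inertia_ellipse(cloud.scores, coverage=0.61)
        _draw_ellipse(ax, spec, colors.get(fam, "gray"), gid)
    ax.set_xlabel(f"PC1 ({100 * pca.explained_variance_fraction[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * pca.explained_variance_fraction[1]:.1f}%)")
    ax.set_title("Niches in ecological space (61% inertia ellipses)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)


def _draw_ellipse(ax, spec, color, label):
    import matplotlib.patches as mpatches

    vals, vecs = np.linalg.eigh(spec.covariance)
    angle = np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1]))
    width, height = 2 * np.sqrt(np.maximum(vals[::-1], 0))
    ax.add_patch(mpatches.Ellipse(spec.center, width, height, angle=angle,
                                  fill=False, color=color, lw=1.5))
    ax.annotate(label, spec.center, color=color, fontsize=8)


if __name__ == "__main__":
    main()
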