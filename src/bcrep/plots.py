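"""Static figures derived strictly from the pipeline's TSV/JSON outputs.

Presentation only — nothing downstream reads these files.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def _save(fig, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def diversity_bars(profiles_by_mode: dict, path) -> None:
    """Normalized diversity per repertoire, one panel per clonotype mode."""
    modes = list(profiles_by_mode)
    fig, axes = plt.subplots(len(modes), 1, figsize=(9, 3.2 * len(modes)), squeeze=False)
    for ax, mode in zip(axes[:, 0], modes):
        profs = sorted(profiles_by_mode[mode], key=lambda p: p["repertoire_id"])
        ids = [p["repertoire_id"] for p in profs]
        vals = [p["normalized_diversity"] for p in profs]
        ax.bar(range(len(ids)), vals, color="steelblue")
        ax.set_xticks(range(len(ids)))
        ax.set_xticklabels(ids, rotation=90, fontsize=6)
        ax.set_ylabel("clonotypes / reads")
        ax.set_title(f"normalized diversity ({mode})", fontsize=9)
    _save(fig, path)


def usage_bars(profiles: list, path) -> None:
    """IGHV gene usage frequencies per repertoire (grouped bars)."""
    genes = sorted({g for p in profiles for g in p["v_usage"]})
    fig, ax = plt.subplots(figsize=(9, 3.5))
    width = 0.9 / max(1, len(profiles))
    for i, p in enumerate(sorted(profiles, key=lambda p: p["repertoire_id"])):
        vals = [p["v_usage"].get(g, 0.0) for g in genes]
        ax.bar(np.arange(len(genes)) + i * width, vals, width=width)
    ax.set_xticks(np.arange(len(genes)) + 0.45)
    ax.set_xticklabels(genes, rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("fraction of clonotypes")
    ax.set_title("IGHV gene usage", fontsize=9)
    _save(fig, path)


def jaccard_heatmap(labels, D, path) -> None:
    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    im = ax.imshow(1.0 - np.asarray(D), cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(len(labels)))
    ax.set_yticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_yticklabels(labels, fontsize=6)
    fig.colorbar(im, label="Jaccard index")
    ax.set_title("pairwise repertoire overlap", fontsize=9)
    _save(fig, path)


def venn3_figure(venn_dict: dict, path) -> None:
    """Three-circle Venn with region counts (labels from the pipeline output)."""
    regions = venn_dict["regions"]
    labels = venn_dict["labels"]
    fig, ax = plt.subplots(figsize=(5, 5))
    centers = [(-0.5, 0.3), (0.5, 0.3), (0.0, -0.55)]
    for (x, y), lab in zip(centers, labels):
        ax.add_patch(plt.Circle((x, y), 1.0, fill=False, lw=1.5))
        ax.text(x * 1.9, y * 1.9, lab, ha="center", fontsize=10)
    pos = {"100": (-0.9, 0.55), "010": (0.9, 0.55), "001": (0.0, -1.1),
           "110": (0.0, 0.6), "101": (-0.55, -0.35), "011": (0.55, -0.35),
           "111": (0.0, 0.0)}
    for key, (x, y) in pos.items():
        ax.text(x, y, str(regions.get(key, 0)), ha="center", fontsize=9)
    ax.set_xlim(-2.2, 2.2)
    ax.set_ylim(-2.2, 2.2)
    ax.set_aspect("equal")
    ax.axis("off")
    _save(fig, path)


def tree_figure(tree, path) -> None:
    """Dendrogram of the UPGMA repertoire tree."""
    from scipy.cluster.hierarchy import dendrogram

    fig, ax = plt.subplots(figsize=(7, 0.35 * len(tree.labels) + 1.5))
    dendrogram(tree.linkage, labels=tree.labels, orientation="left", ax=ax,
               color_threshold=0)
    ax.tick_params(labelsize=7)
    ax.set_xlabel("distance")
    _save(fig, path)
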