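"""Binding-site maps: conservation filtering, hierarchical and density-based
clustering of a PatchScore matrix, cluster-pair link tables and exports.

The feature vector of a patch is its row of PatchScores — over same-target
patches for the local (within-target) step, over all retained patches for the
global step — compared with the Euclidean distance. Average-linkage
agglomerative clustering produces dendrograms and heat-map orderings; DBSCAN
(default eps = 7, min_samples = 10 on the same row vectors) produces flat
per-target clusters with an explicit noise label. A conservation filter first
removes information-poor patches: a patch must have at least ``min_links``
(default 5) pairwise PatchScores >= ``threshold`` (default 2.0) to be kept.

Cluster pairs are summarised by the maximum PatchScore between their members;
pairs at or above the highlight threshold (default 2.0) are flagged — these
are the candidate cross-target similarities (potential polypharmacology).
Outputs include reordered matrices, a raster heat map, Circos-compatible
karyotype/link files, a built-in chord render and a JSON summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import DBSCAN

from .compare import SimilarityMatrix

logger = logging.getLogger(__name__)

NOISE = -1

DEFAULT_MIN_LINKS = 5
DEFAULT_LINK_THRESHOLD = 2.0
DEFAULT_EPS = 7.0
DEFAULT_MIN_SAMPLES = 10


class MappingError(ValueError):
    pass


def conservation_filter(
    matrix: SimilarityMatrix,
    min_links: int = DEFAULT_MIN_LINKS,
    threshold: float = DEFAULT_LINK_THRESHOLD,
) -> list[str]:
    """Ids of patches with >= ``min_links`` off-diagonal scores >= ``threshold``.

    A single pass on the original matrix: links are counted before any patch
    is removed, so the filter is not iterated.
    """
    s = matrix.scores
    n = len(matrix.patch_ids)
    retained = []
    for i in range(n):
        row = np.delete(s[i], i)
        count = int(np.nansum(row >= threshold))
        if count >= min_links:
            retained.append(matrix.patch_ids[i])
    return retained


def _feature_rows(matrix: SimilarityMatrix, row_ids: Sequence[str], col_ids: Sequence[str]) -> np.ndarray:
    ri = [matrix.index_of(i) for i in row_ids]
    ci = [matrix.index_of(i) for i in col_ids]
    rows = matrix.scores[np.ix_(ri, ci)]
    return np.nan_to_num(rows, nan=0.0)


@dataclass
class Dendrogram:
    ids: list[str]
    linkage: Optional[np.ndarray]  # scipy linkage matrix; None for singletons
    leaf_order: list[str]
    flat_labels: Optional[dict[str, int]] = None


def hierarchical_map(
    matrix: SimilarityMatrix,
    target_labels: Optional[Sequence[str]] = None,
    level: str = "global",
    cut_n_clusters: Optional[int] = None,
) -> dict[str, Dendrogram]:
    """Average-linkage clustering of PatchScore row vectors (Euclidean).

    ``level="within_target"`` clusters each target's patches on their
    same-target columns; ``level="global"`` clusters all patches on all
    columns (one entry under the key ``"global"``). When ``cut_n_clusters``
    is given the tree is also cut into that many flat clusters.
    """
    labels = list(target_labels) if target_labels is not None else matrix.target_labels
    if level == "global":
        groups = {"global": list(matrix.patch_ids)}
    elif level == "within_target":
        groups = {}
        for pid, lab in zip(matrix.patch_ids, labels):
            groups.setdefault(lab, []).append(pid)
    else:
        raise MappingError(f"unknown level: {level!r}")

    out: dict[str, Dendrogram] = {}
    for key, ids in groups.items():
        if len(ids) < 2:
            logger.info("hierarchical_map: %r has a single patch; singleton", key)
            out[key] = Dendrogram(ids=ids, linkage=None, leaf_order=list(ids),
                                  flat_labels={i: 1 for i in ids})
            continue
        cols = ids if level == "within_target" else list(matrix.patch_ids)
        rows = _feature_rows(matrix, ids, cols)
        z = linkage(pdist(rows, metric="euclidean"), method="average")
        order = [ids[k] for k in leaves_list(z)]
        flat = None
        if cut_n_clusters is not None:
            fl = fcluster(z, t=min(cut_n_clusters, len(ids)), criterion="maxclust")
            flat = {ids[k]: int(fl[k]) for k in range(len(ids))}
        out[key] = Dendrogram(ids=list(ids), linkage=z, leaf_order=order, flat_labels=flat)
    return out


def dbscan_map(
    matrix: SimilarityMatrix,
    eps: float = DEFAULT_EPS,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    per_target: bool = True,
) -> dict[str, int]:
    """DBSCAN labels (noise = -1) on PatchScore row vectors.

    With ``per_target=True`` (the mapping default) each target is clustered
    independently on its own sub-matrix and labels are namespaced per target;
    otherwise one run covers the whole matrix. A core point has at least
    ``min_samples`` neighbours (itself included) within ``eps``.
    """
    out: dict[str, int] = {}
    if per_target:
        groups: dict[str, list[str]] = {}
        for pid, lab in zip(matrix.patch_ids, matrix.target_labels):
            groups.setdefault(lab, []).append(pid)
        items = sorted(groups.items())
    else:
        items = [("all", list(matrix.patch_ids))]
    for _, ids in items:
        rows = _feature_rows(matrix, ids, ids)
        if len(ids) < min_samples:
            labels = np.full(len(ids), NOISE)
        else:
            labels = DBSCAN(eps=eps, min_samples=min_samples).fit(rows).labels_
        for pid, lab in zip(ids, labels):
            out[pid] = int(lab)
    return out


@dataclass
class ClusterMap:
    """Clustering state of a similarity map."""

    retained_ids: list[str]
    target_of: dict[str, str]
    per_target_labels: dict[str, int]  # DBSCAN-style labels, NOISE = -1
    global_order: list[str]
    dendrograms: dict[str, Dendrogram]
    parameters: dict = field(default_factory=dict)


@dataclass
class LinkRow:
    target_a: str
    cluster_a: int
    target_b: str
    cluster_b: int
    max_patch_score: float
    highlighted: bool
    within_target: bool


def cluster_link_table(
    labels: dict[str, int],
    target_of: dict[str, str],
    matrix: SimilarityMatrix,
    highlight_threshold: float = DEFAULT_LINK_THRESHOLD,
) -> list[LinkRow]:
    """One row per unordered cluster pair: the max member-pair PatchScore.

    Noise-labelled patches are excluded. Rows at or above the highlight
    threshold carry the highlighted flag (the red-ribbon criterion).
    """
    members: dict[tuple[str, int], list[str]] = {}
    for pid, lab in labels.items():
        if lab == NOISE:
            continue
        members.setdefault((target_of[pid], lab), []).append(pid)
    keys = sorted(members)
    rows: list[LinkRow] = []
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            ka, kb = keys[a], keys[b]
            ia = [matrix.index_of(p) for p in members[ka]]
            ib = [matrix.index_of(p) for p in members[kb]]
            block = matrix.scores[np.ix_(ia, ib)]
            if np.all(np.isnan(block)):
                continue
            best = float(np.nanmax(block))
            rows.append(
                LinkRow(
                    target_a=ka[0],
                    cluster_a=ka[1],
                    target_b=kb[0],
                    cluster_b=kb[1],
                    max_patch_score=best,
                    highlighted=best >= highlight_threshold,
                    within_target=ka[0] == kb[0],
                )
            )
    return rows


def build_cluster_map(
    matrix: SimilarityMatrix,
    min_links: int = DEFAULT_MIN_LINKS,
    link_threshold: float = DEFAULT_LINK_THRESHOLD,
    eps: float = DEFAULT_EPS,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> ClusterMap:
    """Conservation filter -> within-target + global clustering -> ClusterMap."""
    retained = conservation_filter(matrix, min_links=min_links, threshold=link_threshold)
    if len(retained) < 2:
        raise MappingError("fewer than 2 patches retained by the conservation filter")
    sub = matrix.submatrix(retained)
    target_of = dict(zip(sub.patch_ids, sub.target_labels))
    dendros = hierarchical_map(sub, level="within_target")
    dendros.update(hierarchical_map(sub, level="global"))
    labels = dbscan_map(sub, eps=eps, min_samples=min_samples, per_target=True)
    return ClusterMap(
        retained_ids=retained,
        target_of=target_of,
        per_target_labels=labels,
        global_order=dendros["global"].leaf_order,
        dendrograms=dendros,
        parameters={
            "min_links": min_links,
            "link_threshold": link_threshold,
            "eps": eps,
            "min_samples": min_samples,
        },
    )


def write_map_outputs(
    cluster_map: ClusterMap,
    link_table: Sequence[LinkRow],
    matrix: SimilarityMatrix,
    out_dir: str | Path,
    highlight_threshold: float = DEFAULT_LINK_THRESHOLD,
) -> dict[str, Path]:
    """Write heat-map, Circos and summary artifacts; byte-stable given inputs.

    Files: ``matrix_ordered.tsv`` (scores under the global leaf order),
    ``heatmap.png``, ``karyotype.txt`` + ``links.txt`` (Circos formats),
    ``chord.png`` (built-in render) and ``summary.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    missing = set(cluster_map.retained_ids) - set(matrix.patch_ids)
    if missing:
        raise MappingError(f"ids not in matrix: {sorted(missing)[:5]}")

    order = cluster_map.global_order
    sub = matrix.submatrix(order)
    paths: dict[str, Path] = {}

    paths["matrix"] = out_dir / "matrix_ordered.tsv"
    sub.save(paths["matrix"])

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(sub.scores, cmap="viridis", vmin=0.0, vmax=4.0, interpolation="nearest")
    ax.set_title("PatchScore similarity (global leaf order)")
    ax.set_xlabel("patch")
    ax.set_ylabel("patch")
    fig.colorbar(im, ax=ax, label="PatchScore")
    paths["heatmap"] = out_dir / "heatmap.png"
    fig.savefig(paths["heatmap"], dpi=100, metadata={"Software": ""})
    plt.close(fig)

    # Circos karyotype: one outer segment per target, one band per cluster
    targets = sorted(set(cluster_map.target_of.values()))
    cluster_sizes: dict[tuple[str, int], int] = {}
    for pid, lab in cluster_map.per_target_labels.items():
        if lab == NOISE:
            continue
        key = (cluster_map.target_of[pid], lab)
        cluster_sizes[key] = cluster_sizes.get(key, 0) + 1
    kar_lines = []
    spans: dict[tuple[str, int], tuple[int, int]] = {}
    for t in targets:
        clusters = sorted(k for k in cluster_sizes if k[0] == t)
        total = sum(cluster_sizes[k] for k in clusters) or 1
        kar_lines.append(f"chr - {t} {t} 0 {total} grey")
        pos = 0
        for k in clusters:
            end = pos + cluster_sizes[k]
            kar_lines.append(f"band {t} c{k[1]} c{k[1]} {pos} {end} gpos50")
            spans[k] = (pos, end)
            pos = end
    paths["karyotype"] = out_dir / "karyotype.txt"
    paths["karyotype"].write_text("\n".join(kar_lines) + "\n")

    link_lines = []
    for row in sorted(
        link_table,
        key=lambda r: (r.target_a, r.cluster_a, r.target_b, r.cluster_b),
    ):
        ka, kb = (row.target_a, row.cluster_a), (row.target_b, row.cluster_b)
        if ka not in spans or kb not in spans:
            continue
        color = "red" if row.highlighted else "grey"
        link_lines.append(
            f"{row.target_a} {spans[ka][0]} {spans[ka][1]} "
            f"{row.target_b} {spans[kb][0]} {spans[kb][1]} "
            f"color={color},score={row.max_patch_score:.3f}"
        )
    paths["links"] = out_dir / "links.txt"
    paths["links"].write_text("\n".join(link_lines) + "\n")

    paths["chord"] = out_dir / "chord.png"
    _render_chord(cluster_map, link_table, paths["chord"])

    summary = {
        "n_retained": len(cluster_map.retained_ids),
        "parameters": cluster_map.parameters,
        "highlight_threshold": highlight_threshold,
        "targets": {
            t: {
                "clusters": {
                    str(k[1]): cluster_sizes[k] for k in sorted(cluster_sizes) if k[0] == t
                },
                "noise": sum(
                    1
                    for pid, lab in cluster_map.per_target_labels.items()
                    if lab == NOISE and cluster_map.target_of[pid] == t
                ),
            }
            for t in targets
        },
        "n_links": len(link_table),
        "n_highlighted": sum(1 for r in link_table if r.highlighted),
    }
    paths["summary"] = out_dir / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=1, sort_keys=True))
    return paths


def _render_chord(
    cluster_map: ClusterMap, link_table: Sequence[LinkRow], path: Path
) -> None:
    """Minimal chord-style render: clusters on a circle, links through it."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    keys = sorted(
        {(cluster_map.target_of[p], lab) for p, lab in cluster_map.per_target_labels.items() if lab != NOISE}
    )
    if not keys:
        keys = [("empty", 0)]
    angles = {k: 2 * np.pi * i / len(keys) for i, k in enumerate(keys)}
    fig, ax = plt.subplots(figsize=(5, 5))
    for k, ang in angles.items():
        ax.plot(np.cos(ang), np.sin(ang), "o", color="grey", markersize=8)
        ax.annotate(f"{k[0]}:{k[1]}", (1.1 * np.cos(ang), 1.1 * np.sin(ang)),
                    ha="center", va="center", fontsize=7)
    for row in link_table:
        ka, kb = (row.target_a, row.cluster_a), (row.target_b, row.cluster_b)
        if ka not in angles or kb not in angles:
            continue
        x = [np.cos(angles[ka]), np.cos(angles[kb])]
        y = [np.sin(angles[ka]), np.sin(angles[kb])]
        ax.plot(x, y, color="red" if row.highlighted else "lightgrey",
                linewidth=2 if row.highlighted else 0.8, zorder=1)
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=100, metadata={"Software": ""})
    plt.close(fig)
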