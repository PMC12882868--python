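"""Expression-atlas and internode clustering stages of the candidate funnel.

Stage one clusters the family's expression profiles across a broad organ /
condition atlas together with the lignin toolbox (the core monolignol
biosynthetic genes): family members falling in the cluster that captures the
toolbox are co-expression candidates. Stage two profiles the four
developmental zones of the elongating internode (meristematic MsZ, cell
expansion CEZ, transitional TZ, maturation MZ, bottom to top), where
secondary-cell-wall deposition begins at TZ; candidates must either
co-cluster with an artificial "terminal" carrying the mean toolbox profile,
or peak in TZ/MZ.

Rows are standardized to unit variance before clustering (mean 0, sample
standard deviation 1, n-1 convention); hierarchical agglomerative clustering
uses correlation distance (1 - Pearson) with average linkage by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

INTERNODE_ZONES = ("MsZ", "CEZ", "TZ", "MZ")
TERMINAL_ID = "__lignin_terminal__"


@dataclass
class ScaledMatrix:
    """Row-standardized expression matrix plus the ids dropped as constant."""

    data: pd.DataFrame
    dropped: list[str] = field(default_factory=list)


@dataclass
class ClusterAssignment:
    labels: dict[str, int]
    merges: list[list[float]]
    k: int

    def members(self, label: int) -> list[str]:
        return [g for g, c in self.labels.items() if c == label]


def validate_expression_matrix(m: pd.DataFrame) -> None:
    if m.index.has_duplicates:
        dups = m.index[m.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups}")
    arr = m.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("expression values must be finite")
    if (arr < 0).any():
        raise ValueError("expression values must be non-negative")


def unit_variance_scale(m: pd.DataFrame) -> ScaledMatrix:
    """Standardize each row to mean 0 and (n-1) standard deviation 1.

    Constant rows cannot be scaled; they are dropped with a logged warning
    and reported in the result's ``dropped`` list.
    """
    arr = m.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.all():
        raise ValueError("all rows are constant; nothing to scale")
    dropped = list(m.index[constant])
    if dropped:
        logger.warning("dropping %d constant rows: %s", len(dropped), dropped[:10])
    keep = ~constant
    scaled = (arr[keep] - arr[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return ScaledMatrix(
        data=pd.DataFrame(scaled, index=m.index[keep], columns=m.columns),
        dropped=dropped,
    )


def _row_distances(arr: np.ndarray, distance: str) -> np.ndarray:
    if distance == "correlation":
        # 1 - Pearson; pdist's 'correlation' metric is exactly this
        return pdist(arr, metric="correlation")
    if distance == "euclidean":
        return pdist(arr, metric="euclidean")
    raise ValueError(f"unknown distance {distance!r}")


def cluster_rows(
    scaled: pd.DataFrame,
    k: int,
    distance: str = "correlation",
    method: str = "average",
) -> ClusterAssignment:
    """Agglomerative hierarchical clustering of rows cut into ``k`` clusters.

    Rows are processed in lexicographic gene-id order so that equal-distance
    ties break deterministically. Cluster labels are renumbered 1..k in order
    of first appearance along the sorted gene list.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > scaled.shape[0]:
        raise ValueError(f"k={k} exceeds row count {scaled.shape[0]}")
    if method not in ("average", "complete", "ward"):
        raise ValueError(f"unknown linkage {method!r}")
    ordered = scaled.sort_index(kind="stable")
    dists = _row_distances(ordered.to_numpy(dtype=float), distance)
    merges = linkage(dists, method=method)
    raw = fcluster(merges, t=k, criterion="maxclust")
    # renumber clusters 1..k by first appearance
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for gene, lab in zip(ordered.index, raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[gene] = remap[lab]
    return ClusterAssignment(labels=labels, merges=merges.tolist(), k=len(remap))


def select_cocluster_candidates(
    assignment: ClusterAssignment,
    toolbox_ids: Sequence[str],
    family_ids: Iterable[str],
) -> tuple[set[str], dict]:
    """Family members sharing the toolbox's cluster (toolbox genes excluded).

    The selected cluster is the one holding the most toolbox genes; ties go
    to the higher toolbox fraction, then to the smaller cluster, then to the
    lower label. A warning is logged when the toolbox is split across
    clusters.
    """
    toolbox_present = [g for g in toolbox_ids if g in assignment.labels]
    if not toolbox_present:
        raise ValueError("no toolbox gene present in the cluster assignment")
    per_cluster: dict[int, int] = {}
    for g in toolbox_present:
        per_cluster[assignment.labels[g]] = per_cluster.get(assignment.labels[g], 0) + 1
    sizes = {c: len(assignment.members(c)) for c in per_cluster}
    selected = min(
        per_cluster,
        key=lambda c: (-per_cluster[c], -per_cluster[c] / sizes[c], sizes[c], c),
    )
    if len(per_cluster) > 1:
        logger.warning(
            "toolbox genes split across clusters %s; selecting cluster %d",
            dict(sorted(per_cluster.items())),
            selected,
        )
    family = set(family_ids)
    members = set(assignment.members(selected))
    candidates = (members & family) - set(toolbox_ids)
    diagnostics = {
        "selected_cluster": selected,
        "cluster_size": sizes[selected],
        "toolbox_in_selected": per_cluster[selected],
        "toolbox_present": len(toolbox_present),
        "toolbox_missing": [g for g in toolbox_ids if g not in assignment.labels],
        "toolbox_split": {int(c): int(n) for c, n in sorted(per_cluster.items())},
    }
    return candidates, diagnostics


def internode_stage(
    m: pd.DataFrame,
    toolbox_ids: Sequence[str],
    mode: str = "cocluster_with_terminal",
    family_ids: Iterable[str] | None = None,
    distance: str = "correlation",
    method: str = "average",
) -> set[str]:
    """Internode-zone selection of candidates peaking where lignification occurs.

    ``m`` must have exactly the four zone columns MsZ, CEZ, TZ, MZ in order.
    In ``cocluster_with_terminal`` mode an artificial row holding the mean
    scaled toolbox profile is appended and the matrix is cut into two
    clusters; family genes sharing the terminal's cluster are returned. In
    ``peak_zone`` mode genes whose scaled profile attains its maximum in TZ
    or MZ are returned. Genes absent from the matrix simply drop out.
    """
    if list(m.columns) != list(INTERNODE_ZONES):
        raise ValueError(
            f"internode matrix must have zone columns {INTERNODE_ZONES}, got {list(m.columns)}"
        )
    family = set(family_ids) if family_ids is not None else set(m.index)
    scaled = unit_variance_scale(m)
    data = scaled.data

    if mode == "peak_zone":
        peaks = data.to_numpy(dtype=float).argmax(axis=1)
        selected = {g for g, p in zip(data.index, peaks) if p >= 2}  # TZ or MZ
        return (selected & family) - set(toolbox_ids)

    if mode != "cocluster_with_terminal":
        raise ValueError(f"unknown mode {mode!r}")
    toolbox_present = [g for g in toolbox_ids if g in data.index]
    if not toolbox_present:
        raise ValueError("no toolbox gene present in the internode matrix")
    terminal = data.loc[toolbox_present].mean(axis=0)
    with_terminal = pd.concat([data, terminal.to_frame(TERMINAL_ID).T])
    assignment = cluster_rows(with_terminal, k=2, distance=distance, method=method)
    terminal_cluster = assignment.labels[TERMINAL_ID]
    members = set(assignment.members(terminal_cluster)) - {TERMINAL_ID}
    return (members & family) - set(toolbox_ids)


def reference_profile(m: pd.DataFrame, toolbox_ids: Sequence[str]) -> pd.Series:
    """Mean unit-variance-scaled profile of the toolbox genes (the terminal)."""
    scaled = unit_variance_scale(m)
    present = [g for g in toolbox_ids if g in scaled.data.index]
    if not present:
        raise ValueError("no toolbox gene present in matrix")
    return scaled.data.loc[present].mean(axis=0)


def save_heatmap(scaled: pd.DataFrame, path, assignment: ClusterAssignment | None = None) -> None:
    """Diagnostic heatmap of a scaled matrix (rows optionally cluster-sorted)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = scaled
    if assignment is not None:
        order = sorted(scaled.index, key=lambda g: (assignment.labels.get(g, 0), g))
        data = scaled.loc[order]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * data.shape[1]), max(4, 0.08 * data.shape[0]))
    )
    im = ax.imshow(data.to_numpy(dtype=float), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(data.shape[1]), data.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="row-scaled expression")
    fig.tight_layout()
    fig.savefig(str(path), dpi=120)
    plt.close(fig)
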