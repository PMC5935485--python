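"""Cross-screen integration and hierarchical clustering of change profiles.

Per-screen 50-entry change profiles are concatenated screen by screen into
one long vector per protein, filtered down to the profiles with strong
signal, and clustered by agglomerative average linkage on the uncentered
correlation distance.  Results can be exported in the CDT/GTR dialect read
by tree-viewing heat-map software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .profiles import PROFILE_LEN, profile_column_names


@dataclass
class ConcatenatedProfile:
    """Screen-ordered concatenation of one protein's change profiles."""

    protein_id: str
    screen_order: list[str]
    z: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (PROFILE_LEN * len(self.screen_order),):
            raise ValueError("length must be 50 x number of screens")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.z)

    @property
    def present_fraction(self) -> float:
        return float(1.0 - self.missing_mask.mean())

    def block(self, screen_id: str) -> np.ndarray:
        b = self.screen_order.index(screen_id)
        return self.z[b * PROFILE_LEN : (b + 1) * PROFILE_LEN]


def concatenate(
    per_screen_z: dict[str, pd.DataFrame], screen_order: list[str]
) -> pd.DataFrame:
    """Stack per-screen z matrices into a proteins x (50*S) matrix.

    ``per_screen_z`` maps screen id to a proteins x 50 z matrix.  Proteins
    absent from a screen get an all-NaN block for it; the row index is the
    union of proteins over the ordered screens.
    """
    if len(set(screen_order)) != len(screen_order):
        raise ValueError("duplicate screen in screen_order")
    missing = [s for s in screen_order if s not in per_screen_z]
    if missing:
        raise KeyError(f"screens without change profiles: {missing}")
    proteins = pd.Index(
        sorted(set().union(*(per_screen_z[s].index for s in screen_order)))
    )
    blocks = []
    for s in screen_order:
        zb = per_screen_z[s].reindex(proteins)
        zb.columns = profile_column_names(s)
        blocks.append(zb)
    out = pd.concat(blocks, axis=1)
    out.index.name = "protein_id"
    return out


def present_fraction(concat_z: pd.DataFrame) -> pd.Series:
    return 1.0 - concat_z.isna().mean(axis=1)


def strong_signal_filter(
    concat_z: pd.DataFrame,
    min_strong: int = 3,
    z_thresh: float = 5.0,
    min_present: float = 0.8,
) -> pd.DataFrame:
    """Keep profiles with >= ``min_strong`` entries |z| strictly above
    ``z_thresh`` and strictly more than ``min_present`` of entries present."""
    if min_strong <= 0 or z_thresh <= 0 or min_present <= 0:
        raise ValueError("filter thresholds must be positive")
    strong = (concat_z.abs() > z_thresh).sum(axis=1) >= min_strong
    present = present_fraction(concat_z) > min_present
    return concat_z.loc[strong & present]


def uncentered_correlation_distance(x, y) -> float:
    """1 - cosine similarity over mutually non-missing entries; range [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        raise ValueError("need at least 2 mutually non-missing entries")
    xs, ys = x[ok], y[ok]
    nx = np.sqrt((xs * xs).sum())
    ny = np.sqrt((ys * ys).sum())
    if nx == 0 or ny == 0:
        raise ValueError("zero norm on shared support")
    return float(1.0 - (xs * ys).sum() / (nx * ny))


def pairwise_uncentered_distances(values: pd.DataFrame) -> np.ndarray:
    """Square matrix of pairwise uncentered correlation distances.

    Missing entries are excluded pairwise; a pair with fewer than 2 shared
    entries or a zero norm on its shared support raises.
    """
    X = values.to_numpy(dtype=float)
    M = (~np.isnan(X)).astype(float)
    X0 = np.where(np.isnan(X), 0.0, X)
    sq = X0 * X0
    cross = X0 @ X0.T
    nx2 = sq @ M.T          # ||x||^2 on each pair's shared support
    ny2 = M @ sq.T
    shared = M @ M.T
    if (shared < 2).any():
        i, j = np.argwhere(shared < 2)[0]
        raise ValueError(
            f"profiles {values.index[i]!r} and {values.index[j]!r} share "
            "fewer than 2 non-missing entries"
        )
    norms = np.sqrt(nx2 * ny2)
    off = ~np.eye(len(X), dtype=bool)
    if (norms[off] == 0).any():
        raise ValueError("zero norm on shared support for some pair")
    with np.errstate(invalid="ignore", divide="ignore"):
        D = 1.0 - cross / norms
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


@dataclass
class Dendrogram:
    """Average-linkage merge tree over a fixed list of leaf labels.

    ``merges`` is the scipy-style (n-1) x 4 linkage matrix: each row merges
    two node ids (leaves are 0..n-1, internal nodes n, n+1, ... in merge
    order) at a given height.
    """

    labels: list[str]
    merges: np.ndarray

    def __post_init__(self):
        self.merges = np.asarray(self.merges, dtype=float)
        n = len(self.labels)
        if self.merges.shape != (n - 1, 4):
            raise ValueError("linkage matrix must have n-1 rows")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in leaves_list(self.merges)]


def average_linkage_tree(values_or_distance, labels: list[str] | None = None) -> Dendrogram:
    """UPGMA-style average-linkage tree.

    Accepts either a profiles DataFrame (distances computed with
    :func:`pairwise_uncentered_distances`) or a precomputed square
    dissimilarity matrix plus labels.  Inter-cluster distance is the
    arithmetic mean of all cross-pair original dissimilarities.
    """
    if isinstance(values_or_distance, pd.DataFrame):
        labels = list(values_or_distance.index)
        D = pairwise_uncentered_distances(values_or_distance)
    else:
        D = np.asarray(values_or_distance, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(len(D))]
    if len(labels) < 2:
        raise ValueError("need at least 2 items to cluster")
    if np.isnan(D).any():
        raise ValueError("undefined pairwise distance")
    Z = linkage(squareform(D, checks=False), method="average")
    return Dendrogram(labels, Z)


@dataclass
class ClusterSet:
    """Disjoint labelled protein clusters with implicated screen blocks."""

    clusters: dict[str, list[str]]
    implicated_screens: dict[str, list[str]] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.clusters.items())

    def sizes(self) -> dict[str, int]:
        return {name: len(members) for name, members in self.clusters.items()}


def extract_clusters(
    tree: Dendrogram,
    cut_height: float,
    min_size: int = 1,
    concat_z: pd.DataFrame | None = None,
    screen_order: list[str] | None = None,
    report_threshold: float = 2.0,
) -> ClusterSet:
    """Cut the tree at ``cut_height``; subtrees below the cut form clusters.

    Clusters smaller than ``min_size`` are discarded.  When the clustered
    matrix and its screen order are supplied, each cluster also reports the
    screens whose block mean |z| exceeds ``report_threshold``.
    """
    if cut_height < 0:
        raise ValueError("cut height must be >= 0")
    assignments = fcluster(tree.merges, t=cut_height, criterion="distance")
    clusters: dict[str, list[str]] = {}
    for lab in np.unique(assignments):
        members = [tree.labels[i] for i in np.where(assignments == lab)[0]]
        if len(members) >= min_size:
            clusters[f"C{lab}"] = sorted(members)
    implicated = {}
    if concat_z is not None and screen_order is not None:
        for name, members in clusters.items():
            block_means = []
            sub = concat_z.loc[members].abs()
            for b, s in enumerate(screen_order):
                block = sub.iloc[:, b * PROFILE_LEN : (b + 1) * PROFILE_LEN]
                m = np.nanmean(block.to_numpy())
                if not np.isnan(m) and m > report_threshold:
                    block_means.append(s)
            implicated[name] = block_means
    return ClusterSet(clusters, implicated)


# ---------------------------------------------------------------------------
# CDT/GTR export (tree-viewer heat-map dialect)

def export_clustered_heatmap(matrix: pd.DataFrame, tree: Dendrogram, path_stem: str):
    """Write ``<stem>.cdt`` and ``<stem>.gtr`` for heat-map viewers.

    The CDT holds the matrix rows in dendrogram leaf order with GID, UNIQID,
    NAME and GWEIGHT columns (missing entries as empty fields); the GTR lists
    the merges with heights expressed on the correlation scale
    ``1 - distance``.  Files round-trip through
    :func:`read_clustered_heatmap`.
    """
    if list(matrix.index) != list(tree.labels):
        raise ValueError("matrix rows must be the tree's leaves (same order)")
    order = leaves_list(tree.merges)
    n = len(tree.labels)
    node_name = {}
    cdt_path, gtr_path = f"{path_stem}.cdt", f"{path_stem}.gtr"
    with open(gtr_path, "w") as gtr:
        for m, (a, b, h, _) in enumerate(tree.merges):
            a, b = int(a), int(b)
            name_a = node_name.get(a, f"GENE{a}X" if a < n else None)
            name_b = node_name.get(b, f"GENE{b}X" if b < n else None)
            node = f"NODE{m + 1}X"
            node_name[n + m] = node
            gtr.write(f"{node}\t{name_a}\t{name_b}\t{1.0 - h:.10g}\n")
    with open(cdt_path, "w") as cdt:
        header = ["GID", "UNIQID", "NAME", "GWEIGHT"] + list(matrix.columns)
        cdt.write("\t".join(header) + "\n")
        cdt.write("EWEIGHT\t\t\t" + "\t1" * len(matrix.columns) + "\n")
        for i in order:
            row = matrix.iloc[i]
            vals = ["" if np.isnan(v) else f"{v:.10g}" for v in row.to_numpy(dtype=float)]
            cdt.write(
                "\t".join([f"GENE{i}X", str(matrix.index[i]), str(matrix.index[i]), "1"] + vals)
                + "\n"
            )


def read_clustered_heatmap(path_stem: str) -> tuple[pd.DataFrame, Dendrogram]:
    """Re-read files written by :func:`export_clustered_heatmap`.

    Returns the matrix in leaf order and a tree with identical topology and
    heights (recovered from the correlation-scaled scores).
    """
    cdt = pd.read_csv(f"{path_stem}.cdt", sep="\t", dtype=str, keep_default_na=False)
    cdt = cdt[cdt["GID"] != "EWEIGHT"]
    gids = cdt["GID"].tolist()
    index = cdt["UNIQID"].tolist()
    data_cols = [c for c in cdt.columns if c not in ("GID", "UNIQID", "NAME", "GWEIGHT")]
    values = cdt[data_cols].replace("", np.nan).astype(float)
    matrix = pd.DataFrame(values.to_numpy(), index=index, columns=data_cols)
    matrix.index.name = "protein_id"

    label_by_leafname = {}
    for g, uid in zip(gids, index):
        label_by_leafname[g] = uid
    gtr = pd.read_csv(
        f"{path_stem}.gtr", sep="\t", header=None,
        names=["node", "a", "b", "score"], dtype={"node": str, "a": str, "b": str},
    )
    n = len(gids)
    # leaves keep their original numeric ids encoded in GENE<i>X
    def node_id(name: str, node_ids: dict[str, int]) -> int:
        if name.startswith("GENE"):
            return int(name[4:-1])
        return node_ids[name]

    node_ids: dict[str, int] = {}
    merges = np.zeros((len(gtr), 4))
    sizes = {i: 1 for i in range(n)}
    for m, row in enumerate(gtr.itertuples(index=False)):
        a = node_id(row.a, node_ids)
        b = node_id(row.b, node_ids)
        h = 1.0 - float(row.score)
        node_ids[row.node] = n + m
        size = sizes[a] + sizes[b]
        sizes[n + m] = size
        merges[m] = [a, b, h, size]
    original_order = [label_by_leafname[f"GENE{i}X"] for i in range(n)]
    return matrix, Dendrogram(original_order, merges)
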