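"""Comparisons of localization-change profiles with other data sources.

Covers: joint filtering of proteins with strong localization or omics
signals, pairwise profile-distance tables for scatter plots, permutation
z-scores for physical-interaction enrichment within clusters,
hypergeometric annotation enrichment with Benjamini-Hochberg correction,
wild-type localization composition of clusters, and the
change-magnitude-versus-abundance-change table.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .detect import magnitudes

logger = logging.getLogger(__name__)


def omics_signal_filter(
    omics: pd.DataFrame,
    concat_z: pd.DataFrame,
    omics_min_count: int = 2,
    omics_thresh: float = 2.0,
    loc_min_count: int = 8,
    loc_thresh: float = 5.0,
) -> list[str]:
    """Union of proteins with a strong omics or localization-change signal.

    A protein qualifies with at least ``omics_min_count`` omics values of
    absolute value strictly above ``omics_thresh`` (for transcript profiles
    the default 2.0 log-fold threshold; pass 50.0 for abundance deltas), or
    at least ``loc_min_count`` localization z-scores strictly above
    ``loc_thresh`` in absolute value.
    """
    strong_omics = (omics.abs() > omics_thresh).sum(axis=1) >= omics_min_count
    strong_loc = (concat_z.abs() > loc_thresh).sum(axis=1) >= loc_min_count
    keep = set(omics.index[strong_omics]) | set(concat_z.index[strong_loc])
    return sorted(keep)


def pearson_correlation_distance(x, y) -> float:
    """Centered Pearson correlation distance 1 - r over shared support."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ValueError("need at least 3 mutually non-missing entries")
    xs, ys = x[ok], y[ok]
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("zero variance on shared support")
    return float(1.0 - np.corrcoef(xs, ys)[0, 1])


def pairwise_profile_distances(
    proteins: list[str],
    profiles_a: pd.DataFrame,
    profiles_b: pd.DataFrame,
    clusters: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Per protein pair, the correlation distance in two profile spaces.

    For every unordered pair of ``proteins`` that has at least 3 shared
    entries in each space, returns a row with the centered Pearson
    correlation distance in ``profiles_a`` and ``profiles_b``; pairs with
    insufficient support are omitted with a logged warning.  When a cluster
    map is given, each pair is annotated with the cluster both members share
    (or None).
    """
    member_of = {}
    if clusters:
        for name, members in clusters.items():
            for p in members:
                member_of[p] = name
    rows = []
    skipped = 0
    for p, q in itertools.combinations(sorted(proteins), 2):
        try:
            da = pearson_correlation_distance(
                profiles_a.loc[p].to_numpy(dtype=float),
                profiles_a.loc[q].to_numpy(dtype=float),
            )
            db = pearson_correlation_distance(
                profiles_b.loc[p].to_numpy(dtype=float),
                profiles_b.loc[q].to_numpy(dtype=float),
            )
        except (ValueError, KeyError):
            skipped += 1
            continue
        shared_cluster = None
        if member_of.get(p) is not None and member_of.get(p) == member_of.get(q):
            shared_cluster = member_of[p]
        rows.append((p, q, da, db, shared_cluster))
    if skipped:
        logger.warning("omitted %d pairs with insufficient shared support", skipped)
    return pd.DataFrame(
        rows, columns=["protein_a", "protein_b", "distance_a", "distance_b", "cluster"]
    )


def _edge_set(interactions) -> set[frozenset]:
    edges = set()
    for a, b in interactions:
        if a == b:
            continue
        edges.add(frozenset((a, b)))
    return edges


@dataclass
class EnrichmentResult:
    """Within-cluster interaction count against a size-preserving null."""

    cluster: str
    observed: int
    null_mean: float
    null_sd: float
    z: float
    n_perm: int
    seed: int


def _within_counts(membership: np.ndarray, sizes: list[int], edges_idx: np.ndarray) -> np.ndarray:
    """Edge counts within each cluster given a membership vector."""
    k = len(sizes)
    counts = np.zeros(k, dtype=int)
    if len(edges_idx) == 0:
        return counts
    ca = membership[edges_idx[:, 0]]
    cb = membership[edges_idx[:, 1]]
    same = ca == cb
    for c in ca[same]:
        counts[c] += 1
    return counts


def ppi_enrichment(
    clusters: dict[str, list[str]],
    interactions,
    n_perm: int = 10000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Permutation z-score of within-cluster physical-interaction counts.

    The observed statistic is the number of interaction edges with both
    endpoints inside the cluster.  The null shuffles proteins uniformly among
    the cluster slots (the permutation universe is the union of clustered
    proteins), preserving cluster sizes, and recounts; the z-score compares
    the observation to the null sample mean and SD (z = 0 by convention when
    the null SD is 0).
    """
    names = sorted(clusters)
    universe = sorted(set().union(*(clusters[c] for c in names))) if names else []
    if not universe:
        raise ValueError("empty permutation universe")
    for c in names:
        if len(set(clusters[c])) != len(clusters[c]):
            raise ValueError(f"duplicate members in cluster {c}")
    idx = {p: i for i, p in enumerate(universe)}
    membership = np.full(len(universe), -1, dtype=int)
    sizes = []
    for ci, c in enumerate(names):
        sizes.append(len(clusters[c]))
        for p in clusters[c]:
            membership[idx[p]] = ci
    edges = _edge_set(interactions)
    edges_idx = np.array(
        [(idx[a], idx[b]) for a, b in (tuple(e) for e in edges) if a in idx and b in idx],
        dtype=int,
    ).reshape(-1, 2)
    observed = _within_counts(membership, sizes, edges_idx)

    rng = np.random.default_rng(seed)
    null = np.zeros((n_perm, len(names)), dtype=int)
    slots = membership.copy()
    for t in range(n_perm):
        rng.shuffle(slots)
        null[t] = _within_counts(slots, sizes, edges_idx)
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    results = []
    for ci, c in enumerate(names):
        z = float((observed[ci] - mean[ci]) / sd[ci]) if sd[ci] > 0 else 0.0
        results.append(
            EnrichmentResult(c, int(observed[ci]), float(mean[ci]), float(sd[ci]), z, n_perm, seed)
        )
    return results


def ppi_enrichment_exhaustive(
    clusters: dict[str, list[str]], interactions
) -> list[EnrichmentResult]:
    """Exact version of :func:`ppi_enrichment` enumerating all permutations.

    Only feasible for tiny universes; the null mean/SD are population
    moments over every equally likely assignment of proteins to slots.
    """
    names = sorted(clusters)
    universe = sorted(set().union(*(clusters[c] for c in names)))
    idx = {p: i for i, p in enumerate(universe)}
    membership = np.full(len(universe), -1, dtype=int)
    sizes = []
    for ci, c in enumerate(names):
        sizes.append(len(clusters[c]))
        for p in clusters[c]:
            membership[idx[p]] = ci
    edges = _edge_set(interactions)
    edges_idx = np.array(
        [(idx[a], idx[b]) for a, b in (tuple(e) for e in edges) if a in idx and b in idx],
        dtype=int,
    ).reshape(-1, 2)
    observed = _within_counts(membership, sizes, edges_idx)
    counts = np.array(
        [
            _within_counts(np.array(perm), sizes, edges_idx)
            for perm in itertools.permutations(membership)
        ]
    )
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=0)
    out = []
    for ci, c in enumerate(names):
        z = float((observed[ci] - mean[ci]) / sd[ci]) if sd[ci] > 0 else 0.0
        out.append(
            EnrichmentResult(c, int(observed[ci]), float(mean[ci]), float(sd[ci]), z, len(counts), -1)
        )
    return out


def annotation_enrichment(
    cluster: list[str],
    background: list[str],
    annotations: dict[str, list[str]],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric term enrichment with BH correction.

    For each annotation term, tests whether the overlap between the cluster
    and the term's proteins (restricted to the background) is larger than
    expected by chance; q-values are Benjamini-Hochberg adjusted over the
    tested terms, and a term is significant at ``q <= fdr``.
    """
    cluster_set = set(cluster)
    bg = set(background)
    if not cluster_set <= bg:
        raise ValueError("cluster must be a subset of the background")
    M, N = len(bg), len(cluster_set)
    rows = []
    for term, members in sorted(annotations.items()):
        term_bg = set(members) & bg
        n = len(term_bg)
        k = len(term_bg & cluster_set)
        p = float(hypergeom.sf(k - 1, M, n, N))  # P(overlap >= k)
        rows.append((term, k, n, p))
    out = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p"])
    if len(out):
        _, q, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
        out["q"] = q
        out["significant"] = out["q"] <= fdr
    else:
        out["q"] = []
        out["significant"] = []
    return out


def localization_composition(
    cluster: list[str], wt_annotations: dict[str, str]
) -> tuple[dict[str, float], int]:
    """Proportion of each wild-type localization class among cluster members.

    Proportions are over annotated members and sum to 1; the count of
    unannotated members is returned separately.
    """
    annotated = [wt_annotations[p] for p in cluster if p in wt_annotations]
    unannotated = len(cluster) - len(annotated)
    if not annotated:
        return {}, unannotated
    classes, counts = np.unique(annotated, return_counts=True)
    return {str(c): float(k) / len(annotated) for c, k in zip(classes, counts)}, unannotated


def magnitude_vs_abundance(
    concat_z: pd.DataFrame, abundance_deltas: pd.Series
) -> pd.DataFrame:
    """Join per-protein change magnitude with |abundance change| for a screen.

    Proteins present in only one input are excluded (logged).
    """
    mags = magnitudes(concat_z)
    shared = mags.index.intersection(abundance_deltas.index)
    dropped = (len(mags) - len(shared)) + (len(abundance_deltas) - len(shared))
    if dropped:
        logger.info("excluded %d proteins present in only one input", dropped)
    out = pd.DataFrame(
        {
            "magnitude": mags.loc[shared],
            "abs_abundance_change": abundance_deltas.loc[shared].abs(),
        }
    )
    out.index.name = "protein_id"
    return out
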