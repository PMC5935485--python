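"""Unsupervised localization change detection.

A pair of screens (a reference and a perturbed screen) is compared per
protein by taking the difference of the two length-50 localization profiles
and standardising each entry against a *local* expectation: the mean and
sample standard deviation of the same difference over the k proteins whose
reference profiles are most similar to the query's.  Because the expectation
is estimated from proteins with similar baseline localization, screen-wide
systematic biases ("global effects") — even ones that depend on where a
protein localizes — cancel, and the 50 z-scores report genuine localization
change.  Positive z means the reference value exceeds the perturbed value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import PROFILE_LEN

DEFAULT_K = 50
DEFAULT_MIN_NEIGHBORS = 10
SD_FLOOR = 1e-8


@dataclass
class ChangeProfile:
    """50 z-scores for one protein between a reference and a target screen."""

    protein_id: str
    reference_screen_id: str
    target_screen_id: str
    z: np.ndarray
    k_used: int

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (PROFILE_LEN,):
            raise ValueError(f"change profile must have length {PROFILE_LEN}")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.z)


def profile_difference(reference, target) -> np.ndarray:
    """Elementwise reference - target profile; NaN where either is missing."""
    ref_vals, ref_id = _values_and_id(reference)
    tgt_vals, tgt_id = _values_and_id(target)
    if ref_id is not None and tgt_id is not None and ref_id != tgt_id:
        raise ValueError(f"protein mismatch: {ref_id!r} vs {tgt_id!r}")
    return ref_vals - tgt_vals


def _values_and_id(profile):
    if hasattr(profile, "values") and hasattr(profile, "protein_id"):
        return np.asarray(profile.values, dtype=float), profile.protein_id
    return np.asarray(profile, dtype=float), None


def masked_euclidean_distances(X: np.ndarray) -> np.ndarray:
    """All-pairs Euclidean distance over mutually non-missing entries.

    NaN entries are excluded pairwise; a pair with no shared entries gets
    distance +inf.
    """
    X = np.asarray(X, dtype=float)
    M = (~np.isnan(X)).astype(float)
    X0 = np.where(np.isnan(X), 0.0, X)
    sq = X0 * X0
    # sum over shared support of x^2 + y^2 - 2xy, built from masked matmuls
    d2 = sq @ M.T + M @ sq.T - 2.0 * (X0 @ X0.T)
    np.maximum(d2, 0.0, out=d2)
    shared = M @ M.T
    d2[shared == 0] = np.inf
    return np.sqrt(d2)


def select_neighbors(
    protein: str, reference_values: pd.DataFrame, k: int = DEFAULT_K
) -> list[str]:
    """The k proteins with reference profiles most similar to the query's.

    Similarity is Euclidean distance over mutually non-missing entries; the
    query never appears in its own neighborhood; ties break lexicographically
    by protein id.  If fewer than k other proteins exist, all are returned.
    """
    if protein not in reference_values.index:
        raise KeyError(f"protein {protein!r} absent from reference screen")
    if len(reference_values) < 2:
        raise ValueError("need at least 2 profiled proteins to form a neighborhood")
    ids = reference_values.index.to_numpy()
    D = masked_euclidean_distances(reference_values.to_numpy(dtype=float))
    qi = int(np.where(ids == protein)[0][0])
    order = _neighbor_order(D[qi], ids, qi)
    return list(ids[order[:k]])


def _neighbor_order(dist_row: np.ndarray, ids: np.ndarray, query_index: int) -> np.ndarray:
    order = np.lexsort((ids, dist_row))
    return order[order != query_index]


def change_profiles(
    reference_values: pd.DataFrame,
    target_values: pd.DataFrame,
    k: int = DEFAULT_K,
    min_neighbors: int = DEFAULT_MIN_NEIGHBORS,
    reference_screen_id: str = "reference",
    target_screen_id: str = "target",
) -> pd.DataFrame:
    """Change profiles for every protein present in both screens.

    Parameters
    ----------
    reference_values, target_values
        proteins x 50 profile matrices (NaN = missing) as produced by
        :func:`locshift.profiles.build_screen_profiles`.
    k
        neighborhood size used to build the local expectation.
    min_neighbors
        minimum number of neighbors with a defined difference at an entry for
        a z-score to be emitted there; fewer leaves the entry missing.

    Returns a proteins x 50 matrix of z-scores over the shared proteins.
    """
    shared = reference_values.index.intersection(target_values.index).sort_values()
    if len(shared) < 2:
        raise ValueError("need at least 2 proteins present in both screens")
    ref = reference_values.loc[shared].to_numpy(dtype=float)
    tgt = target_values.loc[shared].to_numpy(dtype=float)
    diffs = ref - tgt  # NaN propagates where either side is missing
    ids = shared.to_numpy()
    D = masked_euclidean_distances(ref)
    n = len(ids)
    z = np.full((n, PROFILE_LEN), np.nan)
    defined = ~np.isnan(diffs)
    for i in range(n):
        order = _neighbor_order(D[i], ids, i)
        nb = order[:k]
        nd = np.where(defined[nb], diffs[nb], 0.0)
        cnt = defined[nb].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = nd.sum(axis=0) / cnt
            centered = np.where(defined[nb], diffs[nb] - mean, 0.0)
            var = (centered * centered).sum(axis=0) / (cnt - 1)
        sd = np.maximum(np.sqrt(np.maximum(var, 0.0)), SD_FLOOR)
        zi = (diffs[i] - mean) / sd
        zi[cnt < 2] = np.nan
        zi[cnt < min_neighbors] = np.nan
        z[i] = zi
    out = pd.DataFrame(z, index=shared, columns=reference_values.columns)
    out.index.name = "protein_id"
    return out


def change_profile(
    protein: str,
    reference_values: pd.DataFrame,
    target_values: pd.DataFrame,
    k: int = DEFAULT_K,
    min_neighbors: int = DEFAULT_MIN_NEIGHBORS,
    reference_screen_id: str = "reference",
    target_screen_id: str = "target",
) -> ChangeProfile:
    """Change profile for a single protein.

    A protein absent from either screen yields an all-missing profile rather
    than an error (the "absent" result); too few usable neighbors raises.
    """
    if protein not in reference_values.index or protein not in target_values.index:
        return ChangeProfile(
            protein, reference_screen_id, target_screen_id,
            np.full(PROFILE_LEN, np.nan), 0,
        )
    shared = reference_values.index.intersection(target_values.index)
    if len(shared) - 1 < min_neighbors:
        raise ValueError(
            f"only {len(shared) - 1} neighbors profiled in both screens; "
            f"need at least {min_neighbors}"
        )
    z = change_profiles(
        reference_values.loc[shared],
        target_values.loc[shared],
        k=k,
        min_neighbors=min_neighbors,
    )
    k_used = min(k, len(shared) - 1)
    return ChangeProfile(
        protein, reference_screen_id, target_screen_id,
        z.loc[protein].to_numpy(), k_used,
    )


def change_magnitude(z, block: slice | np.ndarray | None = None) -> float:
    """Euclidean norm of the non-missing z-scores (optionally of one block)."""
    zv = z.z if isinstance(z, ChangeProfile) else np.asarray(z, dtype=float)
    if block is not None:
        zv = zv[block]
    zv = zv[~np.isnan(zv)]
    if zv.size == 0:
        raise ValueError("change magnitude of an all-missing profile")
    return float(np.sqrt((zv * zv).sum()))


def magnitudes(z_matrix: pd.DataFrame) -> pd.Series:
    """Per-protein change magnitude over a proteins x features z matrix."""
    z = z_matrix.to_numpy(dtype=float)
    out = np.sqrt(np.nansum(z * z, axis=1))
    out[np.isnan(z).all(axis=1)] = np.nan
    return pd.Series(out, index=z_matrix.index, name="magnitude")


def replicate_agreement(z_a: pd.DataFrame, z_b: pd.DataFrame) -> float:
    """Pearson correlation of per-protein change magnitudes between replicates."""
    ma, mb = magnitudes(z_a), magnitudes(z_b)
    shared = ma.index.intersection(mb.index)
    a = ma.loc[shared].to_numpy()
    b = mb.loc[shared].to_numpy()
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("need at least 3 shared proteins with defined magnitudes")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in magnitudes")
    return float(np.corrcoef(a, b)[0, 1])
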