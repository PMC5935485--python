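"""Per-protein, per-screen localization profiles from single-cell feature tables.

Each segmented cell carries five localization features, a fine cell-cycle
stage keypoint (1..10), a mother/bud label and a mean GFP intensity.  Cells
are placed into 10 bins (5 coarse cell-cycle stages x {mother, bud}) and the
truncated mean of every feature in every bin summarises one protein in one
screen as a length-50 "localization profile".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_FEATURES = 5
N_STAGES = 5
N_BINS = 10
PROFILE_LEN = N_FEATURES * N_BINS

#: canonical column names of the single-cell table
CELL_COLUMNS = [
    "protein_id",
    "screen_id",
    "cell_id",
    "stage_keypoint",
    "cell_type",
    "f1",
    "f2",
    "f3",
    "f4",
    "f5",
    "gfp_intensity",
]
FEATURE_COLUMNS = ["f1", "f2", "f3", "f4", "f5"]
CELL_TYPES = ("mother", "bud")


def flat_index(bin_index: int, feature: int) -> int:
    """Flat position of (bin, feature) in the length-50 profile.

    Bins are the major axis (mother stages 1-5, then bud stages 1-5); the
    five features vary fastest within each bin.
    """
    if not 0 <= bin_index < N_BINS:
        raise ValueError(f"bin_index {bin_index} out of range 0..{N_BINS - 1}")
    if not 0 <= feature < N_FEATURES:
        raise ValueError(f"feature {feature} out of range 0..{N_FEATURES - 1}")
    return bin_index * N_FEATURES + feature


def grid_index(flat: int) -> tuple[int, int]:
    """Inverse of :func:`flat_index`: flat position -> (bin, feature)."""
    if not 0 <= flat < PROFILE_LEN:
        raise ValueError(f"flat index {flat} out of range 0..{PROFILE_LEN - 1}")
    return divmod(flat, N_FEATURES)


def profile_column_names(screen_id: str | None = None) -> list[str]:
    """Header names for the 50 profile entries, optionally screen-prefixed."""
    names = []
    for b in range(N_BINS):
        kind = "m" if b < N_STAGES else "b"
        stage = (b % N_STAGES) + 1
        for f in range(N_FEATURES):
            name = f"f{f + 1}_{kind}{stage}"
            names.append(f"{screen_id}:{name}" if screen_id else name)
    return names


def assign_bin(stage_keypoint: int, cell_type: str, *, coarse: bool = False) -> int:
    """Map a cell-stage keypoint and mother/bud label to a flat bin 0..9.

    Fine keypoints 1..10 are merged pairwise into 5 coarse stages,
    ``coarse = ceil(keypoint / 2)``; already-coarse stages 1..5 are accepted
    with ``coarse=True``.  Mothers occupy bins 0..4, buds bins 5..9.
    """
    stage = int(stage_keypoint)
    if coarse:
        if not 1 <= stage <= N_STAGES:
            raise ValueError(f"coarse stage {stage} out of range 1..{N_STAGES}")
        coarse_stage = stage
    else:
        if not 1 <= stage <= 2 * N_STAGES:
            raise ValueError(f"stage keypoint {stage} out of range 1..{2 * N_STAGES}")
        coarse_stage = math.ceil(stage / 2)
    if cell_type not in CELL_TYPES:
        raise ValueError(f"cell_type must be one of {CELL_TYPES}, got {cell_type!r}")
    offset = 0 if cell_type == "mother" else N_STAGES
    return offset + coarse_stage - 1


def truncated_mean(values, trim: float = 0.05) -> float:
    """Mean after dropping ``floor(trim * n)`` values from each tail.

    With trim=0 this is the arithmetic mean; small samples (n=1, 2) are never
    trimmed because the floor rounds to zero.  If trimming would remove
    everything the median is returned instead.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("truncated_mean of empty input")
    if not 0.0 <= trim < 0.5:
        raise ValueError(f"trim must be in [0, 0.5), got {trim}")
    g = int(math.floor(trim * x.size))
    if 2 * g >= x.size:
        return float(np.median(x))
    xs = np.sort(x)
    return float(xs[g : x.size - g].mean())


@dataclass
class LocalizationProfile:
    """Truncated-mean feature summary of one protein in one screen.

    ``values`` is the length-50 vector (NaN marks bins with no cells);
    ``cell_counts`` gives the number of cells per bin.
    """

    protein_id: str
    screen_id: str
    values: np.ndarray
    cell_counts: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.cell_counts = np.asarray(self.cell_counts, dtype=int)
        if self.values.shape != (PROFILE_LEN,):
            raise ValueError(f"profile must have length {PROFILE_LEN}")
        if self.cell_counts.shape != (N_BINS,):
            raise ValueError(f"cell_counts must have length {N_BINS}")
        if (self.cell_counts < 0).any():
            raise ValueError("cell counts must be >= 0")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass
class AbundanceSummary:
    """Mean GFP intensity of one protein in one screen."""

    protein_id: str
    screen_id: str
    mean_gfp: float
    n_cells: int


def build_localization_profile(
    cells: pd.DataFrame, trim: float = 0.05
) -> LocalizationProfile:
    """Profile one protein in one screen from its single-cell records."""
    if len(cells) == 0:
        raise ValueError("cannot profile a protein with zero cells")
    proteins = cells["protein_id"].unique()
    screens = cells["screen_id"].unique()
    if len(proteins) != 1 or len(screens) != 1:
        raise ValueError("cells must all share one protein_id and one screen_id")
    values = np.full(PROFILE_LEN, np.nan)
    counts = np.zeros(N_BINS, dtype=int)
    bins = _bin_column(cells)
    feats = cells[FEATURE_COLUMNS].to_numpy(dtype=float)
    for b in range(N_BINS):
        in_bin = feats[bins == b]
        counts[b] = in_bin.shape[0]
        if counts[b] == 0:
            continue
        for f in range(N_FEATURES):
            values[flat_index(b, f)] = truncated_mean(in_bin[:, f], trim)
    return LocalizationProfile(str(proteins[0]), str(screens[0]), values, counts)


def _bin_column(cells: pd.DataFrame) -> np.ndarray:
    stages = cells["stage_keypoint"].to_numpy(dtype=int)
    if stages.min() < 1 or stages.max() > 2 * N_STAGES:
        raise ValueError("stage_keypoint out of range 1..10")
    coarse = np.ceil(stages / 2).astype(int)
    types = cells["cell_type"].to_numpy()
    bad = ~np.isin(types, CELL_TYPES)
    if bad.any():
        raise ValueError(f"unknown cell_type values: {set(types[bad])}")
    return (types == "bud") * N_STAGES + coarse - 1


def build_screen_profiles(
    cells: pd.DataFrame, trim: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Profile every protein in one screen's cell table at once.

    Returns ``(values, counts)``: a proteins x 50 matrix (NaN = empty bin) and
    a proteins x 10 matrix of per-bin cell counts, both indexed by protein.
    """
    if len(cells) == 0:
        raise ValueError("empty cell table")
    screens = cells["screen_id"].unique()
    if len(screens) != 1:
        raise ValueError("build_screen_profiles expects a single screen")
    bins = _bin_column(cells)
    work = cells[["protein_id"]].copy()
    work["bin"] = bins
    feats = cells[FEATURE_COLUMNS].to_numpy(dtype=float)
    proteins = np.sort(cells["protein_id"].unique())
    p_index = {p: i for i, p in enumerate(proteins)}
    values = np.full((len(proteins), PROFILE_LEN), np.nan)
    counts = np.zeros((len(proteins), N_BINS), dtype=int)
    grouped = work.groupby(["protein_id", "bin"], sort=False).indices
    for (protein, b), rows in grouped.items():
        i = p_index[protein]
        counts[i, b] = len(rows)
        block = feats[rows]
        n = block.shape[0]
        g = int(math.floor(trim * n))
        if 2 * g >= n:
            col = np.median(block, axis=0)
        elif g == 0:
            col = block.mean(axis=0)
        else:
            col = np.sort(block, axis=0)[g : n - g].mean(axis=0)
        values[i, b * N_FEATURES : (b + 1) * N_FEATURES] = col
    vdf = pd.DataFrame(values, index=proteins, columns=profile_column_names())
    cdf = pd.DataFrame(counts, index=proteins, columns=[f"bin{b}" for b in range(N_BINS)])
    vdf.index.name = cdf.index.name = "protein_id"
    return vdf, cdf


def passes_cell_count_filter(profile, min_per_bin: int = 1) -> bool:
    """True iff every one of the 10 bins holds at least ``min_per_bin`` cells.

    Accepts a :class:`LocalizationProfile` or a length-10 count vector.
    """
    counts = profile.cell_counts if isinstance(profile, LocalizationProfile) else profile
    counts = np.asarray(counts)
    return bool((counts >= min_per_bin).all())


def build_abundance_summary(cells: pd.DataFrame) -> AbundanceSummary:
    """Mean single-cell GFP intensity for one protein in one screen."""
    if len(cells) == 0:
        raise ValueError("cannot summarise abundance of zero cells")
    proteins = cells["protein_id"].unique()
    screens = cells["screen_id"].unique()
    if len(proteins) != 1 or len(screens) != 1:
        raise ValueError("cells must all share one protein_id and one screen_id")
    gfp = cells["gfp_intensity"].to_numpy(dtype=float)
    return AbundanceSummary(str(proteins[0]), str(screens[0]), float(gfp.mean()), len(gfp))


def screen_abundance_table(cells: pd.DataFrame) -> pd.Series:
    """Per-protein mean GFP intensity for one screen's cell table."""
    return cells.groupby("protein_id")["gfp_intensity"].mean()


def screen_abundance_consistency(abund_a: pd.Series, abund_b: pd.Series) -> float:
    """Squared Pearson correlation of per-protein mean GFP between two screens.

    Used as a screen-level quality check that protein abundance estimates are
    consistent with the reference screen.
    """
    shared = abund_a.index.intersection(abund_b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared proteins")
    a = abund_a.loc[shared].to_numpy(dtype=float)
    b = abund_b.loc[shared].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in abundance values")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
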