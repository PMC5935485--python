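"""Synthetic multi-screen single-cell data with planted ground truth.

The generator emulates the statistical structure the analysis assumes:
several screens imaging a shared protein set, each protein's cells spread
over 10 cell-cycle/cell-type bins, per-screen systematic "global effects"
that depend on a protein's baseline localization, planted relocalizations in
chosen (protein, screen) pairs, replicate screens sharing those plants, and
proteins missing from individual screens.  It also fabricates interaction
networks with planted within-cluster edge excess, transcript/abundance
profiles optionally coupled to the planted localization changes, and
time-lapse "movies" of nuclear pulsing as per-frame pixel samples.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import (
    CELL_COLUMNS,
    FEATURE_COLUMNS,
    N_BINS,
    N_FEATURES,
    N_STAGES,
    PROFILE_LEN,
)

# ---------------------------------------------------------------------------
# screen simulation


@dataclass
class PlantedChange:
    """A relocalization planted in a set of proteins for a set of screens.

    ``effect_size`` is the displacement of affected bin means in units of the
    single-cell feature noise SD, directed from the protein's baseline toward
    ``target_archetype``'s centroid along the affected features — or along an
    explicit ``direction`` in feature space (normalised internally), which
    models a response group moving the same way regardless of baseline
    compartment.  ``bins`` restricts the change to specific cell-cycle/
    cell-type bins (stage-gated relocalization); default is all 10.
    """

    proteins: list[str]
    screens: list[str]
    target_archetype: int | None = None
    effect_size: float = 0.0
    bins: list[int] | None = None       # default: all 10 bins
    features: list[int] | None = None   # default: all 5 features
    direction: list[float] | None = None

    def __post_init__(self):
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if self.target_archetype is None and self.direction is None:
            raise ValueError("planted change needs a target_archetype or a direction")


@dataclass
class GlobalEffect:
    """Screen-level affine distortion of feature values.

    ``scale`` and ``offset`` are either length-5 vectors (one screen-wide
    map) or (n_archetypes x 5) arrays, in which case the distortion depends
    on the protein's baseline compartment — a smooth function of baseline
    localization, which is what makes a *local* expectation necessary.
    """

    scale: np.ndarray
    offset: np.ndarray

    def __post_init__(self):
        self.scale = np.asarray(self.scale, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        if self.scale.shape != self.offset.shape:
            raise ValueError("scale and offset must have the same shape")

    @classmethod
    def identity(cls) -> "GlobalEffect":
        return cls(np.ones(N_FEATURES), np.zeros(N_FEATURES))

    def apply(self, values: np.ndarray, archetype: int) -> np.ndarray:
        if self.scale.ndim == 1:
            return values * self.scale + self.offset
        return values * self.scale[archetype] + self.offset[archetype]


@dataclass
class ScreenSimConfig:
    """Parameters of the multi-screen single-cell simulation.

    Defaults are desk-scale: a few hundred proteins in a handful of
    compartment archetypes, ~150 cells per protein per screen (log-normal
    across proteins), unit single-cell feature noise.
    """

    n_proteins: int = 200
    screens: list[str] = field(default_factory=lambda: ["WT", "PERT"])
    replicate_map: dict[str, str] = field(default_factory=dict)
    n_features: int = N_FEATURES
    archetypes: np.ndarray | None = None   # (n_archetypes, 5) feature centroids
    cell_count_median: float = 150.0
    cell_count_sigma: float = 0.4          # log-normal spread of cells/protein
    cell_noise_sd: float = 1.0
    baseline_jitter_sd: float = 0.3        # per-protein offset around its centroid
    bin_wave_amplitude: float = 0.15       # deterministic cell-cycle modulation
    global_effects: dict[str, GlobalEffect] = field(default_factory=dict)
    planted_changes: list[PlantedChange] = field(default_factory=list)
    missing_rate: float = 0.0
    gfp_log_mean: float = 5.0
    gfp_log_sd: float = 0.6
    gfp_cell_cv: float = 0.2
    min_cells_per_bin: int = 1             # 0 allows deliberately empty bins
    seed: int = 0

    def __post_init__(self):
        if self.archetypes is None:
            # four well-separated compartment centroids in feature space
            self.archetypes = np.array(
                [
                    [0.0, 0.0, 0.0, 0.0, 0.0],
                    [6.0, -3.0, 2.0, 0.0, -4.0],
                    [-5.0, 4.0, -2.0, 6.0, 1.0],
                    [3.0, 6.0, 5.0, -4.0, 3.0],
                ]
            )
        self.archetypes = np.asarray(self.archetypes, dtype=float)
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.archetypes.shape[1] != self.n_features:
            raise ValueError(
                f"archetypes have {self.archetypes.shape[1]} features, "
                f"config says {self.n_features}"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if len(set(self.screens)) != len(self.screens):
            raise ValueError("duplicate screen ids")
        self._validate_replicate_plants()

    def _validate_replicate_plants(self):
        # replicate screens must share every planted change
        groups: dict[str, list[str]] = {}
        for s, g in self.replicate_map.items():
            groups.setdefault(g, []).append(s)
        for pc in self.planted_changes:
            for g, members in groups.items():
                hit = [s for s in members if s in pc.screens]
                if hit and len(hit) != len(members):
                    raise ValueError(
                        f"planted change covers only part of replicate group {g!r}"
                    )

    def protein_ids(self) -> list[str]:
        return [f"P{i:04d}" for i in range(self.n_proteins)]


@dataclass
class GroundTruth:
    """What was planted: per (protein, screen) change records and the
    per-screen global-effect parameters and archetype assignments."""

    changes: pd.DataFrame              # protein_id, screen_id, effect_size, ...
    archetype_of: dict[str, int]
    global_effects: dict[str, GlobalEffect]
    missing: set[tuple[str, str]]

    def changed_proteins(self, screen_id: str | None = None) -> set[str]:
        df = self.changes[self.changes["effect_size"] > 0]
        if screen_id is not None:
            df = df[df["screen_id"] == screen_id]
        return set(df["protein_id"])


def _bin_means(config: ScreenSimConfig, baseline: np.ndarray) -> np.ndarray:
    """Per-bin 5-feature means from a protein baseline: a deterministic
    cell-cycle/cell-type modulation shared by all proteins."""
    bins = np.arange(N_BINS)
    means = np.tile(baseline, (N_BINS, 1))
    for f in range(config.n_features):
        wave = config.bin_wave_amplitude * np.sin(
            2.0 * np.pi * (bins % N_STAGES) / N_STAGES + f
        )
        wave = wave + config.bin_wave_amplitude * 0.5 * (bins >= N_STAGES)
        means[:, f] += wave
    return means


def generate_screens(config: ScreenSimConfig) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Simulate one single-cell table per screen plus the ground truth.

    Cells of a planted (protein, screen) pair have their bin means displaced
    by ``effect_size * cell_noise_sd`` toward the target archetype in the
    affected bins/features; every cell in a screen then passes through that
    screen's global-effect transform.  Identical config and seed give
    byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    proteins = config.protein_ids()
    n_arch = config.archetypes.shape[0]
    archetype_of = {p: i % n_arch for i, p in enumerate(proteins)}
    jitter = rng.normal(0.0, config.baseline_jitter_sd, (config.n_proteins, config.n_features))
    baselines = {
        p: config.archetypes[archetype_of[p]] + jitter[i]
        for i, p in enumerate(proteins)
    }
    abundance = np.exp(rng.normal(config.gfp_log_mean, config.gfp_log_sd, config.n_proteins))
    abundance_of = dict(zip(proteins, abundance))

    planted: dict[tuple[str, str], PlantedChange] = {}
    rows = []
    for pc in config.planted_changes:
        unknown = set(pc.screens) - set(config.screens)
        if unknown:
            raise ValueError(f"planted change names unknown screens {unknown}")
        if pc.target_archetype is not None and pc.target_archetype >= n_arch:
            raise ValueError("target archetype out of range")
        for p, s in itertools.product(pc.proteins, pc.screens):
            if (p, s) in planted:
                raise ValueError(f"({p}, {s}) planted twice")
            planted[(p, s)] = pc
            rows.append(
                {
                    "protein_id": p,
                    "screen_id": s,
                    "effect_size": pc.effect_size,
                    "target_archetype": pc.target_archetype,
                    "bins": ",".join(map(str, pc.bins)) if pc.bins else "all",
                    "features": ",".join(map(str, pc.features)) if pc.features else "all",
                }
            )
    changes = pd.DataFrame(
        rows,
        columns=["protein_id", "screen_id", "effect_size", "target_archetype", "bins", "features"],
    )

    missing: set[tuple[str, str]] = set()
    tables: dict[str, pd.DataFrame] = {}
    for s in config.screens:
        effect = config.global_effects.get(s, GlobalEffect.identity())
        screen_rows = []
        for p in proteins:
            if config.missing_rate > 0 and rng.random() < config.missing_rate:
                missing.add((p, s))
                continue
            arch = archetype_of[p]
            means = _bin_means(config, baselines[p])
            key = (p, s)
            if key in planted and planted[key].effect_size > 0:
                pc = planted[key]
                means = _apply_plant(config, means, pc, baselines[p])
            n_cells = max(
                int(round(np.exp(rng.normal(np.log(config.cell_count_median), config.cell_count_sigma)))),
                N_BINS,
            )
            bins = rng.integers(0, N_BINS, n_cells)
            if config.min_cells_per_bin > 0:
                # guarantee occupancy of every bin
                forced = np.repeat(np.arange(N_BINS), config.min_cells_per_bin)
                bins[: forced.size] = forced
            feats = means[bins] + rng.normal(0.0, config.cell_noise_sd, (n_cells, config.n_features))
            feats = effect.apply(feats, arch)
            gfp = abundance_of[p] * np.exp(
                rng.normal(0.0, config.gfp_cell_cv, n_cells)
            )
            stage = (bins % N_STAGES) * 2 + 1 + rng.integers(0, 2, n_cells)
            ctype = np.where(bins < N_STAGES, "mother", "bud")
            df = pd.DataFrame(
                {
                    "protein_id": p,
                    "screen_id": s,
                    "cell_id": [f"{p}_{s}_c{i}" for i in range(n_cells)],
                    "stage_keypoint": stage,
                    "cell_type": ctype,
                }
            )
            for f in range(config.n_features):
                df[FEATURE_COLUMNS[f]] = feats[:, f]
            df["gfp_intensity"] = gfp
            screen_rows.append(df)
        tables[s] = (
            pd.concat(screen_rows, ignore_index=True)[CELL_COLUMNS]
            if screen_rows
            else pd.DataFrame(columns=CELL_COLUMNS)
        )
    truth = GroundTruth(changes, archetype_of, dict(config.global_effects), missing)
    return tables, truth


def _apply_plant(
    config: ScreenSimConfig,
    means: np.ndarray,
    pc: PlantedChange,
    baseline: np.ndarray,
) -> np.ndarray:
    """Displace affected bin means by lambda * sigma toward the target."""
    means = means.copy()
    bins = pc.bins if pc.bins is not None else list(range(N_BINS))
    feats = pc.features if pc.features is not None else list(range(config.n_features))
    direction = np.zeros(config.n_features)
    if pc.direction is not None:
        direction[feats] = np.asarray(pc.direction, dtype=float)[feats]
    else:
        target = config.archetypes[pc.target_archetype]
        direction[feats] = (target - baseline)[feats]
    nrm = np.linalg.norm(direction)
    if nrm == 0:
        direction[feats] = 1.0
        nrm = np.sqrt(len(feats))
    unit = direction / nrm
    means[bins] += pc.effect_size * config.cell_noise_sd * unit
    return means


# ---------------------------------------------------------------------------
# interaction networks


def generate_interactions(
    clusters: dict[str, list[str]],
    background: list[str],
    within_excess: float = 1.0,
    base_rate: float = 0.02,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Random undirected graph with planted within-cluster edge excess.

    Any unordered pair of background proteins gets an edge with probability
    ``base_rate``, boosted to ``base_rate * within_excess`` when both
    endpoints share a cluster.
    """
    if within_excess < 1:
        raise ValueError("within_excess must be >= 1")
    if base_rate * within_excess > 1:
        raise ValueError("base_rate * within_excess exceeds 1")
    members = set(background)
    cluster_of: dict[str, str] = {}
    for name, prots in clusters.items():
        for p in prots:
            if p not in members:
                raise ValueError(f"cluster protein {p} not in background")
            if p in cluster_of:
                raise ValueError(f"protein {p} in two clusters")
            cluster_of[p] = name
    rng = np.random.default_rng(seed)
    edges = []
    if base_rate == 0:
        return edges
    bg = sorted(members)
    for a, b in itertools.combinations(bg, 2):
        rate = base_rate
        if cluster_of.get(a) is not None and cluster_of.get(a) == cluster_of.get(b):
            rate = base_rate * within_excess
        if rng.random() < rate:
            edges.append((a, b))
    return edges


# ---------------------------------------------------------------------------
# omics profiles


def generate_omics(
    ground_truth: GroundTruth,
    proteins: list[str],
    n_conditions: int = 6,
    coupling: float = 0.0,
    signal: float = 3.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transcript log-fold-change and abundance-delta matrices.

    A ``coupling`` fraction of the planted-change proteins receives a strong
    correlated signal (magnitude ``signal`` for transcripts, ``50 * signal``
    for abundance deltas); all other entries are independent noise.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must be in [0, 1]")
    rng = np.random.default_rng(seed)
    changed = sorted(ground_truth.changed_proteins())
    n_coupled = int(round(coupling * len(changed)))
    coupled = set(changed[:n_coupled])  # deterministic subset; magnitudes vary
    cols = [f"cond{i + 1}" for i in range(n_conditions)]
    transcript = pd.DataFrame(
        rng.normal(0.0, noise_sd, (len(proteins), n_conditions)),
        index=sorted(proteins), columns=cols,
    )
    abundance = pd.DataFrame(
        rng.normal(0.0, 50.0 * noise_sd, (len(proteins), n_conditions)),
        index=sorted(proteins), columns=cols,
    )
    for p in sorted(coupled):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        pattern = sign * signal * (1.0 + rng.random(n_conditions))
        transcript.loc[p] += pattern
        abundance.loc[p] += 50.0 * pattern / signal
    transcript.index.name = abundance.index.name = "protein_id"
    return transcript, abundance


# ---------------------------------------------------------------------------
# pulsing movies


@dataclass
class MovieSimConfig:
    """Parameters of the time-lapse pulsing simulation.

    Defaults mirror a 16 h movie at 2.5 min frame intervals.  Nuclear pixels
    are brighter than cytoplasm: during an "on" interval a fixed fraction of
    pixels is drawn from Uniform(nuclear_range) and the rest from the
    cytoplasmic Gaussian.
    """

    n_cells: int = 20
    n_frames: int = 384
    frame_interval_min: float = 2.5
    pixels_per_cell: int = 400
    cytoplasm_mean: float = 200.0
    cytoplasm_sd: float = 10.0
    nuclear_range: tuple[float, float] = (220.0, 1000.0)
    nuclear_fraction_on: float = 0.2
    pulse_on_law: dict = field(default_factory=lambda: {"law": "exponential", "mean": 60.0})
    pulse_off_law: dict = field(default_factory=lambda: {"law": "exponential", "mean": 120.0})
    seed: int = 0

    def __post_init__(self):
        if self.frame_interval_min <= 0:
            raise ValueError("frame interval must be positive")
        lo, hi = self.nuclear_range
        if lo <= self.cytoplasm_mean:
            raise ValueError("nuclear intensities must exceed the cytoplasmic mean")
        if hi <= lo:
            raise ValueError("nuclear_range must be (low, high) with high > low")
        if not 0.0 <= self.nuclear_fraction_on <= 1.0:
            raise ValueError("nuclear_fraction_on must be in [0, 1]")


def _draw_duration(law: dict, rng: np.random.Generator) -> float:
    if law["law"] == "exponential":
        return float(rng.exponential(law["mean"]))
    if law["law"] == "fixed":
        return float(law["value"])
    raise ValueError(f"unknown duration law {law['law']!r}")


def generate_movie(
    config: MovieSimConfig,
) -> tuple[dict[str, np.ndarray], dict[str, list[tuple[float, float]]]]:
    """Per-cell (n_frames x pixels) intensity samples plus true on-intervals.

    Each cell alternates off/on with durations drawn from the configured
    laws, starting off; ground truth records each on interval's (start, end)
    in minutes, clipped to the movie horizon.
    """
    rng = np.random.default_rng(config.seed)
    horizon = config.n_frames * config.frame_interval_min
    movies: dict[str, np.ndarray] = {}
    truth: dict[str, list[tuple[float, float]]] = {}
    times = np.arange(config.n_frames) * config.frame_interval_min
    for ci in range(config.n_cells):
        cell = f"cell{ci:03d}"
        intervals = []
        t = _draw_duration(config.pulse_off_law, rng)
        while t < horizon and config.nuclear_fraction_on > 0:
            on = _draw_duration(config.pulse_on_law, rng)
            intervals.append((t, min(t + on, horizon)))
            t += on + _draw_duration(config.pulse_off_law, rng)
        truth[cell] = intervals
        on_mask = np.zeros(config.n_frames, dtype=bool)
        for a, b in intervals:
            on_mask |= (times >= a) & (times < b)
        pix = rng.normal(
            config.cytoplasm_mean, config.cytoplasm_sd,
            (config.n_frames, config.pixels_per_cell),
        )
        n_nuc = int(round(config.nuclear_fraction_on * config.pixels_per_cell))
        if n_nuc > 0:
            lo, hi = config.nuclear_range
            for fi in np.where(on_mask)[0]:
                pix[fi, :n_nuc] = rng.uniform(lo, hi, n_nuc)
        movies[cell] = np.clip(pix, 0.0, None)
    return movies, truth


def expected_nuclear_share(config: MovieSimConfig) -> float:
    """Closed-form expected nuclear intensity share during an "on" frame."""
    lo, hi = config.nuclear_range
    w = config.nuclear_fraction_on
    nuc = w * 0.5 * (lo + hi)
    cyt = (1.0 - w) * config.cytoplasm_mean
    return nuc / (nuc + cyt)
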