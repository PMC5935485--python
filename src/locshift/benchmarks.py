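"""End-to-end evaluation scenarios on synthetic data with planted truth.

Each function builds a dataset with the synthetic-data generator, runs the
relevant part of the analysis from scratch and returns the measured
quantities (calibration statistics, recovery rates, oracle deviations).
They are used by the acceptance tests and the reproduction script; problem
sizes are desk-scale versions of the analysis conditions.
"""

from __future__ import annotations

import itertools
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import cluster as cl
from . import compare, detect, formats, profiles, pulses, simulate

# ---------------------------------------------------------------------------
# metrics (kept dependency-light; cross-checked against scikit-learn in tests)


def auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the rank-sum identity."""
    labels = np.asarray(labels, bool)
    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes")
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def adjusted_rand_index(a, b) -> float:
    """Adjusted Rand index between two flat partitions."""
    from collections import Counter

    def comb2(n):
        return n * (n - 1) / 2.0

    joint = Counter(zip(a, b))
    sum_ij = sum(comb2(c) for c in joint.values())
    sa = sum(comb2(c) for c in Counter(a).values())
    sb = sum(comb2(c) for c in Counter(b).values())
    n = comb2(len(a))
    expected = sa * sb / n
    max_index = (sa + sb) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def brute_force_average_linkage(D: np.ndarray) -> np.ndarray:
    """O(n^3) reference agglomerator: repeatedly merge the closest pair,
    with inter-cluster distance the mean of all cross-pair original
    distances.  Independent of the production linkage path."""
    n = len(D)
    clusters = {i: [i] for i in range(n)}
    next_id = n
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = float(np.mean([D[i, j] for i in clusters[a] for j in clusters[b]]))
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        merges.append(d)
        next_id += 1
    return np.array(merges)


# ---------------------------------------------------------------------------
# scenario helpers


def _archetype_affine_effects(seed: int) -> simulate.GlobalEffect:
    """A screen-level affine distortion that differs per baseline archetype."""
    rng = np.random.default_rng(seed)
    scale = 1.0 + rng.uniform(-0.15, 0.15, (4, 5))
    offset = rng.uniform(-0.6, 0.6, (4, 5))
    return simulate.GlobalEffect(scale=scale, offset=offset)


def _two_screen_profiles(config):
    tables, truth = simulate.generate_screens(config)
    vals = {s: profiles.build_screen_profiles(t)[0] for s, t in tables.items()}
    return vals, truth


# ---------------------------------------------------------------------------
# scenarios


def null_calibration(seed: int, n_proteins: int = 1000) -> dict:
    """No planted changes, archetype-dependent affine global effect: the
    per-feature z-scores over proteins should be centred with unit-ish SD."""
    config = simulate.ScreenSimConfig(
        n_proteins=n_proteins,
        screens=["WT", "PERT"],
        global_effects={"PERT": _archetype_affine_effects(seed + 1)},
        seed=seed,
    )
    vals, _ = _two_screen_profiles(config)
    z = detect.change_profiles(vals["WT"], vals["PERT"], k=50)
    means = np.nanmean(z.to_numpy(), axis=0)
    sds = np.nanstd(z.to_numpy(), axis=0)
    return {
        "max_abs_feature_mean": float(np.abs(means).max()),
        "feature_sd_min": float(sds.min()),
        "feature_sd_max": float(sds.max()),
        "n": n_proteins,
    }


def planted_recovery(seed: int, n_proteins: int = 1000, n_planted: int = 50) -> dict:
    """50 proteins displaced by 2 cell-noise SDs in 3 features: ranking by
    change magnitude should separate planted from null proteins."""
    planted = [f"P{i:04d}" for i in range(n_planted)]
    pc = simulate.PlantedChange(planted, ["PERT"], 1, 2.0, features=[0, 1, 2])
    config = simulate.ScreenSimConfig(
        n_proteins=n_proteins, screens=["WT", "PERT"], planted_changes=[pc], seed=seed
    )
    vals, _ = _two_screen_profiles(config)
    z = detect.change_profiles(vals["WT"], vals["PERT"], k=50)
    mags = detect.magnitudes(z)
    labels = np.array([p in set(planted) for p in mags.index])
    return {"auroc": auroc(labels, mags.to_numpy()), "n": n_proteins}


def global_shift_exactness(seed: int, n_proteins: int = 300) -> dict:
    """A constant per-feature offset added to every target profile must
    cancel analytically in the z-scores."""
    config = simulate.ScreenSimConfig(
        n_proteins=n_proteins, screens=["WT", "PERT"], seed=seed
    )
    vals, _ = _two_screen_profiles(config)
    z0 = detect.change_profiles(vals["WT"], vals["PERT"], k=50)
    offset = np.tile(np.array([0.7, -1.3, 0.4, 2.0, -0.6]), profiles.N_BINS)
    z1 = detect.change_profiles(vals["WT"], vals["PERT"] + offset, k=50)
    return {
        "max_abs_z_change": float(np.nanmax(np.abs(z1.to_numpy() - z0.to_numpy()))),
        "n": n_proteins,
    }


def linkage_oracle(seed: int, n_matrices: int = 100, n_items: int = 8) -> dict:
    """Production average linkage vs the brute-force agglomerator."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_matrices):
        M = rng.random((n_items, n_items))
        D = (M + M.T) / 2.0
        np.fill_diagonal(D, 0.0)
        tree = cl.average_linkage_tree(D)
        ref = brute_force_average_linkage(D)
        worst = max(worst, float(np.abs(np.sort(tree.heights) - np.sort(ref)).max()))
    return {"max_height_diff": worst, "n": n_matrices}


def distance_oracles(seed: int, n_pairs: int = 1000, length: int = 60) -> dict:
    """Vectorised distances vs direct elementwise formulas, with missing."""
    rng = np.random.default_rng(seed)
    worst_unc = worst_pear = 0.0
    for _ in range(n_pairs):
        x = rng.normal(0, 2, length)
        y = rng.normal(0, 2, length)
        x[rng.random(length) < 0.1] = np.nan
        y[rng.random(length) < 0.1] = np.nan
        ok = ~(np.isnan(x) | np.isnan(y))
        xs, ys = x[ok], y[ok]
        # direct formulas, written out term by term
        unc_ref = 1.0 - sum(a * b for a, b in zip(xs, ys)) / (
            np.sqrt(sum(a * a for a in xs)) * np.sqrt(sum(b * b for b in ys))
        )
        mx, my = xs.mean(), ys.mean()
        pear_ref = 1.0 - sum((a - mx) * (b - my) for a, b in zip(xs, ys)) / (
            np.sqrt(sum((a - mx) ** 2 for a in xs)) * np.sqrt(sum((b - my) ** 2 for b in ys))
        )
        frame = pd.DataFrame([x, y], index=["x", "y"])
        D = cl.pairwise_uncentered_distances(frame)
        worst_unc = max(worst_unc, abs(D[0, 1] - unc_ref),
                        abs(cl.uncentered_correlation_distance(x, y) - unc_ref))
        worst_pear = max(worst_pear, abs(compare.pearson_correlation_distance(x, y) - pear_ref))
    return {"uncentered_max_err": worst_unc, "pearson_max_err": worst_pear, "n": n_pairs}


def cluster_pattern_recovery(seed: int) -> dict:
    """Two relocalization patterns (screens RAP+HU vs AF only; 30 proteins
    each, 440 nulls): strong-signal filtering and a tree cut should recover
    the planted 2-way partition.

    Each pattern group shares a displacement direction while each member's
    change is gated to a random 3-of-10 cell-cycle/cell-type bin subset
    (stage-specific relocalization)."""
    rng = np.random.default_rng(seed)
    prots = [f"P{i:04d}" for i in range(500)]
    g1, g2 = prots[:30], prots[30:60]
    d1 = [1.0, 1.0, -1.0, 0.5, 0.0]
    d2 = [-0.5, 1.0, 1.0, -1.0, 0.5]
    plants = []
    for p in g1:
        bins = sorted(rng.choice(10, 3, replace=False).tolist())
        plants.append(simulate.PlantedChange([p], ["RAP", "HU"], None, 8.0,
                                             bins=bins, direction=d1))
    for p in g2:
        bins = sorted(rng.choice(10, 3, replace=False).tolist())
        plants.append(simulate.PlantedChange([p], ["AF"], None, 8.0,
                                             bins=bins, direction=d2))
    config = simulate.ScreenSimConfig(
        n_proteins=500, screens=["WT", "RAP", "HU", "AF", "WT3"],
        planted_changes=plants, seed=seed,
    )
    tables, _ = simulate.generate_screens(config)
    vals = {s: profiles.build_screen_profiles(t)[0] for s, t in tables.items()}
    change = {
        s: detect.change_profiles(vals["WT"], vals[s], k=50)
        for s in ["RAP", "HU", "AF", "WT3"]
    }
    concat = cl.concatenate(change, ["RAP", "HU", "AF", "WT3"])
    filtered = cl.strong_signal_filter(concat)
    kept = set(filtered.index)
    planted = set(g1) | set(g2)
    recall = len(kept & planted) / len(planted)
    null_retention = len(kept - planted) / (len(prots) - len(planted))
    tree = cl.average_linkage_tree(filtered)
    clusters = cl.extract_clusters(tree, cut_height=0.9, min_size=1)
    assign = {m: name for name, members in clusters for m in members}
    truth_labels = [0 if p in set(g1) else (1 if p in set(g2) else 2)
                    for p in filtered.index]
    pred_labels = [assign[p] for p in filtered.index]
    return {
        "planted_recall": recall,
        "null_retention": null_retention,
        "adjusted_rand": adjusted_rand_index(truth_labels, pred_labels),
        "n": 500,
    }


def ppi_calibration(seed: int, n_repeats: int = 100, n_perm: int = 500) -> dict:
    """Permutation enrichment: calibrated on null graphs, sensitive on
    graphs with a planted within-cluster edge excess, and in agreement with
    exhaustive enumeration on a 4-protein example."""
    prots = [f"P{i:03d}" for i in range(400)]
    clusters = {f"c{j}": prots[j * 20 : (j + 1) * 20] for j in range(20)}
    null_z = []
    for rep in range(n_repeats):
        edges = simulate.generate_interactions(
            clusters, prots, within_excess=1.0, base_rate=0.02, seed=seed + rep
        )
        res = compare.ppi_enrichment(clusters, edges, n_perm=n_perm, seed=seed + rep)
        null_z.extend(r.z for r in res)
    null_z = np.array(null_z)
    edges = simulate.generate_interactions(
        clusters, prots, within_excess=5.0, base_rate=0.02, seed=seed
    )
    res = compare.ppi_enrichment(clusters, edges, n_perm=2000, seed=seed)
    tiny = {"c1": ["a", "b"], "c2": ["c", "d"]}
    tiny_edges = [("a", "b")]
    exact = {r.cluster: r.z for r in compare.ppi_enrichment_exhaustive(tiny, tiny_edges)}
    mc = {r.cluster: r.z
          for r in compare.ppi_enrichment(tiny, tiny_edges, n_perm=40000, seed=seed)}
    return {
        "null_frac_abs_z_lt_3": float((np.abs(null_z) < 3).mean()),
        "planted_median_z": float(np.median([r.z for r in res])),
        "worked_example_z_exact": exact["c1"],
        "worked_example_z_mc": mc["c1"],
        "n": n_repeats,
    }


def hypergeom_check() -> dict:
    """5-of-5 overlap, 10 annotated of 100: exact tail and the BH identity."""
    background = [f"g{i}" for i in range(100)]
    out = compare.annotation_enrichment(background[:5], background,
                                        {"term": background[:10]})
    return {
        "p": float(out.loc[0, "p"]),
        "q": float(out.loc[0, "q"]),
        "expected_p": 252.0 / 75_287_520.0,
        "n": 100,
    }


def mixture_recovery(seed: int, n_frames: int = 200, n_pixels: int = 400) -> dict:
    """Planted nuclear weight 0.2: fitted w near truth; pure-Gaussian frames
    flagged nucleus-not-visible."""
    rng = np.random.default_rng(seed)
    n_nuc = int(0.2 * n_pixels)
    ws = []
    for i in range(n_frames):
        pix = rng.normal(200.0, 10.0, n_pixels)
        pix[:n_nuc] = rng.uniform(220.0, 1000.0, n_nuc)
        fit = pulses.fit_frame_model(pulses.FrameObservation("c", i, pix))
        ws.append(fit.w if fit.nucleus_visible else 0.0)
    flagged = 0
    for i in range(n_frames):
        pix = rng.normal(200.0, 10.0, n_pixels)
        fit = pulses.fit_frame_model(pulses.FrameObservation("c", i, pix))
        flagged += not fit.nucleus_visible
    return {
        "median_w": float(np.median(ws)),
        "zero_nucleus_specificity": flagged / n_frames,
        "n": n_frames,
    }


def pulse_recovery(seed: int) -> dict:
    """Fixed 50-min pulses in an 8-h movie: matched recovered durations stay
    within one frame interval; plus the power of the one-sided duration test
    at group means 123 vs 175 min (SD 60, n=40 per group)."""
    config = simulate.MovieSimConfig(
        n_cells=4, n_frames=192,
        pulse_on_law={"law": "fixed", "value": 50.0},
        pulse_off_law={"law": "fixed", "value": 100.0},
        seed=seed,
    )
    movies, truth = simulate.generate_movie(config)
    worst = 0.0
    for cell, pix in movies.items():
        frames = [pulses.FrameObservation(cell, i, pix[i], config.frame_interval_min)
                  for i in range(config.n_frames)]
        trace = pulses.score_trace(frames)
        recovered = np.sort(pulses.pulse_durations(trace, min_prominence=0.1))
        expected = np.sort([b - a for a, b in truth[cell]])
        matched = recovered[-len(expected):]
        worst = max(worst, float(np.abs(matched - expected).max()))
    rng = np.random.default_rng(seed + 1)
    rejections = 0
    n_repeats = 100
    for _ in range(n_repeats):
        a = np.clip(rng.normal(123.0, 60.0, 40), 1.0, None)
        b = np.clip(rng.normal(175.0, 60.0, 40), 1.0, None)
        _, p = pulses.compare_durations(a, b)
        rejections += p < 0.05
    return {
        "max_duration_error_min": worst,
        "test_power": rejections / n_repeats,
        "n": n_repeats,
    }


def format_round_trips(seed: int) -> dict:
    """Single-cell TSV, profile matrix and CDT/GTR write->read fidelity."""
    config = simulate.ScreenSimConfig(n_proteins=30, screens=["WT", "X"], seed=seed)
    tables, _ = simulate.generate_screens(config)
    vals, _ = profiles.build_screen_profiles(tables["WT"])
    vals = vals.copy()
    vals.iloc[0, 3] = np.nan
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        formats.write_single_cell_table(tables["WT"], tmp / "cells.tsv")
        cells_back = formats.read_single_cell_table(tmp / "cells.tsv")
        cells_err = float(
            np.abs(
                cells_back[profiles.FEATURE_COLUMNS].to_numpy()
                - tables["WT"][profiles.FEATURE_COLUMNS].to_numpy()
            ).max()
        )
        formats.write_matrix(vals, tmp / "m.tsv")
        back = formats.read_matrix(tmp / "m.tsv", expect_screens=1)
        matrix_err = float(np.nanmax(np.abs(back.to_numpy() - vals.to_numpy())))
        mask_ok = (back.isna().to_numpy() == vals.isna().to_numpy()).all()
        tree = cl.average_linkage_tree(vals.fillna(0.0))
        cl.export_clustered_heatmap(vals.fillna(0.0), tree, str(tmp / "heat"))
        hm, tree2 = cl.read_clustered_heatmap(str(tmp / "heat"))
        heat_err = float(np.abs(hm.to_numpy()
                                - vals.fillna(0.0).loc[hm.index].to_numpy()).max())
        tree_ok = tree2.leaf_order() == tree.leaf_order() and np.allclose(
            tree2.heights, tree.heights, atol=1e-9
        )
    return {
        "cells_max_err": cells_err,
        "matrix_max_err": matrix_err,
        "missing_mask_preserved": bool(mask_ok),
        "heatmap_max_err": heat_err,
        "tree_topology_preserved": bool(tree_ok),
        "n": 30,
    }
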