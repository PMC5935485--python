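"""Concatenation, strong-signal filtering, linkage and CDT/GTR export."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locshift import cluster as cl
from locshift.profiles import PROFILE_LEN, profile_column_names


def brute_force_average_linkage(D):
    """O(n^3) agglomerator: average of original cross-pair distances."""
    n = len(D)
    clusters = {i: [i] for i in range(n)}
    next_id = n
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0] - 1e-15 or (
                abs(d - best[0]) <= 1e-15 and (a, b) < (best[1], best[2])
            ):
                best = (d, a, b)
        d, a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, d, len(clusters[next_id])))
        next_id += 1
    return np.array([[a, b, h, s] for a, b, h, s in merges])


def _z_frame(rows: dict[str, np.ndarray], screens=("S1",)):
    cols = [c for s in screens for c in profile_column_names(s)]
    return pd.DataFrame({p: v for p, v in rows.items()}, index=cols).T


def test_concatenate_blocks_and_present_fraction():
    cols = profile_column_names()
    za = pd.DataFrame(1.0, index=["A", "B"], columns=cols)
    zb = pd.DataFrame(2.0, index=["A"], columns=cols)
    out = cl.concatenate({"sa": za, "sb": zb}, ["sa", "sb"])
    assert out.shape == (2, 2 * PROFILE_LEN)
    assert (out.loc["A"].to_numpy() == np.r_[np.ones(50), np.full(50, 2.0)]).all()
    # B absent from sb -> all-missing block, present_fraction 0.5
    assert out.loc["B"][:50].notna().all() and out.loc["B"][50:].isna().all()
    assert cl.present_fraction(out).loc["B"] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        cl.concatenate({"sa": za}, ["sa", "sa"])


def test_concatenate_single_screen_is_identity():
    cols = profile_column_names()
    za = pd.DataFrame(np.arange(100, dtype=float).reshape(2, 50),
                      index=["A", "B"], columns=cols)
    out = cl.concatenate({"s": za}, ["s"])
    np.testing.assert_array_equal(out.to_numpy(), za.to_numpy())


def test_strong_signal_filter_rules():
    n = PROFILE_LEN
    strong = np.zeros(n); strong[:3] = [6.0, -7.0, 5.5]
    weak = np.zeros(n); weak[:3] = [6.0, -7.0, 4.9]
    gappy = strong.copy().astype(float)
    frame = _z_frame({"keep": strong, "drop_weak": weak, "drop_gappy": gappy})
    frame.loc["drop_gappy", frame.columns[37:]] = np.nan  # present 0.74
    kept = cl.strong_signal_filter(frame, min_strong=3, z_thresh=5.0, min_present=0.8)
    assert list(kept.index) == ["keep"]


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_filter_monotone_in_thresholds(seed):
    rng = np.random.default_rng(seed)
    frame = _z_frame({f"P{i}": rng.normal(0, 4, PROFILE_LEN) for i in range(12)})
    base = set(cl.strong_signal_filter(frame, 3, 5.0, 0.8).index)
    stricter_z = set(cl.strong_signal_filter(frame, 3, 6.0, 0.8).index)
    stricter_n = set(cl.strong_signal_filter(frame, 4, 5.0, 0.8).index)
    assert stricter_z <= base and stricter_n <= base


def test_uncentered_distance_examples():
    x = np.array([1.0, 2.0, 3.0])
    assert cl.uncentered_correlation_distance(x, x) == pytest.approx(0.0)
    assert cl.uncentered_correlation_distance(x, -x) == pytest.approx(2.0)
    assert cl.uncentered_correlation_distance([1, 0], [0, 1]) == pytest.approx(1.0)
    # invariant to positive rescaling
    assert cl.uncentered_correlation_distance(x, 17.5 * x) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        cl.uncentered_correlation_distance([1, np.nan], [1, 2])
    with pytest.raises(ValueError):
        cl.uncentered_correlation_distance([0, 0], [1, 2])


def test_pairwise_distances_match_direct_formula_with_missing():
    rng = np.random.default_rng(4)
    X = rng.normal(0, 1, (15, 30))
    X[rng.random(X.shape) < 0.1] = np.nan
    frame = pd.DataFrame(X, index=[f"P{i}" for i in range(15)])
    D = cl.pairwise_uncentered_distances(frame)
    for i, j in itertools.combinations(range(15), 2):
        expected = cl.uncentered_correlation_distance(X[i], X[j])
        assert D[i, j] == pytest.approx(expected, abs=1e-12)
        assert D[j, i] == D[i, j]


def test_average_linkage_three_point_example():
    D = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], dtype=float)
    tree = cl.average_linkage_tree(D, labels=["A", "B", "C"])
    assert tree.heights == pytest.approx([1.0, 4.0])
    assert set(tree.leaf_order()) == {"A", "B", "C"}


def test_average_linkage_equal_distances_equal_heights():
    n = 6
    D = np.ones((n, n)) - np.eye(n)
    tree = cl.average_linkage_tree(D)
    assert tree.heights == pytest.approx(np.ones(n - 1))


def test_average_linkage_matches_brute_force_oracle():
    rng = np.random.default_rng(12)
    for _ in range(20):
        n = 8
        M = rng.random((n, n))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        tree = cl.average_linkage_tree(D)
        oracle = brute_force_average_linkage(D)
        np.testing.assert_allclose(np.sort(tree.heights), np.sort(oracle[:, 2]), atol=1e-12)


def test_extract_clusters_cut_heights():
    D = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], dtype=float)
    tree = cl.average_linkage_tree(D, labels=["A", "B", "C"])
    all_one = cl.extract_clusters(tree, cut_height=5.0)
    assert list(all_one.sizes().values()) == [3]
    split = cl.extract_clusters(tree, cut_height=2.0)
    assert sorted(map(tuple, split.clusters.values())) == [("A", "B"), ("C",)]
    singles = cl.extract_clusters(tree, cut_height=0.5)
    assert len(singles.clusters) == 3
    with pytest.raises(ValueError):
        cl.extract_clusters(tree, cut_height=-1.0)


def test_cdt_gtr_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    X = rng.normal(0, 3, (7, 20))
    X[0, 3] = np.nan
    frame = pd.DataFrame(X, index=[f"P{i}" for i in range(7)],
                         columns=[f"c{j}" for j in range(20)])
    tree = cl.average_linkage_tree(
        cl.pairwise_uncentered_distances(frame), labels=list(frame.index)
    )
    stem = str(tmp_path / "heat")
    cl.export_clustered_heatmap(frame, tree, stem)
    matrix, tree2 = cl.read_clustered_heatmap(stem)
    # leaf order preserved, values and missing mask lossless
    assert list(matrix.index) == tree.leaf_order()
    orig = frame.loc[matrix.index]
    np.testing.assert_allclose(matrix.to_numpy(), orig.to_numpy(), rtol=1e-9)
    assert (matrix.isna().to_numpy() == orig.isna().to_numpy()).all()
    assert tree2.leaf_order() == tree.leaf_order()
    np.testing.assert_allclose(tree2.heights, tree.heights, atol=1e-9)


def test_gtr_node_count_two_rows(tmp_path):
    frame = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["A", "B"], columns=["x", "y"])
    tree = cl.average_linkage_tree(np.array([[0.0, 0.3], [0.3, 0.0]]), labels=["A", "B"])
    stem = str(tmp_path / "tiny")
    cl.export_clustered_heatmap(frame, tree, stem)
    gtr_lines = open(stem + ".gtr").read().strip().splitlines()
    assert len(gtr_lines) == 1
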