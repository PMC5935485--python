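"""Omics filters, pairwise distances, enrichment tests, composition."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from locshift import compare, simulate
from locshift.profiles import profile_column_names


def _loc_frame(rows):
    cols = profile_column_names("S1") + profile_column_names("S2")
    return pd.DataFrame({p: v for p, v in rows.items()}, index=cols).T


def test_omics_signal_filter_union_rules():
    omics = pd.DataFrame(
        {
            "t1": [2.5, 0.0, 0.0, 2.5],
            "t2": [-2.1, 0.0, 0.0, 0.0],
        },
        index=["via_transcript", "via_loc", "neither", "one_strong"],
    )
    z = np.zeros(100)
    strong = z.copy(); strong[:8] = 6.0
    seven = z.copy(); seven[:7] = 6.0
    loc = _loc_frame(
        {"via_transcript": z, "via_loc": strong, "neither": seven, "one_strong": seven}
    )
    kept = compare.omics_signal_filter(omics, loc)
    # 7 strong loc entries + 1 strong transcript entry -> excluded (both strict)
    assert kept == ["via_loc", "via_transcript"]


def test_pearson_distance_examples():
    assert compare.pearson_correlation_distance([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)
    assert compare.pearson_correlation_distance([1, 2, 3], [-1, -2, -3]) == pytest.approx(2.0)
    # hand Pearson r = 0.9820 -> distance 0.0180
    assert compare.pearson_correlation_distance([1, 2, 3], [1, 2, 4]) == pytest.approx(
        0.0180, abs=2e-4
    )


def test_pairwise_profile_distances_table():
    rng = np.random.default_rng(0)
    a = pd.DataFrame(rng.normal(0, 1, (4, 12)), index=list("ABCD"))
    b = pd.DataFrame(rng.normal(0, 1, (4, 12)), index=list("ABCD"))
    out = compare.pairwise_profile_distances(
        ["A", "B", "C", "D"], a, b, clusters={"c1": ["A", "B"]}
    )
    assert len(out) == 6
    row = out[(out.protein_a == "A") & (out.protein_b == "B")].iloc[0]
    assert row.cluster == "c1"
    assert row.distance_a == pytest.approx(
        compare.pearson_correlation_distance(a.loc["A"], a.loc["B"])
    )
    # pair with insufficient support is omitted
    b.loc["D"] = np.nan
    out2 = compare.pairwise_profile_distances(["A", "B", "C", "D"], a, b)
    assert len(out2) == 3 and not (out2[["protein_a", "protein_b"]] == "D").any().any()


def test_ppi_enrichment_worked_example_matches_enumeration():
    clusters = {"c1": ["a", "b"], "c2": ["c", "d"]}
    edges = [("a", "b")]
    exact = compare.ppi_enrichment_exhaustive(clusters, edges)
    by = {r.cluster: r for r in exact}
    # enumeration over all assignments: P(edge within the c1 slot) = 1/6
    assert by["c1"].null_mean == pytest.approx(1 / 6)
    assert by["c1"].null_sd == pytest.approx(np.sqrt(5 / 36))
    assert by["c1"].z == pytest.approx((1 - 1 / 6) / np.sqrt(5 / 36))
    mc = {r.cluster: r for r in compare.ppi_enrichment(clusters, edges, n_perm=40000, seed=3)}
    assert mc["c1"].z == pytest.approx(by["c1"].z, abs=0.05)
    assert mc["c2"].observed == 0


def test_ppi_enrichment_degenerate_graphs():
    clusters = {"c1": ["a", "b"], "c2": ["c", "d"]}
    # empty edge list: statistic constant -> z = 0 by convention
    for r in compare.ppi_enrichment(clusters, [], n_perm=200, seed=0):
        assert r.z == 0.0 and r.observed == 0
    # complete graph: every shuffle identical -> z = 0
    import itertools
    complete = list(itertools.combinations("abcd", 2))
    for r in compare.ppi_enrichment(clusters, complete, n_perm=200, seed=0):
        assert r.z == 0.0 and r.observed == 1
    with pytest.raises(ValueError):
        compare.ppi_enrichment({}, [])


def test_ppi_enrichment_detects_planted_excess():
    prots = [f"P{i:03d}" for i in range(400)]
    clusters = {f"c{j}": prots[j * 20 : (j + 1) * 20] for j in range(20)}
    edges = simulate.generate_interactions(clusters, prots, within_excess=5.0,
                                           base_rate=0.02, seed=7)
    res = compare.ppi_enrichment(clusters, edges, n_perm=500, seed=7)
    assert np.median([r.z for r in res]) > 3.0


def test_annotation_enrichment_hypergeometric():
    background = [f"g{i}" for i in range(100)]
    cluster = background[:5]
    annotations = {"term": background[:10]}  # all 5 cluster members annotated
    out = compare.annotation_enrichment(cluster, background, annotations)
    expected = 252 / 75_287_520
    assert out.loc[0, "p"] == pytest.approx(expected, rel=1e-12)
    # single tested term: BH leaves q = p
    assert out.loc[0, "q"] == pytest.approx(expected, rel=1e-12)
    assert bool(out.loc[0, "significant"])


def test_annotation_enrichment_zero_overlap_and_subset_check():
    background = [f"g{i}" for i in range(50)]
    out = compare.annotation_enrichment(
        background[:5], background, {"t": background[40:45]}
    )
    assert out.loc[0, "p"] > 0.4  # zero overlap: upper tail includes k=0
    with pytest.raises(ValueError):
        compare.annotation_enrichment(["not_in_bg"], background, {})


def test_bh_qvalues_monotone_and_calibrated():
    rng = np.random.default_rng(1)
    background = [f"g{i}" for i in range(200)]
    annotations = {f"t{j}": list(rng.choice(background, 20, replace=False)) for j in range(50)}
    out = compare.annotation_enrichment(list(rng.choice(background, 30, replace=False)),
                                        background, annotations)
    ordered = out.sort_values("p")
    assert (np.diff(ordered["q"].to_numpy()) >= -1e-12).all()
    # all-null terms: essentially nothing significant at FDR 0.05
    assert out["significant"].mean() <= 0.05


def test_localization_composition():
    wt = {"a": "nucleus", "b": "nucleus", "c": "vacuole", "d": "vacuole"}
    props, unann = compare.localization_composition(["a", "b", "c", "d"], wt)
    assert props == {"nucleus": 0.5, "vacuole": 0.5} and unann == 0
    props, unann = compare.localization_composition(["a", "b", "c", "x"], wt)
    assert sum(props.values()) == pytest.approx(1.0) and unann == 1
    assert compare.localization_composition(["a"], wt)[0] == {"nucleus": 1.0}


def test_magnitude_vs_abundance_join_and_coupling():
    cols = profile_column_names("S1")
    rng = np.random.default_rng(2)
    prots = [f"P{i:04d}" for i in range(80)]
    z = pd.DataFrame(rng.normal(0, 1, (80, 50)), index=prots, columns=cols)
    z.iloc[:20] *= 8  # strong changers
    truth = simulate.GroundTruth(
        pd.DataFrame({"protein_id": prots[:20], "screen_id": "S1",
                      "effect_size": 3.0, "target_archetype": 1,
                      "bins": "all", "features": "all"}),
        {}, {}, set(),
    )
    _, abund = simulate.generate_omics(truth, prots, coupling=1.0, noise_sd=0.3, seed=4)
    table = compare.magnitude_vs_abundance(z, abund["cond1"])
    assert len(table) == 80
    rho = spearmanr(table["magnitude"], table["abs_abundance_change"]).statistic
    assert rho > 0.3
    # protein present in one input only is excluded
    table2 = compare.magnitude_vs_abundance(z.iloc[:40], abund["cond1"])
    assert len(table2) == 40
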