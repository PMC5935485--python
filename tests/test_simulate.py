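"""Synthetic-data generator: determinism, calibration, planted structure."""

import numpy as np
import pandas as pd
import pytest

from locshift import profiles, simulate
from locshift.simulate import (
    GlobalEffect,
    MovieSimConfig,
    PlantedChange,
    ScreenSimConfig,
    generate_interactions,
    generate_movie,
    generate_omics,
    generate_screens,
)


def test_config_validation():
    with pytest.raises(ValueError):
        ScreenSimConfig(archetypes=np.ones((2, 3)))  # wrong feature count
    with pytest.raises(ValueError):
        ScreenSimConfig(missing_rate=1.0)
    with pytest.raises(ValueError):
        ScreenSimConfig(screens=["A", "A"])
    with pytest.raises(ValueError):
        PlantedChange(["p"], ["s"], None, 1.0)  # no target, no direction
    with pytest.raises(ValueError):
        # replicate screens must share planted changes
        ScreenSimConfig(
            screens=["WT", "R1", "R2"],
            replicate_map={"R1": "rep", "R2": "rep"},
            planted_changes=[PlantedChange(["P0000"], ["R1"], 1, 2.0)],
        )


def test_ground_truth_counts_and_zero_effect(small_screens):
    config, tables, truth = small_screens
    assert len(truth.changes) == 10
    assert truth.changed_proteins() == {f"P{i:04d}" for i in range(10)}
    # zero effect size -> nothing flagged changed
    pc = PlantedChange([f"P{i:04d}" for i in range(10)], ["PERT"], 1, 0.0)
    cfg0 = ScreenSimConfig(n_proteins=20, screens=["WT", "PERT"],
                           planted_changes=[pc], seed=1)
    _, truth0 = generate_screens(cfg0)
    assert (truth0.changes["effect_size"] == 0).all()
    assert truth0.changed_proteins() == set()


def test_same_seed_byte_identical():
    cfg = ScreenSimConfig(n_proteins=15, screens=["WT", "X"], missing_rate=0.1, seed=9)
    t1, _ = generate_screens(cfg)
    t2, _ = generate_screens(cfg)
    for s in cfg.screens:
        assert t1[s].to_csv(sep="\t") == t2[s].to_csv(sep="\t")


def test_every_protein_has_all_bins_occupied(small_screens):
    _, tables, truth = small_screens
    for s, table in tables.items():
        _, counts = profiles.build_screen_profiles(table)
        assert (counts.to_numpy() >= 1).all()


def test_missing_rate_drops_proteins():
    cfg = ScreenSimConfig(n_proteins=100, screens=["WT", "X"], missing_rate=0.3, seed=2)
    tables, truth = generate_screens(cfg)
    present = tables["X"]["protein_id"].nunique()
    assert 45 <= present <= 90
    assert present + sum(1 for (_, s) in truth.missing if s == "X") == 100


def test_planted_displacement_calibrated():
    # empirical displacement of changed bin means matches lambda*sigma within 3 SE
    lam = 2.0
    planted = [f"P{i:04d}" for i in range(40)]
    pc = PlantedChange(planted, ["X"], 1, lam)
    cfg = ScreenSimConfig(n_proteins=200, screens=["WT", "X"],
                          planted_changes=[pc], cell_noise_sd=1.0, seed=3)
    tables, truth = generate_screens(cfg)
    vw, cw = profiles.build_screen_profiles(tables["WT"])
    vx, cx = profiles.build_screen_profiles(tables["X"])
    diff = (vw.loc[planted] - vx.loc[planted]).to_numpy().reshape(len(planted), 10, 5)
    disp_sq = (diff**2).sum(axis=2)  # per-bin squared displacement
    nw = cw.loc[planted].to_numpy()
    nx = cx.loc[planted].to_numpy()
    noise_var = 5 * (1.0 / nw + 1.0 / nx) * cfg.cell_noise_sd**2  # inflates |d|^2
    est = np.sqrt(max(disp_sq.mean() - noise_var.mean(), 0.0))
    se_mean = disp_sq.std(ddof=1) / np.sqrt(disp_sq.size) / (2 * lam)
    assert abs(est - lam * cfg.cell_noise_sd) < 3 * se_mean


def test_null_replicates_differ_only_by_global_effect():
    ge = GlobalEffect(scale=np.full(5, 1.2), offset=np.linspace(-1, 1, 5))
    cfg = ScreenSimConfig(n_proteins=60, screens=["A", "B"],
                          global_effects={"B": ge}, seed=4)
    tables, _ = generate_screens(cfg)
    va, _ = profiles.build_screen_profiles(tables["A"])
    vb, _ = profiles.build_screen_profiles(tables["B"])
    expected = va.to_numpy().reshape(60, 10, 5) * ge.scale + ge.offset
    resid = vb.to_numpy().reshape(60, 10, 5) - expected
    # residuals are pure sampling noise: small on average
    assert np.abs(resid.mean()) < 0.05
    assert np.abs(resid).mean() < 0.5


def test_interactions_null_and_planted_rates():
    prots = [f"P{i:03d}" for i in range(400)]
    clusters = {f"c{j}": prots[j * 20 : (j + 1) * 20] for j in range(2)}
    assert generate_interactions(clusters, prots, base_rate=0.0) == []
    with pytest.raises(ValueError):
        generate_interactions(clusters, prots, within_excess=60.0, base_rate=0.02)
    edges = generate_interactions(clusters, prots, within_excess=5.0,
                                  base_rate=0.02, seed=11)
    members = set(clusters["c1"]) | set(clusters["c0"])
    within = sum(1 for a, b in edges if a in members and b in members
                 and any(a in c and b in c for c in clusters.values()))
    n_within_pairs = 2 * (20 * 19 // 2)
    expect = n_within_pairs * 0.1
    sd = np.sqrt(n_within_pairs * 0.1 * 0.9)
    assert abs(within - expect) < 3 * sd
    # null construction: within-rate matches base rate in expectation
    edges0 = generate_interactions(clusters, prots, within_excess=1.0,
                                   base_rate=0.02, seed=11)
    within0 = sum(1 for a, b in edges0
                  if any(a in c and b in c for c in clusters.values()))
    sd0 = np.sqrt(n_within_pairs * 0.02 * 0.98)
    assert abs(within0 - n_within_pairs * 0.02) < 3 * sd0


def test_omics_coupling_limits(small_screens):
    _, _, truth = small_screens
    prots = [f"P{i:04d}" for i in range(60)]
    t1, a1 = generate_omics(truth, prots, coupling=1.0, noise_sd=0.0, seed=5)
    changed = sorted(truth.changed_proteins())
    assert (t1.loc[changed].abs().sum(axis=1) > 0).all()
    t0a, _ = generate_omics(truth, prots, coupling=0.0, seed=6)
    t0b, _ = generate_omics(truth, prots, coupling=0.0, seed=6)
    pd.testing.assert_frame_equal(t0a, t0b)  # determinism
    assert (t0a.loc[changed].abs() < 5).all().all()  # pure noise


def test_movie_schedule_and_determinism():
    cfg = MovieSimConfig(n_cells=2, n_frames=384, frame_interval_min=2.5,
                         pulse_on_law={"law": "fixed", "value": 50.0},
                         pulse_off_law={"law": "fixed", "value": 100.0}, seed=6)
    movies, truth = generate_movie(cfg)
    # 16 h horizon: off 100 + cycles of (50 on + 100 off) -> pulses at
    # [100,150), [250,300), [400,450), ... up to 960 min => 6 pulses
    for cell, intervals in truth.items():
        assert len(intervals) == 6
        assert intervals[0] == (100.0, 150.0)
    m2, t2 = generate_movie(cfg)
    assert truth == t2
    np.testing.assert_array_equal(movies["cell000"], m2["cell000"])


def test_movie_zero_nuclear_fraction_all_gaussian():
    cfg = MovieSimConfig(n_cells=1, n_frames=40, nuclear_fraction_on=0.0, seed=7)
    movies, truth = generate_movie(cfg)
    assert truth["cell000"] == []
    pix = movies["cell000"]
    assert pix.max() < cfg.cytoplasm_mean + 6 * cfg.cytoplasm_sd


def test_movie_config_validation():
    with pytest.raises(ValueError):
        MovieSimConfig(nuclear_range=(100.0, 300.0), cytoplasm_mean=200.0)
    with pytest.raises(ValueError):
        MovieSimConfig(frame_interval_min=0.0)
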