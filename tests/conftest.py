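import numpy as np
import pandas as pd
import pytest

from locshift import profiles, simulate


@pytest.fixture(scope="session")
def small_screens():
    """Two-screen synthetic dataset with 10 planted changes (60 proteins)."""
    prots = [f"P{i:04d}" for i in range(60)]
    pc = simulate.PlantedChange(
        proteins=prots[:10], screens=["PERT"], target_archetype=1, effect_size=3.0
    )
    config = simulate.ScreenSimConfig(
        n_proteins=60, screens=["WT", "PERT"], planted_changes=[pc], seed=42
    )
    tables, truth = simulate.generate_screens(config)
    return config, tables, truth


@pytest.fixture(scope="session")
def small_profiles(small_screens):
    _, tables, _ = small_screens
    return {s: profiles.build_screen_profiles(t)[0] for s, t in tables.items()}


def make_cells(protein="P1", screen="S1", per_bin=5, feature_value=1.0, seed=0):
    """Cell table for one protein with a fixed count in every bin."""
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for b in range(10):
        stage = (b % 5) * 2 + 1
        ctype = "mother" if b < 5 else "bud"
        for _ in range(per_bin):
            rows.append(
                {
                    "protein_id": protein,
                    "screen_id": screen,
                    "cell_id": f"c{i}",
                    "stage_keypoint": stage,
                    "cell_type": ctype,
                    **{f"f{k + 1}": feature_value + rng.normal(0, 0.01) for k in range(5)},
                    "gfp_intensity": 100.0,
                }
            )
            i += 1
    return pd.DataFrame(rows)
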