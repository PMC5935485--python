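"""Detect planted relocalizations in a two-screen synthetic dataset.

Simulates a wild-type and a perturbed screen (200 proteins, ~150 cells
each) in which 10 proteins are displaced toward another compartment by 3
cell-noise SDs, builds truncated-mean localization profiles, computes the
local-expectation z-score change profiles and ranks proteins by change
magnitude.  The planted proteins should dominate the top of the ranking.
"""

import numpy as np

from locshift import detect, profiles, simulate

planted = [f"P{i:04d}" for i in range(10)]
config = simulate.ScreenSimConfig(
    n_proteins=200,
    screens=["WT", "RAP"],
    planted_changes=[
        simulate.PlantedChange(planted, ["RAP"], target_archetype=1, effect_size=3.0)
    ],
    seed=0,
)
tables, truth = simulate.generate_screens(config)
print(f"simulated {len(tables)} screens, "
      f"{tables['WT']['protein_id'].nunique()} proteins, "
      f"{len(tables['WT'])} cells in WT")

vals = {s: profiles.build_screen_profiles(t)[0] for s, t in tables.items()}
z = detect.change_profiles(vals["WT"], vals["RAP"], k=50)
mags = detect.magnitudes(z).sort_values(ascending=False)

print("\ntop 12 proteins by change-profile magnitude (|z| over 50 features):")
for p, m in mags.head(12).items():
    tag = "PLANTED" if p in set(planted) else ""
    print(f"  {p}  magnitude {m:6.1f}  {tag}")

null_mags = mags.drop(index=planted)
print(f"\nnull magnitude median {np.median(null_mags):.1f} "
      f"(a calibrated 50-entry z-vector has magnitude ~sqrt(50) = 7.1);")
print("planted magnitudes far above null mean the perturbation response was detected.")
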