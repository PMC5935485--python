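"""Integrate change profiles across screens and cluster the strong signals.

Simulates four perturbation screens plus a reference.  Two response groups
are planted: one relocalizes in RAP and HU, the other only in AF (each
protein's change gated to 3 of the 10 cell-cycle/cell-type bins).  The
concatenated change profiles are filtered to strong signals (>=3 |z| > 5,
>80% present), clustered with uncentered correlation distance and average
linkage, and exported as CDT/GTR heat-map files.
"""

import tempfile
from pathlib import Path

import numpy as np

from locshift import cluster as cl
from locshift import detect, profiles, simulate

rng = np.random.default_rng(1)
prots = [f"P{i:04d}" for i in range(300)]
g1, g2 = prots[:20], prots[20:40]
plants = [
    simulate.PlantedChange([p], ["RAP", "HU"], None, 8.0,
                           bins=sorted(rng.choice(10, 3, replace=False).tolist()),
                           direction=[1.0, 1.0, -1.0, 0.5, 0.0])
    for p in g1
] + [
    simulate.PlantedChange([p], ["AF"], None, 8.0,
                           bins=sorted(rng.choice(10, 3, replace=False).tolist()),
                           direction=[-0.5, 1.0, 1.0, -1.0, 0.5])
    for p in g2
]
config = simulate.ScreenSimConfig(
    n_proteins=300, screens=["WT", "RAP", "HU", "AF"], planted_changes=plants, seed=1
)
tables, _ = simulate.generate_screens(config)
vals = {s: profiles.build_screen_profiles(t)[0] for s, t in tables.items()}
change = {s: detect.change_profiles(vals["WT"], vals[s], k=50)
          for s in ["RAP", "HU", "AF"]}

concat = cl.concatenate(change, ["RAP", "HU", "AF"])
filtered = cl.strong_signal_filter(concat)  # >=3 |z|>5, >80% present
print(f"{len(filtered)} of {len(concat)} concatenated profiles pass the "
      "strong-signal filter")

tree = cl.average_linkage_tree(filtered)
clusters = cl.extract_clusters(tree, cut_height=0.9, min_size=2,
                               concat_z=filtered, screen_order=["RAP", "HU", "AF"])
for name, members in clusters:
    screens = clusters.implicated_screens.get(name, [])
    n_g1 = len(set(members) & set(g1))
    n_g2 = len(set(members) & set(g2))
    print(f"  cluster {name}: {len(members)} proteins "
          f"({n_g1} from group1, {n_g2} from group2), "
          f"strong screens: {', '.join(screens) or 'none'}")

out = Path(tempfile.mkdtemp()) / "heatmap"
cl.export_clustered_heatmap(filtered, tree, str(out))
print(f"\nwrote {out}.cdt and {out}.gtr (open with a TreeView-style viewer);")
print("each cluster groups proteins whose screens-of-change coincide.")
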