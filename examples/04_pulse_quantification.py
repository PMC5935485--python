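"""Quantify nuclear pulsing from a simulated time-lapse movie.

Simulates cells whose tagged protein pulses into the nucleus (fixed 50-min
pulses every 150 min), fits the per-frame Gaussian+uniform pixel mixture,
tracks the nuclear localization score over time, extracts pulse durations
as peak widths at half prominence, and compares two treatment groups with
a one-sided t-test.
"""

import numpy as np

from locshift import pulses, simulate

config = simulate.MovieSimConfig(
    n_cells=3, n_frames=192,  # 8 h at 2.5-min intervals
    pulse_on_law={"law": "fixed", "value": 50.0},
    pulse_off_law={"law": "fixed", "value": 100.0},
    seed=4,
)
movies, truth = simulate.generate_movie(config)

for cell, pix in movies.items():
    frames = [pulses.FrameObservation(cell, i, pix[i], config.frame_interval_min)
              for i in range(config.n_frames)]
    trace = pulses.score_trace(frames)
    durations = pulses.pulse_durations(trace, min_prominence=0.1)
    true_durs = [b - a for a, b in truth[cell]]
    main = sorted(durations)[-len(true_durs):]
    print(f"{cell}: true pulse durations {np.round(true_durs, 1)} min, "
          f"recovered {np.round(sorted(main), 1)} min")

# group comparison at literature-scale dynamics: untreated cells pulse for
# ~123 min on average, drug-treated cells for ~175 min (SD 60, n=40 each)
rng = np.random.default_rng(4)
untreated = np.clip(rng.normal(123, 60, 40), 1, None)
treated = np.clip(rng.normal(175, 60, 40), 1, None)
t, p = pulses.compare_durations(untreated, treated)
print(f"\nmean durations: untreated {untreated.mean():.0f} min, "
      f"treated {treated.mean():.0f} min")
print(f"one-sided pooled t-test (treated > untreated): t = {t:.2f}, p = {p:.2e}")
print("p < 0.05 means the treatment significantly prolongs nuclear residence.")
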