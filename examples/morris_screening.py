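"""Morris elementary-effects screening of the 39 model parameters.

A small screening (r = 6 trajectories, 240 model runs) against the
D/S-ratio; the full design at r = 50 has 2000 runs and takes a few minutes.
Each parameter's influence is summarized by sqrt(mu*^2 + sigma^2), combining
the average effect magnitude (mu*) and its variability/interactions (sigma).
"""

import numpy as np

from graftflow import build_default_parameters, metrics_from_simulation, simulate
from graftflow.model import SimulationError
from graftflow.morris import build_trajectories, default_distributions, elementary_effects, map_to_physical

dists = default_distributions()
design = build_trajectories(dists, r=6, p=4, seed=0, oversample=24)
X = map_to_physical(design, dists)
base = build_default_parameters()

responses = np.full(design.n_points, np.nan)
for i, row in enumerate(X):
    try:
        p = base.replace(**dict(zip(design.names, row)))
        run = simulate(p, n_beats=8)
        responses[i] = metrics_from_simulation(run).median["ds_ratio"]
    except (SimulationError, ValueError):
        pass  # failed corner runs are dropped pairwise

result = elementary_effects(design, responses)
print(f"{design.n_points} runs, {result.n_dropped} elementary effects dropped")
print()
print("top 5 parameters for D/S-ratio (score = sqrt(mu*^2 + sigma^2)):")
print(result.table.sort_values('rank').head(5)[['mu_star', 'sigma', 'score']].round(4))
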