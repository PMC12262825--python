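"""Egocentric reference-point mapping (MVL_max analysis).

For every point on a 20 x 20 grid spanning the arena, the egocentric
bearing tuning curve (the cell's firing rate as a function of where that
point falls relative to the animal's heading) is summarized by its mean
vector length (MVL). The location with the highest MVL is the cell's
preferred egocentric reference point. A pure center-bearing cell peaks at
the arena center; a conjunctive CB x HD cell peaks at its (offset)
generative reference point.
"""

import numpy as np

from openfield import ArenaGeometry, SimulationConfig, default_model, generate_spikes, mvl_map, simulate_trajectory
from openfield.egocentric import precompute_bearing_bins

arena = ArenaGeometry()
tracking = simulate_trajectory(arena, SimulationConfig(), seed=4)
cache = precompute_bearing_bins(tracking, arena)
rng = np.random.default_rng(2)

cb = default_model("cb", rng)
conj = default_model("cb_x_hd", rng, reference_point=(90.0, 40.0))
for name, model in (("pure CB", cb), ("CB x HD", conj)):
    spikes = generate_spikes(tracking, model, seed=30 + len(name), arena=arena)
    m = mvl_map(tracking, spikes, arena, cache=cache)
    print(
        f"{name:8s} generative ref={tuple(round(v, 1) for v in model.reference_point)} "
        f"MVL_max location={m.mvlmax_location} (max MVL={m.max_mvl:.2f})"
    )
print("\nthe recovered MVL_max location sits on the 6 cm reference grid,")
print("within one grid step of the generative reference point.")
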