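"""Cue-rotation triplet: POR-like cells follow the cue, MEC-like cells don't.

Simulates a standard -> cue-moved-to-east-wall -> standard session triplet.
Landmark-modulated HD (LM-HD) cells with cue_gain=1 rotate their preferred
firing direction by +90 degrees in the manipulation session; grid cells
keep their firing map, so their rate-map correlation across sessions is
maximal at 0 degrees rotation. The population V-test checks that LM-HD
shifts cluster at the expected +90.
"""

import numpy as np

from openfield import ArenaGeometry, SimulationConfig, default_model, run_cue_analysis, simulate_cue_triplet
from openfield.pipeline import session_views_from_triplet

arena = ArenaGeometry()
rng = np.random.default_rng(3)
models = {
    **{f"lmhd_{i}": default_model("lm_hd", rng, cue_gain=1.0) for i in range(6)},
    **{f"grid_{i}": default_model("grid", rng) for i in range(4)},
}
triplet = simulate_cue_triplet(arena, SimulationConfig(), models, "ccw_rotation", seed=5)
result = run_cue_analysis(session_views_from_triplet(triplet), scenario="ccw_rotation")

cols = ["cell", "region", "shift_deg", "map_corr_0", "map_corr_90"]
print(result["table"][cols].to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print("\npopulation tests on preferred-direction shifts:")
for region, stats in result["population"].items():
    print(f"  {region}: " + ", ".join(f"{k}={v:.3g}" for k, v in stats.items()))
print("\nPOR shifts cluster at +90 deg (V-test P well below 0.01); grid-cell")
print("maps correlate best at 0 deg, i.e. they ignore the cue.")
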