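"""Cue-duplication triplet: bidirectionality and per-cue modulation.

With an identical second cue card on the opposite wall, landmark-modulated
HD cells split their tuning into two lobes 180 degrees apart. The
bidirectionality index BI = (MVL_doubled - MVL_normal)/(MVL_doubled +
MVL_normal) jumps in the duplication session for POR-like cells and stays
flat for MEC-like HD cells; a bidirectional von Mises fit yields the
south/north cue modulation indices MI_S and MI_N.
"""

import numpy as np

from openfield import ArenaGeometry, SimulationConfig, default_model, run_cue_analysis, simulate_cue_triplet
from openfield.pipeline import session_views_from_triplet

arena = ArenaGeometry()
rng = np.random.default_rng(4)
models = {
    **{f"por_{i}": default_model("lm_hd", rng, duplication_weight=0.5) for i in range(4)},
    **{f"mec_{i}": default_model("hd", rng) for i in range(4)},
}
triplet = simulate_cue_triplet(arena, SimulationConfig(), models, "duplication", seed=6)
result = run_cue_analysis(session_views_from_triplet(triplet), scenario="duplication")

cols = ["cell", "bi_standard1", "bi_manipulation", "delta_bi", "mi_s", "mi_n"]
print(result["table"][cols].to_string(index=False, float_format=lambda v: f"{v:.2f}"))
por = result["table"][result["table"].cell.str.startswith("por")]["delta_bi"].mean()
mec = result["table"][result["table"].cell.str.startswith("mec")]["delta_bi"].mean()
print(f"\nmean delta-BI: POR-like {por:.2f} vs MEC-like {mec:.2f}")
print("POR cells become bidirectional under the doubled cue; MEC cells do not,")
print("and their roughly equal MI_S/MI_N reflects equal-weight lobes (w=0.5).")
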