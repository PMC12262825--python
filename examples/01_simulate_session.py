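"""Simulate one 20-minute place-navigation session and summarize behavior.

A virtual rat forages in a 120 x 120 cm arena, triggering pellet rewards by
entering an uncued 15 cm goal zone (10 s reward timeout). The printed table
compares the goal zone against its three rotationally equivalent zones:
with goal-biased foraging, entries/min and occupancy are highest at the
goal while approach directions stay dispersed (low Rayleigh r), the
signature of place (rather than route) navigation.
"""

from openfield import ArenaGeometry, SimulationConfig, simulate_trajectory
from openfield.behavior import behavior_table

arena = ArenaGeometry()
tracking = simulate_trajectory(arena, SimulationConfig(goal_bias=0.5), seed=5)

table = behavior_table(tracking, arena)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(
    f"\ngoal-zone (NW) rewards honoring the 10 s timeout: "
    f"{int(table.loc[table.zone == 'NW', 'n_rewards'].iloc[0])} in 20 min"
)
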