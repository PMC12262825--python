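# openfield

Single-neuron spatial-coding analysis for open-field place-navigation
sessions: penalized Poisson GLM cell classification, allocentric map scores
(grid score, border score, spatial information), egocentric reference-point
(MVL_max) mapping, and visual-cue-manipulation statistics — together with a
synthetic session generator that produces trajectories and spike trains
with known ground-truth tuning for every supported cell type.

## Who this is for

Systems-neuroscience analysts working with tetrode recordings from freely
moving rodents in square open-field arenas, in paradigms where an animal
shuttles between an uncued goal zone and scattered rewards while cortical
neurons are recorded — postrhinal (POR) egocentric cell types
(center-bearing, center-distance, landmark-modulated head-direction) and
medial-entorhinal/parasubicular (MEC/PaS) allocentric types (grid, border,
non-grid spatial, head-direction). Sessions are plain-text: a tracking CSV
(`time_s,x_cm,y_cm,hd_deg` at 30 Hz), one spike-timestamp text file per
cell, and a small YAML manifest.

## The models and statistics at the core

**Encoding model.** Per-frame spike counts `n_t` are Poisson with rate

```
r_t = exp( Σ_i  X_i(t)ᵀ β_i ),
```

where each behavioral variable *i* — 2D location (20×20 bins), head
direction (30 bins), egocentric bearing of the arena center (30 bins),
center distance (10 bins), linear speed (10 bins) — enters as a one-hot
state vector. Parameters maximize the penalized log-likelihood `l − P`
with `l = Σ_t [n_t log r_t − r_t − log n_t!]` and a smoothness penalty
`P = Σ_i S_i Σ_j ½(β_{i,j+1} − β_{i,j})²` over adjacent bins (S = 2 for
location, 20 otherwise; circular adjacency for angles, a 4-neighbor grid
for location). Variables are selected by 10-fold cross-validated forward
selection with one-sided Wilcoxon signed-rank comparisons across folds;
cells whose best model does not beat a mean-rate-only model are
*unclassified*.

**Map scores.** Firing-rate maps use 2.5 cm bins with 3.75 cm Gaussian
smoothing (edge-renormalized). The grid score is
`min(corr 60°, 120°) − max(corr 30°, 90°, 150°)` of the spatial
autocorrelogram annulus rotated against itself; the border score is
`(c − d)/(c + d)` with `c` the maximum single-wall coverage by one firing
field and `d` the rate-weighted mean nearest-wall distance normalized by
60 cm; spatial information is `Σ_i P_i (R_i/R) log₂(R_i/R)` in bits/spike.
Classification thresholds: grid > 0.4, border > 0.5, tuning-curve MVL > 0.2
and > the within-cell 99th percentile of 400 circularly time-shifted
(≥ 30 s) spike trains, peak rate > 1 Hz.

**Egocentric reference points.** For a 20×20 grid of candidate reference
points, the egocentric-bearing tuning curve (12° bins) is summarized by its
mean vector length; the argmax (`MVL_max` location) is the cell's preferred
reference point — the arena center for pure center-bearing cells, offset
points for conjunctive CB×HD cells.

**Cue manipulations.** Standard → manipulated → standard session triplets
quantify whether tuning follows a wall cue: signed preferred-direction
shifts (V-test against the expected ±90°), the bidirectionality index
`BI = (MVL_doubled − MVL_normal)/(MVL_doubled + MVL_normal)` under cue
duplication, bidirectional von Mises fits with per-cue modulation indices
`MI = (P − Min_fit)/Max_fit`, rate-map correlations at 90° rotations, and
`MVL_max` rotation about the arena center.

## A worked example

```bash
python examples/03_glm_classification.py
```

prints, for five synthetic cells on one 20-minute session:

```
hd    ( 2653 spikes) -> hd
cb    ( 2840 spikes) -> center_bearing
grid  ( 1311 spikes) -> location + center_distance
cd    ( 6317 spikes) -> location + center_distance
null  ( 2445 spikes) -> unclassified
```

Each line is the forward-selected variable set of the penalized Poisson
GLM: the head-direction cell is explained by head direction alone, the
center-bearing cell by egocentric bearing, the grid and center-distance
cells by spatial regressors (the two overlap — a radial rate profile is
also a coarse location signal, so both variables can earn a place in the
model), and the homogeneous-Poisson null beats nothing — it stays
unclassified. The other example scripts walk through behavior
metrics (`01`), rate maps and map scores (`02`), egocentric reference-point
recovery (`04`), and the cue rotation/duplication analyses (`05`, `06`).

A thin CLI wraps the same pipeline for batch use:

```bash
openfield simulate --scenario ccw_rotation --seed 1 --out session_dir
openfield analyze session_dir/standard1/manifest.yaml --out results_dir
```

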