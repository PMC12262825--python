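# Methods

This note documents the models, estimators and numerical choices behind
`openfield`, the assumptions they rest on, and what the synthetic benchmark
does and does not establish.

## Scope and data model

The package analyzes single-unit recordings from a square open-field arena
(default 120 × 120 cm) during a place-navigation task: the animal triggers
scattered pellet rewards by entering an uncued 15 cm goal zone (centered
35 cm from the west wall, 45 cm from the north wall), subject to a 10 s
reward timeout. Sessions are 20 minutes of 30 Hz tracking (position x/y in
cm from the southwest corner, head direction in degrees counterclockwise
from east) plus per-cell spike timestamps. Spikes are assigned to the frame
whose interval `[t_f, t_f + Δt)` contains them; no speed filtering is
applied anywhere.

## Synthetic session generator

The generator exists so that every downstream estimator can be tested
against known ground truth; its defaults are the task conditions above.

**Trajectory.** A correlated random walk: heading persists with
wrapped-Gaussian turning noise (18°/frame), speed follows an
Ornstein–Uhlenbeck process (set point 15 cm/s, sd 6 cm/s, τ = 1 s, clipped
at 60 cm/s), boundaries reflect. With `goal_bias > 0` the walk steers
toward alternating targets — the goal zone, then the 1–4 scattered
"pellets" a rewarded entry produces — with steering gain
`goal_bias × 0.12` per frame. Two second-order behaviors were added to
match the task's occupancy statistics rather than only its entry
statistics: a brief pause at the reward trigger (exponential, mean 2 s) and
goal-approach deceleration (speed × (1 − 0.6·goal_bias) within 20 cm of the
goal), followed by an undirected foraging interval (exponential, mean 40 s)
after pellet retrieval, which sets the reward rate near the task's
~1/minute. Head direction is the movement heading plus von Mises jitter
(κ = 100); head and body axes are deliberately conflated, and no
LED-tracking noise model is included.

**Tuning models.** Each cell's rate is
`baseline + (peak − baseline) × shape` with `shape ∈ [0, 1]`, so rates are
non-negative by construction:

| kind     | shape | defaults |
|----------|-------|----------|
| grid     | normalized three-cosine lattice, sharpened by exponent `max(1, (spacing/width)²/2)` | spacing 40 cm, width 12 cm, peak 15 Hz |
| border   | `exp(−d_wall/decay)` for one wall | decay 8 cm, peak 12 Hz |
| nongrid  | clipped sum of 2–3 Gaussian fields | widths 8–14 cm, peak 12 Hz |
| hd, lm_hd| von Mises in head direction | κ = 4, peak 10 Hz |
| cb       | von Mises in egocentric bearing of a reference point | κ = 4, reference = arena center, peak 10 Hz |
| cd       | linear or Gaussian in center distance | peak 10 Hz |
| cb_x_hd  | product of a bearing factor (κ = 4) and a broad HD factor (κ = 1) | offset reference, peak 15 Hz |

The broad HD factor for conjunctive cells is a deliberate identifiability
choice: with sharp HD gating the cell fires only along one ray through its
reference point, and the bearing MVL then *increases* along that ray beyond
the true reference — the reference point is not recoverable in principle.
Broad HD modulation (which also matches the weaker HD tuning of conjunctive
cells relative to pure HD cells) breaks the degeneracy; see Limitations.

**Spikes.** Per frame, a Poisson count with mean `rate × Δt` (exact at this
discretization; no thinning) with timestamps jittered uniformly within the
frame. All randomness flows through explicit integer seeds.

**Cue triplets.** `simulate_cue_triplet` produces standard → manipulated →
standard sessions. In the manipulated session, POR-like (cue-following)
models change: LM-HD preferred directions rotate by `cue_gain × (±90°)`
(counterclockwise rotation moves the cue south → east), or become two-lobed
mixtures `(1−w)·vm(μ) + w·vm(μ+180°)` under duplication (normalized to
preserve the peak rate); conjunctive CB×HD references rotate about the
arena center by the same gained angle, and under duplication contract
toward the center by `1 − w`. MEC/PaS-like models are identical across the
three sessions.

## Estimators

**Rate maps.** 48 × 48 bins of 2.5 cm; rate = spikes/occupancy per bin;
Gaussian smoothing σ = 3.75 cm with an edge-truncated, renormalized kernel
(missing bins excluded from the kernel support, so wall rates are not
suppressed). Unvisited bins stay missing. Spatial information uses the
smoothed rate map and an occupancy histogram smoothed with the same σ
(the σ for occupancy is not separately specifiable because no evidence
suggested it should differ); `R` is the occupancy-weighted mean rate, which
makes the 4-bin worked example (four equal-occupancy bins, one active)
exactly 2 bits/spike.

**Tuning curves.** Circular variables use 12° bins (30 bins), center
distance 4 cm bins over `[0, 60√2]` cm. The MVL and preferred direction are
computed from the *binned, occupancy-corrected* curve:
`|Σ_b rate_b e^{iθ_b}| / Σ_b rate_b` over bin centers — not from raw spike
angles. Distance curves get unweighted least-squares linear and Gaussian
(amplitude/mean/width/offset) fits; a non-convergent Gaussian fit yields a
missing R² while the linear R² survives. R² of a zero-variance curve is
defined as 0.

**Shuffling.** A circular time shift uniform on
`[30 s, duration − 30 s]`, wrapped modulo the session, repeated 400 times;
the within-cell 99th percentile of the statistic is the significance
threshold. The shift preserves the spike train's internal temporal
structure, so shuffled distance/bearing curves are *smooth* (neighboring
bins share temporal segments) — flexible fits such as the 4-parameter
Gaussian reach high R² on shuffled data (often above 0.95). The
center-distance rule therefore compares each fit type against its own
shuffle distribution; a pooled best-vs-best comparison would let the
Gaussian's shuffle ceiling mask genuine linear tuning. Calibration of the
MVL criterion is verified to hold at its nominal ~1% false-positive rate.

**Occupancy resampling.** 15 cm bins (64 total); the target is the minimum
occupancy over *visited* bins (zero-occupancy bins would degenerate the
rule and are excluded); frames are subsampled without replacement per bin,
keeping original timestamps, and spikes survive iff their frame does.

**GLM.** Sparse one-hot design stored as per-frame bin indices. The
objective `P − l` is minimized by L-BFGS-B with analytic gradients
(`∇_β l` via per-bin count aggregation, `∇_β P = S·Lβ` with graph
Laplacians: cycle for angles, path for distance/speed, 4-neighbor grid for
location), initialized at β = 0, converged at projected-gradient < 1e−6 or
500 iterations (function tolerance 1e−9). Speed is frame displacement
smoothed with a 0.5 s boxcar and binned over [0, 50] cm/s — the bin range
is a package choice. Folds are contiguous tenths of the session. Each
fold's full five-variable model is fit on the training frames (warm-started
from the full-session fit, a pure initialization choice); subset test
log-likelihoods reuse the full model's β blocks with the subset rate
rescaled so its training-mean matches the training mean spike count (the
rescaling method is a package choice). Forward selection grows a nested
path, accepting a larger model when a one-sided Wilcoxon signed-rank test
across the 10 fold log-likelihoods (raw sums, not per-spike normalized) is
significant at α = 0.05, and requires the final model to beat a mean-rate
model. Cells with fewer than 100 spikes are unclassified outright
(degenerate fits otherwise; configurable).

**Autocorrelogram and grid score.** The spatial autocorrelogram is the
overlap-Pearson correlation of the smoothed map with itself at every
integer bin shift, masked below 20 overlapping bins; the central value is
1 by definition. Note the estimator is *not* exactly isotropic even for an
isotropic field: the square overlap window makes equal-radius values
direction-dependent; its exact symmetries (point reflection, and the
symmetry group of the map) are what the tests assert. Ring radii are
estimated from the radial profile — inner = first local minimum after the
central peak, outer = 1.5 × the next local maximum's radius, capped at half
the map extent, with fallback `[2 bins, half extent]` (the "most probable
radii" procedure is a heuristic; no canonical algorithm exists). The
annulus is correlated with itself rotated in 3° steps (bilinear
interpolation), and the score is
`min(corr 60°, 120°) − max(corr 30°, 90°, 150°)`.

**Border score.** Computed on the smoothed map (consistent with the grid
analysis): bins < 20% of peak removed, 4-connected fields ≥ 200 cm² kept;
`c` = the largest fraction of one wall's adjacent bin row covered by a
single field; `d` = rate-weighted mean nearest-wall distance of all field
bins ÷ 60 cm. A one-bin-deep full-wall strip gives
`(1 − 1.25/60)/(1 + 1.25/60) ≈ 0.959`.

**Field detection.** 30% of peak threshold, 4-connectivity, ≥ 150 cm²,
rate-weighted centroids; deterministic component ordering.

**Classification.** grid ⇔ GLM-location ∧ grid score > 0.4;
border ⇔ GLM-location ∧ border score > 0.5 ∧ ¬grid (grid precedence is a
package choice — exclusivity is implied by the non-grid definition but no
tie rule exists); non-grid spatial ⇔ GLM-location ∧ SI > shuffle ∧ ¬grid ∧
¬border; hd/cb ⇔ GLM variable ∧ MVL > shuffle ∧ MVL > 0.2 ∧ peak > 1 Hz;
cd ⇔ GLM-distance ∧ (linear R² > linear-shuffle ∨ Gaussian R² >
Gaussian-shuffle) ∧ peak > 1 Hz — each fit type against the shuffle
distribution of the same fit type, because pooling them lets the flexible
Gaussian dominate the threshold (see below). POR
head-direction cells are reported under the landmark-modulated (`lm_hd`)
label. Shuffle thresholds are computed only for the statistics a cell's
GLM selection makes relevant. The five GLM candidates include speed even
though no speed-cell classification exists.

**Egocentric MVL maps.** Reference grid = centers of a 20 × 20 partition
(6 cm pitch, 3 cm inset from the walls — the inset is a package choice).
Bearing is `atan2(ref − pos) − hd` wrapped to [−180°, 180°), 0° ahead,
+90° to the animal's left (counterclockwise-positive, matching the HD
convention; the sign convention is fixed once, here). Samples within 1 cm
of the reference point are excluded (the bearing is singular at zero
distance). A reference point with under half its bearing bins occupied has
no MVL. Argmax ties break toward the smallest row-major index.

**Cue statistics.** Preferred-direction shifts are signed circular
differences in [−180°, 180°). The bidirectional von Mises fit is
unweighted least squares on the 30-bin curve (not spike-level likelihood)
of `offset ± [A₁·vm(θ; μ, κ) + A₂·vm(θ; μ+180°, κ)]` with shared κ and
separate amplitudes (the lobes' amplitude tie is genuinely open; separate
amplitudes are the weaker assumption), multi-started over 12 initial lobe
directions. Modulation indices attribute the fitted lobe circularly nearest
the session-1 preferred (or trough) direction to the south cue. Rotated-map
correlations rotate the second map back by the labeled angle, so "maximal
at 90°" means the second map *is* the first rotated +90°. The Rayleigh P
uses `exp(−Z)(1 + (2Z − Z²)/4n)` with `Z = nr²`; the V-test uses the
normal approximation of `u = nr·cos(mean − μ₀)·√(2/n)`. Both are
cross-checked against pingouin in the test suite.

## Benchmark problem sizes

The acceptance suite runs 20 cells per type plus 20 nulls for classifier
recovery, 100 null cells × 400 shuffles for calibration, 30 LM-HD + 20
grid + 10 HD cells for rotation, 15 + 15 for duplication, and 20 CB×HD +
10 CB cells for egocentric recovery — all on full 20-minute sessions.
`scripts/acceptance.py` uses 10 cells per type (and proportionally smaller
cue populations) so a full regeneration stays near ten minutes on one CPU;
every reported quantity carries the n it was computed from.

## What the synthetic benchmark shows — and what it does not

Passing tests establish that the estimators recover the generative tuning
they were pointed at, under Poisson spiking, rat-like but simplified
kinematics, and exactly the binning/thresholds above. They do not
establish robustness to non-Poisson firing (bursting, theta rhythmicity),
tracking noise or head-body dissociation, electrode drift, spike-sorting
contamination, or multi-day non-stationarity — none of which the generator
emulates. The goal-bias mechanism (target attraction with reward pauses)
reproduces occupancy and entry statistics, not the microstructure of real
paths.

## Known limitations

- Conjunctive CB×HD reference points are identifiable only when HD gating
  is broad; sharply conjunctive cells have a ray-shaped MVL ridge and their
  MVL_max slides outward. Real data analyses should treat peripheral
  MVL_max locations of strongly HD-tuned cells with suspicion.
- A pure HD cell's MVL map is structured (low centrally, high
  peripherally), not flat; the center-vs-periphery contrast, not map
  flatness, separates HD from CB tuning.
- The center-distance Gaussian-fit shuffle threshold is intrinsically high
  (shuffled curves are smooth and Gaussian-fittable), so Gaussian-profile
  CD cells need very clean tuning to pass; the per-type linear comparison
  carries most of the power for linear-profile cells.
- The grid-score ring-radius heuristic can misestimate radii for maps with
  very large or very small spacing relative to the arena.
- Theta rhythmicity, speed-cell classification and spike-sorting quality
  metrics are out of scope; the per-cell tables are designed to feed
  external mixed-model / ANOVA tooling rather than re-implement it.
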