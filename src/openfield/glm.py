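"""Penalized Poisson GLM encoding model with cross-validated forward
model selection.

The spike count in each 30 Hz frame is modeled as Poisson with rate
``r_t = exp(sum_i X_i(t)^T beta_i)`` where each behavioral variable i
(2D location, head direction, center bearing, center distance, linear
speed) enters through a one-hot binned state vector. Parameter vectors are
fit by minimizing ``P - l``: the Poisson log-likelihood ``l`` minus a
smoothing penalty ``P = sum_i S_i sum_j (beta_{i,j+1} - beta_{i,j})^2 / 2``
over adjacent bins (circular adjacency for angles, a 4-neighbor grid for
location). Variables are selected by 10-fold cross-validation with forward
selection and one-sided Wilcoxon signed-rank comparisons across folds; a
cell whose best model does not beat a mean-rate-only model is unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import gammaln
from scipy.stats import wilcoxon

from .geometry import ArenaGeometry
from .session import SpikeTrain, TrackingData
from .tuning import center_bearing

VARIABLES = ("location", "hd", "center_bearing", "center_distance", "speed")
N_BINS = {"location": 400, "hd": 30, "center_bearing": 30, "center_distance": 10, "speed": 10}
DEFAULT_SMOOTHING = {"location": 2.0, "hd": 20.0, "center_bearing": 20.0, "center_distance": 20.0, "speed": 20.0}
SPEED_MAX = 50.0  # cm/s; faster frames share the top bin


# ------------------------------------------------------------------- design
@dataclass(frozen=True)
class DesignMatrix:
    """One-hot binned behavioral state per frame, stored as bin indices.

    ``indices[var][t]`` is the active bin of variable ``var`` in frame t
    (equivalent to a one-hot row); ``counts[t]`` is the spike count.
    """

    indices: dict[str, np.ndarray]
    counts: np.ndarray
    dt: float

    @property
    def n_frames(self) -> int:
        return self.counts.size


def build_design(
    tracking: TrackingData,
    spikes: SpikeTrain,
    arena: ArenaGeometry | None = None,
    speed_smooth_frames: int = 15,
) -> DesignMatrix:
    """Bin the five behavioral variables and the spike train per frame.

    Location uses a 20 x 20 grid (400 bins), head direction and center
    bearing 30 bins each, center distance and linear speed 10 bins each.
    Speed is displacement per frame smoothed with a short boxcar.
    """
    arena = arena or ArenaGeometry()
    side = arena.side_length
    if np.any(~arena.contains(tracking.x, tracking.y)):
        raise ValueError("tracking contains frames outside the arena")

    n_loc = int(np.sqrt(N_BINS["location"]))
    ix = np.minimum((tracking.x / (side / n_loc)).astype(int), n_loc - 1)
    iy = np.minimum((tracking.y / (side / n_loc)).astype(int), n_loc - 1)
    loc = iy * n_loc + ix

    hd = np.minimum((tracking.hd / (360.0 / N_BINS["hd"])).astype(int), N_BINS["hd"] - 1)

    bearing = center_bearing(tracking, arena.center)
    # the bearing is ill-defined within 1 cm of the center; such frames are
    # vanishingly rare and are assigned to bin 0
    bearing = np.where(np.isfinite(bearing), bearing, -180.0)
    cb = np.minimum(
        (np.mod(bearing, 360.0) / (360.0 / N_BINS["center_bearing"])).astype(int),
        N_BINS["center_bearing"] - 1,
    )

    cx, cy = arena.center
    dist = np.hypot(tracking.x - cx, tracking.y - cy)
    dmax = side / 2.0 * np.sqrt(2.0)
    cd = np.minimum((dist / (dmax / N_BINS["center_distance"])).astype(int), N_BINS["center_distance"] - 1)

    dx = np.diff(tracking.x, prepend=tracking.x[0])
    dy = np.diff(tracking.y, prepend=tracking.y[0])
    speed = np.hypot(dx, dy) / tracking.dt
    if speed_smooth_frames > 1:
        kernel = np.ones(speed_smooth_frames) / speed_smooth_frames
        speed = np.convolve(speed, kernel, mode="same")
    sp = np.minimum(
        (np.clip(speed, 0.0, np.nextafter(SPEED_MAX, 0)) / (SPEED_MAX / N_BINS["speed"])).astype(int),
        N_BINS["speed"] - 1,
    )

    return DesignMatrix(
        indices={
            "location": loc.astype(np.int32),
            "hd": hd.astype(np.int32),
            "center_bearing": cb.astype(np.int32),
            "center_distance": cd.astype(np.int32),
            "speed": sp.astype(np.int32),
        },
        counts=spikes.counts_per_frame(tracking),
        dt=tracking.dt,
    )


# ------------------------------------------------------------- log-likelihood
def poisson_loglik(n, r) -> float:
    """Poisson log-likelihood ``l = sum_t [n_t log r_t - r_t - log(n_t!)]``."""
    n = np.asarray(n, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("rates must be strictly positive")
    return float(np.sum(n * np.log(r) - r - gammaln(n + 1.0)))


# ---------------------------------------------------------- smoothing penalty
def _laplacian_path(n: int) -> np.ndarray:
    L = np.zeros((n, n))
    for j in range(n - 1):
        L[j, j] += 1
        L[j + 1, j + 1] += 1
        L[j, j + 1] -= 1
        L[j + 1, j] -= 1
    return L


def _laplacian_cycle(n: int) -> np.ndarray:
    L = _laplacian_path(n)
    L[0, 0] += 1
    L[-1, -1] += 1
    L[0, -1] -= 1
    L[-1, 0] -= 1
    return L


def _laplacian_grid(n: int) -> np.ndarray:
    """4-neighbor grid Laplacian for an n x n layout, row-major."""
    N = n * n
    L = np.zeros((N, N))
    for iy in range(n):
        for ix in range(n):
            a = iy * n + ix
            for jy, jx in ((iy, ix + 1), (iy + 1, ix)):
                if jy < n and jx < n:
                    b = jy * n + jx
                    L[a, a] += 1
                    L[b, b] += 1
                    L[a, b] -= 1
                    L[b, a] -= 1
    return L


def _penalty_matrix(var: str) -> np.ndarray:
    n = N_BINS[var]
    if var == "location":
        return _laplacian_grid(int(np.sqrt(n)))
    if var in ("hd", "center_bearing"):
        return _laplacian_cycle(n)
    return _laplacian_path(n)


_LAPLACIANS = {v: _penalty_matrix(v) for v in VARIABLES}


# -------------------------------------------------------------------- fitting
@dataclass(frozen=True)
class GLMModelFit:
    """Fitted parameter vectors with convergence diagnostics."""

    betas: dict[str, np.ndarray]
    smoothing: dict[str, float]
    train_loglik: float
    penalty: float
    converged: bool
    n_iter: int
    message: str = ""

    def rate(self, design: DesignMatrix, frames=slice(None), variables=None) -> np.ndarray:
        """Fitted rate per frame using the given variables' beta blocks."""
        variables = tuple(self.betas) if variables is None else tuple(variables)
        eta = np.zeros(design.indices[variables[0]][frames].shape)
        for v in variables:
            eta = eta + self.betas[v][design.indices[v][frames]]
        return np.exp(eta)


def make_objective(design: DesignMatrix, variables: tuple[str, ...], smoothing: dict[str, float], frames=slice(None)):
    """Objective ``P - l`` (up to the constant log n!) and its analytic
    gradient over packed beta vectors, for the given training frames."""
    idx = {v: design.indices[v][frames] for v in variables}
    n = design.counts[frames]
    sizes = [N_BINS[v] for v in variables]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def unpack(beta):
        return {v: beta[offsets[i]: offsets[i + 1]] for i, v in enumerate(variables)}

    def fun(beta):
        parts = unpack(beta)
        eta = np.zeros(n.size)
        for v in variables:
            eta += parts[v][idx[v]]
        r = np.exp(eta)
        nll = float(np.sum(r) - np.sum(n * eta))
        pen = 0.0
        grad = np.empty_like(beta)
        for i, v in enumerate(variables):
            b = parts[v]
            Lb = _LAPLACIANS[v] @ b
            pen += 0.5 * smoothing[v] * float(b @ Lb)
            grad[offsets[i]: offsets[i + 1]] = (
                np.bincount(idx[v], weights=r - n, minlength=N_BINS[v]) + smoothing[v] * Lb
            )
        return nll + pen, grad

    return fun, offsets, unpack


def fit_glm(
    design: DesignMatrix,
    variables: tuple[str, ...] = VARIABLES,
    smoothing: dict[str, float] | None = None,
    frames=slice(None),
    beta0: np.ndarray | None = None,
    max_iter: int = 500,
    gtol: float = 1e-6,
) -> GLMModelFit:
    """Fit the penalized Poisson GLM for the given variables on the given
    frames. Initialization is beta = 0 (or a warm start); convergence when
    the projected gradient norm falls below ``gtol`` or at ``max_iter``."""
    if not variables:
        raise ValueError("variables must be nonempty")
    smoothing = dict(DEFAULT_SMOOTHING if smoothing is None else smoothing)
    fun, offsets, unpack = make_objective(design, tuple(variables), smoothing, frames)
    x0 = np.zeros(offsets[-1]) if beta0 is None else np.asarray(beta0, dtype=float).copy()

    res = optimize.minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-9, "maxcor": 20},
    )
    betas = unpack(res.x)
    n = design.counts[frames]
    r = np.exp(sum(betas[v][design.indices[v][frames]] for v in variables))
    pen = sum(
        0.5 * smoothing[v] * float(betas[v] @ (_LAPLACIANS[v] @ betas[v])) for v in variables
    )
    return GLMModelFit(
        betas={v: betas[v].copy() for v in variables},
        smoothing={v: smoothing[v] for v in variables},
        train_loglik=poisson_loglik(n, r),
        penalty=float(pen),
        converged=bool(res.success),
        n_iter=int(res.nit),
        message=str(res.message),
    )


# ----------------------------------------------------------- model selection
@dataclass(frozen=True)
class ModelSelectionResult:
    """Forward-selection outcome for one cell."""

    selected: tuple[str, ...]           # empty -> unclassified
    fold_logliks: dict                  # subset tuple -> per-fold test LL array
    pvalues: dict                       # (smaller, larger) -> Wilcoxon p
    classified: bool
    n_spikes: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def selected_set(self) -> set[str]:
        return set(self.selected)


def _fold_slices(n_frames: int, k: int) -> list[slice]:
    edges = np.linspace(0, n_frames, k + 1).astype(int)
    return [slice(edges[i], edges[i + 1]) for i in range(k)]


def _subset_test_loglik(design, fit: GLMModelFit, subset, train_sl, test_sl) -> float:
    """Test log-likelihood of a variable subset using the full-model beta
    blocks, with the subset rate rescaled so its training-mean rate matches
    the training mean spike count."""
    n_train = design.counts[train_sl]
    r_train = fit.rate(design, train_sl, subset)
    scale = n_train.mean() / max(r_train.mean(), 1e-300)
    r_test = np.maximum(fit.rate(design, test_sl, subset) * scale, 1e-12)
    return poisson_loglik(design.counts[test_sl], r_test)


def _one_sided_wilcoxon(larger: np.ndarray, smaller: np.ndarray) -> float:
    diff = larger - smaller
    if np.allclose(diff, 0.0):
        return 1.0
    try:
        return float(wilcoxon(diff, alternative="greater").pvalue)
    except ValueError:
        return 1.0


def forward_select(
    design: DesignMatrix,
    k: int = 10,
    alpha: float = 0.05,
    smoothing: dict[str, float] | None = None,
    min_spikes: int = 100,
    max_iter: int = 500,
) -> ModelSelectionResult:
    """Cross-validated forward selection of behavioral variables.

    Per fold, the full five-variable model is fit on the training 9/10 of
    the session; test log-likelihoods for every variable subset are derived
    from the full-model beta blocks. Model growth proceeds while the larger
    model beats the smaller by a one-sided Wilcoxon signed-rank test across
    folds; the final model must also beat a mean-firing-rate-only model,
    else the cell is unclassified.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    n_spikes = int(design.counts.sum())
    if n_spikes < min_spikes:
        return ModelSelectionResult(
            selected=(), fold_logliks={}, pvalues={}, classified=False,
            n_spikes=n_spikes, diagnostics={"reason": f"fewer than {min_spikes} spikes"},
        )

    T = design.n_frames
    folds = _fold_slices(T, k)
    all_frames = np.arange(T)

    # warm start every fold from the full-session fit
    base = fit_glm(design, VARIABLES, smoothing, max_iter=max_iter)
    base_packed = np.concatenate([base.betas[v] for v in VARIABLES])

    from itertools import combinations

    subsets = [tuple(c) for m in range(1, len(VARIABLES) + 1) for c in combinations(VARIABLES, m)]
    fold_ll = {s: np.empty(k) for s in subsets}
    fold_ll[()] = np.empty(k)  # mean-rate-only model
    converged = []

    for j, test_sl in enumerate(folds):
        train_mask = np.ones(T, dtype=bool)
        train_mask[test_sl] = False
        train_idx = all_frames[train_mask]
        fit = fit_glm(design, VARIABLES, smoothing, frames=train_idx, beta0=base_packed, max_iter=max_iter)
        converged.append(fit.converged)
        for s in subsets:
            fold_ll[s][j] = _subset_test_loglik(design, fit, s, train_idx, test_sl)
        mean_rate = max(design.counts[train_idx].mean(), 1e-12)
        fold_ll[()][j] = poisson_loglik(
            design.counts[test_sl], np.full(test_sl.stop - test_sl.start, mean_rate)
        )

    def canon(s) -> tuple[str, ...]:
        return tuple(v for v in VARIABLES if v in s)

    def best_extension(current: tuple[str, ...]) -> tuple[str, ...]:
        cands = [canon(current + (v,)) for v in VARIABLES if v not in current]
        return max(cands, key=lambda s: fold_ll[s].mean())

    pvals = {}
    current = max([(v,) for v in VARIABLES], key=lambda s: fold_ll[s].mean())
    while len(current) < len(VARIABLES):
        nxt = best_extension(current)
        p = _one_sided_wilcoxon(fold_ll[nxt], fold_ll[current])
        pvals[(current, nxt)] = p
        if p < alpha:
            current = nxt
        else:
            break

    p_vs_mean = _one_sided_wilcoxon(fold_ll[current], fold_ll[()])
    pvals[((), current)] = p_vs_mean
    classified = p_vs_mean < alpha
    return ModelSelectionResult(
        selected=current if classified else (),
        fold_logliks={s: fold_ll[s].copy() for s in fold_ll},
        pvalues=pvals,
        classified=classified,
        n_spikes=n_spikes,
        diagnostics={"all_folds_converged": all(converged), "base_fit_iters": base.n_iter},
    )
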