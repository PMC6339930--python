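"""End-to-end arena-geometry studies.

Each study trains the full model (foraging trajectory -> HD sheet ->
oscillators -> LAHN) in a family of arenas, scores grid-like LAHN neurons
with the hexagonal gridness score (HGS), and summarizes how gridness varies
with the manipulated factor:

* connected arenas (square-square / square-circle / circle-circle): local vs
  global HGS across training checkpoints;
* connected arenas with growing compartment separation: final local/global
  HGS vs distance;
* convex arenas (square vs trapezoid): per-half HGS, half-map similarity and
  grid-field ellipticity;
* concave arenas (annulus / horseshoe / S): mean HGS vs inner radius;
* regular polygons: mean HGS vs number of sides;
* transforming arena (rectangle widening to a square): a single-hidden-layer
  MLP decodes the arena configuration from LAHN population responses.

Trend claims are evaluated per seed by ordinary least squares and aggregated
as the majority slope sign with the median R^2, since individual runs are
stochastic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import geometry, spatial_maps
from .errors import (DegenerateLabelsError, DegenerateRegressionError,
                     InsufficientSamplingError)
from .geometry import Environment
from .network import ModelState, NetParams, train_model
from .trajectory import TrajectoryParams

CONNECTED_PAIRS = ("square-square", "square-circle", "circle-circle")


# ---------------------------------------------------------------------------
# Specs and result containers
# ---------------------------------------------------------------------------

@dataclass
class ExperimentSpec:
    """Shared configuration for a study.

    ``duration`` is the foraging time per run in seconds. Desk-scale runs use
    a few hundred seconds; the arenas are small and the spatial code is fine
    (grid period ``2*pi/beta``), so this already covers the arena densely.
    """

    duration: float = 600.0
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5)
    checkpoints: int = 5
    room_size: float = 1.8
    corridor_width: float = 0.8
    distance_d: float = 0.8
    bin_size: float = 0.02
    smoothing_sigma: float = 1.0
    net: NetParams = field(default_factory=NetParams)
    traj: TrajectoryParams = field(default_factory=TrajectoryParams)
    grid_neuron_fraction: float = 0.25

    def n_grid_neurons(self) -> int:
        return max(1, int(round(self.net.n_lahn * self.grid_neuron_fraction)))


@dataclass
class TrendResult:
    """OLS fit of a gridness series against the manipulated variable."""

    x: np.ndarray
    y: np.ndarray
    slope: float
    r_squared: float
    slope_sign: int
    p_value: float


@dataclass
class SeedTrends:
    """Per-seed trend fits plus the majority verdict across seeds."""

    per_seed: list[TrendResult]

    @property
    def majority_sign(self) -> int:
        signs = [t.slope_sign for t in self.per_seed]
        return int(np.sign(np.sum(signs)))

    @property
    def median_r_squared(self) -> float:
        return float(np.median([t.r_squared for t in self.per_seed]))


def trend_regression(x, y) -> TrendResult:
    """OLS slope, R^2 and two-sided p-value for slope != 0 (NaN pairs dropped)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise DegenerateRegressionError("need at least 3 finite points")
    if np.ptp(x) == 0:
        raise DegenerateRegressionError("x is constant")
    fit = stats.linregress(x, y)
    return TrendResult(x=x, y=y, slope=float(fit.slope),
                       r_squared=float(fit.rvalue ** 2),
                       slope_sign=int(np.sign(fit.slope)) if fit.slope != 0 else 0,
                       p_value=float(fit.pvalue))


# ---------------------------------------------------------------------------
# Scoring helpers
# ---------------------------------------------------------------------------

def _neuron_hgs_table(state: ModelState, q, w, bin_size, smoothing) -> np.ndarray:
    """Whole-arena HGS per LAHN neuron for frozen weights (NaN when undefined)."""
    resp = state.replay_responses(q, w)
    out = np.full(resp.shape[1], np.nan)
    for k in range(resp.shape[1]):
        rm = spatial_maps.rate_map(state.trajectory, resp[:, k], bin_size, smoothing)
        try:
            out[k] = spatial_maps.hgs(spatial_maps.autocorrelogram(rm))
        except Exception:
            out[k] = np.nan
    return out


def _grid_neurons(hgs_by_neuron: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k highest-HGS neurons (the run's grid cells)."""
    order = np.argsort(np.nan_to_num(hgs_by_neuron, nan=-np.inf))[::-1]
    return order[:k]


def _final_weights(state: ModelState):
    ck = state.checkpoints[-1]
    return ck.q, ck.w


# ---------------------------------------------------------------------------
# Connected-environment studies
# ---------------------------------------------------------------------------

@dataclass
class ConnectedShapesResult:
    pair: str
    local: SeedTrends
    global_: SeedTrends
    table: pd.DataFrame


def _connected_env(pair: str, spec: ExperimentSpec, d: float | None = None) -> Environment:
    a, b = pair.split("-")
    return geometry.make_connected(a, b, spec.room_size, spec.corridor_width,
                                   spec.distance_d if d is None else d)


def _trip_params(env: Environment, spec: ExperimentSpec) -> TrajectoryParams:
    """Foraging parameters with trips alternating between the two rooms.

    The route passes through the corridor midpoint so the goal bias steers
    toward the opening rather than into the dividing wall.
    """
    cx = env.meta["gap"] / 2 + env.meta["room_size"] / 2
    return replace(spec.traj,
                   goals=((-cx, 0.0), (0.0, 0.0), (cx, 0.0), (0.0, 0.0)),
                   goal_radius=min(env.meta["room_size"] / 4,
                                   env.meta["corridor_width"] / 2))


def run_connected_shapes(pair: str, spec: ExperimentSpec) -> ConnectedShapesResult:
    """Local/global HGS of the best grid neuron across training checkpoints.

    For each seed the model is trained once; at every checkpoint the LAHN is
    replayed with the frozen snapshot weights over the full trajectory, and
    local/global HGS are computed for the neuron with the highest final
    whole-arena HGS. Trends are fitted against the checkpoint iteration.
    """
    if pair not in CONNECTED_PAIRS:
        raise ValueError(f"pair must be one of {CONNECTED_PAIRS}")
    env = _connected_env(pair, spec)
    rows = []
    local_fits, global_fits = [], []
    for seed in spec.seeds:
        state = train_model(env, spec.duration, spec.net, _trip_params(env, spec),
                            spec.checkpoints, seed=seed)
        qf, wf = _final_weights(state)
        best = int(_grid_neurons(_neuron_hgs_table(state, qf, wf, spec.bin_size,
                                                   spec.smoothing_sigma), 1)[0])
        xs, loc, glo = [], [], []
        for ck in state.checkpoints:
            resp = state.replay_responses(ck.q, ck.w)[:, best]
            try:
                l, g = spatial_maps.local_global_hgs(env, state.trajectory, resp,
                                                     spec.bin_size, spec.smoothing_sigma)
            except InsufficientSamplingError:
                l = g = np.nan
            xs.append(ck.iteration)
            loc.append(l)
            glo.append(g)
            rows.append({"pair": pair, "seed": seed, "iteration": ck.iteration,
                         "neuron": best, "hgs_local": l, "hgs_global": g})
        try:
            local_fits.append(trend_regression(xs, loc))
            global_fits.append(trend_regression(xs, glo))
        except DegenerateRegressionError:
            warnings.warn(f"{pair} seed {seed}: too few finite checkpoint scores; "
                          "seed excluded from the trend vote")
    return ConnectedShapesResult(pair=pair, local=SeedTrends(local_fits),
                                 global_=SeedTrends(global_fits),
                                 table=pd.DataFrame(rows))


@dataclass
class ConnectedDistanceResult:
    d_values: tuple[float, ...]
    local: SeedTrends
    global_: SeedTrends
    table: pd.DataFrame


def run_connected_distance(d_values, spec: ExperimentSpec) -> ConnectedDistanceResult:
    """Final local/global HGS vs distance between two square compartments."""
    d_values = tuple(d_values)
    if len(d_values) < 3:
        raise DegenerateRegressionError("need at least 3 distances for a trend")
    if any(np.diff(d_values) <= 0):
        raise ValueError("d_values must be increasing")
    rows = []
    per_seed_local, per_seed_global = [], []
    for seed in spec.seeds:
        loc, glo = [], []
        for d in d_values:
            env = _connected_env("square-square", spec, d=d)
            state = train_model(env, spec.duration, spec.net, _trip_params(env, spec),
                                2, seed=seed)
            qf, wf = _final_weights(state)
            best = int(_grid_neurons(_neuron_hgs_table(state, qf, wf, spec.bin_size,
                                                       spec.smoothing_sigma), 1)[0])
            resp = state.replay_responses(qf, wf)[:, best]
            try:
                l, g = spatial_maps.local_global_hgs(env, state.trajectory, resp,
                                                     spec.bin_size, spec.smoothing_sigma)
            except InsufficientSamplingError:
                l = g = np.nan
            loc.append(l)
            glo.append(g)
            rows.append({"seed": seed, "d": d, "neuron": best,
                         "hgs_local": l, "hgs_global": g})
        try:
            per_seed_local.append(trend_regression(d_values, loc))
            per_seed_global.append(trend_regression(d_values, glo))
        except DegenerateRegressionError:
            warnings.warn(f"distance study seed {seed}: too few finite scores; "
                          "seed excluded from the trend vote")
    return ConnectedDistanceResult(d_values=d_values, local=SeedTrends(per_seed_local),
                                   global_=SeedTrends(per_seed_global),
                                   table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Convex study (square vs trapezoid)
# ---------------------------------------------------------------------------

@dataclass
class ConvexResult:
    """Half-arena gridness and symmetry statistics for square and trapezoid."""

    table: pd.DataFrame               # one row per (shape, seed, neuron)
    summary: pd.DataFrame             # mean per shape over seeds and neurons

    def mean(self, shape: str, column: str) -> float:
        return float(self.summary.loc[shape, column])


def _half_autocorrelogram(state: ModelState, resp: np.ndarray, x_cut: float,
                          side: str, spec: ExperimentSpec):
    traj = state.trajectory
    sel = traj.x < x_cut if side == "left" else traj.x >= x_cut
    if sel.sum() < 100:
        return None
    sub = type(traj)(t=traj.t[sel], pos=traj.pos[sel], heading=traj.heading[sel],
                     speed=traj.speed[sel], dt=traj.dt)
    rm = spatial_maps.rate_map(sub, resp[sel], spec.bin_size, spec.smoothing_sigma)
    try:
        return spatial_maps.autocorrelogram(rm)
    except Exception:
        return None


def run_convex(spec: ExperimentSpec,
               square_side: float = 0.9,
               trapezoid=(0.2, 1.0, 1.9)) -> ConvexResult:
    """Square vs trapezoid: per-half HGS, half-map similarity, ellipticity.

    Both arenas are split by the vertical cut that divides them into equal
    areas. Scores are averaged over each run's grid neurons (the top quartile
    of LAHN neurons by whole-arena HGS).
    """
    arenas = {
        "square": geometry.make_square(square_side),
        "trapezoid": geometry.make_trapezoid(*trapezoid),
    }
    rows = []
    for shape, env in arenas.items():
        x_cut = geometry.equal_area_split_x(env)
        for seed in spec.seeds:
            state = train_model(env, spec.duration, spec.net, spec.traj, 2, seed=seed)
            qf, wf = _final_weights(state)
            hgs_all = _neuron_hgs_table(state, qf, wf, spec.bin_size, spec.smoothing_sigma)
            grid_idx = _grid_neurons(hgs_all, spec.n_grid_neurons())
            resp_all = state.replay_responses(qf, wf)
            for k in grid_idx:
                resp = resp_all[:, k]
                rm = spatial_maps.rate_map(state.trajectory, resp, spec.bin_size,
                                           spec.smoothing_sigma)
                try:
                    ell = spatial_maps.ellipticity(spatial_maps.autocorrelogram(rm))
                except Exception:
                    ell = np.nan
                try:
                    map_corr = spatial_maps.half_map_similarity(rm, "vertical",
                                                                split=x_cut)
                except Exception:
                    map_corr = np.nan
                ac_l = _half_autocorrelogram(state, resp, x_cut, "left", spec)
                ac_r = _half_autocorrelogram(state, resp, x_cut, "right", spec)
                hgs_l = spatial_maps.hgs(ac_l) if ac_l is not None else np.nan
                hgs_r = spatial_maps.hgs(ac_r) if ac_r is not None else np.nan
                # similarity of the halves' spatial structure: correlation of
                # their autocorrelograms (phase-free pattern comparison)
                try:
                    sim = spatial_maps.autocorr_similarity(ac_l, ac_r) \
                        if ac_l is not None and ac_r is not None else np.nan
                except Exception:
                    sim = np.nan
                rows.append({
                    "shape": shape, "seed": seed, "neuron": int(k),
                    "hgs_whole": hgs_all[k],
                    "hgs_left": hgs_l, "hgs_right": hgs_r,
                    "half_similarity": sim, "half_map_corr": map_corr,
                    "ellipticity": ell,
                })
    table = pd.DataFrame(rows)
    summary = table.groupby("shape")[["hgs_whole", "hgs_left", "hgs_right",
                                      "half_similarity", "ellipticity"]].mean()
    return ConvexResult(table=table, summary=summary)


# ---------------------------------------------------------------------------
# Concave and polygon studies
# ---------------------------------------------------------------------------

@dataclass
class LevelTrendResult:
    """Mean HGS per level of the manipulated factor plus trend statistics."""

    levels: tuple[float, ...]
    trend: SeedTrends
    table: pd.DataFrame
    anova_p: float

    def mean_by_level(self) -> pd.Series:
        return self.table.groupby("level")["hgs"].mean()


def _level_study(envs: dict[float, Environment], spec: ExperimentSpec) -> LevelTrendResult:
    # population-average HGS per run: averaging over all LAHN neurons avoids
    # the selection noise a top-k rule adds, which matters for the small
    # between-level effects these studies measure
    rows = []
    fits = []
    for seed in spec.seeds:
        ys = []
        for level, env in envs.items():
            state = train_model(env, spec.duration, spec.net, spec.traj, 2, seed=seed)
            qf, wf = _final_weights(state)
            hgs_all = _neuron_hgs_table(state, qf, wf, spec.bin_size, spec.smoothing_sigma)
            mean_hgs = float(np.nanmean(hgs_all))
            ys.append(mean_hgs)
            rows.append({"seed": seed, "level": level, "hgs": mean_hgs})
        fits.append(trend_regression(list(envs), ys))
    table = pd.DataFrame(rows)
    groups = [g["hgs"].dropna().to_numpy() for _, g in table.groupby("level")]
    anova_p = float(stats.f_oneway(*groups).pvalue) if all(len(g) > 1 for g in groups) else np.nan
    return LevelTrendResult(levels=tuple(envs), trend=SeedTrends(fits),
                            table=table, anova_p=anova_p)


def run_concave(kind: str, radii, spec: ExperimentSpec,
                r_outer: float = 2.2) -> LevelTrendResult:
    """Mean grid-neuron HGS vs inner radius of a concave arena."""
    radii = tuple(radii)
    if any(np.diff(radii) <= 0):
        raise ValueError("radii must be increasing")
    envs = {r: geometry.make_concave(kind, r_outer, r) for r in radii}
    return _level_study(envs, spec)


def run_polygon(n_range, spec: ExperimentSpec, radius: float = 1.0) -> LevelTrendResult:
    """Mean grid-neuron HGS vs number of sides of a regular polygon arena."""
    n_range = tuple(sorted(n_range))
    if any(n < 3 for n in n_range):
        raise ValueError("polygons need at least 3 sides")
    if len(n_range) < 3:
        raise DegenerateRegressionError("need at least 3 polygon sizes for a trend")
    envs = {float(n): geometry.make_polygon(int(n), radius) for n in n_range}
    return _level_study(envs, spec)


# ---------------------------------------------------------------------------
# Configuration decoder (transforming arena)
# ---------------------------------------------------------------------------

@dataclass
class MLPDecoder:
    """Single-hidden-layer backprop classifier over LAHN responses."""

    hidden_size: int = 20
    learning_rate: float = 0.01
    epochs: int = 600
    seed: int = 0
    test_fraction: float = 0.2
    n_blocks: int = 25
    model: object | None = None

    def build(self):
        # raw (unstandardized) inputs: the decoder sees the LAHN responses as
        # they are, so a weakly trained LAHN with small, unnormalized
        # responses genuinely yields a weaker decoder; the full epoch budget
        # is always used (no loss-plateau early stop)
        from sklearn.neural_network import MLPClassifier
        return MLPClassifier(hidden_layer_sizes=(self.hidden_size,),
                             activation="logistic",
                             learning_rate_init=self.learning_rate,
                             max_iter=self.epochs, random_state=self.seed,
                             tol=1e-6, n_iter_no_change=self.epochs)


def _block_split(n: int, labels: np.ndarray, test_fraction: float,
                 n_blocks: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Hold out contiguous time blocks (response streams are autocorrelated,
    so a sample-wise random split would leak near-duplicates into the test
    set). Redraws until both classes appear on both sides."""
    rng = np.random.default_rng(seed)
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    blocks = [np.arange(a, b) for a, b in zip(edges, edges[1:])]
    n_test = max(1, int(round(test_fraction * n_blocks)))
    for _ in range(100):
        order = rng.permutation(n_blocks)
        te = np.concatenate([blocks[i] for i in order[:n_test]])
        tr = np.concatenate([blocks[i] for i in order[n_test:]])
        if len(np.unique(labels[tr])) == 2 and len(np.unique(labels[te])) == 2:
            return tr, te
    raise DegenerateLabelsError("could not split blocks with both classes on both sides")


@dataclass
class DecoderReport:
    decoder: MLPDecoder
    accuracy: float
    mse_per_config: dict[int, float]


def train_decoder(responses: np.ndarray, labels: np.ndarray,
                  decoder: MLPDecoder | None = None) -> DecoderReport:
    """Train the configuration decoder and score it on a held-out split.

    ``accuracy`` is the fraction of held-out samples whose thresholded
    sigmoid output (0.5) matches the label; ``mse_per_config`` is the mean
    squared error of the network output against the 0/1 target, restricted to
    each configuration's held-out samples. The holdout is block-wise over
    contiguous time blocks (see ``_block_split``).
    """
    decoder = decoder or MLPDecoder()
    responses = np.asarray(responses, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise DegenerateLabelsError("both configurations must be present")
    tr, te = _block_split(len(labels), labels, decoder.test_fraction,
                          decoder.n_blocks, decoder.seed)
    Xtr, Xte, ytr, yte = responses[tr], responses[te], labels[tr], labels[te]
    model = decoder.build()
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")  # convergence warnings at fixed epoch budget
        model.fit(Xtr, ytr)
    pos = classes.max()
    proba = model.predict_proba(Xte)[:, list(model.classes_).index(pos)]
    pred = np.where(proba > 0.5, pos, classes.min())
    accuracy = float(np.mean(pred == yte))
    target = (yte == pos).astype(float)
    mse = {}
    for c in classes:
        sel = yte == c
        mse[int(c)] = float(np.mean((proba[sel] - target[sel]) ** 2))
    decoder.model = model
    return DecoderReport(decoder=decoder, accuracy=accuracy, mse_per_config=mse)


@dataclass
class TransformingResult:
    accuracy_trained: float
    accuracy_partial: float
    mse_trained: dict[int, float]
    mse_partial: dict[int, float]
    table: pd.DataFrame
    classification_map: np.ndarray | None = None   # mean decoder output per bin

    @property
    def accuracy_gap(self) -> float:
        return self.accuracy_trained - self.accuracy_partial


def _classification_map(pos: np.ndarray, proba: np.ndarray, length: float,
                        n_bins: int = 25) -> np.ndarray:
    """Mean decoder output (P(config 2)) per spatial bin over the session."""
    edges = np.linspace(0, length, n_bins + 1)
    counts, _, _ = np.histogram2d(pos[:, 1], pos[:, 0], bins=[edges, edges])
    sums, _, _ = np.histogram2d(pos[:, 1], pos[:, 0], bins=[edges, edges],
                                weights=proba)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)


def run_transforming(spec: ExperimentSpec, length: float = 5.0,
                     breadth_start: float = 2.0, decimate: int = 10,
                     partial_fraction: float = 0.1,
                     decoder: MLPDecoder | None = None) -> TransformingResult:
    """Decode the arena configuration (rectangle=1 vs square=2) from the LAHN.

    The arena transforms from a ``length x breadth_start`` rectangle to a
    ``length``-sided square while the model trains online. Two decoders are
    compared: the "trained LAHN" decoder reads the per-timestep responses
    recorded during the session as the LAHN converges (its response
    statistics reflect the learned representation), while the "partially
    learned LAHN" control reads responses replayed with the weight snapshot
    taken at ``partial_fraction`` of the steps to convergence — a fixed
    linear readout of the oscillator phase code, whose positional
    information is aliased at the grid period and therefore carries no
    arena-configuration signal. Responses are decimated to every
    ``decimate``-th sample before the block-wise decoder split.
    """
    rows = []
    accs_t, accs_p, mses_t, mses_p = [], [], [], []
    cmap = None
    for seed in spec.seeds:
        env = geometry.make_transforming(length, breadth_start, length, spec.duration,
                                         schedule="hold-ramp-hold")
        # at least 11 evenly spaced snapshots so the 10%-of-training
        # checkpoint exists exactly
        state = train_model(env, spec.duration, spec.net, spec.traj,
                            n_checkpoints=max(spec.checkpoints, 11), seed=seed)
        labels = np.array([env.config_label(t) for t in state.trajectory.t])
        n_conv = state.convergence_iter or len(state.trajectory)
        target_iter = partial_fraction * n_conv
        partial_ck = min(state.checkpoints, key=lambda c: abs(c.iteration - target_iter))

        sl = slice(None, None, decimate)
        resp_trained = state.response_log[sl]
        resp_partial = state.replay_responses(partial_ck.q, partial_ck.w)[sl]
        lab = labels[sl]
        dec = decoder or MLPDecoder(seed=seed)
        rep_t = train_decoder(resp_trained, lab, replace(dec, seed=seed))
        rep_p = train_decoder(resp_partial, lab, replace(dec, seed=seed))
        if seed == spec.seeds[0]:
            model = rep_t.decoder.model
            proba = model.predict_proba(resp_trained)[:, -1]
            cmap = _classification_map(state.trajectory.pos[sl], proba, length)
        accs_t.append(rep_t.accuracy)
        accs_p.append(rep_p.accuracy)
        mses_t.append(rep_t.mse_per_config)
        mses_p.append(rep_p.mse_per_config)
        rows.append({"seed": seed, "accuracy_trained": rep_t.accuracy,
                     "accuracy_partial": rep_p.accuracy,
                     "mse_trained_1": rep_t.mse_per_config[1],
                     "mse_trained_2": rep_t.mse_per_config[2],
                     "mse_partial_1": rep_p.mse_per_config[1],
                     "mse_partial_2": rep_p.mse_per_config[2],
                     "partial_iter": partial_ck.iteration})
    mse_t = {c: float(np.mean([m[c] for m in mses_t])) for c in (1, 2)}
    mse_p = {c: float(np.mean([m[c] for m in mses_p])) for c in (1, 2)}
    return TransformingResult(accuracy_trained=float(np.mean(accs_t)),
                              accuracy_partial=float(np.mean(accs_p)),
                              mse_trained=mse_t, mse_partial=mse_p,
                              table=pd.DataFrame(rows), classification_map=cmap)
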