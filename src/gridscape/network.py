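"""The three-stage oscillatory grid-cell network.

Stage 1 — head-direction (HD) layer: a Kohonen self-organizing map trained on
unit heading vectors ``psi = [cos(theta), sin(theta)]``; its response to a
heading is the sheet of dot products ``psi . w_k``, i.e. the cosine of the
angle between the heading and each neuron's preferred direction.

Stage 2 — oscillatory path integration: one Hopf-normal-form limit-cycle
oscillator per HD neuron, with instantaneous angular frequency

    omega_k(t) = Omega_PI + beta * s(t) * theta_HD_k(t)

so the phase of oscillator k integrates the component of the animal's motion
along the neuron's preferred direction scaled by the spatial gain ``beta``
(oscillatory-interference path integration). Relative oscillator phases
therefore encode position with spatial period ``2*pi / beta``.

Stage 3 — LAHN (lateral anti-Hebbian network): a single layer of ``n``
neurons with Hebbian (Oja-stabilized) afferent weights ``q`` and
anti-Hebbian lateral weights ``w`` (zero diagonal), driven by the
concatenated oscillator states. Its weights converge to the principal
subspace of the oscillator stream; individual neurons develop spatially
periodic (grid-like) responses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

from .errors import InvalidTrainingError
from .geometry import Environment, TransformingEnvironment
from .trajectory import Trajectory, TrajectoryParams, simulate_trajectory

TWO_PI = 2 * np.pi


# ---------------------------------------------------------------------------
# Head-direction SOM
# ---------------------------------------------------------------------------

@dataclass
class HDLayer:
    """Self-organized head-direction sheet with unit-norm weight vectors."""

    W: np.ndarray                     # (N, 2), rows unit norm
    grid_shape: tuple[int, int]
    trained: bool = False

    @property
    def n_neurons(self) -> int:
        return self.W.shape[0]

    @property
    def preferred_angles(self) -> np.ndarray:
        return np.mod(np.arctan2(self.W[:, 1], self.W[:, 0]), TWO_PI)

    def response(self, heading: float) -> np.ndarray:
        psi = np.array([np.cos(heading), np.sin(heading)])
        return self.W @ psi


def hd_response(hd: HDLayer, heading: float) -> np.ndarray:
    """Activation sheet ``psi^T W`` for a heading (cosine tuning curves)."""
    return hd.response(heading)


def train_hd_som(n_samples: int = 10_000, grid_shape: tuple[int, int] = (8, 8),
                 epochs: int = 1, seed: int = 0) -> HDLayer:
    """Fit a Kohonen SOM on unit vectors with uniformly random angles.

    The neighborhood is Gaussian on the sheet, shrinking from half the sheet
    width to below one neuron; the learning rate decays 0.5 -> 0.01. Weight
    vectors are re-normalized after every update so the layer's responses are
    exact cosine tuning curves.
    """
    if epochs <= 0:
        raise InvalidTrainingError("epochs must be positive")
    rows, cols = grid_shape
    n = rows * cols
    if n < 4:
        raise InvalidTrainingError("grid_shape product must be >= 4")
    rng = np.random.default_rng(seed)
    # initialize on the circle with small angular jitter to break symmetry
    init_ang = rng.uniform(0, TWO_PI, n)
    W = np.column_stack([np.cos(init_ang), np.sin(init_ang)])
    ii, jj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)

    total = n_samples * epochs
    sigma0, sigma1 = max(rows, cols) / 2.0, 0.2
    lr0, lr1 = 0.5, 0.005
    thetas = rng.uniform(0, TWO_PI, total)
    for step, theta in enumerate(thetas):
        frac = step / max(total - 1, 1)
        sigma = sigma0 * (sigma1 / sigma0) ** frac
        lr = lr0 * (lr1 / lr0) ** frac
        psi = np.array([np.cos(theta), np.sin(theta)])
        winner = int(np.argmax(W @ psi))
        d2 = np.sum((coords - coords[winner]) ** 2, axis=1)
        h = np.exp(-d2 / (2 * sigma ** 2))
        W += lr * h[:, None] * (psi[None, :] - W)
        W /= np.linalg.norm(W, axis=1, keepdims=True)
    return HDLayer(W=W, grid_shape=grid_shape, trained=True)


# ---------------------------------------------------------------------------
# Oscillatory path-integration layer
# ---------------------------------------------------------------------------

@dataclass
class OscillatorArray:
    """Hopf limit-cycle oscillators, one per HD neuron.

    State ``(chi_u, chi_v)`` relaxes to the circle of radius ``sqrt(mu)`` and
    rotates at ``Omega_PI + beta * s * theta_HD`` rad/s. The per-step update
    is exact for piecewise-constant input: the phase is rotated by
    ``omega * dt`` and the squared radius follows the closed-form logistic
    solution of ``dr/dt = r (mu - r^2)``. This keeps the limit-cycle radius
    and the phase/displacement relation exact at any dt.
    """

    chi_u: np.ndarray
    chi_v: np.ndarray
    omega_pi: float = 12 * np.pi     # rad/s
    mu: float = 1.0
    beta: float = 50.0               # rad per arena unit (spatial gain)

    @classmethod
    def init(cls, n: int, omega_pi: float = 12 * np.pi, mu: float = 1.0,
             beta: float = 50.0, phase0: float = 0.0) -> "OscillatorArray":
        r0 = np.sqrt(mu)
        return cls(chi_u=np.full(n, r0 * np.cos(phase0)),
                   chi_v=np.full(n, r0 * np.sin(phase0)),
                   omega_pi=omega_pi, mu=mu, beta=beta)

    @property
    def state(self) -> np.ndarray:
        """Concatenated state [chi_u, chi_v]."""
        return np.concatenate([self.chi_u, self.chi_v])

    @property
    def lahn_input(self) -> np.ndarray:
        """State scaled by 1/sqrt(2N): unit total variance on the limit cycle.

        Without this normalization the LAHN response variance grows with the
        oscillator count and the printed learning rates overshoot the
        anti-Hebbian decorrelation equilibrium (the lateral recurrence
        diverges); scaling the input keeps the learning rates meaningful for
        any layer size.
        """
        s = self.state
        return s / np.sqrt(s.size / 2)

    def step(self, hd_act: np.ndarray, s: float, dt: float) -> None:
        omega = self.omega_pi + self.beta * s * hd_act
        ang = omega * dt
        c, sn = np.cos(ang), np.sin(ang)
        u, v = self.chi_u, self.chi_v
        un = u * c - v * sn
        vn = u * sn + v * c
        r2 = un * un + vn * vn
        mu = self.mu
        # closed-form radial relaxation of dr2/dt = 2 r2 (mu - r2)
        e = np.exp(2 * mu * dt)
        r2_new = mu * r2 * e / (mu + r2 * (e - 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.sqrt(np.where(r2 > 0, r2_new / np.where(r2 > 0, r2, 1.0), 0.0))
        self.chi_u = un * scale
        self.chi_v = vn * scale
        if not (np.all(np.isfinite(self.chi_u)) and np.all(np.isfinite(self.chi_v))):
            raise OverflowError("oscillator state became non-finite (dt too large)")


def step_oscillators(osc: OscillatorArray, hd_act: np.ndarray, s: float,
                     dt: float) -> OscillatorArray:
    """One integration step; returns the (mutated) array for chaining."""
    if hd_act.shape != osc.chi_u.shape:
        raise ValueError("HD activation shape does not match oscillator array")
    osc.step(hd_act, s, dt)
    return osc


# ---------------------------------------------------------------------------
# Lateral anti-Hebbian network
# ---------------------------------------------------------------------------

@dataclass
class LAHN:
    """Single-layer network with Hebbian afferent and anti-Hebbian lateral weights."""

    q: np.ndarray                    # (n, m) afferent
    w: np.ndarray                    # (n, n) lateral, zero diagonal
    eta_f: float = 0.01
    eta_l: float = 0.01

    @classmethod
    def init(cls, n: int = 20, m: int = 128, eta_f: float = 0.01,
             eta_l: float = 0.01, seed: int = 0, init_scale: float = 0.1) -> "LAHN":
        rng = np.random.default_rng(seed)
        q = rng.uniform(-init_scale, init_scale, (n, m))
        w = rng.uniform(-init_scale, init_scale, (n, n))
        np.fill_diagonal(w, 0.0)
        return cls(q=q, w=w, eta_f=eta_f, eta_l=eta_l)

    @property
    def n(self) -> int:
        return self.q.shape[0]

    @property
    def m(self) -> int:
        return self.q.shape[1]

    def response(self, chi: np.ndarray, xi_prev: np.ndarray) -> np.ndarray:
        if chi.shape[0] != self.m:
            raise ValueError(f"input length {chi.shape[0]} != m={self.m}")
        return self.q @ chi + self.w @ xi_prev

    def update(self, chi: np.ndarray, xi_t: np.ndarray, xi_prev: np.ndarray) -> float:
        """Apply one plasticity step; returns mean |Delta q| (convergence monitor)."""
        dq = self.eta_f * (np.outer(xi_t, chi) - self.q * (xi_t ** 2)[:, None])
        dw = -self.eta_l * np.outer(xi_t, xi_prev)
        self.q += dq
        self.w += dw
        np.fill_diagonal(self.w, 0.0)
        return float(np.mean(np.abs(dq)))


def lahn_response(lahn: LAHN, chi: np.ndarray,
                  xi_prev: np.ndarray | None = None) -> np.ndarray:
    """Response ``xi = q chi + w xi(t-1)`` (one-step lateral recurrence)."""
    if xi_prev is None:
        xi_prev = np.zeros(lahn.n)
    return lahn.response(chi, xi_prev)


def lahn_update(lahn: LAHN, chi: np.ndarray, xi_t: np.ndarray,
                xi_prev: np.ndarray) -> LAHN:
    lahn.update(chi, xi_t, xi_prev)
    return lahn


# ---------------------------------------------------------------------------
# Full-model training
# ---------------------------------------------------------------------------

@dataclass
class NetParams:
    """Network hyper-parameters (defaults are the model's standard values)."""

    hd_shape: tuple[int, int] = (8, 8)
    som_samples: int = 10_000
    omega_pi: float = 12 * np.pi
    mu: float = 1.0
    beta: float = 50.0
    n_lahn: int = 20
    eta_f: float = 0.01
    eta_l: float = 0.01
    init_scale: float = 0.1
    convergence_tol: float = 1e-5
    convergence_window: int = 1000


@dataclass
class Checkpoint:
    iteration: int
    q: np.ndarray
    w: np.ndarray


@dataclass
class ModelState:
    """Everything produced by one training run."""

    hd: HDLayer
    osc: OscillatorArray
    lahn: LAHN
    trajectory: Trajectory
    response_log: np.ndarray          # (N, n) online LAHN responses
    osc_log: np.ndarray               # (N, 2*N_hd) oscillator states, float32
    checkpoints: list[Checkpoint] = field(default_factory=list)
    convergence_iter: int | None = None

    @property
    def checkpoint_iters(self) -> list[int]:
        return [c.iteration for c in self.checkpoints]

    def replay_responses(self, q: np.ndarray, w: np.ndarray,
                         mode: str = "equilibrium") -> np.ndarray:
        """LAHN responses over the whole run with frozen weights (q, w).

        ``mode="equilibrium"`` (default) evaluates the fixed point of the
        lateral recurrence, ``xi = (I - w)^-1 q chi``; online learning holds
        the lateral spectral radius at the edge of stability, so iterating
        the one-step recurrence with frozen weights over long streams is
        numerically divergent, whereas its fixed point is well defined.
        ``mode="recurrence"`` iterates the literal one-step recurrence.
        """
        if mode == "equilibrium":
            return equilibrium_responses(self.osc_log, q, w)
        return replay_lahn(self.osc_log, q, w)


def equilibrium_responses(osc_log: np.ndarray, q: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Fixed-point LAHN responses ``xi = (I - w)^-1 q chi`` for a stored stream."""
    A = np.linalg.solve(np.eye(w.shape[0]) - w, q)
    return osc_log.astype(np.float64) @ A.T


def replay_lahn(osc_log: np.ndarray, q: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Run the LAHN one-step recurrence over a stored stream without plasticity."""
    drive = osc_log.astype(np.float64) @ q.T          # (N, n)
    n_steps = drive.shape[0]
    xi = np.zeros(q.shape[0])
    out = np.empty_like(drive)
    for t in range(n_steps):
        xi = drive[t] + w @ xi
        out[t] = xi
    return out


def train_model(env: Environment | TransformingEnvironment, duration: float,
                net_params: NetParams | None = None,
                traj_params: TrajectoryParams | None = None,
                n_checkpoints: int = 5, seed: int = 0,
                trajectory: Trajectory | None = None) -> ModelState:
    """Simulate foraging and train the network online along the trajectory.

    Per time step: the heading drives the HD sheet, the HD activations and the
    per-step displacement drive the oscillators, the concatenated oscillator
    state drives the LAHN, and the LAHN plasticity is applied online. LAHN
    weights are snapshotted at ``n_checkpoints`` evenly spaced iterations
    (including the final step). Convergence is declared at the first window
    where the mean |Delta q| drops below ``convergence_tol``.

    ``seed`` fans out to trajectory, SOM and LAHN initialization; two runs
    with the same seeds produce identical logs.
    """
    from dataclasses import replace as _replace

    np_ = net_params or NetParams()
    tp = traj_params or TrajectoryParams()
    if trajectory is None:
        tp_run = _replace(tp, seed=tp.seed if tp.seed else seed)
        trajectory = simulate_trajectory(env, duration, tp_run)
    traj = trajectory
    n_steps = len(traj)
    dt = traj.dt

    hd = train_hd_som(n_samples=np_.som_samples, grid_shape=np_.hd_shape,
                      seed=seed + 1)
    n_hd = hd.n_neurons
    osc = OscillatorArray.init(n_hd, omega_pi=np_.omega_pi, mu=np_.mu, beta=np_.beta)
    lahn = LAHN.init(n=np_.n_lahn, m=2 * n_hd, eta_f=np_.eta_f, eta_l=np_.eta_l,
                     seed=seed + 2, init_scale=np_.init_scale)

    ck_iters = np.unique(np.linspace(0, n_steps - 1, n_checkpoints).astype(int))
    ck_set = set(int(i) for i in ck_iters)
    checkpoints: list[Checkpoint] = []

    # The oscillators start on the limit cycle and the exact radial update
    # keeps them there, so the whole oscillator stream reduces to cumulative
    # phases and can be integrated in one vectorized pass.
    psi_all = np.column_stack([np.cos(traj.heading), np.sin(traj.heading)])
    hd_acts = psi_all @ hd.W.T                                   # (N, N_hd)
    omega = np_.omega_pi + np_.beta * traj.speed[:, None] * hd_acts
    phases = np.cumsum(omega * dt, axis=0)
    # osc_log stores the normalized LAHN input (state / sqrt(N_hd)), see
    # OscillatorArray.lahn_input
    r0 = np.sqrt(np_.mu) / np.sqrt(n_hd)
    osc_log = np.empty((n_steps, 2 * n_hd), dtype=np.float32)
    osc_log[:, :n_hd] = r0 * np.cos(phases)
    osc_log[:, n_hd:] = r0 * np.sin(phases)
    osc.chi_u = osc_log[-1, :n_hd].astype(np.float64) * np.sqrt(n_hd)
    osc.chi_v = osc_log[-1, n_hd:].astype(np.float64) * np.sqrt(n_hd)

    response_log = np.empty((n_steps, lahn.n), dtype=np.float64)
    xi_prev = np.zeros(lahn.n)

    dq_window: list[float] = []
    convergence_iter = None
    win = np_.convergence_window

    for t in range(n_steps):
        chi = osc_log[t].astype(np.float64)
        xi = lahn.response(chi, xi_prev)
        mean_dq = lahn.update(chi, xi, xi_prev)
        xi_prev = xi
        response_log[t] = xi
        dq_window.append(mean_dq)
        if len(dq_window) >= win:
            if convergence_iter is None and np.mean(dq_window) < np_.convergence_tol:
                convergence_iter = t
            dq_window.clear()
        if t and t % 10_000 == 0:
            logger.info("iter %d mean|dq| %.3e response rms %.3f",
                        t, mean_dq, float(np.sqrt(np.mean(xi ** 2))))
        if t in ck_set:
            checkpoints.append(Checkpoint(t, lahn.q.copy(), lahn.w.copy()))

    return ModelState(hd=hd, osc=osc, lahn=lahn, trajectory=traj,
                      response_log=response_log, osc_log=osc_log,
                      checkpoints=checkpoints, convergence_iter=convergence_iter)
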