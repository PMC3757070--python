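"""Spiking sparse-coding network with local plasticity and rate homeostasis.

The network (SAILnet) is a population of leaky integrate-and-fire units
driven feed-forward by whitened image pixels and coupled by learned
recurrent inhibition.  After each image presentation three local rules
update the parameters, with learning rates ``alpha``, ``beta``, ``gamma``
and target firing rate ``p`` (spikes per image):

* inhibition:  dW_ij = alpha * (n_i n_j - p^2)   for i != j,
  rectified so W_ij >= 0 and W_ii = 0 (connections stay inhibitory);
* feed-forward: dQ_im = beta * n_i * (x_m - n_i Q_im);
* threshold homeostasis: dtheta_i = gamma * (n_i - p).

``n_i`` is the integer spike count of neuron i for the presented patch
``x``.  The inhibitory rule decorrelates the units, the threshold rule
drives every unit's long-run rate toward ``p``, and the feed-forward rule
makes the spike counts a linear generative model of the input; together
they produce localized, oriented receptive fields.

Two initialization regimes are provided.  ``init_sparse_regime`` starts
with high thresholds and strong (lognormal) inhibition, so early activity
is sparser than the learned equilibrium and measured sparseness falls
during training.  ``init_dense_regime`` starts with low thresholds and
weak inhibition, so sparseness rises.  The equilibrium itself is set by
(p, alpha, beta, gamma), not by the initial state.
"""

from __future__ import annotations

import dataclasses

import h5py
import numpy as np
import pandas as pd

from . import sparseness as sp
from .synthimg import PatchSampler

__all__ = [
    "SailnetState",
    "LifDynamicsConfig",
    "lif_inference",
    "update_parameters",
    "init_sparse_regime",
    "init_dense_regime",
    "train",
    "save_state",
    "load_state",
]


@dataclasses.dataclass
class LifDynamicsConfig:
    """Discrete-time integrate-and-fire settings for one image presentation.

    ``n_steps`` integration steps are run per image; each step the
    membrane potential relaxes toward the net input with gain ``eta``
    (u <- (1-eta) u + eta * (drive - inhibition)), a spike is emitted
    whenever u crosses the unit's threshold, and the potential resets to
    zero.  Inhibition acts with a one-step delay.
    """

    n_steps: int = 50
    eta: float = 0.1
    reset: str = "zero"

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not (0.0 < self.eta <= 1.0):
            raise ValueError("eta must lie in (0, 1]")
        if self.reset != "zero":
            raise ValueError("only reset-to-zero is implemented")


@dataclasses.dataclass
class SailnetState:
    """Parameters of the spiking network.

    Q : (n_neurons, n_pixels) feed-forward weights (rows are receptive
        fields); W : (n_neurons, n_neurons) non-negative inhibitory
        weights with zero diagonal; theta : per-neuron firing thresholds;
    p : target spikes per neuron per image; alpha, beta, gamma : learning
        rates of W, Q and theta respectively.
    """

    Q: np.ndarray
    W: np.ndarray
    theta: np.ndarray
    p: float
    alpha: float
    beta: float
    gamma: float
    n_neurons: int
    patch_edge: int

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        n, pix = self.Q.shape
        if n != self.n_neurons or pix != self.patch_edge**2:
            raise ValueError("Q shape inconsistent with n_neurons / patch_edge")
        if self.W.shape != (n, n) or self.theta.shape != (n,):
            raise ValueError("W / theta shapes inconsistent")
        self.validate()

    def validate(self) -> None:
        if np.any(np.diag(self.W) != 0):
            raise ValueError("W must have zero diagonal")
        if np.any(self.W < 0):
            raise ValueError("W must be non-negative")
        if np.any(self.theta <= 0):
            raise ValueError("thresholds must be positive")

    def receptive_fields(self) -> np.ndarray:
        """Rows of Q reshaped to (n_neurons, edge, edge)."""
        return self.Q.reshape(self.n_neurons, self.patch_edge, self.patch_edge)


def _flatten_patches(patches: np.ndarray, n_pixels: int) -> np.ndarray:
    x = np.asarray(patches, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    elif x.ndim == 2 and x.shape != (1, n_pixels):
        if x.size == n_pixels and x.shape[0] == x.shape[1]:
            x = x.reshape(1, n_pixels)  # a single 2D patch
        # else: already (batch, n_pixels)
    elif x.ndim == 3:
        x = x.reshape(x.shape[0], -1)
    if x.ndim != 2 or x.shape[1] != n_pixels:
        raise ValueError("patch size does not match Q's pixel dimension")
    return x


def lif_inference(
    state: SailnetState, patches: np.ndarray, cfg: LifDynamicsConfig | None = None
) -> np.ndarray:
    """Integer spike counts in response to one patch or a batch.

    The feed-forward drive ``Q @ x`` is held constant over the
    presentation while membrane potentials follow the leaky dynamics of
    :class:`LifDynamicsConfig`; spikes of the previous step inhibit
    through ``W``.  Simultaneous threshold crossings all spike.

    Returns an int array of shape (n_neurons,) for a single patch or
    (batch, n_neurons) for a batch.
    """
    if cfg is None:
        cfg = LifDynamicsConfig()
    x = np.asarray(patches, dtype=float)
    single = x.ndim == 1 or (x.ndim == 2 and x.shape == (state.patch_edge,) * 2)
    xf = _flatten_patches(x, state.Q.shape[1])
    drive = xf @ state.Q.T  # (batch, n_neurons)
    b = drive.shape[0]
    u = np.zeros_like(drive)
    y_prev = np.zeros_like(drive)
    counts = np.zeros((b, state.n_neurons), dtype=np.int64)
    eta = cfg.eta
    for _ in range(cfg.n_steps):
        u = (1.0 - eta) * u + eta * (drive - y_prev @ state.W.T)
        spike = u > state.theta
        counts += spike
        u = np.where(spike, 0.0, u)
        y_prev = spike.astype(float)
    return counts[0] if single else counts


def update_parameters(
    state: SailnetState, patches: np.ndarray, counts: np.ndarray
) -> SailnetState:
    """Apply the three plasticity rules after a presentation.

    ``counts`` must come from :func:`lif_inference` on the same patches.
    For a batch the updates are averaged over its patches before being
    applied, which is the standard batched form of the per-image rules.
    The recurrent weights are rectified to stay non-negative with zero
    diagonal.  Returns a new state; the input is untouched.
    """
    xf = _flatten_patches(patches, state.Q.shape[1])
    n = np.atleast_2d(np.asarray(counts, dtype=float))
    if n.shape[0] != xf.shape[0] or n.shape[1] != state.n_neurons:
        raise ValueError("counts shape inconsistent with patches / network")
    b = xf.shape[0]

    corr = n.T @ n / b  # <n_i n_j>
    new_w = state.W + state.alpha * (corr - state.p**2)
    np.fill_diagonal(new_w, 0.0)
    np.clip(new_w, 0.0, None, out=new_w)

    nx = n.T @ xf / b  # <n_i x_m>
    nsq = (n**2).mean(axis=0)  # <n_i^2>
    new_q = state.Q + state.beta * (nx - nsq[:, None] * state.Q)

    new_theta = state.theta + state.gamma * (n.mean(axis=0) - state.p)

    return dataclasses.replace(state, Q=new_q, W=new_w, theta=new_theta)


_DEFAULT_RATES = dict(p=0.05, alpha=0.3, beta=0.05, gamma=0.3)


def _init_q(n_neurons: int, n_pixels: int, rng: np.random.Generator, row_l1: float | None):
    q = rng.standard_normal((n_neurons, n_pixels))
    if row_l1 is None:
        # unit drive variance against unit-variance patches (row L2 norm 1),
        # which for Gaussian rows is an L1 norm of sqrt(2 P / pi)
        row_l1 = float(np.sqrt(2.0 * n_pixels / np.pi))
    q *= row_l1 / np.abs(q).sum(axis=1, keepdims=True)
    return q


def init_sparse_regime(
    n_neurons: int,
    patch_edge: int,
    seed: int,
    theta_range: tuple[float, float] = (2.0, 8.0),
    q_row_l1: float | None = None,
    **rates,
) -> SailnetState:
    """Initial state with high thresholds and strong lognormal inhibition.

    Off-diagonal W_ij = exp(-z) with z ~ N(0, 1); thresholds uniform on
    ``theta_range``.  Early activity is sparser than the learned
    equilibrium, so sparseness decreases during training.
    """
    if n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    params = {**_DEFAULT_RATES, **rates}
    rng = np.random.default_rng(seed)
    q = _init_q(n_neurons, patch_edge**2, rng, q_row_l1)
    w = np.exp(-rng.standard_normal((n_neurons, n_neurons)))
    np.fill_diagonal(w, 0.0)
    theta = rng.uniform(*theta_range, size=n_neurons)
    return SailnetState(
        Q=q, W=w, theta=theta, n_neurons=n_neurons, patch_edge=patch_edge, **params
    )


def init_dense_regime(
    n_neurons: int,
    patch_edge: int,
    seed: int,
    theta0: float = 0.5,
    q_row_l1: float | None = None,
    **rates,
) -> SailnetState:
    """Initial state with low thresholds and weak inhibition.

    Off-diagonal W_ij = max(0, z) with z ~ N(0, 1) (rectified to respect
    the inhibitory sign constraint); thresholds all equal ``theta0``.
    Early activity is denser than the learned equilibrium, so sparseness
    increases during training.
    """
    if n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    params = {**_DEFAULT_RATES, **rates}
    rng = np.random.default_rng(seed)
    q = _init_q(n_neurons, patch_edge**2, rng, q_row_l1)
    w = np.clip(rng.standard_normal((n_neurons, n_neurons)), 0.0, None)
    np.fill_diagonal(w, 0.0)
    theta = np.full(n_neurons, float(theta0))
    return SailnetState(
        Q=q, W=w, theta=theta, n_neurons=n_neurons, patch_edge=patch_edge, **params
    )


@dataclasses.dataclass
class MetricsConfig:
    """Settings for the frozen-network sparseness measurements."""

    measure_size: int = 1000  # stimuli in the held-out measurement batch
    group_size: int = 8
    mu_threshold: float = 4.0  # spikes; activity-sparseness threshold, multi-unit
    su_threshold: float = 0.0  # any spike counts as active, single-unit
    grouping_seed: int = 0


def _measure(state, meas_x, cfg, lif_cfg, groups):
    counts = lif_inference(state, meas_x, lif_cfg)
    act = counts.T.astype(float)  # units x stimuli
    mu = sp.make_multiunit(act, groups=groups)
    return dict(
        SA_mu=sp.activity_sparseness(mu, cfg.mu_threshold),
        SP_mu=sp.tr_population_sparseness(mu),
        SL_mu=sp.tr_lifetime_sparseness(mu),
        SA_su=sp.activity_sparseness(act, cfg.su_threshold),
        SP_su=sp.tr_population_sparseness(act),
        SL_su=sp.tr_lifetime_sparseness(act),
        mean_rate=float(act.mean()),
    )


def train(
    state: SailnetState,
    patch_source: PatchSampler,
    n_batches: int,
    batch_size: int = 100,
    measure_every: int | None = None,
    checkpoints: list[int] | None = None,
    lif_cfg: LifDynamicsConfig | None = None,
    metrics_cfg: MetricsConfig | None = None,
    debug_checks: bool = False,
) -> tuple[SailnetState, pd.DataFrame]:
    """Train the network and record a sparseness trajectory.

    Alternates :func:`lif_inference` and :func:`update_parameters` over
    batches from ``patch_source``.  At each checkpoint (``measure_every``
    batches, or an explicit increasing ``checkpoints`` list of batch
    indices) the parameters are frozen and single- and multi-unit
    sparseness is measured on a fixed held-out batch; the multi-unit
    grouping is drawn once per run.  A checkpoint 0 measures the frozen
    initial condition before any update.

    Returns the final state and a DataFrame with columns
    (checkpoint, batch, SA_mu, SP_mu, SL_mu, SA_su, SP_su, SL_su,
    mean_rate).
    """
    if lif_cfg is None:
        lif_cfg = LifDynamicsConfig()
    if metrics_cfg is None:
        metrics_cfg = MetricsConfig()
    if checkpoints is None:
        if measure_every is None:
            raise ValueError("give measure_every or checkpoints")
        checkpoints = list(range(measure_every, n_batches + 1, measure_every))
    if any(b < 0 or b > n_batches for b in checkpoints) or sorted(checkpoints) != list(
        checkpoints
    ):
        raise ValueError("checkpoints must be increasing batch indices in [0, n_batches]")

    meas_x = patch_source.measurement_batch(metrics_cfg.measure_size).flat()
    groups = sp.multiunit_grouping(
        state.n_neurons, metrics_cfg.group_size, metrics_cfg.grouping_seed
    )

    rows = []
    ck = set(checkpoints)
    if 0 in ck:  # pre-training measurement of the initial condition
        m = _measure(state, meas_x, metrics_cfg, lif_cfg, groups)
        rows.append(dict(checkpoint=0, batch=0, **m))
    for batch_idx in range(1, n_batches + 1):
        xb = patch_source.batch(batch_size).flat()
        counts = lif_inference(state, xb, lif_cfg)
        state = update_parameters(state, xb, counts)
        if debug_checks:
            state.validate()
        if batch_idx in ck:
            m = _measure(state, meas_x, metrics_cfg, lif_cfg, groups)
            rows.append(dict(checkpoint=len(rows), batch=batch_idx, **m))
    return state, pd.DataFrame(rows)


def save_state(path, state: SailnetState) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("Q", data=state.Q)
        f.create_dataset("W", data=state.W)
        f.create_dataset("theta", data=state.theta)
        for k in ("p", "alpha", "beta", "gamma", "n_neurons", "patch_edge"):
            f.attrs[k] = getattr(state, k)


def load_state(path) -> SailnetState:
    with h5py.File(path, "r") as f:
        return SailnetState(
            Q=f["Q"][...],
            W=f["W"][...],
            theta=f["theta"][...],
            p=float(f.attrs["p"]),
            alpha=float(f.attrs["alpha"]),
            beta=float(f.attrs["beta"]),
            gamma=float(f.attrs["gamma"]),
            n_neurons=int(f.attrs["n_neurons"]),
            patch_edge=int(f.attrs["patch_edge"]),
        )
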