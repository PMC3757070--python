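"""Generative sparse-coding model with basis-magnitude homeostasis.

A linear generative model: an image patch ``x`` (flattened, P pixels) is
represented by coefficients ``a`` over a basis matrix ``A`` (P x M).
Inference minimizes

    E(a) = ||x - A a||^2 + lambda * sum_u log(1 + (a_u / sigma)^2),

the classic smooth sparse penalty.  Learning takes a gradient step of the
reconstruction error on ``A``, and a slow homeostatic controller rescales
each basis column so the running variance of its coefficient stays near a
set point (``var_target``).

The interplay between this gain homeostasis and the basis-norm
initialization is the point of the module: coefficients scale inversely
with basis magnitude, so large-norm bases produce small, weakly-penalized
(hence dense) coefficients and small-norm bases produce large, strongly
penalized (hence sparse) ones.  The homeostat drags the norms toward a
single equilibrium from either side, so population sparseness increases
during training when the bases start large and decreases when they start
small, while both runs converge to the same mean basis amplitude.
"""

from __future__ import annotations

import dataclasses

import h5py
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import sparseness as sp
from .synthimg import PatchSampler

__all__ = [
    "SparsenetState",
    "CoefficientResult",
    "infer_coefficients",
    "update_basis",
    "gain_adapt",
    "train_sparsenet",
    "mean_l1_norm",
    "norm_plateaued",
    "save_state",
    "load_state",
]

# Operating-point defaults.  The coefficient-variance set point scales
# inversely with the pixel count so the represented power
# M * var_target * ||A_u||^2 tracks the patch power n_pix * v_x with
# basis amplitudes of order one per pixel; the coefficient 0.48 places
# the joint learning/homeostasis equilibrium at a mean absolute basis
# weight of ~0.5 for any patch size (see docs/methods.md).  sigma tracks
# the coefficient scale, and lambda sets the sparseness of the
# equilibrium code.
DEFAULT_VAR_TARGET_COEFF = 0.48
DEFAULT_LAMBDA = 0.5
DEFAULT_KAPPA = 0.02


def default_var_target(patch_edge: int) -> float:
    return DEFAULT_VAR_TARGET_COEFF / patch_edge**2


@dataclasses.dataclass
class SparsenetState:
    """Basis matrix plus penalty and homeostasis parameters.

    A : (n_pixels, n_units) basis matrix, columns are the generative
        fields; lam : sparsity penalty weight; sigma : coefficient scale
        inside the penalty; var_target : per-unit coefficient-variance
        set point; var_est : running variance estimates; basis_lr :
        basis learning rate; kappa : homeostatic gain exponent per batch;
    ema : update weight of the running variance estimate.
    """

    A: np.ndarray
    lam: float
    sigma: float
    var_target: float
    var_est: np.ndarray
    basis_lr: float
    kappa: float = DEFAULT_KAPPA
    ema: float = 0.1
    patch_edge: int = 16

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.var_est = np.asarray(self.var_est, dtype=float)
        if self.A.ndim != 2:
            raise ValueError("A must be 2D (pixels x units)")
        if self.var_est.shape != (self.A.shape[1],):
            raise ValueError("var_est must have one entry per unit")
        if not np.isfinite(self.A).all():
            raise ValueError("A must be finite")
        if self.sigma <= 0 or self.var_target <= 0:
            raise ValueError("sigma and var_target must be positive")

    @property
    def n_units(self) -> int:
        return self.A.shape[1]

    def basis_fields(self) -> np.ndarray:
        """Columns of A reshaped to (n_units, edge, edge)."""
        return self.A.T.reshape(self.n_units, self.patch_edge, self.patch_edge)


@dataclasses.dataclass
class CoefficientResult:
    """Inferred coefficients with a convergence flag."""

    a: np.ndarray
    converged: bool


def _cost_and_grad(a_flat, A, X, lam, sigma):
    M, B = A.shape[1], X.shape[1]
    a = a_flat.reshape(M, B)
    r = X - A @ a
    u = a / sigma
    cost = float((r**2).sum() + lam * np.log1p(u**2).sum())
    grad = -2.0 * (A.T @ r) + lam * (2.0 * u / sigma) / (1.0 + u**2)
    return cost, grad.ravel()


def infer_coefficients(
    state: SparsenetState,
    patch: np.ndarray,
    tol: float = 1e-5,
    max_iter: int = 300,
    callback=None,
) -> CoefficientResult:
    """Minimize the penalized reconstruction cost for one patch or a batch.

    ``patch`` may be (P,), (edge, edge), or a batch (P, B); the problem
    is separable over the batch and solved jointly by L-BFGS from the
    projection warm start ``A.T @ x``.  The warm start matters: the
    log penalty is concave in |a|, so descent keeps the character of its
    starting point — small-norm bases start near zero and land in sparse
    minima, large-norm bases start with a large distributed projection
    and land in dense ones.  That is the mechanism tying basis magnitude
    to code sparseness.  Deterministic given its inputs.  The result is
    flagged unconverged when the iteration cap is hit before the
    projected-gradient tolerance.
    """
    X = np.asarray(patch, dtype=float)
    single = X.ndim == 1 or X.ndim == 2 and X.shape == (state.patch_edge,) * 2
    if X.ndim == 2 and X.shape == (state.patch_edge,) * 2:
        X = X.reshape(-1)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != state.A.shape[0]:
        raise ValueError("patch length does not match A's pixel dimension")
    a0 = state.A.T @ X
    res = minimize(
        _cost_and_grad,
        a0.ravel(),
        args=(state.A, X, state.lam, state.sigma),
        jac=True,
        method="L-BFGS-B",
        tol=None,
        options=dict(maxiter=max_iter, gtol=tol, ftol=1e-14),
        callback=callback,
    )
    a = res.x.reshape(state.A.shape[1], X.shape[1])
    converged = bool(res.success) or res.status == 0
    return CoefficientResult(a=a[:, 0] if single else a, converged=converged)


def update_basis(state: SparsenetState, patch: np.ndarray, a: np.ndarray) -> SparsenetState:
    """Gradient step of the reconstruction error on the basis.

    ``A += basis_lr * (x - A a) a^T`` (averaged over the batch when the
    inputs are batched).  Returns a new state.
    """
    X = np.asarray(patch, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    av = np.asarray(a, dtype=float)
    if av.ndim == 1:
        av = av[:, None]
    b = X.shape[1]
    resid = X - state.A @ av
    new_a = state.A + state.basis_lr * (resid @ av.T) / b
    return dataclasses.replace(state, A=new_a)


def gain_adapt(state: SparsenetState, activities: np.ndarray) -> SparsenetState:
    """Slow multiplicative gain control on the basis columns.

    The running coefficient variance ``var_est`` is updated by an
    exponential moving average of ``a^2``, then each column of ``A`` is
    scaled by ``(var_est / var_target) ** kappa``.  Units whose
    coefficients run hot (variance above the set point) grow their basis
    norm, which shrinks future coefficients — the negative feedback that
    pins the equilibrium.  With ``kappa == 0`` the homeostat is disabled.
    """
    av = np.atleast_2d(np.asarray(activities, dtype=float))
    if av.shape[0] != state.n_units:
        av = av.T
    if av.shape[0] != state.n_units:
        raise ValueError("activities shape inconsistent with number of units")
    var_now = (av**2).mean(axis=1)
    var_est = (1.0 - state.ema) * state.var_est + state.ema * var_now
    factors = (var_est / state.var_target) ** state.kappa
    return dataclasses.replace(state, A=state.A * factors[None, :], var_est=var_est)


def mean_l1_norm(A: np.ndarray) -> float:
    """Mean absolute basis element (column L1 norm / pixels, averaged over units)."""
    return float(np.abs(np.asarray(A)).mean())


def init_state(
    init_variance: float,
    n_units: int = 256,
    patch_edge: int = 16,
    seed: int = 0,
    lam: float = DEFAULT_LAMBDA,
    var_target: float | None = None,
    sigma: float | None = None,
    basis_lr: float | None = None,
    kappa: float = DEFAULT_KAPPA,
    ema: float = 0.1,
) -> SparsenetState:
    """Gaussian white-noise basis of the given element variance."""
    if init_variance <= 0:
        raise ValueError("init_variance must be positive")
    rng = np.random.default_rng(seed)
    A = rng.normal(0.0, np.sqrt(init_variance), size=(patch_edge**2, n_units))
    if var_target is None:
        var_target = default_var_target(patch_edge)
    if sigma is None:
        sigma = float(np.sqrt(var_target))
    if basis_lr is None:
        # effective per-batch relaxation rate basis_lr * var_target ~ 0.0075,
        # slow enough that the gain homeostat governs the norm dynamics
        basis_lr = 0.0075 / var_target
    return SparsenetState(
        A=A,
        lam=lam,
        sigma=sigma,
        var_target=var_target,
        var_est=np.full(n_units, var_target),
        basis_lr=basis_lr,
        kappa=kappa,
        ema=ema,
        patch_edge=patch_edge,
    )


def train_sparsenet(
    init_variance: float,
    n_units: int = 256,
    patch_edge: int = 16,
    n_iterations: int = 300,
    batch_size: int = 100,
    seed: int = 0,
    measure_every: int | None = None,
    measure_size: int = 200,
    sampler: PatchSampler | None = None,
    state: SparsenetState | None = None,
    until_plateau: bool = False,
    max_iterations: int | None = None,
    plateau_rel_tol: float = 0.01,
    **state_kwargs,
) -> tuple[SparsenetState, pd.DataFrame]:
    """Run batched inference / basis-update / gain-adaptation cycles.

    The basis starts as Gaussian white noise of ``init_variance`` (or
    continues from ``state``) and is trained on whitened naturalistic
    patches.  At checkpoints the population (S_P) and lifetime (S_L)
    Treves-Rolls sparseness of |a| on a held-out batch and the mean
    basis amplitude are recorded.

    With ``until_plateau=True`` training continues past ``n_iterations``
    (in 10% increments, up to ``max_iterations``) until the mean-norm
    trajectory changes by less than ``plateau_rel_tol`` over its final
    10% of iterations.

    Returns (final state, trajectory DataFrame with columns
    iteration, S_P, S_L, mean_l1_norm).
    """
    if sampler is None:
        sampler = PatchSampler(patch_edge, seed)
    if state is None:
        state = init_state(
            init_variance, n_units=n_units, patch_edge=patch_edge, seed=seed, **state_kwargs
        )
    if measure_every is None:
        measure_every = max(1, n_iterations // 40)
    meas_x = sampler.measurement_batch(measure_size).flat().T  # (P, B)

    rows: list[dict] = []

    def measure(it: int, st: SparsenetState) -> None:
        am = np.abs(infer_coefficients(st, meas_x).a)
        rows.append(
            dict(
                iteration=it,
                S_P=sp.tr_population_sparseness(am),
                S_L=sp.tr_lifetime_sparseness(am),
                mean_l1_norm=mean_l1_norm(st.A),
            )
        )

    def run_until(stop: int, start: int, st: SparsenetState) -> SparsenetState:
        for it in range(start, stop + 1):
            xb = sampler.batch(batch_size).flat().T
            a = infer_coefficients(st, xb).a
            st = update_basis(st, xb, a)
            st = gain_adapt(st, a)
            if it % measure_every == 0 or it == stop:
                measure(it, st)
        return st

    measure(0, state)  # the initial condition, before any update
    state = run_until(n_iterations, 1, state)
    total = n_iterations
    if until_plateau:
        if max_iterations is None:
            max_iterations = 4 * n_iterations
        while total < max_iterations and not norm_plateaued(
            pd.DataFrame(rows), rel_tol=plateau_rel_tol
        ):
            step = max(measure_every, n_iterations // 10)
            state = run_until(min(total + step, max_iterations), total + 1, state)
            total = min(total + step, max_iterations)
    return state, pd.DataFrame(rows)


def norm_plateaued(
    traj: pd.DataFrame, window_frac: float = 0.1, rel_tol: float = 0.01
) -> bool:
    """Has the mean-norm trajectory changed <``rel_tol`` over its last
    ``window_frac`` of iterations?"""
    if len(traj) < 3:
        return False
    it = traj["iteration"].to_numpy()
    norm = traj["mean_l1_norm"].to_numpy()
    cutoff = it[-1] * (1.0 - window_frac)
    tail = norm[it >= cutoff]
    if len(tail) < 3:  # guard against undersampled windows at coarse checkpoints
        tail = norm[-3:]
    spread = tail.max() - tail.min()
    return bool(spread <= rel_tol * abs(tail[-1]))


def save_state(path, state: SparsenetState) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("A", data=state.A)
        f.create_dataset("var_est", data=state.var_est)
        for k in ("lam", "sigma", "var_target", "basis_lr", "kappa", "ema", "patch_edge"):
            f.attrs[k] = getattr(state, k)


def load_state(path) -> SparsenetState:
    with h5py.File(path, "r") as f:
        return SparsenetState(
            A=f["A"][...],
            var_est=f["var_est"][...],
            lam=float(f.attrs["lam"]),
            sigma=float(f.attrs["sigma"]),
            var_target=float(f.attrs["var_target"]),
            basis_lr=float(f.attrs["basis_lr"]),
            kappa=float(f.attrs["kappa"]),
            ema=float(f.attrs["ema"]),
            patch_edge=int(f.attrs["patch_edge"]),
        )
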