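"""Reproducible pipelines for the developmental-sparseness experiments.

Four seeded experiments are orchestrated here:

* ``fig3`` — SAILnet from the sparse initialization regime (high
  thresholds, strong lognormal inhibition): multi-unit sparseness falls
  while receptive fields form;
* ``fig4`` — SAILnet from the dense regime (low thresholds, weak
  inhibition): the same network, same hyperparameters, but sparseness
  rises toward the same equilibrium;
* ``fig5a`` / ``fig5b`` — the generative model with basis-gain
  homeostasis initialized with large (variance 1) or small (variance
  0.01) white-noise bases: basis norms and sparseness move in opposite
  directions toward a common equilibrium;
* ``rfbench`` — registration-based comparison of trained model RFs
  against a target RF set.

Each run is fully determined by its config and seeds; trend directions
are summarized per metric by comparing the mean of the first two
checkpoints with the mean of the last two, with a majority vote across
seeds.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
import pandas as pd

from . import rfcompare, sailnet, sparsenet
from .sailnet import MetricsConfig
from .synthimg import PatchSampler

__all__ = [
    "ExperimentConfig",
    "TrendReport",
    "run_experiment",
    "trend_sign",
    "compare_final_states",
    "run_rf_benchmark",
    "log_spaced_checkpoints",
    "load_config",
]

SAILNET_EXPERIMENTS = ("fig3", "fig4")
SPARSENET_EXPERIMENTS = ("fig5a", "fig5b")
_FLAT_TOL = 1e-6


@dataclasses.dataclass
class ExperimentConfig:
    """Everything needed to rerun an experiment deterministically."""

    experiment: str
    seeds: tuple[int, ...] = (0, 1, 2)
    # spiking-network settings
    n_neurons: int = 100
    patch_edge: int = 8
    n_batches: int = 2500
    batch_size: int = 100
    sailnet_rates: dict = dataclasses.field(default_factory=dict)
    # generative-model settings
    n_units: int = 64
    sparsenet_patch_edge: int = 8
    n_iterations: int = 300
    sparsenet_kwargs: dict = dataclasses.field(default_factory=dict)
    # measurement settings
    n_checkpoints: int = 12
    measure_size: int = 1000
    group_size: int = 8
    mu_threshold: float = 4.0
    outdir: str | None = None

    def __post_init__(self) -> None:
        known = SAILNET_EXPERIMENTS + SPARSENET_EXPERIMENTS + ("rfbench",)
        if self.experiment not in known:
            raise ValueError(f"experiment must be one of {known}")
        if len(self.seeds) == 0:
            raise ValueError("seeds must be non-empty")

    def matched_hyperparameters(self) -> dict:
        """The fields that must agree for a regime comparison."""
        d = dataclasses.asdict(self)
        for k in ("experiment", "seeds", "outdir"):
            d.pop(k)
        return d


@dataclasses.dataclass
class TrendReport:
    """Per-seed trajectories with initial/final values and trend signs."""

    experiment: str
    seeds: tuple[int, ...]
    metrics: tuple[str, ...]
    trajectories: list[pd.DataFrame]
    initial: dict  # metric -> per-seed array (mean of first two checkpoints)
    final: dict  # metric -> per-seed array (mean of last two checkpoints)
    trend_per_seed: dict  # metric -> list of signs
    trend: dict  # metric -> majority sign
    config: ExperimentConfig
    final_states: list = dataclasses.field(default_factory=list)

    def summary(self) -> dict:
        return dict(
            experiment=self.experiment,
            seeds=list(self.seeds),
            trend={m: self.trend[m] for m in self.metrics},
            initial={m: list(map(float, self.initial[m])) for m in self.metrics},
            final={m: list(map(float, self.final[m])) for m in self.metrics},
        )


def log_spaced_checkpoints(n_batches: int, n_checkpoints: int) -> list[int]:
    """Log-spaced batch indices ending at ``n_batches``, prefixed with a
    batch-0 measurement of the initial condition (sparseness-versus-time
    is read on a log axis)."""
    pts = np.geomspace(1, n_batches, max(2, n_checkpoints - 1))
    return [0] + sorted(set(int(round(p)) for p in pts))


def trend_sign(values: np.ndarray, tol: float = _FLAT_TOL) -> str:
    """'increase', 'decrease' or 'flat' from first-two vs last-two checkpoints."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least two checkpoints")
    head = v[: min(2, len(v) - 1)].mean()
    tail = v[-2:].mean() if len(v) >= 4 else v[-1]
    diff = tail - head
    if diff > tol:
        return "increase"
    if diff < -tol:
        return "decrease"
    return "flat"


def _majority(signs: list[str]) -> str:
    counts = {s: signs.count(s) for s in set(signs)}
    return max(sorted(counts), key=counts.get)


def _build_report(cfg, metrics, trajectories, states) -> TrendReport:
    initial, final, per_seed, majority = {}, {}, {}, {}
    for m in metrics:
        heads, tails, signs = [], [], []
        for traj in trajectories:
            v = traj[m].to_numpy()
            heads.append(v[: min(2, len(v) - 1)].mean())
            tails.append(v[-2:].mean() if len(v) >= 4 else v[-1])
            signs.append(trend_sign(v))
        initial[m] = np.array(heads)
        final[m] = np.array(tails)
        per_seed[m] = signs
        majority[m] = _majority(signs)
    return TrendReport(
        experiment=cfg.experiment,
        seeds=tuple(cfg.seeds),
        metrics=tuple(metrics),
        trajectories=trajectories,
        initial=initial,
        final=final,
        trend_per_seed=per_seed,
        trend=majority,
        config=cfg,
        final_states=states,
    )


def run_experiment(cfg: ExperimentConfig) -> TrendReport:
    """Execute a configured pipeline and summarize trends.

    Spiking-network experiments train from the regime the experiment id
    names and track the multi-unit measures (SA_mu, SP_mu, SL_mu);
    generative-model experiments track S_P, S_L and the mean basis
    amplitude.  Results are written under ``cfg.outdir`` when set.
    """
    trajectories, states = [], []
    if cfg.experiment in SAILNET_EXPERIMENTS:
        metrics = ["SA_mu", "SP_mu", "SL_mu"]
        checkpoints = log_spaced_checkpoints(cfg.n_batches, cfg.n_checkpoints)
        init = (
            sailnet.init_sparse_regime
            if cfg.experiment == "fig3"
            else sailnet.init_dense_regime
        )
        mcfg = MetricsConfig(
            measure_size=cfg.measure_size,
            group_size=cfg.group_size,
            mu_threshold=cfg.mu_threshold,
        )
        for seed in cfg.seeds:
            sampler = PatchSampler(cfg.patch_edge, seed)
            state = init(cfg.n_neurons, cfg.patch_edge, seed, **cfg.sailnet_rates)
            state, traj = sailnet.train(
                state,
                sampler,
                cfg.n_batches,
                batch_size=cfg.batch_size,
                checkpoints=checkpoints,
                metrics_cfg=mcfg,
            )
            trajectories.append(traj)
            states.append(state)
    elif cfg.experiment in SPARSENET_EXPERIMENTS:
        metrics = ["S_P", "S_L", "mean_l1_norm"]
        init_variance = 1.0 if cfg.experiment == "fig5a" else 0.01
        for seed in cfg.seeds:
            state, traj = sparsenet.train_sparsenet(
                init_variance,
                n_units=cfg.n_units,
                patch_edge=cfg.sparsenet_patch_edge,
                n_iterations=cfg.n_iterations,
                batch_size=cfg.batch_size,
                seed=seed,
                **cfg.sparsenet_kwargs,
            )
            trajectories.append(traj)
            states.append(state)
    else:
        raise ValueError("rfbench is run through run_rf_benchmark")

    report = _build_report(cfg, metrics, trajectories, states)
    if cfg.outdir is not None:
        _write_report(report)
    return report


def _write_report(report: TrendReport) -> None:
    out = pathlib.Path(report.config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for seed, traj in zip(report.seeds, report.trajectories):
        traj.to_csv(out / f"trajectory_seed{seed}.csv", index=False)
    for seed, state in zip(report.seeds, report.final_states):
        path = out / f"state_seed{seed}.h5"
        if isinstance(state, sailnet.SailnetState):
            sailnet.save_state(path, state)
        else:
            sparsenet.save_state(path, state)
    with open(out / "trend_report.json", "w") as f:
        json.dump(report.summary(), f, indent=2)


def compare_final_states(
    report_a: TrendReport,
    report_b: TrendReport,
    rf_comparison: dict | None = None,
) -> dict:
    """Compare the converged states of two matched-hyperparameter runs.

    Reports the absolute differences of the seed-averaged final
    sparseness values.  With ``rf_comparison`` (keys: ``n_targets``,
    optional ``dict_size``, ``seed``, plus fit keyword arguments) the
    final receptive fields of regime A are fit both by regime A's other
    RFs (within-regime baseline) and by regime B's RFs (cross-regime),
    and the fraction of explainable variance captured across regimes is
    reported.
    """
    if report_a.config.matched_hyperparameters() != report_b.config.matched_hyperparameters():
        raise ValueError("hyperparameters of the two runs do not match")
    out = {}
    for m in report_a.metrics:
        fa = float(np.mean(report_a.final[m]))
        fb = float(np.mean(report_b.final[m]))
        out[f"final_{m}_a"] = fa
        out[f"final_{m}_b"] = fb
        out[f"abs_diff_{m}"] = abs(fa - fb)
    if rf_comparison is not None:
        rf_kwargs = dict(rf_comparison)
        n_targets = rf_kwargs.pop("n_targets", 12)
        dict_size = rf_kwargs.pop("dict_size", None)
        seed = rf_kwargs.pop("seed", 0)
        rfs_a = _final_rfs(report_a)
        rfs_b = _final_rfs(report_b)
        out.update(
            cross_regime_rf_summary(rfs_a, rfs_b, n_targets, dict_size, seed, **rf_kwargs)
        )
    return out


def _final_rfs(report: TrendReport) -> np.ndarray:
    state = report.final_states[0]
    if isinstance(state, sailnet.SailnetState):
        return state.receptive_fields()
    return state.basis_fields()


def cross_regime_rf_summary(
    rfs_a: np.ndarray,
    rfs_b: np.ndarray,
    n_targets: int = 12,
    dict_size: int | None = None,
    seed: int = 0,
    **fit_kwargs,
) -> dict:
    """Within-regime LOO baseline vs cross-regime best fits.

    Targets are a random subset of regime A's RFs.  The baseline fits
    each target with regime A's remaining RFs; the cross comparison fits
    the same targets with regime B's RFs.  If the two regimes learned
    the same shape dictionary the two mean R^2 values agree.
    """
    rng = np.random.default_rng(seed)
    rfs_a = np.asarray(rfs_a, dtype=float)
    rfs_b = np.asarray(rfs_b, dtype=float)
    t_idx = rng.choice(rfs_a.shape[0], size=min(n_targets, rfs_a.shape[0]), replace=False)

    within_vals, cross_vals = [], []
    for i in t_idx:
        target = rfs_a[i]
        others = np.delete(rfs_a, i, axis=0)
        if dict_size is not None and dict_size < others.shape[0]:
            sel = rng.choice(others.shape[0], size=dict_size, replace=False)
            others = others[sel]
        dict_b = rfs_b
        if dict_size is not None and dict_size < rfs_b.shape[0]:
            sel = rng.choice(rfs_b.shape[0], size=dict_size, replace=False)
            dict_b = rfs_b[sel]
        within_vals.append(
            rfcompare.best_fit_from_dictionary(target, others, **fit_kwargs).r_squared
        )
        cross_vals.append(
            rfcompare.best_fit_from_dictionary(target, dict_b, **fit_kwargs).r_squared
        )
    within = float(np.mean(within_vals))
    cross = float(np.mean(cross_vals))
    return dict(
        rf_within_regime_mean_r2=within,
        rf_cross_regime_mean_r2=cross,
        rf_abs_diff=abs(cross - within),
        rf_fraction_cross_over_within=cross / within if within > 0 else np.nan,
    )


def run_rf_benchmark(
    model: "sailnet.SailnetState | np.ndarray | str",
    targets: "np.ndarray | str",
    window: int | None = None,
    **fit_kwargs,
) -> dict:
    """Fit a target RF set with a trained model's RF dictionary.

    ``model`` may be a trained spiking-network state (its Q rows become
    the dictionary), an RF stack, or a path to either saved form;
    ``targets`` an RF stack or path.  Targets are standardized by
    cropping around their absolute peak to the dictionary's window.
    Returns the mean best-fit R^2, the targets' leave-one-out explainable
    variance, and their ratio (fraction of explainable variance).
    """
    from .synthimg import load_rf_stack

    if isinstance(model, (str, pathlib.Path)):
        try:
            model = sailnet.load_state(model).receptive_fields()
        except KeyError:
            model = load_rf_stack(model)
    if isinstance(model, sailnet.SailnetState):
        model = model.receptive_fields()
    model = np.asarray(model, dtype=float)
    if isinstance(targets, (str, pathlib.Path)):
        targets = load_rf_stack(targets)
    targets = np.asarray(targets, dtype=float)
    if targets.ndim != 3 or targets.shape[0] == 0:
        raise ValueError("target set must be a non-empty stack")
    if window is None:
        window = model.shape[1]
    std_targets = np.stack([rfcompare.standardize_rf(t, window) for t in targets])
    if model.shape[1] != window:
        model = np.stack([rfcompare.standardize_rf(m, window) for m in model])
    result = rfcompare.fraction_explained(model, std_targets, **fit_kwargs)
    return dict(
        mean_model_r2=result["mean_model"],
        sd_model_r2=result["sd_model"],
        mean_explainable_r2=result["mean_loo"],
        sd_explainable_r2=result["sd_loo"],
        fraction_explained=result["fraction"],
        model_fits=result["model_fits"],
        loo_fits=result["loo"].fits,
    )


# ---------------------------------------------------------------------------
# flat key = value config files

_LIST_KEYS = {"seeds"}
_DICT_KEYS = {"sailnet_rates", "sparsenet_kwargs"}


def load_config(path) -> ExperimentConfig:
    """Read an :class:`ExperimentConfig` from a flat ``key = value`` file.

    Values are parsed as JSON where possible (so ``seeds = [0, 1, 2]``
    and ``sailnet_rates = {"gamma": 0.1}`` work); lines starting with
    ``#`` are ignored.
    """
    kwargs = {}
    for line in pathlib.Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip()
        try:
            parsed = json.loads(value)
        except json.JSONDecodeError:
            parsed = value
        if key in _LIST_KEYS and isinstance(parsed, list):
            parsed = tuple(parsed)
        kwargs[key] = parsed
    return ExperimentConfig(**kwargs)
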