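# sparsedev

Does learning a sparse code require sparseness to increase during
development?  Developmental recordings show stimulus-evoked cortical
activity becoming *less* sparse as receptive fields mature, which has
been read as evidence against sparse coding.  `sparsedev` implements the
computational counter-argument: in sparse-coding models with slow
homeostasis, the mature code is set by the model's parameters, while the
initial condition can sit on either side of it — so sparseness can fall
or rise during receptive-field learning, and the mature network performs
sparse coding either way.

The package is aimed at computational neuroscientists who want to
simulate these dynamics, measure sparseness the way experimentalists do,
and compare receptive-field shapes nonparametrically.

## What's inside

* **`sparsedev.sailnet`** — a spiking sparse-coding network: leaky
  integrate-and-fire units with feed-forward weights `Q`, learned
  recurrent inhibition `W` and homeostatic thresholds `θ`, trained by
  three synaptically local rules
  (`ΔWᵢⱼ = α(nᵢnⱼ − p²)`, `ΔQᵢₘ = β nᵢ(xₘ − nᵢQᵢₘ)`,
  `Δθᵢ = γ(nᵢ − p)`), with a sparse-start and a dense-start
  initialization regime.
* **`sparsedev.sparseness`** — activity sparseness `S_A` and the
  Treves–Rolls population/lifetime measures `S_P`, `S_L` (Vinje–Gallant
  normalized), plus the multi-unit emulation (random groups of 8 units,
  summed counts, 4-spike threshold).
* **`sparsedev.sparsenet`** — a generative sparse-coding model
  minimizing `‖x − Aa‖² + λ Σ log(1 + (a/σ)²)` with basis-gain
  homeostasis; basis amplitude controls code sparseness, and amplitudes
  converge to a common equilibrium from large or small initializations.
* **`sparsedev.rfcompare`** — registration-based RF shape comparison:
  the best similarity transform (translation + rotation + isotropic
  scale) maximizing the squared pixel correlation R², exhaustive
  best-of-dictionary search, leave-one-out explainable variance, and
  fraction of explainable variance.
* **`sparsedev.synthimg`** — whitened 1/f² naturalistic images, patch
  extraction, and synthetic Gabor RF sets used as experimental-style
  targets.
* **`sparsedev.experiments`** — seeded end-to-end pipelines
  (`fig3`/`fig4` spiking regimes, `fig5a`/`fig5b` generative-model
  initializations, RF benchmark) with trend reports.

See `docs/methods.md` for the model details, parameter conventions and
limitations.

## Worked example

Train the spiking network from the two initialization regimes and watch
the multi-unit sparseness move in opposite directions toward the same
equilibrium:

```python
from sparsedev import experiments as ex

for exp in ("fig3", "fig4"):
    cfg = ex.ExperimentConfig(experiment=exp, seeds=(0, 1, 2),
                              n_neurons=100, patch_edge=8, n_batches=2500)
    report = ex.run_experiment(cfg)
    print(exp, report.trend,
          "S_P %.3f -> %.3f" % (report.initial["SP_mu"].mean(),
                                report.final["SP_mu"].mean()))
```

prints

```
fig3 {'SA_mu': 'decrease', 'SP_mu': 'decrease', 'SL_mu': 'decrease'} S_P 0.998 -> 0.879
fig4 {'SA_mu': 'increase', 'SP_mu': 'increase', 'SL_mu': 'increase'} S_P 0.568 -> 0.880
```

The sparse-start network (`fig3`) *loses* sparseness while learning its
receptive fields and the dense-start network (`fig4`) *gains* it, yet
both end at the same multi-unit population sparseness (≈ 0.88 — still a
sparse code) with the same target firing rate.  The same reversal holds
for the generative model:

```python
from sparsedev import sparsenet as spn

for init_var in (1.0, 0.01):
    state, traj = spn.train_sparsenet(init_var, n_units=64, patch_edge=8,
                                      n_iterations=250, seed=0)
    print(init_var, "amplitude %.2f -> %.2f   S_P %.2f -> %.2f" % (
        traj.mean_l1_norm.iloc[0], traj.mean_l1_norm.iloc[-1],
        traj.S_P.iloc[0], traj.S_P.iloc[-1]))
```

```
1.0 amplitude 0.80 -> 0.60   S_P 0.58 -> 0.73
0.01 amplitude 0.08 -> 0.54   S_P 0.91 -> 0.85
```

Large-amplitude bases shrink (and the code gets sparser); small ones
grow (and the code gets denser); both head for the gain homeostat's
equilibrium, a mean absolute basis weight near 0.5 (pass
`until_plateau=True` to train all the way there).

A command-line interface mirrors the library
(`sparsedev train-sailnet`, `train-sparsenet`, `gen-images`,
`gen-gabors`, `compare-rf`, `explainable`, `run`, `report`); see
`sparsedev --help`.

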