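# Methods

`sparsedev` studies how the *sparseness* of a neural code evolves while a
sparse-coding network learns receptive fields (RFs) from naturalistic
input, and provides a nonparametric, registration-based way to compare
RF shapes between models (or between a model and experimental data).
The central phenomenon: in models with slow homeostatic regulation, the
mature (equilibrium) code is fixed by the model's parameters, while the
initial condition can be chosen on either side of it — so measured
sparseness can *decrease* or *increase* during learning without any
change to the learning rule, and the mature code is sparse either way.

## Sparseness measures

All measures operate on a non-negative activity matrix `a` (units ×
stimuli; spike counts for the spiking model, |coefficients| for the
generative model) and lie in [0, 1].

* **Activity sparseness** `S_A`: per stimulus, the fraction of units
  whose activity does not rise strictly above a spike-count threshold,
  averaged over stimuli.  Threshold defaults: 0 for single units (any
  spike counts as active), 4 spikes for multi-unit channels.
* **Treves–Rolls (TR) population sparseness** `S_P`: per stimulus,
  `[1 − (Σaᵢ/N)²/(Σaᵢ²/N)] / (1 − 1/N)` across the N units; the
  normalization by `(1 − 1/N)` (Vinje–Gallant) maps a one-hot response
  to exactly 1 and a uniform response to 0.  Averaged over stimuli.
* **TR lifetime sparseness** `S_L`: the identical expression applied per
  unit across M stimuli, averaged over units.

Degenerate input: an all-zero response vector yields 0/0 in the TR
ratio; it is scored 1 (nothing active is maximally sparse), keeping
`S_P` ordinally consistent with `S_A`, and an advisory is logged.  This
case occurs in practice only in near-silent early networks.

**Multi-unit emulation.** Extracellular developmental recordings pool
nearby cells.  We emulate this by partitioning units into random
disjoint groups of 8 and summing counts within groups
(`floor(N/8)` channels; leftovers unused).  The grouping is drawn once
per run and reused at every checkpoint, so trajectories reflect network
change, not grouping resampling.  No spatial topology is modeled — the
model has none.

## Synthetic input

Training input is generated, not downloaded:

1. **Pink images** — Gaussian white noise shaped in the Fourier domain
   by a `1/f` amplitude envelope (the `1/f²` power law of natural
   scenes), zero-mean, unit-variance.
2. **Whitening** — each batch is filtered by
   `envelope(f) / Â(f)`, where `Â(f)` is the batch's own radially
   averaged amplitude spectrum and `envelope(f) = exp(−(f/f₀)⁴)` with
   `f₀ = 0.4 × Nyquist`.  For pink input this reduces to the classic
   ramp-times-roll-off whitening filter; measuring `Â` from the input
   makes the operation idempotent in the mid band and shape-preserving
   for already-white input.  DC is removed; batch variance renormalized.
3. **Patches** — square patches cut at uniform random positions,
   individually mean-subtracted, batch-rescaled to pixel variance 1.
   This unit variance is the scale against which all thresholds and
   learning rates below are stated.

What this input reproduces: the second-order (spectral) statistics of
whitened natural scenes.  What it does not: higher-order structure —
edges, contours, occlusions.  Sparse-coding models driven by such input
still learn localized, oriented, band-pass fields, but the learned
dictionaries are less structured than those trained on real scenes, so
passing tests demonstrate the homeostasis/initialization phenomenology
and the correctness of the machinery, not a quantitative match to
biological RF statistics.

Synthetic **Gabor RF sets** (orientation uniform; spatial frequency
log-uniform in [0.05, 0.25] cycles/px; envelope aspect in [0.5, 2];
optional pixel noise) stand in for experimentally measured simple-cell
RFs in the shape-comparison benchmarks.  They are labeled synthetic
throughout; nothing in the package depends on real recordings.

## Spiking network (SAILnet-style)

N leaky integrate-and-fire units receive constant feed-forward drive
`Q·x` from a patch over a presentation of `n_steps = 50` discrete steps
with update gain `eta = 0.1`:

    u ← (1 − η) u + η (Q·x − W·y_prev),   spike if u > θ, reset u = 0.

Inhibition acts with a one-step delay; simultaneous crossings all spike;
no refractory period.  Spike counts `nᵢ` are integers.  After each
presentation (updates averaged over batches of 100 patches):

    ΔWᵢⱼ = α (nᵢnⱼ − p²)   (i ≠ j; then W clipped ≥ 0, diag W = 0)
    ΔQᵢₘ = β nᵢ (xₘ − nᵢ Qᵢₘ)
    Δθᵢ  = γ (nᵢ − p)

Defaults: `p = 0.05` spikes/image, `α = 0.3`, `β = 0.05`, `γ = 0.3`.
The LIF constants give several membrane time constants per presentation
and counts in a realistic small-integer range.  The learning rates were
chosen for stable convergence of the rate homeostat within the
desk-scale training budget used throughout (100 neurons, 8×8 patches,
2500 batches ≈ 2.5 × 10⁵ presentations); all are configurable.  Rows of
Q are initialized as Gaussian noise rescaled to L1 norm `sqrt(2P/π)`
(unit L2, hence unit drive variance against unit-variance patches) —
this couples the threshold scale to the drive scale, which is what makes
the two threshold regimes below meaningful.

**Initialization regimes.** The *sparse* regime draws thresholds
uniformly from [2, 8] and off-diagonal inhibition from a lognormal
(`Wᵢⱼ = e^{−z}`, `z ~ N(0,1)`; median 1): high thresholds and strong
inhibition make the initial code sparser than the learned equilibrium on
all three multi-unit measures, so sparseness *falls* during training.
The *dense* regime sets all thresholds to 0.5 and uses rectified
Gaussian inhibition (`max(0, z)`; mean ≈ 0.4): the initial code is far
denser than equilibrium, so sparseness *rises*.  Everything except the
initial state is identical, and both runs converge to the same
equilibrium (final multi-unit S_P agrees to well within 0.05 across
regimes at the desk scale; mean rates within 10% of `p`).  The interval
[2, 8] was chosen so that the sparse start clearly satisfies its
defining property (initial sparseness above equilibrium); lower
intervals (e.g. [1, 6]) straddle the equilibrium on `S_A` and blur the
trend.

**Measurement protocol.** At log-spaced checkpoints (including batch 0,
the untouched initial condition) the parameters are frozen and the
network is run on a fixed held-out batch of 1000 patches; single-unit
and multi-unit `S_A`, `S_P`, `S_L` and the mean rate are recorded.
Trend direction compares the mean of the first two checkpoints with the
mean of the last two, per seed, with a majority vote across seeds.

## Generative model (SparseNet-style)

Patches are modeled as `x ≈ A a`.  Inference minimizes

    E(a) = ‖x − A a‖² + λ Σᵤ log(1 + (aᵤ/σ)²)

by L-BFGS from the projection warm start `a₀ = Aᵀx`.  The warm start is
substantive, not incidental: the log penalty is concave in |a|, the
landscape is multimodal, and descent preserves the character of its
start.  Small-norm bases give a near-zero start from which only
strongly-driven units escape the penalty well (a sparse minimum);
large-norm bases give a large distributed start that settles into a
dense minimum.  This is the mechanism by which basis magnitude controls
code sparseness.

Learning is a reconstruction gradient step `A += lr·(x − Aa)aᵀ`
(batch-averaged), and a slow homeostat tracks each unit's coefficient
variance with an EMA (weight 0.1) and rescales its column by
`(var_est/var_target)^κ`, `κ = 0.02` per batch — overactive units grow
their basis norm, which shrinks their future coefficients.

**Operating point.** The homeostat pins `Var(aᵤ) = var_target` at
equilibrium; combined with reconstruction of unit-variance patches this
fixes the equilibrium column norms at
`‖Aᵤ‖₂² ≈ n_pix·v_x·ρ/(M·var_target)` (ρ = reconstructed variance
fraction), and hence the mean absolute basis weight (column L1 norm per
pixel) — the amplitude statistic reported as `mean_l1_norm`, which is
comparable across patch sizes.  For the equilibrium amplitude itself to
be comparable across patch sizes the set point must scale with the
pixel count; the default is

    var_target = 0.48 / n_pix,   σ = sqrt(var_target),
    λ = 0.5,   lr = 0.0075 / var_target.

With these, Gaussian initializations of element variance 1 and 0.01
start at amplitudes ≈ 0.80 and ≈ 0.08 and both converge to ≈ 0.5
(64 units/8×8 and 256 units/16×16 alike): norms fall from the large
start and rise from the small one, while population sparseness moves
in the opposite direction in each case toward the common equilibrium.
The constant 0.48 is the one calibrated quantity, fixed once at the
desk scale; λ sets how sparse the equilibrium code is, and `lr` is slow
enough that the homeostat, not the gradient step, governs the norm
dynamics ("not instantaneous").  Inference tolerance 1e-5 on the
projected gradient with a 300-iteration cap; unconverged solves are
flagged and, in training, used as-is (they are rare after the first few
batches).

Trajectories record `S_P`, `S_L` of |a| on a held-out batch and
`mean_l1_norm` at checkpoints, starting with the untouched initial
state.  Convergence ("plateau") is declared when the amplitude changes
by < 1% over the last 10% of iterations.

## Registration-based RF comparison

Two RFs have the same shape if a similarity transform (translation,
rotation, isotropic scale) maps one onto the other.  The match score is
R², the squared Pearson correlation of the pixel vectors — invariant to
gain, offset and sign of either argument.  Scoring uses all window
pixels (no support masking).

* **Standardization**: RFs larger than the comparison window are cropped
  to window size around their absolute-value peak (first peak in
  row-major order on ties; crops shifted inward at borders).
* **Transform**: rotation and scaling about the window center, then
  translation; cubic-spline interpolation (exact at sample points, so
  the identity is exact); out-of-frame pixels are zero.  Candidates are
  mean-centered before warping so the zero fill matches their surround.
* **Search**: coarse grid over rotation (0–350° in 10° steps) and scale
  (2^[−1,1], 9 log-uniform steps); at each node the translation is
  solved exhaustively by FFT normalized cross-correlation with
  zero-filled shifts; the best node seeds a Nelder–Mead refinement of
  (dx, dy, rotation, log-scale).  The multi-start grid avoids the local
  optima single-start registration suffers on multi-lobed RFs.  A
  non-finite or degenerate fit scores 0 with an identity transform and
  is retained in all statistics.
* **Dictionary fitting**: a target's score against a dictionary is the
  maximum over per-candidate fits (first index on ties); adding
  candidates can only raise it.
* **Explainable variance**: within a target set, each RF is fit by all
  the others (leave-one-out); the mean (± sd) best-fit R² is the ceiling
  that shape repetition plus noise allows.  A model dictionary's mean
  best-fit R² divided by this ceiling is the *fraction of explainable
  variance* it captures.

Known identifiability limits: rotation is recoverable only modulo 180°
(a half-turn flips the carrier sign, which R² ignores), and is poorly
determined for nearly isotropic, low-frequency fields; parameter-
recovery guarantees are therefore stated for non-degenerate Gabors,
while the R² score itself is always well-defined.

## Experiments and reproducibility

`experiments.run_experiment` wires the pipelines: `fig3`/`fig4` (spiking
network, sparse/dense regime), `fig5a`/`fig5b` (generative model,
variance-1/0.01 init), each over ≥ 3 seeds with log-spaced checkpoints;
`run_rf_benchmark` fits a target RF set with a trained dictionary and
reports the fraction of explainable variance.  Regime equivalence is
checked both on final sparseness values and by fitting one regime's
final RFs with the other's dictionary against the within-regime
leave-one-out baseline.  Reports are bit-identical for identical configs
and seeds (all randomness flows from `numpy.random.default_rng` seeds).

Problem sizes used by the test suite and the acceptance script — 100
neurons / 8×8 patches / 2500 batches for the spiking network, 64
units / 8×8 (tests) and 256 units / 16×16 (acceptance script) for the
generative model — are desk-scale choices; the phenomena they probe are
scale-invariant by the constructions above.

## Known limitations

* The LIF integration constants, learning rates, and the generative
  model's operating point are package defaults standing in for values
  the underlying models leave open; conclusions are qualitative trends
  and equilibrium properties, which are insensitive to these choices
  over broad ranges.
* Multi-unit grouping is random, not anatomical; no retinotopy or
  orientation maps.
* The synthetic Gabor sets emulate the diversity of cortical simple-cell
  RFs, not their measured parameter distributions; fraction-of-
  explainable-variance numbers on synthetic targets are internal
  benchmarks, not predictions for physiological data.
* Dale's-law circuits, complex cells, and statistical tests between
  model fits are out of scope.
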